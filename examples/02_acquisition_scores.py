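"""Rank a pool of unlabelled images by the four acquisition functions.

Each score sums a per-pixel information quantity over the image; larger
means the model would learn more from that image's label.  The entropy and
BALD pair use the MC stack alone; the committee divergences compare the
deterministic prediction with the MC mean.
"""

import numpy as np

from abunet import (
    ModelConfig,
    SyntheticSpec,
    build_unet,
    generate_dataset,
    select_top_k,
)
from abunet.acquisition import AcquisitionScore, score_stack
from abunet.inference import mc_predict_batch, predict_batch

images, _ = generate_dataset(SyntheticSpec(n_images=6, seed=7))
net = build_unet(
    ModelConfig(depth=2, base_filters=8, n_classes=5, variant="maxpool_dropout"),
    seed=3,
)

standard = predict_batch(net, images)
mc_mean, stack = mc_predict_batch(net, images, T=10, seed=5)

for fn in ("entropy", "bald", "committee_kl", "committee_jsd"):
    scores = [
        AcquisitionScore(
            j,
            score_stack(fn, standard=standard[j], mc_mean=mc_mean[j],
                        stack=stack[:, j]),
            fn,
        )
        for j in range(len(images))
    ]
    top = select_top_k(scores, 2)
    pretty = ", ".join(f"img{s.image_id}={s.score:,.0f}" for s in scores)
    print(f"{fn:>14}: {pretty}  -> query {top}")
print("Scores are nats summed over 64x64 pixels; the two top-ranked images")
print("would be sent to the oracle for labelling.")
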