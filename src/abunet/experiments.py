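"""Reduced-scale experiment protocols.

These drive the full pipeline — synthetic data, Bayesian U-Net, acquisition,
active-learning loop — at sizes a single CPU handles in minutes, mirroring
the study design of the method: several independently seeded runs per
acquisition function, compared at an equal oracle-label budget by final
MC-validation dice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .active_learning import Oracle, run_active_learning
from .model import ModelConfig
from .synthetic import SyntheticSpec, generate_dataset

__all__ = ["acquisition_efficacy_experiment", "DESK_MODEL"]

#: desk-scale architecture used by the reduced experiments
DESK_MODEL = ModelConfig(depth=2, base_filters=8, n_classes=5,
                         variant="maxpool_dropout", dropout_rate=0.5)


def acquisition_efficacy_experiment(
    acquisitions=("committee_jsd", "random"),
    n_seeds: int = 5,
    pool_size: int = 40,
    val_size: int = 10,
    iterations: int = 5,
    k: int = 2,
    initial_size: int = 2,
    T: int = 10,
    max_epochs: int = 8,
    patience: int = 3,
    model_config: ModelConfig = DESK_MODEL,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare acquisition functions at an equal label budget.

    For each of ``n_seeds`` replicates a fresh 5-class 64x64 synthetic
    dataset is drawn, and every acquisition function runs the identical
    active-learning protocol on it (same seed, so the initial labelled set
    and network initialization are shared — a paired comparison).  Returns a
    tidy frame (acquisition, seed, final_mc_val_dice, n_labeled).
    """
    rows = []
    for r in range(n_seeds):
        run_seed = seed + 1000 * r
        spec = SyntheticSpec(
            n_images=pool_size + val_size, height=64, width=64,
            n_classes=model_config.n_classes, seed=run_seed,
        )
        images, masks = generate_dataset(spec)
        pool = {i: images[i] for i in range(pool_size)}
        val_images, val_masks = images[pool_size:], masks[pool_size:]
        for acq in acquisitions:
            oracle = Oracle({i: masks[i] for i in range(pool_size)})
            state = run_active_learning(
                model_config, pool, oracle, val_images, val_masks,
                acquisition=acq, k=k, iterations=iterations,
                initial_size=initial_size, T=T, seed=run_seed,
                max_epochs=max_epochs, patience=patience,
            )
            rows.append(
                {
                    "acquisition": acq,
                    "seed": run_seed,
                    "final_mc_val_dice": state.history[-1]["val_dice_mean"],
                    "n_labeled": len(state.labeled_ids),
                }
            )
    return pd.DataFrame(rows)
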