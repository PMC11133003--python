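"""Shared fixtures: random masks/models and a small trained risk model."""

from __future__ import annotations

import numpy as np
import pytest

from spinnet import (
    PathwayMask,
    SimConfig,
    SpinConfig,
    SplitSpec,
    TrainParams,
    fit_pipeline,
    generate,
    init_model,
)


def random_mask(rng: np.random.Generator, q: int, r: int) -> PathwayMask:
    """Random binary bi-adjacency with no empty rows/columns."""
    m = (rng.uniform(size=(q, r)) < 0.4).astype(np.int8)
    for i in np.flatnonzero(m.sum(axis=1) == 0):
        m[i, rng.integers(r)] = 1
    for j in np.flatnonzero(m.sum(axis=0) == 0):
        m[rng.integers(q), j] = 1
    return PathwayMask(
        m, [f"g{i}" for i in range(q)], [f"p{j}" for j in range(r)]
    )


def random_model(
    seed: int,
    q: int = 12,
    r: int = 4,
    hidden=(5,),
    task: str = "survival",
):
    """A model with randomized (non-degenerate) weights on a random mask."""
    rng = np.random.default_rng(seed)
    mask = random_mask(rng, q, r)
    model = init_model(mask, SpinConfig(task=task, hidden_sizes=hidden, seed=seed))
    model.W_G_male += rng.standard_normal(model.W_G_male.shape) * mask.matrix
    model.W_G_female += rng.standard_normal(model.W_G_female.shape) * mask.matrix
    model.b_G_male += rng.standard_normal(r) * 0.1
    model.b_G_female += rng.standard_normal(r) * 0.1
    for i, w in enumerate(model.hidden_weights):
        model.hidden_weights[i] = w + rng.standard_normal(w.shape) * 0.3
    model.hidden_biases = [
        b + rng.standard_normal(b.shape) * 0.1 for b in model.hidden_biases
    ]
    model.W_H += rng.standard_normal(model.W_H.shape) * 0.3
    return model


@pytest.fixture(scope="session")
def small_risk_fit():
    """A quickly trained binary-risk model on a small synthetic dataset.

    r = 8 pathways keeps the exact Shapley explainer applicable.
    """
    config = SimConfig(
        n=200, q=60, r=8, genes_per_pathway=6, overlap=1, task="risk",
        effects=[], seed=7,
    )
    from spinnet import EffectSpec

    config.effects = [EffectSpec("PW04", "shared", 3.0)]
    dataset, mask, _ = generate(config)
    result = fit_pipeline(
        dataset,
        mask,
        SpinConfig(task="risk", hidden_sizes=(6,), seed=7),
        SplitSpec(seed=7),
        TrainParams(epochs=150, warmup_epochs=100, patience=40, seed=7),
    )
    return result
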