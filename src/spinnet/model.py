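"""The sex-routed, pathway-masked network.

Architecture (samples are rows throughout):

* gene layer: standardized expression ``G`` (n x q);
* sex-specific pathway layers: ``P = relu(G (W_G^sex * M_G) + b_G^sex)``,
  where ``M_G`` is the binary gene-pathway mask and each sample is routed
  through the weight/bias pair of its sex — the two branches share the mask
  and everything downstream;
* shared hidden layers: ``H_1 = relu(P (W_P * M_P) + b_P)`` and further
  ``H_l = relu(H_{l-1} (W_{l-1} * M_{l-1}) + b_{l-1})``; the hidden masks
  start dense and are sparsified by validation-selected pruning;
* output head: survival task emits a prognostic index ``Z = H W_H`` with no
  bias (the Cox partial likelihood is invariant to an intercept); risk task
  emits ``sigmoid(H W_H + b_H)`` in (0, 1).

All algebra is plain numpy; gradients are computed by the explicit
backward pass in :func:`backward`, which the trainer and the
gradient-x-value importance scores both use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation import PathwayMask
from .data import ExpressionDataset, FEMALE, MALE
from .errors import SchemaError, SpinError

CHECKPOINT_FORMAT = "spinnet-checkpoint-1"

TASKS = ("survival", "risk")


@dataclass
class SpinConfig:
    """Architecture/task configuration fixed before training."""

    task: str = "survival"
    hidden_sizes: tuple[int, ...] = (16,)
    activation: str = "relu"
    seed: int = 0
    #: False collapses the model to a sex-combined ablation: every sample is
    #: routed through one shared pathway layer (the male branch's weights).
    sex_specific: bool = True

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise SchemaError(f"task must be one of {TASKS}, got {self.task!r}")
        self.hidden_sizes = tuple(int(s) for s in self.hidden_sizes)
        if not self.hidden_sizes or any(s <= 0 for s in self.hidden_sizes):
            raise SchemaError("hidden_sizes must be non-empty positive integers")
        if self.activation != "relu":
            raise SchemaError("only the relu activation is supported")


@dataclass
class SpinModel:
    """All weights, biases and masks of the network.

    ``hidden_weights[0]`` is ``W_P`` (pathways -> first hidden layer); its
    mask ``hidden_masks[0]`` is ``M_P``.  Further entries are the
    ``W_l``/``M_l`` pairs between hidden layers.  ``out_bias`` is None for
    the survival task.
    """

    config: SpinConfig
    mask: PathwayMask
    W_G_male: np.ndarray
    W_G_female: np.ndarray
    b_G_male: np.ndarray
    b_G_female: np.ndarray
    hidden_weights: list[np.ndarray]
    hidden_masks: list[np.ndarray]
    hidden_biases: list[np.ndarray]
    W_H: np.ndarray
    out_bias: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def n_genes(self) -> int:
        return self.mask.n_genes

    @property
    def n_pathways(self) -> int:
        return self.mask.n_pathways

    def copy(self) -> "SpinModel":
        return SpinModel(
            config=self.config,
            mask=self.mask,
            W_G_male=self.W_G_male.copy(),
            W_G_female=self.W_G_female.copy(),
            b_G_male=self.b_G_male.copy(),
            b_G_female=self.b_G_female.copy(),
            hidden_weights=[w.copy() for w in self.hidden_weights],
            hidden_masks=[m.copy() for m in self.hidden_masks],
            hidden_biases=[b.copy() for b in self.hidden_biases],
            W_H=self.W_H.copy(),
            out_bias=self.out_bias,
            meta=dict(self.meta),
        )


@dataclass
class ForwardTrace:
    """Activations of one forward pass (all post-ReLU, hence nonnegative)."""

    pathway_activations: np.ndarray  # n x r
    hidden_activations: list[np.ndarray]  # each n x s_l
    output: np.ndarray  # length n


def _masked_fanin_uniform(rng: np.random.Generator, mask: np.ndarray) -> np.ndarray:
    """Uniform init scaled per output node by its unmasked fan-in."""
    fan_in = np.maximum(mask.sum(axis=0), 1)
    bound = np.sqrt(6.0 / fan_in)  # He-style for ReLU
    w = rng.uniform(-1.0, 1.0, size=mask.shape) * bound[None, :]
    return w * mask


def init_model(mask: PathwayMask, config: SpinConfig) -> SpinModel:
    """Build a model with seeded, masked-fan-in-scaled uniform weights."""
    rng = np.random.default_rng(config.seed)
    q, r = mask.n_genes, mask.n_pathways
    m_g = mask.matrix.astype(float)
    sizes = [r, *config.hidden_sizes]
    hidden_weights, hidden_masks, hidden_biases = [], [], []
    w_g_male = _masked_fanin_uniform(rng, m_g)
    w_g_female = _masked_fanin_uniform(rng, m_g)
    for a, b in zip(sizes[:-1], sizes[1:]):
        m = np.ones((a, b))
        hidden_weights.append(_masked_fanin_uniform(rng, m))
        hidden_masks.append(m)
        hidden_biases.append(np.zeros(b))
    s_last = sizes[-1]
    w_h = rng.uniform(-1.0, 1.0, size=s_last) * np.sqrt(6.0 / s_last)
    return SpinModel(
        config=config,
        mask=mask,
        W_G_male=w_g_male,
        W_G_female=w_g_female,
        b_G_male=np.zeros(r),
        b_G_female=np.zeros(r),
        hidden_weights=hidden_weights,
        hidden_masks=hidden_masks,
        hidden_biases=hidden_biases,
        W_H=w_h,
        out_bias=0.0 if config.task == "risk" else None,
    )


def masked_effective_weights(model: SpinModel) -> dict[str, np.ndarray]:
    """Return ``W * M`` for every masked layer (gene layer per sex, hidden)."""
    m_g = model.mask.matrix.astype(float)
    out = {
        "gene_male": model.W_G_male * m_g,
        "gene_female": model.W_G_female * m_g,
    }
    for i, (w, m) in enumerate(zip(model.hidden_weights, model.hidden_masks)):
        out[f"hidden_{i}"] = w * m
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _route(sex: np.ndarray | None, n: int, route_as: str | None) -> np.ndarray:
    """Boolean male-branch indicator per row."""
    if route_as is not None:
        if route_as not in (MALE, FEMALE):
            raise SchemaError(f"route_as must be 'male' or 'female', got {route_as!r}")
        return np.full(n, route_as == MALE)
    if sex is None:
        raise SchemaError("sex labels required when route_as is not given")
    sex = np.asarray(sex, dtype=object)
    if sex.shape != (n,):
        raise SchemaError("one sex label per expression row is required")
    bad = sorted(set(sex) - {MALE, FEMALE})
    if bad:
        raise SchemaError(f"unknown sex labels: {bad}")
    return sex == MALE


def _forward_cache(
    model: SpinModel,
    expression: np.ndarray,
    sex: np.ndarray | None = None,
    route_as: str | None = None,
) -> dict:
    expression = np.atleast_2d(np.asarray(expression, dtype=float))
    n, q = expression.shape
    if q != model.n_genes:
        raise SchemaError(
            f"expression has {q} genes, model expects {model.n_genes}"
        )
    if model.config.sex_specific:
        male = _route(sex, n, route_as)
    else:
        male = np.full(n, True)  # sex-combined ablation: one shared branch
    m_g = model.mask.matrix.astype(float)
    w_m, w_f = model.W_G_male * m_g, model.W_G_female * m_g
    p_pre = np.where(
        male[:, None],
        expression @ w_m + model.b_G_male[None, :],
        expression @ w_f + model.b_G_female[None, :],
    )
    p = np.maximum(p_pre, 0.0)
    hidden_pre, hidden = [], []
    h = p
    for w, m, b in zip(model.hidden_weights, model.hidden_masks, model.hidden_biases):
        z = h @ (w * m) + b[None, :]
        hidden_pre.append(z)
        h = np.maximum(z, 0.0)
        hidden.append(h)
    logit = h @ model.W_H
    if model.config.task == "risk":
        logit = logit + model.out_bias
        output = _sigmoid(logit)
    else:
        output = logit
    return {
        "G": expression,
        "male": male,
        "P_pre": p_pre,
        "P": p,
        "hidden_pre": hidden_pre,
        "hidden": hidden,
        "logit": logit,
        "output": output,
    }


def forward(
    model: SpinModel,
    expression: np.ndarray,
    sex: np.ndarray | None = None,
    route_as: str | None = None,
) -> ForwardTrace:
    """Run the network; each row is routed through its sex's pathway branch.

    `route_as` forces every row through the named branch regardless of its
    sex label — the mechanism for cross-sex counterfactual predictions.  It
    never alters stored parameters.
    """
    c = _forward_cache(model, expression, sex, route_as)
    return ForwardTrace(c["P"], list(c["hidden"]), c["output"])


def backward(model: SpinModel, cache: dict, d_output: np.ndarray) -> dict:
    """Backpropagate ``dL/d output`` through the cached forward pass.

    Returns gradients for every parameter (masked where the layer is masked)
    plus ``d_G`` (n x q input gradient) and ``d_P`` (n x r pathway-node
    gradient); sex-specific gradients accumulate only over rows routed
    through that branch.
    """
    g, male = cache["G"], cache["male"]
    d_logit = np.asarray(d_output, dtype=float)
    if model.config.task == "risk":
        out = cache["output"]
        d_logit = d_logit * out * (1.0 - out)
    h_last = cache["hidden"][-1]
    grads: dict = {
        "W_H": h_last.T @ d_logit,
        "out_bias": float(d_logit.sum()) if model.config.task == "risk" else None,
    }
    d_h = d_logit[:, None] * model.W_H[None, :]
    grads["hidden_weights"] = [None] * len(model.hidden_weights)
    grads["hidden_biases"] = [None] * len(model.hidden_biases)
    for i in reversed(range(len(model.hidden_weights))):
        d_z = d_h * (cache["hidden_pre"][i] > 0)
        below = cache["hidden"][i - 1] if i > 0 else cache["P"]
        grads["hidden_weights"][i] = (below.T @ d_z) * model.hidden_masks[i]
        grads["hidden_biases"][i] = d_z.sum(axis=0)
        d_h = d_z @ (model.hidden_weights[i] * model.hidden_masks[i]).T
    d_p = d_h
    d_p_pre = d_p * (cache["P_pre"] > 0)
    m_g = model.mask.matrix.astype(float)
    d_m, d_f = d_p_pre * male[:, None], d_p_pre * (~male)[:, None]
    grads["W_G_male"] = (g.T @ d_m) * m_g
    grads["W_G_female"] = (g.T @ d_f) * m_g
    grads["b_G_male"] = d_m.sum(axis=0)
    grads["b_G_female"] = d_f.sum(axis=0)
    d_g = np.where(
        male[:, None],
        d_p_pre @ (model.W_G_male * m_g).T,
        d_p_pre @ (model.W_G_female * m_g).T,
    )
    grads["d_G"] = d_g
    grads["d_P"] = d_p
    return grads


def tail_forward(model: SpinModel, pathway_values: np.ndarray) -> np.ndarray:
    """Forward pass of the shared sub-network pathway layer -> output.

    Used by the Shapley explainer, whose players are the pathway nodes.
    """
    h = np.atleast_2d(np.asarray(pathway_values, dtype=float))
    if h.shape[1] != model.n_pathways:
        raise SchemaError(
            f"expected {model.n_pathways} pathway values, got {h.shape[1]}"
        )
    for w, m, b in zip(model.hidden_weights, model.hidden_masks, model.hidden_biases):
        h = np.maximum(h @ (w * m) + b[None, :], 0.0)
    z = h @ model.W_H
    if model.config.task == "risk":
        return _sigmoid(z + model.out_bias)
    return z


def export_pathway_activations(
    model: SpinModel, dataset: ExpressionDataset, path
) -> None:
    """Write the n x r routed pathway-activation table as TSV.

    Columns: sample_id, sex, the outcome column(s), then one column per
    pathway — the plot-ready input for embedding/visualization downstream.
    """
    import pandas as pd

    trace = forward(model, dataset.expression, dataset.sex)
    table = pd.DataFrame(
        trace.pathway_activations,
        columns=model.mask.pathway_ids,
        index=dataset.sample_ids,
    )
    table.index.name = "sample_id"
    table.insert(0, "sex", dataset.sex)
    if dataset.time is not None:
        table.insert(1, "time", dataset.time)
        table.insert(2, "event", dataset.event)
    if dataset.label is not None:
        table.insert(1, "label", dataset.label)
    table.to_csv(path, sep="\t")


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: SpinModel, path, extras: dict | None = None) -> None:
    """Persist all matrices, masks, config and identifiers in one archive."""
    header = {
        "format": CHECKPOINT_FORMAT,
        "task": model.config.task,
        "hidden_sizes": list(model.config.hidden_sizes),
        "activation": model.config.activation,
        "seed": model.config.seed,
        "sex_specific": model.config.sex_specific,
        "gene_ids": model.mask.gene_ids,
        "pathway_ids": model.mask.pathway_ids,
        "n_hidden_layers": len(model.hidden_weights),
        "out_bias": model.out_bias,
        "meta": model.meta,
        "extras": extras or {},
    }
    arrays = {
        "header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        "mask": model.mask.matrix,
        "W_G_male": model.W_G_male,
        "W_G_female": model.W_G_female,
        "b_G_male": model.b_G_male,
        "b_G_female": model.b_G_female,
        "W_H": model.W_H,
    }
    for i, (w, m, b) in enumerate(
        zip(model.hidden_weights, model.hidden_masks, model.hidden_biases)
    ):
        arrays[f"hidden_W_{i}"] = w
        arrays[f"hidden_M_{i}"] = m
        arrays[f"hidden_b_{i}"] = b
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[SpinModel, dict]:
    """Load a model checkpoint; returns ``(model, extras)``."""
    with np.load(path) as npz:
        header = json.loads(bytes(npz["header"]).decode())
        if header.get("format") != CHECKPOINT_FORMAT:
            raise SpinError(
                f"unrecognized checkpoint format {header.get('format')!r}"
            )
        mask = PathwayMask(npz["mask"], header["gene_ids"], header["pathway_ids"])
        config = SpinConfig(
            task=header["task"],
            hidden_sizes=tuple(header["hidden_sizes"]),
            activation=header["activation"],
            seed=header["seed"],
            sex_specific=header.get("sex_specific", True),
        )
        k = header["n_hidden_layers"]
        model = SpinModel(
            config=config,
            mask=mask,
            W_G_male=npz["W_G_male"],
            W_G_female=npz["W_G_female"],
            b_G_male=npz["b_G_male"],
            b_G_female=npz["b_G_female"],
            hidden_weights=[npz[f"hidden_W_{i}"] for i in range(k)],
            hidden_masks=[npz[f"hidden_M_{i}"] for i in range(k)],
            hidden_biases=[npz[f"hidden_b_{i}"] for i in range(k)],
            W_H=npz["W_H"],
            out_bias=header["out_bias"],
            meta=header.get("meta", {}),
        )
    return model, header.get("extras", {})
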