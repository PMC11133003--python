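"""Data splitting, normalization, losses, the training loop and mask pruning.

The pipeline mirrors common survival deep-learning practice: an 80/20
development/test split stratified on sex (and disease status for the binary
task), the development set split 80/20 again into training/validation, and
all partitions standardized per gene with the training-set mean and standard
deviation.  The survival head is fit by minimizing the average negative Cox
log partial likelihood (Breslow ties); the risk head by binary
cross-entropy.  Hidden-layer masks are sparsified by validation-selected
magnitude pruning after convergence, then briefly fine-tuned.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .errors import SchemaError, SpinError
from .model import SpinModel, _forward_cache, backward, masked_effective_weights

logger = logging.getLogger(__name__)

BCE_EPS = 1e-7


# -- splitting -------------------------------------------------------------

@dataclass
class SplitSpec:
    """Stratified 80/20 development/test, then 80/20 train/validation."""

    dev_fraction: float = 0.8
    train_fraction_of_dev: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.dev_fraction, self.train_fraction_of_dev):
            if not 0.0 < f < 1.0:
                raise SpinError(f"split fractions must be in (0,1), got {f}")


def _strata(dataset: ExpressionDataset) -> np.ndarray:
    keys = dataset.sex.astype(str)
    if dataset.label is not None:
        # binary task stratifies jointly on sex and disease status
        keys = np.char.add(np.char.add(keys, "|"), dataset.label.astype(str))
    return keys


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    dataset: ExpressionDataset, spec: SplitSpec
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Split into (train, validation, test); deterministic given `spec.seed`.

    Within each stratum the partition sizes match the spec fractions to
    within rounding; every stratum must be large enough to appear in all
    three partitions.
    """
    rng = np.random.default_rng(spec.seed)
    keys = _strata(dataset)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for key in sorted(set(keys)):
        members = np.flatnonzero(keys == key)
        m = len(members)
        n_test = _round_half_up(m * (1.0 - spec.dev_fraction))
        n_dev = m - n_test
        n_val = _round_half_up(n_dev * (1.0 - spec.train_fraction_of_dev))
        n_train = n_dev - n_val
        if min(n_train, n_val, n_test) < 1:
            raise SpinError(
                f"stratum {key!r} with {m} samples is too small to appear "
                "in train, validation and test partitions"
            )
        perm = rng.permutation(members)
        test_idx.extend(perm[:n_test])
        val_idx.extend(perm[n_test : n_test + n_val])
        train_idx.extend(perm[n_test + n_val :])
    return (
        dataset.subset(np.sort(train_idx)),
        dataset.subset(np.sort(val_idx)),
        dataset.subset(np.sort(test_idx)),
    )


# -- normalization ---------------------------------------------------------

@dataclass
class Normalizer:
    """Per-gene standardization with training-set statistics.

    Uses the population standard deviation; constant training genes are
    dropped with a logged warning.  Transforming an already-normalized
    dataset is rejected so training statistics cannot be applied twice.
    """

    gene_ids: list[str] | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, train: ExpressionDataset) -> "Normalizer":
        mean = train.expression.mean(axis=0)
        sd = train.expression.std(axis=0)  # population formula (ddof=0)
        keep = sd > 0
        if not np.all(keep):
            dropped = [g for g, k in zip(train.gene_ids, keep) if not k]
            msg = f"dropping {len(dropped)} constant gene(s): {dropped[:5]}"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        self.gene_ids = [g for g, k in zip(train.gene_ids, keep) if k]
        self.mean = mean[keep]
        self.sd = sd[keep]
        return self

    def transform(self, dataset: ExpressionDataset) -> ExpressionDataset:
        if not self.fitted:
            raise SpinError("normalizer has not been fitted")
        if dataset.normalized:
            raise SpinError("dataset is already normalized; refusing to rescale")
        aligned = dataset.select_genes(self.gene_ids)
        out = dataclasses.replace(
            aligned, expression=(aligned.expression - self.mean) / self.sd
        )
        out.normalized = True
        return out


def fit_normalizer(train: ExpressionDataset) -> Normalizer:
    return Normalizer().fit(train)


def apply_normalizer(
    normalizer: Normalizer, dataset: ExpressionDataset
) -> ExpressionDataset:
    return normalizer.transform(dataset)


# -- losses ----------------------------------------------------------------

def _cox_parts(z, time, event):
    z = np.asarray(z, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=int).ravel()
    if not (z.shape == time.shape == event.shape):
        raise SpinError("prognostic index, time and event must have equal length")
    d = int(event.sum())
    if d == 0:
        raise SpinError("Cox partial likelihood needs at least one event")
    zmax = z.max()
    # log S(t) = log sum_{j: t_j >= t} exp(z_j), per distinct time
    order = np.argsort(-time, kind="stable")
    cum = np.logaddexp.accumulate(z[order] - zmax)
    t_sorted = time[order]
    # last index of each tie block (risk set is inclusive of ties)
    block_end = np.searchsorted(-t_sorted, -t_sorted, side="right") - 1
    log_s_sorted = cum[block_end] + zmax  # per sorted position, log S(t_sorted)
    log_s = np.empty_like(z)
    log_s[order] = log_s_sorted
    return z, time, event, d, log_s


def cox_loss(z, time, event) -> float:
    """Average negative Cox log partial likelihood (Breslow ties).

    ``-(1/d) * sum_{i: event} [ z_i - log sum_{j: t_j >= t_i} exp(z_j) ]``
    with ``d`` the number of events; tied event times share a risk set.
    """
    z, time, event, d, log_s = _cox_parts(z, time, event)
    ev = event == 1
    return float(-(z[ev] - log_s[ev]).sum() / d)


def cox_loss_grad(z, time, event) -> np.ndarray:
    """Analytic gradient of :func:`cox_loss` with respect to ``z``."""
    z, time, event, d, log_s = _cox_parts(z, time, event)
    ev = event == 1
    # A_k = sum over events i with t_i <= t_k of exp(z_k - log S_i)
    et = time[ev]
    order = np.argsort(et, kind="stable")
    et_sorted = et[order]
    inv_s_sorted = np.exp(-(log_s[ev][order] - z.max()))
    prefix = np.concatenate([[0.0], np.cumsum(inv_s_sorted)])
    pos = np.searchsorted(et_sorted, time, side="right")
    a = np.exp(z - z.max()) * prefix[pos]
    return -(ev.astype(float) - a) / d


def bce_loss(risk, label, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy; risks at 0/1 are clamped at `eps`."""
    risk = np.asarray(risk, dtype=float).ravel()
    label = np.asarray(label, dtype=float).ravel()
    if risk.shape != label.shape:
        raise SpinError("risk and label must have equal length")
    if np.any((risk <= 0) | (risk >= 1)):
        logger.warning("risk scores at the (0,1) boundary clamped at eps=%g", eps)
    r = np.clip(risk, eps, 1.0 - eps)
    return float(-(label * np.log(r) + (1 - label) * np.log(1 - r)).mean())


def bce_grad(risk, label, eps: float = BCE_EPS) -> np.ndarray:
    """Gradient of :func:`bce_loss` with respect to the risk scores."""
    risk = np.asarray(risk, dtype=float).ravel()
    label = np.asarray(label, dtype=float).ravel()
    r = np.clip(risk, eps, 1.0 - eps)
    return (r - label) / (r * (1 - r)) / len(r)


def dataset_loss(model: SpinModel, dataset: ExpressionDataset) -> float:
    """Task loss of `model` on `dataset` (no penalty term)."""
    cache = _forward_cache(model, dataset.expression, dataset.sex)
    if model.config.task == "survival":
        return cox_loss(cache["output"], dataset.time, dataset.event)
    return bce_loss(cache["output"], dataset.label)


# -- training --------------------------------------------------------------

@dataclass
class TrainParams:
    """Optimization hyper-parameters (adaptive gradient, early stopping).

    Two initialization/training strategies are run and the parameters with
    the lower validation loss are retained:

    * ``standard`` — seeded masked-uniform initialization, all parameters
      trained jointly with weight penalty `l2`;
    * ``warm_start`` — both sex branches start as literal pathway
      enrichment scores (equal masked weights, linear-regime bias) and are
      frozen while the shared tail is trained for `warmup_epochs`, after
      which all parameters train jointly with `warm_start_l2`.

    The warm start excels when the pooled pathway-outcome map carries the
    signal; the standard run when the branches must diverge from the start
    (e.g. opposite-direction effects, which the pooled warm-up cannot see).
    """

    learning_rate: float = 1e-2
    epochs: int = 500
    l2: float = 5e-2
    patience: int = 80
    seed: int = 0
    strategies: tuple[str, ...] = ("standard", "warm_start")
    warmup_epochs: int = 300
    warm_start_l2: float = 5e-2
    sparsity_grid: tuple[float, ...] | None = None
    finetune_epochs: int = 60


@dataclass
class TrainReport:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    chosen_strategy: str = ""
    strategy_val_losses: dict[str, float] = field(default_factory=dict)
    chosen_sparsity: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_PARAM_NAMES = ("W_G_male", "W_G_female", "b_G_male", "b_G_female", "W_H")


def _params(model: SpinModel) -> list[tuple[str, np.ndarray]]:
    out = [(name, getattr(model, name)) for name in _PARAM_NAMES]
    for i, w in enumerate(model.hidden_weights):
        out.append((f"hidden_weights[{i}]", w))
    for i, b in enumerate(model.hidden_biases):
        out.append((f"hidden_biases[{i}]", b))
    return out


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_and_doutput(model, cache, dataset):
    if model.config.task == "survival":
        loss = cox_loss(cache["output"], dataset.time, dataset.event)
        d_out = cox_loss_grad(cache["output"], dataset.time, dataset.event)
    else:
        loss = bce_loss(cache["output"], dataset.label)
        d_out = bce_grad(cache["output"], dataset.label)
    return loss, d_out


_GENE_PARAMS = ("W_G_male", "W_G_female", "b_G_male", "b_G_female")


def _train_loop(
    model,
    train_ds,
    val_ds,
    params: TrainParams,
    epochs,
    report,
    l2: float,
    freeze_gene: bool = False,
):
    """Adam on the task loss + L2 on effective weights; returns best-val model.

    Updates ``report`` in place and tracks the globally best validation
    loss, so successive phases/strategies share one selection criterion.
    With `freeze_gene` the sex-specific gene-layer parameters are excluded
    from the update (warm-up phase).
    """
    named = dict(_params(model))
    if freeze_gene:
        for key in _GENE_PARAMS:
            named.pop(key)
    opt = _Adam(
        {k: v.shape for k, v in named.items()},
        lr=params.learning_rate,
    )
    if model.config.task == "risk":
        out_bias = np.array([model.out_bias])
        named["out_bias"] = out_bias
        opt.m["out_bias"] = np.zeros(1)
        opt.v["out_bias"] = np.zeros(1)
    best = model.copy()
    best_loss = dataset_loss(model, val_ds)
    if best_loss < report.best_val_loss:
        report.best_val_loss = float(best_loss)
    since_best = 0
    for _ in range(epochs):
        cache = _forward_cache(model, train_ds.expression, train_ds.sex)
        loss, d_out = _loss_and_doutput(model, cache, train_ds)
        if not np.isfinite(loss):
            raise SpinError(
                f"non-finite training loss ({loss}) at epoch "
                f"{len(report.train_losses)}; try a lower learning rate"
            )
        grads = backward(model, cache, d_out)
        flat = {"W_H": grads["W_H"]}
        if not freeze_gene:
            for key in _GENE_PARAMS:
                flat[key] = grads[key]
        for i in range(len(model.hidden_weights)):
            flat[f"hidden_weights[{i}]"] = grads["hidden_weights"][i]
            flat[f"hidden_biases[{i}]"] = grads["hidden_biases"][i]
        if model.config.task == "risk":
            flat["out_bias"] = np.array([grads["out_bias"]])
        if l2 > 0:
            eff = masked_effective_weights(model)
            if not freeze_gene:
                flat["W_G_male"] = flat["W_G_male"] + 2 * l2 * eff["gene_male"]
                flat["W_G_female"] = (
                    flat["W_G_female"] + 2 * l2 * eff["gene_female"]
                )
            for i in range(len(model.hidden_weights)):
                key = f"hidden_weights[{i}]"
                flat[key] = flat[key] + 2 * l2 * eff[f"hidden_{i}"]
            flat["W_H"] = flat["W_H"] + 2 * l2 * model.W_H
        opt.step(named, flat)
        if model.config.task == "risk":
            model.out_bias = float(named["out_bias"][0])
        val_loss = dataset_loss(model, val_ds)
        report.train_losses.append(float(loss))
        report.val_losses.append(float(val_loss))
        if val_loss < best_loss:
            best_loss = val_loss
            best = model.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best > params.patience:
                break
        if val_loss < report.best_val_loss:
            report.best_val_loss = float(val_loss)
            report.best_epoch = len(report.val_losses) - 1
    return best, float(best_loss)


def enrichment_start(model):
    """Re-initialize both sex branches as pathway enrichment scores.

    Every member gene gets the same weight (scaled so the node has roughly
    unit variance under standardized expression) and the bias is set well
    inside the ReLU's linear regime, so each pathway node initially *is* a
    shifted, scaled pathway mean-expression score.
    """
    model = model.copy()
    m_g = model.mask.matrix.astype(float)
    w0 = m_g / np.sqrt(m_g.sum(axis=0))[None, :]
    model.W_G_male = w0.copy()
    model.W_G_female = w0.copy()
    model.b_G_male = np.full(model.n_pathways, 2.0)
    model.b_G_female = np.full(model.n_pathways, 2.0)
    return model


def _run_strategy(strategy, model, train_ds, val_ds, params, report):
    if strategy == "standard":
        return _train_loop(
            model.copy(), train_ds, val_ds, params, params.epochs, report,
            l2=params.l2,
        )
    if strategy == "warm_start":
        warm = enrichment_start(model)
        if params.warmup_epochs > 0:
            warm, _ = _train_loop(
                warm, train_ds, val_ds, params, params.warmup_epochs, report,
                l2=params.warm_start_l2, freeze_gene=True,
            )
        return _train_loop(
            warm, train_ds, val_ds, params, params.epochs, report,
            l2=params.warm_start_l2,
        )
    raise SpinError(f"unknown training strategy {strategy!r}")


def train(
    model: SpinModel,
    train_ds: ExpressionDataset,
    val_ds: ExpressionDataset,
    params: TrainParams | None = None,
) -> tuple[SpinModel, TrainReport]:
    """Fit the model by full-batch adaptive gradient descent.

    Each strategy in ``params.strategies`` is run from the given model's
    initialization and the parameters with the best validation loss across
    strategies are retained (ties keep the earlier strategy).  When
    ``params.sparsity_grid`` is set, hidden masks are then sparsified by
    validation-selected magnitude pruning and the model is briefly
    fine-tuned.  Deterministic given the model's init seed.
    """
    params = params or TrainParams()
    if not params.strategies:
        raise SpinError("at least one training strategy is required")
    if train_ds.task != model.config.task:
        raise SchemaError(
            f"model task {model.config.task!r} does not match dataset outcome "
            f"{train_ds.task!r}"
        )
    report = TrainReport(seed=params.seed)
    best, best_loss, best_l2 = None, np.inf, params.l2
    for strategy in params.strategies:
        candidate, cand_loss = _run_strategy(
            strategy, model, train_ds, val_ds, params, report
        )
        report.strategy_val_losses[strategy] = cand_loss
        if cand_loss < best_loss:
            best, best_loss = candidate, cand_loss
            report.chosen_strategy = strategy
            best_l2 = params.l2 if strategy == "standard" else params.warm_start_l2
    if params.sparsity_grid is not None:
        best, chosen = sparse_code_masks(best, val_ds, params.sparsity_grid)
        report.chosen_sparsity = chosen
        if params.finetune_epochs > 0:
            finetune = dataclasses.replace(
                params, strategies=("standard",), l2=best_l2,
                epochs=params.finetune_epochs, sparsity_grid=None,
            )
            refined, refined_loss = _train_loop(
                best.copy(), train_ds, val_ds, finetune,
                params.finetune_epochs, report, l2=best_l2,
            )
            pruned_loss = dataset_loss(best, val_ds)
            if refined_loss < pruned_loss:
                best = refined
    return best, report


# -- sparse coding of hidden masks ----------------------------------------

def sparse_code_masks(
    model: SpinModel,
    val_ds: ExpressionDataset,
    sparsity_grid,
) -> tuple[SpinModel, dict[str, float]]:
    """Sparsify hidden-layer masks by validation-selected magnitude pruning.

    For each hidden layer (the gene-pathway mask is fixed by annotation) and
    each fraction ``rho`` in the grid, the ``floor(rho * #entries)``
    smallest-magnitude effective weights are masked out (ties broken by
    row-major index, so pruned sets are nested across rho); the ``rho``
    minimizing the validation loss is kept, ties resolved toward the larger
    ``rho``.  Masks remain shared across both sex branches (they live after
    the pathway layer).  Layers are processed in order, each conditioned on
    the previous choices.
    """
    grid = sorted(float(r) for r in np.atleast_1d(np.asarray(sparsity_grid, float)))
    if not grid:
        raise SpinError("sparsity grid must be non-empty")
    if grid[0] < 0 or grid[-1] > 1:
        raise SpinError("sparsity fractions must lie in [0, 1]")
    model = model.copy()
    chosen: dict[str, float] = {}
    for layer in range(len(model.hidden_weights)):
        eff = model.hidden_weights[layer] * model.hidden_masks[layer]
        order = np.argsort(np.abs(eff).ravel(), kind="stable")
        best_rho, best_loss = None, np.inf
        best_mask = None
        for rho in grid:
            k = int(np.floor(rho * eff.size))
            cand = np.ones(eff.size)
            cand[order[:k]] = 0.0
            cand = cand.reshape(eff.shape)
            saved = model.hidden_masks[layer]
            model.hidden_masks[layer] = cand
            loss = dataset_loss(model, val_ds)
            model.hidden_masks[layer] = saved
            if loss <= best_loss:  # ties go to the larger (sparser) rho
                best_loss, best_rho, best_mask = loss, rho, cand
        model.hidden_masks[layer] = best_mask
        chosen[f"hidden_{layer}"] = best_rho
    return model, chosen
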