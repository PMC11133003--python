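"""Synthetic expression datasets with planted sex-dependent pathway effects.

The generator emulates the statistical structure the network assumes:
standard-normal expression per gene, a block of pathways over the gene
universe (adjacent pathways overlap slightly so the mask is not orthogonal),
and an outcome driven by a linear predictor over *pathway scores* (the mean
expression of a pathway's member genes).  Planted effects may be sex-shared,
male-only, female-only or of opposite direction between sexes — the last is
the net-canceling configuration that sex-pooled analyses miss.

Survival times are exponential with hazard proportional to
``exp(linear predictor)``; censoring is independent uniform with its upper
bound tuned numerically to the target censoring rate.  Binary labels are
Bernoulli draws from ``sigmoid(linear predictor)`` with optional label-flip
noise.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import GeneSet, GeneSetCollection, PathwayMask, write_gmt
from .data import ExpressionDataset, FEMALE, MALE, write_dataset
from .errors import SpinError
from .model import _sigmoid

EFFECT_CLASSES = ("shared", "male_only", "female_only", "opposite")

#: Default planted effect size for recovery scenarios.  A pathway score is a
#: mean of 15 standard-normal genes (sd ~0.26), so beta=3 corresponds to a
#: linear-predictor sd of ~0.8 per planted pathway — a strong but realistic
#: single-pathway signal that within-sex tests can resolve at n ~ 600.
DEFAULT_BETA = 3.0


@dataclass
class EffectSpec:
    """A planted pathway effect on the outcome.

    ``beta`` is the common magnitude; per-sex signed coefficients follow
    from the class (``opposite`` means +beta in males, -beta in females).
    """

    pathway_id: str
    effect_class: str
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise SpinError(
                f"effect class must be one of {EFFECT_CLASSES}, "
                f"got {self.effect_class!r}"
            )

    @property
    def beta_male(self) -> float:
        return 0.0 if self.effect_class == "female_only" else self.beta

    @property
    def beta_female(self) -> float:
        if self.effect_class == "male_only":
            return 0.0
        if self.effect_class == "opposite":
            return -self.beta
        return self.beta


@dataclass
class SimConfig:
    """Generator settings; defaults describe the desk-scale study condition."""

    n: int = 600
    q: int = 500
    r: int = 30
    genes_per_pathway: int = 15
    overlap: int = 2  # genes shared between adjacent pathways (~10%)
    sex_ratio: float = 0.5  # fraction male
    task: str = "survival"
    effects: list[EffectSpec] = field(default_factory=list)
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.1
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("survival", "risk"):
            raise SpinError(f"unknown task {self.task!r}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise SpinError("censoring rate must be in [0, 1)")
        if not 0.0 < self.sex_ratio < 1.0:
            raise SpinError("sex ratio must be in (0, 1)")
        if len(self.effects) > self.r:
            raise SpinError(
                f"{len(self.effects)} planted pathways exceed r={self.r}"
            )
        step = self.genes_per_pathway - self.overlap
        if step <= 0:
            raise SpinError("overlap must be smaller than genes_per_pathway")
        needed = step * (self.r - 1) + self.genes_per_pathway
        if needed > self.q:
            raise SpinError(
                f"q={self.q} genes cannot host r={self.r} pathways of "
                f"{self.genes_per_pathway} genes with overlap {self.overlap} "
                f"(need {needed})"
            )


def _gene_ids(q: int) -> list[str]:
    width = max(4, len(str(q)))
    return [f"G{i:0{width}d}" for i in range(1, q + 1)]


def _pathway_ids(r: int) -> list[str]:
    return [f"PW{j:02d}" for j in range(1, r + 1)]


def make_collection(config: SimConfig) -> GeneSetCollection:
    """Gene sets over the synthetic gene universe (adjacent sets overlap)."""
    genes = _gene_ids(config.q)
    step = config.genes_per_pathway - config.overlap
    sets = []
    for j, pid in enumerate(_pathway_ids(config.r)):
        start = j * step
        sets.append(
            GeneSet(pid, f"synthetic pathway {j + 1}",
                    genes[start : start + config.genes_per_pathway])
        )
    return GeneSetCollection(sets)


def _mask_from_collection(config: SimConfig) -> PathwayMask:
    collection = make_collection(config)
    genes = _gene_ids(config.q)
    order = {g: i for i, g in enumerate(genes)}
    annotated = sorted({g for s in collection.sets for g in s.genes},
                       key=order.__getitem__)
    matrix = np.zeros((len(annotated), len(collection.sets)), dtype=np.int8)
    row = {g: i for i, g in enumerate(annotated)}
    for j, s in enumerate(collection.sets):
        for g in s.genes:
            matrix[row[g], j] = 1
    return PathwayMask(matrix, annotated, [s.pathway_id for s in collection.sets])


def pathway_scores(expression: np.ndarray, gene_ids, mask: PathwayMask) -> np.ndarray:
    """n x r matrix of pathway scores: mean expression over member genes."""
    col = {g: i for i, g in enumerate(gene_ids)}
    cols = np.array([col[g] for g in mask.gene_ids])
    sub = expression[:, cols]
    m = mask.matrix.astype(float)
    return sub @ (m / m.sum(axis=0))


def linear_predictor(
    scores: np.ndarray, sex: np.ndarray, pathway_ids, effects
) -> np.ndarray:
    """Per-sample sum of sex-signed planted effects times pathway scores."""
    eta = np.zeros(scores.shape[0])
    male = np.asarray(sex, dtype=object) == MALE
    pidx = list(pathway_ids)
    for eff in effects:
        j = pidx.index(eff.pathway_id)
        beta = np.where(male, eff.beta_male, eff.beta_female)
        eta += beta * scores[:, j]
    return eta


def _tune_censor_bound(times: np.ndarray, target: float) -> float:
    """Upper bound c of U(0, c) censoring hitting the target censor rate.

    Censoring probability given the drawn times is
    ``mean_i P(C < t_i) = mean_i min(t_i / c, 1)``, monotone decreasing in
    ``c``; solved by bisection on a log grid.
    """
    if target <= 0:
        return float(np.inf)

    def rate(c):
        return float(np.mean(np.minimum(times / c, 1.0)))

    lo, hi = times.min() * 1e-6, times.max() * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if rate(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate(
    config: SimConfig,
    censor_bound: float | None = None,
) -> tuple[ExpressionDataset, PathwayMask, list[EffectSpec]]:
    """Draw a dataset with the configured planted effects.

    `censor_bound` overrides the numerically tuned uniform-censoring upper
    bound (used to keep matched dataset pairs identically censored).
    """
    mask = _mask_from_collection(config)
    missing = [e.pathway_id for e in config.effects
               if e.pathway_id not in mask.pathway_ids]
    if missing:
        raise SpinError(f"planted pathways not in the collection: {missing}")
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.q)
    expression = rng.standard_normal((config.n, config.q))
    n_male = int(round(config.n * config.sex_ratio))
    sex = np.array([MALE] * n_male + [FEMALE] * (config.n - n_male), dtype=object)
    rng.shuffle(sex)
    scores = pathway_scores(expression, genes, mask)
    eta = linear_predictor(scores, sex, mask.pathway_ids, config.effects)
    sample_ids = [f"S{i:04d}" for i in range(1, config.n + 1)]
    outcome_u = rng.uniform(size=config.n)  # one outcome draw per sample
    if config.task == "survival":
        hazard = config.baseline_hazard * np.exp(eta)
        times = -np.log(outcome_u) / hazard
        c = censor_bound if censor_bound is not None else _tune_censor_bound(
            times, config.censoring_rate
        )
        censor = rng.uniform(0.0, 1.0, size=config.n) * c
        event = (times <= censor).astype(int)
        observed = np.minimum(times, censor)
        dataset = ExpressionDataset(
            expression, sex, sample_ids, genes, time=observed, event=event
        )
    else:
        labels = (outcome_u < _sigmoid(eta)).astype(int)
        if config.label_noise > 0:
            flip = rng.uniform(size=config.n) < config.label_noise
            labels = np.where(flip, 1 - labels, labels)
        dataset = ExpressionDataset(
            expression, sex, sample_ids, genes, label=labels
        )
    return dataset, mask, list(config.effects)


def _latent_times(config: SimConfig) -> np.ndarray:
    """Replay the generator's uncensored survival times for `config`."""
    mask = _mask_from_collection(config)
    rng = np.random.default_rng(config.seed)
    expression = rng.standard_normal((config.n, config.q))
    n_male = int(round(config.n * config.sex_ratio))
    sex = np.array([MALE] * n_male + [FEMALE] * (config.n - n_male), dtype=object)
    rng.shuffle(sex)
    scores = pathway_scores(expression, _gene_ids(config.q), mask)
    eta = linear_predictor(scores, sex, mask.pathway_ids, config.effects)
    u = rng.uniform(size=config.n)
    return -np.log(u) / (config.baseline_hazard * np.exp(eta))


def opposite_effect_scenario(
    n: int = 600,
    seed: int = 0,
    task: str = "survival",
    beta: float = 1.0,
    **config_kwargs,
) -> tuple[
    tuple[ExpressionDataset, PathwayMask, list[EffectSpec]],
    tuple[ExpressionDataset, PathwayMask, list[EffectSpec]],
]:
    """Matched dataset pair demonstrating the net-canceling effect.

    Returns ``(opposite, shared)``: the first plants a single pathway with
    +beta in males and -beta in females, the second the same pathway with
    +beta in both sexes.  Expression, sex labels, random draws and (for the
    survival task) the censoring bound are identical, so the two datasets
    differ only in how the flipped female coefficient enters the female
    outcomes.
    """
    base = SimConfig(n=n, seed=seed, task=task, **config_kwargs)
    pid = _pathway_ids(base.r)[base.r // 2]
    opp_cfg = replace(base, effects=[EffectSpec(pid, "opposite", beta)])
    shr_cfg = replace(base, effects=[EffectSpec(pid, "shared", beta)])
    bound = None
    if task == "survival":
        bound = _tune_censor_bound(_latent_times(opp_cfg), base.censoring_rate)
    opposite = generate(opp_cfg, censor_bound=bound)
    shared = generate(shr_cfg, censor_bound=bound)
    return opposite, shared


def interpretation_recovery_scenario(
    seed: int = 0,
    n: int = 600,
    beta: float = DEFAULT_BETA,
    **config_kwargs,
) -> tuple[ExpressionDataset, PathwayMask, list[EffectSpec]]:
    """Binary-outcome dataset with one male-only, one female-only and one
    shared planted pathway among otherwise-null pathways."""
    cfg = SimConfig(n=n, seed=seed, task="risk", **config_kwargs)
    pids = _pathway_ids(cfg.r)
    effects = [
        EffectSpec(pids[2], "male_only", beta),
        EffectSpec(pids[10], "female_only", beta),
        EffectSpec(pids[20], "shared", beta),
    ]
    return generate(replace(cfg, effects=effects))


def write_fixture(dataset: ExpressionDataset, mask: PathwayMask, outdir) -> dict:
    """Write expression TSV, clinical TSV and GMT; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "gmt": outdir / "pathways.gmt",
    }
    write_dataset(dataset, paths["expression"], paths["clinical"])
    sets = [
        GeneSet(pid, f"synthetic pathway {j + 1}", mask.members(pid))
        for j, pid in enumerate(mask.pathway_ids)
    ]
    write_gmt(GeneSetCollection(sets), paths["gmt"])
    return {k: str(v) for k, v in paths.items()}
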