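"""Global and local interpretation of a trained network.

Global: per-feature, per-sex importance scores (mean |gradient x node
value| over that sex's samples), a two-sample rank-sum test of node values
between outcome groups within each sex, Benjamini-Hochberg FDR within each
(level, sex) family, and the shared/male-specific/female-specific call:
significant in both sexes -> shared, in exactly one -> that sex's specific
label, in neither -> none.  A feature whose importance is exactly zero in a
sex (e.g. a pathway disconnected by masks) is never called significant
there — a node with no influence on the prediction is not part of the
predictive mechanism, whatever its marginal association.

Local: Shapley-value attributions of a single prediction over the pathway
nodes, computed on the shared sub-network pathway layer -> output against a
background of reference pathway activations.  Exact subset enumeration is
used for small pathway counts, antithetic permutation sampling otherwise;
either way attributions satisfy ``base + sum(phi) = prediction``.  Routing
a sample through the opposite sex's pathway branch before explaining gives
the cross-sex counterfactual attribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset, FEMALE, MALE
from .errors import SchemaError, SpinError
from .model import SpinModel, _forward_cache, backward, forward, tail_forward

EXACT_MAX_PATHWAYS = 15
DEFAULT_ALPHA = 1e-5
BACKGROUND_CAP = 200


# -- global interpretation -------------------------------------------------

@dataclass
class ImportanceReport:
    """Per-feature, per-sex importance with significance calls.

    ``table`` is indexed by feature identifier with columns
    ``importance_{male,female}``, ``p_{male,female}``, ``q_{male,female}``,
    ``significant_{male,female}`` and ``feature_class``.
    """

    table: pd.DataFrame
    level: str
    alpha: float

    def counts(self) -> dict[str, int]:
        return self.table["feature_class"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t")


def _outcome_groups(dataset: ExpressionDataset, output: np.ndarray, rows):
    """High/low outcome group indicator within a sex's rows (or None).

    Binary task: cases vs controls.  Survival: top vs bottom tertile of the
    predicted prognostic index (middle tertile unused).
    """
    if dataset.label is not None:
        hi = dataset.label[rows] == 1
        lo = ~hi
    else:
        pi = output[rows]
        lo_cut, hi_cut = np.quantile(pi, [1 / 3, 2 / 3])
        hi = pi >= hi_cut
        lo = pi <= lo_cut
    return hi, lo


def _rank_p(values: np.ndarray, hi: np.ndarray, lo: np.ndarray) -> float:
    a, b = values[hi], values[lo]
    if np.all(values == values[0]):
        return 1.0  # degenerate: identical node values carry no signal
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def global_importance(
    model: SpinModel,
    dataset: ExpressionDataset,
    level: str = "pathway",
    alpha: float = DEFAULT_ALPHA,
) -> ImportanceReport:
    """Sex-specific importance scores and shared/specific classification.

    Importance of a feature in a sex is the mean over that sex's samples of
    |d output / d node x node value| at the feature's layer (genes: input
    layer; pathways: the routed pathway layer).  Raw p-values come from a
    two-sided rank-sum test of node values between outcome groups within
    the sex; FDR adjustment is Benjamini-Hochberg within each (level, sex)
    family, and the class follows the both/one-sex rule at adjusted
    ``p < alpha``.
    """
    if level not in ("gene", "pathway"):
        raise SpinError(f"level must be 'gene' or 'pathway', got {level!r}")
    cache = _forward_cache(model, dataset.expression, dataset.sex)
    grads = backward(model, cache, np.ones(dataset.n_samples))
    if level == "gene":
        values = cache["G"]
        saliency = np.abs(grads["d_G"] * values)
        features = model.mask.gene_ids
    else:
        values = cache["P"]
        saliency = np.abs(grads["d_P"] * values)
        features = model.mask.pathway_ids
    table = pd.DataFrame(index=pd.Index(features, name="feature"))
    for sex in (MALE, FEMALE):
        rows = dataset.sex == sex
        if rows.sum() == 0:
            raise SpinError(f"no {sex} samples present")
        hi, lo = _outcome_groups(dataset, cache["output"], rows)
        if hi.sum() < 2 or lo.sum() < 2:
            raise SpinError(
                f"{sex} samples have <2 members in an outcome group"
            )
        vals = values[rows]
        imp = saliency[rows].mean(axis=0)
        pvals = np.array([_rank_p(vals[:, j], hi, lo) for j in range(vals.shape[1])])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        table[f"importance_{sex}"] = imp
        table[f"p_{sex}"] = pvals
        table[f"q_{sex}"] = qvals
        table[f"significant_{sex}"] = (qvals < alpha) & (imp > 0)
    sig_m = table["significant_male"].to_numpy()
    sig_f = table["significant_female"].to_numpy()
    table["feature_class"] = np.select(
        [sig_m & sig_f, sig_m, sig_f],
        ["shared", "male_specific", "female_specific"],
        default="none",
    )
    return ImportanceReport(table=table, level=level, alpha=alpha)


# -- local interpretation --------------------------------------------------

@dataclass
class LocalExplanation:
    """Shapley attribution of one prediction over the pathway nodes.

    ``base_value + phi.sum()`` equals ``prediction`` (up to float error).
    ``enriched[j]`` is True when the sample's pathway activation lies above
    the background mean (the waterfall up-arrow).
    """

    sample_id: str
    routed_sex: str
    pathway_ids: list[str]
    phi: np.ndarray
    base_value: float
    prediction: float
    pathway_values: np.ndarray
    enriched: np.ndarray

    def additivity_gap(self) -> float:
        return float(abs(self.base_value + self.phi.sum() - self.prediction))


def shap_background(
    model: SpinModel,
    dataset: ExpressionDataset,
    route_as: str,
    cap: int = BACKGROUND_CAP,
    seed: int = 0,
) -> np.ndarray:
    """Reference pathway activations: `dataset` rows routed through
    `route_as`'s branch, subsampled to at most `cap` rows (seeded)."""
    trace = forward(model, dataset.expression, dataset.sex, route_as=route_as)
    p = trace.pathway_activations
    if p.shape[0] > cap:
        rng = np.random.default_rng(seed)
        p = p[rng.choice(p.shape[0], size=cap, replace=False)]
    return p


def _coalition_values(model, p, background, r):
    """v(S) for every coalition bitmask S (mean tail output on hybrids)."""
    v = np.empty(1 << r)
    for s in range(1 << r):
        hybrid = background.copy()
        members = [j for j in range(r) if s >> j & 1]
        hybrid[:, members] = p[members]
        v[s] = tail_forward(model, hybrid).mean()
    return v


def _exact_shapley(model, p, background) -> np.ndarray:
    r = len(p)
    v = _coalition_values(model, p, background, r)
    weights = [factorial(k) * factorial(r - k - 1) / factorial(r) for k in range(r)]
    phi = np.zeros(r)
    for s in range(1 << r):
        k = bin(s).count("1")
        for j in range(r):
            if not s >> j & 1:
                phi[j] += weights[k] * (v[s | 1 << j] - v[s])
    return phi


def _sampled_shapley(model, p, background, n_permutations, rng) -> np.ndarray:
    r = len(p)
    phi = np.zeros(r)
    for _ in range(n_permutations):
        perm = rng.permutation(r)
        hybrid = background.copy()
        prev = tail_forward(model, hybrid).mean()
        for j in perm:
            hybrid[:, j] = p[j]
            cur = tail_forward(model, hybrid).mean()
            phi[j] += cur - prev
            prev = cur
    return phi / n_permutations


def shap_explain(
    model: SpinModel,
    expression_row: np.ndarray,
    sex: str,
    background: np.ndarray,
    route_as: str | None = None,
    sample_id: str = "",
    exact_max: int = EXACT_MAX_PATHWAYS,
    n_permutations: int = 64,
    seed: int = 0,
) -> LocalExplanation:
    """Shapley attribution of one sample's prediction over pathway nodes.

    The sample's expression is routed through `route_as` (default: its own
    sex) to obtain its pathway activations; attributions are computed on
    the shared pathway->output sub-network against `background` (reference
    pathway activations, rows x pathways).  Exact enumeration when the
    pathway count is at most `exact_max`, else permutation sampling with
    the (telescoping-exact) additivity residual spread uniformly.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise SpinError("background must contain at least one reference sample")
    if background.shape[1] != model.n_pathways:
        raise SchemaError("background pathway count does not match the model")
    routed = route_as or sex
    trace = forward(
        model, np.atleast_2d(expression_row), sex=np.array([sex], dtype=object),
        route_as=routed,
    )
    p = trace.pathway_activations[0]
    prediction = float(trace.output[0])
    base = float(tail_forward(model, background).mean())
    r = model.n_pathways
    if r <= exact_max:
        phi = _exact_shapley(model, p, background)
    else:
        rng = np.random.default_rng(seed)
        phi = _sampled_shapley(model, p, background, n_permutations, rng)
        phi += (prediction - base - phi.sum()) / r  # enforce additivity
    return LocalExplanation(
        sample_id=sample_id,
        routed_sex=routed,
        pathway_ids=list(model.mask.pathway_ids),
        phi=phi,
        base_value=base,
        prediction=prediction,
        pathway_values=p,
        enriched=p > background.mean(axis=0),
    )


def waterfall_data(explanation: LocalExplanation, top_k: int = 15) -> pd.DataFrame:
    """Waterfall-plot table: top-|phi| pathways plus an "others" aggregate.

    Rows are ordered by |phi| descending; when more than `top_k` pathways
    exist the remainder is summed into a final ``others`` row, so the base
    value plus all listed terms equals the prediction.
    """
    r = len(explanation.phi)
    if top_k > r:
        raise SpinError(f"top_k={top_k} exceeds the {r} pathways")
    order = np.argsort(-np.abs(explanation.phi), kind="stable")
    rows = [
        {
            "pathway": explanation.pathway_ids[j],
            "phi": float(explanation.phi[j]),
            "enriched": bool(explanation.enriched[j]),
        }
        for j in order[:top_k]
    ]
    rest = order[top_k:]
    if len(rest):
        rows.append(
            {
                "pathway": f"{len(rest)} other pathways",
                "phi": float(explanation.phi[rest].sum()),
                "enriched": None,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["base_value"] = explanation.base_value
    out.attrs["prediction"] = explanation.prediction
    return out


def summary_data(
    explanations: list[LocalExplanation], groups: list[str]
) -> pd.DataFrame:
    """Long-format table for beeswarm-style summary plots.

    One row per (group, pathway, sample) with the attribution and the
    pathway node value; nothing is aggregated, so per-sample points are
    preserved.  Group labels must be given per explanation.
    """
    if len(groups) != len(explanations):
        raise SpinError("one group label per explanation is required")
    bad = [g for g in groups if not isinstance(g, str) or not g]
    if bad:
        raise SpinError(f"unknown group label(s): {bad[:5]}")
    rows = []
    for expl, group in zip(explanations, groups):
        for j, pid in enumerate(expl.pathway_ids):
            rows.append(
                {
                    "group": group,
                    "pathway": pid,
                    "sample_id": expl.sample_id,
                    "phi": float(expl.phi[j]),
                    "node_value": float(expl.pathway_values[j]),
                }
            )
    columns = ["group", "pathway", "sample_id", "phi", "node_value"]
    return pd.DataFrame(rows, columns=columns)


def cohort_contrast(
    explanations_female: list[LocalExplanation],
    explanations_male: list[LocalExplanation],
) -> pd.DataFrame:
    """Pair each sample's attributions under both sex routings.

    Returns one row per (sample, pathway) with ``phi_female`` / ``phi_male``
    and a per-row ``sign_flip`` flag (strictly opposite signs between the
    routings); ``attrs["pathway_sign_flip"]`` summarizes the per-pathway
    majority.  Explanations must list pathways in the same order.
    """
    if len(explanations_female) != len(explanations_male):
        raise SpinError("need both-routing explanations for each sample")
    rows = []
    for ef, em in zip(explanations_female, explanations_male):
        if ef.pathway_ids != em.pathway_ids:
            raise SpinError("pathway ordering differs between routings")
        for j, pid in enumerate(ef.pathway_ids):
            pf, pm = float(ef.phi[j]), float(em.phi[j])
            rows.append(
                {
                    "sample_id": ef.sample_id,
                    "pathway": pid,
                    "phi_female": pf,
                    "phi_male": pm,
                    "sign_flip": pf * pm < 0,
                }
            )
    out = pd.DataFrame(
        rows, columns=["sample_id", "pathway", "phi_female", "phi_male", "sign_flip"]
    )
    majority = (
        out.groupby("pathway", sort=False)["sign_flip"].mean() > 0.5
    )
    out.attrs["pathway_sign_flip"] = majority.to_dict()
    return out
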