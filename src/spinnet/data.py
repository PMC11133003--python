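"""Expression datasets with sex labels and a survival or binary outcome.

The container couples an ``n x q`` expression matrix (samples x genes) with
per-sample sex labels and exactly one outcome: right-censored survival
(``time``, ``event``) or a binary disease label.  Expression and clinical
tables are exchanged as plain TSV/CSV with sample identifiers in the first
column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)


@dataclass
class ExpressionDataset:
    """Samples x genes expression with sex and outcome annotations.

    Parameters
    ----------
    expression
        Real matrix of shape ``(n, q)``; no missing values.
    sex
        Length-``n`` array of ``"male"`` / ``"female"`` labels.
    sample_ids, gene_ids
        Row and column identifiers.
    time, event
        Survival outcome: positive times and binary event indicators
        (1 = event observed, 0 = censored).  Mutually exclusive with `label`.
    label
        Binary disease label for the risk task.
    normalized
        Set by :class:`spinnet.training.Normalizer`; guards against applying
        training statistics twice.
    """

    expression: np.ndarray
    sex: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    label: np.ndarray | None = None
    normalized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        self.sample_ids = list(map(str, self.sample_ids))
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        n, q = self.expression.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != q:
            raise SchemaError(
                f"identifier lengths ({len(self.sample_ids)}, {len(self.gene_ids)}) "
                f"do not match expression shape {(n, q)}"
            )
        if self.sex.shape != (n,):
            raise SchemaError("one sex label per sample is required")
        bad = sorted(set(self.sex) - set(SEXES))
        if bad:
            raise SchemaError(f"unknown sex labels: {bad}")
        if not np.all(np.isfinite(self.expression)):
            raise SchemaError("expression contains missing/non-finite values")
        has_surv = self.time is not None or self.event is not None
        has_bin = self.label is not None
        if has_surv and has_bin:
            raise SchemaError("provide either survival outcome or binary label, not both")
        if has_surv:
            if self.time is None or self.event is None:
                raise SchemaError("survival outcome needs both time and event")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=int)
            if self.time.shape != (n,) or self.event.shape != (n,):
                raise SchemaError("time/event must have one entry per sample")
            if np.any(self.time <= 0):
                raise SchemaError("survival times must be positive")
            if not set(np.unique(self.event)) <= {0, 1}:
                raise SchemaError("event indicator must be binary")
        if has_bin:
            self.label = np.asarray(self.label, dtype=int)
            if self.label.shape != (n,):
                raise SchemaError("label must have one entry per sample")
            if not set(np.unique(self.label)) <= {0, 1}:
                raise SchemaError("label must be binary")

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def task(self) -> str:
        """``"survival"`` or ``"risk"`` depending on the outcome present."""
        if self.time is not None:
            return "survival"
        if self.label is not None:
            return "risk"
        raise SchemaError("dataset has no outcome")

    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    # -- subsetting -------------------------------------------------------
    def subset(self, rows: np.ndarray) -> "ExpressionDataset":
        """Row subset (boolean mask or index array), preserving outcome type."""
        rows = np.asarray(rows)
        return dataclasses.replace(
            self,
            expression=self.expression[rows],
            sex=self.sex[rows],
            sample_ids=[self.sample_ids[i] for i in np.arange(self.n_samples)[rows]],
            time=None if self.time is None else self.time[rows],
            event=None if self.event is None else self.event[rows],
            label=None if self.label is None else self.label[rows],
        )

    def select_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        """Column subset/reorder to exactly `gene_ids` (all must be present)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise SchemaError(f"genes absent from dataset: {missing}")
        cols = np.array([index[g] for g in gene_ids], dtype=int)
        return dataclasses.replace(
            self, expression=self.expression[:, cols], gene_ids=list(gene_ids)
        )


# -- I/O -------------------------------------------------------------------

def _sniff_sep(path) -> str:
    """Tab wins over comma if present in the header line (TSV or CSV)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","

def write_dataset(dataset: ExpressionDataset, expression_path, clinical_path) -> None:
    """Write expression and clinical tables as TSV (repr floats round-trip)."""
    expr = pd.DataFrame(
        dataset.expression, index=dataset.sample_ids, columns=dataset.gene_ids
    )
    expr.index.name = "sample_id"
    # %.17g round-trips IEEE doubles exactly
    expr.to_csv(expression_path, sep="\t", float_format="%.17g")
    clin = pd.DataFrame({"sample_id": dataset.sample_ids, "sex": dataset.sex})
    if dataset.time is not None:
        clin["time"] = dataset.time
        clin["event"] = dataset.event
    if dataset.label is not None:
        clin["label"] = dataset.label
    clin.to_csv(clinical_path, sep="\t", index=False, float_format="%.17g")


def load_dataset(expression_path, clinical_path) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from expression + clinical TSV/CSV.

    The expression table has sample identifiers in the first column and gene
    identifiers in the header.  The clinical table needs columns
    ``sample_id``, ``sex`` and either (``time``, ``event``) or ``label``.
    Clinical rows are matched to expression rows by sample identifier.
    """
    expr = pd.read_csv(
        expression_path, sep=_sniff_sep(expression_path), index_col=0,
        float_precision="round_trip",
    )
    clin = pd.read_csv(
        clinical_path, sep=_sniff_sep(clinical_path),
        float_precision="round_trip",
    )
    if "sample_id" not in clin.columns or "sex" not in clin.columns:
        raise SchemaError("clinical table must have 'sample_id' and 'sex' columns")
    clin = clin.set_index("sample_id")
    missing = [s for s in expr.index.astype(str) if s not in clin.index.astype(str)]
    if missing:
        raise SchemaError(f"samples without clinical rows: {missing[:5]}")
    clin = clin.loc[expr.index]
    kwargs: dict = {}
    if {"time", "event"} <= set(clin.columns):
        kwargs["time"] = clin["time"].to_numpy()
        kwargs["event"] = clin["event"].to_numpy()
    elif "label" in clin.columns:
        kwargs["label"] = clin["label"].to_numpy()
    else:
        raise SchemaError("clinical table needs either time+event or label columns")
    return ExpressionDataset(
        expression=expr.to_numpy(dtype=float),
        sex=clin["sex"].to_numpy(),
        sample_ids=list(expr.index.astype(str)),
        gene_ids=list(expr.columns.astype(str)),
        **kwargs,
    )
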