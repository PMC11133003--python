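"""Pathway gene sets (GMT) and the binary gene-pathway mask.

The first masked layer of the network is wired by a bi-adjacency matrix
``M_G`` over genes x pathways: entry ``(i, j)`` is 1 iff gene ``i`` belongs to
pathway ``j``.  Gene sets come from a user-supplied GMT file (e.g. KEGG);
sets are size-filtered after restriction to the dataset's gene universe, and
genes annotated to no surviving pathway are excluded from the model — the
architecture admits only pathway-annotated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset
from .errors import GmtParseError, MaskError

DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 500


@dataclass
class GeneSet:
    pathway_id: str
    description: str
    genes: list[str]  # ordered, unique


@dataclass
class GeneSetCollection:
    """Ordered gene sets with unique pathway identifiers."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [s.pathway_id for s in self.sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GmtParseError(f"duplicate pathway ids: {dupes}")
        for s in self.sets:
            if not s.genes:
                raise GmtParseError(f"pathway {s.pathway_id!r} has no genes")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PathwayMask:
    """Binary genes x pathways bi-adjacency matrix with identifier maps.

    Invariants: entries in {0, 1}; every gene (row) belongs to at least one
    pathway and every pathway (column) retains at least one gene.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    pathway_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not set(np.unique(self.matrix)) <= {0, 1}:
            raise MaskError("mask entries must be binary")
        self.matrix = self.matrix.astype(np.int8)
        q, r = self.matrix.shape
        if len(self.gene_ids) != q or len(self.pathway_ids) != r:
            raise MaskError("identifier lengths do not match mask shape")
        if q == 0 or r == 0:
            raise MaskError("mask must be non-empty")
        if np.any(self.matrix.sum(axis=1) == 0):
            raise MaskError("every gene must belong to >=1 pathway")
        if np.any(self.matrix.sum(axis=0) == 0):
            raise MaskError("every pathway must retain >=1 gene")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pathways(self) -> int:
        return self.matrix.shape[1]

    def members(self, pathway_id: str) -> list[str]:
        j = self.pathway_ids.index(pathway_id)
        return [g for g, m in zip(self.gene_ids, self.matrix[:, j]) if m]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated gene set per line.

    Each line is ``pathway_id<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate gene symbols within a line are collapsed (first occurrence
    kept); blank lines are skipped.  A line with fewer than three fields
    raises :class:`GmtParseError` naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pathway_id, description = fields[0].strip(), fields[1].strip()
            genes = list(dict.fromkeys(g.strip() for g in fields[2:] if g.strip()))
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: no gene symbols")
            sets.append(GeneSet(pathway_id, description, genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.pathway_id, s.description, *s.genes]) + "\n")


def build_mask(
    genes: list[str],
    collection: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> PathwayMask:
    """Build ``M_G`` from a gene universe and a gene-set collection.

    Pathways are restricted to genes present in `genes`; those whose
    restricted size falls outside ``[min_size, max_size]`` are dropped, and
    genes annotated to no surviving pathway are removed from the rows.  Row
    order follows the input gene order, column order the GMT line order.
    """
    if not genes:
        raise MaskError("empty gene universe")
    if not (1 <= min_size <= max_size):
        raise MaskError(f"invalid size filter [{min_size}, {max_size}]")
    genes = [str(g).strip() for g in genes]
    universe = set(genes)
    kept_sets: list[tuple[str, set[str]]] = []
    for s in collection.sets:
        members = [g for g in s.genes if g in universe]
        if min_size <= len(members) <= max_size:
            kept_sets.append((s.pathway_id, set(members)))
    if not kept_sets:
        raise MaskError(
            f"no pathway of size in [{min_size}, {max_size}] after restriction "
            f"to the {len(genes)} supplied genes"
        )
    annotated = set().union(*(m for _, m in kept_sets))
    gene_ids = [g for g in genes if g in annotated]
    matrix = np.zeros((len(gene_ids), len(kept_sets)), dtype=np.int8)
    row = {g: i for i, g in enumerate(gene_ids)}
    for j, (_, members) in enumerate(kept_sets):
        for g in members:
            matrix[row[g], j] = 1
    return PathwayMask(matrix, gene_ids, [pid for pid, _ in kept_sets])


def align_dataset(dataset: ExpressionDataset, mask: PathwayMask) -> ExpressionDataset:
    """Subset/reorder dataset columns to exactly ``mask.gene_ids``.

    Idempotent; raises listing the missing genes if any mask gene is absent.
    """
    missing = sorted(set(mask.gene_ids) - set(dataset.gene_ids))
    if missing:
        raise MaskError(f"mask genes absent from dataset: {missing}")
    return dataset.select_genes(mask.gene_ids)
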