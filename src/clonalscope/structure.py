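"""Population structure: imputation, allele encoding, PCA, MST and the
2N-constrained randomization control.

The ordination pipeline mirrors the standard treatment of codominant
microsatellite data: missing cells are replaced by the closest neighbour's
data (only for the ordination — downstream clone detection always uses the
raw table), genotypes are encoded as a binary allele-presence matrix (one
column per observed (locus, allele) pair, which treats diploids and
triploids uniformly), a PCA is run on the centred matrix, and a minimum
spanning tree is built on the leading principal-component scores.

Because putative triploids carry more alleles than diploids, the observed
clustering could in principle be an artefact of allele *quantity*.  The
``constrain_to_2n`` control tests this: at every locus showing 3 alleles,
one allele is deleted uniformly at random, and the analysis is repeated on
the 2N-constrained table; high label concordance indicates the structure
rests on which alleles are carried, not how many.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeError,
    IsolateTable,
    MultilocusGenotype,
)
from .group_assignment import GroupAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "AllelePresenceMatrix",
    "PcaResult",
    "SpanningTree",
    "ConcordanceReport",
    "pairwise_distance_matrix",
    "impute_missing_nn",
    "encode_alleles",
    "run_pca",
    "minimum_spanning_tree",
    "constrain_to_2n",
    "clustering_concordance",
    "plot_mst",
]


def pairwise_distance_matrix(table: IsolateTable) -> np.ndarray:
    """All-pairs Dice distance matrix (see ``allele_sharing_distance``),
    with NaN for pairs sharing no non-missing locus.

    Vectorised per locus through presence indicators so that tables of a
    few thousand isolates stay fast: at one locus the Dice numerator for
    every pair is ``P @ P.T`` of the presence matrix.
    """
    n = len(table)
    records = table.records
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for locus in table.panel:
        sets = [rec.genotype[locus] for rec in records]
        alleles = sorted(set().union(*sets))
        if not alleles:
            continue
        index = {a: j for j, a in enumerate(alleles)}
        P = np.zeros((n, len(alleles)))
        for i, s in enumerate(sets):
            for a in s:
                P[i, index[a]] = 1.0
        sizes = P.sum(axis=1)
        present = sizes > 0
        inter = P @ P.T
        denom = sizes[:, None] + sizes[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - 2.0 * inter / denom
        mask = present[:, None] & present[None, :]
        num[mask] += d[mask]
        cnt += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    np.fill_diagonal(D, 0.0)
    return D


def impute_missing_nn(table: IsolateTable, seed: int = 0) -> IsolateTable:
    """Closest-neighbour replacement of missing cells (ordination only).

    For each missing (isolate, locus) cell, the donor is the nearest other
    isolate (shared-allele distance over mutually non-missing loci) that
    has data at that locus; the donor's whole allele set is copied.  Ties
    are broken by smallest strain id (ids are unique, so *seed* is never
    actually consulted; it is accepted for interface stability).  A cell
    with no eligible donor is left missing with a warning.  The input table
    is untouched; the returned table is flagged ``imputed``.
    """
    D = pairwise_distance_matrix(table)
    records = list(table.records)
    ids = [rec.strain_id for rec in records]
    out = []
    n_unimputable = 0
    for i, rec in enumerate(records):
        missing = [locus for locus in table.panel if not rec.genotype[locus]]
        if not missing:
            out.append(replace(rec))
            continue
        genotype: MultilocusGenotype = dict(rec.genotype)
        for locus in missing:
            candidates = [
                (D[i, j], ids[j], j)
                for j in range(len(records))
                if j != i and records[j].genotype[locus] and np.isfinite(D[i, j])
            ]
            if not candidates:
                n_unimputable += 1
                continue
            _, _, donor = min(candidates)
            genotype[locus] = records[donor].genotype[locus]
        out.append(replace(rec, genotype=genotype))
    if n_unimputable:
        logger.warning("%d cells had no comparable donor and remain missing", n_unimputable)
    return IsolateTable(table.panel, out, imputed=True)


@dataclass
class AllelePresenceMatrix:
    """Binary strain x (locus, allele) presence matrix for ordination."""

    data: pd.DataFrame  # index strain_id, MultiIndex columns (locus, allele)

    @property
    def strain_ids(self) -> list:
        return list(self.data.index)


def encode_alleles(table: IsolateTable) -> AllelePresenceMatrix:
    """Encode genotypes as 0/1 presence of each observed (locus, allele).

    Requires a complete (imputed) table: residual missing cells would be
    indistinguishable from absence of every allele.
    """
    for rec in table:
        for locus in table.panel:
            if not rec.genotype[locus]:
                raise GenotypeError(
                    f"{rec.strain_id}: missing data at {locus}; run "
                    "impute_missing_nn before encoding"
                )
    columns = []
    for locus in table.panel:
        observed = sorted(set().union(*(rec.genotype[locus] for rec in table)))
        columns.extend((locus, a) for a in observed)
    col_index = {c: j for j, c in enumerate(columns)}
    X = np.zeros((len(table), len(columns)), dtype=np.int8)
    for i, rec in enumerate(table):
        for locus in table.panel:
            for a in rec.genotype[locus]:
                X[i, col_index[(locus, a)]] = 1
    df = pd.DataFrame(
        X,
        index=pd.Index(table.strain_ids(), name="strain_id"),
        columns=pd.MultiIndex.from_tuples(columns, names=["locus", "allele"]),
    )
    return AllelePresenceMatrix(df)


@dataclass
class PcaResult:
    """Principal-component scores and explained-variance fractions."""

    coordinates: pd.DataFrame  # index strain_id, columns PC1..PCk
    explained_variance: np.ndarray  # fraction of total variance per component

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def run_pca(m: AllelePresenceMatrix, n_components: int = 2) -> PcaResult:
    """PCA of the column-centred presence matrix via SVD.

    Deterministic up to sign, and the sign is fixed: each component is
    flipped so that its largest-magnitude loading is positive.  Requesting
    more components than the matrix rank truncates with a warning.
    """
    if m.data.shape[0] < 2:
        raise GenotypeError("PCA needs at least 2 isolates")
    X = m.data.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank == 0:
        raise GenotypeError("presence matrix has zero variance")
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("requested %d components but rank is %d; truncating",
                       n_components, rank)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * s[:k]
    total_var = float((s**2).sum())
    explained = (s[:k] ** 2) / total_var
    coords = pd.DataFrame(
        scores,
        index=m.data.index.copy(),
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return PcaResult(coords, explained)


@dataclass
class SpanningTree:
    """Minimum spanning tree over isolates in the PCA embedding."""

    edges: List[Tuple[str, str, float]]  # (strain_a, strain_b, weight), a < b

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["strain_a", "strain_b", "weight"])


def minimum_spanning_tree(p: PcaResult, n_axes: int = 2) -> SpanningTree:
    """Kruskal MST under Euclidean distance in the first *n_axes* scores.

    Ties between equal-weight edges are broken lexicographically by the
    (strain_a, strain_b) pair so the tree is deterministic; duplicate
    coordinates simply yield zero-weight edges.
    """
    ids = list(p.coordinates.index)
    n = len(ids)
    if n < 2:
        raise GenotypeError("MST needs at least 2 isolates")
    k = min(n_axes, p.n_components)
    X = p.coordinates.to_numpy(dtype=float)[:, :k]
    order = sorted(range(n), key=lambda i: ids[i])

    ii, jj = np.triu_indices(n, k=1)
    diff = X[ii] - X[jj]
    w = np.sqrt((diff**2).sum(axis=1))
    # lexicographic rank of each endpoint pair, for deterministic tie-breaks
    pos = np.empty(n, dtype=int)
    for rank_, i in enumerate(order):
        pos[i] = rank_
    a = np.minimum(pos[ii], pos[jj])
    b = np.maximum(pos[ii], pos[jj])
    edge_order = np.lexsort((b, a, w))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: List[Tuple[str, str, float]] = []
    for e in edge_order:
        i, j = int(ii[e]), int(jj[e])
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        parent[ri] = rj
        sa, sb = sorted((ids[i], ids[j]))
        edges.append((sa, sb, float(w[e])))
        if len(edges) == n - 1:
            break
    edges.sort(key=lambda e: (e[0], e[1]))
    return SpanningTree(edges)


def _cell_rng(seed: int, strain_id: str, locus: str) -> np.random.Generator:
    # per-cell sub-stream keyed by (seed, strain, locus): edits elsewhere in
    # the table cannot shift this cell's draw
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(strain_id.encode()), zlib.crc32(locus.encode())]
    )


def constrain_to_2n(table: IsolateTable, seed: int = 0) -> IsolateTable:
    """Randomly delete one allele from every 3-allele cell.

    The choice is uniform over the three alleles and reproducible for a
    given seed; diploid cells are untouched, so the output never shows more
    than 2 alleles anywhere.
    """
    records = []
    for rec in table:
        genotype: Optional[MultilocusGenotype] = None
        for locus in table.panel:
            alleles = rec.genotype[locus]
            if len(alleles) == 3:
                if genotype is None:
                    genotype = dict(rec.genotype)
                rng = _cell_rng(seed, rec.strain_id, locus)
                drop = sorted(alleles)[rng.integers(3)]
                genotype[locus] = frozenset(a for a in alleles if a != drop)
        records.append(replace(rec, genotype=genotype) if genotype else replace(rec))
    return IsolateTable(table.panel, records, imputed=table.imputed)


@dataclass
class ConcordanceReport:
    """Fraction of isolates keeping their group label after the 2N control."""

    overall: float
    per_group: Dict[str, float]
    n: int


def clustering_concordance(
    full: List[GroupAssignment], constrained: List[GroupAssignment]
) -> ConcordanceReport:
    """Compare group labels before/after the 2N constraint on the same strains."""
    by_id_full = {a.strain_id: a.group_name for a in full}
    by_id_con = {a.strain_id: a.group_name for a in constrained}
    if set(by_id_full) != set(by_id_con):
        raise GenotypeError("concordance requires identical strain sets")
    agree_total = 0
    per_group_n: Dict[str, int] = {}
    per_group_agree: Dict[str, int] = {}
    for sid, name in by_id_full.items():
        per_group_n[name] = per_group_n.get(name, 0) + 1
        same = by_id_con[sid] == name
        agree_total += same
        per_group_agree[name] = per_group_agree.get(name, 0) + same
    per_group = {g: per_group_agree.get(g, 0) / n for g, n in per_group_n.items()}
    return ConcordanceReport(agree_total / len(by_id_full), per_group, len(by_id_full))


def plot_mst(
    p: PcaResult,
    tree: SpanningTree,
    path,
    *,
    group_labels: Optional[Dict[str, str]] = None,
    clone_sizes: Optional[Dict[str, int]] = None,
) -> None:
    """Scatter of PC1/PC2 with MST edges; point area scales with
    log10(clone size) when clone sizes are given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = p.coordinates
    fig, ax = plt.subplots(figsize=(7, 6))
    for a, b, _ in tree.edges:
        xs = [coords.loc[a, "PC1"], coords.loc[b, "PC1"]]
        ys = [coords.loc[a, "PC2"], coords.loc[b, "PC2"]]
        ax.plot(xs, ys, color="0.7", lw=0.5, zorder=1)
    sizes = [
        20.0 * (1.0 + np.log10(clone_sizes.get(sid, 1))) if clone_sizes else 20.0
        for sid in coords.index
    ]
    if group_labels:
        labels = [group_labels.get(sid, "?") for sid in coords.index]
        for lbl in sorted(set(labels)):
            mask = [l == lbl for l in labels]
            ax.scatter(
                coords.loc[mask, "PC1"], coords.loc[mask, "PC2"],
                s=[s for s, m in zip(sizes, mask) if m], label=lbl, zorder=2,
            )
        ax.legend(fontsize=7)
    else:
        ax.scatter(coords["PC1"], coords["PC2"], s=sizes, zorder=2)
    ev = p.explained_variance
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    if len(ev) > 1:
        ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
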