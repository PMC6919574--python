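"""Putative-ploidy inference and reference-anchored genetic-group assignment.

Mixed-ploidy populations of this yeast resolve into six genetic groups,
each anchored by a published reference strain and a putative ploidy level
(2N or 3N).  Because the groups were delimited once on the full species
collection, new isolates are assigned by supervised nearest-reference
classification rather than by re-clustering: each isolate is labelled with
the group of the reference genotype closest under a shared-allele (Dice)
distance, and the margin to the runner-up reference is reported as an
assignment-confidence proxy.

Putative ploidy follows the codominant-marker rule: the maximum number of
distinct alleles seen at any locus (2 -> possible diploid, 3 -> possible
triploid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, List, Optional

import pandas as pd

from .genotype_io import (
    GenotypeError,
    IsolateTable,
    LocusPanel,
    MultilocusGenotype,
    MAX_ALLELES_PER_LOCUS,
    METADATA_COLUMNS,
    format_allele_field,
    make_genotype,
    parse_allele_field,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UNASSIGNED_LABEL",
    "DEFAULT_GROUP_INFO",
    "ReferenceGroup",
    "ReferencePanel",
    "GroupAssignment",
    "IncomparablePairError",
    "infer_ploidy",
    "allele_sharing_distance",
    "bruvo_like_distance",
    "assign_groups",
    "read_reference_panel",
    "write_reference_panel",
]

UNASSIGNED_LABEL = "unassigned"

#: the six published genetic groups: (group name, colour label,
#: reference strain, putative ploidy)
DEFAULT_GROUP_INFO = (
    ("Wine 2N", "darkcyan", "CBS 2499", 2),
    ("Wine/Kombucha 2N", "lightgreen", "L14165", 2),
    ("Wine/Beer 3N", "orange", "AWRI1608", 3),
    ("1st Wine 3N", "red", "AWRI1499", 3),
    ("2nd Wine 3N", "turquoise", "L0308", 3),
    ("Tequila/Bioethanol 3N", "darkblue", "CBS 5512", 3),
)


class IncomparablePairError(GenotypeError):
    """Two genotypes share no mutually non-missing locus."""


@dataclass(frozen=True)
class ReferenceGroup:
    """One genetic group anchored by a reference strain's genotype."""

    name: str
    color: str
    reference_strain_id: str
    genotype: MultilocusGenotype
    ploidy: int


@dataclass(frozen=True)
class ReferencePanel:
    """Ordered collection of reference groups (order breaks assignment ties)."""

    panel: LocusPanel
    groups: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise GenotypeError("reference group names must be unique")
        for g in self.groups:
            if set(g.genotype) != set(self.panel.names):
                raise GenotypeError(f"reference {g.name}: genotype does not match panel")

    def __iter__(self) -> Iterator[ReferenceGroup]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def group_names(self) -> list:
        return [g.name for g in self.groups]


@dataclass(frozen=True)
class GroupAssignment:
    """Nearest-reference label for one isolate.

    ``distance_to_reference`` is the Dice distance to the winning
    reference; ``runner_up_margin`` the gap to the second-closest one
    (0 for an exact tie, which panel order resolves).
    """

    strain_id: str
    group_name: str
    distance_to_reference: float
    runner_up_margin: float


def infer_ploidy(g: MultilocusGenotype) -> int:
    """Putative ploidy = max distinct alleles at any locus.

    Loci with a single allele are read as homozygous, not haploid, so the
    result is at least 2 for any genotype with data.
    """
    counts = [len(alleles) for alleles in g.values() if alleles]
    if not counts:
        raise GenotypeError("cannot infer ploidy: all loci missing")
    return max(2, max(counts))


def allele_sharing_distance(a: MultilocusGenotype, b: MultilocusGenotype) -> float:
    """Dice dissimilarity averaged over mutually non-missing loci.

    Per locus: ``1 - 2|A∩B| / (|A|+|B|)``.  Size-agnostic (a 2 bp shift is
    as different as a 50 bp one) and symmetric; 0 for identical genotypes,
    1 for fully disjoint allele sets.  Loci missing in either genotype are
    excluded pairwise, not imputed.
    """
    total = 0.0
    n = 0
    for locus, aa in a.items():
        bb = b[locus]
        if not aa or not bb:
            continue
        total += 1.0 - 2.0 * len(aa & bb) / (len(aa) + len(bb))
        n += 1
    if n == 0:
        raise IncomparablePairError("no mutually non-missing locus")
    return total / n


def bruvo_like_distance(
    a: MultilocusGenotype, b: MultilocusGenotype, *, repeat_step: int = 2
) -> float:
    """Stepwise-mutation-aware distance (optional alternative to Dice).

    Per allele pair the distance is ``1 - 2**(-|size difference| /
    repeat_step)``, so one repeat unit of slippage costs ~0.5 and large
    jumps saturate at 1.  Alleles of the two sets are matched by a
    minimum-cost assignment; unmatched alleles (ploidy difference) cost 1.
    """
    from scipy.optimize import linear_sum_assignment
    import numpy as np

    total = 0.0
    n = 0
    for locus, aa in a.items():
        bb = b[locus]
        if not aa or not bb:
            continue
        xs, ys = sorted(aa), sorted(bb)
        k = max(len(xs), len(ys))
        cost = np.ones((k, k))
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                cost[i, j] = 1.0 - 2.0 ** (-abs(x - y) / repeat_step)
        rows, cols = linear_sum_assignment(cost)
        total += cost[rows, cols].sum() / k
        n += 1
    if n == 0:
        raise IncomparablePairError("no mutually non-missing locus")
    return total / n


_METRICS = {"dice": allele_sharing_distance, "bruvo": bruvo_like_distance}


def assign_groups(
    table: IsolateTable, refs: ReferencePanel, *, metric: str = "dice"
) -> List[GroupAssignment]:
    """Label every isolate with its nearest reference group.

    Ties are broken by reference-panel order.  Isolates incomparable with
    every reference (all loci missing) are labelled ``"unassigned"`` with
    NaN distances and a warning.  ``IsolateRecord.group_label`` is filled
    in place on *table*; the assignment list is returned.
    """
    dist = _METRICS[metric]
    assignments = []
    n_unassigned = 0
    for rec in table:
        distances = []
        for idx, ref in enumerate(refs):
            try:
                d = dist(rec.genotype, ref.genotype)
            except IncomparablePairError:
                continue
            distances.append((d, idx))
        if not distances:
            n_unassigned += 1
            rec.group_label = UNASSIGNED_LABEL
            assignments.append(
                GroupAssignment(rec.strain_id, UNASSIGNED_LABEL, float("nan"), float("nan"))
            )
            continue
        distances.sort(key=lambda t: t)
        best_d, best_idx = distances[0]
        margin = distances[1][0] - best_d if len(distances) > 1 else float("inf")
        name = refs.groups[best_idx].name
        rec.group_label = name
        assignments.append(GroupAssignment(rec.strain_id, name, best_d, margin))
    if n_unassigned:
        logger.warning("%d isolates had no comparable locus and were left unassigned",
                       n_unassigned)
    return assignments


_REF_META = ("group_name", "color", "reference_strain_id", "ploidy")


def read_reference_panel(path, panel: Optional[LocusPanel] = None) -> ReferencePanel:
    """Read a reference-panel CSV (group_name, color, reference_strain_id,
    ploidy + the locus columns in the isolate-CSV allele dialect)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REF_META:
        if col not in df.columns:
            raise GenotypeError(f"reference CSV missing column {col!r}")
    if panel is None:
        loci = [c for c in df.columns if c not in _REF_META and c not in METADATA_COLUMNS]
        panel = LocusPanel(tuple(loci))
    groups = []
    for _, row in df.iterrows():
        genotype = {locus: parse_allele_field(row[locus]) for locus in panel}
        groups.append(
            ReferenceGroup(
                name=row["group_name"].strip(),
                color=row["color"].strip(),
                reference_strain_id=row["reference_strain_id"].strip(),
                genotype=make_genotype(panel, genotype),
                ploidy=int(row["ploidy"]),
            )
        )
    return ReferencePanel(panel, tuple(groups))


def write_reference_panel(refs: ReferencePanel, path) -> None:
    rows = []
    for g in refs:
        row = {
            "group_name": g.name,
            "color": g.color,
            "reference_strain_id": g.reference_strain_id,
            "ploidy": g.ploidy,
        }
        for locus in refs.panel:
            row[locus] = format_allele_field(g.genotype[locus])
        rows.append(row)
    columns = list(_REF_META) + list(refs.panel.names)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
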