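"""Clone detection, winery persistence, geographic dispersal and temporal
group dynamics.

A *clone group* is a set of isolates with identical genotypes at all 12
loci.  Identity is computed on the raw (non-imputed) table and read
strictly: an isolate with any missing locus cannot be proven identical to
another, so it is excluded from multi-member groups and tracked as a
singleton.  From the clone partition the module derives

* winery persistence — the same genotype re-isolated in one winery across
  different vintages, with the spanned interval in years;
* dispersal — great-circle distances between all member pairs of each
  clone, binned into distance classes ([0,1), [1,100), [100,750),
  [750,1000), [1000,inf) km; pairs under 100 km are "local clone pairs");
* regional/sample distributions of the genetic groups; and
* vintage-binned group proportions over 20-year bins (..., 1981-2000,
  2001-2020) with percentile-bootstrap CIs.

Temporal binning is driven by the *vintage* (year the wine was produced),
not the isolation year: isolates are routinely cultured from bottles
decades after bottling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeError,
    IsolateTable,
    genotype_is_complete,
    genotype_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "DISTANCE_CLASS_EDGES",
    "CloneGroup",
    "PersistenceRecord",
    "DistanceClassDistribution",
    "VintageBin",
    "find_clone_groups",
    "winery_persistence",
    "haversine_km",
    "clone_pair_distances",
    "bin_distances",
    "region_group_distribution",
    "sample_group_diversity",
    "vintage_bin",
    "temporal_group_proportions",
    "plot_distance_classes",
    "plot_temporal_proportions",
]

#: IUGG mean Earth radius; distances use a spherical model, no ellipsoid
EARTH_RADIUS_KM = 6371.0088

#: distance-class edges in km; classes are half-open [lo, hi)
DISTANCE_CLASS_EDGES = (0.0, 1.0, 100.0, 750.0, 1000.0, math.inf)

DISTANCE_CLASS_LABELS = ("<1 km", "1-100 km", "100-750 km", "750-1000 km", ">1000 km")


@dataclass
class CloneGroup:
    """Isolates sharing one multilocus genotype at all 12 loci."""

    clone_id: int
    genotype_key: str
    members: List[str]
    wineries: Set[str] = field(default_factory=set)
    vintages: Tuple[int, ...] = ()
    countries: Set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)


def find_clone_groups(table: IsolateTable) -> List[CloneGroup]:
    """Partition complete-genotype isolates into clone groups (size >= 2).

    Isolates with one or more missing loci cannot satisfy strict 12-locus
    identity; they are excluded (counted in a warning) and effectively
    remain singletons, as do unique complete genotypes.  Groups are sorted
    by descending size, then genotype key, and numbered from 1.
    """
    buckets: Dict[str, List] = {}
    n_excluded = 0
    for rec in table:
        if not genotype_is_complete(rec.genotype):
            n_excluded += 1
            continue
        key = genotype_key(rec.genotype, table.panel)
        buckets.setdefault(key, []).append(rec)
    if n_excluded:
        logger.warning(
            "%d isolates with missing loci excluded from clone grouping "
            "(kept as singletons)", n_excluded,
        )
    multi = [(key, recs) for key, recs in buckets.items() if len(recs) >= 2]
    multi.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    groups = []
    for i, (key, recs) in enumerate(multi, start=1):
        groups.append(
            CloneGroup(
                clone_id=i,
                genotype_key=key,
                members=[r.strain_id for r in recs],
                wineries={r.winery for r in recs if r.winery},
                vintages=tuple(sorted({r.vintage_year for r in recs
                                       if r.vintage_year is not None})),
                countries={r.country for r in recs if r.country},
            )
        )
    return groups


@dataclass(frozen=True)
class PersistenceRecord:
    """One clone re-isolated in one winery over >= 2 distinct vintages."""

    winery: str
    clone_id: int
    vintages: Tuple[int, ...]

    @property
    def interval_years(self) -> int:
        return self.vintages[-1] - self.vintages[0]


def winery_persistence(
    groups: Sequence[CloneGroup], table: IsolateTable
) -> List[PersistenceRecord]:
    """Per (winery, clone) with >= 2 distinct vintages: the sorted vintage
    list and the spanned interval (max - min years).  Members lacking a
    winery or vintage are skipped with a log message."""
    by_id = {rec.strain_id: rec for rec in table}
    records = []
    n_skipped = 0
    for group in groups:
        vintages_by_winery: Dict[str, Set[int]] = {}
        for sid in group.members:
            rec = by_id[sid]
            if rec.winery is None or rec.vintage_year is None:
                n_skipped += 1
                continue
            vintages_by_winery.setdefault(rec.winery, set()).add(rec.vintage_year)
        for winery, vintages in sorted(vintages_by_winery.items()):
            if len(vintages) >= 2:
                records.append(
                    PersistenceRecord(winery, group.clone_id, tuple(sorted(vintages)))
                )
    if n_skipped:
        logger.info("%d clone members lacked winery or vintage and were skipped",
                    n_skipped)
    records.sort(key=lambda r: (-r.interval_years, r.winery, r.clone_id))
    return records


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a sphere of radius 6371.0088 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise GenotypeError(f"latitude {lat} out of range")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise GenotypeError(f"longitude {lon} out of range")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def clone_pair_distances(
    groups: Sequence[CloneGroup], table: IsolateTable
) -> List[Tuple[int, float]]:
    """Great-circle distance for every unordered member pair of each clone.

    All pairs enter, including co-located isolates from the same wine
    sample (which pull the distribution toward zero — deliberately, so the
    local fraction is read against the full pair set).  Pairs with a
    missing coordinate are skipped with a log message.
    """
    by_id = {rec.strain_id: rec for rec in table}
    out = []
    n_skipped = 0
    for group in groups:
        members = [by_id[sid] for sid in group.members]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if not (a.has_coordinates() and b.has_coordinates()):
                    n_skipped += 1
                    continue
                out.append(
                    (group.clone_id,
                     haversine_km(a.latitude, a.longitude, b.latitude, b.longitude))
                )
    if n_skipped:
        logger.info("%d clone pairs lacked coordinates and were skipped", n_skipped)
    return out


@dataclass
class DistanceClassDistribution:
    """Counts/fractions of clone pairs per distance class."""

    counts: Tuple[int, ...]
    labels: Tuple[str, ...] = DISTANCE_CLASS_LABELS

    @property
    def n_pairs(self) -> int:
        return sum(self.counts)

    @property
    def fractions(self) -> Tuple[float, ...]:
        n = self.n_pairs
        if n == 0:
            return tuple(0.0 for _ in self.counts)
        return tuple(c / n for c in self.counts)

    @property
    def local_fraction(self) -> float:
        """Fraction of pairs under 100 km ('local clone pairs')."""
        n = self.n_pairs
        return (self.counts[0] + self.counts[1]) / n if n else 0.0

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "counts": dict(zip(self.labels, self.counts)),
            "fractions": dict(zip(self.labels, self.fractions)),
            "local_fraction": self.local_fraction,
        }


def bin_distances(pairs: Sequence[float]) -> DistanceClassDistribution:
    """Bin pair distances (km) into the half-open distance classes."""
    counts = [0] * (len(DISTANCE_CLASS_EDGES) - 1)
    for km in pairs:
        for k in range(len(counts)):
            if DISTANCE_CLASS_EDGES[k] <= km < DISTANCE_CLASS_EDGES[k + 1]:
                counts[k] += 1
                break
    if not pairs:
        logger.warning("no clone pairs to bin; distribution is all-zero")
    return DistanceClassDistribution(tuple(counts))


def region_group_distribution(table: IsolateTable, by: str = "region") -> pd.DataFrame:
    """Contingency table of isolates per (area x genetic group), with
    per-area fractions; *by* is ``"region"`` or ``"country"``."""
    if by not in ("region", "country"):
        raise ValueError("by must be 'region' or 'country'")
    rows = [
        {"area": getattr(rec, by), "group": rec.group_label}
        for rec in table
        if getattr(rec, by) and rec.group_label
    ]
    if not rows:
        return pd.DataFrame(columns=["area", "group", "count", "fraction"])
    df = pd.DataFrame(rows)
    counts = df.groupby(["area", "group"]).size().rename("count").reset_index()
    totals = counts.groupby("area")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts.sort_values(["area", "group"]).reset_index(drop=True)


@dataclass
class SampleDiversitySummary:
    """Per-sample genetic heterogeneity for samples with enough isolates."""

    per_sample: pd.DataFrame  # sample_id, n_isolates, n_groups, n_genotypes
    min_isolates: int

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    @property
    def n_multi_group(self) -> int:
        """Samples harbouring isolates from >= 2 genetic groups."""
        return int((self.per_sample["n_groups"] >= 2).sum())


def sample_group_diversity(
    table: IsolateTable, min_isolates: int = 5
) -> SampleDiversitySummary:
    """For each wine sample with >= *min_isolates* isolates, the number of
    distinct genetic groups and genotypes found within it."""
    by_sample: Dict[str, List] = {}
    for rec in table:
        if rec.sample_id:
            by_sample.setdefault(rec.sample_id, []).append(rec)
    rows = []
    for sample_id, recs in sorted(by_sample.items()):
        if len(recs) < min_isolates:
            continue
        groups = {r.group_label for r in recs if r.group_label}
        keys = {genotype_key(r.genotype, table.panel) for r in recs}
        rows.append(
            {
                "sample_id": sample_id,
                "n_isolates": len(recs),
                "n_groups": len(groups),
                "n_genotypes": len(keys),
            }
        )
    df = pd.DataFrame(rows, columns=["sample_id", "n_isolates", "n_groups", "n_genotypes"])
    return SampleDiversitySummary(df, min_isolates)


@dataclass(frozen=True)
class VintageBin:
    """Inclusive 20-year vintage interval, e.g. 1981-2000."""

    start_year: int
    end_year: int

    @property
    def label(self) -> str:
        return f"{self.start_year}-{self.end_year}"


def vintage_bin(year: int) -> VintageBin:
    """20-year bin of a vintage, anchored so 1981-2000 and 2001-2020 are bins."""
    if not 1800 <= year <= 2100:
        raise GenotypeError(f"implausible vintage year {year}")
    start = 2001 + 20 * math.floor((year - 2001) / 20)
    return VintageBin(start, start + 19)


def temporal_group_proportions(
    table: IsolateTable, n_boot: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Per vintage bin: fraction of isolates in each genetic group, with
    95% percentile-bootstrap CIs from resampling isolates within the bin.

    Isolates without a vintage or group label are skipped; empty bins are
    omitted.  Columns: bin, bin_start, group, n_bin, count, proportion,
    ci_low, ci_high.
    """
    eligible = [rec for rec in table if rec.vintage_year is not None and rec.group_label]
    by_bin: Dict[VintageBin, List] = {}
    for rec in eligible:
        by_bin.setdefault(vintage_bin(rec.vintage_year), []).append(rec)

    rng = np.random.default_rng(seed)
    rows = []
    for vb in sorted(by_bin, key=lambda b: b.start_year):
        recs = by_bin[vb]
        labels = np.array([r.group_label for r in recs])
        groups = sorted(set(labels))
        n = len(labels)
        boot_props = {g: [] for g in groups}
        for _ in range(n_boot):
            resample = labels[rng.integers(0, n, size=n)]
            for g in groups:
                boot_props[g].append((resample == g).mean())
        for g in groups:
            count = int((labels == g).sum())
            lo, hi = np.percentile(boot_props[g], [2.5, 97.5])
            rows.append(
                {
                    "bin": vb.label,
                    "bin_start": vb.start_year,
                    "group": g,
                    "n_bin": n,
                    "count": count,
                    "proportion": count / n,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["bin", "bin_start", "group", "n_bin", "count",
                 "proportion", "ci_low", "ci_high"],
    )


def plot_distance_classes(dist: DistanceClassDistribution, path) -> None:
    """Bar chart of the clone-pair distance-class fractions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(dist.labels, [100 * f for f in dist.fractions])
    ax.set_ylabel("% of clone pairs")
    ax.set_xlabel("distance class")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_temporal_proportions(df: pd.DataFrame, path) -> None:
    """Grouped bars of per-bin group proportions with bootstrap error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = list(dict.fromkeys(df["bin"]))
    groups = sorted(df["group"].unique())
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    for gi, g in enumerate(groups):
        sub = df[df["group"] == g].set_index("bin")
        xs, ys, errs = [], [], []
        for bi, b in enumerate(bins):
            if b in sub.index:
                row = sub.loc[b]
                xs.append(bi + gi * width)
                ys.append(row["proportion"])
                errs.append(
                    [row["proportion"] - row["ci_low"], row["ci_high"] - row["proportion"]]
                )
        if xs:
            ax.bar(xs, ys, width=width,
                   yerr=np.array(errs).T if errs else None, capsize=2, label=g)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(bins))])
    ax.set_xticklabels(bins, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("proportion of isolates")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
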