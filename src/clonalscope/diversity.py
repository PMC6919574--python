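"""Clonal diversity statistics per genetic group, with bootstrap CIs.

Diversity is measured on the multilocus-genotype frequency spectrum of
each group: richness R (distinct genotypes), Shannon's index H (natural
log), Shannon evenness H / ln R, the inverse Simpson index D = 1 / sum p^2
and Simpson equitability D / R.  All estimators are the plug-in
(maximum-likelihood) forms with no small-sample correction; 95% confidence
intervals come from a percentile bootstrap resampling isolates with
replacement within the group (100 replicates by default).

Groups with a single isolate are reported "NR" (not relevant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotype_io import GenotypeError, IsolateTable, genotype_key

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeFrequencySpectrum",
    "frequency_spectrum",
    "shannon_index",
    "shannon_evenness",
    "inverse_simpson",
    "simpson_equitability",
    "bootstrap_ci",
    "diversity_report",
    "write_diversity_report",
]


@dataclass
class GenotypeFrequencySpectrum:
    """Genotype -> isolate-count spectrum for one genetic group."""

    group_name: str
    counts: Dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)

    def proportions(self) -> np.ndarray:
        c = np.array(list(self.counts.values()), dtype=float)
        return c / c.sum()


def frequency_spectrum(table: IsolateTable, group: str) -> GenotypeFrequencySpectrum:
    """Count isolates per canonical genotype key within *group*."""
    counts: Dict[str, int] = {}
    for rec in table:
        if rec.group_label != group:
            continue
        key = genotype_key(rec.genotype, table.panel)
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise GenotypeError(f"group {group!r} has no isolates")
    return GenotypeFrequencySpectrum(group, counts)


def shannon_index(s: GenotypeFrequencySpectrum) -> float:
    """Shannon diversity H = -sum p ln p (nats)."""
    p = s.proportions()
    return float(-(p * np.log(p)).sum())


def shannon_evenness(H: float, R: int) -> Optional[float]:
    """Shannon equitability (evenness) E_H = H / ln R; undefined for R = 1."""
    if R < 2:
        logger.warning("evenness undefined for a single genotype (R=%d)", R)
        return None
    return H / float(np.log(R))


def inverse_simpson(s: GenotypeFrequencySpectrum) -> float:
    """Inverse Simpson index D = 1 / sum p^2 (effective genotype number)."""
    p = s.proportions()
    return float(1.0 / (p**2).sum())


def simpson_equitability(D: float, R: int) -> float:
    """Simpson equitability E_D = D / R."""
    return D / R


def _index_from_counts(counts: np.ndarray, which: str) -> Optional[float]:
    p = counts / counts.sum()
    R = len(counts)
    if which == "richness":
        return float(R)
    if which == "shannon":
        return float(-(p * np.log(p)).sum())
    if which == "inverse_simpson":
        return float(1.0 / (p**2).sum())
    if which == "shannon_evenness":
        if R < 2:
            return None
        return float(-(p * np.log(p)).sum() / np.log(R))
    if which == "simpson_equitability":
        return float(1.0 / (p**2).sum() / R)
    raise ValueError(f"unknown statistic {which!r}")


STATISTICS = (
    "richness",
    "shannon",
    "shannon_evenness",
    "inverse_simpson",
    "simpson_equitability",
)


def bootstrap_ci(
    table: IsolateTable,
    group: str,
    statistic: str,
    n_boot: int = 100,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile-bootstrap 95% CI for one diversity statistic.

    Isolates (not genotypes) are resampled with replacement within the
    group; the 2.5th/97.5th percentiles of the replicate statistics are
    returned.  The observed value may coincide with a bound (e.g. when the
    observed spectrum is already the most diverse reachable one).
    """
    spectrum = frequency_spectrum(table, group)
    keys = list(spectrum.counts)
    # expand to one entry per isolate, as integer codes
    codes = np.repeat(np.arange(len(keys)), [spectrum.counts[k] for k in keys])
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        resample = rng.choice(codes, size=codes.size, replace=True)
        counts = np.bincount(resample)
        counts = counts[counts > 0].astype(float)
        v = _index_from_counts(counts, statistic)
        if v is not None:
            values.append(v)
    if not values:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def diversity_report(
    table: IsolateTable,
    n_boot: int = 100,
    seed: int = 0,
    group_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-group diversity table: n, richness, H, evenness, D, equitability
    and their bootstrap 95% CIs.

    Groups with a single isolate get NaN indices (rendered "NR" on write).
    Row order follows *group_order* when given (e.g. reference-panel
    order), otherwise first appearance in the table.
    """
    seen = []
    for rec in table:
        if rec.group_label and rec.group_label not in seen:
            seen.append(rec.group_label)
    if group_order is not None:
        ordered = [g for g in group_order if g in seen]
        ordered += [g for g in seen if g not in ordered]
    else:
        ordered = seen

    rows = []
    for gi, group in enumerate(ordered):
        s = frequency_spectrum(table, group)
        row: Dict[str, object] = {
            "group": group,
            "n_isolates": s.n,
            "richness": s.richness,
        }
        if s.n < 2:
            for stat in ("shannon", "shannon_evenness", "inverse_simpson",
                         "simpson_equitability"):
                row[stat] = np.nan
                row[f"{stat}_ci_low"] = np.nan
                row[f"{stat}_ci_high"] = np.nan
        else:
            H = shannon_index(s)
            D = inverse_simpson(s)
            row["shannon"] = H
            row["shannon_evenness"] = shannon_evenness(H, s.richness)
            row["inverse_simpson"] = D
            row["simpson_equitability"] = simpson_equitability(D, s.richness)
            for stat in ("shannon", "shannon_evenness", "inverse_simpson",
                         "simpson_equitability"):
                lo, hi = bootstrap_ci(table, group, stat, n_boot=n_boot,
                                      seed=seed + gi)
                row[f"{stat}_ci_low"] = lo
                row[f"{stat}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def write_diversity_report(report: pd.DataFrame, path) -> None:
    """Write the report CSV, 3 decimals, NaN rendered as ``NR``."""
    out = report.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(3)
    out.to_csv(path, index=False, na_rep="NR")
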