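"""Data model and I/O for multilocus microsatellite genotype tables.

A genotype here is codominant microsatellite data: at each of 12 loci an
isolate carries a *set* of integer allele sizes (fragment lengths in bp).
Diploids show at most 2 distinct alleles per locus, triploids at most 3;
an empty set marks a missing datum.  Tables are wide CSV, one row per
isolate, with provenance metadata (winery, sample, region, coordinates,
vintage and isolation year, microplate) followed by one column per locus
holding "/"-separated allele sizes.

The module also implements microplate normalization: fragment-sizing runs
spread over many 96-well plates drift by a few bp, so a control strain is
genotyped on every plate and each plate is shifted back onto the reference
plate, per locus, by the modal control-allele difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from collections import Counter
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ALLELE_SEPARATOR",
    "MISSING_TOKENS",
    "KEY_MISSING_TOKEN",
    "MAX_ALLELES_PER_LOCUS",
    "METADATA_COLUMNS",
    "DEFAULT_PANEL",
    "AlleleSet",
    "MultilocusGenotype",
    "LocusPanel",
    "IsolateRecord",
    "IsolateTable",
    "PlateControl",
    "GenotypeError",
    "parse_allele_field",
    "format_allele_field",
    "make_genotype",
    "genotype_key",
    "genotype_is_complete",
    "read_isolates",
    "write_isolates",
    "missing_fraction",
    "plate_offsets",
    "normalize_plates",
    "drop_plate_controls",
]

#: separator between allele sizes inside one CSV cell
ALLELE_SEPARATOR = "/"
#: cell contents treated as a missing datum
MISSING_TOKENS = ("", "NA")
#: token standing for a missing locus inside a canonical genotype key
KEY_MISSING_TOKEN = "."
#: codominant markers in this organism show at most 3 alleles (triploids)
MAX_ALLELES_PER_LOCUS = 3

#: metadata columns of an isolate CSV, in canonical order
METADATA_COLUMNS = (
    "strain_id",
    "winery",
    "sample_id",
    "region",
    "country",
    "latitude",
    "longitude",
    "vintage_year",
    "isolation_year",
    "plate_id",
    "group_label",
)

# Type aliases: an allele set is a frozenset of fragment sizes (bp); a
# multilocus genotype maps every panel locus to one (possibly empty) set.
AlleleSet = FrozenSet[int]
MultilocusGenotype = Dict[str, AlleleSet]


class GenotypeError(ValueError):
    """Raised for malformed allele fields, tables or genotypes."""


@dataclass(frozen=True)
class LocusPanel:
    """Ordered panel of the 12 microsatellite loci used for genotyping."""

    names: tuple

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) != 12:
            raise GenotypeError(f"locus panel must have exactly 12 loci, got {len(names)}")
        if len(set(names)) != len(names):
            raise GenotypeError("locus panel names must be unique")

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


#: default locus names (synthetic panel labels)
DEFAULT_PANEL = LocusPanel(tuple(f"Bbr{i:02d}" for i in range(1, 13)))


def parse_allele_field(raw: str, *, where: str = "") -> AlleleSet:
    """Parse one CSV locus cell into a set of integer allele sizes.

    ``""`` and ``"NA"`` mean missing; sizes are "/"-separated; duplicate
    sizes collapse.  More than 3 distinct sizes violates the ploidy bound.
    """
    text = raw.strip() if isinstance(raw, str) else ""
    if text in MISSING_TOKENS:
        return frozenset()
    alleles = set()
    for token in text.split(ALLELE_SEPARATOR):
        token = token.strip()
        try:
            size = int(token)
        except ValueError:
            raise GenotypeError(f"non-integer allele size {token!r}{where}") from None
        if size <= 0:
            raise GenotypeError(f"allele size must be positive, got {size}{where}")
        alleles.add(size)
    if len(alleles) > MAX_ALLELES_PER_LOCUS:
        raise GenotypeError(
            f"{len(alleles)} distinct alleles exceed the ploidy bound of "
            f"{MAX_ALLELES_PER_LOCUS}{where}"
        )
    return frozenset(alleles)


def format_allele_field(alleles: AlleleSet) -> str:
    """Inverse of :func:`parse_allele_field`; missing becomes ``""``."""
    return ALLELE_SEPARATOR.join(str(a) for a in sorted(alleles))


def make_genotype(panel: LocusPanel, alleles: Mapping[str, Iterable[int]]) -> MultilocusGenotype:
    """Build a genotype conforming to *panel* (absent loci become missing)."""
    extra = set(alleles) - set(panel.names)
    if extra:
        raise GenotypeError(f"loci not in panel: {sorted(extra)}")
    g: MultilocusGenotype = {}
    for locus in panel:
        aset = frozenset(int(a) for a in alleles.get(locus, ()))
        if len(aset) > MAX_ALLELES_PER_LOCUS:
            raise GenotypeError(f"locus {locus}: more than {MAX_ALLELES_PER_LOCUS} alleles")
        if any(a <= 0 for a in aset):
            raise GenotypeError(f"locus {locus}: allele sizes must be positive")
        g[locus] = aset
    return g


def genotype_key(g: MultilocusGenotype, panel: LocusPanel) -> str:
    """Canonical string identity of a genotype: loci in panel order,
    alleles ascending.  Equal genotypes map to equal keys and vice versa."""
    parts = []
    for locus in panel:
        alleles = g[locus]
        parts.append(format_allele_field(alleles) if alleles else KEY_MISSING_TOKEN)
    return ";".join(parts)


def genotype_is_complete(g: MultilocusGenotype) -> bool:
    """True when no locus is missing."""
    return all(g[locus] for locus in g)


@dataclass
class IsolateRecord:
    """One genotyped isolate with its provenance metadata.

    ``vintage_year`` is the year the wine was produced; ``isolation_year``
    the year the isolate was cultured from it — old vintages are often
    sampled decades later, so the two are kept distinct.
    """

    strain_id: str
    genotype: MultilocusGenotype
    winery: Optional[str] = None
    sample_id: Optional[str] = None
    region: Optional[str] = None
    country: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    vintage_year: Optional[int] = None
    isolation_year: Optional[int] = None
    plate_id: Optional[str] = None
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise GenotypeError(f"{self.strain_id}: latitude {self.latitude} out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise GenotypeError(f"{self.strain_id}: longitude {self.longitude} out of range")
        if (
            self.vintage_year is not None
            and self.isolation_year is not None
            and self.vintage_year > self.isolation_year
        ):
            raise GenotypeError(
                f"{self.strain_id}: vintage {self.vintage_year} later than "
                f"isolation year {self.isolation_year}"
            )

    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass
class IsolateTable:
    """Ordered collection of isolates sharing one locus panel."""

    panel: LocusPanel
    records: list = field(default_factory=list)
    imputed: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.strain_id in seen:
                raise GenotypeError(f"duplicate strain_id {rec.strain_id!r}")
            seen.add(rec.strain_id)
            if set(rec.genotype) != set(self.panel.names):
                raise GenotypeError(
                    f"{rec.strain_id}: genotype loci do not match the panel"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IsolateRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IsolateTable):
            return NotImplemented
        return self.panel == other.panel and self.records == other.records

    def get(self, strain_id: str) -> IsolateRecord:
        for rec in self.records:
            if rec.strain_id == strain_id:
                return rec
        raise KeyError(strain_id)

    def strain_ids(self) -> list:
        return [rec.strain_id for rec in self.records]

    def subset(self, strain_ids: Sequence[str]) -> "IsolateTable":
        wanted = set(strain_ids)
        return IsolateTable(
            self.panel,
            [rec for rec in self.records if rec.strain_id in wanted],
            imputed=self.imputed,
        )


@dataclass(frozen=True)
class PlateControl:
    """Control strain used to align fragment sizes across microplates.

    The control is genotyped once per plate; its row carries the plate's
    id and a strain id of either ``control_strain_id`` or
    ``"<control_strain_id>@<plate_id>"`` (replicate naming keeps strain
    ids unique within a table).
    """

    control_strain_id: str
    reference_plate_id: str


def _fmt_opt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_opt_float(text: str, where: str) -> Optional[float]:
    text = text.strip()
    if text in MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise GenotypeError(f"non-numeric value {text!r}{where}") from None


def _parse_opt_int(text: str, where: str) -> Optional[int]:
    text = text.strip()
    if text in MISSING_TOKENS:
        return None
    try:
        return int(float(text)) if "." in text else int(text)
    except ValueError:
        raise GenotypeError(f"non-integer value {text!r}{where}") from None


def read_isolates(path, panel: Optional[LocusPanel] = None) -> IsolateTable:
    """Read a wide isolate CSV into an :class:`IsolateTable`.

    The header must contain ``strain_id`` plus the 12 locus columns; other
    metadata columns are optional.  When *panel* is omitted, all header
    columns that are not metadata are taken as the locus panel.  The count
    and fraction of missing allele cells are logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "strain_id" not in df.columns:
        raise GenotypeError("isolate CSV must contain a 'strain_id' column")
    if panel is None:
        loci = [c for c in df.columns if c not in METADATA_COLUMNS]
        panel = LocusPanel(tuple(loci))
    else:
        missing_cols = [c for c in panel.names if c not in df.columns]
        if missing_cols:
            raise GenotypeError(f"missing locus columns: {missing_cols}")

    records = []
    n_missing_cells = 0
    for idx, row in df.iterrows():
        sid = row["strain_id"].strip()
        genotype: MultilocusGenotype = {}
        for locus in panel:
            where = f" (row {idx + 2}, column {locus})"
            aset = parse_allele_field(row[locus], where=where)
            if not aset:
                n_missing_cells += 1
            genotype[locus] = aset
        where = f" (row {idx + 2})"
        rec = IsolateRecord(
            strain_id=sid,
            genotype=genotype,
            winery=row.get("winery", "").strip() or None,
            sample_id=row.get("sample_id", "").strip() or None,
            region=row.get("region", "").strip() or None,
            country=row.get("country", "").strip() or None,
            latitude=_parse_opt_float(row.get("latitude", ""), where),
            longitude=_parse_opt_float(row.get("longitude", ""), where),
            vintage_year=_parse_opt_int(row.get("vintage_year", ""), where),
            isolation_year=_parse_opt_int(row.get("isolation_year", ""), where),
            plate_id=row.get("plate_id", "").strip() or None,
            group_label=row.get("group_label", "").strip() or None,
        )
        records.append(rec)

    table = IsolateTable(panel, records)
    n_cells = max(len(records) * len(panel), 1)
    logger.info(
        "read %d isolates from %s; %d missing allele cells (%.1f%%)",
        len(records), path, n_missing_cells, 100.0 * n_missing_cells / n_cells,
    )
    return table


def write_isolates(table: IsolateTable, path) -> None:
    """Write *table* as CSV; inverse of :func:`read_isolates`.

    Missing allele sets become empty cells, missing metadata empty strings;
    the output is byte-stable for a given table.
    """
    rows = []
    for rec in table:
        row = {
            "strain_id": rec.strain_id,
            "winery": _fmt_opt(rec.winery),
            "sample_id": _fmt_opt(rec.sample_id),
            "region": _fmt_opt(rec.region),
            "country": _fmt_opt(rec.country),
            "latitude": _fmt_opt(rec.latitude),
            "longitude": _fmt_opt(rec.longitude),
            "vintage_year": _fmt_opt(rec.vintage_year),
            "isolation_year": _fmt_opt(rec.isolation_year),
            "plate_id": _fmt_opt(rec.plate_id),
            "group_label": _fmt_opt(rec.group_label),
        }
        for locus in table.panel:
            row[locus] = format_allele_field(rec.genotype[locus])
        rows.append(row)
    columns = list(METADATA_COLUMNS) + list(table.panel.names)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def missing_fraction(table: IsolateTable) -> float:
    """Fraction of strain x locus cells that are missing."""
    if not len(table):
        return 0.0
    n_missing = sum(1 for rec in table for locus in table.panel if not rec.genotype[locus])
    return n_missing / (len(table) * len(table.panel))


def _is_control_record(rec: IsolateRecord, control_strain_id: str) -> bool:
    return (
        rec.strain_id == control_strain_id
        or rec.strain_id.split("@", 1)[0] == control_strain_id
    )


def _control_by_plate(table: IsolateTable, control: PlateControl):
    by_plate = {}
    for rec in table:
        if _is_control_record(rec, control.control_strain_id) and rec.plate_id:
            by_plate[rec.plate_id] = rec
    return by_plate


def plate_offsets(table: IsolateTable, control: PlateControl):
    """Per (plate, locus) integer size offset relative to the reference plate.

    The offset is the modal element-wise difference between the plate's
    sorted control alleles and the reference plate's sorted control alleles.
    A locus where the control shows a different allele count on the two
    plates cannot be aligned: it is skipped with a warning (offset omitted).
    """
    controls = _control_by_plate(table, control)
    if control.reference_plate_id not in controls:
        raise GenotypeError(
            f"control {control.control_strain_id!r} absent from reference "
            f"plate {control.reference_plate_id!r}"
        )
    reference = controls[control.reference_plate_id]

    plates = sorted({rec.plate_id for rec in table if rec.plate_id})
    absent = [p for p in plates if p not in controls]
    if absent:
        raise GenotypeError(
            f"control {control.control_strain_id!r} absent from plates: {absent}"
        )

    offsets = {}
    for plate in plates:
        ctrl = controls[plate]
        for locus in table.panel:
            ref_alleles = sorted(reference.genotype[locus])
            plate_alleles = sorted(ctrl.genotype[locus])
            if not ref_alleles or not plate_alleles:
                continue
            if len(ref_alleles) != len(plate_alleles):
                logger.warning(
                    "plate %s locus %s: control allele count mismatch "
                    "(%d vs %d on reference); locus skipped",
                    plate, locus, len(plate_alleles), len(ref_alleles),
                )
                continue
            diffs = [p - r for p, r in zip(plate_alleles, ref_alleles)]
            counts = Counter(diffs)
            top = max(counts.values())
            # deterministic tie-break: smallest-magnitude, then smallest offset
            offset = min((d for d, c in counts.items() if c == top), key=lambda d: (abs(d), d))
            offsets[(plate, locus)] = offset
    return offsets


def normalize_plates(
    table: IsolateTable, control: PlateControl, *, check_only: bool = False
) -> IsolateTable:
    """Align all plates onto the reference plate by subtracting per-plate,
    per-locus control offsets from every allele.

    With ``check_only=True`` the offsets are computed and logged but the
    table is returned unchanged.  Missing cells stay missing; rows without
    a plate id are left untouched.  Idempotent: a normalized table has all
    offsets 0.
    """
    offsets = plate_offsets(table, control)
    nonzero = {k: v for k, v in offsets.items() if v}
    if nonzero:
        logger.info("non-zero plate offsets detected: %s", nonzero)
    if check_only:
        return table

    records = []
    for rec in table:
        genotype = rec.genotype
        if rec.plate_id is not None:
            shifted: MultilocusGenotype = {}
            for locus in table.panel:
                off = offsets.get((rec.plate_id, locus), 0)
                alleles = rec.genotype[locus]
                shifted[locus] = frozenset(a - off for a in alleles) if off else alleles
            genotype = shifted
        records.append(replace(rec, genotype=genotype))
    return IsolateTable(table.panel, records, imputed=table.imputed)


def drop_plate_controls(table: IsolateTable, control: PlateControl) -> IsolateTable:
    """Remove per-plate control replicate rows before population analyses
    (the replicated control would otherwise masquerade as a clone group)."""
    records = [rec for rec in table if not _is_control_record(rec, control.control_strain_id)]
    return IsolateTable(table.panel, records, imputed=table.imputed)
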