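"""Shared fixtures: small hand-built genotype tables and builders."""

from __future__ import annotations

import pytest

from clonalscope.genotype_io import (
    DEFAULT_PANEL,
    IsolateRecord,
    IsolateTable,
    make_genotype,
)


@pytest.fixture(scope="session")
def panel():
    return DEFAULT_PANEL


def make_record(panel, strain_id, allele_lists, **meta):
    """Build an IsolateRecord from a list of per-locus allele tuples
    (shorter lists leave trailing loci missing; None = missing locus)."""
    alleles = {}
    for locus, entry in zip(panel, allele_lists):
        if entry is not None:
            alleles[locus] = entry
    return IsolateRecord(strain_id=strain_id,
                         genotype=make_genotype(panel, alleles), **meta)


def make_table(panel, rows, **common_meta):
    """rows: list of (strain_id, allele_lists) or (strain_id, allele_lists,
    meta-dict) entries."""
    records = []
    for row in rows:
        sid, allele_lists = row[0], row[1]
        meta = dict(common_meta)
        if len(row) > 2:
            meta.update(row[2])
        records.append(make_record(panel, sid, allele_lists, **meta))
    return IsolateTable(panel, records)


@pytest.fixture
def uniform_diploid_lists():
    """12 diploid loci, alleles well separated within each locus."""
    return [(100 + 10 * i, 150 + 10 * i) for i in range(12)]


@pytest.fixture
def trio_table(panel, uniform_diploid_lists):
    """Three isolates: s1 == s2 at all loci, s3 differs at the first locus."""
    other = list(uniform_diploid_lists)
    other[0] = (102, 150)
    return make_table(
        panel,
        [
            ("s1", uniform_diploid_lists),
            ("s2", uniform_diploid_lists),
            ("s3", other),
        ],
    )
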