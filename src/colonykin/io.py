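"""Read and write multilocus genotype tables.

Three dialects are supported:

``csv-wide``
    One row per individual; one column per locus holding ``a/b`` (diploid),
    ``a`` (haploid) or ``0`` (missing).
``csv-long``
    One row per (individual, locus) with explicit ``allele1``/``allele2``
    columns; metadata repeated on every row.
``genepop``
    The classic population-genetics text format (title line, one locus name
    per line, ``Pop`` separators, fixed-width numeric allele codes, zeros for
    missing).  Haploid males must be exported as homozygous pseudo-diploids
    (`haploids_as_homozygous=True`); the native CSV dialects keep true ploidy.

All writers are byte-stable for a fixed table (fixed column order, ``\\n``
newlines), so re-serialisation of an unchanged table is the identity.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import (
    MISSING,
    META_COLUMNS,
    GenotypeFormatError,
    GenotypeTable,
    ValidationReport,
    _normalise_call,
)

DIALECTS = ("csv-wide", "csv-long", "genepop")
_GENEPOP_TITLE = "colonykin genotype export"


def read_genotype_table(
    path: str | Path,
    dialect: str,
    min_typed_loci: int = 10,
    drop_flagged: bool = False,
) -> tuple[GenotypeTable, ValidationReport]:
    """Read and validate a genotype table.

    Individuals below the minimum-typed-loci threshold (default 10, after the
    study design of requiring at least 10 of 12 successful loci) are flagged
    in the returned :class:`ValidationReport`; they are only removed when
    ``drop_flagged`` is set.
    """
    path = Path(path)
    if dialect == "csv-wide":
        table = _read_csv_wide(path)
    elif dialect == "csv-long":
        table = _read_csv_long(path)
    elif dialect == "genepop":
        table = read_genepop(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    report = table.validate_coverage(min_typed_loci)
    if drop_flagged and report.flagged:
        keep = [i for i in table.ids if i not in set(report.flagged)]
        table = table.subset(keep)
    return table, report


def write_genotype_table(table: GenotypeTable, path: str | Path, dialect: str) -> None:
    path = Path(path)
    if dialect == "csv-wide":
        _write_csv_wide(table, path)
    elif dialect == "csv-long":
        _write_csv_long(table, path)
    elif dialect == "genepop":
        export_genepop(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# --------------------------------------------------------------------- csv-wide
def _format_call_wide(a: int, b: int, ploidy: int) -> str:
    if a == MISSING:
        return "0"
    if ploidy == 1:
        return str(a)
    return f"{a}/{b}"


def _parse_call_wide(text: str, ind: str, locus: str, ploidy: int):
    text = text.strip()
    if text in ("", "0", "0/0", "?"):
        return None
    parts = text.split("/")
    if len(parts) > 2:
        raise GenotypeFormatError(
            f"individual {ind!r}, locus {locus!r}: {len(parts)} alleles in one call"
        )
    if len(parts) == 1:
        if ploidy == 2:
            raise GenotypeFormatError(
                f"individual {ind!r}, locus {locus!r}: diploid call needs two alleles, got {text!r}"
            )
        return (int(parts[0]),)
    return (int(parts[0]), int(parts[1]))


def _write_csv_wide(table: GenotypeTable, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["id", *META_COLUMNS, *table.loci])
        for i, ind in enumerate(table.ids):
            row = [ind] + [str(table.meta.iloc[i][c]) for c in META_COLUMNS]
            ploidy = int(table.meta.iloc[i]["ploidy"])
            for l in range(len(table.loci)):
                a, b = table.alleles[i, l]
                row.append(_format_call_wide(int(a), int(b), ploidy))
            w.writerow(row)


def _read_csv_wide(path: Path) -> GenotypeTable:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise GenotypeFormatError(f"{path}: empty file")
    header = rows[0]
    expected_meta = ["id", *META_COLUMNS]
    if header[: len(expected_meta)] != expected_meta:
        raise GenotypeFormatError(
            f"{path}: csv-wide header must start with {expected_meta}, got {header[:5]}"
        )
    loci = header[len(expected_meta):]
    records = []
    for row in rows[1:]:
        if not row:
            continue
        ind, colony, site, caste, ploidy = row[:5]
        ploidy = int(ploidy)
        calls = {
            locus: _parse_call_wide(cell, ind, locus, ploidy)
            for locus, cell in zip(loci, row[5:])
        }
        records.append((ind, colony, site, caste, ploidy, calls))
    return GenotypeTable.from_records(records, loci=loci)


# --------------------------------------------------------------------- csv-long
def _write_csv_long(table: GenotypeTable, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["id", *META_COLUMNS, "locus", "allele1", "allele2"])
        for i, ind in enumerate(table.ids):
            meta = [str(table.meta.iloc[i][c]) for c in META_COLUMNS]
            ploidy = int(table.meta.iloc[i]["ploidy"])
            for l, locus in enumerate(table.loci):
                a, b = (int(x) for x in table.alleles[i, l])
                if ploidy == 1 and a != MISSING:
                    w.writerow([ind, *meta, locus, a, ""])
                else:
                    w.writerow([ind, *meta, locus, a, b])


def _read_csv_long(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"id": str, "colony": str, "site": str, "caste": str})
    needed = {"id", *META_COLUMNS, "locus", "allele1"}
    if not needed.issubset(df.columns):
        raise GenotypeFormatError(f"{path}: csv-long needs columns {sorted(needed)}")
    loci = list(dict.fromkeys(df["locus"]))
    records = []
    for ind, grp in df.groupby("id", sort=False):
        meta = grp.iloc[0]
        ploidy = int(meta["ploidy"])
        calls = {}
        for _, row in grp.iterrows():
            a1 = int(row["allele1"])
            a2 = row.get("allele2")
            if a2 is None or (isinstance(a2, float) and np.isnan(a2)) or str(a2).strip() == "":
                call = None if a1 == MISSING else (a1,)
            else:
                a2 = int(float(a2))
                call = None if a1 == MISSING and a2 == MISSING else (a1, a2)
            calls[str(row["locus"])] = call
        records.append((ind, meta["colony"], meta["site"], meta["caste"], ploidy, calls))
    return GenotypeTable.from_records(records, loci=loci)


# ---------------------------------------------------------------------- genepop
def _genepop_code_width(table: GenotypeTable) -> int:
    biggest = int(table.alleles.max(initial=0))
    if biggest > 999:
        raise GenotypeFormatError(
            f"allele label {biggest} too large for Genepop (3-digit codes max 999)"
        )
    return 3 if biggest > 99 else 2


def export_genepop(
    table: GenotypeTable,
    path: str | Path,
    haploids_as_homozygous: bool = True,
    title: str = _GENEPOP_TITLE,
) -> None:
    """Write a Genepop file with one ``Pop`` block per site.

    Genepop is a diploid-only format: haploid males are encoded as
    homozygous pseudo-diploids when ``haploids_as_homozygous`` is set,
    otherwise their presence is an error.  The individual label encodes
    ``site|colony|id`` so that a re-import reproduces the table's grouping
    (standard Genepop consumers ignore label content).
    """
    if not haploids_as_homozygous and (table.meta["ploidy"] == 1).any():
        raise GenotypeFormatError("Genepop is diploid-only; enable haploids_as_homozygous")
    width = _genepop_code_width(table)
    lines = [title]
    lines.extend(table.loci)
    for site in table.sites():
        lines.append("Pop")
        sub = table.filter(site=site)
        for i, ind in enumerate(sub.ids):
            colony = sub.meta.iloc[i]["colony"]
            codes = [
                f"{int(a):0{width}d}{int(b):0{width}d}" for a, b in sub.alleles[i]
            ]
            lines.append(f"{site}|{colony}|{ind} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop file (2- or 3-digit allele codes, auto-detected).

    Individuals come back as diploid workers unless the site|colony|id label
    convention written by :func:`export_genepop` is present, in which case
    grouping metadata is restored.  Unlabelled ``Pop`` blocks are named
    ``pop1``, ``pop2``, ...
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise GenotypeFormatError(f"{path}: not a Genepop file (too short)")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names: one per line, or a single comma-separated line
        loci.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenotypeFormatError(f"{path}: no 'Pop' line found")
    records = []
    pop_n = 0
    site = None
    for ln in lines[i:]:
        if ln.strip().lower() == "pop":
            pop_n += 1
            site = f"pop{pop_n}"
            continue
        if "," not in ln:
            raise GenotypeFormatError(f"{path}: malformed individual line {ln!r}")
        label, geno = ln.split(",", 1)
        label = label.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenotypeFormatError(
                f"{path}: individual {label!r} has {len(fields)} genotypes for {len(loci)} loci"
            )
        parts = label.split("|")
        if len(parts) == 3:
            site_name, colony, ind = parts
        elif len(parts) == 2:
            site_name, (colony, ind) = site, parts
        else:
            site_name, colony, ind = site, label, label
        calls = {}
        for locus, field in zip(loci, fields):
            if len(field) not in (4, 6):
                raise GenotypeFormatError(
                    f"{path}: individual {label!r}, locus {locus!r}: "
                    f"bad code width in {field!r}"
                )
            w = len(field) // 2
            a, b = int(field[:w]), int(field[w:])
            calls[locus] = None if a == MISSING and b == MISSING else (a, b)
        records.append((ind, colony, site_name or "pop1", "worker", 2, calls))
    return GenotypeTable.from_records(records, loci=loci)
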