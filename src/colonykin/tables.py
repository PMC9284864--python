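"""Multilocus genotype tables for social-insect colony genetics.

The :class:`GenotypeTable` is the container every analysis stage operates on:
individuals (workers, queens, haploid males) with colony/site metadata, typed
at an ordered set of codominant loci.  Allele identities are positive
integers (microsatellite-style labels); ``0`` encodes a missing call.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: allele code for a missing call
MISSING = 0
#: sentinel for an unobserved ("wildcard") queen allele in reconstructions
WILDCARD = -1

CASTES = ("worker", "queen", "male")
META_COLUMNS = ("colony", "site", "caste", "ploidy")


class GenotypeFormatError(ValueError):
    """A genotype call or table violates the format contract."""


@dataclass(frozen=True)
class ValidationReport:
    """Coverage validation: who fails the minimum-typed-loci rule.

    Flagged individuals are reported, never silently dropped; callers decide
    whether to apply a hard filter.
    """

    min_typed_loci: int
    flagged: tuple[str, ...]
    typed_counts: Mapping[str, int]
    messages: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flagged and not self.messages


def _normalise_call(ind: str, locus: str, call, ploidy: int) -> tuple[int, int]:
    """Validate one call and return it as a sorted (a, b) pair; (0, 0) = missing.

    Haploids are stored as a duplicated single allele; a heterozygous call on
    a haploid individual is a ploidy error.
    """
    if call is None:
        return (MISSING, MISSING)
    alleles = tuple(int(a) for a in (call if isinstance(call, (tuple, list)) else (call,)))
    if len(alleles) > 2:
        raise GenotypeFormatError(
            f"individual {ind!r}, locus {locus!r}: {len(alleles)} alleles in one call"
        )
    if len(alleles) == 1:
        alleles = (alleles[0], alleles[0])
    if any(a < 0 for a in alleles):
        raise GenotypeFormatError(
            f"individual {ind!r}, locus {locus!r}: negative allele label {alleles}"
        )
    if (alleles[0] == MISSING) != (alleles[1] == MISSING):
        raise GenotypeFormatError(
            f"individual {ind!r}, locus {locus!r}: half-missing call {alleles}"
        )
    if ploidy == 1 and alleles[0] != alleles[1]:
        raise GenotypeFormatError(
            f"individual {ind!r}, locus {locus!r}: haploid with heterozygous call {alleles}"
        )
    return (min(alleles), max(alleles))


class GenotypeTable:
    """Individuals x loci allele calls with colony/site/caste/ploidy metadata.

    Parameters
    ----------
    meta
        DataFrame indexed by individual id with columns
        ``colony, site, caste, ploidy``.
    loci
        Ordered locus identifiers.
    alleles
        ``(n_individuals, n_loci, 2)`` integer array of sorted allele pairs;
        ``(0, 0)`` marks a missing call.  Haploids duplicate their single
        allele.
    """

    def __init__(self, meta: pd.DataFrame, loci: Sequence[str], alleles: np.ndarray):
        meta = meta.copy()
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise GenotypeFormatError(f"metadata missing column {col!r}")
        if meta.index.has_duplicates:
            dupes = meta.index[meta.index.duplicated()].unique().tolist()
            raise GenotypeFormatError(f"duplicate individual ids: {dupes}")
        bad_caste = set(meta["caste"]) - set(CASTES)
        if bad_caste:
            raise GenotypeFormatError(f"unknown caste(s): {sorted(bad_caste)}")
        bad_ploidy = set(meta["ploidy"]) - {1, 2}
        if bad_ploidy:
            raise GenotypeFormatError(f"ploidy must be 1 or 2, got {sorted(bad_ploidy)}")
        alleles = np.asarray(alleles, dtype=np.int64)
        if alleles.shape != (len(meta), len(loci), 2):
            raise GenotypeFormatError(
                f"allele array shape {alleles.shape} != {(len(meta), len(loci), 2)}"
            )
        alleles = np.sort(alleles, axis=2)
        # re-validate invariants on the array form
        half_missing = (alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, l = np.argwhere(half_missing)[0]
            raise GenotypeFormatError(
                f"individual {meta.index[i]!r}, locus {loci[l]!r}: half-missing call"
            )
        haploid = (meta["ploidy"].to_numpy() == 1)
        het = alleles[:, :, 0] != alleles[:, :, 1]
        bad = haploid[:, None] & het
        if bad.any():
            i, l = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"individual {meta.index[i]!r}, locus {loci[l]!r}: "
                "haploid with heterozygous call"
            )
        self.meta = meta
        self.loci = list(loci)
        self.alleles = alleles
        self._index = {ind: i for i, ind in enumerate(meta.index)}

    # ------------------------------------------------------------------ build
    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        loci: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        """Build a table from ``(id, colony, site, caste, ploidy, calls)`` rows.

        ``calls`` maps locus -> allele pair / single allele / ``None``.
        Locus order is taken from ``loci`` or from the first record.
        """
        records = list(records)
        if loci is None:
            if not records:
                raise GenotypeFormatError("cannot infer loci from an empty record set")
            loci = list(records[0][5].keys())
        loci = list(loci)
        ids, meta_rows = [], []
        arr = np.zeros((len(records), len(loci), 2), dtype=np.int64)
        for r, (ind, colony, site, caste, ploidy, calls) in enumerate(records):
            ids.append(str(ind))
            meta_rows.append((str(colony), str(site), str(caste), int(ploidy)))
            for l, locus in enumerate(loci):
                arr[r, l] = _normalise_call(ind, locus, calls.get(locus), int(ploidy))
        meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS), index=pd.Index(ids, name="id"))
        return cls(meta, loci, arr)

    @classmethod
    def concat(cls, tables: Sequence["GenotypeTable"]) -> "GenotypeTable":
        if not tables:
            raise GenotypeFormatError("cannot concatenate zero tables")
        loci = tables[0].loci
        for t in tables[1:]:
            if t.loci != loci:
                raise GenotypeFormatError("locus order differs between tables")
        meta = pd.concat([t.meta for t in tables])
        alleles = np.concatenate([t.alleles for t in tables], axis=0)
        return cls(meta, loci, alleles)

    # ------------------------------------------------------------------ access
    @property
    def n_individuals(self) -> int:
        return len(self.meta)

    @property
    def ids(self) -> list[str]:
        return list(self.meta.index)

    def ploidy(self, ind: str) -> int:
        return int(self.meta.at[ind, "ploidy"])

    def call(self, ind: str, locus: str) -> tuple[int, ...] | None:
        """The call for one individual at one locus.

        Returns an unordered pair for diploids, a 1-tuple for haploids, or
        ``None`` if missing.
        """
        a, b = self.alleles[self._index[ind], self.loci.index(locus)]
        if a == MISSING:
            return None
        if self.ploidy(ind) == 1:
            return (int(a),)
        return (int(a), int(b))

    def genotype(self, ind: str, as_diploid: bool = False) -> dict[str, tuple[int, ...] | None]:
        """Full multilocus genotype as ``{locus: call}``.

        With ``as_diploid=True`` haploids are returned as homozygous
        pseudo-diploids (the convention used for relatedness estimation).
        """
        i = self._index[ind]
        hap = self.ploidy(ind) == 1 and not as_diploid
        out: dict[str, tuple[int, ...] | None] = {}
        for l, locus in enumerate(self.loci):
            a, b = self.alleles[i, l]
            if a == MISSING:
                out[locus] = None
            elif hap:
                out[locus] = (int(a),)
            else:
                out[locus] = (int(a), int(b))
        return out

    def typed_counts(self) -> pd.Series:
        """Number of non-missing loci per individual."""
        n = (self.alleles[:, :, 0] != MISSING).sum(axis=1)
        return pd.Series(n, index=self.meta.index, name="typed_loci")

    def validate_coverage(self, min_typed_loci: int = 10) -> ValidationReport:
        counts = self.typed_counts()
        flagged = tuple(counts.index[counts < min_typed_loci])
        return ValidationReport(
            min_typed_loci=min_typed_loci,
            flagged=flagged,
            typed_counts=dict(counts),
        )

    # ------------------------------------------------------------------ subset
    def subset(self, ids: Sequence[str]) -> "GenotypeTable":
        idx = [self._index[i] for i in ids]
        return GenotypeTable(self.meta.iloc[idx], self.loci, self.alleles[idx])

    def filter(
        self,
        caste: str | None = None,
        colony: str | None = None,
        site: str | None = None,
        ploidy: int | None = None,
    ) -> "GenotypeTable":
        mask = np.ones(self.n_individuals, dtype=bool)
        if caste is not None:
            mask &= (self.meta["caste"] == caste).to_numpy()
        if colony is not None:
            mask &= (self.meta["colony"] == colony).to_numpy()
        if site is not None:
            mask &= (self.meta["site"] == site).to_numpy()
        if ploidy is not None:
            mask &= (self.meta["ploidy"] == ploidy).to_numpy()
        return GenotypeTable(self.meta.loc[mask], self.loci, self.alleles[mask])

    def colonies(self) -> list[str]:
        """Colony ids in first-appearance order."""
        return list(dict.fromkeys(self.meta["colony"]))

    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.meta["site"]))

    # ------------------------------------------------------------------ compare
    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.loci == other.loci
            and self.meta.equals(other.meta)
            and np.array_equal(self.alleles, other.alleles)
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"GenotypeTable({self.n_individuals} individuals, {len(self.loci)} loci, "
            f"{len(self.colonies())} colonies, {len(self.sites())} sites)"
        )
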