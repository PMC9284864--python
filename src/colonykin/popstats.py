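"""Population-level statistics: heterozygosity, Weir-Cockerham F-statistics.

F-statistics follow the Weir & Cockerham (1984) variance-components
estimators (the ones Genepop reports): per allele and per locus the
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from sample sizes, allele
frequencies and heterozygote frequencies, then combined ratio-of-sums over
alleles and loci:

    theta (F_ST) = sum(a) / sum(a + b + c)
    f     (F_IS) = 1 - sum(c) / sum(b + c)

Negative estimates are reported as computed, never truncated.  Haploids are
excluded (their within-individual component is undefined); missing calls
are handled pairwise-complete per locus.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import MISSING, GenotypeTable


class PopStatsError(ValueError):
    pass


# -------------------------------------------------------------- heterozygosity
@dataclass(frozen=True)
class HeterozygositySummary:
    per_locus: pd.DataFrame  # index locus, columns n, Ho, He
    ho: float                # unweighted mean across loci
    he: float


def heterozygosity(table: GenotypeTable, site: str | None = None) -> HeterozygositySummary:
    """Observed and unbiased expected heterozygosity per locus.

    Ho is the fraction of heterozygous diploid calls; He is Nei's unbiased
    expected heterozygosity ``2n/(2n-1) * (1 - sum p^2)`` from the same
    individuals.  Loci with no diploid calls are omitted with a warning.
    """
    sub = table.filter(site=site, ploidy=2) if site else table.filter(ploidy=2)
    if sub.n_individuals == 0:
        raise PopStatsError("no diploid individuals to analyse")
    rows = []
    for l, locus in enumerate(sub.loci):
        a = sub.alleles[:, l, 0]
        b = sub.alleles[:, l, 1]
        typed = a != MISSING
        n = int(typed.sum())
        if n == 0:
            warnings.warn(f"locus {locus!r}: no diploid calls; omitted")
            continue
        ho = float((a[typed] != b[typed]).mean())
        alleles, counts = np.unique(np.concatenate([a[typed], b[typed]]), return_counts=True)
        p = counts / counts.sum()
        he = (2 * n / (2 * n - 1)) * (1.0 - float((p ** 2).sum()))
        rows.append((locus, n, ho, he))
    if not rows:
        raise PopStatsError("no locus had any diploid calls")
    df = pd.DataFrame(rows, columns=["locus", "n", "Ho", "He"]).set_index("locus")
    return HeterozygositySummary(per_locus=df, ho=float(df["Ho"].mean()), he=float(df["He"].mean()))


# ------------------------------------------------------------- Weir-Cockerham
@dataclass(frozen=True)
class PopStats:
    """Weir-Cockerham estimates plus the per-component audit trail."""

    populations: tuple[str, ...]
    theta: float | None                # multilocus F_ST over all populations
    fis: float | None                  # multilocus F_IS over all populations
    fis_by_population: Mapping[str, float]
    pairwise_fst: pd.DataFrame         # symmetric, NaN diagonal
    components: pd.DataFrame           # locus x allele x (a, b, c)
    warnings_: tuple[str, ...] = ()


def _wc_components(
    pop_alleles: Sequence[np.ndarray],
) -> list[tuple[int, float, float, float]]:
    """Per-allele (a, b, c) components for one locus.

    ``pop_alleles[i]`` is an (n_i, 2) array of the typed diploid calls of
    population i at this locus.  With a single population the
    among-population variance is zero by construction (s2 = 0, a = 0), which
    reduces b and c to the single-population Weir-Cockerham forms used for
    F_IS.
    """
    r = len(pop_alleles)
    n = np.array([len(x) for x in pop_alleles], dtype=float)
    nbar = n.mean()
    if nbar <= 1:
        return []
    if r > 1:
        nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    else:
        nc = nbar
    all_alleles = sorted(set(np.concatenate(pop_alleles).ravel().tolist()))
    out = []
    for allele in all_alleles:
        p_i = np.array([((x == allele).sum()) / (2 * len(x)) for x in pop_alleles])
        h_i = np.array(
            [((x[:, 0] != x[:, 1]) & ((x[:, 0] == allele) | (x[:, 1] == allele))).mean()
             for x in pop_alleles]
        )
        pbar = (n * p_i).sum() / (r * nbar)
        hbar = (n * h_i).sum() / (r * nbar)
        s2 = ((n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)) if r > 1 else 0.0
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2 if r > 1 else pbar * (1 - pbar)
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1)) if r > 1 else 0.0
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        out.append((int(allele), a, b, c))
    return out


def _locus_pop_arrays(
    table: GenotypeTable, pops: Mapping[str, Sequence[int]], l: int
) -> dict[str, np.ndarray]:
    arrays = {}
    for pop, idx in pops.items():
        arr = table.alleles[idx, l, :]
        typed = arr[:, 0] != MISSING
        arrays[pop] = arr[typed]
    return arrays


def f_statistics(
    table: GenotypeTable,
    population_of: str | Mapping[str, str] = "site",
    min_per_pop: int = 2,
) -> PopStats:
    """Weir-Cockerham theta (F_ST) and f (F_IS), overall and pairwise.

    ``population_of`` is either a metadata column name (default ``site``) or
    an explicit id -> population mapping.  A locus enters a statistic only
    where every involved population has at least ``min_per_pop`` typed
    diploid individuals (pairwise-complete handling of missing data).
    """
    diploid = table.filter(ploidy=2)
    n_haploid = table.n_individuals - diploid.n_individuals
    warns = []
    if n_haploid:
        warns.append(f"excluded {n_haploid} haploid individuals from F-statistics")
    if isinstance(population_of, str):
        labels = diploid.meta[population_of]
    else:
        labels = pd.Series({i: population_of[i] for i in diploid.ids})
    pops: dict[str, list[int]] = {}
    for i, ind in enumerate(diploid.ids):
        pops.setdefault(str(labels[ind]), []).append(i)
    pop_names = tuple(pops)
    # reject populations with fewer than min_per_pop typed diploids everywhere
    for pop, idx in pops.items():
        typed_any = (diploid.alleles[idx, :, 0] != MISSING).sum(axis=0)
        if (typed_any < min_per_pop).all():
            raise PopStatsError(
                f"population {pop!r} has fewer than {min_per_pop} typed individuals at every locus"
            )

    def multilocus(selected: Sequence[str]) -> tuple[float | None, float | None, list]:
        comp_rows = []
        A = B = C = 0.0
        for l, locus in enumerate(diploid.loci):
            arrays = _locus_pop_arrays(diploid, {p: pops[p] for p in selected}, l)
            if any(len(x) < min_per_pop for x in arrays.values()):
                continue
            for allele, a, b, c in _wc_components([arrays[p] for p in selected]):
                comp_rows.append((locus, allele, a, b, c))
                A += a
                B += b
                C += c
        theta = A / (A + B + C) if comp_rows and (A + B + C) != 0 else None
        fis = 1.0 - C / (B + C) if comp_rows and (B + C) != 0 else None
        return theta, fis, comp_rows

    theta_all, fis_all, comp_rows = multilocus(pop_names) if len(pop_names) >= 1 else (None, None, [])
    if len(pop_names) < 2:
        theta_all = None

    fis_by_pop = {}
    for pop in pop_names:
        _, f, _ = multilocus((pop,))
        fis_by_pop[pop] = f

    fst = pd.DataFrame(np.nan, index=list(pop_names), columns=list(pop_names))
    for i, p1 in enumerate(pop_names):
        for p2 in pop_names[i + 1:]:
            t, _, _ = multilocus((p1, p2))
            fst.loc[p1, p2] = fst.loc[p2, p1] = np.nan if t is None else t
    components = pd.DataFrame(comp_rows, columns=["locus", "allele", "a", "b", "c"])
    return PopStats(
        populations=pop_names,
        theta=theta_all,
        fis=fis_all,
        fis_by_population=fis_by_pop,
        pairwise_fst=fst,
        components=components,
        warnings_=tuple(warns),
    )


FST_CATEGORIES = ("low", "medium", "high", "very_high")


def classify_fst(value: float) -> str:
    """Differentiation category: low [0, 0.05), medium [0.05, 0.15),
    high [0.15, 0.25], very high (> 0.25).  Negative estimates are treated
    as zero for classification."""
    if not math.isfinite(value):
        raise ValueError(f"cannot classify non-finite F_ST {value}")
    v = max(value, 0.0)
    if v < 0.05:
        return "low"
    if v < 0.15:
        return "medium"
    if v <= 0.25:
        return "high"
    return "very_high"


# ------------------------------------------------------------------- t-test
@dataclass(frozen=True)
class TTestResult:
    mean: float
    sd: float
    n: int
    mu: float
    t: float
    df: int
    p: float


def one_sample_ttest(values: Sequence[float], mu: float) -> TTestResult:
    """Two-sided one-sample t-test of the mean against ``mu``.

    Used to compare per-colony nestmate relatedness against the
    haplodiploid full-sister expectation of 0.75.  A zero-variance sample
    equal to ``mu`` returns the degenerate t = 0, p = 1; a zero-variance
    sample away from ``mu`` is indeterminate and raises.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise PopStatsError(f"need n >= 2 values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise PopStatsError("non-finite values in t-test input")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    n = int(arr.size)
    if sd <= 1e-12 * max(1.0, abs(mean)):
        if abs(mean - mu) <= 1e-12 * max(1.0, abs(mu)):
            return TTestResult(mean=mean, sd=0.0, n=n, mu=mu, t=0.0, df=n - 1, p=1.0)
        raise PopStatsError("zero standard deviation with mean != mu: t undefined")
    t = (mean - mu) / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return TTestResult(mean=mean, sd=sd, n=n, mu=mu, t=t, df=n - 1, p=min(p, 1.0))
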