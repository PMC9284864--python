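"""Pairwise relatedness estimation from codominant marker genotypes.

Two estimators are provided:

* :func:`qg_pairwise` — the Queller & Goodnight moment estimator in its
  symmetrized multilocus ratio-of-sums form.  Relatedness is measured
  relative to population allele frequencies: unrelated pairs centre on 0,
  haplodiploid full sisters on 0.75, negative values mean "less similar than
  random draws".
* :func:`ml_pairwise` — a maximum-likelihood estimator over the three
  identity-by-descent modes (0, 1 or 2 alleles IBD, no inbreeding), the
  model used by ML-RELATE.  It returns (k0, k1, k2) on the simplex and
  r = k2 + k1/2, which is non-negative by construction.

Haploid genotypes (1-tuples) are treated as homozygous pseudo-diploids,
the only convention compatible with diploid-oriented estimators; this is
how queen-male relatedness is computed.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .tables import MISSING, GenotypeTable

Genotype = Mapping[str, tuple[int, ...] | None]

_EPS = 1e-12


class FrequencyError(ValueError):
    """Allele-frequency estimation failed (e.g. a locus with no data)."""


@dataclass
class AlleleFrequencies:
    """Per-locus allele -> frequency maps with provenance.

    ``n_reference`` is the number of individuals that defined the
    frequencies; alleles that appear in analysed genotypes but not in the
    reference set are floored at ``1/(2N + 1)`` and the locus renormalised,
    so every analysed allele has strictly positive frequency.
    """

    frequencies: dict[str, dict[int, float]]
    provenance: str = ""
    n_reference: int | None = None

    def __post_init__(self) -> None:
        for locus, freqs in self.frequencies.items():
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise FrequencyError(f"locus {locus!r}: frequencies sum to {total}, not 1")

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)

    @property
    def floor(self) -> float:
        n = self.n_reference if self.n_reference else 500
        return 1.0 / (2 * n + 1)

    def locus_frequencies(self, locus: str, observed: Iterable[int] = ()) -> dict[int, float]:
        """Frequencies at one locus, floored for unseen-but-observed alleles."""
        base = self.frequencies[locus]
        unseen = sorted({int(a) for a in observed} - set(base))
        if not unseen:
            return base
        fl = self.floor
        scale = 1.0 - fl * len(unseen)
        out = {a: p * scale for a, p in base.items()}
        out.update({a: fl for a in unseen})
        return out

    def is_polymorphic(self, locus: str) -> bool:
        return sum(p > _EPS for p in self.frequencies[locus].values()) > 1


ReferenceSelector = str | Sequence[str] | Callable[[GenotypeTable], Sequence[str]]


def estimate_allele_frequencies(
    table: GenotypeTable,
    reference: ReferenceSelector = "all",
    seed: int | None = None,
) -> AlleleFrequencies:
    """Count-based allele frequencies from a chosen reference individual set.

    ``reference`` may be ``"all"``, ``"workers"``, ``"per-colony-one-worker"``
    (one worker drawn at random per colony — mirrors a design that genotypes
    a single worker per colony for the population-level picture), an explicit
    id sequence, or a callable.  Haploids contribute one allele copy,
    diploids two; missing calls are skipped per locus.
    """
    if callable(reference):
        ids = list(reference(table))
        prov = "custom selector"
    elif reference == "all":
        ids = table.ids
        prov = "all individuals"
    elif reference == "workers":
        ids = table.filter(caste="worker").ids
        prov = "all workers"
    elif reference == "per-colony-one-worker":
        rng = np.random.default_rng(seed)
        workers = table.filter(caste="worker")
        ids = []
        for colony in workers.colonies():
            members = workers.filter(colony=colony).ids
            ids.append(members[rng.integers(len(members))])
        prov = "one random worker per colony"
    elif isinstance(reference, (list, tuple)):
        ids = list(reference)
        prov = f"explicit set of {len(reference)} individuals"
    else:
        raise ValueError(f"unknown reference selector {reference!r}")
    if not ids:
        raise FrequencyError("reference selector yielded no individuals")

    sub = table.subset(ids)
    freqs: dict[str, dict[int, float]] = {}
    ploidy = sub.meta["ploidy"].to_numpy()
    for l, locus in enumerate(sub.loci):
        counts: dict[int, float] = {}
        for i in range(sub.n_individuals):
            a, b = sub.alleles[i, l]
            if a == MISSING:
                continue
            if ploidy[i] == 1:
                counts[int(a)] = counts.get(int(a), 0) + 1
            else:
                counts[int(a)] = counts.get(int(a), 0) + 1
                counts[int(b)] = counts.get(int(b), 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise FrequencyError(f"locus {locus!r}: no non-missing calls in reference set")
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
    return AlleleFrequencies(freqs, provenance=prov, n_reference=len(ids))


# ------------------------------------------------------------------ QG moment
@dataclass(frozen=True)
class PairRelatedness:
    """Symmetrized Queller-Goodnight estimate for one pair."""

    pair: tuple[str, str]
    r: float
    defined: bool
    loci_used: int
    numerator: float
    denominator: float
    per_locus: Mapping[str, tuple[float, float]] = field(default_factory=dict, compare=False)


def _as_diploid(call: tuple[int, ...] | None) -> tuple[int, int] | None:
    if call is None:
        return None
    if len(call) == 1:
        return (call[0], call[0])
    return (call[0], call[1])


def _share(genotype: tuple[int, int], allele: int) -> float:
    return ((genotype[0] == allele) + (genotype[1] == allele)) / 2.0


def _qg_direction(
    focal: tuple[int, int], other: tuple[int, int], p: Mapping[int, float]
) -> tuple[float, float] | None:
    """One direction of the QG estimator at one locus; None when undefined
    (focal homozygous for an allele at frequency 1)."""
    if focal[0] == focal[1] and p[focal[0]] >= 1.0 - _EPS:
        return None
    num = den = 0.0
    for allele in focal:
        num += _share(other, allele) - p[allele]
        den += _share(focal, allele) - p[allele]
    return num, den


def qg_pairwise(
    x_genotype: Genotype,
    y_genotype: Genotype,
    freqs: AlleleFrequencies,
    pair: tuple[str, str] = ("x", "y"),
) -> PairRelatedness:
    """Symmetrized multilocus Queller-Goodnight relatedness.

    Numerators and denominators are summed over loci and over both
    directions before dividing (ratio-of-sums), the standard multilocus form
    that stabilises low-information loci.  A zero total denominator yields
    ``defined=False`` rather than an exception.
    """
    num = den = 0.0
    per_locus: dict[str, tuple[float, float]] = {}
    used = 0
    for locus in freqs.loci:
        gx = _as_diploid(x_genotype.get(locus))
        gy = _as_diploid(y_genotype.get(locus))
        if gx is None or gy is None:
            continue
        p = freqs.locus_frequencies(locus, observed=(*gx, *gy))
        locus_num = locus_den = 0.0
        contributed = False
        for focal, other in ((gx, gy), (gy, gx)):
            d = _qg_direction(focal, other, p)
            if d is None:
                continue
            locus_num += d[0]
            locus_den += d[1]
            contributed = True
        if contributed:
            per_locus[locus] = (locus_num, locus_den)
            num += locus_num
            den += locus_den
            used += 1
    if used == 0 or abs(den) < _EPS:
        return PairRelatedness(pair, float("nan"), False, used, num, den, per_locus)
    return PairRelatedness(pair, num / den, True, used, num, den, per_locus)


@dataclass(frozen=True)
class GroupRelatedness:
    """Mean pairwise relatedness within one group (e.g. nestmate workers)."""

    group: str
    mean: float
    sd: float
    n_pairs: int
    n_undefined: int
    values: tuple[float, ...] = field(compare=False, default=())


def mean_within_group_relatedness(
    table: GenotypeTable,
    group_id: str,
    freqs: AlleleFrequencies,
    caste: str = "worker",
) -> GroupRelatedness:
    """Mean QG relatedness over all unordered member pairs of one colony.

    Undefined pairs (zero total denominator) are excluded and counted.
    """
    members = table.filter(colony=group_id, caste=caste)
    ids = members.ids
    if len(ids) < 2:
        raise ValueError(f"group {group_id!r}: need >= 2 usable members, got {len(ids)}")
    genotypes = {i: members.genotype(i, as_diploid=True) for i in ids}
    values = []
    undefined = 0
    for a, b in itertools.combinations(ids, 2):
        est = qg_pairwise(genotypes[a], genotypes[b], freqs, pair=(a, b))
        if est.defined:
            values.append(est.r)
        else:
            undefined += 1
    if not values:
        raise ValueError(f"group {group_id!r}: no defined pairwise estimates")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GroupRelatedness(
        group=group_id,
        mean=float(arr.mean()),
        sd=sd,
        n_pairs=len(values),
        n_undefined=undefined,
        values=tuple(values),
    )


# ------------------------------------------------------------- ML (k0, k1, k2)
@dataclass(frozen=True)
class MLResult:
    """Maximum-likelihood IBD-mode estimate for one pair."""

    pair: tuple[str, str]
    k0: float
    k1: float
    k2: float
    r: float
    log_likelihood: float
    loci_used: int


class LikelihoodError(ValueError):
    """Degenerate pairwise likelihood (impossible genotype pair)."""


def _genotype_prob(g: tuple[int, int], p: Mapping[int, float]) -> float:
    a, b = g
    return p[a] ** 2 if a == b else 2 * p[a] * p[b]


def _conditional_prob(g: tuple[int, int], shared: int, p: Mapping[int, float]) -> float:
    """P(observe unordered genotype g | one allele is the IBD allele `shared`)."""
    a, b = g
    if shared not in g:
        return 0.0
    if a == b:
        return p[a]
    return p[b] if shared == a else p[a]


def pair_mode_probabilities(
    gx: tuple[int, int], gy: tuple[int, int], p: Mapping[int, float]
) -> tuple[float, float, float]:
    """(P0, P1, P2): probability of the genotype pair given 0/1/2 IBD alleles."""
    p0 = _genotype_prob(gx, p) * _genotype_prob(gy, p)
    p1 = sum(
        p[s] * _conditional_prob(gx, s, p) * _conditional_prob(gy, s, p)
        for s in set(gx) & set(gy)
    )
    p2 = _genotype_prob(gx, p) if tuple(sorted(gx)) == tuple(sorted(gy)) else 0.0
    return p0, p1, p2


def _simplex_grid(step: float) -> np.ndarray:
    ticks = int(round(1.0 / step))
    pts = []
    for i in range(ticks + 1):
        for j in range(ticks + 1 - i):
            k0 = i * step
            k1 = j * step
            pts.append((k0, k1, 1.0 - k0 - k1))
    return np.asarray(pts)


def ml_pairwise(
    x_genotype: Genotype,
    y_genotype: Genotype,
    freqs: AlleleFrequencies,
    pair: tuple[str, str] = ("x", "y"),
    grid_step: float = 0.02,
    refine: bool = True,
) -> MLResult:
    """ML relatedness over the (k0, k1, k2) IBD-mode simplex.

    The likelihood ``prod_loci sum_m k_m P_m(gx, gy | p)`` is evaluated on a
    dense simplex grid (default step 0.02) and the best grid point is refined
    by constrained local optimisation; the procedure is deterministic.  The
    three modes assume no inbreeding (the standard ML-RELATE setting).
    """
    probs = []
    used = 0
    for locus in freqs.loci:
        gx = _as_diploid(x_genotype.get(locus))
        gy = _as_diploid(y_genotype.get(locus))
        if gx is None or gy is None:
            continue
        p = freqs.locus_frequencies(locus, observed=(*gx, *gy))
        row = pair_mode_probabilities(gx, gy, p)
        if max(row) <= 0.0:
            raise LikelihoodError(f"locus {locus!r}: all IBD-mode probabilities are zero")
        probs.append(row)
        used += 1
    if used == 0:
        raise LikelihoodError("no loci with both genotypes non-missing")
    P = np.asarray(probs)  # (L, 3)

    def negloglik(k: np.ndarray) -> float:
        lik = P @ k
        if (lik <= 0).any():
            return np.inf
        return -float(np.log(lik).sum())

    grid = _simplex_grid(grid_step)
    with np.errstate(divide="ignore"):
        loglik = np.where((grid @ P.T > 0).all(axis=1),
                          np.log(np.maximum(grid @ P.T, 1e-300)).sum(axis=1),
                          -np.inf)
    best = int(np.argmax(loglik))
    k_best = grid[best]
    best_ll = float(loglik[best])

    if refine:
        res = minimize(
            lambda v: negloglik(np.array([1.0 - v[0] - v[1], v[0], v[1]])),
            x0=np.array([k_best[1], k_best[2]]),
            method="SLSQP",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            constraints=[{"type": "ineq", "fun": lambda v: 1.0 - v[0] - v[1]}],
        )
        if res.success:
            cand = np.array([1.0 - res.x[0] - res.x[1], res.x[0], res.x[1]])
            cand = np.clip(cand, 0.0, 1.0)
            cand /= cand.sum()
            cand_ll = -negloglik(cand)
            if cand_ll >= best_ll:
                k_best, best_ll = cand, cand_ll
    k0, k1, k2 = (float(v) for v in k_best)
    return MLResult(
        pair=pair,
        k0=k0,
        k1=k1,
        k2=k2,
        r=k2 + k1 / 2.0,
        log_likelihood=best_ll,
        loci_used=used,
    )
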