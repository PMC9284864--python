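"""Non-random mating test: are queens more related to their own mates than
to the pool of available males?

From reconstructed monandrous colonies the observed sample is one
(queen, own mate) relatedness value per colony; the null sample is the
relatedness of every other (queen, male) cross-colony combination — for
n colonies, n x (n - 1) pairs (26 colonies give the classic 650).  The two
samples are compared with a one-sided two-sample Kolmogorov-Smirnov test:

    D = sup_t [ F_null(t) - F_obs(t) ]

for the alternative "observed pairs are stochastically greater (more
related)".  Both the large-sample bound p = exp(-2 D^2 n1 n2 / (n1 + n2))
and a label-permutation p-value are reported; the permutation p is the
headline number because the null pairs re-use each queen and male 25 times
and are therefore not independent draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .relatedness import AlleleFrequencies, ml_pairwise, qg_pairwise
from .reconstruct import CLASS_MONANDROUS, ColonyReconstruction


class MatingTestError(ValueError):
    pass


# ------------------------------------------------------------------ pair sets
@dataclass(frozen=True)
class PairSets:
    """Observed mate-pair and null cross-pair relatedness samples."""

    estimator: str
    mate_values: tuple[float, ...]
    null_values: tuple[float, ...]
    colony_ids: tuple[str, ...]
    n_excluded: int  # colonies without a usable monandrous queen+mate

    @property
    def n_mate_pairs(self) -> int:
        return len(self.mate_values)

    @property
    def n_null_pairs(self) -> int:
        return len(self.null_values)


def build_pair_sets(
    reconstructions: Mapping[str, ColonyReconstruction],
    freqs: AlleleFrequencies,
    estimator: str = "qg",
) -> PairSets:
    """Relatedness of queens to own mates vs all cross-colony queen x male pairs.

    Only monandrous reconstructions contribute (polyandrous, multi-queen and
    undetermined colonies are excluded); queen and father genotypes are the
    unambiguous inferred ones, with the haploid father entering as a
    homozygous pseudo-diploid.  Swapping which partner is called "queen"
    leaves every value unchanged (estimator symmetry).
    """
    if estimator not in ("qg", "ml"):
        raise MatingTestError(f"estimator must be 'qg' or 'ml', got {estimator!r}")
    queens, males, used = [], [], []
    excluded = 0
    for cid, recon in reconstructions.items():
        if recon.classification != CLASS_MONANDROUS:
            excluded += 1
            continue
        q = recon.queen_genotype_map(0)
        m = recon.father_genotype_map(0)
        if all(v is None for v in q.values()) or all(v is None for v in m.values()):
            excluded += 1
            continue
        queens.append(q)
        males.append(m)
        used.append(cid)
    if len(used) < 2:
        raise MatingTestError(
            f"need >= 2 monandrous colonies with inferred queen and mate, got {len(used)}"
        )

    def rel(qg_geno, male_geno, pair):
        if estimator == "qg":
            est = qg_pairwise(qg_geno, male_geno, freqs, pair=pair)
            return est.r if est.defined else None
        return ml_pairwise(qg_geno, male_geno, freqs, pair=pair).r

    mate_values, null_values = [], []
    for i, cid in enumerate(used):
        for j, cjd in enumerate(used):
            v = rel(queens[i], males[j], (f"{cid}:queen", f"{cjd}:male"))
            if v is None:
                continue
            (mate_values if i == j else null_values).append(v)
    if not mate_values or not null_values:
        raise MatingTestError("no defined relatedness values for the pair sets")
    return PairSets(
        estimator=estimator,
        mate_values=tuple(mate_values),
        null_values=tuple(null_values),
        colony_ids=tuple(used),
        n_excluded=excluded,
    )


# ------------------------------------------------------------------------- KS
@dataclass(frozen=True)
class KSResult:
    D: float
    direction: str
    p_asymptotic: float
    p_permutation: float | None
    n_permutations: int
    n1: int  # observed
    n2: int  # null
    seed: int | None = None


def _d_plus(observed: np.ndarray, null: np.ndarray) -> float:
    """sup_t [F_null(t) - F_obs(t)] over the pooled support."""
    support = np.concatenate([observed, null])
    support.sort()
    f_obs = np.searchsorted(np.sort(observed), support, side="right") / observed.size
    f_null = np.searchsorted(np.sort(null), support, side="right") / null.size
    return float(np.max(f_null - f_obs))


def ks_one_sided(
    observed: Sequence[float],
    null: Sequence[float],
    alternative: str = "observed_greater",
    n_permutations: int = 0,
    seed: int | None = None,
) -> KSResult:
    """One-sided two-sample KS test.

    ``alternative="observed_greater"`` asks whether the observed sample is
    stochastically greater than the null (its ECDF lies below); the opposite
    direction is available as ``"observed_less"``.  The asymptotic p-value
    is the one-sided large-sample bound exp(-2 D^2 n1 n2/(n1+n2)); if
    ``n_permutations > 0`` a permutation p-value is computed by pooling the
    samples and resampling group labels, deterministic under ``seed``.
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if obs.size == 0 or nul.size == 0:
        raise MatingTestError("both samples must be nonempty")
    if alternative == "observed_greater":
        d = _d_plus(obs, nul)
    elif alternative == "observed_less":
        d = _d_plus(-obs, -nul)
    else:
        raise MatingTestError(f"unknown alternative {alternative!r}")
    n1, n2 = obs.size, nul.size
    p_asym = float(min(1.0, np.exp(-2.0 * d * d * n1 * n2 / (n1 + n2))))
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([obs, nul]) if alternative == "observed_greater" else np.concatenate([-obs, -nul])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _d_plus(perm[:n1], perm[n1:]) >= d - 1e-12:
                hits += 1
        p_perm = (1 + hits) / (1 + n_permutations)
    return KSResult(
        D=d,
        direction=alternative,
        p_asymptotic=p_asym,
        p_permutation=p_perm,
        n_permutations=n_permutations,
        n1=n1,
        n2=n2,
        seed=seed,
    )
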