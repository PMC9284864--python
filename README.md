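# colonykin

Colony-level genetic analysis for haplodiploid social insects (ants, bees,
wasps): reconstruct queen and mate genotypes from worker microsatellite
genotypes, classify queen mating frequency, estimate relatedness, compute
F-statistics, and test whether queens mate with males more related to them
than expected by chance.

It is aimed at researchers analysing codominant multilocus genotype tables
of workers sampled colony by colony — the classic design for asking "how
many queens? how many matings? any stray foreigners?" in species such as
rock-dwelling *Temnothorax* ants — and ships a Mendelian colony simulator
so every analysis stage can be exercised against known ground truth.

## What it computes

**Pedigree reconstruction.** In haplodiploids, males are haploid and
workers diploid, so a worker's genotype at each locus is one of its queen's
two alleles plus its father's single allele. Given a colony's workers, the
search finds the most parsimonious explanation in lexicographic order
*(number of queens, number of fathers, number of alien workers)*: the queen
genotype per locus must cover every worker, and each patriline must share a
consistent haploid father genotype. The search is exact (all co-optimal
queen solutions are kept, unobserved queen alleles are reported as explicit
wildcards), and a worker is only called alien when excluding it strictly
reduces the father count *and* its genotype is irreconcilable with every
queen solution at ≥ 2 loci.

**Relatedness.** The Queller–Goodnight moment estimator in its symmetrized
multilocus ratio-of-sums form,

    r_xy = [ Σ_l Σ_a (p_a(y) − p̄_a) + Σ_l Σ_a (p_a(x) − p̄_a) ]
           / [ Σ_l Σ_a (p_a(x) − p̄_a) + … ]

(shared-allele frequencies within the partner's genotype minus population
frequencies p̄), and a maximum-likelihood estimator over the three
identity-by-descent modes (k₀, k₁, k₂) with r̂ = k₂ + k₁/2, as used by
ML-RELATE. Full sisters in haplodiploids expect r = 0.75; the package's
calibration suite verifies this on simulated colonies.

**Population statistics.** Observed/unbiased expected heterozygosity,
Weir–Cockerham (1984) variance-component estimators θ̂ (F_ST, overall and
pairwise between sites) and f̂ (F_IS), with the conventional
low/medium/high/very-high differentiation categories, plus the one-sample
t-test of nestmate relatedness against 0.75.

**Non-random mating.** Per monandrous colony, the relatedness of the
inferred queen to her own mate versus all cross-colony queen × male pairs
(n colonies → n·(n−1) null pairs), compared with a one-sided two-sample
Kolmogorov–Smirnov test, D = sup_t [F_null(t) − F_obs(t)], reporting both
the asymptotic bound exp(−2D²n₁n₂/(n₁+n₂)) and a permutation p-value.

## Worked example

A two-site study of 14 colonies, 13 monandrous and one with a strongly
skewed second patriline (14:2):

```yaml
# study.yaml
seed: 5
simulation:
  population:
    n_loci: 12
    alleles_per_locus: 20
    sites: [north, south]
  colonies:
    north:
      - {n_workers: 8, count: 10}
      - {n_workers: 16, n_fathers_per_queen: 2, paternity_counts: [14, 2]}
    south:
      - {n_workers: 8, count: 3}
analysis:
  ks_permutations: 1000
```

```
$ colonykin run --config study.yaml
colonykin study report (v0.1.0, seed 5)

Colonies analysed: 14
  monandrous 13, polyandrous 1, multi-queen 0, undetermined 0, alien workers 0

Nestmate relatedness: mean 0.738 +/- 0.035 (SD), SE 0.009, n = 14 colonies
  vs r = 0.75: t = -1.240, df = 13, p = 0.237

F_IS overall: 0.013
  north: 0.021
  south: -0.022
  F_ST north vs south: -0.005 (low)

Queen-mate KS (QG): D = 0.135, asymptotic p = 0.6473, permutation p = 0.6084  (n = 13 mate pairs vs 156 cross pairs)
Queen-mate KS (ML): D = 0.122, asymptotic p = 0.7005, permutation p = 0.3706  (n = 13 mate pairs vs 156 cross pairs)
```

Reading it: the planted polyandrous colony is found (13 + 1), mean nestmate
relatedness sits at the full-sister expectation (t-test does not reject
0.75), the two sites are genetically undifferentiated (F_ST ≈ 0, "low"),
both populations are at Hardy–Weinberg equilibrium (F_IS ≈ 0), and — since
mates were drawn at random in this simulation — the KS test finds no excess
relatedness between queens and their own mates.

Other entry points: `colonykin simulate` (genotypes + truth tables from a
simulation spec), `colonykin convert` (csv-wide / csv-long / Genepop),
`colonykin reconstruct`, `colonykin relatedness`, `colonykin popstats`,
`colonykin matingtest`. Everything is also available as a library
(`import colonykin`).

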