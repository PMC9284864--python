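# Methods

This note documents the models, algorithms and numerical choices behind
colonykin, and what the bundled simulator does and does not emulate.

## Inheritance model and scope

All analyses assume haplodiploid sex determination: queens and workers are
diploid, males haploid (from unfertilized eggs). A worker therefore carries
one maternal allele and its father's entire haploid genome, which is what
gives full sisters an expected relatedness of 0.75 and makes colony
pedigrees unusually reconstructable from worker genotypes alone. Markers
are unlinked codominant loci with integer allele labels (microsatellite
style); `0` encodes a missing call. The package does not model genotyping
error beyond missingness, linkage, mutation, null alleles, or inbreeding in
the likelihood model (see limitations).

## Colony simulator

`colonykin.simulate` generates colonies with known truth:

* **Population model.** Per-locus allele frequencies, either uniform
  (equifrequent) or drawn once from a symmetric Dirichlet(α). The reference
  test design is 12 loci × 20 equifrequent alleles — a deliberately
  high-information panel comparable to a polymorphic microsatellite set
  (field panels of this kind run ~9–28 alleles per locus).
* **Between-site divergence.** Each site's frequency vector is an
  independent Dirichlet draw with concentration ((1−F)/F)·p_ancestral
  (Balding–Nichols). This makes the drift parameter F the analytic
  expectation of Weir–Cockerham θ̂ between sites, giving the F-statistics a
  quantitative oracle; divergence 0 copies the ancestral vector exactly.
* **Colonies.** One diploid queen (optionally two) × one or more haploid
  males. Each own worker gets a uniformly chosen queen allele plus its
  father's allele; fathers are assigned per worker either stochastically by
  `paternity_weights` (multinomial) or exactly by `paternity_counts`. The
  exact-count option exists because strongly skewed paternity (e.g. a 14:2
  split) is a *scenario*, not a random outcome — under stochastic weights
  of 7:1 the minority patriline is empty in ~12% of draws, which would make
  "detect the second father" tests meaningless.
* **Aliens.** A stray worker picked up during collection is simulated as
  the offspring of an independent monandrous queen × male from the same
  site — a real ant from a neighbouring nest, not a bag of random alleles.
* **Missingness.** Independent Bernoulli mask per (individual, locus); no
  locus-level dropout model. This is sufficient to exercise the
  minimum-typed-loci validation rule (default: flag individuals with < 10
  of 12 loci typed; flagged, never silently dropped).
* **Determinism.** All randomness flows from `numpy.random.SeedSequence`;
  study-level simulation spawns one child seed per colony, so output is
  independent of consumption order and byte-stable under a fixed seed.

Passing tests on these data show the algorithms are correct under clean
Mendelian inheritance with known frequencies; they do not certify
robustness to genotyping artefacts (allele dropout, stutter, null alleles),
which real studies handle with upstream QC.

## Pedigree reconstruction

At one locus, a queen genotype hypothesis is an unordered pair {a, b} over
the alleles observed in the colony such that every non-missing worker
carries a or b; additionally {a, \*} (wildcard: the queen's second allele
was inherited by no sampled worker) is admitted when a alone covers every
worker. Wildcards are reported as such and never silently concretised.
Missing worker calls constrain nothing.

Given a candidate queen, each worker's possible paternal alleles at a locus
are its alleles not forced to be maternal; a patriline (set of workers
sharing one father) is feasible iff the intersection of these sets is
non-empty at every locus. Loci are independent given the partition of
workers into patrilines, so feasibility is checked per locus against all
surviving queen candidates.

**Search.** The minimal father count for a worker set is found by iterative
deepening on the patriline count with a canonical-assignment depth-first
search; the search state tracks, per locus and per surviving queen
candidate, the running paternal-allele intersection of every patriline, so
infeasible branches die early. The overall objective is lexicographic
**(n_queens, n_fathers, n_aliens)**: queens are minimised first, then mates
per queen, and alien exclusion is accepted only when it strictly reduces
the father count. Fathers must precede aliens in the objective because a
single-queen zero-alien explanation with inflated father counts exists for
almost any worker set (per locus, the pair {father allele, one allele of
the odd worker} covers everybody); an aliens-before-fathers order would
therefore never flag a genuinely foreign worker, while the chosen order
still prefers "one queen, two fathers" over "one queen, one father, plus
aliens" whenever both explain the data equally well.

Safeguards and conventions:

* A worker is flagged alien only if, additionally, its genotype shares no
  allele with any co-optimal queen solution at ≥ 2 loci
  (`alien_conflict_loci`, configurable; wildcard solutions are treated
  permissively so this undercounts conflicts). This guards against a
  single aberrant locus relabelling a true nestmate.
* Two queens are considered only when no single-queen explanation exists at
  any alien count ≤ `max_aliens` (consistent with the lexicographic
  objective); the two-queen search enumerates maternity bipartitions and
  solves each side independently. With none feasible the colony is
  `undetermined`.
* All co-optimal queen solutions per locus are retained; the reported
  representative is the lexicographically smallest concrete pair (wildcard
  pairs only when no concrete solution exists). Ties everywhere break
  lexicographically, so reports are reproducible.
* A node budget (`exhaustive_limit`) caps the search; when exceeded the
  result is marked `heuristic` and a first-fit father assignment is used.
  The search is exhaustive well beyond 16 workers × 12 loci in practice.
* Verification against an empirically genotyped queen counts a locus as a
  mismatch only when *no* co-optimal solution contains the observed pair
  (wildcards match anything containing their concrete allele).

The test suite checks the search against an independent brute-force
enumeration of every (queen combination, partition, alien subset,
maternity split) explanation on random ≤ 6-worker, ≤ 4-locus colonies.

## Relatedness estimators

**Queller–Goodnight.** Per locus and direction x→y, the numerator sums
(frequency of each of x's alleles within y's genotype − population
frequency) and the denominator the same with frequencies within x's own
genotype; both directions and all loci are summed before dividing
(ratio-of-sums — the standard multilocus form, which stabilises
low-information loci). A direction is skipped at a locus where the focal
individual is homozygous for an allele at frequency 1 (undefined
denominator); a pair whose total denominator is zero yields an explicit
"undefined" result, not an exception. Haploid males enter as homozygous
pseudo-diploids — the only convention compatible with diploid-oriented
estimators — and the same convention is used for inferred fathers in the
mating test.

**Allele frequencies.** The reference set is an explicit, logged choice:
all individuals, all workers, one random worker per colony (the default in
the pipeline, mirroring population-level designs that genotype one worker
per colony and avoiding family pseudo-replication), an explicit id list, or
the simulator's true frequencies. Alleles observed in analysed genotypes
but absent from the reference set are floored at 1/(2N+1) (N = reference
individuals) and the locus renormalised, so likelihoods and denominators
stay finite.

**Maximum likelihood (k₀, k₁, k₂).** The likelihood of a genotype pair is
Π_loci Σ_m k_m·P_m(g_x, g_y | p) over the three IBD modes (0, 1, 2 alleles
identical by descent; no inbreeding modes — the standard ML-RELATE setting,
appropriate for populations at Hardy–Weinberg equilibrium). The simplex is
scanned on a dense grid (step 0.02) and the best point refined by
constrained SLSQP; the refined optimum is accepted only if it does not fall
below the grid optimum, so the procedure is deterministic and
grid-dominant. r̂ = k₂ + k₁/2 is non-negative by construction.

## Population statistics

Observed heterozygosity is the heterozygote fraction among non-missing
diploid calls; expected heterozygosity uses the unbiased small-sample form
(2n/(2n−1))(1−Σp²). F-statistics are the Weir & Cockerham (1984)
variance-component estimators: per allele and locus the components a
(among populations), b (among individuals within populations) and c
(within individuals), combined ratio-of-sums over alleles and loci —
θ̂ = Σa/Σ(a+b+c), f̂ = 1 − Σc/Σ(b+c) — matching what Genepop reports.
Negative estimates are reported as computed. With a single population the
among-population variance is zero by construction, which reduces b and c to
the single-population forms used for per-site F_IS. Haploids are excluded
(c is undefined for them); missing data are handled pairwise-complete per
locus, and a locus enters a statistic only where every involved population
has ≥ 2 typed diploids. The pipeline computes population statistics on one
randomly chosen worker per colony so that sibling structure within colonies
does not masquerade as inbreeding or site differentiation; feeding all
workers to `f_statistics` directly is possible but conflates family and
population structure. Pairwise F_ST values are labelled with the
conventional categories: low [0, 0.05), medium [0.05, 0.15), high
[0.15, 0.25], very high (> 0.25); negative values classify as low.

The one-sample t-test (per-colony mean nestmate relatedness vs 0.75) is the
standard t = (x̄−μ)/(s/√n) with n−1 df, two-sided. Degenerate input is
resolved explicitly: a zero-variance sample equal to μ returns t = 0,
p = 1; a zero-variance sample away from μ raises (t is undefined, not
infinite, on such data). Published analyses of this kind occasionally print
t statistics that the standard formula cannot reproduce from the reported
mean, SD and n; this implementation always applies the standard formula to
clearly named observation units (per-colony means).

## Mating test

Eligible colonies are reconstructed monandrous colonies whose queen and
father genotypes are unambiguous at ≥ 1 locus (ambiguous loci — multiple
co-optimal queen solutions, wildcards, multi-allele father sets — are
treated as missing for this analysis). The observed sample is one
queen × own-mate relatedness per colony; the null is the full cross set of
every queen with every *other* colony's male (n·(n−1) pairs), not a random
subsample — with 26 colonies this is exactly 650 pairs. The one-sided KS
statistic D = sup_t [F_null(t) − F_obs(t)] (alternative: mate pairs
stochastically more related) is evaluated over the pooled support including
both sides of each step, so ties are handled exactly. Two p-values are
reported: the asymptotic one-sided bound exp(−2D²n₁n₂/(n₁+n₂)), and a
label-permutation p (pool both samples, permute group labels, count
permuted D ≥ observed D, with the +1 correction), deterministic under the
given seed. The permutation p is the headline number because null pairs
re-use each queen and male many times and are not independent draws; note
that permuting at the pair-value level mirrors common practice but does not
remove that dependence — a colony-level block permutation would be
stricter and is a known limitation.

## Pipeline

`run_pipeline` executes load/simulate → reconstruct → relatedness +
t-test → F-statistics → mating test and assembles a JSON + text report with
a provenance block (version, seed, config echo, frequency reference). A
single master seed fans out to stages through fixed `SeedSequence` spawn
keys, so adding or reordering stages cannot silently reshuffle another
stage's randomness, and identical config + seed gives byte-identical
reports. Degenerate inputs degrade explicitly (e.g. a single-colony study
skips the mating test with a note); stage failures carry the stage name.

## Problem sizes in the test and calibration suites

The reference conditions are colonies of 8 workers (16 for the skew and
alien scenarios) at 12 loci × 20 equifrequent alleles. The calibration
script averages ~11,000 sister pairs over 400 colonies (the full-sister
mean is reproducible to ±0.01 at ≥ 200 colonies); recovery rates for the
14:2 polyandry and single-alien scenarios use 100 seeded replicates each;
θ̂ recovery uses 20 replicate two-site studies of 50 + 50 unrelated
diploids; KS null uniformity uses 500 replicates × 199 permutations. These
sizes keep every check comfortably reproducible on a laptop.

## Known limitations

* No genotyping-error model inside the reconstruction search: one bad call
  can in principle inflate father counts (the ≥ 2-conflicting-loci alien
  guard mitigates the alien side of this).
* No likelihood-based sibship reconstruction (COLONY-style) and no
  splitting of colonies across satellite nests.
* The ML relatedness model excludes inbreeding (9-coefficient Jacquard
  modes); with substantial inbreeding both estimators are biased.
* The two-queen tier enumerates maternity bipartitions exhaustively and is
  practical only for moderately sized colonies; it is also searched without
  simultaneous alien exclusion.
* Genepop export is diploid-only by format; haploids are encoded as
  homozygous pseudo-diploids, and site/colony grouping survives round-trips
  only through the label convention written by this package.
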