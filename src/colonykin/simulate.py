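"""Synthetic haplodiploid colony genotypes with known truth.

Emulates a microsatellite study design on a rock-dwelling ant: colonies of
one diploid queen mated to one or two haploid males, diploid worker
offspring typed at ~12 unlinked codominant loci of high allelic richness,
multiple collection sites with tunable divergence, plus the field
irregularities that matter downstream — paternity skew, stray ("alien")
workers from foreign nests, a second queen, and missing genotypes.

Between-site divergence follows the Balding-Nichols construction: each
site's frequency vector is an independent Dirichlet draw with concentration
``(1 - F)/F * p_ancestral``, so the drift parameter ``F`` is the analytic
expectation of Weir-Cockerham theta between sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .relatedness import AlleleFrequencies
from .tables import MISSING, GenotypeTable

RngSeed = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------- population
@dataclass(frozen=True)
class PopulationModel:
    """Per-site allele frequencies for a set of unlinked codominant loci.

    ``site_frequencies[s][l]`` is the frequency vector of locus ``l`` at site
    ``s``; ``allele_labels[l]`` maps vector positions to integer allele
    labels (microsatellite-style, base 100 step 2).
    """

    loci: tuple[str, ...]
    alleles_per_locus: tuple[int, ...]
    frequency_scheme: str
    n_sites: int
    divergence: float
    seed: int
    site_names: tuple[str, ...]
    allele_labels: tuple[tuple[int, ...], ...]
    ancestral_frequencies: tuple[np.ndarray, ...] = field(repr=False)
    site_frequencies: tuple[tuple[np.ndarray, ...], ...] = field(repr=False)

    def site_index(self, site: str | int) -> int:
        if isinstance(site, int):
            if not 0 <= site < self.n_sites:
                raise ValueError(f"site index {site} out of range")
            return site
        try:
            return self.site_names.index(site)
        except ValueError:
            raise ValueError(f"unknown site {site!r}; sites are {self.site_names}") from None

    def allele_frequencies(self, site: str | int) -> AlleleFrequencies:
        """The true (simulation) frequencies at one site."""
        s = self.site_index(site)
        freqs = {
            locus: {
                int(a): float(p)
                for a, p in zip(self.allele_labels[l], self.site_frequencies[s][l])
            }
            for l, locus in enumerate(self.loci)
        }
        return AlleleFrequencies(freqs, provenance="true (simulation)", n_reference=None)

    def ancestral_allele_frequencies(self) -> AlleleFrequencies:
        """The shared ancestral (pre-divergence) frequencies."""
        freqs = {
            locus: {
                int(a): float(p)
                for a, p in zip(self.allele_labels[l], self.ancestral_frequencies[l])
            }
            for l, locus in enumerate(self.loci)
        }
        return AlleleFrequencies(freqs, provenance="true ancestral (simulation)", n_reference=None)


def make_population_model(
    n_loci: int = 12,
    alleles_per_locus: int | Sequence[int] = 20,
    frequency_scheme: str = "uniform",
    n_sites: int = 1,
    divergence: float = 0.0,
    seed: int = 0,
    dirichlet_alpha: float = 1.0,
    loci: Sequence[str] | None = None,
    site_names: Sequence[str] | None = None,
    allele_label_base: int = 100,
    allele_label_step: int = 2,
) -> PopulationModel:
    """Build a reproducible per-site frequency model.

    ``frequency_scheme`` is ``"uniform"`` (equifrequent alleles) or
    ``"dirichlet"`` (ancestral frequencies drawn once from a symmetric
    Dirichlet with concentration ``dirichlet_alpha``).  With
    ``divergence == 0`` all sites share the ancestral vector exactly.
    """
    if n_loci <= 0:
        raise ValueError(f"n_loci must be positive, got {n_loci}")
    if n_sites <= 0:
        raise ValueError(f"n_sites must be positive, got {n_sites}")
    if divergence < 0 or divergence >= 1:
        raise ValueError(f"divergence must be in [0, 1), got {divergence}")
    counts = (
        tuple([int(alleles_per_locus)] * n_loci)
        if isinstance(alleles_per_locus, (int, np.integer))
        else tuple(int(k) for k in alleles_per_locus)
    )
    if len(counts) != n_loci:
        raise ValueError(f"alleles_per_locus has {len(counts)} entries for {n_loci} loci")
    if any(k < 1 for k in counts):
        raise ValueError(f"allele counts must be >= 1, got {counts}")
    if frequency_scheme not in ("uniform", "dirichlet"):
        raise ValueError(f"frequency_scheme must be 'uniform' or 'dirichlet', got {frequency_scheme!r}")
    loci = tuple(loci) if loci is not None else tuple(f"L{i + 1:02d}" for i in range(n_loci))
    if len(loci) != n_loci:
        raise ValueError("loci names do not match n_loci")
    site_names = (
        tuple(site_names)
        if site_names is not None
        else tuple(f"site{i + 1}" for i in range(n_sites))
    )
    if len(site_names) != n_sites:
        raise ValueError("site_names do not match n_sites")

    rng = _rng(seed)
    labels = tuple(
        tuple(allele_label_base + allele_label_step * i for i in range(k)) for k in counts
    )
    ancestral = []
    for k in counts:
        if frequency_scheme == "uniform":
            ancestral.append(np.full(k, 1.0 / k))
        else:
            ancestral.append(rng.dirichlet(np.full(k, dirichlet_alpha)))
    sites = []
    for _ in range(n_sites):
        if divergence == 0.0:
            sites.append(tuple(p.copy() for p in ancestral))
        else:
            conc = (1.0 - divergence) / divergence
            perturbed = []
            for p in ancestral:
                alpha = np.maximum(conc * p, 1e-9)
                perturbed.append(rng.dirichlet(alpha))
            sites.append(tuple(perturbed))
    return PopulationModel(
        loci=loci,
        alleles_per_locus=counts,
        frequency_scheme=frequency_scheme,
        n_sites=n_sites,
        divergence=float(divergence),
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        site_names=site_names,
        allele_labels=labels,
        ancestral_frequencies=tuple(ancestral),
        site_frequencies=tuple(sites),
    )


# --------------------------------------------------------------------- colony
@dataclass(frozen=True)
class ColonyConfig:
    """Composition of one simulated colony.

    ``n_workers`` is the total number of sampled workers including any
    aliens; ``n_aliens`` of them are offspring of an independent monandrous
    queen from the same site (a stray forager picked up during collection).
    ``paternity_weights`` gives each father's siring probability per worker
    (stochastic, multinomial); ``paternity_counts`` instead forces an exact
    per-father split of the colony's own workers.
    """

    n_workers: int = 8
    n_queens: int = 1
    n_fathers_per_queen: int = 1
    paternity_weights: tuple[float, ...] | None = None
    paternity_counts: tuple[int, ...] | None = None
    n_aliens: int = 0
    missing_rate: float = 0.0
    include_queen_genotype: bool = False

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError(f"n_workers must be positive, got {self.n_workers}")
        if self.n_queens not in (1, 2):
            raise ValueError(f"n_queens must be 1 or 2, got {self.n_queens}")
        if self.n_fathers_per_queen < 1:
            raise ValueError(f"n_fathers_per_queen must be positive, got {self.n_fathers_per_queen}")
        if not 0 <= self.n_aliens < self.n_workers:
            raise ValueError(f"need 0 <= n_aliens < n_workers, got {self.n_aliens}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if self.paternity_weights is not None:
            w = tuple(float(x) for x in self.paternity_weights)
            if len(w) != self.n_fathers_per_queen:
                raise ValueError("paternity_weights length must equal n_fathers_per_queen")
            if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("paternity_weights must be nonnegative and sum to 1")
            object.__setattr__(self, "paternity_weights", w)
        if self.paternity_counts is not None:
            c = tuple(int(x) for x in self.paternity_counts)
            if len(c) != self.n_fathers_per_queen:
                raise ValueError("paternity_counts length must equal n_fathers_per_queen")
            if any(x < 0 for x in c):
                raise ValueError("paternity_counts must be nonnegative")
            object.__setattr__(self, "paternity_counts", c)

    def weights(self) -> np.ndarray:
        if self.paternity_weights is None:
            return np.full(self.n_fathers_per_queen, 1.0 / self.n_fathers_per_queen)
        return np.asarray(self.paternity_weights)


@dataclass(frozen=True)
class WorkerTruth:
    queen_index: int | None
    father_index: int | None
    alien: bool


@dataclass(frozen=True)
class ColonyTruth:
    """Ground truth of a simulated colony, for recovery tests."""

    colony: str
    site: str
    queen_genotypes: tuple[dict, ...]          # per queen: {locus: (a, b)}
    father_genotypes: tuple[tuple[dict, ...], ...]  # per queen, per father: {locus: a}
    workers: dict[str, WorkerTruth]
    alien_ids: tuple[str, ...]

    def patriline_counts(self, queen: int = 0) -> tuple[int, ...]:
        counts = [0] * len(self.father_genotypes[queen])
        for w in self.workers.values():
            if not w.alien and w.queen_index == queen:
                counts[w.father_index] += 1
        return tuple(counts)


def _draw_diploid(rng, labels, p) -> tuple[int, int]:
    a, b = rng.choice(len(labels), size=2, p=p)
    return (int(labels[a]), int(labels[b]))


def _draw_haploid(rng, labels, p) -> int:
    return int(labels[rng.choice(len(labels), p=p)])


def simulate_colony(
    model: PopulationModel,
    site: str | int,
    config: ColonyConfig = ColonyConfig(),
    seed=0,
    colony_id: str = "C1",
) -> tuple[GenotypeTable, ColonyTruth]:
    """Simulate one colony under Mendelian haplodiploid inheritance.

    Queens are two independent draws per locus from the site frequencies,
    fathers one draw per locus.  Each of the colony's own workers receives
    one uniformly chosen queen allele plus its father's allele; aliens are
    offspring of an independent random queen x male from the same site.
    Missing calls are masked independently per (individual, locus).
    """
    rng = _rng(seed)
    s = model.site_index(site)
    site_name = model.site_names[s]
    L = len(model.loci)

    def sample_queen():
        return {
            locus: tuple(sorted(_draw_diploid(rng, model.allele_labels[l], model.site_frequencies[s][l])))
            for l, locus in enumerate(model.loci)
        }

    def sample_male():
        return {
            locus: _draw_haploid(rng, model.allele_labels[l], model.site_frequencies[s][l])
            for l, locus in enumerate(model.loci)
        }

    def offspring(queen, father):
        child = {}
        for locus in model.loci:
            maternal = queen[locus][rng.integers(2)]
            child[locus] = tuple(sorted((maternal, father[locus])))
        return child

    queens = tuple(sample_queen() for _ in range(config.n_queens))
    fathers = tuple(
        tuple(sample_male() for _ in range(config.n_fathers_per_queen))
        for _ in range(config.n_queens)
    )

    n_own = config.n_workers - config.n_aliens
    # own workers round-robin across queens; fathers by counts or weights
    queen_of = [i % config.n_queens for i in range(n_own)]
    if config.paternity_counts is not None:
        per_queen_father: dict[int, list[int]] = {}
        for q in range(config.n_queens):
            seq = [
                f for f, c in enumerate(config.paternity_counts) for _ in range(c)
            ]
            n_q = queen_of.count(q)
            if len(seq) != n_q:
                raise ValueError(
                    f"paternity_counts sum {len(seq)} != workers of queen {q} ({n_q})"
                )
            rng.shuffle(seq)
            per_queen_father[q] = seq
        cursor = {q: 0 for q in range(config.n_queens)}
        father_of = []
        for q in queen_of:
            father_of.append(per_queen_father[q][cursor[q]])
            cursor[q] += 1
    else:
        w = config.weights()
        father_of = [int(rng.choice(config.n_fathers_per_queen, p=w)) for _ in queen_of]

    records = []
    workers: dict[str, WorkerTruth] = {}
    alien_ids = []
    for i in range(n_own):
        wid = f"{colony_id}_w{i + 1}"
        child = offspring(queens[queen_of[i]], fathers[queen_of[i]][father_of[i]])
        records.append((wid, colony_id, site_name, "worker", 2, child))
        workers[wid] = WorkerTruth(queen_of[i], father_of[i], alien=False)
    for j in range(config.n_aliens):
        wid = f"{colony_id}_w{n_own + j + 1}"
        child = offspring(sample_queen(), sample_male())
        records.append((wid, colony_id, site_name, "worker", 2, child))
        workers[wid] = WorkerTruth(None, None, alien=True)
        alien_ids.append(wid)
    if config.include_queen_genotype:
        for q in range(config.n_queens):
            qid = f"{colony_id}_q{q + 1}"
            records.append((qid, colony_id, site_name, "queen", 2, dict(queens[q])))

    table = GenotypeTable.from_records(records, loci=model.loci)
    if config.missing_rate > 0:
        mask = rng.random((table.n_individuals, L)) < config.missing_rate
        alleles = table.alleles.copy()
        alleles[mask] = MISSING
        table = GenotypeTable(table.meta, table.loci, alleles)
    truth = ColonyTruth(
        colony=colony_id,
        site=site_name,
        queen_genotypes=queens,
        father_genotypes=fathers,
        workers=workers,
        alien_ids=tuple(alien_ids),
    )
    return table, truth


# ---------------------------------------------------------------------- study
@dataclass(frozen=True)
class SyntheticStudy:
    """A multi-site collection of simulated colonies plus its truth registry."""

    table: GenotypeTable
    truths: dict[str, ColonyTruth]
    model: PopulationModel

    def colony_ids(self) -> list[str]:
        return list(self.truths)


def simulate_study(
    model: PopulationModel,
    design: Mapping[str, Sequence[ColonyConfig]],
    seed=0,
) -> SyntheticStudy:
    """Simulate every colony of a study design.

    ``design`` maps site name -> one :class:`ColonyConfig` per colony.
    Colony seeds are spawned from the master seed, so output is
    deterministic and independent of downstream consumption order.
    """
    if not design or any(len(cfgs) == 0 for cfgs in design.values()):
        raise ValueError("design must request at least one colony per site")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    n_total = sum(len(cfgs) for cfgs in design.values())
    children = ss.spawn(n_total)
    tables, truths = [], {}
    k = 0
    for site, cfgs in design.items():
        model.site_index(site)  # validates
        for c, cfg in enumerate(cfgs):
            cid = f"{site}-C{c + 1:03d}"
            tbl, truth = simulate_colony(model, site, cfg, seed=children[k], colony_id=cid)
            tables.append(tbl)
            truths[cid] = truth
            k += 1
    return SyntheticStudy(table=GenotypeTable.concat(tables), truths=truths, model=model)


def write_truth_csv(study: SyntheticStudy, path) -> None:
    """Per-worker truth (maternity, patriline, alien flag) keyed by id."""
    rows = []
    for cid, truth in study.truths.items():
        for wid, wt in truth.workers.items():
            rows.append(
                {
                    "id": wid,
                    "colony": cid,
                    "site": truth.site,
                    "queen_index": "" if wt.queen_index is None else wt.queen_index,
                    "father_index": "" if wt.father_index is None else wt.father_index,
                    "alien": int(wt.alien),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------------ yaml spec
def study_from_spec(spec: Mapping) -> tuple[PopulationModel, dict[str, list[ColonyConfig]], int]:
    """Build model + design from a simulation spec mapping (see
    :func:`study_from_yaml` for the schema)."""
    seed = int(spec.get("seed", 0))
    pop = dict(spec.get("population", {}))
    sites = pop.get("sites") or [f"site{i + 1}" for i in range(int(pop.get("n_sites", 1)))]
    model = make_population_model(
        n_loci=int(pop.get("n_loci", 12)),
        alleles_per_locus=pop.get("alleles_per_locus", 20),
        frequency_scheme=pop.get("frequency_scheme", "uniform"),
        n_sites=len(sites),
        divergence=float(pop.get("divergence", 0.0)),
        seed=seed,
        dirichlet_alpha=float(pop.get("dirichlet_alpha", 1.0)),
        site_names=sites,
    )
    design: dict[str, list[ColonyConfig]] = {}
    for site, entries in spec.get("colonies", {}).items():
        cfgs: list[ColonyConfig] = []
        for entry in entries:
            entry = dict(entry)
            count = int(entry.pop("count", 1))
            for key in ("paternity_weights", "paternity_counts"):
                if entry.get(key) is not None:
                    entry[key] = tuple(entry[key])
            cfgs.extend([ColonyConfig(**entry)] * count)
        design[site] = cfgs
    return model, design, seed


def study_from_yaml(path) -> tuple[PopulationModel, dict[str, list[ColonyConfig]], int]:
    """Load a simulation spec: population model, per-site colony designs, seed.

    Schema::

        seed: 7
        population:
          n_loci: 12
          alleles_per_locus: 20        # or a per-locus list
          frequency_scheme: uniform    # or dirichlet
          dirichlet_alpha: 1.0
          divergence: 0.0
          sites: [north, south]
        colonies:
          north:
            - {n_workers: 8, count: 23}
            - {n_workers: 16, n_fathers_per_queen: 2, paternity_counts: [14, 2]}
          south:
            - {n_workers: 8, count: 3}
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return study_from_spec(spec)
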