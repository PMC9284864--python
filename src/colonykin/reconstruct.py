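"""Queen/father pedigree reconstruction from worker genotypes.

Haplodiploid Mendelian logic: each diploid worker carries one of its
queen's two alleles plus its haploid father's single allele at every locus.
Given a colony's worker genotypes, the reconstruction searches for the most
parsimonious explanation in lexicographic objective order

    (number of queens, number of fathers, number of alien workers)

i.e. queens are minimised first, then mates per queen, with alien exclusion
as the final tie-break; excluding up to ``max_aliens`` stray workers is
preferred over invoking a second queen.  Fathers must come before aliens in
the objective because a single-queen zero-alien explanation with inflated
father counts exists for almost any worker set (per locus, the pair
{father allele, one allele of the odd worker} covers everybody), so an
aliens-first order would never flag a genuinely foreign worker.  The
father count is minimised by an exact search over worker partitions
(patrilines) jointly with per-locus queen genotype choices; all co-optimal
queen solutions are retained.

A queen allele that no worker happened to inherit is representable as a
wildcard (the queen may be homozygous, or carry an unobserved allele); the
wildcard is reported distinctly and never silently concretised.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .tables import MISSING, WILDCARD, GenotypeTable

Pair = tuple[int, int]
Call = tuple[int, int] | None

CLASS_MONANDROUS = "monogyne_monandrous"
CLASS_POLYANDROUS = "monogyne_polyandrous"
CLASS_MULTI_QUEEN = "multi_queen"
CLASS_UNDETERMINED = "undetermined"


class ReconstructionError(ValueError):
    pass


class _BudgetExceeded(Exception):
    pass


@dataclass
class ReconstructionOptions:
    """Search knobs.

    ``alien_conflict_loci``: a worker is only flagged alien if its exclusion
    strictly improves the objective AND its genotype is irreconcilable with
    every co-optimal queen solution at at least this many loci — a guard
    against single-locus genotyping artifacts.  ``exhaustive_limit`` caps the
    number of search nodes; beyond it the result is marked heuristic.
    """

    max_aliens: int = 1
    allow_two_queens: bool = True
    exhaustive_limit: int = 500_000
    alien_conflict_loci: int = 2


# ---------------------------------------------------------------- primitives
def candidate_queen_genotypes(worker_calls_at_locus: Sequence[Call]) -> set[Pair]:
    """All single-queen genotypes consistent with the worker calls at one locus.

    A pair {a, b} (a == b allowed) over the colony's observed alleles is a
    candidate iff every non-missing worker call contains a or b.  A wildcard
    pair (WILDCARD, a) — queen carries a plus an allele unobserved among the
    workers — is admitted only when allele a alone covers every worker.
    An empty result means no single queen can explain this locus.
    """
    observed = [c for c in worker_calls_at_locus if c is not None]
    if not observed:
        raise ReconstructionError("need at least one non-missing worker call")
    return _locus_candidates(worker_calls_at_locus)


def _locus_candidates(calls: Sequence[Call]) -> set[Pair]:
    observed = [c for c in calls if c is not None]
    if not observed:
        return {(WILDCARD, WILDCARD)}
    alleles = sorted({a for c in observed for a in c})
    cands: set[Pair] = set()
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            if all(a in c or b in c for c in observed):
                cands.add((a, b))
    for a in alleles:
        if all(a in c for c in observed):
            cands.add((WILDCARD, a))
    return cands


def _queen_has(queen: Pair, allele: int, permissive_wildcard: bool = False) -> bool:
    qa, qb = queen
    if qa == WILDCARD and qb == WILDCARD:
        return True
    if qa == WILDCARD:
        # the wildcard allele is by construction unobserved among the workers
        # that defined the candidate, so a worker's maternal allele must be qb
        # — unless we are asked to be permissive (conflict scoring of workers
        # outside that set, who could carry the unobserved allele).
        return permissive_wildcard or allele == qb
    return allele == qa or allele == qb


def _paternal_options(call: Pair, queen: Pair) -> frozenset[int]:
    x, y = call
    poss = set()
    if _queen_has(queen, x):
        poss.add(y)
    if _queen_has(queen, y):
        poss.add(x)
    return frozenset(poss)


# ------------------------------------------------------------- single queen
@dataclass
class _SingleQueenSolution:
    worker_index: tuple[int, ...]            # indices into the caller's worker list
    partition: tuple[tuple[int, ...], ...]   # patrilines, as positions in worker_index
    queen_solutions: tuple[tuple[Pair, ...], ...]  # per locus, feasible queen pairs
    father_alleles: tuple[tuple[frozenset[int] | None, ...], ...]  # per patriline per locus
    n_fathers: int


class _Budget:
    def __init__(self, limit: int):
        self.limit = limit
        self.used = 0

    def tick(self, n: int = 1) -> None:
        self.used += n
        if self.used > self.limit:
            raise _BudgetExceeded()


class _SingleQueenSearch:
    """Minimal-father explanation of a worker set under one queen.

    ``calls[w][l]`` is worker w's call at locus l.  Exact search: iterative
    deepening on the number of patrilines with a canonical-assignment DFS;
    per-locus state tracks, for every still-viable queen candidate, the
    running intersection of paternal possibilities per patriline.
    """

    def __init__(self, calls: Sequence[Sequence[Call]], budget: _Budget):
        self.calls = calls
        self.budget = budget
        self.n = len(calls)
        self.L = len(calls[0]) if self.n else 0
        self.feasible = True
        self.poss: list[dict[Pair, list[frozenset[int] | None]]] = []
        for l in range(self.L):
            cands = sorted(_locus_candidates([calls[w][l] for w in range(self.n)]))
            by_cand: dict[Pair, list[frozenset[int] | None]] = {}
            for cand in cands:
                row: list[frozenset[int] | None] = []
                ok = True
                for w in range(self.n):
                    c = calls[w][l]
                    if c is None:
                        row.append(None)
                        continue
                    opts = _paternal_options(c, cand)
                    if not opts:
                        ok = False
                        break
                    row.append(opts)
                if ok:
                    by_cand[cand] = row
            if not by_cand:
                self.feasible = False
                return
            self.poss.append(by_cand)

    def _assign(self, state, w, g):
        self.budget.tick()
        new_state = []
        for l in range(self.L):
            surviving = {}
            for cand, groups in state[l].items():
                pw = self.poss[l][cand][w]
                if g < len(groups):
                    cur = groups[g]
                    if cur is None:
                        merged = pw
                    elif pw is None:
                        merged = cur
                    else:
                        merged = cur & pw
                        if not merged:
                            continue
                    new_groups = groups[:g] + (merged,) + groups[g + 1:]
                else:
                    new_groups = groups + (pw,)
                surviving[cand] = new_groups
            if not surviving:
                return None
            new_state.append(surviving)
        return new_state

    def solve(self) -> _SingleQueenSolution | None:
        if not self.feasible:
            return None
        if self.n == 0:
            return None
        init = [{cand: () for cand in self.poss[l]} for l in range(self.L)]
        for m in range(1, self.n + 1):
            hit = self._dfs(init, [0] * self.n, 0, 0, m)
            if hit is not None:
                state, assignment, n_groups = hit
                return self._finalise(state, assignment, n_groups)
        return None

    def _dfs(self, state, assignment, w, n_groups, m):
        if w == self.n:
            return state, list(assignment), n_groups
        for g in range(min(n_groups + 1, m)):
            nxt = self._assign(state, w, g)
            if nxt is not None:
                assignment[w] = g
                hit = self._dfs(nxt, assignment, w + 1, max(n_groups, g + 1), m)
                if hit is not None:
                    return hit
        return None

    def greedy(self) -> _SingleQueenSolution:
        """First-fit fallback when the node budget is exhausted.

        Always succeeds (a covering queen candidate guarantees every worker a
        nonempty paternal set, so a fresh patriline is always admissible) but
        the father count carries no optimality proof.
        """
        state = [{cand: () for cand in self.poss[l]} for l in range(self.L)]
        assignment = []
        n_groups = 0
        unlimited = _Budget(float("inf"))
        saved, self.budget = self.budget, unlimited
        try:
            for w in range(self.n):
                placed = False
                for g in range(n_groups + 1):
                    nxt = self._assign(state, w, g)
                    if nxt is not None:
                        state = nxt
                        assignment.append(g)
                        n_groups = max(n_groups, g + 1)
                        placed = True
                        break
                if not placed:  # cannot happen; defensive
                    raise ReconstructionError("greedy placement failed")
        finally:
            self.budget = saved
        return self._finalise(state, assignment, n_groups)

    def _finalise(self, state, assignment, n_groups) -> _SingleQueenSolution:
        queen_solutions = tuple(tuple(sorted(state[l].keys())) for l in range(self.L))
        rep = tuple(_representative_pair(qs) for qs in queen_solutions)
        father_alleles = []
        for g in range(n_groups):
            per_locus = []
            for l in range(self.L):
                per_locus.append(state[l][rep[l]][g] if g < len(state[l][rep[l]]) else None)
            father_alleles.append(tuple(per_locus))
        partition = tuple(
            tuple(w for w in range(self.n) if assignment[w] == g) for g in range(n_groups)
        )
        return _SingleQueenSolution(
            worker_index=tuple(range(self.n)),
            partition=partition,
            queen_solutions=queen_solutions,
            father_alleles=tuple(father_alleles),
            n_fathers=n_groups,
        )


def _representative_pair(solutions: Sequence[Pair]) -> Pair:
    """Deterministic representative: concrete pairs first, lexicographic."""
    concrete = [s for s in solutions if WILDCARD not in s]
    return min(concrete) if concrete else min(solutions)


# -------------------------------------------------------------------- results
@dataclass(frozen=True)
class ColonyReconstruction:
    """Inferred pedigree of one colony.

    ``queen_solutions[q][l]`` holds every equally parsimonious queen genotype
    at locus l (pairs; WILDCARD = unobserved allele); ``queen_genotype`` is
    the deterministic representative.  ``fathers[f][l]`` is the set of
    alleles still possible for father f at locus l (None = unconstrained).
    ``assignment`` maps worker id -> "alien" or (queen_index, father_index).
    """

    colony: str
    loci: tuple[str, ...]
    worker_ids: tuple[str, ...]
    n_queens: int
    n_fathers: int
    n_aliens: int
    classification: str
    queen_solutions: tuple[tuple[tuple[Pair, ...], ...], ...]
    queen_genotype: tuple[tuple[Pair, ...], ...]
    fathers: tuple[tuple[frozenset[int] | None, ...], ...]
    father_queen: tuple[int, ...]
    assignment: Mapping[str, object]
    heuristic: bool = False
    notes: tuple[str, ...] = ()

    @property
    def alien_ids(self) -> tuple[str, ...]:
        return tuple(w for w, a in self.assignment.items() if a == "alien")

    def objective(self) -> tuple[int, int, int]:
        """(n_queens, n_fathers, n_aliens): the lexicographic parsimony score."""
        return (self.n_queens, self.n_fathers, self.n_aliens)

    def queen_genotype_map(self, queen: int = 0) -> dict[str, Pair | None]:
        """Unambiguous concrete queen genotype per locus (None if ambiguous).

        A locus counts as ambiguous when several co-optimal solutions remain
        or the single solution carries a wildcard; used when the inferred
        queen feeds further analyses (e.g. mate relatedness).
        """
        out: dict[str, Pair | None] = {}
        for l, locus in enumerate(self.loci):
            sols = self.queen_solutions[queen][l]
            if len(sols) == 1 and WILDCARD not in sols[0]:
                out[locus] = sols[0]
            else:
                out[locus] = None
        return out

    def father_genotype_map(self, father: int = 0) -> dict[str, tuple[int] | None]:
        """Unambiguous haploid father genotype per locus (None if ambiguous)."""
        out: dict[str, tuple[int] | None] = {}
        for l, locus in enumerate(self.loci):
            opts = self.fathers[father][l]
            if opts is not None and len(opts) == 1:
                out[locus] = (next(iter(opts)),)
            else:
                out[locus] = None
        return out


# ------------------------------------------------------------------ top level
def _extract_worker_calls(
    table: GenotypeTable, colony: str | None
) -> tuple[list[str], list[list[Call]], list[str]]:
    sub = table.filter(colony=colony, caste="worker") if colony else table.filter(caste="worker")
    ids, calls = [], []
    for ind in sub.ids:
        g = sub.genotype(ind, as_diploid=True)
        row = [g[locus] for locus in sub.loci]
        if all(c is None for c in row):
            continue  # no usable genotype
        ids.append(ind)
        calls.append(row)
    return ids, calls, list(sub.loci)


def reconstruct_colony(
    table: GenotypeTable,
    colony: str | None = None,
    options: ReconstructionOptions | None = None,
) -> ColonyReconstruction:
    """Infer the minimal pedigree explaining one colony's worker genotypes.

    Tier order (lexicographic objective): single queen with 0 aliens, single
    queen excluding up to ``max_aliens`` workers, two queens; father count
    minimised within each tier by exact search.  If no tier succeeds the
    colony is classified undetermined.
    """
    opts = options or ReconstructionOptions()
    ids, calls, loci = _extract_worker_calls(table, colony)
    cid = colony if colony is not None else (table.colonies()[0] if table.colonies() else "?")
    if len(ids) < 2:
        raise ReconstructionError(f"colony {cid!r}: need >= 2 workers with usable genotypes")
    budget = _Budget(opts.exhaustive_limit)
    heuristic = False
    notes: list[str] = []

    def single_queen(sub_idx: Sequence[int]):
        nonlocal heuristic
        sub_calls = [calls[i] for i in sub_idx]
        search = _SingleQueenSearch(sub_calls, budget)
        try:
            return search.solve()
        except _BudgetExceeded:
            heuristic = True
            notes.append("search budget exhausted; first-fit father assignment used")
            return search.greedy() if search.feasible else None

    everyone = list(range(len(ids)))

    # single-queen candidates: for each alien count k, the min-father solution;
    # ranked by (n_fathers, k) so an exclusion is only accepted when it
    # strictly reduces the father count
    candidates: list[tuple[int, int, tuple[int, ...], _SingleQueenSolution]] = []
    sol = single_queen(everyone)
    if sol is not None:
        candidates.append((sol.n_fathers, 0, (), sol))
    if not (sol is not None and sol.n_fathers == 1):
        for k in range(1, opts.max_aliens + 1):
            if k >= len(ids):
                break
            best: tuple[int, tuple[int, ...], _SingleQueenSolution] | None = None
            for excluded in itertools.combinations(everyone, k):
                kept = [i for i in everyone if i not in excluded]
                s = single_queen(kept)
                if s is not None and (best is None or s.n_fathers < best[0]):
                    best = (s.n_fathers, excluded, s)
            if best is not None:
                candidates.append((best[0], k, best[1], best[2]))
    for n_fathers, k, excluded, s in sorted(candidates, key=lambda c: (c[0], c[1])):
        if k == 0:
            return _build_single(cid, loci, ids, everyone, [], s, heuristic, notes)
        conflicts = {
            ids[i]: _conflict_locus_count(calls[i], s.queen_solutions) for i in excluded
        }
        if all(c >= opts.alien_conflict_loci for c in conflicts.values()):
            kept = [i for i in everyone if i not in excluded]
            return _build_single(cid, loci, ids, kept, list(excluded), s, heuristic, notes)
        notes.append(
            "alien exclusion rejected: conflicting at fewer than "
            f"{opts.alien_conflict_loci} loci ({conflicts})"
        )

    # final tier: two queens
    if opts.allow_two_queens and len(ids) >= 2:
        try:
            two = _solve_two_queens(calls, budget)
        except _BudgetExceeded:
            heuristic = True
            notes.append("two-queen search budget exhausted")
            two = None
        if two is not None:
            return _build_two(cid, loci, ids, two, heuristic, notes)

    assignment = {w: "undetermined" for w in ids}
    return ColonyReconstruction(
        colony=cid,
        loci=tuple(loci),
        worker_ids=tuple(ids),
        n_queens=0,
        n_fathers=0,
        n_aliens=0,
        classification=CLASS_UNDETERMINED,
        queen_solutions=(),
        queen_genotype=(),
        fathers=(),
        father_queen=(),
        assignment=assignment,
        heuristic=heuristic,
        notes=tuple(notes),
    )


def _conflict_locus_count(worker_calls: Sequence[Call], queen_solutions) -> int:
    """Loci where the worker cannot carry any allele of any queen solution.

    Wildcard queen alleles are treated permissively (the excluded worker
    could carry the unobserved allele), so this undercounts rather than
    overcounts conflicts.
    """
    n = 0
    for l, call in enumerate(worker_calls):
        if call is None:
            continue
        compatible = any(
            _queen_has(q, call[0], permissive_wildcard=True)
            or _queen_has(q, call[1], permissive_wildcard=True)
            for q in queen_solutions[l]
        )
        if not compatible:
            n += 1
    return n


def _solve_two_queens(calls, budget):
    """Best (min total fathers) split of workers between two queens."""
    n = len(calls)
    best = None
    for mask in range(1, 2 ** (n - 1)):
        budget.tick()
        group_a = [0] + [w for w in range(1, n) if not (mask >> (w - 1)) & 1]
        group_b = [w for w in range(1, n) if (mask >> (w - 1)) & 1]
        sa = _SingleQueenSearch([calls[w] for w in group_a], budget).solve()
        if sa is None:
            continue
        sb = _SingleQueenSearch([calls[w] for w in group_b], budget).solve()
        if sb is None:
            continue
        total = sa.n_fathers + sb.n_fathers
        if best is None or total < best[0]:
            best = (total, group_a, group_b, sa, sb)
            if total == 2:
                break
    return best


def _build_single(cid, loci, ids, kept, excluded, sol, heuristic, notes):
    assignment: dict[str, object] = {}
    for g, members in enumerate(sol.partition):
        for pos in members:
            assignment[ids[kept[pos]]] = (0, g)
    for i in excluded:
        assignment[ids[i]] = "alien"
    classification = CLASS_MONANDROUS if sol.n_fathers == 1 else CLASS_POLYANDROUS
    return ColonyReconstruction(
        colony=cid,
        loci=tuple(loci),
        worker_ids=tuple(ids),
        n_queens=1,
        n_fathers=sol.n_fathers,
        n_aliens=len(excluded),
        classification=classification,
        queen_solutions=(sol.queen_solutions,),
        queen_genotype=(tuple(_representative_pair(q) for q in sol.queen_solutions),),
        fathers=sol.father_alleles,
        father_queen=tuple([0] * sol.n_fathers),
        assignment=assignment,
        heuristic=heuristic,
        notes=tuple(notes),
    )


def _build_two(cid, loci, ids, two, heuristic, notes):
    _, group_a, group_b, sa, sb = two
    assignment: dict[str, object] = {}
    for g, members in enumerate(sa.partition):
        for pos in members:
            assignment[ids[group_a[pos]]] = (0, g)
    for g, members in enumerate(sb.partition):
        for pos in members:
            assignment[ids[group_b[pos]]] = (1, sa.n_fathers + g)
    return ColonyReconstruction(
        colony=cid,
        loci=tuple(loci),
        worker_ids=tuple(ids),
        n_queens=2,
        n_fathers=sa.n_fathers + sb.n_fathers,
        n_aliens=0,
        classification=CLASS_MULTI_QUEEN,
        queen_solutions=(sa.queen_solutions, sb.queen_solutions),
        queen_genotype=(
            tuple(_representative_pair(q) for q in sa.queen_solutions),
            tuple(_representative_pair(q) for q in sb.queen_solutions),
        ),
        fathers=sa.father_alleles + sb.father_alleles,
        father_queen=tuple([0] * sa.n_fathers + [1] * sb.n_fathers),
        assignment=assignment,
        heuristic=heuristic,
        notes=tuple(notes),
    )


def reconstruct_all(
    table: GenotypeTable, options: ReconstructionOptions | None = None
) -> dict[str, ColonyReconstruction]:
    """Reconstruct every colony in a table (workers only)."""
    out = {}
    for colony in table.colonies():
        out[colony] = reconstruct_colony(table, colony, options)
    return out


# --------------------------------------------------------------- derived ops
@dataclass(frozen=True)
class PaternityPartition:
    counts: tuple[int, ...]
    fractions: tuple[float, ...]


def paternity_partition(recon: ColonyReconstruction) -> PaternityPartition:
    """Per-father worker counts and fractions over the colony's own workers.

    Fathers are reported in descending count order, which makes the result
    invariant under father relabeling.
    """
    if recon.classification == CLASS_UNDETERMINED:
        raise ReconstructionError("cannot partition paternity of an undetermined colony")
    counts = [0] * recon.n_fathers
    for a in recon.assignment.values():
        if a != "alien":
            counts[a[1]] += 1
    total = sum(counts)
    counts = tuple(sorted(counts, reverse=True))
    return PaternityPartition(counts=counts, fractions=tuple(c / total for c in counts))


@dataclass(frozen=True)
class MatchReport:
    """Per-locus comparison of an inferred queen against an observed genotype."""

    per_locus: Mapping[str, str]  # "match" | "mismatch" | "ambiguous"

    @property
    def n_match(self) -> int:
        return sum(v == "match" for v in self.per_locus.values())

    @property
    def n_mismatch(self) -> int:
        return sum(v == "mismatch" for v in self.per_locus.values())

    @property
    def n_ambiguous(self) -> int:
        return sum(v == "ambiguous" for v in self.per_locus.values())

    @property
    def ok(self) -> bool:
        return self.n_mismatch == 0


def _solution_matches(solution: Pair, observed: Pair) -> bool:
    qa, qb = solution
    if qa == WILDCARD and qb == WILDCARD:
        return True
    if qa == WILDCARD:
        return qb in observed
    return tuple(sorted(solution)) == tuple(sorted(observed))


def verify_against_queen(
    recon: ColonyReconstruction,
    observed_queen_genotype: Mapping[str, tuple[int, ...] | None],
    queen: int = 0,
) -> MatchReport:
    """Compare an empirically genotyped queen with the inferred solutions.

    A locus is a mismatch only if no co-optimal queen solution contains the
    observed pair; wildcard solutions match anything containing their
    concrete allele.  Loci missing in the observation, or without worker
    information, are ambiguous.
    """
    if recon.n_queens == 0:
        raise ReconstructionError("undetermined reconstruction has no queen to verify")
    per_locus: dict[str, str] = {}
    for l, locus in enumerate(recon.loci):
        obs = observed_queen_genotype.get(locus)
        if obs is None:
            per_locus[locus] = "ambiguous"
            continue
        obs_pair = (obs[0], obs[-1])
        sols = recon.queen_solutions[queen][l]
        if sols == ((WILDCARD, WILDCARD),):
            per_locus[locus] = "ambiguous"
        elif any(_solution_matches(s, obs_pair) for s in sols):
            per_locus[locus] = "match"
        else:
            per_locus[locus] = "mismatch"
    return MatchReport(per_locus=per_locus)
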