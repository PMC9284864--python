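"""Independent brute-force pedigree parsimony oracle for tiny colonies.

Enumerates, with no code shared with the package, every explanation of a
set of worker genotypes: all queen-genotype choices per locus (including
"queen carries an unobserved allele"), all set partitions of workers into
patrilines, all alien subsets, and all two-queen maternity splits.  Returns
the lexicographically minimal (n_queens, n_fathers, n_aliens) objective.
Feasible only for a handful of workers and loci.
"""
import itertools

UNSEEN = "unseen"  # the queen's second allele was inherited by no worker


def _queen_pairs(calls):
    """All queen genotype hypotheses covering every non-missing call at a locus."""
    observed = [c for c in calls if c is not None]
    if not observed:
        return [("any", "any")]
    alleles = sorted({a for c in observed for a in c})
    pairs = []
    for a, b in itertools.combinations_with_replacement(alleles, 2):
        if all(a in c or b in c for c in observed):
            pairs.append((a, b))
    for a in alleles:
        if all(a in c for c in observed):
            pairs.append((a, UNSEEN))
    return pairs


def _maternal_ok(queen, allele):
    a, b = queen
    if a == "any":
        return True
    if b == UNSEEN:
        return allele == a
    return allele in (a, b)


def _partition_feasible(groups, loci_calls):
    """groups: lists of worker indices; loci_calls[l][w]: call of worker w."""
    members = [w for g in groups for w in g]
    for calls in loci_calls:
        member_calls = [calls[w] for w in members]
        ok_here = False
        for queen in _queen_pairs(member_calls):
            if all(_group_father_exists(g, calls, queen) for g in groups):
                ok_here = True
                break
        if not ok_here:
            return False
    return True


def _group_father_exists(group, calls, queen):
    options = None
    for w in group:
        c = calls[w]
        if c is None:
            continue
        x, y = c
        opts = set()
        if _maternal_ok(queen, x):
            opts.add(y)
        if _maternal_ok(queen, y):
            opts.add(x)
        if not opts:
            return False
        options = opts if options is None else options & opts
        if options is not None and not options:
            return False
    return True


def _set_partitions(items):
    """All set partitions via restricted-growth strings."""
    items = list(items)
    if not items:
        yield []
        return

    def rec(i, groups):
        if i == len(items):
            yield [list(g) for g in groups]
            return
        for g in groups:
            g.append(items[i])
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([items[i]])
        yield from rec(i + 1, groups)
        groups.pop()

    yield from rec(0, [])


def min_fathers(worker_idx, loci_calls):
    """Minimal patriline count for one queen over a worker subset, or None."""
    best = None
    for partition in _set_partitions(worker_idx):
        if best is not None and len(partition) >= best:
            continue
        if _partition_feasible(partition, loci_calls):
            best = len(partition)
    return best


def minimal_objective(worker_calls, max_aliens=1, allow_two_queens=True):
    """Lexicographic-min (n_queens, n_fathers, n_aliens) over all explanations.

    ``worker_calls[w][l]``: unordered pair or None.  Returns None when no
    explanation exists within the allowed tiers.
    """
    n = len(worker_calls)
    L = len(worker_calls[0])
    loci_calls = [[worker_calls[w][l] for w in range(n)] for l in range(L)]
    options = []
    for k in range(0, min(max_aliens, n - 1) + 1):
        for aliens in itertools.combinations(range(n), k):
            kept = [w for w in range(n) if w not in aliens]
            f = min_fathers(kept, loci_calls)
            if f is not None:
                options.append((1, f, k))
    if allow_two_queens and n >= 2:
        for size_a in range(1, n):
            for group_a in itertools.combinations(range(1, n), size_a - 1):
                ga = [0, *group_a]
                gb = [w for w in range(1, n) if w not in group_a]
                fa = min_fathers(ga, loci_calls)
                fb = min_fathers(gb, loci_calls)
                if fa is not None and fb is not None:
                    options.append((2, fa + fb, 0))
    return min(options) if options else None
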