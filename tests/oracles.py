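"""Independent oracles shared by the unit and acceptance suites.

Every function here recomputes a quantity by a route deliberately different
from the implementation it checks: direct scalar arithmetic for the score
combination, exhaustive path enumeration for local alignment, combinatorial
enumeration for the hypergeometric tail, a sort/scale/running-minimum pass
for BH, and naive full-table scans for the store queries.
"""

from itertools import combinations
from math import comb


def combine_oracle(scores: dict, p: float) -> float:
    """Channel combination by direct scalar evaluation."""
    prod = 1.0
    for s in scores.values():
        c = (s - p) / (1.0 - p)
        if c < 0.0:
            c = 0.0
        prod = prod * (1.0 - c)
    return p + (1.0 - p) * (1.0 - prod)


def merge_oracle(sources, p: float) -> float:
    """Within-channel noisy-OR of prior-corrected source scores."""
    sources = list(sources)
    corrected = [(s - p) / (1.0 - p) for s in sources if s > p]
    if len(corrected) <= 1:
        return max(sources) if sources else 0.0
    prod = 1.0
    for c in corrected:
        prod = prod * (1.0 - c)
    return p + (1.0 - p) * (1.0 - prod)


def sw_oracle(a: str, b: str, scheme) -> float:
    """Optimal local alignment score by exhaustive enumeration.

    Enumerates every monotone residue matching; unmatched residues between
    consecutive matched pairs form one affine gap per sequence (a gap of
    length L costs open + (L-1)*extend).
    """
    best = 0.0
    for k in range(1, min(len(a), len(b)) + 1):
        for ai in combinations(range(len(a)), k):
            for bj in combinations(range(len(b)), k):
                score = 0.0
                for t in range(k):
                    score += scheme.substitution(a[ai[t]], b[bj[t]])
                    if t:
                        for gap in (ai[t] - ai[t - 1] - 1,
                                    bj[t] - bj[t - 1] - 1):
                            if gap:
                                score += (scheme.gap_open
                                          + (gap - 1) * scheme.gap_extend)
                best = max(best, score)
    return best


def tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """Hypergeometric upper tail by combinatorial enumeration."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(n, K) + 1)) / total


def bh_oracle(ps):
    """BH adjusted p-values: sort, i/m scaling, running minimum."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, ps[i] * m / (rank + 1))
        adjusted[i] = running
    return adjusted


def scan_edges(store, ids, cutoff):
    """Naive full-table scan: rows with both endpoints in ids, >= cutoff."""
    ids = set(ids)
    return {
        (p1, p2)
        for p1, p2, row in store.iter_rows()
        if p1 in ids and p2 in ids and row.combined >= cutoff
    }


def transfer_store_oracle(world, maps, channels):
    """Pair-by-pair penalty + aggregation, expressed as integer thousandths.

    ``channels`` is the fixed channel tuple, passed in so this module does
    not import the package under test.
    """
    prior = world.full.prior
    (h1, p1), (h2, p2) = next(iter(world.host_pairs.items()))
    o_host, o_para = maps[(h1, h2)], maps[(p1, p2)]
    if world.species[h1].lineage["class"] != world.species[h2].lineage["class"]:
        return {}
    if world.species[p1].lineage["genus"] != world.species[p2].lineage["genus"]:
        return {}
    incoming = {}
    for hp, pp, row in world.full.iter_cross_pairs(h1, p1):
        hit_h = o_host.entries.get(hp)
        hit_p = o_para.entries.get(pp)
        if hit_h is None or hit_p is None:
            continue
        (ht, sh), (pt, sp) = hit_h, hit_p
        factor = sh * sp
        vec = {c: row.direct[c] * factor for c in row.direct}
        key = tuple(sorted((ht, pt)))
        incoming.setdefault(key, []).append(vec)
    expected = {}
    for key, vecs in incoming.items():
        direct_row = world.full.get_pair(*key)
        direct = dict(direct_row.direct.items()) if direct_row else {}
        merged = {}
        for c in channels:
            sources = [direct.get(c, 0.0)] + [v.get(c, 0.0) for v in vecs]
            if any(s > 0 for s in sources):
                merged[c] = merge_oracle(sources, prior)
        expected[key] = {c: round(min(v, 0.999) * 1000)
                         for c, v in merged.items()}
    return expected
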