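"""Independent naive oracles used to cross-check the implementation.

Everything here is deliberately written as plain-Python brute force over
simple data structures (sets, dicts, lists of lists) and never calls into
the package, so it can serve as an independent recomputation path.
"""

import math


def dice(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return 2 * len(a & b) / (len(a) + len(b))


def bandock(fp, predictions, variant="max-dice"):
    """predictions: list of (ligand_bit_set, confidence)."""
    if fp is None or not predictions:
        return 0.0
    pairs = [(dice(fp, lig), conf) for lig, conf in predictions]
    if variant == "max-product":
        return max(d * c for d, c in pairs)
    best_d = max(d for d, _ in pairs)
    best_c = max(c for d, c in pairs if d == best_d)
    return best_d * best_c


def cosine(x, y) -> float:
    nx = math.sqrt(sum(v * v for v in x))
    ny = math.sqrt(sum(v * v for v in y))
    if nx == 0.0 or ny == 0.0:
        return 1.0
    return max(0.0, 1.0 - sum(a * b for a, b in zip(x, y)) / (nx * ny))


def rank_lists(rows, ids):
    """rows: list of signature vectors aligned with ids. Returns
    {query_id: [(hit_id, distance, rank), ...]} with the package's tie rule
    (distance ascending, then id ascending) re-derived independently."""
    out = {}
    for i, q in enumerate(ids):
        hits = [(cosine(rows[i], rows[j]), ids[j]) for j in range(len(ids)) if j != i]
        hits.sort()
        out[q] = [(hid, d, r + 1) for r, (d, hid) in enumerate(hits)]
    return out


def consensus_counts(approved, lists, cutoff):
    """{compound: (consensus_score, average_rank)} by direct recount."""
    tallies = {}
    for d in sorted(approved):
        if d not in lists:
            continue
        for hid, _dist, rank in lists[d]:
            if rank <= cutoff:
                tallies.setdefault(hid, []).append(rank)
    return {cid: (len(rs), sum(rs) / len(rs)) for cid, rs in tallies.items()}


def consensus_order(counts):
    """Ranked compound ids: consensus desc, average asc, id asc."""
    return sorted(counts, key=lambda c: (-counts[c][0], counts[c][1], c))


def binomial_tail(k, n, p):
    """P(X >= k) by enumerating all 2^n inclusion patterns."""
    total = 0.0
    for pattern in range(2 ** n):
        bits = bin(pattern).count("1")
        if bits >= k:
            total += p ** bits * (1 - p) ** (n - bits)
    return total


def ia(approved, lists, cutoff):
    drugs = sorted(d for d in approved if d in lists)
    succ = 0
    for d in drugs:
        others = set(drugs) - {d}
        if any(hid in others for hid, _, r in lists[d] if r <= cutoff):
            succ += 1
    return 100.0 * succ / len(drugs)


def nia(approved, lists, cutoff):
    counts = consensus_counts(approved, lists, cutoff)
    order = consensus_order(counts)
    ranks = {cid: i + 1 for i, cid in enumerate(order)}
    hits = sum(1 for d in approved if d in ranks and ranks[d] <= cutoff)
    return 100.0 * hits / len(approved)


def ndcg(approved, lists, cutoff):
    drugs = sorted(d for d in approved if d in lists)
    total = 0.0
    for d in drugs:
        others = set(drugs) - {d}
        dcg = sum((1.0 / math.log2(r + 1)) for hid, _, r in lists[d]
                  if r <= cutoff and hid in others)
        ideal = min(len(others), cutoff)
        idcg = sum(1.0 / math.log2(i + 2) for i in range(ideal))
        total += dcg / idcg if idcg > 0 else 0.0
    return total / len(drugs)


def nndcg(approved, lists, cutoff):
    counts = consensus_counts(approved, lists, cutoff)
    order = consensus_order(counts)
    dcg = sum(1.0 / math.log2(i + 2) for i, cid in enumerate(order[:cutoff])
              if cid in approved)
    ideal = min(len(approved), cutoff)
    idcg = sum(1.0 / math.log2(i + 2) for i in range(ideal))
    return dcg / idcg if idcg > 0 else 0.0


def control_ia(n_approved, cutoff, library_size):
    pool = library_size - 1
    if cutoff >= pool or pool - (n_approved - 1) < cutoff:
        return 100.0
    miss = 1.0
    # sequential draw without replacement, avoiding all K-1 relevant items
    for t in range(cutoff):
        miss *= (pool - (n_approved - 1) - t) / (pool - t)
    return 100.0 * (1.0 - miss)
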