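"""Independent brute-force oracles used to validate the implementations.

Everything here is written as plain, step-by-step Python against the
definitions, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math


def es_oracle(genes, scores, members, p=1.0):
    """Running-sum enrichment by direct enumeration.

    Walks the ranked list one gene at a time, adding |score|^p / (total hit
    weight) at members and subtracting 1/(N - N_H) elsewhere; returns
    (es, running_sum) where es is the deviation of maximal magnitude
    (positive wins an exact tie).
    """
    members = set(members)
    n = len(genes)
    hits = [g in members for g in genes]
    nh = sum(hits)
    assert 0 < nh < n
    wsum = sum(abs(s) ** p for g, s in zip(genes, scores) if g in members)
    running = []
    cur = 0.0
    for g, s, is_hit in zip(genes, scores, hits):
        if is_hit:
            cur += (abs(s) ** p) / wsum if wsum > 0 else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
    hi = max(running)
    lo = min(running)
    es = hi if hi >= -lo else lo
    return es, running


def ks_oracle(genes, scores, members):
    """Classical two-sample KS-style signed deviation between the rank
    distribution of members and non-members (the p = 0 special case),
    computed from the two empirical CDFs."""
    members = set(members)
    n = len(genes)
    nh = sum(1 for g in genes if g in members)
    best = 0.0
    n_hit = n_miss = 0
    for g in genes:
        if g in members:
            n_hit += 1
        else:
            n_miss += 1
        dev = n_hit / nh - n_miss / (n - nh)
        if abs(dev) > abs(best) or (abs(dev) == abs(best) and dev > best):
            best = dev
    return best


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up by the textbook recipe."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        q = min(prev, pvals[i] * m / rank_from_end)
        adjusted[i] = q
        prev = q
    return adjusted


def paired_t_oracle(diffs):
    """Classical paired t from the per-pair differences of one feature."""
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    se = math.sqrt(var / n)
    return mean / se, n - 1


def collapse_oracle(rows, method="abs"):
    """Group probeset rows by gene, keep the most extreme score."""
    by_gene: dict[str, list[float]] = {}
    for _ps, gene, score in rows:
        if gene is None or gene == "":
            continue
        by_gene.setdefault(gene, []).append(score)
    key = abs if method == "abs" else (lambda x: x)
    return {g: max(vals, key=key) for g, vals in by_gene.items()}
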