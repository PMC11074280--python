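"""Independent brute-force oracles used by the metric and acceptance tests.

Deliberately implemented with plain Python/math primitives (dicts, loops,
math.comb) so they share no code path with the package implementations.
"""

import math


def oracle_ari(pred, true):
    table = {}
    for p, t in zip(pred, true):
        table[(p, t)] = table.get((p, t), 0) + 1
    a, b = {}, {}
    for (p, t), c in table.items():
        a[p] = a.get(p, 0) + c
        b[t] = b.get(t, 0) + c
    n = len(pred)
    s_ij = sum(math.comb(c, 2) for c in table.values())
    s_a = sum(math.comb(c, 2) for c in a.values())
    s_b = sum(math.comb(c, 2) for c in b.values())
    exp = s_a * s_b / math.comb(n, 2)
    mx = (s_a + s_b) / 2
    if mx == exp:
        return 1.0
    return (s_ij - exp) / (mx - exp)


def oracle_ami(pred, true):
    n = len(pred)
    rows = sorted(set(pred))
    cols = sorted(set(true))
    tab = [[0] * len(cols) for _ in rows]
    for p, t in zip(pred, true):
        tab[rows.index(p)][cols.index(t)] += 1
    a = [sum(r) for r in tab]
    b = [sum(tab[i][j] for i in range(len(rows))) for j in range(len(cols))]
    mi = 0.0
    for i in range(len(rows)):
        for j in range(len(cols)):
            nij = tab[i][j]
            if nij:
                mi += nij / n * math.log(n * nij / (a[i] * b[j]))
    emi = 0.0
    for ai in a:
        for bj in b:
            for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                p_hyper = (
                    math.comb(bj, nij)
                    * math.comb(n - bj, ai - nij)
                    / math.comb(n, ai)
                )
                emi += nij / n * math.log(n * nij / (ai * bj)) * p_hyper
    h_a = -sum(x / n * math.log(x / n) for x in a if x)
    h_b = -sum(x / n * math.log(x / n) for x in b if x)
    denom = 0.5 * (h_a + h_b) - emi
    if abs(denom) < 1e-15:
        return 1.0 if abs(mi - emi) < 1e-15 and (h_a + h_b) > 0 else 0.0
    return (mi - emi) / denom


def oracle_binary_mcc(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0
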