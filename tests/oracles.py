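"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives the expected result from the declared semantics with
the simplest possible code (plain loops, exhaustive enumeration) and shares
no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# inverted repeats: exhaustive local DP over S x revcomp(S), arms disjoint
# ---------------------------------------------------------------------------

def ir_oracle(seq, match=3, mismatch=-4, gap=12, min_score=50, max_sep=80000):
    """All accepted inverted-repeat pairs as (s1, e1, s2, e2, score)."""
    n = len(seq)
    X = seq
    Y = rc(seq)
    H = [[0] * (n + 1) for _ in range(n + 1)]
    for a in range(1, n):
        for b in range(1, n - a + 1):
            xa, yb = X[a - 1], Y[b - 1]
            s = match if (xa == yb and xa != "N") else mismatch
            best = 0
            if H[a - 1][b - 1] + s > best:
                best = H[a - 1][b - 1] + s
            if H[a - 1][b] - gap > best:
                best = H[a - 1][b] - gap
            if H[a][b - 1] - gap > best:
                best = H[a][b - 1] - gap
            H[a][b] = best

    cells = []
    for a in range(1, n):
        for b in range(1, n - a + 1):
            if H[a][b] >= min_score:
                cells.append((-H[a][b], a, b))
    cells.sort()

    accepted = []
    for negh, a, b in cells:
        # traceback, preferring diagonal > up > left
        aa, bb = a, b
        while H[aa][bb] > 0:
            xa, yb = X[aa - 1], Y[bb - 1]
            s = match if (xa == yb and xa != "N") else mismatch
            if H[aa][bb] == H[aa - 1][bb - 1] + s:
                aa, bb = aa - 1, bb - 1
            elif H[aa][bb] == H[aa - 1][bb] - gap:
                aa -= 1
            elif H[aa][bb] == H[aa][bb - 1] - gap:
                bb -= 1
            else:  # pragma: no cover
                break
        s1, e1 = aa, a
        s2, e2 = n - b, n - bb
        if e1 <= s1 or e2 <= s2 or e2 - s1 > max_sep:
            continue
        clash = False
        for (t1, u1, t2, u2, _sc) in accepted:
            if (s1 < u1 and t1 < e1) or (s2 < u2 and t2 < e2):
                clash = True
                break
        if not clash:
            accepted.append((s1, e1, s2, e2, -negh))
    accepted.sort(key=lambda p: (p[0], p[2]))
    return accepted


# ---------------------------------------------------------------------------
# TSD calling: naive enumeration of every (length, left pad, right pad)
# ---------------------------------------------------------------------------

def tsd_oracle(left, right, min_tsd=4, max_tsd=25, max_offset=3, max_mismatch=2):
    """Best duplication as (left_copy, right_copy, mism, o_l, o_r) or None."""
    candidates = []
    for L in range(min_tsd, max_tsd + 1):
        for o_l in range(max_offset + 1):
            for o_r in range(max_offset + 1):
                if o_l + L > len(left) or o_r + L > len(right):
                    continue
                lc = left[len(left) - o_l - L : len(left) - o_l]
                rcp = right[o_r : o_r + L]
                mism = sum(x != y for x, y in zip(lc, rcp))
                if mism > max_mismatch or mism > L // 5:
                    continue
                candidates.append(
                    ((L - 2 * mism, L, -(o_l + o_r), -mism), (lc, rcp, mism, o_l, o_r))
                )
    if not candidates:
        return None
    return max(candidates, key=lambda c: c[0])[1]


# ---------------------------------------------------------------------------
# Barber modularity: exhaustive set partitions, component by component
# ---------------------------------------------------------------------------

def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def barber_optimum(edges):
    """Maximum Barber modularity over all partitions.

    ``edges`` is a list of (genome, ortholog, weight). Merging nodes from
    different connected components only adds negative null-model terms, so
    the optimum is the sum of per-component optima, each found by exhaustive
    enumeration of set partitions.
    """
    m = sum(w for _, _, w in edges)
    k = {}
    d = {}
    adj = {}
    for g, o, w in edges:
        k[g] = k.get(g, 0) + w
        d[o] = d.get(o, 0) + w
        adj.setdefault(g, set()).add(o)
        adj.setdefault(o, set()).add(g)

    # connected components
    seen = set()
    components = []
    for start in adj:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        components.append(comp)

    weight = {(g, o): w for g, o, w in edges}
    total = 0.0
    for comp in components:
        best = None
        for part in _set_partitions(comp):
            q = 0.0
            for block in part:
                genomes = [u for u in block if u in k]
                orthos = [u for u in block if u in d]
                for g in genomes:
                    for o in orthos:
                        q += weight.get((g, o), 0.0) - k[g] * d[o] / m
            q /= m
            if best is None or q > best:
                best = q
        total += best
    return total
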