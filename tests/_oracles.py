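"""Independent brute-force reference implementations used only by tests.

Everything here is written from the defining formulas with elementary
Python (explicit rank enumeration, direct contingency arithmetic,
exhaustive subset enumeration), deliberately sharing no code with the
package, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

from scipy import stats


# ---------------------------------------------------------------- ranks

def average_ranks(values) -> list[float]:
    """Mid-ranks computed by explicit enumeration of equal-value groups."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # positions are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y):
    """Spearman r² and Student-t p-value from first principles."""
    n = len(x)
    rx, ry = average_ranks(x), average_ranks(y)
    mx = sum(rx) / n
    my = sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    r2 = r * r
    if r2 >= 1.0:
        return 1.0, 0.0
    t = r * math.sqrt((n - 2) / (1 - r2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r2, p


# ---------------------------------------------------------- contingency

def contingency_table(x, y):
    counts = Counter(zip(x, y))
    rows = sorted({a for a, _ in counts})
    cols = sorted({b for _, b in counts})
    return [[counts.get((a, b), 0) for b in cols] for a in rows]


def cramers_brute(x, y):
    """Bias-corrected squared Cramér's V and χ² p-value by direct arithmetic."""
    table = contingency_table(x, y)
    r, c = len(table), len(table[0])
    n = sum(sum(row) for row in table)
    row_sums = [sum(row) for row in table]
    col_sums = [sum(table[i][j] for i in range(r)) for j in range(c)]
    chi2 = 0.0
    for i in range(r):
        for j in range(c):
            e = row_sums[i] * col_sums[j] / n
            chi2 += (table[i][j] - e) ** 2 / e
    df = (r - 1) * (c - 1)
    p = stats.chi2.sf(chi2, df)
    phi2 = chi2 / n
    phi2_t = max(0.0, phi2 - df / (n - 1))
    r_t = r - (r - 1) ** 2 / (n - 1)
    c_t = c - (c - 1) ** 2 / (n - 1)
    effect = phi2_t / min(r_t - 1, c_t - 1)
    return max(0.0, min(1.0, effect)), p


# --------------------------------------------------------------- KW/Dunn

def kw_dunn_brute(x, g):
    """Z²max/n effect and tie-corrected Kruskal–Wallis p, from the formulas."""
    n = len(x)
    ranks = average_ranks(x)
    levels = sorted(set(g), key=str)
    groups = {lev: [ranks[i] for i in range(n) if g[i] == lev] for lev in levels}

    # H with tie correction
    h = 12.0 / (n * (n + 1)) * sum(
        len(rs) * (sum(rs) / len(rs)) ** 2 for rs in groups.values()
    ) - 3 * (n + 1)
    ties = Counter(x)
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    h /= correction
    p = stats.chi2.sf(h, len(levels) - 1)

    tie_term = sum(t**3 - t for t in ties.values()) / (12.0 * (n - 1))
    pooled = n * (n + 1) / 12.0 - tie_term
    z_max = 0.0
    for a, b in itertools.combinations(levels, 2):
        ra, rb = groups[a], groups[b]
        se = math.sqrt(pooled * (1 / len(ra) + 1 / len(rb)))
        z = abs(sum(ra) / len(ra) - sum(rb) / len(rb)) / se
        z_max = max(z_max, z)
    return min(1.0, z_max**2 / n), p


# ----------------------------------------------------------------- trees

def spanning_tree_min_weight(nodes, edges):
    """Minimum total weight over ALL spanning trees, by exhaustive enumeration.

    ``edges`` is a list of (u, v, w); feasible only for tiny graphs.
    """
    n = len(nodes)
    best = math.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = {v: v for v in nodes}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        acyclic = True
        for u, v, _ in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                acyclic = False
                break
            parent[ru] = rv
        if acyclic:
            best = min(best, sum(w for _, _, w in subset))
    return best


def tree_bc_closed_form(tree_adj):
    """Normalized BC of every node of a tree via component-size products.

    For a tree, the number of (j, k) pairs whose unique path crosses i is
    the sum over distinct component pairs (after removing i) of the product
    of their sizes.
    """
    nodes = list(tree_adj)
    n = len(nodes)
    out = {}
    for i in nodes:
        remaining = set(nodes) - {i}
        comps = []
        while remaining:
            start = next(iter(remaining))
            comp, stack = set(), [start]
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(w for w in tree_adj[v] if w in remaining and w not in comp)
            comps.append(len(comp))
            remaining -= comp
        pairs_through = sum(
            a * b for a, b in itertools.combinations(comps, 2)
        )
        out[i] = pairs_through / ((n - 1) * (n - 2) / 2) if n >= 3 else 0.0
    return out


def contracted_edges_brute(parent_edges, labels):
    """Inter-cluster edges of a contraction: {(cu, cv): min distance}."""
    out = {}
    for u, v, d in parent_edges:
        cu, cv = labels[u], labels[v]
        if cu == cv:
            continue
        key = (min(cu, cv), max(cu, cv))
        out[key] = min(out.get(key, math.inf), d)
    return out


# ------------------------------------------------------------------ AMI

def entropy(labels):
    n = len(labels)
    return -sum(c / n * math.log(c / n) for c in Counter(labels).values())


def mutual_information(a, b):
    n = len(a)
    joint = Counter(zip(a, b))
    ca, cb = Counter(a), Counter(b)
    mi = 0.0
    for (la, lb), nij in joint.items():
        mi += nij / n * math.log(n * nij / (ca[la] * cb[lb]))
    return mi


def expected_mi_brute(a, b):
    """E[MI] under the permutation model, by the exact hypergeometric sum."""
    n = len(a)
    ca = list(Counter(a).values())
    cb = list(Counter(b).values())
    emi = 0.0
    for ai in ca:
        for bj in cb:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                pr = (
                    math.comb(bj, nij) * math.comb(n - bj, ai - nij) / math.comb(n, ai)
                )
                emi += pr * nij / n * math.log(n * nij / (ai * bj))
    return emi


def ami_brute(a, b):
    """Adjusted mutual information, arithmetic-mean normalization."""
    mi = mutual_information(a, b)
    emi = expected_mi_brute(a, b)
    denom = (entropy(a) + entropy(b)) / 2.0 - emi
    if abs(denom) < 1e-15:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom
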