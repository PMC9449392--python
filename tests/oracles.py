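"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plain double loops / enumeration, deliberately
ignoring the vectorised code paths under test.
"""

from __future__ import annotations

import numpy as np


def hp_oracle(n_major, n_minor) -> float:
    smaj = sum(float(x) for x in n_major)
    smin = sum(float(x) for x in n_minor)
    tot = smaj + smin
    return 2.0 * smaj * smin / tot**2 if tot else float("nan")


def wc_fst_oracle(geno_a, geno_b) -> float:
    """Scalar Weir & Cockerham (1984) theta-hat for one SNP, two populations.

    geno_* are lists of diploid dosages (missing entries excluded by caller).
    """
    r = 2
    pops = [list(map(int, geno_a)), list(map(int, geno_b))]
    n = [len(g) for g in pops]
    p = [sum(g) / (2 * len(g)) for g in pops]
    hobs = [sum(1 for x in g if x == 1) / len(g) for g in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, hobs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


def pi_pairwise_oracle(haps: np.ndarray, length_bp: float) -> float:
    """Mean pairwise hamming distance over all haplotype pairs, per bp."""
    n = haps.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(haps[i] != haps[j]))
            pairs += 1
    return total / pairs / length_bp


def ehh_oracle(haps, positions, core, direction, cutoff=0.05, max_gap=200_000):
    """Pairwise-identity EHH curve (O(n^2 L)), mirroring the stop rules."""
    n = haps.shape[0]
    step = -1 if direction == "upstream" else 1

    def h_at(cols):
        cnt = 0
        for a in range(n):
            for b in range(a + 1, n):
                if np.array_equal(haps[a, cols], haps[b, cols]):
                    cnt += 1
        return cnt / (n * (n - 1) / 2)

    cols = [core]
    dists = [0.0]
    curve = [h_at(cols)]
    j = core
    prev = positions[core]
    while curve[-1] >= cutoff:
        j += step
        if j < 0 or j >= haps.shape[1]:
            break
        if abs(positions[j] - prev) > max_gap:
            break
        cols.append(j)
        curve.append(h_at(cols))
        dists.append(float(abs(positions[j] - positions[core])))
        prev = positions[j]
    return np.array(dists), np.array(curve)


def ihh_oracle(haps, positions, core, cutoff=0.05, max_gap=200_000) -> float:
    total = 0.0
    for d in ("upstream", "downstream"):
        x, y = ehh_oracle(haps, positions, core, d, cutoff, max_gap)
        if len(x) >= 2:
            total += float(np.trapezoid(y, x))
    return total


def r2_hap_oracle(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r^2 from haplotype counts: D^2 / (pA qA pB qB)."""
    n = len(hap_a)
    p_a = np.mean(hap_a)
    p_b = np.mean(hap_b)
    p_ab = np.mean((hap_a == 1) & (hap_b == 1))
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    return float(d * d / denom) if denom > 0 else float("nan")


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths; returns
    (newick string, taxa labels, tip-tip distance matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    items = list(labels)
    newicks = {lab: lab for lab in labels}
    counter = 0
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        la = round(float(rng.uniform(0.1, 5.0)), 6)
        lb = round(float(rng.uniform(0.1, 5.0)), 6)
        name = f"({newicks[a]}:{la},{newicks[b]}:{lb})"
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        key = f"n{counter}"
        counter += 1
        newicks[key] = name
        items.append(key)
    newick = newicks[items[0]] + ";"
    from skbio import TreeNode

    tree = TreeNode.read([newick])
    dm = tree.tip_tip_distances(list(labels))
    order = [list(dm.ids).index(l) for l in labels]
    mat = dm.data[np.ix_(order, order)]
    return newick, labels, mat
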