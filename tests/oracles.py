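"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths (KD-trees, Kabsch
SVD, sklearn metrics, scipy tests) so that agreement is a real check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_contact_pairs(complex_, cutoff: float) -> set[tuple[int, int]]:
    """All cross-chain residue index pairs with any atom pair <= cutoff."""
    out = set()
    for i, ra in enumerate(complex_.antigen):
        for j, rb in enumerate(complex_.nanobody):
            done = False
            for a in ra.atoms:
                for b in rb.atoms:
                    if np.linalg.norm(a.xyz - b.xyz) <= cutoff:
                        out.add((i, j))
                        done = True
                        break
                if done:
                    break
    return out


def quaternion_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion method."""
    P = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    Q = np.asarray(target, float) - np.mean(target, axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.max(np.linalg.eigvalsh(K))
    sq = (np.sum(P**2) + np.sum(Q**2) - 2.0 * lam) / len(P)
    return float(np.sqrt(max(sq, 0.0)))


def threshold_pr_auc(labels, scores) -> float:
    """PR-AUC by exhaustive threshold enumeration (step interpolation)."""
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s = s[order]
    n_pos = y.sum()
    auc = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # all samples tied at this score
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        auc += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(auc)


def exact_signed_rank_p(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p by enumerating all sign patterns."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd)
    ranks = np.empty(n)
    # midranks for ties
    sorted_abs = absd[order]
    r = np.arange(1, n + 1, dtype=float)
    for v in np.unique(sorted_abs):
        mask = sorted_abs == v
        r[mask] = r[mask].mean()
    ranks[order] = r
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    obs_dev = abs(w_obs - mu)
    count = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(rk for rk, sgn in zip(ranks, signs) if sgn)
        if abs(w - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total
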