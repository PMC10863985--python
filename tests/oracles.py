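"""Independent reference implementations used only to check the package.

Everything here deliberately avoids the code paths under test: quaternion
(Horn) superposition instead of SVD Kabsch, O(n^2) double loops instead of
KD-trees, Monte-Carlo instead of deterministic quadrature, exhaustive
permutation enumeration instead of closed-form null distributions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def quaternion_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal rigid superposition via Horn's quaternion method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    X, Y = P - cp, Q - cq
    S = X.T @ Y
    K = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    eigvals, eigvecs = np.linalg.eigh(K)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def bruteforce_contacts(model, cutoff: float, atom_filter=None):
    """Interchain residue pairs within cutoff by an O(n^2) double loop."""
    assert len(model.chains) == 2
    chain_a, chain_b = model.chains
    pairs = set()
    for ra in chain_a.residues:
        atoms_a = [a for a in ra.heavy_atoms
                   if atom_filter is None or atom_filter(ra, a)]
        for rb in chain_b.residues:
            atoms_b = [b for b in rb.heavy_atoms
                       if atom_filter is None or atom_filter(rb, b)]
            for a in atoms_a:
                done = False
                for b in atoms_b:
                    if np.linalg.norm(a.xyz - b.xyz) <= cutoff:
                        pairs.add((
                            (chain_a.chain_id, ra.seq_index),
                            (chain_b.chain_id, rb.seq_index),
                        ))
                        done = True
                        break
                if done:
                    break
    return pairs


def bruteforce_cb_contacts(model, cutoff: float):
    """Interchain Cbeta (Calpha for Gly) residue pairs within cutoff."""
    chain_a, chain_b = model.chains

    def anchor(res):
        a = res.atom("CB") if res.name != "GLY" else res.atom("CA")
        return a if a is not None else res.atom("CA")

    pairs = []
    for ra in chain_a.residues:
        aa = anchor(ra)
        if aa is None:
            continue
        for rb in chain_b.residues:
            ab = anchor(rb)
            if ab is None:
                continue
            if np.linalg.norm(aa.xyz - ab.xyz) <= cutoff:
                pairs.append((
                    (chain_a.chain_id, ra.seq_index),
                    (chain_b.chain_id, rb.seq_index),
                ))
    return sorted(pairs)


def monte_carlo_sasa(coords, radii, probe: float, n_points: int, seed: int = 0):
    """Per-atom SASA by uniform random directions on each inflated sphere."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    inflated = np.asarray(radii, float) + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + inflated[i] * v
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= inflated[j]
        out[i] = 4.0 * math.pi * inflated[i] ** 2 * accessible.mean()
    return out


def exact_ks_pvalue(a, b):
    """P(D >= D_obs) over all C(n+m, n) label assignments (exhaustive)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n = len(a)

    def ks_d(x, y):
        support = sorted(set(x) | set(y))
        d = 0.0
        for s in support:
            fx = sum(1 for v in x if v <= s) / len(x)
            fy = sum(1 for v in y if v <= s) / len(y)
            d = max(d, abs(fx - fy))
        return d

    d_obs = ks_d(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if ks_d(x, y) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def exact_ranksum_onesided(x, y):
    """P(W >= W_obs) for the rank-sum of x, by exhaustive enumeration
    (mid-ranks for ties)."""
    pooled = list(map(float, x)) + list(map(float, y))
    n = len(x)

    def ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        r = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            mid = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = mid
            i = j + 1
        return r

    r = ranks(pooled)
    w_obs = sum(r[:n])
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        w = sum(r[i] for i in idx)
        total += 1
        if w >= w_obs - 1e-12:
            count += 1
    return w_obs, count / total


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
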