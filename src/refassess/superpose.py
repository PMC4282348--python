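"""Rigid-body superposition and the multi-cutoff GDT superposition search.

GDT-style scores ask, for a distance cutoff d, for the superposition that
maximizes the number of paired Cα atoms within d Å.  That maximum is found
here by a seed-and-extend search: superpose on a seed subset of the pairing,
take the atoms within the cutoff as inliers, re-superpose on the inliers,
and iterate to a fixed point, keeping the best count seen.  Seeds are
contiguous sequence windows (lengths 3, 5, 7 and the full set) for ordinary
problem sizes; for tiny point sets (n ≤ 12) every subset of size ≥ 3 is used
as a seed, which makes the search provably exact over subset-seeded
superpositions.  All seeds are processed simultaneously with batched
weighted Kabsch fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

#: below this many paired atoms the search enumerates all size-≥3 seed subsets
EXHAUSTIVE_MAX_N = 12

#: contiguous seed-window lengths for the heuristic regime
SEED_WINDOW_LENGTHS = (3, 5, 7)

MAX_REFIT_ITERATIONS = 20


@dataclass
class RigidTransform:
    """Proper rotation + translation; maps model coordinates onto the target."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_points: int


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of point set P onto Q.

    Returns the proper rotation (no reflection) and translation minimizing
    the RMSD of the transformed P to Q, via SVD of the covariance matrix.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(RigidTransform(R, t), rmsd, P.shape[0])


def _batched_fit(P: np.ndarray, Q: np.ndarray, masks: np.ndarray):
    """Weighted Kabsch fit of P onto Q for each boolean row of ``masks``.

    Returns rotations (k,3,3) and the per-seed centroids so that the
    transformed model is ``R @ (x - cp) + cq``.
    """
    w = masks.astype(float)
    nw = w.sum(axis=1)  # (k,)
    cp = (w @ P) / nw[:, None]
    cq = (w @ Q) / nw[:, None]
    Pc = P[None, :, :] - cp[:, None, :]
    Qc = Q[None, :, :] - cq[:, None, :]
    H = np.matmul(np.transpose(Pc * w[:, :, None], (0, 2, 1)), Qc)
    U, _, Vt = np.linalg.svd(H)
    # proper rotations only: flip the smallest singular direction on reflections
    det = np.linalg.det(np.einsum("kji,klj->kil", Vt, U))  # det(V @ U^T)
    Vt_adj = Vt.copy()
    Vt_adj[:, 2, :] *= np.sign(det)[:, None]
    R = np.einsum("kji,klj->kil", Vt_adj, U)  # V_adj @ U^T per seed
    return R, cp, cq


def _seed_masks(n: int) -> np.ndarray:
    """Seed subsets as a boolean (k, n) array."""
    if n <= EXHAUSTIVE_MAX_N:
        rows = []
        idx = range(n)
        for size in range(3, n + 1):
            for comb in combinations(idx, size):
                row = np.zeros(n, dtype=bool)
                row[list(comb)] = True
                rows.append(row)
        return np.array(rows)
    rows = []
    for length in SEED_WINDOW_LENGTHS:
        if length > n:
            continue
        for start in range(0, n - length + 1):
            row = np.zeros(n, dtype=bool)
            row[start : start + length] = True
            rows.append(row)
    rows.append(np.ones(n, dtype=bool))
    return np.array(rows)


#: refit trajectories started per cutoff after the seed pass
TRAJECTORIES_PER_CUTOFF = 8


def _search_multi(
    model: np.ndarray, target: np.ndarray, cutoffs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best (inlier count, inlier RMSD) per cutoff over the seeded search.

    Phase 1 fits every seed subset once and scores the resulting
    superpositions against all cutoffs (so the reported fractions are
    non-decreasing in the cutoff by construction).  Phase 2 takes the most
    promising inlier sets per cutoff and refits each trajectory — superpose
    on the inliers, reselect inliers — to a fixed point; a seen-set breaks
    refit cycles, and every trajectory's superpositions keep being scored
    against all cutoffs.
    """
    n = model.shape[0]
    cut2 = np.asarray(cutoffs, dtype=float) ** 2
    n_cut = len(cut2)
    best_count = np.zeros(n_cut, dtype=int)
    best_rms = np.full(n_cut, np.inf)

    def fit_and_score(masks: np.ndarray) -> np.ndarray:
        """Fit each mask row, update per-cutoff bests, return d2 (k, n)."""
        R, cp, cq = _batched_fit(model, target, masks)
        moved = (
            np.matmul(model[None, :, :] - cp[:, None, :], np.transpose(R, (0, 2, 1)))
            + cq[:, None, :]
        )
        d2 = np.sum((moved - target[None, :, :]) ** 2, axis=2)
        for c in range(n_cut):
            inl = d2 <= cut2[c]
            counts = inl.sum(axis=1)
            cmax = int(counts.max(initial=0))
            if cmax > 0 and cmax >= best_count[c]:
                cand = counts == cmax
                rmin = float(np.sqrt(((d2 * inl).sum(axis=1)[cand] / cmax).min()))
                if cmax > best_count[c] or rmin < best_rms[c]:
                    best_count[c], best_rms[c] = cmax, rmin
        return d2

    d2 = fit_and_score(_seed_masks(n))

    # start refit trajectories from the best seed-pass inlier sets per cutoff
    seen: list[set[bytes]] = [set() for _ in range(n_cut)]
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for c in range(n_cut):
        inl = d2 <= cut2[c]
        counts = inl.sum(axis=1)
        taken = 0
        for k in np.argsort(-counts, kind="stable"):
            if counts[k] < 3 or taken >= TRAJECTORIES_PER_CUTOFF:
                break
            key = np.packbits(inl[k]).tobytes()
            if key in seen[c]:
                continue
            seen[c].add(key)
            rows.append(inl[k])
            labels.append(c)
            taken += 1
    masks = np.array(rows) if rows else np.empty((0, n), dtype=bool)
    lab = np.array(labels, dtype=int)

    for _ in range(MAX_REFIT_ITERATIONS):
        if masks.shape[0] == 0:
            break
        d2 = fit_and_score(masks)
        inliers = d2 <= cut2[lab][:, None]
        counts = inliers.sum(axis=1)
        keep = []
        for k in range(masks.shape[0]):
            if counts[k] < 3 or bool(np.all(inliers[k] == masks[k])):
                continue
            key = np.packbits(inliers[k]).tobytes()
            if key in seen[lab[k]]:
                continue
            seen[lab[k]].add(key)
            keep.append(k)
        masks = inliers[keep]
        lab = lab[keep]
    return best_count, best_rms


def gdt_fractions(
    model_ca: np.ndarray, target_ca: np.ndarray, cutoffs
) -> np.ndarray:
    """GDT fractions (percentages) for several cutoffs in one batched search."""
    model_ca = np.asarray(model_ca, dtype=float)
    target_ca = np.asarray(target_ca, dtype=float)
    if model_ca.shape != target_ca.shape:
        raise ValueError("model/target Cα sets differ in size")
    n = model_ca.shape[0]
    if n < 3:
        raise ValueError(f"need ≥3 paired Cα atoms, got {n}")
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any(cutoffs <= 0):
        raise ValueError("cutoffs must be positive")
    counts, _ = _search_multi(model_ca, target_ca, cutoffs)
    return 100.0 * counts / n


def gdt_fraction(model_ca: np.ndarray, target_ca: np.ndarray, cutoff: float) -> float:
    """Maximum percentage of paired Cα atoms within ``cutoff`` Å over the
    superpositions explored by the seeded search.

    ``model_ca`` and ``target_ca`` are aligned (n, 3) arrays of corresponding
    Cα coordinates (the residue correspondence is established upstream).
    """
    model_ca = np.asarray(model_ca, dtype=float)
    target_ca = np.asarray(target_ca, dtype=float)
    if model_ca.shape != target_ca.shape:
        raise ValueError("model/target Cα sets differ in size")
    return float(gdt_fractions(model_ca, target_ca, [cutoff])[0])


def masked_gdt_fraction(
    model_ca: np.ndarray,
    target_ca: np.ndarray,
    cutoff: float,
    exclude: set,
    keys: list | None = None,
) -> float:
    """GDT fraction on the correspondence with some residues excluded.

    ``exclude`` holds indices into the paired arrays, or residue keys if a
    parallel ``keys`` list is given (one key per pair).  Used for masked
    Cα-only re-evaluation when flexible or crystal-contact residues are to
    be discarded.
    """
    model_ca = np.asarray(model_ca, dtype=float)
    target_ca = np.asarray(target_ca, dtype=float)
    n = model_ca.shape[0]
    if keys is not None:
        if len(keys) != n:
            raise ValueError("keys must parallel the paired arrays")
        keep = [i for i, k in enumerate(keys) if k not in exclude]
    else:
        keep = [i for i in range(n) if i not in exclude]
    if len(keep) < 3:
        raise ValueError("fewer than 3 residues remain after masking")
    return gdt_fraction(model_ca[keep], target_ca[keep], cutoff)
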