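"""Independent brute-force oracles used to pin down metric semantics.

Each oracle is written as plain loops, independent of the batched
implementations it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def plain_kabsch(P: np.ndarray, Q: np.ndarray):
    """Reference least-squares superposition (rotation, translation, rmsd)."""
    cp, cq = P.mean(0), Q.mean(0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    return R, t, float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))


def exhaustive_gdt(M: np.ndarray, T: np.ndarray, cutoff: float) -> float:
    """Max inlier percentage over a Kabsch fit on every subset of size ≥ 3."""
    n = len(M)
    best = 0
    for size in range(3, n + 1):
        for comb in combinations(range(n), size):
            idx = list(comb)
            R, t, _ = plain_kabsch(M[idx], T[idx])
            moved = M @ R.T + t
            cnt = int(np.sum(np.linalg.norm(moved - T, axis=1) <= cutoff))
            best = max(best, cnt)
    return 100.0 * best / n


def brute_force_hbonds(structure) -> set:
    """All-pairs hydrogen-bond assignment with the package's stated
    criteria, written as explicit loops."""
    from refassess.hbonds import (
        MAX_DONOR_ACCEPTOR_DIST,
        SIDECHAIN_ACCEPTORS,
        SIDECHAIN_DONORS,
    )

    bonds = set()
    residues = structure.residues
    for rd in residues:
        for ra in residues:
            for ad in rd.atoms:
                d_side = ad.name in SIDECHAIN_DONORS.get(rd.resname, set())
                d_main = ad.name == "N" and rd.resname != "PRO"
                if not (d_side or d_main):
                    continue
                # antecedent: nearest other heavy atom of the donor residue
                ante, bd = None, np.inf
                for other in rd.atoms:
                    dist = np.linalg.norm(other.coord - ad.coord)
                    if 0.0 < dist < bd:
                        ante, bd = other.coord, dist
                if ante is None:
                    continue
                for aa in ra.atoms:
                    a_side = aa.name in SIDECHAIN_ACCEPTORS.get(ra.resname, set())
                    a_main = aa.name in ("O", "OXT")
                    if not (a_side or a_main):
                        continue
                    if rd.key == ra.key:
                        continue
                    dmc = ad.name in ("N", "O")
                    amc = aa.name in ("O", "OXT")
                    if (
                        dmc
                        and amc
                        and rd.chain == ra.chain
                        and abs(rd.seqnum - ra.seqnum) < 2
                    ):
                        continue
                    if np.linalg.norm(ad.coord - aa.coord) > MAX_DONOR_ACCEPTOR_DIST:
                        continue
                    v1 = ante - ad.coord
                    v2 = aa.coord - ad.coord
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if cosang > 1e-12:  # angle < 90°
                        continue
                    bonds.add((rd.key, ad.name, ra.key, aa.name))
    return bonds


def double_loop_energy(net, coords_by_key: dict) -> float:
    """Term-by-term elastic energy summation over the network springs."""
    total = 0.0
    for (i, j), d0 in zip(net.springs, net.rest_lengths):
        xi = coords_by_key[net.node_keys[i]]
        xj = coords_by_key[net.node_keys[j]]
        d = float(np.linalg.norm(np.asarray(xi) - np.asarray(xj)))
        total += 0.5 * net.k * (d - d0) ** 2
    return total


def per_sphere_fractions(model, target, corr, radius=6.0, inner=2.0, min_atoms=3):
    """Hand-assembled per-residue sphere fractions for SphereGrinder."""
    model_by_key = {r.key: r for r in model.residues}
    pair_model = dict((t, m) for m, t in corr.pairs)
    target_atoms = []
    for res in target.residues:
        if res.key not in pair_model:
            continue
        for a in res.atoms:
            target_atoms.append((res.key, a.name, a.coord))
    fractions = []
    for mkey, tkey in corr.pairs:
        ca = next(a.coord for r in target.residues if r.key == tkey for a in r.atoms if a.name == "CA")
        sphere = [
            (rk, an, c) for rk, an, c in target_atoms if np.linalg.norm(c - ca) <= radius
        ]
        if len(sphere) < min_atoms:
            continue
        pairs = []
        for rk, an, c in sphere:
            mres = model_by_key.get(pair_model[rk])
            matom = mres.atom(an) if mres is not None else None
            pairs.append((c, matom.coord if matom is not None else None))
        present = [(t, m) for t, m in pairs if m is not None]
        if len(present) < 3:
            fractions.append(0.0)
            continue
        Tc = np.array([t for t, _ in present])
        Mc = np.array([m for _, m in present])
        R, t, _ = plain_kabsch(Mc, Tc)
        moved = Mc @ R.T + t
        within = np.sum(np.linalg.norm(moved - Tc, axis=1) <= inner)
        fractions.append(within / len(sphere))
    return fractions
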