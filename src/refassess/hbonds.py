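"""Geometric hydrogen-bond assignment and model-vs-target bond comparison.

Neither predicted nor experimental structures carry explicit hydrogens, so
bonds are assigned from heavy-atom geometry alone: a donor–acceptor pair is
a hydrogen bond when the heavy-atom distance is ≤ 3.5 Å and the angle
antecedent–donor–acceptor is ≥ 90°, where the antecedent is the heavy atom
covalently bound to the donor (taken as the nearest heavy atom in the same
residue).  Same-residue pairs and main-chain pairs of sequence-adjacent
residues (covalently too close to bond) are excluded.

A model's bond set is scored against the target's as a binary classification
— precision, recall and F1 — with bond identity given by donor and acceptor
residue keys and atom names, in both an all-atom and a main-chain-only
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from refassess.structio import ResidueKey, Structure

MAX_DONOR_ACCEPTOR_DIST = 3.5  # Å
MIN_ANTECEDENT_ANGLE_DEG = 90.0

#: side-chain donor atoms by residue type (protonated at physiological pH)
SIDECHAIN_DONORS = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "CYS": {"SG"},
}

#: side-chain acceptor atoms by residue type
SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "CYS": {"SG"},
}

#: bond identity: (donor residue key, donor atom, acceptor residue key, acceptor atom)
BondId = tuple[ResidueKey, str, ResidueKey, str]


@dataclass(frozen=True)
class HBond:
    donor: tuple[ResidueKey, str]
    acceptor: tuple[ResidueKey, str]
    mainchain_only: bool

    @property
    def identity(self) -> BondId:
        return (self.donor[0], self.donor[1], self.acceptor[0], self.acceptor[1])


@dataclass
class HBondSet:
    bonds: set[HBond] = field(default_factory=set)

    @property
    def n_all(self) -> int:
        return len(self.bonds)

    @property
    def n_mainchain(self) -> int:
        return sum(1 for b in self.bonds if b.mainchain_only)

    def identities(self, scope: str = "all") -> set[BondId]:
        if scope == "all":
            return {b.identity for b in self.bonds}
        if scope == "mainchain":
            return {b.identity for b in self.bonds if b.mainchain_only}
        raise ValueError(f"unknown scope {scope!r}")


def _collect_sites(s: Structure):
    """Donor and acceptor sites: (coord, antecedent coord, residue key,
    atom name, is_mainchain, chain, seqnum)."""
    donors, acceptors = [], []
    for res in s.residues:
        heavy = [(a.name, a.coord) for a in res.atoms]
        if len(heavy) < 2:
            continue

        def antecedent(coord):
            best, bd = None, np.inf
            for _, c in heavy:
                d = np.linalg.norm(c - coord)
                if 0.0 < d < bd:
                    best, bd = c, d
            return best

        sd = SIDECHAIN_DONORS.get(res.resname, set())
        sa = SIDECHAIN_ACCEPTORS.get(res.resname, set())
        for a in res.atoms:
            mc = a.name in ("N", "O")
            if (a.name == "N" and res.resname != "PRO") or a.name in sd:
                ante = antecedent(a.coord)
                if ante is not None:
                    donors.append((a.coord, ante, res.key, a.name, mc, res.chain, res.seqnum))
            if a.name in ("O", "OXT") or a.name in sa:
                acceptors.append((a.coord, res.key, a.name, a.name in ("O", "OXT"), res.chain, res.seqnum))
    return donors, acceptors


def assign_hbonds(s: Structure) -> HBondSet:
    """Assign hydrogen bonds from heavy-atom geometry (criteria above)."""
    donors, acceptors = _collect_sites(s)
    bonds: set[HBond] = set()
    if not donors or not acceptors:
        return HBondSet(bonds)
    dcoords = np.array([d[0] for d in donors])
    acoords = np.array([a[0] for a in acceptors])
    dist = cdist(dcoords, acoords)
    for i, j in zip(*np.nonzero(dist <= MAX_DONOR_ACCEPTOR_DIST)):
        dco, ante, dkey, dname, dmc, dchain, dseq = donors[i]
        aco, akey, aname, amc, achain, aseq = acceptors[j]
        if dkey == akey:
            continue
        if dmc and amc and dchain == achain and abs(dseq - aseq) < 2:
            continue  # main-chain pair covalently too close (e.g. N(i+1)–O(i))
        v1 = ante - dco
        v2 = aco - dco
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if cosang > np.cos(np.deg2rad(MIN_ANTECEDENT_ANGLE_DEG)) + 1e-12:
            continue
        bonds.add(HBond(donor=(dkey, dname), acceptor=(akey, aname), mainchain_only=dmc and amc))
    return HBondSet(bonds)


@dataclass
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def hbond_prf(model_set: HBondSet, target_set: HBondSet, scope: str = "all") -> PRF:
    """Precision/recall/F1 of the model's bond set against the target's.

    The target's bonds are the observations, the model's the predictions;
    degenerate denominators yield 0.
    """
    m = model_set.identities(scope)
    t = target_set.identities(scope)
    tp = len(m & t)
    return PRF(tp=tp, fp=len(m) - tp, fn=len(t) - tp)


def hbond_group_scores(f1_by_target: dict[str, dict[str, float]]) -> dict[str, float]:
    """Per-group median of clipped robust Z-scores of F1 values.

    ``f1_by_target`` maps target id → {group id → F1 of the group's model 1}.
    F1 is higher-better, so Z-scores are clipped below zero; each group is
    scored by the median over the targets it predicted.
    """
    from refassess.ranking import robust_z

    per_group: dict[str, list[float]] = {}
    for target, scores in f1_by_target.items():
        groups = list(scores.keys())
        if len(groups) < 2:
            continue  # robust Z undefined for a single entry
        z = robust_z(np.array([scores[g] for g in groups]))
        for g, zg in zip(groups, z):
            per_group.setdefault(g, []).append(max(zg, 0.0))
    return {g: float(np.median(v)) for g, v in per_group.items()}
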