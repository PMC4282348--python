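"""Synthetic refinement rounds: natives, starting models, group submissions.

The generator emulates the structure of a community refinement experiment:
per target, an ideal-geometry native fold, a starting model at a controlled
distance from it, and up-to-five-model submissions from groups whose
behaviour follows planted profiles — a signed *skill* (mean fraction of the
remaining distance to native that the group closes; negative skill moves
away), a *consistency* (spread of that fraction), an *adventurousness*
(scale of deliberate non-native conformational change) and a
*ranking_acumen* (probability that the group labels its genuinely best
model as model 1).  Fabricated external score tables (MolProbity-like and
LLG-like scalars, clearly synthetic) exercise the external-scalar plumbing.

Natives are backbone + CB chains built from ideal internal coordinates
(trans peptides, fold-dependent φ/ψ), so consecutive Cα atoms sit 3.8 Å
apart and α-helical segments carry the i→i+4 backbone hydrogen bonds the
hydrogen-bond module expects.  Starting models apply per-atom zero-mean
Gaussian noise plus one rigid loop-segment rotation.  All randomness flows
from a single seed; every artifact is reproducible per seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from refassess.structio import AtomRecord, ResidueRecord, Structure, write_pdb

FOLDS = ("helix", "helix-turn-helix", "sheet-like")

# ideal backbone internal coordinates (Å, degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.530}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8, "N-CA-CB": 110.4}

_HELIX = (-57.0, -47.0)
_STRAND = (-130.0, 125.0)

#: residue types used for synthetic sequences (all carry a CB atom)
_SEQ_POOL = (
    "ALA LEU SER VAL THR ILE ASN GLN LYS GLU ASP ARG PHE TYR HIS".split()
)

DEFAULT_STARTING_SIGMA = 1.0  # Å
DEFAULT_P_MISSING = 0.02
DEFAULT_N_TARGETS = 27
DEFAULT_N_RES_RANGE = (32, 48)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A, B, C, the C–D bond length, B–C–D angle and
    A–B–C–D torsion (degrees)."""
    theta = np.deg2rad(angle)
    chi = np.deg2rad(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi), bond * np.sin(theta) * np.sin(chi)]
    )
    M = np.column_stack([bc, m, n])
    return c + M @ d_local


def _fold_torsions(n_res: int, fold: str) -> list[tuple[float, float]]:
    if fold == "helix":
        return [_HELIX] * n_res
    if fold == "helix-turn-helix":
        h1 = max(4, int(0.45 * n_res))
        turn = [(-75.0, 140.0), (-60.0, -30.0), (-90.0, 0.0), (-75.0, 140.0)]
        out = [_HELIX] * h1 + turn
        out += [_HELIX] * (n_res - len(out))
        return out[:n_res]
    if fold == "sheet-like":
        s1 = max(4, (n_res - 4) // 2)
        turn = [(-60.0, -30.0), (-90.0, 0.0), (-60.0, -30.0), (-90.0, 0.0)]
        out = [_STRAND] * s1 + turn
        out += [_STRAND] * (n_res - len(out))
        return out[:n_res]
    raise ValueError(f"unknown fold {fold!r}; choose from {FOLDS}")


def generate_native(seed: int, n_res: int, fold: str = "helix", id: str = "native") -> Structure:
    """Ideal-geometry backbone+CB native chain, deterministic per seed.

    The seed picks the amino-acid sequence; the geometry is fixed by the
    fold's φ/ψ schedule (trans peptide bonds throughout).
    """
    if n_res < 8:
        raise ValueError("need at least 8 residues")
    torsions = _fold_torsions(n_res, fold)
    rng = np.random.default_rng(seed)
    seq = rng.choice(_SEQ_POOL, size=n_res)

    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    C = CA + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])

    coords = [{"N": N, "CA": CA, "C": C}]
    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        prev = coords[-1]
        Ni = _nerf(prev["N"], prev["CA"], prev["C"], _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        CAi = _nerf(prev["CA"], prev["C"], Ni, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        phi_i = torsions[i][0]
        Ci = _nerf(prev["C"], Ni, CAi, _BOND["CA-C"], _ANGLE["N-CA-C"], phi_i)
        coords.append({"N": Ni, "CA": CAi, "C": Ci})

    residues = []
    for i, atoms in enumerate(coords):
        psi = torsions[i][1]
        O = _nerf(atoms["N"], atoms["CA"], atoms["C"], _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
        CB = _nerf(atoms["C"], atoms["N"], atoms["CA"], _BOND["CA-CB"], _ANGLE["N-CA-CB"], -120.0)
        recs = [
            AtomRecord("N", "N", atoms["N"]),
            AtomRecord("CA", "C", atoms["CA"]),
            AtomRecord("C", "C", atoms["C"]),
            AtomRecord("O", "O", O),
            AtomRecord("CB", "C", CB),
        ]
        residues.append(ResidueRecord(chain="A", seqnum=i + 1, icode="", resname=str(seq[i]), atoms=recs))
    return Structure(id=id, residues=residues, source="native")


def _structure_coords(s: Structure) -> np.ndarray:
    return np.array([a.coord for r in s.residues for a in r.atoms])


def _with_coords(s: Structure, coords: np.ndarray, id: str, source: str) -> Structure:
    out = []
    k = 0
    for r in s.residues:
        atoms = []
        for a in r.atoms:
            atoms.append(AtomRecord(a.name, a.element, coords[k].copy(), a.occupancy, a.altloc))
            k += 1
        out.append(ResidueRecord(r.chain, r.seqnum, r.icode, r.resname, atoms))
    return Structure(id=id, residues=out, source=source)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def make_starting_model(native: Structure, seed: int, sigma: float = DEFAULT_STARTING_SIGMA) -> Structure:
    """Perturb a native into a starting model: per-atom zero-mean Gaussian
    displacement of width ``sigma`` plus one rigid rotation of a loop-sized
    segment.  ``sigma`` = 0 returns an identical copy."""
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    coords = _structure_coords(native)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, sigma, coords.shape)
        # rigid rotation of a 6-residue segment about its first Cα
        n_res = len(native.residues)
        start = int(0.55 * n_res)
        seg = range(start, min(start + 6, n_res))
        atom_idx = []
        k = 0
        for i, r in enumerate(native.residues):
            for _ in r.atoms:
                if i in seg:
                    atom_idx.append(k)
                k += 1
        pivot = coords[atom_idx[0]]
        angle = np.deg2rad(min(30.0, 12.0 * sigma))
        R = _rotation_matrix(rng.normal(size=3), angle)
        coords[atom_idx] = (coords[atom_idx] - pivot) @ R.T + pivot
    return _with_coords(native, coords, id=f"{native.id}_starting", source="starting")


@dataclass
class GroupProfile:
    group_id: str
    skill: float  # mean fraction of starting→native distance closed (signed)
    consistency: float = 0.0  # SD of that fraction; ≥ 0
    adventurousness: float = 0.0  # Å scale of non-native conformational change
    ranking_acumen: float = 1.0  # P(true best of 5 labelled model 1)
    type: str = "human"

    def __post_init__(self) -> None:
        if self.consistency < 0:
            raise ValueError("consistency must be ≥ 0")
        if not 0.0 <= self.ranking_acumen <= 1.0:
            raise ValueError("ranking_acumen must be in [0, 1]")


def default_profiles() -> list[GroupProfile]:
    """Ten groups spanning the behavioural axes seen in real rounds: one
    perfect refiner, one naive-equivalent, and skills symmetric about zero
    so that the per-target median Δ sits near zero."""
    return [
        GroupProfile("perfect", 1.0, 0.0, 0.0, 1.0),
        GroupProfile("naive-equiv", 0.0, 0.0, 0.0, 1.0),
        GroupProfile("strong-plus", 0.30, 0.08, 0.10, 0.8),
        GroupProfile("mid-plus", 0.20, 0.08, 0.10, 0.2),
        GroupProfile("weak-plus", 0.10, 0.08, 0.10, 0.5, type="server"),
        GroupProfile("marginal-plus", 0.05, 0.08, 0.10, 0.5),
        GroupProfile("marginal-minus", -0.05, 0.08, 0.10, 0.5),
        GroupProfile("weak-minus", -0.10, 0.08, 0.10, 0.5, type="server"),
        GroupProfile("mid-minus", -0.20, 0.08, 0.10, 0.5),
        GroupProfile("strong-minus", -0.30, 0.08, 0.10, 0.5),
    ]


def generate_submission(
    starting: Structure,
    native: Structure,
    profile: GroupProfile,
    model_index: int,
    seed: int,
    fraction: float | None = None,
) -> Structure:
    """One submission: interpolate starting→native by a fraction drawn from
    Normal(skill, consistency) clamped to [−0.5, 1], then add an
    adventurousness-scaled smooth non-native perturbation."""
    rng = np.random.default_rng(seed)
    if fraction is None:
        fraction = float(np.clip(rng.normal(profile.skill, profile.consistency), -0.5, 1.0))
    xs = _structure_coords(starting)
    xn = _structure_coords(native)
    coords = (1.0 - fraction) * xs + fraction * xn
    adv = profile.adventurousness
    if adv > 0:
        n = coords.shape[0]
        t = np.arange(n) / n
        for k in (1, 2):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            phase = rng.uniform(0, 2 * np.pi)
            amp = adv * rng.normal(0, 0.6)
            coords = coords + amp * np.sin(2 * np.pi * k * t + phase)[:, None] * u
        coords = coords + rng.normal(0.0, 0.2 * adv, coords.shape)
    sid = f"{native.id}_{profile.group_id}_{model_index}"
    return _with_coords(native, coords, id=sid, source="prediction")


@dataclass
class SubmissionEntry:
    group: str
    target: str
    model_index: int
    model_id: str
    path: str | None = None
    truncated: bool = False


@dataclass
class TargetEntry:
    target: str
    n_res: int
    fold: str
    native_path: str | None = None
    starting_path: str | None = None


@dataclass
class RoundManifest:
    seed: int
    targets: list[TargetEntry]
    submissions: list[SubmissionEntry]
    truth: dict[str, dict]
    mp_scores: dict[str, float]
    llg_scores: dict[str, float]
    starting_llg: dict[str, float]
    # in-memory structures, keyed by target id / model id
    natives: dict[str, Structure] = field(default_factory=dict)
    startings: dict[str, Structure] = field(default_factory=dict)
    models: dict[str, Structure] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "targets": [asdict(t) for t in self.targets],
                "submissions": [asdict(s) for s in self.submissions],
                "truth": self.truth,
                "starting_llg": self.starting_llg,
            },
            indent=1,
            sort_keys=True,
        )


def _delete_terminal_residue(s: Structure) -> Structure:
    return Structure(id=s.id, residues=[r for r in s.residues[:-1]], source=s.source)


def _mean_dist(a: Structure, b: Structure) -> float:
    xa, xb = _structure_coords(a), _structure_coords(b)
    n = min(len(xa), len(xb))
    return float(np.mean(np.linalg.norm(xa[:n] - xb[:n], axis=1)))


def _fake_mp(dist: float) -> float:
    """Synthetic MolProbity-like score: worse (larger) for models further
    from native, with a deterministic wiggle so nearby models still differ.
    A deterministic function of the distance keeps identical models at
    identical scores."""
    return float(np.clip(0.8 + 2.2 * dist / (dist + 1.5) + 0.08 * np.sin(137.0 * dist), 0.3, 4.5))


def _fake_llg(dist: float) -> float:
    """Synthetic LLG-like score decaying with distance to native."""
    return float(max(150.0 * np.exp(-dist / 1.2) + 2.0 * np.sin(71.0 * dist), 1.0))


def generate_round(
    seed: int,
    n_targets: int = DEFAULT_N_TARGETS,
    profiles: list[GroupProfile] | None = None,
    out_dir: str | None = None,
    n_res_range: tuple[int, int] = DEFAULT_N_RES_RANGE,
    starting_sigma: float = DEFAULT_STARTING_SIGMA,
    p_missing: float = DEFAULT_P_MISSING,
    n_models: int = 5,
) -> RoundManifest:
    """A complete synthetic refinement round.

    Structures are kept in memory on the manifest; with ``out_dir`` the
    round is also written to disk as ``targets/<T>/{native,starting}.pdb``,
    ``submissions/<T>/<group>_<i>.pdb``, fabricated external score tables
    (``scores/mp.tsv``, ``scores/llg.tsv``, ``scores/starting_llg.tsv``) and
    ``manifest.json`` with the planted truth.
    """
    if profiles is None:
        profiles = default_profiles()
    ids = [p.group_id for p in profiles]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate group ids")
    rng = np.random.default_rng(seed)
    manifest = RoundManifest(
        seed=seed,
        targets=[],
        submissions=[],
        truth={p.group_id: asdict(p) for p in profiles},
        mp_scores={},
        llg_scores={},
        starting_llg={},
    )
    for ti in range(n_targets):
        tid = f"T{ti + 1:02d}"
        n_res = int(rng.integers(n_res_range[0], n_res_range[1] + 1))
        fold = FOLDS[ti % len(FOLDS)]
        native = generate_native(int(rng.integers(2**31)), n_res, fold, id=tid)
        starting = make_starting_model(native, int(rng.integers(2**31)), starting_sigma)
        manifest.natives[tid] = native
        manifest.startings[tid] = starting
        manifest.targets.append(TargetEntry(tid, n_res, fold))
        manifest.starting_llg[tid] = _fake_llg(_mean_dist(starting, native))
        manifest.mp_scores[f"{tid}_starting"] = _fake_mp(_mean_dist(starting, native))
        for prof in profiles:
            candidates = []
            for _ in range(n_models):
                sub = generate_submission(
                    starting, native, prof, 0, int(rng.integers(2**31))
                )
                candidates.append(sub)
            dists = [_mean_dist(c, native) for c in candidates]
            best = int(np.argmin(dists))
            # label the true best model 1 with probability ranking_acumen,
            # otherwise bury it uniformly among indices 2..n
            order = [i for i in range(n_models) if i != best]
            rng.shuffle(order)
            if rng.uniform() < prof.ranking_acumen:
                labels = [best] + order
            else:
                pos = int(rng.integers(1, n_models))
                labels = order[:pos] + [best] + order[pos:]
            for idx, ci in enumerate(labels, start=1):
                sub = candidates[ci]
                truncated = bool(rng.uniform() < p_missing)
                if truncated:
                    sub = _delete_terminal_residue(sub)
                mid = f"{tid}_{prof.group_id}_{idx}"
                sub.id = mid
                manifest.models[mid] = sub
                manifest.submissions.append(
                    SubmissionEntry(prof.group_id, tid, idx, mid, truncated=truncated)
                )
                manifest.mp_scores[mid] = _fake_mp(dists[ci])
                manifest.llg_scores[mid] = _fake_llg(dists[ci])
    if out_dir is not None:
        _write_round(manifest, out_dir)
    return manifest


def _write_round(manifest: RoundManifest, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for t in manifest.targets:
        tdir = os.path.join(out_dir, "targets", t.target)
        os.makedirs(tdir, exist_ok=True)
        t.native_path = os.path.join(tdir, "native.pdb")
        t.starting_path = os.path.join(tdir, "starting.pdb")
        write_pdb(manifest.natives[t.target], t.native_path)
        write_pdb(manifest.startings[t.target], t.starting_path)
    for s in manifest.submissions:
        sdir = os.path.join(out_dir, "submissions", s.target)
        os.makedirs(sdir, exist_ok=True)
        s.path = os.path.join(sdir, f"{s.group}_{s.model_index}.pdb")
        write_pdb(manifest.models[s.model_id], s.path)
    sdir = os.path.join(out_dir, "scores")
    os.makedirs(sdir, exist_ok=True)
    header = "# synthetic scores fabricated by refassess.synthdata — not real program output\n"
    with open(os.path.join(sdir, "mp.tsv"), "w") as fh:
        fh.write(header)
        for mid, v in manifest.mp_scores.items():
            fh.write(f"{mid}\t{v:.3f}\n")
    with open(os.path.join(sdir, "llg.tsv"), "w") as fh:
        fh.write(header)
        for mid, v in manifest.llg_scores.items():
            fh.write(f"{mid}\t{v:.2f}\n")
    with open(os.path.join(sdir, "starting_llg.tsv"), "w") as fh:
        fh.write(header)
        for tid, v in manifest.starting_llg.items():
            fh.write(f"{tid}\t{v:.2f}\n")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
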