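"""Elastic-network deformation energy between two conformations.

A Hookean pairwise elastic network is built on the Cα trace of a reference
structure: every Cα pair within a cutoff (default 12 Å) becomes a spring at
its reference distance, with a uniform force constant (default
1 kcal/mol/Å²).  The deformation energy of another conformation is the sum
of ½·k·(d − d₀)² over springs — a function of internal distances only, hence
invariant to rigid motion and requiring no superposition.

The absolute scale of this energy is not calibrated against any published
deformation-energy program; its contract here is ordinal — filtering
near-native starting models out of the thermal ensemble of the target, and
ranking how adventurous a refinement move is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from refassess.structio import ResidueCorrespondence, Structure

DEFAULT_CUTOFF = 12.0
DEFAULT_SPRING_K = 1.0
#: per-residue deformation energy at or below which a conformation is
#: considered within the thermal ensemble of the reference (kcal/mol/residue)
THERMAL_ENSEMBLE_THRESHOLD = 0.89


@dataclass
class ElasticNetwork:
    nodes: np.ndarray  # (n, 3) reference Cα coordinates
    node_keys: list  # residue keys, parallel to nodes
    springs: np.ndarray  # (m, 2) index pairs, i < j
    rest_lengths: np.ndarray  # (m,) Å
    k: float = DEFAULT_SPRING_K
    cutoff: float = DEFAULT_CUTOFF


@dataclass
class DeformationEnergy:
    total: float  # kcal/mol
    per_residue: float  # kcal/mol/residue
    n_residues: int


def build_network(
    reference: Structure, cutoff: float = DEFAULT_CUTOFF, k: float = DEFAULT_SPRING_K
) -> ElasticNetwork:
    """Connect all Cα pairs of the reference within ``cutoff`` Å by springs
    at their reference distance."""
    coords = reference.ca_coords()
    if len(coords) < 2:
        raise ValueError("need at least 2 Cα atoms")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    iu, ju = np.triu_indices(len(coords), k=1)
    within = dist[iu, ju] <= cutoff
    if not within.any():
        raise ValueError(f"no Cα pair within {cutoff} Å — cutoff too small")
    springs = np.stack([iu[within], ju[within]], axis=1)
    return ElasticNetwork(
        nodes=coords,
        node_keys=[r.key for r in reference.residues],
        springs=springs,
        rest_lengths=dist[iu[within], ju[within]],
        k=k,
        cutoff=cutoff,
    )


def deformation_energy(
    net: ElasticNetwork, other: Structure, corr: ResidueCorrespondence | None = None
) -> DeformationEnergy:
    """Σ ½·k·(d_ij − d0_ij)² over springs, evaluated on ``other``.

    Every network node must have a Cα counterpart in ``other``; counterparts
    are matched by residue key (via ``corr`` when the two structures do not
    share numbering).
    """
    key_map = {}
    if corr is not None:
        # corr pairs are (model_key, target_key) with the network on the target
        key_map = {t: m for m, t in corr.pairs}
    other_idx = {r.key: r for r in other.residues}
    coords = np.empty_like(net.nodes)
    for i, key in enumerate(net.node_keys):
        okey = key_map.get(key, key)
        res = other_idx.get(okey)
        if res is None or res.atom("CA") is None:
            raise ValueError(f"no Cα counterpart for network node {key}")
        coords[i] = res.atom("CA").coord
    i, j = net.springs[:, 0], net.springs[:, 1]
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    total = float(0.5 * net.k * np.sum((d - net.rest_lengths) ** 2))
    n = len(net.nodes)
    return DeformationEnergy(total=total, per_residue=total / n, n_residues=n)


def thermal_ensemble_filter(
    e: DeformationEnergy, threshold: float = THERMAL_ENSEMBLE_THRESHOLD
) -> bool:
    """True when the conformation lies within the thermal ensemble of the
    reference (per-residue energy ≤ threshold, boundary inclusive) — i.e.
    too close to the native to pose a refinement challenge."""
    return e.per_residue <= threshold


@dataclass
class AdventurousnessRow:
    group: str
    n_positive_targets: int
    mean_energy: float | None
    max_energy: float | None


def adventurousness_report(
    records: list[dict],
) -> list[AdventurousnessRow]:
    """Per-group mean/max per-residue deformation energy versus the starting
    model, restricted to models whose GDT-HA improved on the starting model.

    ``records`` rows need keys: group, target, delta_gdt_ha, energy_per_residue.
    Groups with no qualifying model are reported with empty statistics.
    """
    by_group: dict[str, list[float]] = {}
    groups_seen: list[str] = []
    for rec in records:
        g = rec["group"]
        if g not in by_group:
            by_group[g] = []
            groups_seen.append(g)
        if rec["delta_gdt_ha"] > 0:
            by_group[g].append(rec["energy_per_residue"])
    rows = []
    for g in groups_seen:
        vals = by_group[g]
        rows.append(
            AdventurousnessRow(
                group=g,
                n_positive_targets=len(vals),
                mean_energy=float(np.mean(vals)) if vals else None,
                max_energy=float(np.max(vals)) if vals else None,
            )
        )
    return rows
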