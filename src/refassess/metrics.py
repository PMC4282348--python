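"""The five per-model quality measures.

Four are structural: GDT-HA (mean Cα GDT fraction at 0.5/1/2/4 Å), Cα RMSD
after optimal superposition, GDC-SC (threshold-weighted mean of GDT fractions
on one characteristic side-chain atom per residue at 0.5–5.0 Å), and
SphereGrinder (mean, over residues, of the fraction of atoms within 2 Å
after independently aligning each 6 Å Cα-centred sphere).  The fifth, the
MolProbity score, is a stereochemistry composite consumed as an external
scalar — it is never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from refassess.structio import ResidueCorrespondence, ResidueKey, Structure
from refassess.superpose import gdt_fractions, kabsch

GDT_HA_CUTOFFS = (0.5, 1.0, 2.0, 4.0)
GDC_SC_CUTOFFS = tuple(0.5 * i for i in range(1, 11))
SPHERE_RADIUS = 6.0
SPHERE_INNER_CUTOFF = 2.0
MIN_SPHERE_ATOMS = 3


@dataclass
class MetricVector:
    """Per-model quality scores; ``mp`` is externally supplied (lower better)
    and may be absent."""

    gdt_ha: float
    rmsd: float
    gdc_sc: float
    sphgr: float
    mp: float | None = None

    def as_dict(self) -> dict:
        return {
            "gdt_ha": self.gdt_ha,
            "rmsd": self.rmsd,
            "gdc_sc": self.gdc_sc,
            "sphgr": self.sphgr,
            "mp": self.mp,
        }


def load_characteristic_atoms(path=None) -> dict[str, str]:
    """Residue-name → characteristic-atom-name table for GDC-SC."""
    if path is None:
        text = resources.files("refassess").joinpath("data/characteristic_atoms.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        resname, atom = line.split("\t")
        table[resname] = atom
    return table


def gdc_weights(k: int = 10) -> np.ndarray:
    """Linearly decreasing threshold weights w_i = (k − i + 1)/Σ, i = 1..k."""
    w = np.arange(k, 0, -1, dtype=float)
    return w / w.sum()


def _paired_ca(model: Structure, target: Structure, corr: ResidueCorrespondence):
    return model.ca_coords(corr.model_keys), target.ca_coords(corr.target_keys)


def gdt_ha(
    model: Structure,
    target: Structure,
    corr: ResidueCorrespondence,
    exclude: set[ResidueKey] | None = None,
) -> float:
    """Mean GDT fraction at the high-accuracy cutoffs 0.5, 1, 2, 4 Å.

    ``exclude`` optionally drops target residues (flagged as flexible or
    forming crystal contacts) from the correspondence before scoring.
    """
    if exclude:
        corr = corr.restricted(exclude)
        if corr.n_common < 3:
            raise ValueError("fewer than 3 residues remain after masking")
    mc, tc = _paired_ca(model, target, corr)
    return float(np.mean(gdt_fractions(mc, tc, GDT_HA_CUTOFFS)))


def ca_rmsd(model: Structure, target: Structure, corr: ResidueCorrespondence) -> float:
    """Cα RMSD after optimal (least-squares) superposition."""
    mc, tc = _paired_ca(model, target, corr)
    return kabsch(mc, tc).rmsd


def _characteristic_points(
    model: Structure,
    target: Structure,
    corr: ResidueCorrespondence,
    table: Mapping[str, str],
):
    """Paired characteristic-atom coordinates; CB fallback when the distal
    atom is missing on either side.  Glycine has no entry and is skipped."""
    mpts, tpts, fallbacks = [], [], 0
    for mkey, tkey in corr.pairs:
        tres = target.residue(tkey)
        mres = model.residue(mkey)
        atom_name = table.get(tres.resname)
        if atom_name is None:
            continue
        ta, ma = tres.atom(atom_name), mres.atom(atom_name)
        if ta is None or ma is None:
            ta, ma = tres.atom("CB"), mres.atom("CB")
            if ta is None or ma is None:
                continue
            fallbacks += 1
        mpts.append(ma.coord)
        tpts.append(ta.coord)
    return np.asarray(mpts, dtype=float), np.asarray(tpts, dtype=float), fallbacks


def gdc_sc(
    model: Structure,
    target: Structure,
    corr: ResidueCorrespondence,
    table: Mapping[str, str] | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted mean of GDT fractions on characteristic side-chain atoms.

    Ten thresholds 0.5, 1.0, …, 5.0 Å, each with its own best superposition;
    weights decrease linearly with the threshold and sum to one.
    """
    if table is None:
        table = load_characteristic_atoms()
    if weights is None:
        weights = gdc_weights(len(GDC_SC_CUTOFFS))
    mpts, tpts, _ = _characteristic_points(model, target, corr, table)
    if len(mpts) < 3:
        raise ValueError("fewer than 3 paired characteristic atoms")
    fracs = gdt_fractions(mpts, tpts, GDC_SC_CUTOFFS)
    return float(np.dot(weights, fracs))


def sphere_grinder(model: Structure, target: Structure, corr: ResidueCorrespondence) -> float:
    """Superposition-local score: for each target residue, align the set of
    atoms within 6 Å of its Cα and score the fraction of model atoms landing
    within 2 Å of their counterparts; average over residues.

    Sphere membership is decided on the target only; atoms the model lacks
    count as outside 2 Å.  Residues whose sphere holds fewer than 3 atoms are
    skipped; if fewer than 3 counterpart atoms exist in the model the sphere
    cannot be aligned and scores 0.
    """
    model_by_key = {r.key: r for r in model.residues}
    # flat target atom list with owning pair index
    pair_of_target_key = {t: i for i, (_, t) in enumerate(corr.pairs)}
    t_coords, t_names, t_pair = [], [], []
    for res in target.residues:
        i = pair_of_target_key.get(res.key)
        if i is None:
            continue
        for a in res.atoms:
            t_coords.append(a.coord)
            t_names.append(a.name)
            t_pair.append(i)
    t_coords = np.asarray(t_coords, dtype=float)
    t_pair = np.asarray(t_pair)

    # model counterpart coordinates in the same flat order (NaN when absent)
    m_coords = np.full_like(t_coords, np.nan)
    for j, (name, i) in enumerate(zip(t_names, t_pair)):
        mres = model_by_key.get(corr.pairs[i][0])
        if mres is None:
            continue
        ma = mres.atom(name)
        if ma is not None:
            m_coords[j] = ma.coord

    ca_target = target.ca_coords(corr.target_keys)
    fractions = []
    for i in range(corr.n_common):
        d = np.linalg.norm(t_coords - ca_target[i], axis=1)
        member = d <= SPHERE_RADIUS
        n_sphere = int(member.sum())
        if n_sphere < MIN_SPHERE_ATOMS:
            continue
        present = member & ~np.isnan(m_coords[:, 0])
        if present.sum() < 3:
            fractions.append(0.0)
            continue
        fit = kabsch(m_coords[present], t_coords[present])
        moved = fit.transform.apply(m_coords[present])
        within = np.linalg.norm(moved - t_coords[present], axis=1) <= SPHERE_INNER_CUTOFF
        fractions.append(within.sum() / n_sphere)
    if not fractions:
        raise ValueError("no residue qualifies for SphereGrinder")
    return float(100.0 * np.mean(fractions))


def compute_metrics(
    model: Structure,
    target: Structure,
    corr: ResidueCorrespondence | None = None,
    table: Mapping[str, str] | None = None,
    mp: float | None = None,
) -> MetricVector:
    """All structural measures for one model against its target."""
    from refassess.structio import map_common_residues

    if corr is None:
        corr = map_common_residues(model, target)
    return MetricVector(
        gdt_ha=gdt_ha(model, target, corr),
        rmsd=ca_rmsd(model, target, corr),
        gdc_sc=gdc_sc(model, target, corr, table=table),
        sphgr=sphere_grinder(model, target, corr),
        mp=mp,
    )


def read_score_table(path) -> dict[str, float]:
    """Two-column TSV (model_id, value); '#' comments allowed; duplicate ids
    are an error."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            model_id, value = line.split("\t")[:2]
            if model_id in scores:
                raise ValueError(f"duplicate model id in score table: {model_id}")
            scores[model_id] = float(value)
    return scores


def attach_external_scores(
    model_ids: list[str], table: Mapping[str, float]
) -> dict[str, float | None]:
    """Join external scalar scores (MolProbity, LLG) onto model ids.

    Ids missing from the table map to ``None`` — flagged absent, never
    defaulted — and are excluded downstream from statistics based on that
    score.
    """
    ids = list(table.keys())
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate model id in score table")
    return {mid: table.get(mid) for mid in model_ids}
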