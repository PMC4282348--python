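import numpy as np
import pytest

from oracles import exhaustive_gdt, per_sphere_fractions
from refassess import structio, synthdata
from refassess.metrics import (
    GDT_HA_CUTOFFS,
    attach_external_scores,
    ca_rmsd,
    compute_metrics,
    gdc_sc,
    gdc_weights,
    gdt_ha,
    load_characteristic_atoms,
    read_score_table,
    sphere_grinder,
)
from refassess.structio import map_common_residues


@pytest.fixture(scope="module")
def native():
    return synthdata.generate_native(7, 20, "helix-turn-helix", id="t")


@pytest.fixture(scope="module")
def identity_corr(native):
    return map_common_residues(native, native)


class TestIdentity:
    def test_all_metrics_perfect_for_identity_model(self, native, identity_corr):
        mv = compute_metrics(native, native, identity_corr)
        assert mv.gdt_ha == 100.0
        assert mv.gdc_sc == pytest.approx(100.0)
        assert mv.sphgr == 100.0
        assert mv.rmsd == pytest.approx(0.0, abs=1e-9)


class TestGdtHa:
    def test_is_mean_of_four_cutoff_fractions(self, native, identity_corr):
        from refassess.superpose import gdt_fractions

        start = synthdata.make_starting_model(native, 3, 1.0)
        corr = map_common_residues(start, native)
        mc = start.ca_coords(corr.model_keys)
        tc = native.ca_coords(corr.target_keys)
        per_cutoff = gdt_fractions(mc, tc, GDT_HA_CUTOFFS)
        assert gdt_ha(start, native, corr) == pytest.approx(np.mean(per_cutoff))

    def test_small_toy_matches_exhaustive_oracle_mean(self):
        nat = synthdata.generate_native(5, 10, "helix")
        start = synthdata.make_starting_model(nat, 9, 1.5)
        corr = map_common_residues(start, nat)
        mc = start.ca_coords(corr.model_keys)
        tc = nat.ca_coords(corr.target_keys)
        expected = np.mean([exhaustive_gdt(mc, tc, c) for c in GDT_HA_CUTOFFS])
        assert gdt_ha(start, nat, corr) == pytest.approx(expected)

    def test_masked_variant_drops_excluded_residues(self, native, identity_corr):
        # displace three residues far away; masking them restores 100
        residues = []
        bad = {("A", 5, ""), ("A", 6, ""), ("A", 7, "")}
        for r in native.residues:
            atoms = [
                structio.AtomRecord(a.name, a.element, a.coord + (50.0 if r.key in bad else 0.0), a.occupancy)
                for a in r.atoms
            ]
            residues.append(structio.ResidueRecord(r.chain, r.seqnum, r.icode, r.resname, atoms))
        model = structio.Structure(id="m", residues=residues)
        corr = map_common_residues(model, native)
        assert gdt_ha(model, native, corr, exclude=bad) == 100.0
        assert gdt_ha(model, native, corr) < 100.0


class TestCaRmsd:
    def test_rigid_motion_is_zero(self, native, identity_corr):
        rng = np.random.default_rng(0)
        coords = np.array([a.coord for r in native.residues for a in r.atoms])
        R = np.array([[0, 1, 0], [-1, 0, 0], [0, 0, 1]], float)
        moved = synthdata._with_coords(native, coords @ R.T + rng.normal(size=3), "m", "prediction")
        corr = map_common_residues(moved, native)
        assert ca_rmsd(moved, native, corr) == pytest.approx(0.0, abs=1e-9)


class TestGdcSc:
    def test_weights_sum_to_one(self):
        assert gdc_weights().sum() == pytest.approx(1.0, abs=1e-12)

    def test_weight_formula_on_stated_fractions(self):
        # all thresholds at 100% except the tightest: weighted mean 45/55
        c = np.array([0.0] + [100.0] * 9)
        assert float(np.dot(gdc_weights(), c)) == pytest.approx(100 * 45 / 55)

    def test_characteristic_table_covers_19_residues(self):
        table = load_characteristic_atoms()
        assert len(table) == 19
        assert "GLY" not in table
        assert table["ALA"] == "CB"

    def test_all_atoms_far_off_scores_zero(self, native, identity_corr):
        coords = np.array([a.coord for r in native.residues for a in r.atoms])
        rng = np.random.default_rng(1)
        scrambled = synthdata._with_coords(
            native, rng.normal(scale=40.0, size=coords.shape), "m", "prediction"
        )
        corr = map_common_residues(scrambled, native)
        assert gdc_sc(scrambled, native, corr) == pytest.approx(0.0)


class TestSphereGrinder:
    def test_single_residue_identity_scores_100(self):
        nat = synthdata.generate_native(3, 8, "helix")
        one = structio.Structure(id="one", residues=nat.residues[:1])
        corr = map_common_residues(one, one)
        assert sphere_grinder(one, one, corr) == 100.0

    def test_rigid_motion_invariance(self, native):
        coords = np.array([a.coord for r in native.residues for a in r.atoms])
        R = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], float)
        moved = synthdata._with_coords(native, coords @ R.T + 7.0, "m", "prediction")
        corr = map_common_residues(moved, native)
        assert sphere_grinder(moved, native, corr) == pytest.approx(100.0)

    def test_matches_per_sphere_oracle_on_perturbed_model(self, native):
        start = synthdata.make_starting_model(native, 21, 0.8)
        corr = map_common_residues(start, native)
        expected = 100.0 * np.mean(per_sphere_fractions(start, native, corr))
        assert sphere_grinder(start, native, corr) == pytest.approx(expected)

    def test_displaced_side_chain_penalized_per_oracle(self, native):
        # move one residue's CB far away, all else identity
        residues = []
        for r in native.residues:
            atoms = []
            for a in r.atoms:
                off = 30.0 if (r.seqnum == 10 and a.name == "CB") else 0.0
                atoms.append(structio.AtomRecord(a.name, a.element, a.coord + off, a.occupancy))
            residues.append(structio.ResidueRecord(r.chain, r.seqnum, r.icode, r.resname, atoms))
        model = structio.Structure(id="m", residues=residues)
        corr = map_common_residues(model, native)
        expected = 100.0 * np.mean(per_sphere_fractions(model, native, corr))
        got = sphere_grinder(model, native, corr)
        assert got == pytest.approx(expected)
        assert got < 100.0


class TestMonotoneDegradation:
    def test_metrics_degrade_with_noise(self):
        """Median quality decays (RMSD grows) as coordinate noise increases."""
        nat = synthdata.generate_native(13, 16, "helix")
        sigmas = (0.25, 1.0, 3.0)
        medians = {}
        rng = np.random.default_rng(0)
        for sigma in sigmas:
            rows = []
            for _ in range(20):
                model = synthdata.make_starting_model(nat, int(rng.integers(2**31)), sigma)
                corr = map_common_residues(model, nat)
                rows.append(compute_metrics(model, nat, corr))
            medians[sigma] = {
                "gdt_ha": np.median([m.gdt_ha for m in rows]),
                "gdc_sc": np.median([m.gdc_sc for m in rows]),
                "sphgr": np.median([m.sphgr for m in rows]),
                "rmsd": np.median([m.rmsd for m in rows]),
            }
        for q in ("gdt_ha", "gdc_sc", "sphgr"):
            vals = [medians[s][q] for s in sigmas]
            assert vals[0] >= vals[1] >= vals[2], (q, vals)
        rms = [medians[s]["rmsd"] for s in sigmas]
        assert rms[0] <= rms[1] <= rms[2]


class TestExternalScores:
    def test_join_and_missing_flagged(self):
        out = attach_external_scores(["a", "b", "c"], {"a": 1.5, "c": 2.0})
        assert out == {"a": 1.5, "b": None, "c": 2.0}

    def test_duplicate_id_in_table_is_error(self, tmp_path):
        p = tmp_path / "mp.tsv"
        p.write_text("# scores\na\t1.0\na\t2.0\n")
        with pytest.raises(ValueError):
            read_score_table(p)

    def test_read_score_table_skips_comments(self, tmp_path):
        p = tmp_path / "mp.tsv"
        p.write_text("# header\nm1\t2.5\nm2\t1.0\n")
        assert read_score_table(p) == {"m1": 2.5, "m2": 1.0}
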