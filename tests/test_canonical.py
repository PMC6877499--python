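"""Canonical-cluster medians: metric, assignment, macrostate mapping,
kinetics report."""

import numpy as np
import pytest

from loopmsm.canonical import (CanonicalMedian, CanonicalReport, assign_frames,
                               dihedral_distance, kinetics_report,
                               map_medians_to_macrostates, parse_median_name,
                               read_median_library, write_median_library)
from loopmsm.features import torsions_to_features
from loopmsm.msm import cluster_microstates, estimate_msm, pcca_plus
from loopmsm.synthetic import emit_torsions, generate_ensemble, three_state_spec
from loopmsm.tica import fit_tica, tica_transform


def medians_from_spec(spec, prefix="L3"):
    out = []
    for i in range(spec.n_states):
        m = spec.state_medians[i]
        cis = [r + 1 for r in range(spec.loop_length) if abs(m[r, 0]) < 90]
        cis_part = f"cis{','.join(map(str, cis))}-" if cis else ""
        out.append(CanonicalMedian(f"{prefix}-{spec.loop_length}-{cis_part}{i + 1}", m))
    return out


class TestNameGrammar:
    @pytest.mark.parametrize("name,expect", [
        ("L3-9-cis7-1", ("L3", 9, (7,), 1)),
        ("L3-9-2", ("L3", 9, (), 2)),
        ("L3-10-cis7,8-1", ("L3", 10, (7, 8), 1)),
        ("H3-12-3", ("H3", 12, (), 3)),
    ])
    def test_valid_names(self, name, expect):
        assert parse_median_name(name) == expect

    @pytest.mark.parametrize("bad", ["L3-9", "9-cis7-1", "L3-x-1", "L3--1"])
    def test_invalid_names(self, bad):
        with pytest.raises(ValueError):
            parse_median_name(bad)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            CanonicalMedian("L3-9-1", np.zeros((5, 3)))


class TestDihedralDistance:
    def test_identical_is_zero(self, rng):
        a = rng.uniform(-180, 180, size=(6, 3))
        assert dihedral_distance(a, a) == 0.0

    def test_antipodal_is_four(self):
        a = np.zeros((4, 3))
        b = np.full((4, 3), -180.0)
        assert dihedral_distance(a, b) == pytest.approx(4.0)

    def test_quarter_turn_is_two(self):
        a = np.zeros((4, 3))
        b = np.full((4, 3), 90.0)
        assert dihedral_distance(a, b) == pytest.approx(2.0)

    def test_symmetry_and_mod360(self, rng):
        a = rng.uniform(-180, 180, size=(5, 3))
        b = rng.uniform(-180, 180, size=(5, 3))
        assert dihedral_distance(a, b) == pytest.approx(dihedral_distance(b, a))
        from loopmsm.geometry import wrap_degrees
        assert dihedral_distance(a, wrap_degrees(b + 360)) == pytest.approx(
            dihedral_distance(a, b), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dihedral_distance(np.zeros((4, 3)), np.zeros((5, 3)))


class TestAssignFrames:
    def test_exact_median_distance_zero(self, spec3):
        meds = medians_from_spec(spec3)
        t = emit_torsions(np.array([1]), spec3)
        t.angles[0] = spec3.state_medians[1]
        df = assign_frames(t, meds)
        assert df["name"][0] == meds[1].name
        assert df["distance"][0] == 0.0

    def test_high_kappa_assignment_accuracy(self, spec3):
        ens = generate_ensemble(spec3, 4, 500)
        meds = medians_from_spec(spec3)
        correct = 0
        total = 0
        for t, lab in zip(ens.trajectories, ens.hidden_labels):
            df = assign_frames(t, meds)
            true_names = [meds[s].name for s in lab]
            correct += (df["name"].to_numpy() == np.array(true_names)).sum()
            total += len(lab)
        assert correct / total >= 0.99

    def test_zero_radius_unassigns_noisy_frames(self, spec3):
        ens = generate_ensemble(spec3, 1, 100)
        df = assign_frames(ens.trajectories[0], medians_from_spec(spec3),
                           radius=0.0)
        assert (df["name"] == "unassigned").all()

    def test_accuracy_monotone_in_kappa(self):
        accs = []
        for kappa in (1.0, 4.0, 16.0):
            spec = three_state_spec(seed=17, kappa=kappa)
            ens = generate_ensemble(spec, 2, 400)
            meds = medians_from_spec(spec)
            ok, tot = 0, 0
            for t, lab in zip(ens.trajectories, ens.hidden_labels):
                df = assign_frames(t, meds)
                ok += (df["name"].to_numpy()
                       == np.array([meds[s].name for s in lab])).sum()
                tot += len(lab)
            accs.append(ok / tot)
        assert accs[0] <= accs[1] <= accs[2]

    def test_empty_median_list_raises(self, spec3):
        ens = generate_ensemble(spec3, 1, 10)
        with pytest.raises(ValueError, match="empty"):
            assign_frames(ens.trajectories[0], [])


class TestLibraryIO:
    def test_roundtrip(self, tmp_path, spec3):
        meds = medians_from_spec(spec3)
        write_median_library(meds, tmp_path / "lib.txt")
        back = read_median_library(tmp_path / "lib.txt")
        assert [m.name for m in back] == [m.name for m in meds]
        for a, b in zip(meds, back):
            assert np.abs(a.torsions - b.torsions).max() < 1e-4


@pytest.fixture(scope="module")
def msm_pipeline3():
    """Shared 3-state MSM pipeline for mapping/report tests."""
    spec = three_state_spec(seed=5)
    ens = generate_ensemble(spec, 10, 800)
    feats = [torsions_to_features(t) for t in ens.trajectories]
    tmodel = fit_tica(feats, 5)
    Ys = [tica_transform(tmodel, f) for f in feats]
    micro = cluster_microstates(Ys, 40, seed=0)
    model, _, _, _ = estimate_msm(micro.labels, 5,
                                  frame_stride_ns=spec.frame_stride_ns)
    coarse = pcca_plus(model, 3)
    return spec, ens, micro, coarse


class TestMacrostateMapping:
    def test_medians_map_to_distinct_dominated_macrostates(self, msm_pipeline3):
        spec, ens, micro, coarse = msm_pipeline3
        meds = medians_from_spec(spec)
        hosted, unobserved, _ = map_medians_to_macrostates(
            meds, ens.trajectories, coarse, micro.labels, radius=1.0)
        assert not unobserved
        assert len(hosted) == 3  # one macrostate per metastable state

    def test_far_median_reported_unobserved(self, msm_pipeline3):
        spec, ens, micro, coarse = msm_pipeline3
        far = CanonicalMedian(f"L3-{spec.loop_length}-9",
                              np.full((spec.loop_length, 3), 17.0))
        hosted, unobserved, _ = map_medians_to_macrostates(
            [far], ens.trajectories, coarse, micro.labels, radius=0.05)
        assert unobserved == [far.name]
        assert not hosted

    def test_co_located_medians_share_macrostate(self, msm_pipeline3):
        spec, ens, micro, coarse = msm_pipeline3
        base = spec.state_medians[0]
        twin = np.clip(base + 3.0, -180, 179.999)
        meds = [CanonicalMedian(f"L3-{spec.loop_length}-1", base),
                CanonicalMedian(f"L3-{spec.loop_length}-2", twin)]
        hosted, unobserved, _ = map_medians_to_macrostates(
            meds, ens.trajectories, coarse, micro.labels, radius=1.0)
        assert len(hosted) == 1
        (names,) = hosted.values()
        assert sorted(names) == [m.name for m in meds]


class TestKineticsReport:
    def test_same_minimum_flagged_with_zero_mfpt(self, msm_pipeline3):
        _, _, _, coarse = msm_pipeline3
        hosted = {0: ["L3-7-1", "L3-7-2"], 1: ["L3-7-3"]}
        rep = kinetics_report(coarse, hosted, [])
        row = rep.pair_mfpt_ns.set_index(["from", "to"]).loc[("L3-7-1", "L3-7-2")]
        assert row["same_minimum"] and row["mfpt_ns"] == 0.0
        cross = rep.pair_mfpt_ns.set_index(["from", "to"]).loc[("L3-7-1", "L3-7-3")]
        assert not cross["same_minimum"] and cross["mfpt_ns"] > 0

    def test_populations_sum_to_one(self, msm_pipeline3):
        _, _, _, coarse = msm_pipeline3
        rep = kinetics_report(coarse, {0: ["L3-7-1"]}, [])
        assert rep.populations.sum() == pytest.approx(1.0, abs=1e-10)

    def test_report_json_roundtrip(self, msm_pipeline3):
        _, _, _, coarse = msm_pipeline3
        rep = kinetics_report(coarse, {0: ["L3-7-1"], 1: ["L3-7-2"]},
                              ["L3-7-9"], representative_frames={0: 5, 1: 9})
        back = CanonicalReport.from_json(rep.to_json())
        assert back.to_json() == rep.to_json()
        assert back.unobserved == ["L3-7-9"]

    def test_every_median_hosted_or_unobserved_once(self, msm_pipeline3):
        spec, ens, micro, coarse = msm_pipeline3
        meds = medians_from_spec(spec)
        far = CanonicalMedian(f"L3-{spec.loop_length}-8",
                              np.full((spec.loop_length, 3), 11.0))
        hosted, unobserved, _ = map_medians_to_macrostates(
            meds + [far], ens.trajectories, coarse, micro.labels, radius=0.5)
        seen = sorted([n for v in hosted.values() for n in v] + unobserved)
        assert seen == sorted(m.name for m in meds + [far])
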