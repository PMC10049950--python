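"""Grouped contact occurrence, display filtering, and domain orientation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from fabstab.descriptors import ContactEvents
from fabstab.interface import (DomainFrame, OccurrenceMatrix, domain_frame,
                               group_contacts, interdomain_orientation,
                               occurrence_filter, orientation_shift,
                               state_window_occurrence, write_flareplot_json)
from fabstab.reweighting import reweighted_occurrence
from fabstab.statemodel import TransitionReport


def _events(rows, present):
    meta = pd.DataFrame(rows, columns=["chainA", "resA", "groupA",
                                       "chainB", "resB", "groupB", "type"])
    return ContactEvents(meta=meta, present=np.asarray(present, dtype=bool))


class TestGroupContacts:
    def test_single_pair_propagates(self):
        ev = _events([("H", 1, "h_HI", "L", 1, "l_GH", "hbond_bb_bb")],
                     [[True, False, True]])
        g = group_contacts(ev)
        assert g.pairs == [("h_HI", "l_GH")]
        assert list(g.present[0]) == [True, False, True]

    def test_or_semantics_within_group_pair(self):
        ev = _events(
            [("H", 1, "h_HI", "L", 1, "l_GH", "hbond_bb_bb"),
             ("H", 2, "h_HI", "L", 2, "l_GH", "salt_bridge")],
            [[True, False, False], [False, True, False]])
        g = group_contacts(ev)
        assert list(g.present[0]) == [True, True, False]

    def test_unlabeled_residue_rejected(self):
        ev = _events([("H", 1, "", "L", 1, "l_GH", "hbond_bb_bb")], [[True]])
        with pytest.raises(ValueError, match="H:1"):
            group_contacts(ev)

    def test_matches_brute_force_or_oracle(self):
        rng = np.random.default_rng(0)
        groups_h = ["h_HI", "h_C", "h_G"]
        groups_l = ["l_GH", "l_AB"]
        rows, present = [], []
        for i in range(12):
            rows.append(("H", i, groups_h[i % 3], "L", i, groups_l[i % 2],
                         "hydrophobic"))
            present.append(rng.random(20) < 0.4)
        g = group_contacts(_events(rows, present))
        for k, pair in enumerate(g.pairs):
            members = [i for i, r in enumerate(rows)
                       if tuple(sorted((r[2], r[5]))) == pair]
            expect = np.any([present[i] for i in members], axis=0)
            assert np.array_equal(g.present[k], expect)

    def test_group_occurrence_at_least_member_occurrence(self):
        rng = np.random.default_rng(1)
        rows = [("H", i, "h_HI", "L", i, "l_GH", "hydrophobic") for i in range(4)]
        present = [rng.random(50) < 0.3 for _ in range(4)]
        g = group_contacts(_events(rows, present))
        w = np.ones(50) / 50
        group_occ = reweighted_occurrence(g.present[0], w)
        member_occs = [reweighted_occurrence(p, w) for p in present]
        assert group_occ >= max(member_occs) - 1e-12


class TestStateWindowOccurrence:
    @pytest.fixture
    def grouped(self):
        ev = _events([("H", 1, "h_HI", "L", 1, "l_GH", "hbond_bb_bb")],
                     [np.r_[np.ones(40), np.zeros(60)].astype(bool)])
        return group_contacts(ev)

    @pytest.fixture
    def report(self):
        return TransitionReport(bound_encounter=(50, 2.3),
                                encounter_unbound=(80, 2.9))

    def test_full_presence_window_is_one(self, grouped, report):
        w = np.ones(100) / 100
        mats = state_window_occurrence(grouped, w, report, span_frames=20)
        assert mats["bound"].values[0] == 1.0

    def test_half_present_window(self, grouped, report):
        w = np.ones(100) / 100
        mats = state_window_occurrence(grouped, w, report, span_frames=20,
                                       states=("bound_encounter_transition",))
        # transition window [50, 70): contact present nowhere there
        assert mats["bound_encounter_transition"].values[0] == 0.0
        rep2 = TransitionReport(bound_encounter=(30, 2.2),
                                encounter_unbound=None)
        mats2 = state_window_occurrence(grouped, w, rep2, span_frames=20,
                                        states=("bound_encounter_transition",))
        assert mats2["bound_encounter_transition"].values[0] == \
            pytest.approx(0.5, abs=1e-12)

    def test_zero_span_rejected(self, grouped, report):
        with pytest.raises(ValueError):
            state_window_occurrence(grouped, np.ones(100) / 100, report,
                                    span_frames=0)

    def test_window_past_end_truncated_with_warning(self, grouped):
        rep = TransitionReport(bound_encounter=(95, 3.9),
                               encounter_unbound=None)
        with pytest.warns(UserWarning, match="truncated"):
            mats = state_window_occurrence(
                grouped, np.ones(100) / 100, rep, span_frames=20,
                states=("bound_encounter_transition",))
        assert mats["bound_encounter_transition"].values[0] == 0.0

    def test_missing_transition_rejected(self, grouped):
        rep = TransitionReport(bound_encounter=None, encounter_unbound=None)
        with pytest.raises(ValueError, match="transition"):
            state_window_occurrence(grouped, np.ones(100) / 100, rep,
                                    span_frames=10,
                                    states=("bound_encounter_transition",))


class TestOccurrenceFilter:
    def _matrix(self, values):
        labels = [(f"g{i}", f"h{i}") for i in range(len(values))]
        return OccurrenceMatrix(labels=labels, values=np.asarray(values),
                                state="bound")

    def test_strictly_greater_boundary(self):
        out = occurrence_filter(self._matrix([0.2, 0.3, 0.31]), 0.3)
        assert list(out.values) == [0.31]

    def test_zero_keeps_nonzero_and_one_empties(self):
        m = self._matrix([0.0, 0.1, 0.9])
        assert len(occurrence_filter(m, 0.0).values) == 2
        assert len(occurrence_filter(m, 1.0).values) == 0

    def test_idempotent(self):
        m = self._matrix([0.2, 0.5, 0.8])
        once = occurrence_filter(m, 0.3)
        twice = occurrence_filter(once, 0.3)
        assert list(once.values) == list(twice.values)

    def test_flareplot_json(self, tmp_path):
        import json
        m = self._matrix([0.4, 0.8])
        write_flareplot_json({"bound": m}, tmp_path / "f.json")
        data = json.loads((tmp_path / "f.json").read_text())
        assert len(data["edges"]) == 2 and "g0" in data["nodes"]


class TestDomainFrame:
    def _cloud(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        # anisotropic cloud: dominant x, medium y, small z
        return rng.normal(0, 1, (n, 3)) * [1.0, 0.3, 0.1]

    def test_elongated_cloud_first_axis(self):
        rng = np.random.default_rng(2)
        pts = np.c_[np.linspace(-1, 1, 30), rng.normal(0, 0.02, 30),
                    rng.normal(0, 0.01, 30)]
        fr = domain_frame(pts)
        ang = np.degrees(np.arccos(abs(fr.axes[0] @ [1, 0, 0])))
        assert ang < 5.0

    def test_equivariant_under_rotation(self):
        pts = self._cloud(3)
        R = Rotation.random(random_state=11).as_matrix()
        a = domain_frame(pts)
        b = domain_frame(pts @ R.T + [1.0, 2.0, 3.0])
        assert np.allclose(b.axes, a.axes @ R.T, atol=1e-9)
        assert np.allclose(b.origin, R @ a.origin + [1.0, 2.0, 3.0], atol=1e-9)

    def test_sign_stable_under_perturbation(self):
        pts = self._cloud(4)
        base = domain_frame(pts)
        rng = np.random.default_rng(5)
        for _ in range(25):
            fr = domain_frame(pts + rng.normal(0, 0.01, pts.shape))
            assert fr.axes[0] @ base.axes[0] > 0
            assert fr.axes[1] @ base.axes[1] > 0

    def test_right_handed(self):
        fr = domain_frame(self._cloud(6))
        assert np.linalg.det(fr.axes) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_rejected(self):
        pts = np.c_[np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)]
        with pytest.raises(ValueError, match="degenerate"):
            domain_frame(pts)


def _frame(origin, a1, a2):
    a1 = np.asarray(a1, float) / np.linalg.norm(a1)
    a2 = np.asarray(a2, float) / np.linalg.norm(a2)
    return DomainFrame(origin=np.asarray(origin, float),
                       axes=np.vstack([a1, a2, np.cross(a1, a2)]))


class TestInterdomainOrientation:
    def test_parallel_frames_aligned_case(self):
        a = _frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
        b = _frame([0, 0, 2], [1, 0, 0], [0, 1, 0])
        ang = interdomain_orientation(a, b)
        assert ang.distance == pytest.approx(2.0)
        assert ang.hl == pytest.approx(0.0, abs=1e-9)
        assert ang.hc1 == pytest.approx(90.0)
        assert ang.hc2 == pytest.approx(90.0)

    def test_rotation_about_interorigin_axis_shifts_torsion_only(self):
        a = _frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
        c = np.array([0, 0, 1.0])
        R = Rotation.from_rotvec(np.radians(30) * c).as_matrix()
        b0 = _frame([0, 0, 2], [1, 0, 0], [0, 1, 0])
        b1 = _frame([0, 0, 2], R @ [1, 0, 0], R @ [0, 1, 0])
        r0 = interdomain_orientation(a, b0)
        r1 = interdomain_orientation(a, b1)
        assert r1.hl - r0.hl == pytest.approx(30.0, abs=1e-9)
        for attr in ("hc1", "hc2", "lc1", "lc2", "distance"):
            assert getattr(r1, attr) == pytest.approx(getattr(r0, attr),
                                                      abs=1e-9)

    def test_swap_preserves_distance_and_torsion_magnitude(self):
        # both the projection axis and the cross product flip on swap, so a
        # rotation-invariant torsion is swap-invariant (magnitude and sign)
        a = _frame([0, 0, 0], [1, 0, 0.2], [0, 1, 0])
        b = _frame([0.3, 0.1, 2], [0.8, 0.4, 0], [0, 0.9, 0.3])
        ab = interdomain_orientation(a, b)
        ba = interdomain_orientation(b, a)
        assert ba.distance == pytest.approx(ab.distance)
        assert abs(ba.hl) == pytest.approx(abs(ab.hl), abs=1e-9)
        assert (ba.lc1, ba.lc2) == pytest.approx((ab.hc1, ab.hc2), abs=1e-9)

    def test_global_rigid_motion_invariance(self):
        a = _frame([0, 0, 0], [1, 0, 0.2], [0, 1, 0])
        b = _frame([0.3, 0.1, 2], [0.8, 0.4, 0], [0, 0.9, 0.3])
        base = interdomain_orientation(a, b)
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([4.0, -1.0, 0.5])
        a2 = DomainFrame(origin=R @ a.origin + t, axes=a.axes @ R.T)
        b2 = DomainFrame(origin=R @ b.origin + t, axes=b.axes @ R.T)
        moved = interdomain_orientation(a2, b2)
        for attr in ("hc1", "hc2", "lc1", "lc2", "hl", "distance"):
            assert getattr(moved, attr) == pytest.approx(
                getattr(base, attr), abs=1e-9)

    def test_coincident_origins_rejected(self):
        a = _frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
        with pytest.raises(ValueError, match="coincident"):
            interdomain_orientation(a, a)


class TestOrientationShift:
    def _series(self, cols):
        n = len(next(iter(cols.values())))
        df = pd.DataFrame({"frame": np.arange(n)})
        for k in ("hc1", "hc2", "lc1", "lc2", "hl"):
            df[k] = cols.get(k, np.zeros(n))
        df["distance"] = 2.0
        return df

    def test_constant_series_zero_shift_and_sd(self):
        out = orientation_shift(self._series({"hc1": np.full(100, 30.0)}))
        assert np.allclose(out["shift_deg"], 0.0)
        assert np.allclose(out["sd_deg"], 0.0)

    def test_linear_ramp_matches_closed_form(self):
        n, w = 100, 10
        ramp = np.linspace(0, 40, n)
        out = orientation_shift(self._series({"hc2": ramp}), window_frames=w)
        expect = ramp[-w:].mean() - ramp[:w].mean()
        got = out.loc[out["angle"] == "hc2", "shift_deg"].iloc[0]
        assert got == pytest.approx(expect, abs=1e-9)
        sd = out.loc[out["angle"] == "hc2", "sd_deg"].iloc[0]
        assert sd == pytest.approx(np.std(ramp), abs=1e-9)

    def test_torsion_dominated_dissociation(self):
        n = 100
        hl = np.linspace(-170, 170, n)   # wraps through the branch cut
        out = orientation_shift(self._series({"hl": hl,
                                              "hc1": np.linspace(0, 5, n)}))
        assert out.loc[out["max_shift"], "angle"].iloc[0] == "hl"

    def test_span_ends_at_encounter_unbound(self):
        ramp = np.r_[np.linspace(0, 40, 50), np.full(50, 80.0)]
        rep = TransitionReport(bound_encounter=(10, 2.0),
                               encounter_unbound=(49, 3.0))
        out = orientation_shift(self._series({"hc1": ramp}), report=rep,
                                window_frames=5)
        got = out.loc[out["angle"] == "hc1", "shift_deg"].iloc[0]
        expect = ramp[45:50].mean() - ramp[:5].mean()
        assert got == pytest.approx(expect, abs=1e-9)
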