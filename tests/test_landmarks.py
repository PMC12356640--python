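"""Landmark data model, I/O, centroid size, GPA and limb assembly."""

import numpy as np
import pandas as pd
import pytest

import limbshape as ls
from limbshape.landmarks import (LandmarkError, configs_to_frame,
                                 element_length, _optimal_rotation)
from conftest import random_configs


def _square(spec="a", taxon="t"):
    pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
    return ls.LandmarkConfiguration(spec, taxon, pts, ["fixed"] * 4,
                                    ["femur"] * 4, [None] * 4)


class TestIO:
    def test_csv_readback(self, tmp_path):
        configs = [_square("a"), _square("b")]
        path = tmp_path / "lm.csv"
        ls.write_landmarks(configs, path)
        back = ls.read_landmarks(path)
        assert len(back) == 2
        assert back[0].n_points == 4
        np.testing.assert_allclose(back[1].points, configs[1].points)

    def test_inconsistent_point_count_names_specimen(self, tmp_path):
        df = configs_to_frame([_square("a"), _square("b")])
        df = df.drop(df.index[-1])        # second specimen loses a point
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(LandmarkError, match="b"):
            ls.read_landmarks(path)

    def test_unknown_bone_tag_rejected(self):
        with pytest.raises(LandmarkError, match="bone"):
            ls.LandmarkConfiguration("a", "t", np.zeros((2, 3)),
                                     ["fixed"] * 2, ["humerus"] * 2,
                                     [None] * 2)

    def test_roundtrip_canonical_form(self, tmp_path, template):
        # write -> read -> write reproduces the file byte-for-byte
        cfg, _ = template
        rng = np.random.default_rng(7)
        configs = random_configs(20, cfg, seed=3)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ls.write_landmarks(configs, p1)
        ls.write_landmarks(ls.read_landmarks(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tps_dialect(self, tmp_path):
        text = "LM3=2\n0 0 0\n1 1 1\nID=alpha\nLM3=2\n0 0 1\n2 2 2\nID=beta\n"
        path = tmp_path / "f.tps"
        path.write_text(text)
        configs = ls.read_landmarks(path, format="tps")
        assert [c.specimen_id for c in configs] == ["alpha", "beta"]
        np.testing.assert_allclose(configs[1].points, [[0, 0, 1], [2, 2, 2]])


class TestCentroidSize:
    def test_closed_form_square(self):
        assert ls.centroid_size(_square()) == pytest.approx(2 * np.sqrt(2))

    def test_homogeneous_and_rigid_invariant(self, template):
        cfg, _ = template
        cs = ls.centroid_size(cfg)
        assert ls.centroid_size(cfg.with_points(cfg.points * 3.5)) == \
            pytest.approx(3.5 * cs)
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert ls.centroid_size(cfg.with_points(cfg.points @ q + 9.0)) == \
            pytest.approx(cs)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((28, 3))
        direct = np.sqrt(sum(
            np.sum((p - pts.mean(axis=0)) ** 2) for p in pts))
        cfg = ls.LandmarkConfiguration("a", "t", pts, ["fixed"] * 28,
                                       ["femur"] * 28, [None] * 28)
        assert ls.centroid_size(cfg) == pytest.approx(direct, abs=1e-12)

    def test_coincident_points_warn_zero(self):
        cfg = ls.LandmarkConfiguration("a", "t", np.ones((3, 3)),
                                       ["fixed"] * 3, ["femur"] * 3,
                                       [None] * 3)
        with pytest.warns(UserWarning):
            assert ls.centroid_size(cfg) == 0.0


class TestGPA:
    def test_identical_configs_zero_distance(self, template):
        cfg, _ = template
        al = ls.gpa_align([cfg, cfg.with_points(cfg.points, specimen_id="b")],
                          project_to_tangent=False)
        d = np.linalg.norm(al.aligned[0].points - al.aligned[1].points)
        assert d < 1e-12
        np.testing.assert_allclose(al.consensus.points, al.aligned[0].points,
                                   atol=1e-12)

    def test_similarity_invariance(self, template):
        cfg, _ = template
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = cfg.with_points(cfg.points @ q.T * 2.3 + 11.0,
                                specimen_id="b")
        al = ls.gpa_align([cfg, moved], project_to_tangent=False)
        rms = np.sqrt(np.mean(
            (al.aligned[0].points - al.aligned[1].points) ** 2))
        assert rms < 1e-8

    def test_alignment_invariants(self, small_configs):
        al = ls.gpa_align(small_configs, project_to_tangent=False)
        for a in al.aligned:
            assert np.linalg.norm(a.points.mean(axis=0)) < 1e-9
            assert np.sqrt((a.points ** 2).sum()) == pytest.approx(1, abs=1e-9)
        mean = np.mean([a.points for a in al.aligned], axis=0)
        mean /= np.sqrt((mean ** 2).sum())
        np.testing.assert_allclose(mean, al.consensus.points, atol=1e-9)

    def test_tangent_coords_invariant_to_input_similarity(self, small_configs):
        al1 = ls.gpa_align(small_configs)
        rng = np.random.default_rng(2)
        moved = []
        for c in small_configs:
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            moved.append(c.with_points(
                c.points @ q.T * rng.uniform(0.5, 2.0) + rng.normal(size=3)))
        al2 = ls.gpa_align(moved)
        # tangent coordinates agree after aligning the two consensuses
        r = _optimal_rotation(al2.consensus.points, al1.consensus.points)
        t2 = (al2.tangent_coords.reshape(len(moved), -1, 3) @ r).reshape(
            len(moved), -1)
        np.testing.assert_allclose(t2, al1.tangent_coords, atol=1e-7)

    def test_degenerate_rank_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 6), np.zeros(6), np.zeros(6)])
        cfg = ls.LandmarkConfiguration("a", "t", line, ["fixed"] * 6,
                                       ["femur"] * 6, [None] * 6)
        with pytest.raises(LandmarkError, match="rank"):
            ls.gpa_align([cfg, cfg.with_points(line * 2, specimen_id="b")])

    def test_local_optimality_against_rotation_perturbations(self, template):
        # converged objective is a local minimum w.r.t. rotating any specimen
        cfg, _ = template
        configs = random_configs(5, cfg, seed=9, rigid=True)
        al = ls.gpa_align(configs, project_to_tangent=False)
        X = np.array([a.points for a in al.aligned])
        obj = _gpa_objective(X)
        rng = np.random.default_rng(10)
        for _ in range(100):
            i = rng.integers(len(configs))
            Y = X.copy()
            Y[i] = Y[i] @ _small_rotation(rng, 1e-3)
            assert _gpa_objective(Y) >= obj - 1e-12


def _gpa_objective(X):
    mean = X.mean(axis=0)
    return float(((X - mean) ** 2).sum())


def _small_rotation(rng, scale):
    w = rng.standard_normal(3) * scale
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    from scipy.linalg import expm
    return expm(K)


class TestTaxonMeans:
    def test_duplicate_specimens_mean_is_specimen(self, template):
        cfg, _ = template
        dup = [cfg.with_points(cfg.points, specimen_id=f"s{i}", taxon_id="tax")
               for i in range(3)]
        other = cfg.with_points(cfg.points * 1.2 + 3.0, specimen_id="o",
                                taxon_id="other")
        means = ls.taxon_mean_shape(dup + [other])
        m = next(c for c in means if c.taxon_id == "tax")
        assert ls.centroid_size(m) == pytest.approx(ls.centroid_size(cfg))
        check = ls.gpa_align([m, cfg], project_to_tangent=False)
        rms = np.sqrt(np.mean(
            (check.aligned[0].points - check.aligned[1].points) ** 2))
        assert rms < 1e-8

    def test_mean_is_coordinatewise_midpoint(self, template):
        # two small opposite deformations of the template average back to it
        cfg, _ = template
        rng = np.random.default_rng(3)
        delta = 1e-3 * rng.standard_normal(cfg.points.shape)
        a = cfg.with_points(cfg.points + delta, specimen_id="a",
                            taxon_id="tax")
        b = cfg.with_points(cfg.points - delta, specimen_id="b",
                            taxon_id="tax")
        m = ls.taxon_mean_shape([a, b])[0]
        check = ls.gpa_align([m, cfg], project_to_tangent=False)
        rms = np.sqrt(np.mean(
            (check.aligned[0].points - check.aligned[1].points) ** 2))
        assert rms < 1e-6

    def test_mean_minimizes_procrustes_ss(self, template):
        cfg, _ = template
        configs = random_configs(4, cfg, seed=13)
        for c in configs:
            c.taxon_id = "tax"
        al = ls.gpa_align(configs, project_to_tangent=False)
        X = np.array([a.points for a in al.aligned])
        mean = X.mean(axis=0)
        base = ((X - mean) ** 2).sum()
        rng = np.random.default_rng(14)
        for _ in range(500):
            pert = mean + 1e-3 * rng.standard_normal(mean.shape)
            assert ((X - pert) ** 2).sum() >= base


class TestAssembly:
    def _bar(self, length, spec="e", bone="femur", width=0.2):
        z = np.linspace(-length / 2, length / 2, 6)
        pts = np.concatenate([
            np.column_stack([np.full(6, width), np.zeros(6), z]),
            np.column_stack([np.full(6, -width), np.full(6, 0.1), z])])
        k = len(pts)
        return ls.LandmarkConfiguration(spec, "t", pts, ["fixed"] * k,
                                        [bone] * k, [None] * k)

    def test_zero_gap_composite_length(self):
        femur = self._bar(10.0, bone="femur")
        tibia = self._bar(6.0, bone="tibia")
        fibula = self._bar(6.0, bone="fibula")
        limb = ls.assemble_limb(femur, tibia, fibula,
                                ls.AssemblyConfig(gap_fraction=0.0))
        extent = limb.points[:, 2].max() - limb.points[:, 2].min()
        assert extent == pytest.approx(16.0, rel=1e-9)

    def test_two_percent_gap_of_1000mm_femur(self):
        femur = self._bar(1000.0, bone="femur")
        tibia = self._bar(600.0, bone="tibia")
        fibula = self._bar(580.0, bone="fibula")
        limb = ls.assemble_limb(femur, tibia, fibula,
                                ls.AssemblyConfig(gap_fraction=0.02))
        femur_bottom = limb.points[np.array(limb.bones) == "femur", 2].min()
        zeug_top = limb.points[np.array(limb.bones) != "femur", 2].max()
        assert femur_bottom - zeug_top == pytest.approx(20.0, rel=1e-9)

    def test_composite_extent_matches_axis_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            lf, lt, lfb = rng.uniform(5, 15, size=3)
            femur = self._bar(lf, bone="femur")
            tibia = self._bar(lt, bone="tibia")
            fibula = self._bar(lfb, bone="fibula")
            gapf = rng.uniform(0, 0.05)
            limb = ls.assemble_limb(femur, tibia, fibula,
                                    ls.AssemblyConfig(gap_fraction=gapf))
            expected = (element_length(femur) + gapf * element_length(femur)
                        + max(element_length(tibia), element_length(fibula)))
            extent = limb.points[:, 2].max() - limb.points[:, 2].min()
            assert extent == pytest.approx(expected, rel=1e-6)

    def test_missing_element_rejected(self):
        femur = self._bar(10.0)
        with pytest.raises(LandmarkError, match="tibia"):
            ls.assemble_limb(femur, None, self._bar(6.0, bone="fibula"))
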