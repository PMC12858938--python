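"""Structural descriptors: analytic oracles and generator recovery."""

import math

import numpy as np
import pytest

from graymorph import morphometry as m
from graymorph.morphometry import Branch, SubSegment
from graymorph.swc import read_swc
from graymorph.synthetic import SyntheticCellSpec, generate_cell

from conftest import make_cell


def straight_branch(n=10, spacing=5.0, radius=0.5, order=1):
    pts = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    return Branch(pts, np.full(n, radius), order)


def semicircle_branch(R=20.0, step_deg=1.0):
    ang = np.radians(np.arange(0.0, 180.0 + step_deg, step_deg))
    pts = np.column_stack([R * np.cos(ang), R * np.sin(ang), np.zeros_like(ang)])
    return Branch(pts, np.full(len(ang), 0.5), 1)


class TestSomaSeparation:
    def test_threshold_partition(self):
        text = ("1 1 0 0 0 5 -1\n2 3 3 0 0 0.5 1\n3 3 10 0 0 0.5 2\n")
        soma_ids, projs = m.separate_soma(read_swc(text))
        assert set(soma_ids) == {1, 2}
        assert len(projs) == 1
        # entry node sits on the threshold sphere
        entry = projs[0].nodes[projs[0].root_id]
        assert np.linalg.norm(entry.xyz) == pytest.approx(5.0, abs=1e-9)

    def test_no_projection_error(self):
        text = "1 1 0 0 0 5 -1\n2 3 3 0 0 0.5 1\n"
        with pytest.raises(m.NoProjectionsError):
            m.separate_soma(read_swc(text))

    def test_generator_projection_count(self, default_cell):
        cell, gt = default_cell
        assert m.count_projections(cell) == gt.n_projections


class TestBranchDecomposition:
    def test_unbranched_path_single_branch(self):
        rows = [(1, 1, 0, 0, 0, 1.0, None)] + [
            (i, 3, (i - 1) * 3.0, 0, 0, 0.5, i - 1) for i in range(2, 12)
        ]
        _, projs = m.separate_soma(make_cell(rows))
        assert len(m.decompose_branches(projs)) == 1

    def test_y_tree_three_branches(self, y_cell):
        _, projs = m.separate_soma(y_cell)
        branches = m.decompose_branches(projs)
        assert len(branches) == 3
        assert sorted(b.order for b in branches) == [1, 2, 2]

    def test_terminals_plus_bifurcations_conservation(self, default_cell):
        cell, gt = default_cell
        _, projs = m.separate_soma(cell)
        branches = m.decompose_branches(projs)
        n_terminal = sum(
            1 for p in projs
            for nid, kids in p.children_map().items() if not kids
        )
        n_bif = sum(
            1 for p in projs
            for nid, kids in p.children_map().items() if len(kids) >= 2
        )
        assert len(branches) == n_terminal + n_bif


class TestBranchGeometry:
    def test_straight_path_length(self):
        assert m.branch_length(straight_branch()) == pytest.approx(45.0)

    def test_semicircle_arc_length(self):
        assert m.branch_length(semicircle_branch()) == pytest.approx(
            math.pi * 20.0, rel=1e-3
        )

    def test_tortuosity_straight_and_semicircle(self):
        assert m.branch_tortuosity(straight_branch()) == pytest.approx(1.0)
        assert m.branch_tortuosity(semicircle_branch()) == pytest.approx(
            2.0 / math.pi, rel=1e-3
        )

    def test_beading_cv(self):
        assert m.branch_beading_cv(straight_branch()) == 0.0
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        b = Branch(pts, np.ones(3), 1, subsegments=[
            SubSegment(pts[0], pts[1], 0.5, 0.5),
            SubSegment(pts[1], pts[2], 1.5, 1.5),
        ])
        assert m.branch_beading_cv(b) == pytest.approx(0.5)

    def test_surface_to_volume(self):
        assert m.branch_sv(straight_branch(radius=0.5)) == pytest.approx(4.0)
        assert m.branch_sv(straight_branch(radius=0.6)) == pytest.approx(2 / 0.6)
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        b = Branch(pts, np.ones(3), 1, subsegments=[
            SubSegment(pts[0], pts[1], 0.5, 0.5),
            SubSegment(pts[1], pts[2], 1.0, 1.0),
        ])
        assert m.branch_sv(b) == pytest.approx(2.4)

    def test_undulation_zigzag(self):
        alpha = math.radians(20)
        h = math.tan(alpha)
        pts = np.array(
            [[0, 0, 0], [1, h, 0], [2, 0, 0], [3, h, 0], [4, 0, 0.0]]
        )
        b = Branch(pts, np.full(5, 0.5), 1)
        assert m.branch_undulation(b) == pytest.approx(alpha, abs=1e-9)
        assert m.branch_undulation(straight_branch()) == 0.0

    def test_curvature_radius_circle(self):
        b = semicircle_branch(R=10.0)
        assert m.branch_curvature_radius(b) == pytest.approx(10.0, abs=1e-6)

    def test_curvature_radius_straight_is_missing(self):
        assert math.isnan(m.branch_curvature_radius(straight_branch()))

    def test_curvature_radius_helix(self):
        a, b_pitch = 10.0, 3.0
        t = np.linspace(0, 4 * math.pi, 400)
        pts = np.column_stack(
            [a * np.cos(t), a * np.sin(t), b_pitch * t]
        )
        br = Branch(pts, np.full(len(t), 0.5), 1)
        expected = (a**2 + b_pitch**2) / a
        assert m.branch_curvature_radius(br) == pytest.approx(expected, rel=0.02)

    def test_branch_angle_symmetric_y(self, y_cell):
        _, projs = m.separate_soma(y_cell)
        branches = m.decompose_branches(projs)
        angles = m.branch_angles(branches)
        assert len(angles) == 1
        assert angles[0] == pytest.approx(math.pi / 2, abs=1e-9)


class TestCellDescriptors:
    def test_branch_order_binary_tree_depth3(self):
        spec = SyntheticCellSpec(
            n_projections=2, branching_depth=3, branch_length_median=20,
            undulation_amplitude=0.0,
        )
        cell, gt = generate_cell(spec, seed=2)
        rec = m.structural_record(cell)
        assert rec.BO == 4 == gt.expected_BO

    def test_domain_radius_star(self):
        rows = [(1, 1, 0, 0, 0, 2.0, None)]
        nid = 2
        for d in np.eye(3):
            parent = 1
            for k in (50, 100):
                rows.append((nid, 3, *(d * k), 0.5, parent))
                parent = nid
                nid += 1
        assert m.domain_radius(make_cell(rows)) == pytest.approx(100.0)

    def test_mr_effective_radius(self):
        assert m.mr_effective_radius([0.7, 0.7, 0.7]) == pytest.approx(0.7)
        assert m.mr_effective_radius([3, 10], (7, 3)) == pytest.approx(
            ((3**7 + 10**7) / (3**3 + 10**3)) ** 0.25
        )
        assert m.mr_effective_radius([0.5, 1.0], (6, 2)) == pytest.approx(
            (0.5078125 / 0.625) ** 0.25
        )
        with pytest.raises(ValueError):
            m.mr_effective_radius([])

    def test_mr_radius_at_least_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = rng.uniform(0.1, 5.0, size=rng.integers(2, 20))
            assert m.mr_effective_radius(r) >= np.mean(r) - 1e-12

    def test_eta_soma(self):
        S = 4 * math.pi * 25
        assert m.eta_soma(S, [1.0]) == pytest.approx(0.01)
        assert m.eta_soma(S, []) == 0.0

    def test_domain_sv_sphere_plus_cylinder(self):
        R, r, L = 5.0, 0.5, 100.0
        soma = m.SomaRegion([1], V_soma=4 / 3 * math.pi * R**3,
                            S_soma=4 * math.pi * R**2)
        soma.eta_soma = m.eta_soma(soma.S_soma, [r])
        b = straight_branch(n=101, spacing=1.0, radius=r)
        expected = (
            soma.S_soma * (1 - soma.eta_soma) + 2 * math.pi * r * L
        ) / (soma.V_soma + math.pi * r**2 * L)
        assert m.domain_sv(soma, [b]) == pytest.approx(expected)


class TestScalingAndRecovery:
    def test_uniform_rescaling_laws(self, plain_cell):
        cell, _ = plain_cell
        c = 2.5
        scaled = cell.copy()
        for n in scaled.nodes.values():
            n.x *= c; n.y *= c; n.z *= c; n.radius *= c
        r1 = m.structural_record(cell)
        r2 = m.structural_record(scaled)
        assert r2.R_domain == pytest.approx(c * r1.R_domain, rel=1e-6)
        assert r2.L_branch == pytest.approx(c * r1.L_branch, rel=1e-6)
        assert r2.R_soma == pytest.approx(c * r1.R_soma, rel=1e-3)
        assert r2.SV_branch == pytest.approx(r1.SV_branch / c, rel=1e-6)
        assert r2.SV_domain == pytest.approx(r1.SV_domain / c, rel=1e-3)
        assert r2.tau_branch == pytest.approx(r1.tau_branch, rel=1e-9)
        assert r2.CV_branch == pytest.approx(r1.CV_branch, rel=1e-9)
        assert r2.muOD_branch == pytest.approx(r1.muOD_branch, abs=1e-6)
        assert (r2.BO, r2.N_proj) == (r1.BO, r1.N_proj)
        assert r2.theta_branch == pytest.approx(r1.theta_branch, rel=1e-9)

    def test_partition_conservation(self, default_cell):
        cell, _ = default_cell
        soma_ids, projs = m.separate_soma(cell)
        proj_ids = set()
        for p in projs:
            proj_ids.update(i for i in p.nodes if i > 0)  # entry nodes are negative
        assert len(soma_ids) + len(proj_ids) == cell.n_nodes()

    def test_tau_in_unit_interval(self, default_cell):
        cell, _ = default_cell
        _, projs = m.separate_soma(cell)
        for b in m.decompose_branches(projs):
            assert 0.0 < m.branch_tortuosity(b) <= 1.0 + 1e-12

    def test_ground_truth_recovery(self, plain_cell):
        cell, gt = plain_cell
        rec = m.structural_record(cell)
        assert rec.N_proj == gt.n_projections
        assert rec.BO == gt.expected_BO
        assert rec.R_soma == pytest.approx(gt.soma_radius, rel=0.02)
        L = np.sort(rec.branches_L)
        assert np.allclose(L, np.sort(gt.branch_lengths), rtol=0.01)
        R = np.sort(rec.branches_R)
        assert np.allclose(R, np.sort(gt.branch_mean_radii), rtol=0.02)
        tau = np.sort(rec.branches_tau)
        assert np.allclose(tau, np.sort(gt.branch_tau), atol=0.01)
        for th in rec.thetas:
            assert abs(th - gt.bifurcation_angle) < 0.05

    def test_undulation_recovery(self, default_cell):
        cell, gt = default_cell
        rec = m.structural_record(cell)
        assert rec.muOD_branch == pytest.approx(
            float(np.mean(gt.branch_muOD)), rel=0.05
        )

    def test_beading_cv_recovery(self):
        # pure sinusoidal beading: CV approaches a / (r sqrt(2))
        spec = SyntheticCellSpec(
            taper_rate=0.0, node_spacing=1.0, undulation_amplitude=0.0,
            beading_amplitude=0.12,
        )
        cell, gt = generate_cell(spec, seed=8)
        rec = m.structural_record(cell)
        assert gt.beading_cv == pytest.approx(0.12 / (0.6 * math.sqrt(2)))
        assert rec.CV_branch == pytest.approx(gt.beading_cv, rel=0.10)
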