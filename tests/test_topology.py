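"""TMD barcodes, persistence images, distances, bootstrap."""

import math

import numpy as np
import pytest

from graymorph import morphometry as m
from graymorph import topology as tp
from graymorph.synthetic import SyntheticCellSpec, generate_cell, generate_population

from conftest import make_cell


def projection_from_rows(rows):
    """Rows rooted at the projection origin (no soma separation)."""
    return make_cell(rows)


def barcode_set(bc):
    return sorted((round(b, 6), round(d, 6)) for b, d in bc.bars)


class TestBarcodes:
    def test_unbranched_path(self):
        rows = [(1, 3, 0, 0, 0, 0.5, None)] + [
            (i, 3, (i - 1) * 10.0, 0, 0, 0.5, i - 1) for i in range(2, 12)
        ]
        bc = tp.tmd_barcode(projection_from_rows(rows))
        assert barcode_set(bc) == [(0.0, 100.0)]

    def test_two_terminal_y(self):
        # trunk to 50, daughters reaching path lengths 90 and 80
        rows = [
            (1, 3, 0, 0, 0, 0.5, None),
            (2, 3, 50, 0, 0, 0.5, 1),
            (3, 3, 90, 0, 0, 0.5, 2),
            (4, 3, 50, 30, 0, 0.5, 2),
        ]
        bc = tp.tmd_barcode(projection_from_rows(rows))
        assert barcode_set(bc) == [(0.0, 90.0), (50.0, 80.0)]

    def test_full_binary_tree_depth3(self):
        # bifurcations at path lengths 10, 30, 60; all terminals at 100
        alpha = 0.2
        rows = [(1, 3, 0, 0, 0, 0.5, None), (2, 3, 10, 0, 0, 0.5, 1)]
        nid = 3
        level = [2]
        pos = {2: np.array([10.0, 0.0])}
        for step in (20.0, 30.0, 40.0):  # each segment IS a path increment
            nxt = []
            for parent in level:
                for sign in (+1, -1):
                    p = pos[parent] + step * np.array(
                        [math.cos(alpha), sign * math.sin(alpha)]
                    )
                    rows.append((nid, 3, p[0], p[1], 0, 0.5, parent))
                    pos[nid] = p
                    nxt.append(nid)
                    nid += 1
            level = nxt
        bc = tp.tmd_barcode(projection_from_rows(rows))
        assert len(bc) == 8  # one bar per terminal
        expected = [(0.0, 100.0), (10.0, 100.0)] + [(30.0, 100.0)] * 2 \
            + [(60.0, 100.0)] * 4
        assert barcode_set(bc) == sorted(expected)

    def test_bar_count_equals_terminal_count_random_trees(self):
        spec = SyntheticCellSpec(
            branching_depth=2, branch_length_median=20, n_projections=2,
        )
        for i, (cell, _) in enumerate(generate_population(spec, 20, seed=9)):
            _, projs = m.separate_soma(cell)
            for p in projs:
                n_term = sum(1 for kids in p.children_map().values() if not kids)
                assert len(tp.tmd_barcode(p)) == n_term

    def test_rigid_motion_invariance(self, default_cell):
        cell, _ = default_cell
        _, projs = m.separate_soma(cell)
        ref = barcode_set(tp.cell_barcode(projs))
        moved = cell.copy()
        theta = 0.7
        R = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        for n in moved.nodes.values():
            n.x, n.y, n.z = R @ n.xyz + np.array([10.0, -5.0, 3.0])
        _, projs2 = m.separate_soma(moved)
        assert barcode_set(tp.cell_barcode(projs2)) == ref

    def test_uniform_scaling_scales_bars(self, default_cell):
        cell, _ = default_cell
        _, projs = m.separate_soma(cell)
        ref = tp.cell_barcode(projs).as_array()
        scaled = cell.copy()
        for n in scaled.nodes.values():
            n.x *= 3; n.y *= 3; n.z *= 3; n.radius *= 3
        _, projs2 = m.separate_soma(scaled)
        out = tp.cell_barcode(projs2).as_array()
        assert np.allclose(
            np.sort(out, axis=0), 3 * np.sort(ref, axis=0), rtol=1e-9
        )


class TestImages:
    def test_unit_sum_and_argmax(self):
        bc = tp.PersistenceBarcode([(20.0, 80.0)])
        img = tp.persistence_image(bc, grid_extent=100.0, resolution=50,
                                   bandwidth=5.0)
        assert img.pixels.sum() == pytest.approx(1.0, abs=1e-12)
        i, j = np.unravel_index(img.pixels.argmax(), img.pixels.shape)
        ax = np.linspace(0, 100, 50)
        assert ax[i] == pytest.approx(20.0, abs=2.1)
        assert ax[j] == pytest.approx(80.0, abs=2.1)

    def test_duplication_invariance(self):
        bars = [(10.0, 50.0), (5.0, 90.0)]
        img1 = tp.persistence_image(tp.PersistenceBarcode(bars),
                                    grid_extent=100, bandwidth=4.0)
        img2 = tp.persistence_image(tp.PersistenceBarcode(bars * 2),
                                    grid_extent=100, bandwidth=4.0)
        assert np.allclose(img1.pixels, img2.pixels, atol=1e-12)

    def test_empty_barcode_rejected(self):
        with pytest.raises(ValueError):
            tp.persistence_image(tp.PersistenceBarcode([]))


class TestDistance:
    def _img(self, bars, bw=4.0):
        return tp.persistence_image(tp.PersistenceBarcode(bars),
                                    grid_extent=100, resolution=50,
                                    bandwidth=bw)

    def test_identity_and_symmetry(self):
        a = self._img([(10.0, 60.0)])
        b = self._img([(30.0, 90.0)])
        assert tp.topological_distance(a, a) == 0.0
        assert tp.topological_distance(a, b) == pytest.approx(
            tp.topological_distance(b, a)
        )

    def test_disjoint_support_distance_two(self):
        a = self._img([(5.0, 10.0)], bw=0.5)
        b = self._img([(80.0, 95.0)], bw=0.5)
        assert tp.topological_distance(a, b) == pytest.approx(2.0, abs=1e-6)

    def test_triangle_inequality_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            imgs = []
            for _ in range(3):
                bars = [
                    (b, b + d)
                    for b, d in rng.uniform(1, 45, size=(5, 2))
                ]
                imgs.append(self._img(bars))
            dab = tp.topological_distance(imgs[0], imgs[1])
            dbc = tp.topological_distance(imgs[1], imgs[2])
            dac = tp.topological_distance(imgs[0], imgs[2])
            assert dac <= dab + dbc + 1e-12

    def test_grid_mismatch_rejected(self):
        a = self._img([(10.0, 60.0)])
        b = tp.persistence_image(tp.PersistenceBarcode([(10.0, 60.0)]),
                                 grid_extent=100, resolution=40, bandwidth=4.0)
        with pytest.raises(ValueError):
            tp.topological_distance(a, b)


def _group_barcodes(spec, n, seed):
    out = []
    for cell, _ in generate_population(spec, n, seed):
        _, projs = m.separate_soma(cell)
        out.append(tp.cell_barcode(projs))
    return out


class TestBootstrap:
    def test_identical_groups(self):
        spec = SyntheticCellSpec(branching_depth=1, branch_length_median=30)
        A = _group_barcodes(spec, 4, seed=3)
        res = tp.bootstrap_distance(A, A, n_boot=200, seed=0, resolution=40)
        assert res.D == 0.0
        assert res.p_value == 1.0

    def test_separated_specs_significant(self):
        longs = SyntheticCellSpec(branching_depth=1, branch_length_median=150)
        shorts = SyntheticCellSpec(branching_depth=1, branch_length_median=30)
        A = _group_barcodes(longs, 30, seed=1)
        B = _group_barcodes(shorts, 30, seed=2)
        res = tp.bootstrap_distance(A, B, n_boot=1000, seed=3, resolution=50)
        assert res.p_value < 0.01

    def test_degenerate_groups_rejected(self):
        spec = SyntheticCellSpec(branching_depth=0)
        A = _group_barcodes(spec, 2, seed=1)
        with pytest.raises(ValueError):
            tp.bootstrap_distance(A[:1], A, n_boot=10, seed=0)
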