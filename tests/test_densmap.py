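"""Map I/O, statistics, interpolation, segmentation, simulation, shells."""

import numpy as np
import pytest

from cryoswim.densmap import (DensityMap, read_map, write_map, segment_map,
                              simulate_map, shell_mask, sample_shell_grid,
                              per_residue_shell_mask, SIGMA_FACTOR)
from cryoswim.model import Atom, AtomicModel


def _water(coord, seq=1):
    return Atom("O", "O", tuple(coord), "S", seq, "HOH")


class TestIO:
    def test_round_trip_identity(self, tmp_path, rng):
        grid = rng.random((8, 8, 8))
        m = DensityMap(grid, 0.5, (0.0, 0.0, 0.0))
        path = tmp_path / "m.mrc"
        write_map(m, path)
        m2 = read_map(path)
        np.testing.assert_allclose(m2.grid, grid, rtol=1e-6)

    def test_anisotropic_voxels_preserved(self, tmp_path, rng):
        m = DensityMap(rng.random((4, 6, 8)), (0.5, 0.6, 0.7), (0, 0, 0))
        write_map(m, tmp_path / "m.mrc")
        m2 = read_map(tmp_path / "m.mrc")
        np.testing.assert_allclose(m2.voxel_size, [0.5, 0.6, 0.7], rtol=1e-6)

    def test_origin_round_trip(self, tmp_path, rng):
        m = DensityMap(rng.random((4, 4, 4)), 1.0, (10.0, 20.0, 30.0))
        write_map(m, tmp_path / "m.mrc")
        m2 = read_map(tmp_path / "m.mrc")
        np.testing.assert_allclose(m2.to_coord([0, 0, 0]), [10, 20, 30])


class TestStats:
    def test_constant_grid(self):
        m = DensityMap(np.full((5, 5, 5), 3.25), 1.0, (0, 0, 0))
        st = m.stats()
        assert st.avgD == 3.25 and st.sigma == 0.0

    def test_two_level_grid(self):
        g = np.zeros((4, 4, 4))
        g[:2] = 2.0
        st = DensityMap(g, 1.0, (0, 0, 0)).stats()
        assert st.avgD == 1.0 and st.sigma == 1.0

    def test_matches_brute_force(self, rng):
        g = rng.random((9, 7, 5))
        st = DensityMap(g, 1.0, (0, 0, 0)).stats()
        # independent two-pass computation
        n = g.size
        mean = sum(float(v) for v in g.ravel()) / n
        var = sum((float(v) - mean) ** 2 for v in g.ravel()) / n
        assert abs(st.avgD - mean) < 1e-12
        assert abs(st.sigma - np.sqrt(var)) < 1e-12


class TestInterpolate:
    def test_voxel_center_exact(self, rng):
        g = rng.random((6, 6, 6))
        m = DensityMap(g, 0.7, (1.0, 2.0, 3.0))
        assert m.interpolate(m.to_coord([2, 3, 4])) == pytest.approx(
            g[2, 3, 4], abs=1e-14)

    def test_midpoint(self):
        g = np.zeros((3, 3, 3))
        g[1, 1, 1] = 0.0
        g[2, 1, 1] = 1.0
        m = DensityMap(g, 1.0, (0, 0, 0))
        assert m.interpolate([1.5, 1.0, 1.0]) == pytest.approx(0.5)

    def test_matches_closed_form_oracle(self, rng):
        g = rng.random((10, 10, 10))
        m = DensityMap(g, 1.0, (0, 0, 0))
        pts = rng.uniform(0, 9, (100, 3))
        got = m.interpolate(pts)
        for p, v in zip(pts, got):
            i0 = np.floor(p).astype(int)
            f = p - i0
            val = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((f[0] if dx else 1 - f[0])
                             * (f[1] if dy else 1 - f[1])
                             * (f[2] if dz else 1 - f[2]))
                        val += w * g[min(i0[0] + dx, 9), min(i0[1] + dy, 9),
                                     min(i0[2] + dz, 9)]
            assert abs(val - v) < 1e-10

    def test_out_of_bounds_raises(self):
        m = DensityMap(np.zeros((4, 4, 4)), 1.0, (0, 0, 0))
        with pytest.raises(ValueError):
            m.interpolate([5.0, 0.0, 0.0])


def _gaussian_map(centers, amps, shape=(24, 24, 24), voxel=0.5, sd=0.6):
    axes = [np.arange(s) * voxel for s in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    g = np.zeros(shape)
    for c, a in zip(centers, amps):
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        g += a * np.exp(-0.5 * r2 / sd ** 2)
    return DensityMap(g, voxel, (0, 0, 0))


class TestSegmentation:
    def test_single_blob(self):
        m = _gaussian_map([(6.1, 6.3, 5.9)], [1.0])
        segs = segment_map(m, 0.05)
        assert len(segs) == 1
        assert np.linalg.norm(segs[0].pmax - [6.1, 6.3, 5.9]) < 0.25 * 0.5

    def test_two_blobs_sorted_by_volume(self):
        m = _gaussian_map([(4, 4, 4), (8, 8, 8)], [1.0, 0.6])
        segs = segment_map(m, 0.05)
        assert len(segs) == 2
        assert segs[0].volume >= segs[1].volume
        assert np.linalg.norm(segs[0].pmax - [4, 4, 4]) < 0.3

    def test_empty_above_threshold(self):
        m = DensityMap(np.zeros((8, 8, 8)), 1.0, (0, 0, 0))
        assert segment_map(m, 0.5) == []

    def test_partition_of_superthreshold_region(self, rng):
        from scipy.ndimage import gaussian_filter
        g = gaussian_filter(rng.random((16, 16, 16)), 1.5)
        m = DensityMap(g, 1.0, (0, 0, 0))
        thr = float(np.percentile(g, 70))
        segs = segment_map(m, thr)
        covered = np.zeros(g.shape, dtype=int)
        for s in segs:
            covered[tuple(s.voxels.T)] += 1
        mask = g >= thr
        assert np.array_equal(covered > 0, mask)
        assert covered.max() == 1  # disjoint

    def test_matches_steepest_ascent_oracle(self, rng):
        from scipy.ndimage import gaussian_filter
        g = gaussian_filter(rng.random((12, 12, 12)), 1.2)
        m = DensityMap(g, 1.0, (0, 0, 0))
        thr = float(np.percentile(g, 60))
        segs = segment_map(m, thr)
        label_of = {}
        for si, s in enumerate(segs):
            for v in map(tuple, s.voxels):
                label_of[v] = si

        # oracle: follow steepest ascent per voxel, one step at a time
        def root(v):
            shape = g.shape
            cur = v
            while True:
                best_val = g[cur]
                best_idx = np.ravel_multi_index(cur, shape)
                best = cur
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            if (di, dj, dk) == (0, 0, 0):
                                continue
                            n = (cur[0] + di, cur[1] + dj, cur[2] + dk)
                            if any(x < 0 or x >= s
                                   for x, s in zip(n, shape)):
                                continue
                            lin = np.ravel_multi_index(n, shape)
                            if g[n] > best_val or (g[n] == best_val
                                                   and lin < best_idx):
                                best_val, best_idx, best = g[n], lin, n
                if best == cur:
                    return cur
                cur = best

        mask = g >= thr
        roots = {}
        for v in map(tuple, np.argwhere(mask)):
            r = root(v)
            roots.setdefault(r, set()).add(v)
        oracle_groups = {frozenset(s) for s in roots.values()}
        got_groups = {frozenset(map(tuple, s.voxels)) for s in segs}
        assert got_groups == oracle_groups


class TestSimulateMap:
    def test_single_atom_profile(self):
        model = AtomicModel([_water((5.0, 5.0, 5.0))])
        m = simulate_map(model, resolution=2.0, voxel=0.5, margin=4.0)
        sd = 2.0 * SIGMA_FACTOR
        peak_idx = np.unravel_index(np.argmax(m.grid), m.shape)
        np.testing.assert_allclose(m.to_coord(peak_idx), [5, 5, 5],
                                   atol=1e-9)
        probe = np.array([5.0 + 0.5, 5.0, 5.0])
        expected = np.exp(-0.5 * 0.25 / sd ** 2)
        assert m.interpolate(probe) == pytest.approx(expected, abs=1e-3)

    def test_species_weight_ratio(self):
        w = AtomicModel([_water((3.0, 5.0, 5.0))])
        mg = AtomicModel([Atom("MG", "MG", (3.0, 5.0, 5.0), "S", 1, "MG")])
        probe = [4.0, 5.0, 5.0]
        mw = simulate_map(w, 2.0, 0.5, margin=4.0)
        mm = simulate_map(mg, 2.0, 0.5, origin=mw.origin, shape=mw.shape)
        assert mm.interpolate(probe) == pytest.approx(
            1.5 * mw.interpolate(probe), rel=1e-9)

    def test_integral_matches_gaussian_normalization(self):
        model = AtomicModel([_water((8.0, 8.0, 8.0))])
        res, vox = 2.0, 0.4
        m = simulate_map(model, res, vox, margin=7.0)
        sd = res * SIGMA_FACTOR
        integral = m.grid.sum() * vox ** 3
        assert integral == pytest.approx((2 * np.pi * sd ** 2) ** 1.5,
                                         rel=1e-3)

    def test_linear_in_species_weights(self):
        model = AtomicModel([_water((5, 5, 5)),
                             Atom("MG", "MG", (8, 5, 5), "S", 2, "MG")])
        m1 = simulate_map(model, 2.0, 0.5, margin=4.0)
        m2 = simulate_map(model, 2.0, 0.5, margin=4.0,
                          species_weights={"water": 2.0, "MG": 3.0})
        half = simulate_map(AtomicModel([model.atoms[0]]), 2.0, 0.5,
                            origin=m1.origin, shape=m1.shape)
        # doubling/tripling weights = adding scaled single-species maps
        mg_only = m1.grid - half.grid
        np.testing.assert_allclose(m2.grid, 2 * half.grid + 2 * mg_only,
                                   atol=1e-12)

    def test_bad_resolution(self):
        with pytest.raises(ValueError):
            simulate_map(AtomicModel([_water((0, 0, 0))]), 0.0)


class TestShellMask:
    def test_all_residues_unresolved_gives_empty(self, small_rna):
        m = simulate_map(small_rna, 2.2, 1.0, margin=5.0)
        q = {k: 0.0 for k in small_rna.residues()}
        assert shell_mask(m, small_rna, q).n_voxels == 0

    def test_single_atom_analytic_volume(self):
        atom = Atom("O", "OP1", (10.0, 10.0, 10.0), "A", 1, "A")
        model = AtomicModel([atom])
        vox = 0.4
        grid = DensityMap(np.zeros((51, 51, 51)), vox, (0, 0, 0))
        sm = shell_mask(grid, model, {("A", 1): 1.0})
        vol = sm.n_voxels * vox ** 3
        analytic = 4 / 3 * np.pi * (3.5 ** 3 - 1.8 ** 3)
        assert vol == pytest.approx(analytic, rel=0.05)

    def test_inner_bound_excludes(self):
        atom = Atom("O", "OP1", (5.0, 5.0, 5.0), "A", 1, "A")
        model = AtomicModel([atom])
        grid = DensityMap(np.zeros((21, 21, 21)), 0.5, (0, 0, 0))
        sm = shell_mask(grid, model, {("A", 1): 1.0})
        # voxel at 1.7 A from the atom must be excluded
        idx = grid.to_index([5.0 + 1.7, 5.0, 5.0])
        assert not sm.mask[tuple(np.round(idx).astype(int))]

    def test_monotone_in_qmin(self, map_fixture, q_by_res):
        fx = map_fixture
        lo = shell_mask(fx.full, fx.model, q_by_res, q_min=0.2)
        hi = shell_mask(fx.full, fx.model, q_by_res, q_min=0.9)
        assert hi.n_voxels <= lo.n_voxels
        assert np.all(lo.mask[hi.mask])


class TestSampleShellGrid:
    def test_single_atom_distance_bounds(self):
        atom = Atom("O", "OP1", (0.0, 0.0, 0.0), "A", 1, "A")
        model = AtomicModel([atom])
        pts = sample_shell_grid(model, {("A", 1): 1.0})
        r = np.linalg.norm(pts, axis=1)
        assert len(pts) > 0
        assert np.all((r >= 1.5) & (r <= 3.5))

    def test_no_resolved_residues_empty(self, small_rna):
        pts = sample_shell_grid(small_rna,
                                {k: 0.0 for k in small_rna.residues()})
        assert len(pts) == 0

    def test_matches_brute_force_enumeration(self):
        atoms = [Atom("O", "OP1", (0.0, 0.0, 0.0), "A", 1, "A"),
                 Atom("O", "OP1", (4.0, 0.0, 0.0), "A", 2, "A")]
        model = AtomicModel(atoms)
        q = {("A", 1): 1.0, ("A", 2): 0.3}
        pts = sample_shell_grid(model, q, spacing=1.67)
        coords = model.coords
        lo = coords.min(0) - 3.5
        hi = coords.max(0) + 3.5
        count = 0
        for x in np.arange(lo[0], hi[0] + 0.835, 1.67):
            for y in np.arange(lo[1], hi[1] + 0.835, 1.67):
                for z in np.arange(lo[2], hi[2] + 0.835, 1.67):
                    p = np.array([x, y, z])
                    d1 = np.linalg.norm(p)                 # resolved atom
                    d2 = np.linalg.norm(p - [4, 0, 0])     # unresolved
                    if min(d1, d2) >= 1.5 and d1 <= 3.5:
                        count += 1
        assert len(pts) == count
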