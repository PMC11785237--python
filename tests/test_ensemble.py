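"""Ensemble binding-site analysis: detection, assignment, occupancy,
RMSF, residence time, composite densities, flexibility, unit conversion."""

import numpy as np
import pandas as pd
import pytest

from cryoswim import fixtures
from cryoswim.densmap import DensityMap
from cryoswim.ensemble import (EnsembleFrameSet, _residence_events,
                               accumulate_density, assign_frames,
                               detect_sites, molarity_to_number_density,
                               number_density_to_molarity,
                               occupancy_density, refine_site_binders,
                               retained_frames, rna_flexibility,
                               site_statistics)


@pytest.fixture(scope="module")
def ens_fixture():
    spec = fixtures.EnsembleSpec(n_frames=500,
                                 site_occupancies=(0.2, 0.5, 0.9),
                                 site_jitter_sd=0.3, seed=5)
    fix = fixtures.make_ensemble(spec)
    ens = EnsembleFrameSet.from_fixture(fix)
    return fix, ens


@pytest.fixture(scope="module")
def site_pipeline(ens_fixture):
    fix, ens = ens_fixture
    keep = retained_frames(ens, [fix.model.rna.coords])
    dens = occupancy_density(ens, "water", frame_mask=keep)
    sites = refine_site_binders(
        ens, detect_sites(dens, "water", fix.model))
    asg = assign_frames(ens, sites, fix.model)
    stats = site_statistics(asg, sites, keep)
    return fix, ens, keep, sites, stats


class TestMolarity:
    def test_bulk_water(self):
        assert molarity_to_number_density(55.0) == pytest.approx(0.033,
                                                                 abs=5e-4)

    def test_90_molar(self):
        assert molarity_to_number_density(90.0) == pytest.approx(0.054,
                                                                 abs=5e-4)

    def test_zero(self):
        assert molarity_to_number_density(0.0) == 0.0

    def test_round_trip(self):
        assert number_density_to_molarity(
            molarity_to_number_density(37.2)) == pytest.approx(37.2)


class TestDetection:
    def test_planted_sites_found_near_plants(self, site_pipeline):
        fix, ens, keep, sites, stats = site_pipeline
        plants = [p for p in fix.sites if p.species == "water"]
        assert len(sites) == len(plants)
        for s in sites:
            d = min(np.linalg.norm(s.peak - p.coord) for p in plants)
            assert d <= 0.5

    def test_peak_dedup_keeps_denser(self):
        g = np.zeros((20, 20, 20))
        m = DensityMap(g, 0.4, (0, 0, 0))
        # two Gaussian bumps 0.8 A apart with densities 5 and 7
        axes = [np.arange(20) * 0.4 for _ in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        for c, a in (((4.0, 4.0, 4.0), 5.0), ((4.8, 4.0, 4.0), 7.0)):
            r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
            g += a * np.exp(-0.5 * r2 / 0.3 ** 2)
        from cryoswim.model import Atom, AtomicModel
        rna = AtomicModel([Atom("O", "OP1", (4.4, 7.0, 4.0), "A", 1, "G")])
        sites = detect_sites(DensityMap(g, 0.4, (0, 0, 0)), "water", rna,
                             threshold=1.0)
        assert len(sites) == 1
        assert np.linalg.norm(sites[0].peak - [4.8, 4.0, 4.0]) < 0.3

    def test_separated_peaks_both_kept(self):
        g = np.zeros((24, 24, 24))
        axes = [np.arange(24) * 0.4 for _ in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        for c in ((4.0, 4.0, 4.0), (5.5, 4.0, 4.0)):
            r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
            g += 5.0 * np.exp(-0.5 * r2 / 0.25 ** 2)
        from cryoswim.model import Atom, AtomicModel
        rna = AtomicModel([Atom("O", "OP1", (4.7, 7.0, 4.0), "A", 1, "G")])
        sites = detect_sites(DensityMap(g, 0.4, (0, 0, 0)), "water", rna,
                             threshold=1.0)
        assert len(sites) == 2


class TestOccupancy:
    def test_recovery_within_tolerance(self, site_pipeline):
        fix, ens, keep, sites, stats = site_pipeline
        plants = [p for p in fix.sites if p.species == "water"]
        for _, row in stats.iterrows():
            s = sites[int(row["site"])]
            i = int(np.argmin([np.linalg.norm(s.peak - p.coord)
                               for p in plants]))
            assert row["occupancy"] == pytest.approx(plants[i].occupancy,
                                                     abs=0.05)

    def test_full_occupancy_zero_jitter(self):
        spec = fixtures.EnsembleSpec(n_frames=50, site_occupancies=(1.0,),
                                     site_jitter_sd=0.0, n_diffuse=0,
                                     seed=1)
        fix = fixtures.make_ensemble(spec)
        ens = EnsembleFrameSet.from_fixture(fix)
        keep = np.ones(len(ens), bool)
        dens = occupancy_density(ens, "water", frame_mask=keep)
        sites = refine_site_binders(
            ens, detect_sites(dens, "water", fix.model))
        asg = assign_frames(ens, sites, fix.model)
        stats = site_statistics(asg, sites, keep)
        assert stats["occupancy"].iloc[0] == pytest.approx(1.0)
        assert stats["rmsf"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_displaced_frames_excluded(self):
        spec = fixtures.EnsembleSpec(n_frames=200, site_occupancies=(1.0,),
                                     site_jitter_sd=0.0, n_diffuse=0,
                                     displaced_fraction=0.1, seed=4)
        fix = fixtures.make_ensemble(spec)
        ens = EnsembleFrameSet.from_fixture(fix)
        keep = retained_frames(ens, [fix.model.rna.coords])
        # exactly the constructed displacement labels are filtered out
        np.testing.assert_array_equal(keep, ~fix.displaced)


class TestResidence:
    def test_single_frame_gap_merges(self):
        # presence 1,1,0,1 -> one event of length 4
        events = _residence_events(np.array([0, 1, 3]), 4)
        assert events == [4]

    def test_two_frame_gap_splits(self):
        events = _residence_events(np.array([0, 1, 4, 5]), 6)
        assert events == [2, 2]

    def test_empty(self):
        assert _residence_events(np.array([]), 10) == []

    def test_mg_site_residence(self):
        spec = fixtures.EnsembleSpec(n_frames=100, site_occupancies=(),
                                     n_diffuse=0, mg_site=True,
                                     mg_occupancy=1.0, seed=2)
        fix = fixtures.make_ensemble(spec)
        ens = EnsembleFrameSet.from_fixture(fix)
        keep = np.ones(len(ens), bool)
        dens = occupancy_density(ens, "MG", frame_mask=keep)
        sites = refine_site_binders(
            ens, detect_sites(dens, "MG", fix.model))
        assert len(sites) == 1
        asg = assign_frames(ens, sites, fix.model)
        stats = site_statistics(asg, sites, keep)
        assert stats["max_residence_frames"].iloc[0] == 100
        assert stats["n_events"].iloc[0] == 1


class TestCompositeDensity:
    def _submap(self, value, origin=(0, 0, 0)):
        return DensityMap(np.full((11, 11, 11), float(value)), 1.0, origin)

    def test_equidistant_centers_average(self):
        subs = [((2.0, 5.0, 5.0), self._submap(1.0)),
                ((8.0, 5.0, 5.0), self._submap(3.0))]
        comp = accumulate_density(subs, voxel=1.0)
        v = comp.interpolate([5.0, 5.0, 5.0])
        assert v == pytest.approx(2.0)

    def test_single_coverage_passthrough(self):
        subs = [((2.0, 5.0, 5.0), self._submap(1.0)),
                ((30.0, 5.0, 5.0), self._submap(3.0, origin=(25, 0, 0)))]
        comp = accumulate_density(subs, voxel=1.0)
        idx = np.round(comp.to_index([4.0, 5.0, 5.0])).astype(int)
        assert comp.grid[tuple(idx)] == pytest.approx(1.0)

    def test_identical_submaps_identity(self):
        subs = [((4.0, 5.0, 5.0), self._submap(2.5)),
                ((6.0, 5.0, 5.0), self._submap(2.5))]
        comp = accumulate_density(subs, voxel=1.0)
        inside = ~np.isnan(comp.grid)
        assert np.allclose(comp.grid[inside], 2.5)

    def test_uncovered_voxels_missing(self):
        subs = [((2.0, 2.0, 2.0), self._submap(1.0))]
        comp = accumulate_density(subs, voxel=1.0, radius=3.0)
        assert np.isnan(comp.grid).any()


class TestFlexibility:
    def test_static_ensemble_zero(self):
        spec = fixtures.EnsembleSpec(n_frames=10, site_occupancies=(),
                                     n_diffuse=0, rna_jitter_sd=0.0, seed=0)
        fix = fixtures.make_ensemble(spec)
        ens = EnsembleFrameSet.from_fixture(fix)
        flex = rna_flexibility(ens, fix.model)
        assert np.allclose(flex["rmsf"], 0.0, atol=1e-9)
        assert np.allclose(flex["B"], 0.0, atol=1e-9)

    def test_b_factor_formula(self):
        assert (8 * np.pi ** 2 / 3) * 1.0 ** 2 == pytest.approx(26.32,
                                                                abs=0.01)

    def test_isotropic_jitter_recovery(self):
        """Gaussian jitter of sd s per axis gives RMSF = s*sqrt(3)."""
        s = 0.2
        spec = fixtures.EnsembleSpec(n_frames=1000, site_occupancies=(),
                                     n_diffuse=0, rna_jitter_sd=s, seed=9)
        fix = fixtures.make_ensemble(spec)
        ens = EnsembleFrameSet.from_fixture(fix)
        flex = rna_flexibility(ens, fix.model)
        assert flex["rmsf"].mean() == pytest.approx(s * np.sqrt(3),
                                                    rel=0.05)

    def test_single_frame_raises(self):
        spec = fixtures.EnsembleSpec(n_frames=1, site_occupancies=(),
                                     n_diffuse=0, seed=0)
        fix = fixtures.make_ensemble(spec)
        ens = EnsembleFrameSet.from_fixture(fix)
        with pytest.raises(ValueError):
            rna_flexibility(ens, fix.model)


class TestTableAdapter:
    def test_round_trip_through_table(self, ens_fixture):
        fix, ens = ens_fixture
        rows = []
        for f, fr in enumerate(ens.frames[:5]):
            for sp in ("rna", "water", "MG"):
                for x, y, z in fr[sp]:
                    rows.append({"frame": f, "species": sp,
                                 "x": x, "y": y, "z": z})
        df = pd.DataFrame(rows)
        ens2 = EnsembleFrameSet.from_table(df, ens.rna_atom_keys)
        assert len(ens2) == 5
        np.testing.assert_allclose(ens2.frames[0]["rna"],
                                   ens.frames[0]["rna"])
        np.testing.assert_allclose(ens2.frames[2]["water"],
                                   ens.frames[2]["water"])
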