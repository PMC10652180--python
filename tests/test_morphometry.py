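"""Shape and tissue metrics against analytic and quadrature oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import digitize_ellipsoid, match_ground_truth
from lacumorph.geometry import (
    ellipsoid_surface_area,
    ellipsoid_volume,
    sphericity_from_vs,
)
from lacumorph.morphometry import (
    bvtv,
    cortical_thickness,
    fit_ellipsoid,
    measure_lacunae,
    measure_surface_area,
    measure_volume,
    oblateness,
    sphericity,
    summarize_sample,
)


class TestQuadratureOracle:
    """The quadrature SA must agree with classical closed forms."""

    def test_sphere(self):
        assert ellipsoid_surface_area(6, 6, 6) == pytest.approx(4 * np.pi * 36, rel=1e-9)

    def test_prolate_spheroid(self):
        a, c = 8.0, 4.0
        e = np.sqrt(1 - (c / a) ** 2)
        closed = 2 * np.pi * c**2 * (1 + (a / (c * e)) * np.arcsin(e))
        assert ellipsoid_surface_area(a, c, c) == pytest.approx(closed, rel=1e-9)

    def test_oblate_spheroid(self):
        a, c = 8.0, 4.0
        e = np.sqrt(1 - (c / a) ** 2)
        closed = 2 * np.pi * a**2 + np.pi * (c**2 / e) * np.log((1 + e) / (1 - e))
        assert ellipsoid_surface_area(a, a, c) == pytest.approx(closed, rel=1e-9)


class TestVolume:
    def test_single_voxel(self):
        assert measure_volume(1, 1.2) == pytest.approx(1.728)

    def test_unit_voxels(self):
        assert measure_volume(1000, 1.0) == pytest.approx(1000.0)

    def test_digitized_sphere(self):
        grid = digitize_ellipsoid((6, 6, 6), 1.2)
        v = measure_volume(grid, 1.2)
        assert v == pytest.approx(4 / 3 * np.pi * 216, rel=0.10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            measure_volume(np.zeros((3, 3, 3), bool), 1.2)


class TestSurfaceArea:
    def test_digitized_sphere_within_8pct(self):
        grid = digitize_ellipsoid((6, 6, 6), 1.2)
        sa, method = measure_surface_area(grid, 1.2)
        assert method == "mesh"
        assert sa == pytest.approx(4 * np.pi * 36, rel=0.08)

    def test_digitized_ellipsoid_vs_quadrature(self):
        grid = digitize_ellipsoid((8, 4, 4), 1.2)
        sa, _ = measure_surface_area(grid, 1.2)
        assert sa == pytest.approx(ellipsoid_surface_area(8, 4, 4), rel=0.08)

    def test_convergence_with_resolution(self):
        """Sphere-SA error decreases monotonically over a refinement ladder."""
        truth = 4 * np.pi * 36
        errs = []
        for vs in (2.4, 1.2, 0.6):
            sa, _ = measure_surface_area(digitize_ellipsoid((6, 6, 6), vs), vs)
            errs.append(abs(sa - truth) / truth)
        assert errs[0] > errs[1] > errs[2]

    def test_speck_falls_back_to_faces(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[2, 2, 2] = True
        sa, method = measure_surface_area(grid, 1.2)
        assert method == "faces"
        assert sa == pytest.approx(6 * 1.44)


class TestSphericity:
    def test_sphere_identity_exact(self):
        # V and SA of the r=3 sphere: Sr must be exactly 1
        assert sphericity(4 / 3 * np.pi * 27, 36 * np.pi) == pytest.approx(1.0, abs=1e-12)

    def test_linear_in_inverse_sa(self):
        v = 4 / 3 * np.pi * 216
        sa = 4 * np.pi * 36
        assert sphericity(v, 2 * sa) == pytest.approx(0.5, abs=1e-12)

    def test_scale_invariance(self):
        for s in (0.5, 2.0, 7.3):
            a, b, c = 8.0, 5.0, 3.0
            sr1 = sphericity_from_vs(ellipsoid_volume(a, b, c),
                                     ellipsoid_surface_area(a, b, c))
            sr2 = sphericity_from_vs(ellipsoid_volume(s * a, s * b, s * c),
                                     ellipsoid_surface_area(s * a, s * b, s * c))
            assert sr1 == pytest.approx(sr2, rel=1e-9)

    def test_digitized_prolate_matches_oracle(self):
        grid = digitize_ellipsoid((8, 4, 4), 1.2)
        v = measure_volume(grid, 1.2)
        sa, _ = measure_surface_area(grid, 1.2)
        measured = sphericity(v, sa)
        oracle = sphericity_from_vs(ellipsoid_volume(8, 4, 4),
                                    ellipsoid_surface_area(8, 4, 4))
        assert measured == pytest.approx(oracle, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sphericity(-1.0, 10.0)


class TestOblateness:
    def test_prolate_oblate_sphere(self):
        assert oblateness(8, 4, 4) == -1.0
        assert oblateness(8, 8, 4) == +1.0
        assert oblateness(5, 5, 5) == 0.0

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            oblateness(4, 8, 4)

    @given(
        a=st.floats(1.0, 50.0),
        fb=st.floats(0.0, 1.0),
        fc=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_for_any_ordered_axes(self, a, fb, fc):
        c = a * (0.05 + 0.95 * fc)
        b = c + (a - c) * fb
        assert -1.0 <= oblateness(a, b, c) <= 1.0


class TestEllipsoidFit:
    def test_recovers_triaxial_axes(self):
        grid = digitize_ellipsoid((12, 6, 3.6), 1.2)
        (a, b, c), degenerate = fit_ellipsoid(grid, 1.2)
        assert not degenerate
        for got, want in zip((a, b, c), (12, 6, 3.6)):
            assert got == pytest.approx(want, rel=0.10)

    def test_sphere_nearly_isotropic(self):
        grid = digitize_ellipsoid((6, 6, 6), 1.2)
        (a, _, c), _ = fit_ellipsoid(grid, 1.2)
        assert a / c <= 1.05

    def test_single_voxel_degenerate(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[2, 2, 2] = True
        axes, degenerate = fit_ellipsoid(grid, 1.2)
        assert degenerate and axes is None

    def test_coplanar_degenerate(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[2, 1:4, 1:4] = True
        _, degenerate = fit_ellipsoid(grid, 1.2)
        assert degenerate


class TestTissueMetrics:
    def test_bvtv_half_filled(self):
        env = np.ones((10, 10, 10), bool)
        bone = env.copy()
        bone[5:] = False
        assert bvtv(bone, env) == pytest.approx(50.0)

    def test_bvtv_empty_bone(self):
        env = np.ones((6, 6, 6), bool)
        assert bvtv(np.zeros_like(env), env) == 0.0

    def test_bvtv_empty_envelope_rejected(self):
        with pytest.raises(ValueError):
            bvtv(np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool))

    def test_ct_th_slab_identity(self):
        """1.2 mm solid slab at 6 um voxels -> 1.20 mm within 2 voxel pitches."""
        g = np.zeros((220, 40, 40), bool)
        g[10:210] = True
        assert cortical_thickness(g, 6.0) == pytest.approx(1.2, abs=0.012)

    def test_ct_th_linearity(self):
        g = np.zeros((120, 40, 40), bool)
        g[10:110] = True
        assert cortical_thickness(g, 6.0) == pytest.approx(0.6, abs=0.012)

    def test_ct_th_insensitive_to_lacunar_voids(self):
        g = np.zeros((220, 40, 40), bool)
        g[10:210] = True
        solid = cortical_thickness(g, 6.0)
        rng = np.random.default_rng(0)
        holey = g.copy()
        for _ in range(80):
            z, y, x = rng.integers(30, 190), rng.integers(4, 36), rng.integers(4, 36)
            holey[z - 1 : z + 1, y - 1 : y + 1, x - 1 : x + 1] = False
        assert cortical_thickness(holey, 6.0) == pytest.approx(solid, rel=0.02)

    def test_ct_th_empty_rejected(self):
        with pytest.raises(ValueError):
            cortical_thickness(np.zeros((4, 4, 4), bool), 6.0)


class TestSummaries:
    def _recs(self, volumes, regions=None):
        import pandas as pd

        n = len(volumes)
        return pd.DataFrame(
            dict(volume_um3=volumes, sphericity=[0.7] * n, oblateness=[-0.3] * n,
                 region=regions or ["unassigned"] * n)
        )

    def test_mean_volume(self):
        s = summarize_sample(self._recs([100.0, 200.0]), "s", "cortical", 0.001, 90.0)
        assert s.lc_v_um3 == pytest.approx(150.0)

    def test_density(self):
        s = summarize_sample(self._recs([100.0] * 100), "s", "cortical", 0.01, 90.0)
        assert s.lc_n_bv_mm3 == pytest.approx(10_000.0)
        # recomputing from the stored pieces reproduces the value exactly
        assert s.lc_n_bv_mm3 == s.lc_n / 0.01

    def test_regional_counts_sum(self):
        s = summarize_sample(
            self._recs([1.0] * 10, ["peripheral"] * 4 + ["central"] * 6),
            "s", "trabecular", 0.001, 15.0,
        )
        assert s.lc_n_peripheral + s.lc_n_central == s.lc_n

    def test_empty_records(self):
        s = summarize_sample(self._recs([]), "s", "cortical", 0.001, 90.0)
        assert s.lc_n == 0 and np.isnan(s.lc_v_um3)


class TestPhantomRecovery:
    def test_density_target_recovered(self):
        """Phantom at 13,000 lacunae per mm^3 of bone: measured Lc.N/BV
        within 5% of the target."""
        from lacumorph.phantom import PhantomSpec, generate_phantom
        from lacumorph.segmentation import compute_threshold, extract_voids, label_and_classify

        spec = PhantomSpec(
            compartment="cortical", grid_shape=(110, 100, 100),
            slab_thickness_um=110.0, lacuna_density_mm3=13_000.0,
            volume_clip_um3=(100.0, 600.0), seed=5,
        )
        res = generate_phantom(spec)
        thr = compute_threshold(res.volume, res.envelope)
        lab = label_and_classify(extract_voids(res.volume, res.envelope, thr), 1.2)
        bone = (res.volume.voxels >= thr) & res.envelope
        bv_mm3 = bone.sum() * (1.2e-3) ** 3
        assert lab.n_lacunae / bv_mm3 == pytest.approx(13_000.0, rel=0.05)

    def test_median_shape_recovery(self, reference_phantom, reference_segmentation):
        """Median per-lacuna errors vs ground truth: Lc.V within 10%,
        Lc.Sr within 0.05, Lc.O within 0.15 (lacunae >= 100 um^3).

        The medians are the right summary here: the PSF blur erodes the
        thinnest lacunae, so individual errors have a heavy negative tail
        that is physics, not estimator failure.
        """
        labeled = reference_segmentation["labeled"]
        records = reference_segmentation["records"].set_index("label")
        dv, ds, do = [], [], []
        for row, lbl in match_ground_truth(reference_phantom, labeled):
            if lbl in records.index:
                rec = records.loc[lbl]
                dv.append(abs(rec.volume_um3 - row.volume_um3) / row.volume_um3)
                ds.append(abs(rec.sphericity - row.sphericity))
                do.append(abs(rec.oblateness - row.oblateness))
        assert len(dv) >= 95
        assert np.median(dv) <= 0.10
        assert np.median(ds) <= 0.05
        assert np.median(do) <= 0.15
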