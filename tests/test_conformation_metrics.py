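import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petprofiler.conformation_metrics import (
    DivergenceProfile, Region, RegionSet, divergence_profile, region_summary,
    rmsf, wrapped_delta,
)
from petprofiler.geometry import backbone_torsions
from petprofiler.seq_align import AlignmentMap
from petprofiler.synthetic_data import (
    GeneratorConfig, make_ensemble, make_ideal_structure, perturb_torsions,
)

from test_geometry import random_rigid


def torus_distance(a, b):
    """Wrapped Ramachandran distance between two (phi, psi) points."""
    return math.hypot(wrapped_delta(a[0], b[0]), wrapped_delta(a[1], b[1]))


class TestWrappedDelta:
    @pytest.mark.parametrize("a,b,expected", [
        (170.0, -170.0, -20.0),   # across the seam
        (30.0, 10.0, 20.0),
        (-170.0, 170.0, 20.0),
        (90.0, -90.0, 180.0),
    ])
    def test_reference_values(self, a, b, expected):
        assert wrapped_delta(a, b) == pytest.approx(expected)

    @given(st.floats(-180, 180))
    @settings(deadline=None)
    def test_identity(self, x):
        assert wrapped_delta(x, x) == 0.0

    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    @settings(deadline=None)
    def test_range_and_bound(self, a, b):
        d = wrapped_delta(a, b)
        assert -180.0 <= d <= 180.0
        assert abs(d) <= abs(a - b) + 1e-9 or abs(a - b) > 180.0


class TestTorusMetric:
    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-180, 180, size=(2000, 3, 2))
        for x, y, z in pts:
            dxy = torus_distance(x, y)
            assert dxy == pytest.approx(torus_distance(y, x), abs=1e-12)
            assert dxy <= torus_distance(x, z) + torus_distance(z, y) + 1e-9

    def test_wrapped_never_exceeds_unwrapped(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            a, b = rng.uniform(-180, 180, 2), rng.uniform(-180, 180, 2)
            unwrapped = math.hypot(a[0] - b[0], a[1] - b[1])
            assert torus_distance(a, b) <= unwrapped + 1e-9


class TestDivergenceProfile:
    def test_self_divergence_is_zero(self, helix30):
        prof = backbone_torsions(helix30, "A")
        d = divergence_profile(prof, prof, AlignmentMap.identity(30))
        assert all(e.distance == pytest.approx(0.0, abs=1e-9)
                   for e in d.defined_entries())

    def test_three_four_five(self, helix30):
        ta = backbone_torsions(helix30, "A")
        tb = backbone_torsions(helix30, "A")
        e = tb.entries[5]
        e.phi, e.psi = e.phi + 3.0, e.psi + 4.0
        d = divergence_profile(ta, tb, AlignmentMap.identity(30))
        assert d.entries[5].distance == pytest.approx(5.0, abs=1e-9)

    def test_seam_separates_modes(self, helix30):
        ta = backbone_torsions(helix30, "A")
        tb = backbone_torsions(helix30, "A")
        ta.entries[5].phi, tb.entries[5].phi = 179.0, -179.0
        tb.entries[5].psi = ta.entries[5].psi
        amap = AlignmentMap.identity(30)
        wrapped = divergence_profile(ta, tb, amap, mode="wrapped")
        unwrapped = divergence_profile(ta, tb, amap, mode="unwrapped")
        assert wrapped.entries[5].distance == pytest.approx(2.0, abs=1e-9)
        assert unwrapped.entries[5].distance == pytest.approx(358.0, abs=1e-9)

    def test_undefined_angles_flagged(self, helix30):
        ta = backbone_torsions(helix30, "A")
        d = divergence_profile(ta, ta, AlignmentMap.identity(30))
        assert not d.entries[0].defined      # phi undefined at chain start
        assert not d.entries[-1].defined     # psi undefined at chain end
        assert all(e.defined for e in d.entries[1:-1])

    def test_wrapped_distance_bound(self, helix30):
        ta = backbone_torsions(helix30, "A")
        tb = backbone_torsions(
            perturb_torsions(helix30, range(1, 31), 120.0, GeneratorConfig(seed=2)),
            "A")
        d = divergence_profile(ta, tb, AlignmentMap.identity(30))
        bound = 180.0 * math.sqrt(2.0)
        assert all(0.0 <= e.distance <= bound + 1e-9 for e in d.defined_entries())

    def test_localization_end_to_end(self, helix30):
        """Perturbing a synthetic loop must put exactly those residues on top —
        the synthetic mirror of localizing divergent active-site loops."""
        perturbed = perturb_torsions(helix30, range(10, 15), 20.0,
                                     GeneratorConfig(seed=3))
        d = divergence_profile(backbone_torsions(helix30, "A"),
                               backbone_torsions(perturbed, "A"),
                               AlignmentMap.identity(30))
        top = sorted(e.key[0] for e in d.top_k(5))
        assert top == [10, 11, 12, 13, 14]


class TestRegionSummary:
    def _profile_with_distances(self, dists):
        prof = DivergenceProfile()
        from petprofiler.conformation_metrics import DivergenceEntry
        for i, dist in enumerate(dists, start=1):
            prof.entries.append(DivergenceEntry(
                key=(i, ""), partner_key=(i, ""),
                dphi=dist, dpsi=0.0, distance=dist,
                defined=dist is not None))
        return prof

    def test_mean_max_count(self):
        prof = self._profile_with_distances([0.0, 5.0, 10.0])
        out = region_summary(prof, RegionSet([Region("loop", "A", 1, 3)]))
        assert out["loop"] == {"count": 3, "mean": 5.0, "max": 10.0}

    def test_empty_region_flagged_missing(self):
        prof = self._profile_with_distances([1.0, 2.0])
        out = region_summary(prof, RegionSet([Region("far", "A", 50, 60)]))
        assert out["far"]["count"] == 0
        assert math.isnan(out["far"]["mean"])

    def test_disjoint_union_additivity(self):
        prof = self._profile_with_distances([1.0, 2.0, 3.0, 4.0])
        regions = RegionSet([Region("a", "A", 1, 2), Region("b", "A", 3, 4),
                             Region("ab", "A", 1, 4)])
        out = region_summary(prof, regions)
        assert out["a"]["count"] + out["b"]["count"] == out["ab"]["count"]

    def test_perturbed_region_ranks_highest(self, helix30):
        perturbed = perturb_torsions(helix30, range(10, 15), 20.0,
                                     GeneratorConfig(seed=4))
        d = divergence_profile(backbone_torsions(helix30, "A"),
                               backbone_torsions(perturbed, "A"),
                               AlignmentMap.identity(30))
        regions = RegionSet([Region("core1", "A", 2, 9),
                             Region("loop", "A", 10, 14),
                             Region("core2", "A", 15, 29)])
        out = region_summary(d, regions)
        assert out["loop"]["mean"] > out["core1"]["mean"]
        assert out["loop"]["mean"] > out["core2"]["mean"]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            Region("bad", "A", 10, 5)


class TestRmsf:
    def test_identical_frames_need_two(self):
        ref = np.random.default_rng(0).normal(size=(5, 3))
        frames = np.stack([ref, ref, ref])
        prof = rmsf(frames, ref, presuperpose=False)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)
        assert prof.n_frames == 3

    def test_isotropic_noise_analytic_limit(self, helix30):
        sigma = 0.5
        frames = make_ensemble(helix30, sigma, 10000, GeneratorConfig(seed=5))
        prof = rmsf(frames, helix30.ca_coords("A"), presuperpose=False)
        expected = sigma * math.sqrt(3.0)
        np.testing.assert_allclose(prof.values, expected, rtol=0.02)

    def test_linearity_in_sigma(self, helix30):
        f1 = make_ensemble(helix30, 0.3, 4000, GeneratorConfig(seed=6))
        f2 = make_ensemble(helix30, 0.6, 4000, GeneratorConfig(seed=6))
        r1 = rmsf(f1, helix30.ca_coords("A"), presuperpose=False).values
        r2 = rmsf(f2, helix30.ca_coords("A"), presuperpose=False).values
        np.testing.assert_allclose(r2 / r1, 2.0, rtol=0.05)

    def test_common_rigid_transform_invariance(self, helix30):
        frames = make_ensemble(helix30, 0.4, 200, GeneratorConfig(seed=7))
        ref = helix30.ca_coords("A")
        base = rmsf(frames, ref, presuperpose=True).values
        R, t = random_rigid(np.random.default_rng(8))
        moved = frames @ R.T + t
        again = rmsf(moved, ref, presuperpose=True).values
        np.testing.assert_allclose(again, base, atol=1e-9)

    def test_input_validation(self):
        ref = np.zeros((5, 3))
        with pytest.raises(ValueError):
            rmsf(np.zeros((1, 5, 3)), ref)          # one frame
        with pytest.raises(ValueError):
            rmsf(np.zeros((3, 4, 3)), ref)          # selection mismatch
        with pytest.raises(ValueError):
            rmsf(np.zeros((3, 2, 3)), np.zeros((2, 3)))  # too short
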