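"""Rentian scaling: fits, partition semantics, mesh calibration, p_min."""

import numpy as np
import pytest

from planarnets.generators import make_fixture
from planarnets.rent import (
    PartitionSample,
    fit_rent_exponent,
    fit_topological_exponent,
    p_min,
    physical_partition_samples,
    topological_partition_samples,
)


class TestFit:
    def test_exact_power_law(self):
        samples = [PartitionSample(4, 2, 1), PartitionSample(16, 4, 2), PartitionSample(64, 8, 3)]
        with pytest.warns(UserWarning, match="few samples"):
            fit = fit_rent_exponent(samples)
        assert fit.exponent == pytest.approx(0.5)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_m_gives_zero_slope(self):
        samples = [PartitionSample(n, 7, 1) for n in (4, 8, 16, 32, 64, 128, 256, 512, 1024, 2048)]
        assert fit_rent_exponent(samples).exponent == pytest.approx(0.0)

    def test_noisy_power_law_recovery(self):
        """Exponent 0.6 with lognormal noise sigma=0.1 over 500 samples must be
        recovered within +-0.02."""
        rng = np.random.default_rng(0)
        n = 10 ** rng.uniform(0.5, 3.0, size=500)
        m = n**0.6 * np.exp(rng.normal(0, 0.1, size=500))
        samples = [PartitionSample(a, b, 1) for a, b in zip(n, m)]
        fit = fit_rent_exponent(samples)
        assert fit.exponent == pytest.approx(0.6, abs=0.02)

    def test_zero_samples_excluded(self):
        samples = [PartitionSample(0, 3, 1), PartitionSample(5, 0, 1)] + [
            PartitionSample(2**k, 2 ** (k // 2), 1) for k in range(2, 13)
        ]
        fit = fit_rent_exponent(samples)
        assert fit.n_samples == 11

    def test_identical_samples_error(self):
        with pytest.raises(ValueError, match="identical"):
            fit_rent_exponent([PartitionSample(4, 2, 1)] * 20)


class TestPMin:
    @pytest.mark.parametrize("t,expected", [(0.3, 0.5), (0.5, 0.5), (0.7, 0.7), (1.0, 1.0)])
    def test_formula_cases(self, t, expected):
        assert p_min(t) == expected


class TestTopologicalPartitions:
    def test_first_bisection_halves_share_m(self, mycelium_small):
        runs = topological_partition_samples(mycelium_small, runs=1, seed=0)
        level1 = [s for s in runs[0] if s.scale == 1]
        assert len(level1) == 2
        assert level1[0].m == level1[1].m
        assert level1[0].n + level1[1].n == mycelium_small.n_nodes

    def test_path16_optimal_cuts_are_single_edges(self):
        """Cutting a path costs one edge per cut; halves see m=1, interior
        quarters at most 2."""
        runs = topological_partition_samples(make_fixture("path", 16), runs=1, seed=1)
        by_level = {}
        for s in runs[0]:
            by_level.setdefault(s.scale, []).append(s)
        assert all(s.m == 1 for s in by_level[1])
        assert all(s.m in (1, 2) for s in by_level[2])

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            topological_partition_samples(make_fixture("path", 10), min_partition=8)


def _ideal_grid_bisection(L, min_part=8, boundary="crossing"):
    """Exact recursive bisection of an L x L mesh into rectangles (enumeration
    oracle): optimal cuts are straight lines across the shorter side."""
    out = []
    stack = [(0, 0, L, L)]
    while stack:
        x0, y0, w, h = stack.pop()
        if w * h < min_part:
            continue
        if w >= h:
            cut = h
            parts = [(x0, y0, w // 2, h), (x0 + w // 2, y0, w - w // 2, h)]
        else:
            cut = w
            parts = [(x0, y0, w, h // 2), (x0, y0 + h // 2, w, h - h // 2)]
        for a, b, ww, hh in parts:
            if boundary == "cut":
                m = cut
            else:
                m = (hh if a > 0 else 0) + (hh if a + ww < L else 0)
                m += (ww if b > 0 else 0) + (ww if b + hh < L else 0)
            out.append(PartitionSample(ww * hh, m, 1))
            stack.append((a, b, ww, hh))
    return out


@pytest.mark.parametrize("L", [16, 32])
@pytest.mark.parametrize("boundary", ["crossing", "cut"])
def test_mesh_partitioner_adequacy(L, boundary):
    """The spectral bisection estimator must reproduce, within +-0.05, the
    exponent of an exact optimal recursive bisection of the same mesh (the
    partitions of an L x L grid are rectangles with straight min cuts)."""
    ideal = fit_rent_exponent(_ideal_grid_bisection(L, boundary=boundary)).exponent
    t, _, _ = fit_topological_exponent(
        make_fixture("grid", L), runs=3, seed=0, boundary=boundary
    )
    assert t == pytest.approx(ideal, abs=0.05)


class TestPhysicalPartitions:
    @pytest.mark.parametrize("L", [16, 32])
    def test_mesh_exponent_half(self, L):
        """Square boxes on a 2D mesh: n ~ s^2 nodes, m ~ 4s boundary edges."""
        samples = physical_partition_samples(make_fixture("grid", L), n_boxes=3000, seed=0)
        fit = fit_rent_exponent(samples, flavor="physical")
        assert fit.exponent == pytest.approx(0.5, abs=0.05)
        assert fit.pearson_r > 0.9

    def test_boxes_confined_to_hull(self, mycelium_small):
        samples = physical_partition_samples(mycelium_small, n_boxes=500, seed=1)
        assert len(samples) == 500
        assert all(s.n <= mycelium_small.n_nodes for s in samples)
        # a box that covers the whole hull cannot satisfy corner containment
        assert max(s.n for s in samples) < mycelium_small.n_nodes

    def test_empty_boxes_dropped_from_fit(self, mycelium_small):
        samples = physical_partition_samples(mycelium_small, n_boxes=2000, seed=2)
        fit = fit_rent_exponent(samples, flavor="physical")
        assert fit.n_samples <= len(samples)
        assert fit.n_min >= 1

    def test_collinear_cloud_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            physical_partition_samples(make_fixture("path", 30))
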