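"""Gating vs a ray-casting oracle; MFI and relative-increase statistics."""

import numpy as np
import pandas as pd
import pytest

from srsquant.exceptions import ValidationError
from srsquant.flow import (GateSpec, apply_gates_batch, default_cell_gate,
                           default_singlet_gate, fluorescence_histogram, mfi,
                           polygon_gate, relative_mfi_increase, singlet_gate)
from srsquant.phantom import FlowPhantomSpec, generate_flow_events


def ray_casting_inside(px, py, vertices):
    """Independent even-odd point-in-polygon (boundary handled as inside
    by nudging: points exactly on an edge are resolved separately)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
            return True
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def table(xs, ys):
    return pd.DataFrame({"FSC-A": xs, "SSC-A": ys,
                         "SSC-H": ys, "FL-green": np.ones(len(xs))})


UNIT_SQUARE = GateSpec("FSC-A", "SSC-A",
                       ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)))


class TestPolygonGate:
    def test_interior_point_retained_exterior_removed(self):
        t = table([0.5, 2.0], [0.5, 2.0])
        out = polygon_gate(t, UNIT_SQUARE)
        assert list(out.index) == [0]

    def test_boundary_events_retained(self):
        t = table([0.0, 1.0, 0.5], [0.5, 0.5, 1.0])
        out = polygon_gate(t, UNIT_SQUARE)
        assert len(out) == 3

    def test_matches_ray_casting_oracle_on_random_events(self):
        rng = np.random.default_rng(0)
        vertices = ((0.1, 0.0), (0.9, 0.2), (1.0, 0.9), (0.4, 1.1), (0.0, 0.5))
        gate = GateSpec("FSC-A", "SSC-A", vertices)
        xs = rng.uniform(-0.2, 1.2, 10_000)
        ys = rng.uniform(-0.2, 1.2, 10_000)
        out = polygon_gate(table(xs, ys), gate)
        oracle = {i for i in range(10_000)
                  if ray_casting_inside(xs[i], ys[i], vertices)}
        assert set(out.index) == oracle

    def test_order_preserved(self):
        rng = np.random.default_rng(1)
        t = table(rng.random(100), rng.random(100))
        out = polygon_gate(t, UNIT_SQUARE)
        assert list(out.index) == sorted(out.index)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValidationError):
            polygon_gate(table([0.5], [0.5]),
                         GateSpec("nope", "SSC-A", UNIT_SQUARE.vertices))

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValidationError):
            GateSpec("FSC-A", "SSC-A", ((0, 0), (1, 1), (2, 2)))
        with pytest.raises(ValidationError):
            GateSpec("FSC-A", "SSC-A", ((0, 0), (1, 1)))

    def test_gate_composability_order_independent(self):
        rng = np.random.default_rng(2)
        t = table(rng.random(500), rng.random(500))
        a = GateSpec("FSC-A", "SSC-A", ((0.0, 0.0), (0.7, 0.0), (0.7, 1.0), (0.0, 1.0)))
        b = GateSpec("FSC-A", "SSC-A", ((0.3, 0.0), (1.0, 0.0), (1.0, 1.0), (0.3, 1.0)))
        ab = polygon_gate(polygon_gate(t, a), b)
        ba = polygon_gate(polygon_gate(t, b), a)
        pd.testing.assert_frame_equal(ab, ba)


class TestSingletGate:
    def test_phantom_doublet_discrimination(self):
        events, _ = generate_flow_events(FlowPhantomSpec(n_events=20_000, seed=3))
        gated = singlet_gate(events, default_singlet_gate())
        singlets = events["population"] == "singlet"
        doublets = events["population"] == "doublet"
        kept = events.index.isin(gated.index)
        assert (kept & singlets).sum() / singlets.sum() >= 0.95
        assert (kept & doublets).sum() / max(doublets.sum(), 1) <= 0.05

    def test_requires_ssc_channels(self):
        with pytest.raises(ValidationError):
            singlet_gate(table([0.5], [0.5]), UNIT_SQUARE)

    def test_empty_table_passes_through(self):
        events, _ = generate_flow_events(FlowPhantomSpec(n_events=0))
        assert len(singlet_gate(events, default_singlet_gate())) == 0

    def test_full_plane_gate_is_identity(self):
        events, _ = generate_flow_events(FlowPhantomSpec(n_events=1000, seed=4))
        huge = GateSpec("SSC-A", "SSC-H",
                        ((-1e9, -1e9), (1e9, -1e9), (1e9, 1e9), (-1e9, 1e9)))
        assert len(singlet_gate(events, huge)) == 1000


class TestMfi:
    def test_arithmetic_mean(self):
        t = pd.DataFrame({"FL-green": [100.0, 200.0]})
        assert mfi(t) == 150.0
        assert mfi(pd.DataFrame({"FL-green": [42.0]})) == 42.0

    def test_lognormal_phantom_matches_analytic_mean(self):
        events, truth = generate_flow_events(FlowPhantomSpec(
            n_events=100_000, fraction_debris=0.0, fraction_doublets=0.0,
            singlet_mfi=250.0, seed=5))
        assert mfi(events) == pytest.approx(250.0, rel=0.01)

    def test_geometric_option(self):
        t = pd.DataFrame({"FL-green": [10.0, 1000.0]})
        assert mfi(t, method="geometric") == pytest.approx(100.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValidationError):
            mfi(pd.DataFrame({"FL-green": []}))


class TestRelativeMfiIncrease:
    @pytest.mark.parametrize("m30,m0,expect", [
        (153.0, 100.0, 53.0), (100.0, 100.0, 0.0), (50.0, 100.0, 50.0),
    ])
    def test_substitution_cases(self, m30, m0, expect):
        assert relative_mfi_increase(m30, m0) == pytest.approx(expect)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValidationError):
            relative_mfi_increase(100.0, 0.0)

    def test_end_to_end_recovery_of_programmed_shift(self):
        """0 Gy vs 30 Gy tables at MFI ratio 1.53 → relative increase ≈ 53%
        after the full gate chain."""
        gates = [default_cell_gate(), default_singlet_gate()]
        e0, _ = generate_flow_events(FlowPhantomSpec(n_events=50_000, seed=6))
        e1, _ = generate_flow_events(FlowPhantomSpec(
            n_events=50_000, seed=7, mfi_shift_factor=1.53, condition="30 Gy"))
        g0, g1 = apply_gates_batch([e0, e1], gates)
        rel = relative_mfi_increase(mfi(g1), mfi(g0))
        assert rel == pytest.approx(53.0, abs=2.0)


class TestFluorescenceHistogram:
    def test_single_bin_is_100(self):
        t = pd.DataFrame({"FL-green": np.full(50, 7.0)})
        edges, pct = fluorescence_histogram(t, log_axis=False, n_bins=10)
        assert pct.max() == 100.0
        assert (pct > 0).sum() == 1

    def test_uniform_counts_all_100(self):
        t = pd.DataFrame({"FL-green": np.arange(10) + 0.5})
        edges, pct = fluorescence_histogram(t, log_axis=False, n_bins=10)
        np.testing.assert_allclose(pct, 100.0)

    def test_log_axis_mode_near_lognormal_median(self):
        """On a log axis the histogram mode of a lognormal sits within one
        bin of exp(μ)."""
        rng = np.random.default_rng(8)
        mu, sigma = 4.0, 0.5
        t = pd.DataFrame({"FL-green": rng.lognormal(mu, sigma, 200_000)})
        edges, pct = fluorescence_histogram(t, log_axis=True, n_bins=60)
        k = int(np.argmax(pct))
        lo, hi = edges[max(k - 1, 0)], edges[min(k + 2, len(edges) - 1)]
        assert lo <= np.exp(mu) <= hi

    def test_nonpositive_values_rejected_on_log_axis(self):
        t = pd.DataFrame({"FL-green": [1.0, 0.0, -2.0]})
        with pytest.raises(ValidationError, match="2 events"):
            fluorescence_histogram(t, log_axis=True)
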