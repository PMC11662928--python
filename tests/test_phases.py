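"""Phase segmentation, exponential fitting, slope estimator, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npkinetics.lattice import ForceClampTrace, LatticeConfig, reference_params, simulate_trace
from npkinetics.phases import (
    fit_biexponential,
    fit_exponential,
    initial_slope_rate,
    segment_phases,
    summarize_condition,
)

from conftest import make_protocol


def _trace(t, x, conc=None, force=30.0):
    conc = np.zeros_like(t) if conc is None else conc
    return ForceClampTrace(t, x, force, conc)


class TestSegmentation:
    def test_single_exponential_is_one_phase(self):
        t = np.arange(0, 100, 0.1)
        x = 1000 + 2000 * np.exp(-0.2 * t)
        segs = segment_phases(_trace(t, x))
        assert len(segs) == 1
        assert segs[0].direction == "shortening"
        assert segs[0].i_start == 0
        assert segs[0].i_end == len(t) - 1

    def test_decay_then_rise_breakpoint_near_true_minimum(self):
        """Analytic two-phase construct: equal amplitudes, rates 0.4 and
        0.1 1/s; the minimum sits at ln(4)/0.3 s and the detected
        breakpoint must fall within two smoothing windows of it."""
        t = np.arange(0, 120, 0.1)
        x = 3000 + 500 * np.exp(-0.4 * t) + 500 * (1 - np.exp(-0.1 * t))
        t_min = np.log(0.4 / 0.1) / (0.4 - 0.1)
        segs = segment_phases(_trace(t, x), smoothing_window=2.0,
                              min_amplitude=5.0)
        assert len(segs) == 2
        assert segs[0].direction == "shortening"
        assert segs[1].direction == "elongation"
        assert abs(segs[0].t_end - t_min) <= 4.0

    def test_flat_noisy_trace_has_no_phases(self, rng):
        t = np.arange(0, 60, 0.1)
        x = 4000 + rng.normal(0, 1.0, len(t))
        segs = segment_phases(_trace(t, x), min_amplitude=30.0)
        assert segs == []

    def test_washout_instant_is_always_a_breakpoint(self, params):
        tr = simulate_trace(LatticeConfig(), params,
                            make_protocol(conc=30.0, seed=3))
        segs = segment_phases(tr, min_amplitude=30.0)
        assert any(abs(s.t_start - 100.0) < 1e-9 for s in segs)
        assert not any(s.t_start < 100.0 < s.t_end for s in segs)

    def test_short_record_rejected(self):
        t = np.arange(0, 1.0, 0.1)
        with pytest.raises(ValueError):
            segment_phases(_trace(t, np.ones_like(t)))
        t = np.arange(0, 1.5, 0.05)
        with pytest.raises(ValueError, match="smoothing window"):
            segment_phases(_trace(t, np.ones_like(t)), smoothing_window=5.0)


class TestExponentialFit:
    @pytest.mark.parametrize("rate", [0.002, 0.02, 0.25, 2.0])
    def test_exact_recovery_across_three_decades(self, rate):
        """Noiseless exponential input is recovered to <= 1e-9 relative
        error in all three parameters."""
        span = 8.0 / rate
        t = np.linspace(0, span, 400)
        x = 1000.0 + 500.0 * np.exp(-rate * t)
        fit = fit_exponential(t, x)
        assert fit.rate == pytest.approx(rate, rel=1e-9)
        assert fit.plateau == pytest.approx(1000.0, rel=1e-9)
        assert fit.amplitude * 8100 == pytest.approx(500.0, rel=1e-9)

    def test_reference_example(self):
        t = np.arange(0, 60, 0.1)
        x = 1000 + 500 * np.exp(-0.25 * t)
        fit = fit_exponential(t, x, n_nt=8100)
        assert fit.rate == pytest.approx(0.25, rel=1e-9)
        assert fit.amplitude == pytest.approx(500 / 8100, rel=1e-9)

    def test_noisy_rate_within_5_percent_over_repeats(self):
        """100 s record at 10 Hz with 2 nm noise: the mean fitted rate
        over 100 seeded repeats stays within 5% of truth."""
        t = np.arange(0, 100, 0.1)
        rates = []
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = 1000 + 500 * np.exp(-0.25 * t) + rng.normal(0, 2.0, len(t))
            rates.append(fit_exponential(t, x).rate)
        assert np.mean(rates) == pytest.approx(0.25, rel=0.05)

    def test_constant_segment_raises(self):
        t = np.arange(0, 20, 0.1)
        with pytest.raises(ValueError, match="no decay"):
            fit_exponential(t, np.full_like(t, 1234.0))

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError):
            fit_exponential(np.arange(5.0), np.arange(5.0) * 1.0)


class TestBiexponentialFit:
    def test_exact_recovery(self):
        t = np.arange(0, 600, 0.1)
        x = 4000 + 1500 * np.exp(-0.11 * t) - 2400 * np.exp(-0.007 * t)
        k1, k2, (u0, u1, u2), rms = fit_biexponential(t, x)
        assert k1 == pytest.approx(0.11, rel=1e-5)
        assert k2 == pytest.approx(0.007, rel=1e-5)
        assert u0 == pytest.approx(4000, rel=1e-6)
        assert rms < 1e-6


class TestInitialSlope:
    def test_pure_exponential_returns_its_rate(self):
        t = np.arange(0, 60, 0.1)
        x = 2000 + 800 * np.exp(-0.11 * t)
        k = initial_slope_rate(t, x, total_amplitude=800.0, rate_hint=0.11)
        assert k == pytest.approx(0.11, rel=0.02)

    def test_equal_mixture_reference_value(self):
        """Equal-amplitude 0.11/0.010 mixture has initial-slope rate
        (0.11 + 0.010)/2 = 0.060."""
        t = np.arange(0, 300, 0.1)
        x = 1000 + 400 * np.exp(-0.11 * t) + 400 * np.exp(-0.010 * t)
        k = initial_slope_rate(t, x, total_amplitude=800.0, rate_hint=0.11)
        assert k == pytest.approx(0.060, rel=0.02)

    def test_flat_segment_raises(self):
        t = np.arange(0, 20, 0.1)
        with pytest.raises(ValueError):
            initial_slope_rate(t, np.full_like(t, 5.0), total_amplitude=100.0)
        with pytest.raises(ValueError):
            initial_slope_rate(t, np.exp(-t), total_amplitude=0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        k1=st.floats(0.02, 0.3),
        k2=st.floats(0.002, 0.02),
        a1=st.floats(100.0, 1000.0),
        a2=st.floats(100.0, 1000.0),
    )
    def test_amplitude_weighted_mean_for_mixtures(self, k1, k2, a1, a2):
        """For any finite exponential mixture the estimator returns the
        amplitude-weighted mean rate."""
        t = np.arange(0, 400, 0.1)
        x = 500 + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)
        k = initial_slope_rate(t, x, total_amplitude=a1 + a2, rate_hint=k1)
        expected = (a1 * k1 + a2 * k2) / (a1 + a2)
        assert k == pytest.approx(expected, rel=0.05)


class TestSummarize:
    @pytest.fixture(scope="class")
    def traces_30nM(self, params=None):
        params = reference_params()
        cfg = LatticeConfig()
        proto = make_protocol(conc=30.0, washout=400.0, seed=0)
        traces = [simulate_trace(cfg, params,
                                 make_protocol(conc=30.0, washout=400.0,
                                               seed=100 + i))
                  for i in range(6)]
        return traces, proto

    def test_30nM_has_four_phases_with_rate_ordering(self, traces_30nM):
        traces, proto = traces_30nM
        s = summarize_condition(traces, proto)
        assert None not in (s.k_plus_i, s.k_plus_f, s.k_minus_i, s.k_minus_f)
        assert s.k_plus_i > s.k_plus_f
        assert s.k_minus_i > s.k_minus_f
        assert s.replicates >= 4
        assert s.sem  # SEMs reported with >= 3 replicates

    def test_initial_compaction_exceeds_equilibrium_compaction(self,
                                                               traces_30nM):
        """The de-compaction phase only ever lengthens the strand."""
        traces, proto = traces_30nM
        s = summarize_condition(traces, proto)
        assert s.dx_plus_i >= s.dx_plus_f

    def test_1nM_is_effectively_single_phase(self):
        params = reference_params()
        cfg = LatticeConfig()
        proto = make_protocol(conc=1.0, seed=0)
        traces = [simulate_trace(cfg, params,
                                 make_protocol(conc=1.0, seed=300 + i))
                  for i in range(6)]
        s = summarize_condition(traces, proto)
        assert s.dx_plus_i is not None
        # equilibrium stays close to the initial compaction: the second
        # binding phase is weak at 1 nM
        assert s.equilibrium_reduction >= 0.75 * s.dx_plus_i

    def test_empty_trace_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_condition([], make_protocol())
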