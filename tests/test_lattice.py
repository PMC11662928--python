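"""Stochastic lattice simulator: propensities, calibration, ODE oracle."""

import numpy as np
import pytest

from npkinetics.lattice import (
    MODE_151P,
    MODE_MONOMER,
    LatticeConfig,
    LatticeState,
    Protocol,
    Segment,
    calibrate_reference,
    k_df,
    k_olig,
    k_rec,
    meanfield_trace,
    propensities,
    r_dec,
    r_on,
    reference_params,
    simulate_trace,
)
from npkinetics.polymer import fjc_extension_per_nt

from conftest import make_protocol


class TestPropensities:
    def test_zero_concentration_kills_binding_and_decompaction(self, params):
        st = LatticeState.empty(LatticeConfig())
        st.states[:10] = 1  # some compact sites
        pr = propensities(st, 0.0, 30.0, params)
        assert np.all(pr["bind"] == 0)
        assert np.all(pr["decompact"] == 0)

    def test_single_site_on_rate_at_1nM(self, params):
        # saturating form: 0.042*0.45/(0.042 + 0.45) at c = 1 nM
        assert r_on(1.0, params) == pytest.approx(0.042 * 0.45 / 0.492,
                                                  rel=1e-12)

    def test_decompact_site_recompacts_at_kdi0_at_washout(self, params):
        st = LatticeState.empty(LatticeConfig())
        st.states[0] = 2
        pr = propensities(st, 0.0, 30.0, params)
        assert pr["recompact"][0] == pytest.approx(0.11, rel=1e-12)

    def test_oligomer_flag_divides_dissociation_type_rates(self, params, kBT):
        st = LatticeState.empty(LatticeConfig())
        st.states[:2] = [1, 2]
        st.flags[:2] = True
        pr = propensities(st, 0.0, 30.0, params)
        lam = params.lambda_oligo
        assert pr["unbind"][0] == pytest.approx(k_df(30.0, params, kBT) / lam)
        assert pr["recompact"][1] == pytest.approx(params.k_di0 / lam)

    def test_ratio_invariance_under_flag(self, params, kBT):
        """(D->C)/(C->E) equals k_di0/k_df0 whether or not oligomerized."""
        for flagged in (False, True):
            st = LatticeState.empty(LatticeConfig())
            st.states[:2] = [2, 1]
            st.flags[:2] = flagged
            pr = propensities(st, 0.0, 30.0, params)
            ratio = pr["recompact"][0] / pr["unbind"][1]
            assert ratio == pytest.approx(params.k_di0 / params.k_df0,
                                          rel=1e-9)

    def test_oligomerization_needs_occupied_neighbour(self, params):
        st = LatticeState.empty(LatticeConfig())
        st.states[0] = 1       # isolated site: no occupied neighbour
        st.states[50] = 1
        st.states[51] = 2      # adjacent pair
        pr = propensities(st, 30.0, 30.0, params)
        assert pr["oligomerize"][0] == 0
        assert pr["oligomerize"][50] > 0
        assert pr["oligomerize"][51] > 0

    def test_151p_mode_never_oligomerizes(self, params):
        st = LatticeState.empty(LatticeConfig(mode=MODE_151P))
        st.states[:] = 1
        pr = propensities(st, 30.0, 30.0, params,
                          LatticeConfig(mode=MODE_151P))
        assert np.all(pr["oligomerize"] == 0)

    def test_monomer_mode_channels(self, params):
        cfg = LatticeConfig(mode=MODE_MONOMER)
        st = LatticeState.empty(cfg)
        st.states[0] = 3
        pr = propensities(st, 30.0, 30.0, params, cfg)
        assert set(pr) == {"bind", "unbind"}
        assert pr["unbind"][0] == params.k_off_mono
        assert pr["bind"][1] > 0

    def test_negative_concentration_rejected(self, params):
        st = LatticeState.empty(LatticeConfig())
        with pytest.raises(ValueError):
            propensities(st, -1.0, 30.0, params)

    def test_low_force_suppresses_decompaction(self, params):
        cfg = LatticeConfig()
        assert r_dec(30.0, params, force=5.0, config=cfg) == 0.0
        assert r_dec(30.0, params, force=10.0, config=cfg) > 0.0


class TestCalibration:
    def test_kbd_solves_midpoint_balance(self):
        p = calibrate_reference()
        # r_dec(3 nM) must balance k_rec(3 nM) = 0.11*3/6 = 0.055
        assert p.k_bd == pytest.approx(0.0289, abs=2e-4)
        assert r_dec(3.0, p) == pytest.approx(k_rec(3.0, p), rel=1e-9)

    def test_kdf0_reproduces_on_off_ratio(self):
        p = calibrate_reference()
        assert p.k_df0 == pytest.approx(0.0070, abs=1e-4)
        k_on_eff = r_on(0.3, p) / 0.3
        assert p.k_df0 / k_on_eff == pytest.approx(0.17, rel=1e-9)

    def test_oligomerization_rate_at_reference_force(self, kBT):
        p = calibrate_reference()
        assert k_olig(30.0, p, kBT) == pytest.approx(0.01, rel=1e-12)

    def test_infeasible_calibration_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_reference({"k_dec_max": 0.01})  # below k_rec(midpoint)


class TestSimulate:
    def test_protein_free_trace_is_flat_at_bare(self, params, small_config):
        proto = Protocol(force=30.0, schedule=(Segment(50.0, 0.0),),
                         seed=3, noise_sd=2.0)
        tr = simulate_trace(small_config, params, proto)
        bare = small_config.n_nt * fjc_extension_per_nt(30.0)
        assert np.abs(tr.extension - bare).max() < 10.0  # noise only
        assert tr.extension.std() < 4.0

    def test_bit_identical_reproducibility(self, params, small_config):
        proto = make_protocol(seed=11, incubation=30.0, washout=30.0)
        a = simulate_trace(small_config, params, proto)
        b = simulate_trace(small_config, params, proto)
        np.testing.assert_array_equal(a.extension, b.extension)
        assert a.provenance == b.provenance

    def test_different_seeds_differ(self, params, small_config):
        a = simulate_trace(small_config, params, make_protocol(seed=1))
        b = simulate_trace(small_config, params, make_protocol(seed=2))
        assert not np.array_equal(a.extension, b.extension)

    def test_four_phase_shape_at_30nM(self, params):
        """Binding at 30 nM then washout: compaction, partial elongation,
        re-compaction, slow final elongation."""
        cfg = LatticeConfig()
        proto = make_protocol(conc=30.0, seed=5)
        tr = simulate_trace(cfg, params, proto)
        t = tr.time
        bare = tr.extension[0]

        def mean_at(t0, t1):
            return tr.extension[(t >= t0) & (t < t1)].mean()

        compacted = mean_at(8, 12)       # after initial compaction
        equilibrated = mean_at(90, 100)  # de-compacted equilibrium
        recompacted = mean_at(130, 140)  # after washout re-compaction
        assert compacted < bare - 500
        assert equilibrated > compacted + 300   # partial elongation
        assert recompacted < equilibrated - 300  # washout re-compaction

    def test_state_bookkeeping_consistent(self, params, small_config):
        st = LatticeState.empty(small_config)
        simulate_trace(small_config, params, make_protocol(seed=7), state=st)
        trimers = st.trimers_per_site
        assert set(np.unique(trimers)) <= {0, 1, 2}
        np.testing.assert_array_equal(trimers == 1, st.states == 1)
        np.testing.assert_array_equal(trimers == 2, st.states == 2)
        # oligomer flags only on occupied sites
        assert not np.any(st.flags & (st.states == 0))

    def test_washout_monotone_and_returns_to_bare_151p(self, params):
        """Oligomerization-deficient washout empties the lattice and the
        extension converges to the protein-free value."""
        cfg = LatticeConfig(n_nt=1000, mode=MODE_151P)
        st = LatticeState.empty(cfg)
        proto1 = Protocol(force=30.0, schedule=(Segment(100.0, 30.0),),
                          seed=9, noise_sd=0.0)
        simulate_trace(cfg, params, proto1, state=st)
        occ0 = int(np.sum(st.states != 0))
        assert occ0 > 15
        occupancies = [occ0]
        for leg in range(4):
            proto = Protocol(force=30.0, schedule=(Segment(250.0, 0.0),),
                             seed=20 + leg, noise_sd=0.0)
            tr = simulate_trace(cfg, params, proto, state=st)
            occupancies.append(int(np.sum(st.states != 0)))
        assert all(a >= b for a, b in zip(occupancies, occupancies[1:]))
        assert occupancies[-1] <= 2
        bare = cfg.n_nt * fjc_extension_per_nt(30.0)
        assert abs(tr.extension[-1] - bare) < 25.0


class TestMeanField:
    def test_fractions_sum_to_one(self, params, small_config):
        mf = meanfield_trace(small_config, params, make_protocol(seed=0))
        total = sum(mf.fractions.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_protein_free_steady_state_is_empty(self, params, small_config):
        # the flag-protected compact state drains slowly (k_df0/lambda),
        # so reaching the empty absorbing state takes several 1000 s
        proto = Protocol(force=30.0, schedule=(Segment(20000.0, 0.0),),
                         sample_interval=20.0, noise_sd=0.0)
        mf = meanfield_trace(small_config, params, proto,
                             y0=[0.0, 0.5, 0.0, 0.5, 0.0])
        assert mf.fractions["empty"][-1] > 0.999

    def test_equal_occupancy_at_isotherm_midpoint(self, params):
        """Without oligomerization the long-time C/D balance at 3 nM is
        50/50, the calibration condition."""
        cfg = LatticeConfig(n_nt=1000, mode=MODE_151P)
        proto = Protocol(force=30.0, schedule=(Segment(4000.0, 3.0),),
                         sample_interval=10.0, noise_sd=0.0)
        mf = meanfield_trace(cfg, params, proto)
        c = mf.fractions["compact"][-1] + mf.fractions["compact_oligo"][-1]
        d = mf.fractions["decompact"][-1] + mf.fractions["decompact_oligo"][-1]
        assert d / (c + d) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("mode", ["WT", MODE_151P, MODE_MONOMER])
    def test_gillespie_matches_ode_oracle(self, params, mode):
        """Ensemble mean of 200 stochastic runs agrees with the mean-field
        ODE within 3x the ensemble SEM, pointwise, on a 20-site lattice."""
        cfg = LatticeConfig(n_nt=1000, mode=mode)
        proto = Protocol(force=30.0,
                         schedule=(Segment(60.0, 10.0), Segment(60.0, 0.0)),
                         seed=0, noise_sd=0.0)
        exts = []
        for i in range(200):
            p_i = Protocol(force=30.0,
                           schedule=(Segment(60.0, 10.0), Segment(60.0, 0.0)),
                           seed=i, noise_sd=0.0)
            exts.append(simulate_trace(cfg, params, p_i).extension)
        exts = np.asarray(exts)
        mean = exts.mean(axis=0)
        sem = exts.std(axis=0, ddof=1) / np.sqrt(len(exts))
        mf = meanfield_trace(cfg, params, proto)
        diff = np.abs(mean - mf.extension)
        assert np.all(diff <= 3 * np.maximum(sem, 0.05))


class TestValidation:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            LatticeConfig(n_nt=8105)  # not divisible by 50
        with pytest.raises(ValueError):
            LatticeConfig(mode="dimer")
        assert LatticeConfig().n_sites == 162
        assert LatticeConfig(mode=MODE_MONOMER).n_sites == 476

    def test_rate_params_invariants(self, params):
        with pytest.raises(ValueError):
            type(params)(k_b=-0.1)
        with pytest.raises(ValueError):
            type(params)(lambda_oligo=0.5)
        with pytest.raises(ValueError):
            type(params)(K_r=0.0)

    def test_protocol_invariants(self):
        with pytest.raises(ValueError):
            Protocol(force=0.0, schedule=(Segment(1.0, 1.0),))
        with pytest.raises(ValueError):
            Segment(-1.0, 1.0)
        with pytest.raises(ValueError):
            Segment(10.0, -1.0)
        proto = make_protocol(incubation=10.0, washout=20.0)
        np.testing.assert_allclose(proto.boundaries, [0.0, 10.0, 30.0])
        np.testing.assert_allclose(proto.concentration_at([5.0, 15.0]),
                                   [30.0, 0.0])
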