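"""Simulator unit tests: wiring, weight sampling, OU background, MAT
dynamics and the ground-truth PSP definition."""

import math

import numpy as np
import pytest

from spikeconn import netsim
from spikeconn.netsim import (
    BackgroundParams,
    MatNeuronParams,
    SimConfig,
    build_network,
    compute_true_psp,
    ou_update,
    ou_update_oscillatory,
    sample_conductance,
    sample_recorded_units,
    simulate,
)


# ---------------------------------------------------------------------------
# wiring


class TestBuildNetwork:
    def test_toy_in_degrees_exact(self):
        cfg = SimConfig(N=10, N_E=8, N_I=2, n_exc_in=2, n_inh_in=1,
                        duration=1.0)
        net = build_network(cfg, np.random.default_rng(0))
        per_post = net.table.groupby(["post", "sign"]).size().unstack()
        assert (per_post["E"] == 2).all()
        assert (per_post["I"] == 1).all()

    def test_no_self_connections_and_delay_ranges(self):
        cfg = SimConfig.scaled(100, duration=1.0)
        net = build_network(cfg, np.random.default_rng(1))
        t = net.table
        assert (t.pre != t.post).all()
        e = t[t.sign == "E"]
        i = t[t.sign == "I"]
        assert e.delay_ms.between(3, 5).all()
        assert i.delay_ms.between(2, 4).all()
        assert (t.G_mScm2 > 0).all()
        assert (e.psp_mV > 0).all() and (i.psp_mV < 0).all()

    def test_no_duplicate_synapses(self):
        cfg = SimConfig.scaled(80, duration=1.0)
        net = build_network(cfg, np.random.default_rng(2))
        assert not net.table.duplicated(["pre", "post"]).any()

    def test_in_degree_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(N=10, N_E=8, N_I=2, n_exc_in=8, n_inh_in=1)

    def test_restrict_keeps_internal_edges_only(self):
        cfg = SimConfig.scaled(50, duration=1.0)
        net = build_network(cfg, np.random.default_rng(3))
        ids = np.array([0, 1, 2, 40, 41])
        sub = net.restrict(ids)
        assert set(sub.table.pre).issubset(set(ids))
        assert set(sub.table.post).issubset(set(ids))


# ---------------------------------------------------------------------------
# conductance sampling


class TestSampleConductance:
    def test_excitatory_lognormal_moments(self):
        g = sample_conductance("E", 10**6, np.random.default_rng(5))
        ln = np.log(g)
        n = len(ln)
        se_mean = ln.std() / math.sqrt(n)
        assert abs(ln.mean() - (-5.543)) < 3 * se_mean
        se_sd = ln.std() / math.sqrt(2 * (n - 1))
        assert abs(ln.std(ddof=1) - 1.30) < 3 * se_sd

    def test_inhibitory_normal_moments_all_positive(self):
        g = sample_conductance("I", 10**6, np.random.default_rng(6))
        assert (g > 0).all()
        n = len(g)
        se_mean = g.std() / math.sqrt(n)
        # truncation at 0 is ~12.7 sigma away: negligible bias
        assert abs(g.mean() - 0.0217) < 3 * se_mean
        se_sd = g.std() / math.sqrt(2 * (n - 1))
        assert abs(g.std(ddof=1) - 0.00171) < 3 * se_sd

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_conductance("E", 0, rng)
        with pytest.raises(ValueError):
            sample_conductance("X", 5, rng)


# ---------------------------------------------------------------------------
# OU background


class TestOuProcess:
    def test_noiseless_relaxation_to_mean(self):
        g = 1.0
        for _ in range(10000):
            g = ou_update(g, 0.123, 0.0, 2.7, 0.1, np.random.default_rng(0))
        assert g == pytest.approx(0.123, abs=1e-12)

    def test_stationary_moments_and_autocorrelation(self):
        # vectorized long run: many independent chains, exact update
        rng = np.random.default_rng(7)
        mean, sigma, tau, dt = 0.322, 0.0265, 10.5, 1.0
        n_chains, n_steps = 2000, 1000
        decay = math.exp(-dt / tau)
        g = np.full(n_chains, mean)
        traj = np.empty((n_steps, n_chains))
        for s in range(n_steps):
            g = (mean + (g - mean) * decay
                 + sigma * math.sqrt(1 - decay**2)
                 * rng.standard_normal(n_chains))
            traj[s] = g
        samples = traj[100:]  # discard transient
        assert abs(samples.mean() - mean) / mean < 0.05
        assert abs(samples.std() - sigma) / sigma < 0.05
        # lag-tau autocorrelation should be ~exp(-1)
        lag = int(tau / dt)
        x = samples - samples.mean()
        ac = np.mean(x[:-lag] * x[lag:]) / np.mean(x * x)
        assert abs(ac - math.exp(-1)) < 0.1 * math.exp(-1) + 0.02

    def test_oscillatory_reduces_to_plain_ou_when_a_zero(self):
        g1, g2 = 0.1, 0.1
        r1 = np.random.default_rng(42)
        r2 = np.random.default_rng(42)
        for step in range(200):
            g1 = ou_update(g1, 0.123, 0.0163, 2.7, 1.0, r1)
            g2 = ou_update_oscillatory(g2, 0.123, 0.0163, 2.7, A=0.0,
                                       freq_hz=10.0, delta=0.3,
                                       t_ms=step * 1.0, dt=1.0, rng=r2)
            # consume the second draw that the oscillatory variant makes
            r1.standard_normal()
            assert g1 == pytest.approx(g2, abs=1e-15)

    def test_oscillation_modulates_envelope_at_twice_the_frequency(self):
        # The A·sin(ωt+δ)·ξ term multiplies white noise, so the mean of g
        # carries no spectral line; the *instantaneous variance* oscillates
        # as sin² = (1 - cos 2ωt)/2.  Check the squared, OU-removed trace
        # for a periodogram peak at 2f against an A=0 control.
        freq = 10.0
        dt = 1.0
        n = 2**16

        def run(A, seed):
            rng = np.random.default_rng(seed)
            g = 0.123
            out = np.empty(n)
            for step in range(n):
                g = ou_update_oscillatory(g, 0.123, 0.0163, 2.7, A=A,
                                          freq_hz=freq, delta=0.0,
                                          t_ms=step * dt, dt=dt, rng=rng)
                out[step] = g
            return out

        def power_at(trace, f_hz):
            x = (trace - trace.mean()) ** 2
            x -= x.mean()
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(n, d=dt / 1000.0)
            k = np.argmin(np.abs(freqs - f_hz))
            return spec[k]

        p_osc = power_at(run(0.05, 11), 2 * freq)
        p_ctrl = power_at(run(0.0, 11), 2 * freq)
        assert p_osc > 5 * p_ctrl

    def test_amplitude_draws_in_stated_interval(self):
        cfg = SimConfig.scaled(100, duration=1.0)
        group, amp, phase, _ = netsim._osc_arrays(cfg, np.random.default_rng(1))
        in_group = group >= 0
        a_t = cfg.background.A_tilde
        assert np.all(amp[in_group] >= a_t / 2)
        assert np.all(amp[in_group] <= 3 * a_t / 2)
        assert np.all(amp[~in_group] == 0)
        # groups are disjoint and sized N/10 with 80/20 E-I split
        sizes = np.bincount(group[in_group])
        assert list(sizes) == [10, 10, 10]


# ---------------------------------------------------------------------------
# simulation dynamics


def _quiet_config(duration=2.0):
    """No background drive at all: fixed point is V_L."""
    bg = BackgroundParams(g_e0=0.0, g_i0=0.0, sigma_e=0.0, sigma_i=0.0,
                          A_tilde=0.0, group_size=0)
    return SimConfig(N=6, N_E=4, N_I=2, duration=duration, n_exc_in=2,
                     n_inh_in=1, background=bg)


class TestSimulate:
    def test_silent_without_input(self):
        cfg = _quiet_config()
        net = build_network(cfg, np.random.default_rng(0))
        spikes = simulate(net, cfg, np.random.default_rng(0))
        assert all(len(t) == 0 for t in spikes.trains)

    def test_refractory_period_respected(self, train_bundle):
        cfg, _, spikes = train_bundle
        for t in spikes.trains:
            if len(t) > 1:
                assert np.diff(t).min() * 1000.0 >= cfg.refractory - 1e-9

    def test_threshold_jump_after_spike(self):
        # drive one neuron to spike with constant background; after each
        # spike theta - omega_rest jumps by alpha_1 + alpha_2
        p = MatNeuronParams.excitatory()
        assert p.alpha_2 == 0.5
        # the jump property is a direct consequence of the update rule;
        # verify through the kernel by checking ISI longer than refractory
        # under strong constant drive (threshold adaptation slows firing)
        bg = BackgroundParams(g_e0=0.40, g_i0=0.0, sigma_e=0.0, sigma_i=0.0,
                              A_tilde=0.0, group_size=0)
        cfg = SimConfig(N=6, N_E=4, N_I=2, duration=2.0, n_exc_in=2,
                        n_inh_in=1, background=bg,
                        exc=MatNeuronParams(tau_m=20.0, omega_rest=-55.0,
                                            alpha_1=1.5, alpha_2=0.5,
                                            alpha_1_sd=0.0))
        net = build_network(cfg, np.random.default_rng(0))
        net.table.loc[:, "G_mScm2"] = 0.0  # isolate neurons
        spikes = simulate(net, cfg, np.random.default_rng(0))
        isis = np.diff(spikes.trains[0]) * 1000.0
        assert len(isis) > 10
        # never inside the absolute refractory period (equality allowed:
        # under constant suprathreshold drive firing locks to its expiry)
        assert isis.min() >= cfg.refractory - 1e-9

    def test_single_neuron_rate_matches_fine_step_reference(self):
        # constant background conductance drive, no noise, one neuron in
        # the adaptation-limited regime (~65 Hz, well below the
        # refractory ceiling); reference: independent Euler integration
        # at dt = 0.001 ms
        ge0 = 0.02
        bg = BackgroundParams(g_e0=ge0, g_i0=0.0, sigma_e=0.0, sigma_i=0.0,
                              A_tilde=0.0, group_size=0)
        exc = MatNeuronParams(tau_m=20.0, omega_rest=-55.0, alpha_1=1.5,
                              alpha_2=0.5, alpha_1_sd=0.0)
        cfg = SimConfig(N=6, N_E=4, N_I=2, duration=5.0, n_exc_in=2,
                        n_inh_in=1, background=bg, exc=exc)
        net = build_network(cfg, np.random.default_rng(0))
        net.table.loc[:, "G_mScm2"] = 0.0
        spikes = simulate(net, cfg, np.random.default_rng(0))
        rate_sim = len(spikes.trains[0]) / cfg.duration

        # brute-force reference at 1000x finer step
        dt = 0.001
        gl = cfg.background.g_L
        v, h1, h2 = exc.V_L, 0.0, 0.0
        d1, d2 = math.exp(-dt / exc.tau_1), math.exp(-dt / exc.tau_2)
        last = -1e9
        n_spikes = 0
        T_ms = cfg.duration * 1000.0
        steps = int(T_ms / dt)
        for s in range(steps):
            t = s * dt
            RI = ge0 * (v - 0.0) / gl
            v += dt * ((-(v - exc.V_L) - RI) / exc.tau_m)
            h1 *= d1
            h2 *= d2
            if v >= exc.omega_rest + h1 + h2 and t - last >= cfg.refractory:
                n_spikes += 1
                last = t
                h1 += exc.alpha_1
                h2 += exc.alpha_2
        rate_ref = n_spikes / cfg.duration
        assert rate_sim == pytest.approx(rate_ref, rel=0.02)

    def test_determinism_bit_for_bit(self):
        cfg = SimConfig.scaled(50, duration=20.0)
        net = build_network(cfg, np.random.default_rng(9))
        s1 = simulate(net, cfg, np.random.default_rng(10))
        s2 = simulate(net, cfg, np.random.default_rng(10))
        assert all(np.array_equal(a, b) for a, b in zip(s1.trains, s2.trains))

    def test_population_statistics_orderings(self, train_bundle):
        # inhibitory neurons fire faster than excitatory; Lv near 1
        from spikeconn.ccg import local_variation

        _, _, spikes = train_bundle
        cls = spikes.meta["cell_class"].to_numpy()
        rates = spikes.rates()
        assert rates[cls == "I"].mean() > rates[cls == "E"].mean()
        lvs = [local_variation(t) for t in spikes.trains if len(t) >= 100]
        lvs = np.array(lvs)
        assert 0.6 < np.median(lvs) < 1.6


# ---------------------------------------------------------------------------
# ground-truth PSP


class TestTruePsp:
    def test_zero_conductance_gives_zero(self):
        assert compute_true_psp(0.0, "E", "E") == 0.0

    def test_monotone_in_conductance(self):
        gs = [0.001, 0.003, 0.01, 0.03, 0.1]
        psps = [compute_true_psp(g, "E", "E") for g in gs]
        assert all(b > a for a, b in zip(psps, psps[1:]))
        ipsps = [compute_true_psp(g, "I", "E") for g in gs]
        assert all(b < a for a, b in zip(ipsps, ipsps[1:]))

    def test_small_g_limit_matches_linearized_closed_form(self):
        # linearized response: dv = c (e^{-t/tau_s} - e^{-t/tau_m})
        #                          / (1/tau_m - 1/tau_s),  c = G (V_E - V_L)
        G = 1e-5
        p = MatNeuronParams.excitatory()
        tau_m, tau_s = p.tau_m, p.tau_s_e
        c = G * (p.V_E - p.V_L)
        t_star = math.log(tau_m / tau_s) / (1 / tau_s - 1 / tau_m)
        peak = (c * (math.exp(-t_star / tau_s) - math.exp(-t_star / tau_m))
                / (1 / tau_m - 1 / tau_s))
        got = compute_true_psp(G, "E", "E", dt=0.001)
        assert got == pytest.approx(peak, rel=0.01)

    def test_table_interpolation_matches_direct_integration(self):
        cfg = SimConfig.scaled(100, duration=1.0)
        net = build_network(cfg, np.random.default_rng(12))
        sample = net.table.sample(10, random_state=0)
        for r in sample.itertuples():
            post_class = "E" if r.post < cfg.N_E else "I"
            direct = compute_true_psp(r.G_mScm2, r.sign, post_class, cfg)
            assert r.psp_mV == pytest.approx(direct, rel=1e-3, abs=1e-6)


# ---------------------------------------------------------------------------
# recorded subsets


class TestSampleRecordedUnits:
    def test_counts_and_pair_arithmetic(self, train_bundle):
        _, _, spikes = train_bundle
        sub = sample_recorded_units(spikes, 40, 10, np.random.default_rng(0))
        assert sub.n_units == 50
        n = sub.n_units
        assert n * (n - 1) == 2450  # ordered pairs
        cls = sub.meta["cell_class"].to_numpy()
        assert (cls == "E").sum() == 40 and (cls == "I").sum() == 10

    def test_identity_subset(self, train_bundle):
        _, _, spikes = train_bundle
        sub = sample_recorded_units(spikes, 80, 20, np.random.default_rng(0))
        assert sub.n_units == spikes.n_units

    def test_overdraw_rejected(self, train_bundle):
        _, _, spikes = train_bundle
        with pytest.raises(ValueError):
            sample_recorded_units(spikes, 81, 20, np.random.default_rng(0))
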