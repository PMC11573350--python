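"""Phase extraction, PTE (vs brute-force oracle), PLV, net outflow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ieegflow import connectivity as cn
from ieegflow.connectivity import PTEConfig

from conftest import pte_bruteforce


class TestInstantaneousPhase:
    def test_cosine_amplitude_and_phase_slope(self):
        fs = 500.0
        t = np.arange(int(2 * fs)) / fs
        a = cn.instantaneous_phase(np.cos(2 * np.pi * 10 * t))
        core = slice(100, -100)
        np.testing.assert_allclose(a.amplitude[core], 1.0, atol=0.01)
        slope = np.diff(np.unwrap(a.phase[core])).mean() * fs
        assert slope == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_amplitude_linearity(self):
        fs = 500.0
        t = np.arange(int(2 * fs)) / fs
        a = cn.instantaneous_phase(3 * np.cos(2 * np.pi * 10 * t))
        assert np.median(a.amplitude) == pytest.approx(3.0, abs=0.03)

    def test_chirp_instantaneous_frequency(self):
        fs = 500.0
        dur = 4.0
        t = np.arange(int(dur * fs)) / fs
        f0, f1 = 5.0, 15.0
        k = (f1 - f0) / dur
        x = np.cos(2 * np.pi * (f0 * t + k * t**2 / 2))
        a = cn.instantaneous_phase(x)
        inst_f = np.diff(np.unwrap(a.phase)) * fs / (2 * np.pi)
        expected = f0 + k * t[:-1]
        core = slice(200, -200)
        assert np.abs(inst_f[core] - expected[core]).max() < 0.5

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cn.instantaneous_phase(np.ones(100))

    def test_phase_range(self):
        x = np.random.default_rng(0).standard_normal(1000)
        a = cn.instantaneous_phase(x)
        assert (a.phase >= -np.pi).all() and (a.phase < np.pi).all()
        assert (a.amplitude >= 0).all()


class TestDefaultDelay:
    def test_ten_hz_twin_series(self):
        # 10 Hz at 500 Hz, 1000 samples: the phase changes sign twice per
        # cycle (zero crossing + wrap), so M_pm ~ 80 over both series and
        # tau = round(2*1000/80) = 25.
        fs = 500.0
        t = np.arange(1000) / fs
        phi = cn.instantaneous_phase(np.cos(2 * np.pi * 10 * t)).phase
        # brute-force sign-change count as the oracle
        flips = sum(
            1 for i in range(len(phi) - 1) if (phi[i] < 0) != (phi[i + 1] < 0)
        )
        assert 2 * flips == pytest.approx(80, abs=4)
        assert cn.default_delay(phi, phi) == 25

    def test_iid_uniform_phases(self):
        rng = np.random.default_rng(0)
        m = 10_000
        pa = rng.uniform(-np.pi, np.pi, m)
        pb = rng.uniform(-np.pi, np.pi, m)
        assert cn.default_delay(pa, pb) in (1, 2, 3)

    def test_constant_positive_phase_falls_back_with_warning(self):
        phi = np.full(100, 0.5)
        with pytest.warns(UserWarning, match="tau = 1"):
            assert cn.default_delay(phi, phi) == 1


class TestDefaultBins:
    def test_uniform_phases_scott(self):
        rng = np.random.default_rng(1)
        m = 1000
        pa = rng.uniform(-np.pi, np.pi, m)
        pb = rng.uniform(-np.pi, np.pi, m)
        # STD ~ pi/sqrt(3); h = 3.49*STD*M^(-1/3) ~ 0.633 rad -> 10 bins
        assert cn.default_bins(pa, pb) == 10

    def test_as_printed_mode_degenerates_to_clamp(self):
        rng = np.random.default_rng(2)
        pa = rng.uniform(-np.pi, np.pi, 1000)
        pb = rng.uniform(-np.pi, np.pi, 1000)
        assert cn.default_bins(pa, pb, mode="as_printed") == 2

    def test_bin_count_scaling_with_m(self):
        rng = np.random.default_rng(3)
        pa = rng.uniform(-np.pi, np.pi, 4000)
        pb = rng.uniform(-np.pi, np.pi, 4000)
        n_small = cn.default_bins(pa[:1000], pb[:1000])
        n_large = cn.default_bins(pa, pb)
        assert n_large == pytest.approx(n_small * 4 ** (1 / 3), abs=1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cn.default_bins(np.zeros(100), np.zeros(100))


class TestPTE:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = int(rng.integers(50, 500))
            nb = int(rng.integers(2, 9))
            tau = int(rng.integers(1, 10))
            pa = rng.uniform(-np.pi, np.pi, m)
            pb = rng.uniform(-np.pi, np.pi, m)
            fast = cn.pte(pa, pb, PTEConfig(tau, nb))
            slow = pte_bruteforce(pa, pb, tau, nb)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pa = rng.uniform(-np.pi, np.pi, 200)
            pb = rng.uniform(-np.pi, np.pi, 200)
            assert cn.pte(pa, pb, PTEConfig(3, 5)) >= -1e-12

    def test_independent_phases_symmetric(self):
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(100):
            pa = rng.uniform(-np.pi, np.pi, 5000)
            pb = rng.uniform(-np.pi, np.pi, 5000)
            cfg = PTEConfig(2, 8)
            diffs.append(cn.pte(pa, pb, cfg) - cn.pte(pb, pa, cfg))
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * se + 1e-6

    def test_noiseless_delayed_copy_detected(self):
        rng = np.random.default_rng(3)
        tau = 5
        hits = 0
        for _ in range(100):
            # smooth driver phases: wrapped random walk
            pa = np.angle(np.exp(1j * np.cumsum(rng.normal(0, 0.3, 2000))))
            pb = np.roll(pa, tau)
            pb[:tau] = pa[0]
            cfg = PTEConfig(tau, 8)
            hits += cn.pte(pa, pb, cfg) > cn.pte(pb, pa, cfg)
        assert hits >= 95

    def test_shuffled_inputs_sign_symmetric(self):
        rng = np.random.default_rng(4)
        signs = []
        for _ in range(500):
            pa = rng.permutation(rng.uniform(-np.pi, np.pi, 300))
            pb = rng.permutation(rng.uniform(-np.pi, np.pi, 300))
            cfg = PTEConfig(2, 4)
            signs.append(np.sign(cn.pte(pa, pb, cfg) - cn.pte(pb, pa, cfg)))
        signs = np.asarray(signs)
        n_pos = int((signs > 0).sum())
        n_nonzero = int((signs != 0).sum())
        from scipy.stats import binomtest

        assert binomtest(n_pos, n_nonzero).pvalue > 0.01

    def test_tau_too_large_rejected(self):
        with pytest.raises(ValueError):
            cn.pte(np.zeros(10), np.zeros(10), PTEConfig(10, 4))


class TestPLV:
    def test_identical_phases(self):
        phi = np.random.default_rng(0).uniform(-np.pi, np.pi, 1000)
        assert cn.plv(phi, phi) == pytest.approx(1.0)

    def test_constant_offset(self):
        phi = np.random.default_rng(1).uniform(-np.pi, np.pi, 1000)
        assert cn.plv(phi, phi + 1.3) == pytest.approx(1.0)

    def test_common_rotation_invariance(self):
        rng = np.random.default_rng(2)
        pa = rng.uniform(-np.pi, np.pi, 500)
        pb = rng.uniform(-np.pi, np.pi, 500)
        assert cn.plv(pa + 0.7, pb + 0.7) == pytest.approx(cn.plv(pa, pb), abs=1e-12)

    def test_independent_phases_rayleigh_mean(self):
        rng = np.random.default_rng(3)
        m = 10_000
        vals = [
            cn.plv(rng.uniform(-np.pi, np.pi, m), rng.uniform(-np.pi, np.pi, m))
            for _ in range(200)
        ]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(m))
        assert np.mean(vals) == pytest.approx(expected, rel=0.2)

    def test_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = cn.plv(rng.uniform(-np.pi, np.pi, 100), rng.uniform(-np.pi, np.pi, 100))
            assert 0 <= v <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cn.plv(np.array([]), np.array([]))


def _pte_result_from_matrix(nodes, matrix):
    """Build a PTEResult table from a directed adjacency matrix."""
    rows = []
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i == j:
                continue
            rows.append(
                {
                    "source_channel": a,
                    "target_channel": b,
                    "source_region": a,
                    "target_region": b,
                    "n_trials": 1,
                    "pte_mean": matrix[i, j],
                    "tau_median": 1.0,
                    "bins_median": 4.0,
                }
            )
    return cn.PTEResult(table=pd.DataFrame(rows), per_trial=np.zeros((len(rows), 1)))


class TestNetOutflow:
    def test_two_node_definition(self):
        res = _pte_result_from_matrix(["A", "B"], np.array([[0, 0.6], [0.4, 0]]))
        flow = cn.net_outflow(res)
        assert flow.net("A") == pytest.approx(0.2)
        assert flow.net("B") == pytest.approx(-0.2)

    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30)
    def test_sum_mode_conserves(self, n_nodes, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"N{i}" for i in range(n_nodes)]
        res = _pte_result_from_matrix(nodes, rng.uniform(0, 1, (n_nodes, n_nodes)))
        flow = cn.net_outflow(res, mode="sum")
        assert abs(flow.table["net"].sum()) < 1e-12

    def test_mean_mode_degree_invariant(self):
        # a hub with many weak neighbours should not be inflated by degree
        nodes = ["H", "a", "b", "c"]
        m = np.zeros((4, 4))
        m[0, 1:] = 0.5  # H -> others
        m[1:, 0] = 0.3  # others -> H
        res = _pte_result_from_matrix(nodes, m)
        flow = cn.net_outflow(res, mode="mean")
        assert flow.net("H") == pytest.approx(0.2)

    def test_hub_recovery_in_simulation(self, hub_session):
        import warnings

        from ieegflow import pipeline

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pipeline.session_connectivity(hub_session, ("encoding",))["encoding"]
        flow = cn.net_outflow(res)
        assert flow.ranking()[0] == "AI"


class TestPTEEpochs:
    def test_empty_pairs(self, hub_session):
        from ieegflow import preprocess
        from ieegflow.session import BANDS

        filtered = preprocess.bandpass(hub_session, BANDS["broadband"])
        epochs = preprocess.epoch(filtered, "encoding")
        res = cn.pte_epochs(epochs, [])
        assert len(res.table) == 0

    def test_both_directions_present(self, hub_session):
        import warnings

        from ieegflow import preprocess
        from ieegflow.session import BANDS

        filtered = preprocess.bandpass(hub_session, BANDS["broadband"])
        epochs = preprocess.epoch(filtered, "encoding")
        names = filtered.channels["name"]
        pair = (names.iloc[0], names.iloc[2])
        res = cn.pte_epochs(epochs, [pair])
        assert len(res.table) == 2
        assert set(zip(res.table["source_channel"], res.table["target_channel"])) == {
            pair,
            pair[::-1],
        }
        assert (res.table["pte_mean"] >= 0).all()

    def test_duplicated_trials_same_means(self, hub_session):
        from ieegflow import preprocess
        from ieegflow.session import BANDS

        filtered = preprocess.bandpass(hub_session, BANDS["broadband"])
        epochs = preprocess.epoch(filtered, "encoding")
        names = filtered.channels["name"]
        pair = (names.iloc[0], names.iloc[2])
        res1 = cn.pte_epochs(epochs, [pair])
        doubled = epochs.with_data(np.concatenate([epochs.data, epochs.data]))
        res2 = cn.pte_epochs(doubled, [pair])
        np.testing.assert_allclose(
            res1.table["pte_mean"].to_numpy(), res2.table["pte_mean"].to_numpy(), atol=1e-12
        )
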