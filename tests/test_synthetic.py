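import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from dfcmanifold import (
    PairIndex,
    SyntheticSpec,
    ValidationError,
    gen_core_periphery_graph,
    gen_dfc_direct,
    gen_roi_timeseries_tv,
    gen_two_class_coreness,
    make_window_plan,
    sliding_window_dfc,
)


class TestDfcDirect:
    def test_deterministic(self):
        spec = SyntheticSpec(seed=7, M=6, n=435, D=120, snr=3.0)
        S1, m1, _ = gen_dfc_direct(spec)
        S2, m2, _ = gen_dfc_direct(spec)
        assert np.array_equal(S1, S2) and np.array_equal(m1, m2)

    def test_noiseless_limit_trivially_clusterable(self):
        spec = SyntheticSpec(seed=1, M=4, n=200, D=80, snr=1e9)
        S, membership, _ = gen_dfc_direct(spec)
        labels = KMeans(n_clusters=4, n_init=10, random_state=0).fit_predict(S)
        assert adjusted_rand_score(membership, labels) == 1.0

    def test_module_means_match_prototypes(self):
        spec = SyntheticSpec(seed=3, M=4, n=400, D=100, snr=10.0)
        S, membership, G = gen_dfc_direct(spec)
        for m in range(4):
            mean_row = S[membership == m].mean(axis=0)
            r = np.corrcoef(mean_row, G[m])[0, 1]
            assert r > 0.99

    def test_rows_are_valid_z_trajectories(self):
        S, _, _ = gen_dfc_direct(SyntheticSpec(seed=2, M=3, n=60, D=50, snr=2.0))
        r = np.tanh(S)
        assert np.all(np.abs(r) < 1)

    def test_bad_snr(self):
        with pytest.raises(ValidationError):
            gen_dfc_direct(SyntheticSpec(seed=0, snr=0.0))


class TestRoiTimeseriesTv:
    def test_constant_sigma_fisher_z_variance(self):
        # no modulation: windowed z fluctuates with var ~ 1/(L-3)
        ts, blocks, _ = gen_roi_timeseries_tv(
            R=8, T=1200, tr_seconds=1.0, seed=4, modulated_pairs=[])
        plan = make_window_plan(1200, 1.0, 40.0, 10)
        S = sliding_window_dfc(ts, plan).S
        pidx = PairIndex(8)
        between = [pidx.to_index(i, j) for i, j in pidx.pairs()
                   if blocks[i] != blocks[j]]
        z = S[between]
        assert abs(z.mean()) < 0.02                      # null coupling
        assert np.isclose(z.std(), 1 / np.sqrt(plan.L - 3), rtol=0.15)

    def test_modulation_spectral_peak(self):
        period = 100.0
        ts, blocks, sched = gen_roi_timeseries_tv(
            R=12, T=400, tr_seconds=1.0, seed=5, period_seconds=period)
        plan = make_window_plan(400, 1.0, 40.0, 2)
        S = sliding_window_dfc(ts, plan).S
        pidx = PairIndex(12)
        p = pidx.to_index(0, 1)  # blocks 0 and 1 (round-robin assignment)
        assert blocks[0] != blocks[1]
        row = S[p] - S[p].mean()
        freqs = np.fft.rfftfreq(row.size, d=plan.step_trs * ts.tr_seconds)
        power = np.abs(np.fft.rfft(row)) ** 2
        peak = freqs[1:][np.argmax(power[1:])]
        df = freqs[1] - freqs[0]
        assert abs(peak - 1 / period) <= df  # peak at the modulation frequency

    def test_bad_correlation(self):
        with pytest.raises(ValidationError):
            gen_roi_timeseries_tv(R=6, T=50, tr_seconds=1.0, seed=0,
                                  within_rho=1.2)


class TestCorePeripheryGraph:
    def test_ideal_graph(self):
        A, is_core = gen_core_periphery_graph(30, 0.2, 1.0, 1.0, 0.0, seed=0)
        assert np.array_equal(A, A.T) and not A.diagonal().any()
        periph = ~is_core
        assert A[np.ix_(periph, periph)].sum() == 0       # no p-p edges
        assert np.all(A[np.ix_(is_core, is_core)] + np.eye(is_core.sum()) == 1)

    def test_block_densities_match_probabilities(self):
        A, is_core = gen_core_periphery_graph(100, 0.2, 0.9, 0.5, 0.05, seed=1)
        nc = int(is_core.sum())
        for sel_a, sel_b, p in [(is_core, is_core, 0.9),
                                (is_core, ~is_core, 0.5),
                                (~is_core, ~is_core, 0.05)]:
            block = A[np.ix_(sel_a, sel_b)]
            if sel_a is sel_b:
                n_possible = sel_a.sum() * (sel_a.sum() - 1) / 2
                n_edges = block.sum() / 2
            else:
                n_possible = sel_a.sum() * sel_b.sum()
                n_edges = block.sum()
            # 4-sigma binomial envelope
            sd = np.sqrt(n_possible * p * (1 - p))
            assert abs(n_edges - n_possible * p) < 4 * sd + 1

    def test_structureless_control(self):
        # equal probabilities: Erdos-Renyi, degree cannot find the "core"
        aucs = []
        for seed in range(20):
            A, is_core = gen_core_periphery_graph(100, 0.2, 0.3, 0.3, 0.3, seed=seed)
            aucs.append(roc_auc_score(is_core, A.sum(axis=1)))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_bad_probability(self):
        with pytest.raises(ValidationError):
            gen_core_periphery_graph(20, 0.2, 1.5, 0.5, 0.1, seed=0)


class TestTwoClassCoreness:
    def test_determinism(self):
        X1, y1, m1 = gen_two_class_coreness(100, 10, 1.0, seed=9)
        X2, y2, m2 = gen_two_class_coreness(100, 10, 1.0, seed=9)
        assert np.array_equal(X1, X2)

    def test_effect_confined_to_subset(self):
        X, y, mask = gen_two_class_coreness(300, 200, 2.0, seed=3)
        gap = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        assert np.all(gap[mask] > 1.5)
        assert np.all(np.abs(gap[~mask]) < 0.5)

    def test_parameter_errors(self):
        with pytest.raises(ValidationError):
            gen_two_class_coreness(10, 1, 1.0, seed=0)
        with pytest.raises(ValidationError):
            gen_two_class_coreness(10, 5, -1.0, seed=0)
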