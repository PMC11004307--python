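import numpy as np
import pytest

import irplab as il
from irplab.montage import REGIONS
from irplab.network import NETWORK_WINDOWS


def _stable_coefs():
    A = np.zeros((2, 4, 4))
    A[0] = 0.4 * np.eye(4)
    A[0][1, 0] = 0.35
    A[0][3, 2] = -0.3
    A[1] = -0.25 * np.eye(4)
    A[1][2, 1] = 0.2
    return A


class TestFitMvar:
    def test_known_model_recovery(self):
        A = _stable_coefs()
        X = il.simulate_mvar(A, n_trials=50, n_samples=150, seed=0)
        model = il.fit_mvar(X, order=2)
        assert model.stable
        assert np.abs(model.coefs - A).max() <= 0.05

    def test_white_noise_gives_null_coefficients(self):
        X = np.random.default_rng(1).standard_normal((50, 4, 150))
        model = il.fit_mvar(X, order=2)
        assert np.abs(model.coefs).max() <= 0.05

    def test_order_zero_rejected(self):
        X = np.random.default_rng(2).standard_normal((5, 4, 100))
        with pytest.raises(ValueError):
            il.fit_mvar(X, order=0)

    def test_too_short_trials_rejected(self):
        X = np.random.default_rng(3).standard_normal((5, 8, 20))
        with pytest.raises(ValueError):
            il.fit_mvar(X, order=5)

    def test_matches_statsmodels_var_on_single_trial(self):
        """Pooled LS with one trial equals an ordinary VAR fit."""
        from statsmodels.tsa.api import VAR

        A = _stable_coefs()
        X = il.simulate_mvar(A, n_trials=1, n_samples=2000, seed=4)
        model = il.fit_mvar(X, order=2)
        ref = VAR(X[0].T - X[0].T.mean(axis=0)).fit(2, trend="n")
        np.testing.assert_allclose(model.coefs, ref.coefs, atol=1e-8)

    def test_aic_selects_generating_order(self):
        A = _stable_coefs()
        X = il.simulate_mvar(A, n_trials=30, n_samples=200, seed=5)
        model = il.fit_mvar(X, order=None, max_order=6)
        assert model.order == 2


class TestPdc:
    def test_uncoupled_model_zero_off_diagonal(self):
        model = il.MVARModel(order=1, coefs=0.5 * np.eye(3)[None],
                             resid_cov=np.eye(3), fs=250.0)
        net = il.pdc(model, np.linspace(1, 6, 8))
        off = net.pdc * (1 - np.eye(3))[:, :, None]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_column_normalization(self):
        A = _stable_coefs()
        X = il.simulate_mvar(A, n_trials=20, n_samples=200, seed=6)
        model = il.fit_mvar(X, order=2)
        net = il.pdc(model, np.linspace(0.5, 30, 40))
        sums = (net.pdc**2).sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_bivariate_closed_form(self):
        """PDC(2<-1) for x2 driven by x1 with a21=0.5, a11=a22=0.3."""
        fs = 250.0
        coefs = np.array([[[0.3, 0.0], [0.5, 0.3]]])
        model = il.MVARModel(order=1, coefs=coefs, resid_cov=np.eye(2),
                             fs=fs)
        freqs = np.linspace(1.0, 40.0, 10)
        net = il.pdc(model, freqs)
        w = 2 * np.pi * freqs / fs
        a11 = np.abs(1 - 0.3 * np.exp(-1j * w))
        a21 = np.abs(-0.5 * np.exp(-1j * w))
        expected = a21 / np.sqrt(a11**2 + a21**2)
        np.testing.assert_allclose(net.pdc[1, 0], expected, atol=1e-12)
        # no influence 1 <- 2
        np.testing.assert_allclose(net.pdc[0, 1], 0.0, atol=1e-12)

    def test_directionality_recovered_from_data(self):
        """One-way coupling 1 -> 2 shows as PDC(2<-1) > PDC(1<-2)."""
        coefs = np.array([[[0.5, 0.0], [0.4, 0.5]]])
        hits = 0
        for seed in range(5):
            X = il.simulate_mvar(coefs, n_trials=30, n_samples=100,
                                 seed=seed)
            net = il.band_average(
                il.pdc(il.fit_mvar(X, order=1), np.linspace(1, 6, 8)))
            if net.band_summary[1, 0] > net.band_summary[0, 1]:
                hits += 1
        assert hits >= 4


class TestWindowNetworks:
    def test_visual_preset_window(self, small_epochs):
        _, repochs = small_epochs
        nets = il.window_networks(repochs, "visual", condition="go",
                                  order=3)
        assert len(nets) == 1
        assert nets[0].window == (0.35, 0.60)
        assert nets[0].band_summary is not None

    def test_auditory_preset_value(self):
        assert NETWORK_WINDOWS["auditory"] == (0.65, 0.90)

    def test_sliding_windows(self, small_epochs):
        _, repochs = small_epochs
        nets = il.window_networks(repochs, "sliding", condition="go",
                                  order=2)
        assert len(nets) == 9  # (-0.2 .. 0.6) starts at 100 ms steps
        assert nets[0].window[0] == pytest.approx(-0.2)

    def test_window_outside_epoch(self, small_epochs):
        _, repochs = small_epochs
        with pytest.raises(ValueError):
            il.window_networks(repochs, [(1.5, 1.7)], condition="go",
                               order=2)


class TestThresholdAdjacency:
    def _net(self, seed=0):
        rng = np.random.default_rng(seed)
        W = rng.random((8, 8))
        return il.PDCNetwork(pdc=W[:, :, None], freqs=np.array([3.0]),
                             nodes=REGIONS, band_summary=W, band=(1, 6))

    def test_full_density_complete_graph(self):
        net = il.threshold_adjacency(self._net(), q=1.0)
        assert net.adjacency.sum() == 56
        assert not np.diag(net.adjacency).any()

    def test_cutoff_above_max_empty(self):
        net = il.threshold_adjacency(self._net(), method="absolute",
                                     cutoff=2.0)
        assert not net.adjacency.any()

    def test_default_density_17_edges(self):
        net = il.threshold_adjacency(self._net(), q=0.3)
        assert int(net.adjacency.sum()) == round(0.3 * 56)

    def test_invalid_density(self):
        with pytest.raises(ValueError):
            il.threshold_adjacency(self._net(), q=0.0)


def brute_force_directed_clustering(A):
    """Triangle-motif enumeration oracle (Fagiolo's definition)."""
    A = (np.asarray(A) > 0).astype(float)
    n = len(A)
    S = A + A.T
    out = np.zeros(n)
    for i in range(n):
        d_tot = int(A[i].sum() + A[:, i].sum())
        d_bi = int((A[i] * A[:, i]).sum())
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        tri = 0.0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) == 3:
                    tri += S[i, j] * S[j, k] * S[k, i]
        out[i] = (tri / 2.0) / denom if denom > 0 else 0.0
    return out


class TestClustering:
    def test_complete_graph_all_one(self):
        A = 1.0 - np.eye(8)
        np.testing.assert_allclose(il.clustering_coefficients(A), 1.0)

    def test_empty_graph_all_zero(self):
        np.testing.assert_allclose(
            il.clustering_coefficients(np.zeros((8, 8))), 0.0)

    def test_directed_three_cycle(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 2] = A[2, 0] = 1.0
        np.testing.assert_allclose(il.clustering_coefficients(A),
                                   brute_force_directed_clustering(A))

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            A = (rng.random((n, n)) < 0.4).astype(float)
            np.fill_diagonal(A, 0)
            np.testing.assert_allclose(
                il.clustering_coefficients(A),
                brute_force_directed_clustering(A), atol=1e-12)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(8)
        A = (rng.random((8, 8)) < 0.5).astype(float)
        np.fill_diagonal(A, 0)
        cc = il.clustering_coefficients(A)
        assert ((cc >= 0) & (cc <= 1)).all()

    def test_self_loops_rejected(self):
        with pytest.raises(ValueError):
            il.clustering_coefficients(np.eye(3))

    def test_undirected_option(self):
        import networkx as nx

        rng = np.random.default_rng(9)
        A = (rng.random((6, 6)) < 0.5).astype(float)
        np.fill_diagonal(A, 0)
        cc = il.clustering_coefficients(A, kind="undirected")
        G = nx.from_numpy_array((A > 0), create_using=nx.DiGraph)
        ref = nx.clustering(G.to_undirected())
        np.testing.assert_allclose(cc, [ref[i] for i in range(6)])


class TestCompareConditions:
    def test_identical_conditions(self):
        vals = np.random.default_rng(10).random((6, 8))
        table = il.compare_conditions(vals, vals.copy())
        assert (table["cohens_d"] == 0).all()
        assert (table["p"] == 1).all()
        assert not table["significant"].any()

    def test_summary_reproduces_printed_effect(self):
        d = il.effect_from_summary(0.24, 0.02, 0.22, 0.02)
        assert round(d, 2) == 1.00

    def test_known_coupling_shift_detected(self):
        """Stronger frontal->parietal Go coupling raises frontal/parietal
        clustering in the Go networks."""
        base = np.eye(8) * 0.4
        go_c = base.copy()
        # Go: frontal/parietal nodes (0..3) mutually coupled, frontal
        # driving parietal hardest -> dense triangle-rich F/P subgraph
        for i in range(4):
            for j in range(4):
                if i != j:
                    go_c[i, j] = 0.12
        go_c[2, 0] = go_c[3, 1] = 0.25
        hits = 0
        n_runs = 5
        for run in range(n_runs):
            go_cc = np.empty((6, 8))
            nogo_cc = np.empty((6, 8))
            for s in range(6):
                seed = 1000 + run * 20 + s
                for name, C, out in (("go", go_c, go_cc),
                                     ("nogo", base, nogo_cc)):
                    X = il.simulate_mvar(C[None], 40, 64, seed=seed
                                         + (0 if name == "go" else 7))
                    net = il.band_average(
                        il.pdc(il.fit_mvar(X, order=1),
                               np.linspace(1, 6, 8)))
                    net = il.threshold_adjacency(net)
                    out[s] = il.clustering_coefficients(net.adjacency)
            table = il.compare_conditions(go_cc, nogo_cc)
            d_front_par = table.set_index("region").loc[
                ["FL", "FR", "PL", "PR"], "cohens_d"].mean()
            if d_front_par > 0:
                hits += 1
        assert hits >= 4

    def test_null_specificity_on_uncoupled_regions(self):
        """Uncoupled region dynamics produce no spurious Go/Nogo
        clustering-coefficient effects: |d| < 0.5 and p > 0.05 in >= 80%
        of (run, region) cells over 20 seeded runs."""
        base = np.eye(8) * 0.4
        n_subjects = 20  # study-scale group size
        ok = 0
        total = 0
        for run in range(20):
            go_cc = np.empty((n_subjects, 8))
            nogo_cc = np.empty((n_subjects, 8))
            for s in range(n_subjects):
                for name, out in (("go", go_cc), ("nogo", nogo_cc)):
                    seed = 5000 + run * 64 + s * 2 + (name == "go")
                    X = il.simulate_mvar(base[None], 40, 64, seed=seed)
                    net = il.band_average(
                        il.pdc(il.fit_mvar(X, order=1),
                               np.linspace(1, 6, 8)))
                    net = il.threshold_adjacency(net)
                    out[s] = il.clustering_coefficients(net.adjacency)
            table = il.compare_conditions(go_cc, nogo_cc)
            ok += int(((table["cohens_d"].abs() < 0.5)
                       & (table["p"] > 0.05)).sum())
            total += len(table)
        assert ok / total >= 0.8

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError):
            il.compare_conditions(np.zeros((4, 8)), np.zeros((5, 8)))
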