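import itertools

import numpy as np
import pytest
from scipy.stats import kstest, pearsonr, spearmanr

from matcher import (CellFeatureMatrix, MatcherError, MatcherModel, RunConfig,
                     SimSpec, build_modality_model, cross_modality_correlation,
                     decoupling_test, fisher_r_to_z, fit_shared_gplvm,
                     identify_lagging_cells, infer_correspondence, orient,
                     shared_master_time, simulate_modality,
                     simulate_paired_modalities)
from matcher.simulation import parse_warp


def _fit_small(sim, config):
    return build_modality_model(sim.Y, config)


@pytest.fixture(scope="module")
def fit():
    sim = simulate_modality(SimSpec(n_cells=50, n_features=20,
                                    warp_family="identity", noise_sigma=0.5,
                                    seed=3, modality_name="o"))
    from matcher import BayesianGPLVM
    return BayesianGPLVM(sim.Y, n_restarts=1, max_iter=300).fit(seed=0)


class TestOrient:
    def test_marker_sign_logic(self, fit):
        latent = fit.latent_mean
        applied, oriented = orient(fit, "marker:m:decreasing", marker_values=-latent)
        assert applied == "keep"
        np.testing.assert_array_equal(oriented, latent)
        applied, oriented = orient(fit, "marker:m:decreasing", marker_values=latent)
        assert applied == "reverse"
        np.testing.assert_array_equal(oriented, -latent)

    def test_uninformative_marker_refused(self, fit):
        # a marker alternating with the latent's rank order has Spearman ~ 0
        n = len(fit.cell_ids)
        marker = np.empty(n)
        marker[np.argsort(fit.latent_mean)] = np.arange(n) % 2
        with pytest.raises(MatcherError, match="uninformative marker"):
            orient(fit, "marker:m:increasing", marker_values=marker)

    def test_explicit_rules(self, fit):
        assert orient(fit, "keep")[0] == "keep"
        applied, oriented = orient(fit, "reverse")
        assert applied == "reverse"
        np.testing.assert_array_equal(oriented, -fit.latent_mean)

    def test_missing_marker_rejected(self, fit):
        with pytest.raises(MatcherError, match="not present"):
            orient(fit, "marker:absent_gene:increasing")

    def test_marker_orientation_always_positively_correlated(self):
        """With a monotone marker of known direction, oriented master time is
        positively correlated with the truth in every seeded run."""
        for seed in range(8):
            sim = simulate_modality(SimSpec(n_cells=60, n_features=40,
                                            warp_family="identity", noise_sigma=2.0,
                                            seed=seed, modality_name="mk"))
            sign = sim.feature_params["sign"][0]
            rule = f"marker:mk_g0000:{'increasing' if sign > 0 else 'decreasing'}"
            cfg = RunConfig(seed=seed, n_restarts=1, max_iter=300,
                            orientation={"mk": rule})
            model = build_modality_model(sim.Y, cfg)
            assert pearsonr(model.master_time, sim.true_master).statistic > 0


class TestBuildModalityModel:
    def test_noiseless_recovery(self):
        sim = simulate_modality(SimSpec(n_cells=100, n_features=100,
                                        warp_family="power:2", noise_sigma=0.0,
                                        seed=11, modality_name="nl"))
        model = _fit_small(sim, RunConfig(seed=11, n_restarts=1))
        r = pearsonr(model.master_time, sim.true_master).statistic
        assert abs(r) >= 0.99
        assert kstest(model.master_time, "uniform").statistic < 0.1

    def test_two_modalities_share_master_frame(self):
        """Modalities with different warps land on comparable master times."""
        a, b, _ = simulate_paired_modalities(
            SimSpec(seed=1, n_cells=100, n_features=100, warp_family="identity",
                    noise_sigma=1.0, modality_name="a"),
            SimSpec(seed=2, n_cells=100, n_features=100, warp_family="power:3",
                    noise_sigma=1.0, modality_name="b"),
            seed=7)
        cfg = RunConfig(seed=7, n_restarts=1, orientation={
            "a": _marker_rule(a), "b": _marker_rule(b)})
        ma = build_modality_model(a.Y, cfg)
        mb = build_modality_model(b.Y, cfg)
        qa = np.quantile(ma.master_time, np.linspace(0.05, 0.95, 19))
        qb = np.quantile(mb.master_time, np.linspace(0.05, 0.95, 19))
        assert np.max(np.abs(qa - qb)) < 0.1


def _marker_rule(sim):
    sign = sim.feature_params["sign"][0]
    name = sim.Y.feature_ids[0]
    return f"marker:{name}:{'increasing' if sign > 0 else 'decreasing'}"


@pytest.fixture(scope="module")
def pair():
    # noise at 25% of the feature range, the paired-benchmark regime
    a, b, corr = simulate_paired_modalities(
        SimSpec(seed=5, n_cells=120, n_features=80, warp_family="identity",
                noise_sigma=4.0, modality_name="a"),
        SimSpec(seed=6, n_cells=120, n_features=80, warp_family="power:2",
                noise_sigma=4.0, modality_name="b"),
        subsample=(0.5, 0.5), seed=17)
    cfg = RunConfig(seed=17, n_restarts=1, orientation={
        "a": _marker_rule(a), "b": _marker_rule(b)})
    return a, b, build_modality_model(a.Y, cfg), build_modality_model(b.Y, cfg)


class TestCorrespondence:
    def test_self_correspondence_consistency(self, smooth_sim, fast_config):
        model = _fit_small(smooth_sim, fast_config)
        cs = infer_correspondence(model, model)
        obs = smooth_sim.Y.values
        gen = cs.generated.to_numpy()
        rs = [pearsonr(obs[i], gen[i]).statistic for i in range(obs.shape[0])]
        assert np.median(rs) >= 0.8

    def test_generated_tracks_target_truth(self, pair):
        """Generated target features track the target's generating functions
        at the pivot master times, within twice the noise level."""
        a, b, ma, mb = pair
        cs = infer_correspondence(ma, mb)
        t_target = parse_warp(b.spec.warp_family)(a.true_master)
        truth = b.noiseless(t_target)
        rmse = np.sqrt(np.mean((cs.generated.to_numpy() - truth) ** 2))
        assert rmse <= 2.0 * b.spec.noise_sigma

    def test_master_zero_maps_to_smallest_target_anchor(self, pair):
        _, _, ma, mb = pair
        i = int(np.argmin(ma.master_time))
        ma.master_time[i] = 0.0
        cs = infer_correspondence(ma, mb, cells=[ma.cell_ids[i]])
        assert cs.pivot_master_time[0] == 0.0

    def test_empty_subset_rejected(self, pair):
        _, _, ma, mb = pair
        with pytest.raises(MatcherError, match="empty"):
            infer_correspondence(ma, mb, cells=[])


class TestCrossModalityCorrelation:
    def test_self_diagonal_near_one_noiseless(self):
        sim = simulate_modality(SimSpec(n_cells=80, n_features=10,
                                        warp_family="identity", noise_sigma=0.0,
                                        seed=9, modality_name="s"))
        model = _fit_small(sim, RunConfig(seed=9, n_restarts=1))
        feats = sim.Y.feature_ids[:5]
        C = cross_modality_correlation(model, model, feats, feats, "spearman")
        assert np.all(np.abs(np.diag(C.to_numpy())) > 0.95)

    def test_opposite_trends_give_negative_correlation(self):
        a, b, _ = simulate_paired_modalities(
            SimSpec(seed=30, n_cells=100, n_features=40, warp_family="identity",
                    noise_sigma=0.5, modality_name="a"),
            SimSpec(seed=31, n_cells=100, n_features=40, warp_family="identity",
                    noise_sigma=0.5, modality_name="b"),
            seed=32)
        cfg = RunConfig(seed=32, n_restarts=1, orientation={
            "a": _marker_rule(a), "b": _marker_rule(b)})
        ma, mb = build_modality_model(a.Y, cfg), build_modality_model(b.Y, cfg)
        up_a = a.Y.feature_ids[int(np.argmax(a.feature_params["sign"] > 0))]
        down_b = b.Y.feature_ids[int(np.argmax(b.feature_params["sign"] < 0))]
        inferred = cross_modality_correlation(ma, mb, [up_a], [down_b]).iloc[0, 0]
        true_r = spearmanr(a.noiseless()[:, a.Y.feature_ids.index(up_a)],
                           b.noiseless()[:, b.Y.feature_ids.index(down_b)]).statistic
        assert true_r < 0 and inferred < 0

    def test_zero_variance_feature_flagged_nan(self, smooth_sim, fast_config):
        vals = smooth_sim.Y.values.copy()
        vals[:, 0] = 3.0
        Y = CellFeatureMatrix(vals, smooth_sim.Y.cell_ids,
                              smooth_sim.Y.feature_ids, "toy")
        model = build_modality_model(Y, fast_config)
        C = cross_modality_correlation(model, model, [Y.feature_ids[0]],
                                       [Y.feature_ids[1]])
        assert np.isnan(C.iloc[0, 0])


class TestDecoupling:
    def test_identical_master_times(self, rng):
        m = rng.uniform(0, 1, 60)
        res = decoupling_test(m, m.copy(), split=0.3, n_perm=100, seed=0)
        assert res.r_before == pytest.approx(1.0)
        assert res.r_after == pytest.approx(1.0)
        assert res.fisher_z == pytest.approx(0.0)
        assert res.p_fisher == pytest.approx(0.5)

    def test_fisher_closed_form(self):
        """z = (atanh 0.8 - atanh 0.5)/sqrt(1/27 + 1/67): direct evaluation
        gives 2.40974 (one-tailed p = 0.00798)."""
        z, p = fisher_r_to_z(0.8, 30, 0.5, 70)
        expected_z = (np.arctanh(0.8) - np.arctanh(0.5)) / np.sqrt(1 / 27 + 1 / 67)
        assert z == pytest.approx(expected_z, abs=1e-12)
        assert z == pytest.approx(2.4097379294, abs=1e-9)
        assert p == pytest.approx(0.0079819916, abs=1e-9)

    def test_permutation_matches_exhaustive_enumeration(self):
        """On 8 cells, the sampled permutation p agrees with exhaustive
        enumeration of all C(8,2) 30/70-compatible splits."""
        rng = np.random.default_rng(4)
        m1 = rng.uniform(0, 1, 8)
        m2 = m1 + rng.normal(0, 0.4, 8)
        m1[3] = 0.05  # ensure 4 cells fall on each side of 0.5
        res = decoupling_test(np.sort(m1), m2, split=float(np.sort(m1)[4] - 1e-6),
                              n_perm=20000, seed=1)
        # independent oracle: enumerate all size-2 group-1 choices
        n = 8
        k = int(np.floor(0.3 * n))
        s1 = np.sort(m1)
        stats = []
        for g1 in itertools.combinations(range(n), k):
            g1 = list(g1)
            g2 = [i for i in range(n) if i not in g1]
            d = (spearmanr(s1[g1], m2[g1]).statistic
                 - spearmanr(s1[g2], m2[g2]).statistic)
            stats.append(d)
        exact_p = np.mean(np.asarray(stats) >= res.observed_perm_stat)
        assert res.p_perm == pytest.approx(exact_p, abs=0.02)

    def test_preconditions(self, rng):
        m = rng.uniform(0, 1, 30)
        with pytest.raises(MatcherError, match="outside"):
            decoupling_test(m, m, split=1.5)
        with pytest.raises(MatcherError, match="too-small"):
            decoupling_test(m, m, split=0.001)


class TestSharedMasterTime:
    def test_duplicated_modality_matches_single_pipeline(self, smooth_sim, fast_config):
        Y = smooth_sim.Y
        Y2 = CellFeatureMatrix(Y.values.copy(), Y.cell_ids, Y.feature_ids, "copy")
        shared_fit = fit_shared_gplvm(Y, Y2, fast_config)
        master, warp, _ = shared_master_time(shared_fit, fast_config)
        single = build_modality_model(Y, fast_config)
        r = pearsonr(master, single.master_time).statistic
        assert abs(r) >= 0.95

    def test_uniformization(self):
        a, b, _ = simulate_paired_modalities(
            SimSpec(seed=41, n_cells=100, n_features=60, warp_family="identity",
                    noise_sigma=1.0, modality_name="a"),
            SimSpec(seed=42, n_cells=100, n_features=60, warp_family="power:2",
                    noise_sigma=1.0, modality_name="b"),
            seed=43)
        cfg = RunConfig(seed=43, n_restarts=1)
        shared_fit = fit_shared_gplvm(a.Y, b.Y, cfg)
        master, _, _ = shared_master_time(shared_fit, cfg)
        assert kstest(master, "uniform").statistic < 0.1
        assert abs(pearsonr(master, a.true_master).statistic) >= 0.9


class TestLaggingCells:
    def test_hand_worked_example(self):
        master = np.array([0.1, 0.2, 0.15, 0.5])
        tps = ["tp0", "tp0", "tp1", "tp1"]
        flags = identify_lagging_cells(master, tps, ["tp0", "tp1"])
        np.testing.assert_array_equal(flags, [False, False, True, False])

    def test_no_overlap_no_flags(self):
        flags = identify_lagging_cells([0.1, 0.2, 0.3, 0.4],
                                       ["tp0", "tp0", "tp1", "tp1"],
                                       ["tp0", "tp1"])
        assert not flags.any()

    def test_single_time_point_never_lags(self):
        flags = identify_lagging_cells([0.1, 0.9], ["tp0", "tp0"], ["tp0"])
        assert not flags.any()

    def test_only_immediately_preceding_time_point_counts(self):
        # cell at 0.25 in tp2 overlaps tp0's range but not tp1's
        master = np.array([0.3, 0.1, 0.2, 0.25, 0.6])
        tps = ["tp0", "tp0", "tp1", "tp2", "tp2"]
        flags = identify_lagging_cells(master, tps, ["tp0", "tp1", "tp2"])
        np.testing.assert_array_equal(flags, [False, False, True, False, False])

    def test_unordered_labels_rejected(self):
        with pytest.raises(MatcherError, match="unordered"):
            identify_lagging_cells([0.1, 0.2], ["tp0", "tpX"], ["tp0", "tp1"])


class TestMatcherModelFacade:
    def test_fit_and_summary(self, smooth_sim, fast_config):
        results = MatcherModel([smooth_sim.Y], fast_config).fit()
        table = results.master_time_table()
        assert set(table.columns) == {"cell_id", "modality", "pseudotime",
                                      "master_time"}
        assert len(table) == smooth_sim.Y.n_cells
        text = results.summary()
        assert "toy" in text and "KS" in text

    def test_end_to_end_determinism(self, smooth_sim, fast_config):
        t1 = MatcherModel([smooth_sim.Y], fast_config).fit().master_time_table()
        t2 = MatcherModel([smooth_sim.Y], fast_config).fit().master_time_table()
        assert t1.to_csv() == t2.to_csv()
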