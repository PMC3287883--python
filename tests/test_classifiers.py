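import numpy as np
import pandas as pd
import pytest

from ebrisk.classifiers import (PredictionRule, ShrinkConfig,
                                estimate_gene_correlation, fit_covariate_model,
                                fit_model, gene_weight, predict,
                                weight_from_pvalues, weighted_score)
from ebrisk.data_io import AnnotationTable, GenotypeDataset
from ebrisk.gene_scores import madsen_browning_scores
from ebrisk.synthetic import SimConfig, simulate_dataset

IDENTITY = ShrinkConfig(identity=True)


# ---------------------------------------------------------------------------
# gene weights


class TestGeneWeight:
    def test_weight_formula(self):
        assert weight_from_pvalues(0.01, 0.09) == pytest.approx(0.9)
        assert weight_from_pvalues(0.5, 0.5) == 0.5
        assert weight_from_pvalues(0.0, 0.0) == 0.5

    def test_identical_channels_give_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = (rng.random(200) < 0.4).astype(int)
        smoke = (rng.random(200) < 0.3).astype(float)
        gw = gene_weight(x, x.copy(), y, smoke)
        assert gw.w == pytest.approx(0.5, abs=1e-9)

    def test_absent_channel_fallback(self):
        gw = gene_weight(None, np.ones(10), np.zeros(10), None)
        assert gw.fallback
        assert gw.w is None

    def test_stronger_nonsyn_gives_larger_weight(self):
        rng = np.random.default_rng(1)
        n = 400
        y = (rng.random(n) < 0.4).astype(int)
        xn = y * 1.0 + rng.normal(size=n)       # associated
        xs = rng.normal(size=n)                  # noise
        gw = gene_weight(xn, xs, y, None)
        assert gw.w > 0.8


class TestWeightedScore:
    def test_extremes(self):
        xn = np.array([2.0])
        xs = np.array([1.0])
        assert weighted_score(xn, xs, 1.0)[0] == 2.0
        assert weighted_score(xn, xs, 0.0)[0] == 1.0

    def test_hand_arithmetic(self):
        assert weighted_score(np.array([2.0]), np.array([1.0]), 0.9)[0] == \
            pytest.approx(1.9)


class TestGeneCorrelation:
    def test_collinear_clipped(self):
        x = np.random.default_rng(2).normal(size=50)
        y = (np.arange(50) < 20).astype(int)
        P = estimate_gene_correlation(x, x, y)
        assert P[0, 1] == 0.99

    def test_hand_fixture(self):
        # 6 individuals, 3 per class; residuals computed by hand
        xn = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
        xs = np.array([2.0, 1.0, 3.0, 8.0, 6.0, 4.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        rn = np.r_[xn[:3] - 2.0, xn[3:] - 6.0]
        rs = np.r_[xs[:3] - 2.0, xs[3:] - 6.0]
        expected = (rn * rs).sum() / np.sqrt((rn ** 2).sum() * (rs ** 2).sum())
        P = estimate_gene_correlation(xn, xs, y)
        assert P[0, 1] == pytest.approx(expected, abs=1e-12)
        assert P[1, 0] == P[0, 1]
        np.testing.assert_array_equal(np.diag(P), [1.0, 1.0])

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(3)
        xn = rng.normal(size=500)
        xs = rng.normal(size=500)
        y = (rng.random(500) < 0.3).astype(int)
        assert abs(estimate_gene_correlation(xn, xs, y)[0, 1]) <= 0.1


# ---------------------------------------------------------------------------
# oracle equivalence: identity shrinkage == brute-force diagonal LDA


def brute_force_diag_lda(G, gene_cols, Y, x_eval):
    """Independently coded diagonal LDA on Z-bar over stacked replicates.

    ``gene_cols`` maps gene -> column index of a precomputed score matrix.
    Everything is computed with explicit loops, no shared pipeline code.
    """
    n, R = Y.shape
    out = np.zeros(x_eval.shape[0])
    c_ns = []
    for r in range(R):
        n1 = Y[:, r].sum()
        n2 = n - n1
        c_ns.append(np.sqrt(1 / n1 + 1 / n2))
    c_n = float(np.mean(c_ns))
    for g, col in gene_cols.items():
        x = G[:, col]
        zs = []
        for r in range(R):
            y = Y[:, r]
            m1 = x[y == 1].mean()
            m2 = x[y == 0].mean()
            ss = ((x[y == 1] - m1) ** 2).sum() + ((x[y == 0] - m2) ** 2).sum()
            sd = np.sqrt(ss / (n - 2))
            zs.append((m1 - m2) / (sd * np.sqrt(1 / y.sum() + 1 / (n - y.sum()))))
        zbar = float(np.mean(zs))
        # pooled (replicate-stacked) class means and sd
        xs_long = np.tile(x, R)
        ys_long = Y.T.ravel()
        mu1 = xs_long[ys_long == 1].mean()
        mu2 = xs_long[ys_long == 0].mean()
        ss = ((xs_long[ys_long == 1] - mu1) ** 2).sum() + \
             ((xs_long[ys_long == 0] - mu2) ** 2).sum()
        sd = np.sqrt(ss / (n * R - 2))
        m = (mu1 + mu2) / 2
        out += zbar * c_n * (x_eval[:, col] - m) / sd
    return out


@pytest.fixture(scope="module")
def small_signal_data():
    cfg = SimConfig(n=50, n_genes=5, snps_per_gene=(2, 6), R=4, n_causal=2,
                    effect_size=1.5, frac_nonsyn=0.6,
                    covariate_effects={"Age": 0, "Sex": 0, "Smoke": 0},
                    prevalence=0.4, seed=21)
    return simulate_dataset(cfg)


def test_identity_shrinkage_matches_brute_force_oracle(small_signal_data):
    geno, annot, phen, cov, _ = small_signal_data
    model = fit_model(geno, annot, phen.Y, kind="eb", shrink=IDENTITY,
                      use_covariates=False)
    scores = madsen_browning_scores(geno, annot, "all")
    cols = {g: i for i, g in enumerate(scores.gene_ids)}
    oracle = brute_force_diag_lda(scores.X, cols, phen.Y, scores.X)
    mine = model.decision_values(model.n_genes)
    np.testing.assert_allclose(mine, oracle, atol=1e-10)


# ---------------------------------------------------------------------------
# algebraic reductions


def test_web_half_weights_equals_eb_on_averaged_scores(small_signal_data):
    geno, annot, phen, cov, _ = small_signal_data
    web = fit_model(geno, annot, phen.Y, kind="web", shrink=IDENTITY,
                    use_covariates=False, weight_override=0.5)
    # independent route: univariate pipeline on the channel-averaged matrix
    from ebrisk.classifiers import _fit_channel
    fn = madsen_browning_scores(geno, annot, "nonsynonymous").to_frame()
    fs = madsen_browning_scores(geno, annot, "synonymous").to_frame()
    genes = sorted(set(fn.columns) & set(fs.columns), key=str)
    assert genes, "fixture must have dual-channel genes"
    Xavg = np.column_stack([(fn[g] + fs[g]) / 2 for g in genes])
    ch = _fit_channel(Xavg, np.asarray(genes, dtype=object), phen.Y,
                      IDENTITY, None)
    web_genes = {g: k for k, g in enumerate(web.gene_ids)}
    for i, g in enumerate(ch.gene_ids):
        k = web_genes[g]
        col_web = web._contrib[:, k]
        col_avg = ch.delta_hat[i] * web.c_n * \
            (Xavg[:, genes.index(g)] - ch.center[i]) / ch.scale[i]
        np.testing.assert_allclose(col_web, col_avg, atol=1e-10)


def test_jc_identity_correlation_reduces_to_univariate_sum(small_signal_data):
    geno, annot, phen, cov, _ = small_signal_data
    jc = fit_model(geno, annot, phen.Y, kind="jc", shrink=IDENTITY,
                   use_covariates=False, correlation_override=np.eye(2))
    from ebrisk.classifiers import _fit_channel
    contrib = {}
    for cls in ("nonsynonymous", "synonymous"):
        s = madsen_browning_scores(geno, annot, cls)
        ch = _fit_channel(s.X, s.gene_ids, phen.Y, IDENTITY, None)
        frame = pd.DataFrame(s.X, columns=s.gene_ids)
        for i, g in enumerate(ch.gene_ids):
            col = ch.delta_hat[i] * jc.c_n * \
                (frame[g].to_numpy() - ch.center[i]) / ch.scale[i]
            contrib[g] = contrib.get(g, 0) + col
    jc_cols = {g: jc._contrib[:, k] for k, g in enumerate(jc.gene_ids)}
    assert set(contrib) == set(jc_cols)
    for g, expected in contrib.items():
        np.testing.assert_allclose(jc_cols[g], expected, atol=1e-10)


# ---------------------------------------------------------------------------
# fit_rule behaviour


def test_null_fit_shrinks_selected_genes(sim_null_bundle):
    geno, annot, phen, cov, _ = sim_null_bundle
    model = fit_model(geno, annot, phen.Y, kind="eb", use_covariates=False)
    zb_model = fit_model(geno, annot, phen.Y, kind="eb", shrink=IDENTITY,
                         use_covariates=False)
    k = 10
    top = model.gene_ids[:k]
    zbar = dict(zip(zb_model.gene_ids,
                    np.abs(np.asarray(zb_model.delta_hat, dtype=float))))
    mean_delta = np.mean(np.abs(np.asarray(model.delta_hat[:k], dtype=float)))
    mean_zbar = np.mean([zbar[g] for g in top])
    assert mean_delta < mean_zbar


def test_single_causal_gene_selected():
    hits = 0
    for seed in range(10):
        cfg = SimConfig(n=600, n_genes=40, snps_per_gene=(2, 10), R=6,
                        n_causal=1, effect_size=2.0,
                        covariate_effects={"Age": 0, "Sex": 0, "Smoke": 0},
                        prevalence=0.4, seed=200 + seed)
        geno, annot, phen, cov, truth = simulate_dataset(cfg)
        model = fit_model(geno, annot, phen.Y, kind="eb",
                          shrink=ShrinkConfig(n_bins=20, degree=3),
                          use_covariates=False)
        hits += model.selected_genes(1) == truth.causal_genes
    assert hits >= 9


def test_k_truncated_to_available_genes(small_signal_data):
    geno, annot, phen, *_ = small_signal_data
    model = fit_model(geno, annot, phen.Y, kind="eb", shrink=IDENTITY,
                      use_covariates=False)
    rule = model.to_rule(10_000)
    assert len(rule.gene_ids) == model.n_genes


def test_permuting_gene_order_is_invariant(small_signal_data):
    geno, annot, phen, cov, _ = small_signal_data
    model = fit_model(geno, annot, phen.Y, kind="eb", shrink=IDENTITY,
                      use_covariates=False)
    rng = np.random.default_rng(4)
    perm = rng.permutation(geno.n_snps)
    geno2 = GenotypeDataset(geno.sample_ids, geno.snp_ids[perm], geno.G[:, perm])
    annot2 = AnnotationTable(annot.table.sample(frac=1, random_state=1))
    model2 = fit_model(geno2, annot2, phen.Y, kind="eb", shrink=IDENTITY,
                       use_covariates=False)
    np.testing.assert_allclose(model.decision_values(model.n_genes),
                               model2.decision_values(model2.n_genes), atol=1e-9)
    assert model.predict(3).tolist() == model2.predict(3).tolist()


def test_jc_all_nonsyn_dataset_falls_back():
    cfg = SimConfig(n=80, n_genes=10, snps_per_gene=(2, 5), R=3, frac_nonsyn=1.0,
                    covariate_effects={"Age": 0, "Sex": 0, "Smoke": 0}, seed=5)
    geno, annot, phen, cov, _ = simulate_dataset(cfg)
    model = fit_model(geno, annot, phen.Y, kind="jc", use_covariates=False,
                      shrink=IDENTITY)
    assert not model.extras["dual"].any()


# ---------------------------------------------------------------------------
# discriminant / predict


class TestDiscriminant:
    def test_centered_input_gives_zero(self, small_signal_data):
        geno, annot, phen, *_ = small_signal_data
        model = fit_model(geno, annot, phen.Y, kind="eb", shrink=IDENTITY,
                          use_covariates=False)
        rule = model.to_rule(3)
        # an individual sitting exactly at every gene center scores 0
        contrib = rule.delta_hat * rule.c_n * (rule.center - rule.center) / rule.scale
        assert contrib.sum() == 0.0

    def test_hand_arithmetic(self):
        # single gene: delta=1, c_n=0.1, sigma=1, x - m = 2 -> 0.2
        assert 1.0 * 0.1 * (2.0 - 0.0) / 1.0 == pytest.approx(0.2)

    def test_scale_equivariance(self, small_signal_data):
        geno, annot, phen, *_ = small_signal_data
        model = fit_model(geno, annot, phen.Y, kind="eb", shrink=IDENTITY,
                          use_covariates=False)
        rule = model.to_rule(1)
        x = rule.center[0] + 2.0
        base = rule.delta_hat[0] * rule.c_n * (x - rule.center[0]) / rule.scale[0]
        doubled = rule.delta_hat[0] * rule.c_n * (x - rule.center[0]) / (2 * rule.scale[0])
        assert doubled == pytest.approx(base / 2)


class TestPredict:
    def test_balanced_tau_zero(self):
        Y = np.array([[1, 0, 1, 0]]).T
        from ebrisk.classifiers import _pooled_tau
        assert _pooled_tau(Y) == 0.0

    def test_gaw17_like_imbalance(self):
        Y = np.r_[np.ones(209), np.zeros(488)][:, None].astype(int)
        from ebrisk.classifiers import _pooled_tau
        assert _pooled_tau(Y) == pytest.approx(np.log(488 / 209), abs=1e-12)
        # log(488/209) = 0.84798 to 5 places
        assert _pooled_tau(Y) == pytest.approx(0.848, abs=5e-4)

    def test_zero_discriminant_predicts_control(self, small_signal_data):
        geno, annot, phen, *_ = small_signal_data
        model = fit_model(geno, annot, phen.Y, kind="eb", shrink=IDENTITY,
                          use_covariates=False)
        assert model.tau > 0  # unbalanced fixture
        # all-zero decision values with tau > 0 -> all control
        assert ((np.zeros(geno.n) > model.tau).astype(int) == 0).all()

    def test_predict_via_rule_matches_fitted_model(self, small_signal_data):
        geno, annot, phen, cov, _ = small_signal_data
        model = fit_model(geno, annot, phen.Y, kind="eb", covariates=cov,
                          shrink=IDENTITY, use_covariates=True)
        rule = model.to_rule(3)
        labels, scores = predict(rule, geno, annot, cov)
        np.testing.assert_allclose(scores, model.decision_values(3), atol=1e-9)
        assert labels.tolist() == model.predict(3).tolist()

    @pytest.mark.parametrize("kind", ["eb", "web", "jc"])
    def test_rule_json_roundtrip(self, small_signal_data, kind):
        geno, annot, phen, cov, _ = small_signal_data
        model = fit_model(geno, annot, phen.Y, kind=kind, covariates=cov,
                          shrink=IDENTITY)
        rule = model.to_rule(4)
        rule2 = PredictionRule.from_json(rule.to_json())
        labels1, s1 = predict(rule, geno, annot, cov)
        labels2, s2 = predict(rule2, geno, annot, cov)
        np.testing.assert_allclose(s1, s2, atol=1e-12)
        assert labels1.tolist() == labels2.tolist()


def test_covariate_model_recovers_direction(sim_bundle):
    geno, annot, phen, cov, truth = sim_bundle
    cm = fit_covariate_model(cov, phen.Y)
    # Age and Smoke have positive true effects in the fixture
    coef = dict(zip(cm.names, cm.coef[1:]))
    assert coef["Age"] > 0
    assert coef["Smoke"] > 0
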