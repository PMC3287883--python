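"""Shrunken-LDA prediction rules: EB, weighted EB (WEB), joint covariance (JC).

All three rules share one pipeline: per-gene burden scores -> per-replicate
two-sample Z -> replicate mean Z-bar with correlation correction -> Tweedie
shrinkage on the unit-variance scale -> shrunken effects delta_hat -> a
diagonal-LDA discriminant over the top-K genes,

    sum_{i in S} delta_hat_i * c_n * (x_i - m_i) / sigma_i,

with m_i the midpoint of the class means, sigma_i the pooled within-class sd
and c_n = sqrt(1/n1 + 1/n2).  They differ in the score matrix fed in:

* EB uses the all-SNP burden score of each gene.
* WEB forms a per-gene convex combination w*X_nonsyn + (1-w)*X_syn, where
  w = p_syn / (p_nonsyn + p_syn) from logistic-regression p-values of each
  channel (adjusted for Smoke), so the channel with the stronger marginal
  association dominates.
* JC keeps the two channels as a bivariate feature with a per-gene 2x2
  within-class correlation matrix P_i; channels are shrunk separately (two
  Tweedie fits, one per channel population) and the per-gene term becomes
  delta_hat' P_i^{-1} u_i with u_i the standardized channel deviations.

Covariates enter unshrunk as a logistic linear predictor added to the gene
part; the classification threshold is tau = log(n2/n1) without covariates
(class imbalance) and 0 with them (the intercept absorbs prevalence).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import (AnnotationTable, CovariateTable, DataValidationError,
                      GenotypeDataset)
from .eb_shrink import IdentityShrinkage, ShrinkageModel, fit_marginal_density
from .gene_scores import GeneScoreMatrix, madsen_browning_scores
from .zstats import (aggregate_replicates, estimate_rho, rescale_shrunken,
                     standardize, z_matrix)

logger = logging.getLogger(__name__)

MODEL_KINDS = ("eb", "web", "jc")


@dataclass
class ShrinkConfig:
    """Knobs for the Lindsey/Tweedie shrinker; identity=True disables shrinkage."""
    n_bins: int = 120
    degree: int = 5
    identity: bool = False

    def fit(self, zstar):
        if self.identity:
            return IdentityShrinkage()
        return fit_marginal_density(zstar, self.n_bins, self.degree)


@dataclass
class GeneWeight:
    gene_id: object
    p_nonsyn: float | None
    p_syn: float | None
    w: float | None
    fallback: bool = False   # one channel absent -> single-channel EB
    flagged: bool = False    # a logistic fit failed; its p-value was set to 1


@dataclass
class CovariateModel:
    """Unshrunk logistic linear predictor (intercept first)."""
    names: list
    coef: np.ndarray

    def linear_predictor(self, covariates: CovariateTable) -> np.ndarray:
        M = covariates.matrix(self.names)
        return self.coef[0] + M @ self.coef[1:]


def _wald_p(logit_result, idx: int) -> float:
    return float(logit_result.pvalues[idx])


def _fit_logistic(y, X):
    """Logit fit returning (result, converged) without raising on separation."""
    import warnings as _warnings
    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        ok = bool(res.mle_retvals.get("converged", False)) and np.isfinite(
            res.params).all() and np.isfinite(res.bse).all()
        return res, ok
    except Exception:
        return None, False


def logistic_score_pvalue(score, smoke, y) -> tuple[float, bool]:
    """Two-sided Wald p-value for the score coefficient in y ~ score + Smoke.

    ``smoke`` may be None (no covariate available).  Returns (p, flagged);
    non-convergence or separation yields p = 1, flagged.
    """
    score = np.asarray(score, dtype=float)
    cols = [np.ones_like(score), score]
    if smoke is not None:
        cols.append(np.asarray(smoke, dtype=float))
    X = np.column_stack(cols)
    res, ok = _fit_logistic(np.asarray(y, dtype=float), X)
    if not ok:
        return 1.0, True
    return _wald_p(res, 1), False


def weight_from_pvalues(p_nonsyn: float, p_syn: float) -> float:
    """w = p_syn / (p_nonsyn + p_syn): in [0,1], 0.5 at equality, larger when
    the nonsynonymous channel is more significant."""
    if p_nonsyn + p_syn == 0:  # both exactly zero: equally important
        return 0.5
    return float(p_syn / (p_nonsyn + p_syn))


def gene_weight(score_nonsyn, score_syn, y, smoke, gene_id="gene") -> GeneWeight:
    """Relative importance of the nonsynonymous channel: w = p_s/(p_n + p_s)."""
    if score_nonsyn is None or score_syn is None:
        return GeneWeight(gene_id, None, None, None, fallback=True)
    p_n, f1 = logistic_score_pvalue(score_nonsyn, smoke, y)
    p_s, f2 = logistic_score_pvalue(score_syn, smoke, y)
    return GeneWeight(gene_id, p_n, p_s, weight_from_pvalues(p_n, p_s),
                      flagged=f1 or f2)


def weighted_score(Xn, Xs, w):
    """Convex combination w*Xn + (1-w)*Xs of the two channel scores."""
    return w * np.asarray(Xn, dtype=float) + (1.0 - w) * np.asarray(Xs, dtype=float)


def estimate_gene_correlation(Xn, Xs, labels) -> np.ndarray:
    """Pooled within-class Pearson correlation of the two channels (2x2).

    Residuals are centered per class; the off-diagonal is clipped to
    |r| <= 0.99 so the matrix stays invertible.
    """
    xn = np.asarray(Xn, dtype=float)
    xs = np.asarray(Xs, dtype=float)
    y = np.asarray(labels)
    rn = xn.copy()
    rs = xs.copy()
    for cls in (0, 1):
        m = y == cls
        rn[m] -= rn[m].mean()
        rs[m] -= rs[m].mean()
    denom = np.sqrt((rn ** 2).sum() * (rs ** 2).sum())
    r = 0.0 if denom == 0 else (rn * rs).sum() / denom
    r = float(np.clip(r, -0.99, 0.99))
    return np.array([[1.0, r], [r, 1.0]])


# ---------------------------------------------------------------------------
# pooled training statistics


def _pooled_class_stats(X, Y):
    """Class means, midpoints and pooled sds over stacked training replicates."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, R = Y.shape
    n1_tot = Y.sum()
    n2_tot = n * R - n1_tot
    mu1 = (Y.T @ X).sum(axis=0) / n1_tot
    mu2 = ((1 - Y).T @ X).sum(axis=0) / n2_tot
    sum_sq = (X ** 2).sum(axis=0) * R
    ss = sum_sq - n1_tot * mu1 ** 2 - n2_tot * mu2 ** 2
    sd = np.sqrt(np.maximum(ss, 0.0) / (n * R - 2))
    return mu1, mu2, 0.5 * (mu1 + mu2), sd


def _mean_c_n(Y) -> float:
    n1 = Y.sum(axis=0).astype(float)
    n2 = Y.shape[0] - n1
    return float(np.mean(np.sqrt(1.0 / n1 + 1.0 / n2)))


def _pooled_tau(Y) -> float:
    n1 = float(Y.sum())
    n2 = float(Y.size - n1)
    return float(np.log(n2 / n1))


def _stack(v, R):
    return np.tile(np.asarray(v, dtype=float), R)


def fit_covariate_model(covariates: CovariateTable, Y) -> CovariateModel:
    """Pooled logistic regression of disease on all covariate columns."""
    R = Y.shape[1]
    M = covariates.matrix()
    Xd = np.column_stack([np.ones(M.shape[0] * R),
                          np.vstack([M] * R)])
    y = np.asarray(Y, dtype=float).T.ravel()  # replicate-stacked
    res, ok = _fit_logistic(y, Xd)
    if not ok:
        raise RuntimeError("covariate logistic regression failed to converge")
    return CovariateModel(covariates.names, np.asarray(res.params))


# ---------------------------------------------------------------------------
# channel pipeline (shared by all three rules)


@dataclass
class ChannelFit:
    """Univariate shrinkage pipeline for one score matrix (genes as columns)."""
    gene_ids: np.ndarray
    zbar: np.ndarray
    zstar: np.ndarray
    delta_hat: np.ndarray
    rho: float
    shrinker: object
    center: np.ndarray
    scale: np.ndarray


def _fit_channel(X, gene_ids, Ytrain, shrink: ShrinkConfig, rho=None) -> ChannelFit:
    Z, degen = z_matrix(X, Ytrain)
    keep = ~degen
    if degen.any():
        logger.info("dropping %d degenerate genes (zero pooled sd)", int(degen.sum()))
    X, gene_ids, Z = X[:, keep], np.asarray(gene_ids, dtype=object)[keep], Z[keep]
    if Z.shape[0] == 0:
        raise RuntimeError("no non-degenerate genes left")
    R = Ytrain.shape[1]
    zbar = aggregate_replicates(Z)
    if rho is None:
        rho = estimate_rho(Z) if R >= 2 else 0.0
    zstar = standardize(zbar, rho, R)
    shrinker = shrink.fit(zstar)
    delta_hat = rescale_shrunken(shrinker.posterior_mean(zstar), rho, R)
    mu1, mu2, center, sd = _pooled_class_stats(X, Ytrain)
    pos = sd > 0
    return ChannelFit(gene_ids[pos], zbar[pos], zstar[pos], delta_hat[pos],
                      float(rho), shrinker, center[pos], sd[pos])


# ---------------------------------------------------------------------------
# fitted model / rule


@dataclass
class PredictionRule:
    """Serializable prediction rule over a selected gene subset S."""
    kind: str
    gene_ids: list                      # ranked, |S| = K
    delta_hat: np.ndarray               # (K,) or (K, 2) for jc
    center: np.ndarray                  # same leading shape
    scale: np.ndarray
    c_n: float
    tau: float
    jc_p_inv: np.ndarray | None = None  # (K, 2, 2) for jc dual-channel genes
    jc_dual: np.ndarray | None = None   # (K,) bool; False -> univariate fallback
    web_weights: dict | None = None
    covariate_model: CovariateModel | None = None

    def to_json(self) -> str:
        doc = {
            "format_version": 1,
            "kind": self.kind,
            "gene_ids": [str(g) for g in self.gene_ids],
            "delta_hat": np.asarray(self.delta_hat).tolist(),
            "center": np.asarray(self.center).tolist(),
            "scale": np.asarray(self.scale).tolist(),
            "c_n": self.c_n,
            "tau": self.tau,
            "jc_p_inv": None if self.jc_p_inv is None else self.jc_p_inv.tolist(),
            "jc_dual": None if self.jc_dual is None else np.asarray(self.jc_dual).astype(bool).tolist(),
            "web_weights": None if self.web_weights is None else
                {str(k): v for k, v in self.web_weights.items()},
            "covariates": None if self.covariate_model is None else {
                "names": list(self.covariate_model.names),
                "coef": np.asarray(self.covariate_model.coef).tolist(),
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PredictionRule":
        doc = json.loads(text)
        cov = doc.get("covariates")
        return cls(
            kind=doc["kind"],
            gene_ids=doc["gene_ids"],
            delta_hat=np.asarray(doc["delta_hat"], dtype=float),
            center=np.asarray(doc["center"], dtype=float),
            scale=np.asarray(doc["scale"], dtype=float),
            c_n=float(doc["c_n"]),
            tau=float(doc["tau"]),
            jc_p_inv=None if doc["jc_p_inv"] is None else np.asarray(doc["jc_p_inv"], dtype=float),
            jc_dual=None if doc["jc_dual"] is None else np.asarray(doc["jc_dual"], dtype=bool),
            web_weights=doc["web_weights"],
            covariate_model=None if cov is None else CovariateModel(
                cov["names"], np.asarray(cov["coef"], dtype=float)),
        )


class FittedModel:
    """Fitted pipeline caching per-gene discriminant contributions.

    Genes are stored in ranked order so the gene part of the discriminant
    for any K is the row sum of the first K contribution columns; this makes
    the cross-validation sweep over K cheap.
    """

    def __init__(self, kind, gene_ids, contributions, delta_hat, center, scale,
                 c_n, tau_nocov, covariate_model, cov_part, extras=None):
        self.kind = kind
        self.gene_ids = np.asarray(gene_ids, dtype=object)
        self._contrib = contributions      # (n, G_ranked) on training samples
        self.delta_hat = delta_hat
        self.center = center
        self.scale = scale
        self.c_n = c_n
        self._tau_nocov = tau_nocov
        self.covariate_model = covariate_model
        self._cov_part = cov_part          # (n,) or None
        self.extras = extras or {}

    @property
    def n_genes(self) -> int:
        return self._contrib.shape[1]

    @property
    def tau(self) -> float:
        return 0.0 if self.covariate_model is not None else self._tau_nocov

    def gene_part(self, K: int) -> np.ndarray:
        K = min(K, self.n_genes)
        return self._contrib[:, :K].sum(axis=1)

    def decision_values(self, K: int) -> np.ndarray:
        d = self.gene_part(K)
        if self._cov_part is not None:
            d = d + self._cov_part
        return d

    def predict(self, K: int) -> np.ndarray:
        return (self.decision_values(K) > self.tau).astype(np.int8)

    def selected_genes(self, K: int) -> list:
        return list(self.gene_ids[: min(K, self.n_genes)])

    def to_rule(self, K: int) -> PredictionRule:
        K = min(K, self.n_genes)
        sl = slice(0, K)
        jc_p_inv = jc_dual = None
        web_weights = None
        if self.kind == "jc":
            jc_p_inv = self.extras["p_inv"][sl]
            jc_dual = self.extras["dual"][sl]
        if self.kind == "web":
            keep = set(self.gene_ids[sl])
            web_weights = {g: w for g, w in self.extras["weights"].items() if g in keep}
        return PredictionRule(
            kind=self.kind,
            gene_ids=list(self.gene_ids[sl]),
            delta_hat=self.delta_hat[sl],
            center=self.center[sl],
            scale=self.scale[sl],
            c_n=self.c_n,
            tau=self.tau,
            jc_p_inv=jc_p_inv,
            jc_dual=jc_dual,
            web_weights=web_weights,
            covariate_model=self.covariate_model,
        )


def _rank_order(stat: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Descending by |stat|, ties broken by gene id."""
    keys = [str(g) for g in gene_ids]
    return np.lexsort((keys, -np.abs(stat)))


def _channel_frames(geno, annot):
    """Score DataFrames for the two functional classes; empty frame when a
    class has no polymorphic SNPs anywhere."""
    frames = []
    for cls in ("nonsynonymous", "synonymous"):
        try:
            frames.append(madsen_browning_scores(geno, annot, cls).to_frame())
        except DataValidationError:
            frames.append(pd.DataFrame(index=range(geno.n)))
    return frames


def _web_scores(geno, annot, Ytrain, covariates, weight_override=None):
    """Per-gene weighted scores, weights, and the union gene set."""
    fn, fs = _channel_frames(geno, annot)
    genes = sorted(set(fn.columns) | set(fs.columns), key=str)
    if not genes:
        raise RuntimeError("no scorable genes in either functional class")
    R = Ytrain.shape[1]
    y_stack = np.asarray(Ytrain, dtype=float).T.ravel()
    smoke_stack = None
    if weight_override is None and covariates is not None and "Smoke" in covariates.names:
        smoke_stack = _stack(covariates.table["Smoke"].to_numpy(), R)
    cols = []
    weights: dict = {}
    weight_objs: dict = {}
    for g in genes:
        xn = fn[g].to_numpy() if g in fn.columns else None
        xs = fs[g].to_numpy() if g in fs.columns else None
        if xn is None or xs is None:
            gw = GeneWeight(g, None, None, None, fallback=True)
            cols.append(xn if xn is not None else xs)
        elif weight_override is not None:
            gw = GeneWeight(g, None, None, float(weight_override))
            cols.append(weighted_score(xn, xs, gw.w))
        else:
            gw = gene_weight(_stack(xn, R), _stack(xs, R), y_stack, smoke_stack, g)
            cols.append(weighted_score(xn, xs, gw.w))
        weights[g] = gw.w
        weight_objs[g] = gw
    X = np.column_stack(cols)
    return X, np.asarray(genes, dtype=object), weights, weight_objs


def fit_model(genotypes: GenotypeDataset, annotation: AnnotationTable, Ytrain,
              covariates: CovariateTable | None = None, kind: str = "eb",
              shrink: ShrinkConfig | None = None, rho: float | None = None,
              use_covariates: bool = True, weight_override: float | None = None,
              correlation_override: np.ndarray | None = None) -> FittedModel:
    """Fit the full pipeline for one rule kind on the training replicates.

    ``Ytrain`` is (n, R_train) binary.  ``rho`` overrides the moment
    estimate; ``weight_override`` forces all WEB weights (testing hook);
    ``correlation_override`` replaces every JC 2x2 correlation block.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"kind must be one of {MODEL_KINDS}")
    shrink = shrink or ShrinkConfig()
    Ytrain = np.asarray(Ytrain)
    if Ytrain.ndim == 1:
        Ytrain = Ytrain[:, None]
    c_n = _mean_c_n(Ytrain)
    tau_nocov = _pooled_tau(Ytrain)

    cov_model = cov_part = None
    if use_covariates and covariates is not None:
        cov_model = fit_covariate_model(covariates, Ytrain)
        cov_part = cov_model.linear_predictor(covariates)

    extras: dict = {}
    if kind in ("eb", "web"):
        if kind == "eb":
            sm_all = madsen_browning_scores(genotypes, annotation, "all")
            X, gene_ids = sm_all.X, sm_all.gene_ids
        else:
            X, gene_ids, weights, weight_objs = _web_scores(
                genotypes, annotation, Ytrain, covariates, weight_override)
            extras = {"weights": weights, "weight_objects": weight_objs}
        ch = _fit_channel(X, gene_ids, Ytrain, shrink, rho)
        order = _rank_order(ch.delta_hat, ch.gene_ids)
        frame = pd.DataFrame(X, columns=gene_ids)
        Xk = frame[ch.gene_ids[order]].to_numpy(dtype=float)
        delta, center, scale = (ch.delta_hat[order], ch.center[order], ch.scale[order])
        contrib = delta[None, :] * c_n * (Xk - center[None, :]) / scale[None, :]
        return FittedModel(kind, ch.gene_ids[order], contrib, delta, center,
                           scale, c_n, tau_nocov, cov_model, cov_part, extras)

    # joint covariance: two channels, separate shrinkage populations
    return _fit_jc(genotypes, annotation, Ytrain, shrink, rho, c_n, tau_nocov,
                   cov_model, cov_part, correlation_override)


def _fit_jc(genotypes, annotation, Ytrain, shrink, rho, c_n, tau_nocov,
            cov_model, cov_part, correlation_override):
    fn, fs = _channel_frames(genotypes, annotation)
    ch_n = (_fit_channel(fn.to_numpy(dtype=float), fn.columns.to_numpy(object),
                         Ytrain, shrink, rho) if len(fn.columns) else None)
    ch_s = (_fit_channel(fs.to_numpy(dtype=float), fs.columns.to_numpy(object),
                         Ytrain, shrink, rho) if len(fs.columns) else None)
    if ch_n is None and ch_s is None:
        raise RuntimeError("no scorable genes in either functional class")
    dn = {} if ch_n is None else {g: i for i, g in enumerate(ch_n.gene_ids)}
    ds = {} if ch_s is None else {g: i for i, g in enumerate(ch_s.gene_ids)}
    genes = sorted(set(dn) | set(ds), key=str)

    # pooled labels for the within-class correlation (replicate-stacked)
    R = Ytrain.shape[1]
    y_stack = np.asarray(Ytrain).T.ravel()

    rows = []
    for g in genes:
        has_n, has_s = g in dn, g in ds
        delta = np.zeros(2)
        center = np.zeros(2)
        scale = np.ones(2)
        if has_n:
            i = dn[g]
            delta[0], center[0], scale[0] = ch_n.delta_hat[i], ch_n.center[i], ch_n.scale[i]
        if has_s:
            i = ds[g]
            delta[1], center[1], scale[1] = ch_s.delta_hat[i], ch_s.center[i], ch_s.scale[i]
        dual = has_n and has_s
        if dual:
            if correlation_override is not None:
                P = np.asarray(correlation_override, dtype=float)
            else:
                P = estimate_gene_correlation(_stack(fn[g].to_numpy(), R),
                                              _stack(fs[g].to_numpy(), R), y_stack)
            P_inv = np.linalg.inv(P)
        else:
            P_inv = np.eye(2)
        a = P_inv @ delta
        stat = float(delta @ P_inv @ delta)
        rows.append((g, dual, delta, center, scale, P_inv, a, stat))

    stats = np.array([r[7] for r in rows])
    keys = [str(r[0]) for r in rows]
    order = np.lexsort((keys, -stats))
    rows = [rows[i] for i in order]

    n = genotypes.n
    contrib = np.zeros((n, len(rows)))
    for k, (g, dual, delta, center, scale, P_inv, a, _) in enumerate(rows):
        un = (fn[g].to_numpy() - center[0]) / scale[0] if g in fn.columns else np.zeros(n)
        us = (fs[g].to_numpy() - center[1]) / scale[1] if g in fs.columns else np.zeros(n)
        contrib[:, k] = c_n * (a[0] * un + a[1] * us)

    extras = {
        "p_inv": np.stack([r[5] for r in rows]),
        "dual": np.array([r[1] for r in rows], dtype=bool),
        "channel_rho": (None if ch_n is None else ch_n.rho,
                        None if ch_s is None else ch_s.rho),
    }
    gene_ids = np.asarray([r[0] for r in rows], dtype=object)
    delta = np.stack([r[2] for r in rows])
    center = np.stack([r[3] for r in rows])
    scale = np.stack([r[4] for r in rows])
    return FittedModel("jc", gene_ids, contrib, delta, center, scale, c_n,
                       tau_nocov, cov_model, cov_part, extras)


# ---------------------------------------------------------------------------
# applying a serialized rule to (possibly new) data


def _score_frame(genotypes, annotation, class_filter):
    s = madsen_browning_scores(genotypes, annotation, class_filter)
    return s.to_frame()


def discriminant(rule: PredictionRule, genotypes: GenotypeDataset,
                 annotation: AnnotationTable,
                 covariates: CovariateTable | None = None) -> np.ndarray:
    """Decision value (gene part + covariate part) for each individual."""
    n = genotypes.n
    if rule.kind in ("eb", "web"):
        if rule.kind == "eb":
            frame = _score_frame(genotypes, annotation, "all")
        else:
            fn = _score_frame(genotypes, annotation, "nonsynonymous")
            fs = _score_frame(genotypes, annotation, "synonymous")
        gene_part = np.zeros(n)
        for k, g in enumerate(rule.gene_ids):
            if rule.kind == "eb":
                x = frame[g].to_numpy()
            else:
                w = rule.web_weights.get(str(g)) if rule.web_weights else None
                has_n, has_s = g in fn.columns, g in fs.columns
                if w is None:
                    x = fn[g].to_numpy() if has_n else fs[g].to_numpy()
                else:
                    x = weighted_score(fn[g].to_numpy(), fs[g].to_numpy(), w)
            gene_part += rule.delta_hat[k] * rule.c_n * (x - rule.center[k]) / rule.scale[k]
    else:
        fn = _score_frame(genotypes, annotation, "nonsynonymous")
        fs = _score_frame(genotypes, annotation, "synonymous")
        gene_part = np.zeros(n)
        for k, g in enumerate(rule.gene_ids):
            un = ((fn[g].to_numpy() - rule.center[k, 0]) / rule.scale[k, 0]
                  if g in fn.columns else np.zeros(n))
            us = ((fs[g].to_numpy() - rule.center[k, 1]) / rule.scale[k, 1]
                  if g in fs.columns else np.zeros(n))
            a = rule.jc_p_inv[k] @ rule.delta_hat[k]
            gene_part += rule.c_n * (a[0] * un + a[1] * us)
    if rule.covariate_model is not None:
        if covariates is None:
            raise ValueError("rule has a covariate model but no covariates given")
        gene_part = gene_part + rule.covariate_model.linear_predictor(covariates)
    return gene_part


def predict(rule: PredictionRule, genotypes: GenotypeDataset,
            annotation: AnnotationTable,
            covariates: CovariateTable | None = None):
    """Binary labels (case iff discriminant > tau) plus the continuous score."""
    d = discriminant(rule, genotypes, annotation, covariates)
    return (d > rule.tau).astype(np.int8), d
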