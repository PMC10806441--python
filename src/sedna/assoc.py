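"""Community-level association testing and per-taxon indicator detection.

A multivariate binomial/cloglog GLM in the manyglm tradition: every
taxon's presence/absence is fit against the same environmental design;
evidence is pooled across taxa into a community statistic and assessed
by resampling, giving distribution-free p-values that respect the
correlation among taxa.

Terms are tested sequentially (type-I style): the null model for term
k contains terms 1..k-1. Per-taxon signed statistics z_j (Wald
beta/se by default, score optional) are combined into

    W = sqrt( z' R(lambda)^-1 z ),

where R(lambda) = lambda I + (1 - lambda) R_hat is the among-taxon
correlation of the null model's Pearson residuals, shrunk
toward identity with the analytic Schafer-Strimmer intensity. At
lambda = 1 the squared statistic reduces to the plain sum of squared
per-taxon statistics.

The null distribution comes from PIT residual resampling: each taxon's
observed response is carried into uniform probability-integral
residuals under the null fit, rows are permuted jointly across taxa
(preserving among-taxon correlation), and pseudo-responses are
reconstructed from the null fitted probabilities. Per-taxon multiple
testing uses the Westfall-Young step-down maxT procedure on the same
resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage

from .glm import BatchGlmFit, fit_cloglog_batch, score_z, wald_z

_NORM_EPS = 1e-10


# ---------------------------------------------------------------------------
# presence matrix hygiene

def screen_presence(Y: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop taxa that are absent or present in every sample (their GLM
    fit is degenerate and carries no gradient information)."""
    arr = Y.to_numpy(dtype=bool)
    prev = arr.mean(axis=0)
    keep = (prev > 0) & (prev < 1)
    excluded = Y.columns[~keep].tolist()
    if excluded:
        warnings.warn(f"excluded {len(excluded)} degenerate taxa (prevalence 0 or 1)")
    return Y.loc[:, keep], excluded


# ---------------------------------------------------------------------------
# shrunk among-taxon correlation

def shrink_intensity(resid: np.ndarray) -> float:
    """Schafer-Strimmer analytic shrinkage intensity toward identity.

    lambda* = sum of estimated variances of the off-diagonal sample
    correlations over the sum of their squares, clipped to [0, 1].
    """
    n, m = resid.shape
    Xs = (resid - resid.mean(axis=0)) / (resid.std(axis=0, ddof=1) + _NORM_EPS)
    R = (Xs.T @ Xs) / (n - 1)
    W = np.einsum("ni,nj->nij", Xs, Xs) / 1.0
    wbar = W.mean(axis=0)
    var_r = (n / ((n - 1) ** 3)) * ((W - wbar) ** 2).sum(axis=0)
    off = ~np.eye(m, dtype=bool)
    denom = (R[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    lam = var_r[off].sum() / denom
    return float(np.clip(lam, 0.0, 1.0))


def shrunk_correlation(resid: np.ndarray, intensity: float | None = None) -> tuple[np.ndarray, float]:
    n, m = resid.shape
    Xs = (resid - resid.mean(axis=0)) / (resid.std(axis=0, ddof=1) + _NORM_EPS)
    R = (Xs.T @ Xs) / (n - 1)
    np.fill_diagonal(R, 1.0)
    lam = shrink_intensity(resid) if intensity is None else float(intensity)
    Rs = lam * np.eye(m) + (1.0 - lam) * R
    return Rs, lam


def _quadform_stat(z: np.ndarray, Rs: np.ndarray) -> float:
    """sqrt(z' Rs^-1 z) with a jitter fallback for ill conditioning."""
    try:
        sol = np.linalg.solve(Rs, z)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(Rs + 1e-8 * np.eye(len(z)), z)
    return float(np.sqrt(max(z @ sol, 0.0)))


# ---------------------------------------------------------------------------
# PIT residual resampling

def _pit_uniforms(Y: np.ndarray, mu0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomized probability-integral-transform residuals under the
    null: u ~ U(F(y-), F(y)) with F the Bernoulli(mu0) CDF; marginally
    U(0,1) when the null holds."""
    V = rng.random(Y.shape)
    f0 = 1.0 - mu0  # P(Y = 0)
    return np.where(Y > 0.5, f0 + V * mu0, V * f0)


def _reconstruct(u: np.ndarray, mu0: np.ndarray) -> np.ndarray:
    """Invert the PIT at the null fit: y* = 1{u > P(Y=0 | null)}."""
    return (u > 1.0 - mu0).astype(float)


def _pearson_resid(Y: np.ndarray, mu0: np.ndarray) -> np.ndarray:
    """Deterministic residuals for correlation estimation (randomized
    quantile residuals would make the observed statistic depend on the
    RNG and on row order)."""
    return (Y - mu0) / np.sqrt(mu0 * (1.0 - mu0))


def _observed_z(Yarr, X_null, X_full, fit_null, statistic, term_idx) -> tuple[np.ndarray, BatchGlmFit | None]:
    if statistic == "wald":
        fit_full = fit_cloglog_batch(Yarr, X_full)
        return wald_z(fit_full, term_idx), fit_full
    elif statistic == "score":
        return score_z(Yarr, X_full, fit_null, term_idx), None
    raise ValueError(f"unknown statistic {statistic!r}; use 'wald' or 'score'")


@dataclass
class AssociationResult:
    """Sequential community ANOVA plus per-taxon indicator statistics."""

    anova: pd.DataFrame                      # terms x [res_df, df, stat, p_value]
    per_taxon: dict[str, pd.DataFrame]       # term -> taxa x [z, stat, coef_sign, raw_p, adj_p]
    coefficients: pd.DataFrame               # taxa x (intercept + terms), full model
    taxa: list[str]
    excluded_taxa: list[str]
    n_resamples: int
    statistic: str
    shrink_intensities: dict[str, float]
    seed: int
    clusters: pd.Series | None = None

    def to_anova_tsv(self, path) -> None:
        out = self.anova.copy()
        out.index.name = "variable"
        out.to_csv(path, sep="\t")


def community_anova(Y: pd.DataFrame, X: pd.DataFrame,
                    term_order: list[str] | None = None,
                    n_resamples: int = 1000, seed: int = 0,
                    statistic: str = "wald",
                    shrink: float | None = None) -> AssociationResult:
    """Sequential resampling ANOVA for the community GLM.

    Parameters
    ----------
    Y
        samples x taxa presence/absence (bool or 0/1).
    X
        samples x covariates design, already centred/scaled; an
        intercept is added internally.
    term_order
        order in which covariates enter the sequential tests
        (default: X column order).
    n_resamples
        resampling draws B; p-values are (1 + #{W* >= W}) / (B + 1).
    statistic
        'wald' (default) or 'score'.
    shrink
        fixed shrinkage intensity in [0, 1], or None for the analytic
        Schafer-Strimmer estimate (1 = identity correlation, plain sum).
    """
    if n_resamples < 99:
        raise ValueError("n_resamples must be >= 99 for a meaningful p-value")
    terms = list(term_order or X.columns)
    missing = [t for t in terms if t not in X.columns]
    if missing:
        raise ValueError(f"terms not in design: {missing}")
    Y = Y.loc[X.index] if set(X.index) <= set(Y.index) else Y
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X disagree on samples")
    Yscr, excluded = screen_presence(Y)
    taxa = Yscr.columns.tolist()
    Yarr = Yscr.to_numpy(dtype=float)
    n, m = Yarr.shape

    ones = np.ones((n, 1))
    anova_rows = []
    per_taxon: dict[str, pd.DataFrame] = {}
    lams: dict[str, float] = {}

    for k, term in enumerate(terms, start=1):
        rng = np.random.default_rng([seed, k])
        X_null = np.column_stack([ones] + [X[t].to_numpy() for t in terms[:k - 1]])
        X_full = np.column_stack([X_null, X[term].to_numpy()])
        term_idx = X_full.shape[1] - 1

        fit_null = fit_cloglog_batch(Yarr, X_null)
        z_obs, fit_full = _observed_z(Yarr, X_null, X_full, fit_null, statistic, term_idx)

        resid = _pearson_resid(Yarr, fit_null.mu)
        Rs, lam = shrunk_correlation(resid, intensity=shrink)
        W_obs = _quadform_stat(z_obs, Rs)

        B = n_resamples
        W_null = np.empty(B)
        Z_null = np.empty((B, m))
        for b in range(B):
            perm = rng.permutation(n)
            u_b = _pit_uniforms(Yarr, fit_null.mu, rng)[perm]
            Yb = _reconstruct(u_b, fit_null.mu)
            degen = (Yb.min(axis=0) == Yb.max(axis=0))
            fit_null_b = fit_cloglog_batch(Yb, X_null)
            z_b, _ = _observed_z(Yb, X_null, X_full, fit_null_b, statistic, term_idx)
            z_b = np.where(degen, 0.0, z_b)
            Z_null[b] = z_b
            Rs_b, _ = shrunk_correlation(_pearson_resid(Yb, fit_null_b.mu), intensity=shrink)
            W_null[b] = _quadform_stat(z_b, Rs_b)

        p = (1.0 + np.sum(W_null >= W_obs - 1e-12)) / (B + 1.0)
        anova_rows.append({"res_df": n - 1 - k, "df": 1,
                           "stat": W_obs, "p_value": p})
        lams[term] = lam

        # per-taxon raw and Westfall-Young step-down adjusted p-values
        raw_p = (1.0 + (np.abs(Z_null) >= np.abs(z_obs)[None, :] - 1e-12).sum(axis=0)) / (B + 1.0)
        adj_p = _stepdown_adjust(np.abs(z_obs), np.abs(Z_null))
        coef_sign = np.sign(fit_full.coef[:, term_idx]) if fit_full is not None else np.sign(z_obs)
        per_taxon[term] = pd.DataFrame(
            {"z": z_obs, "stat": z_obs ** 2, "coef_sign": coef_sign,
             "raw_p": raw_p, "adj_p": adj_p},
            index=pd.Index(taxa, name="taxon"))

    # full-model coefficients for clustering / indicator signs
    X_all = np.column_stack([ones] + [X[t].to_numpy() for t in terms])
    fit_all = fit_cloglog_batch(Yarr, X_all)
    coefficients = pd.DataFrame(fit_all.coef, index=taxa, columns=["intercept"] + terms)

    anova = pd.DataFrame(anova_rows, index=pd.Index(terms, name="variable"))
    return AssociationResult(anova=anova, per_taxon=per_taxon,
                             coefficients=coefficients, taxa=taxa,
                             excluded_taxa=excluded, n_resamples=n_resamples,
                             statistic=statistic, shrink_intensities=lams, seed=seed)


# ---------------------------------------------------------------------------
# Westfall-Young step-down maxT

def _stepdown_adjust(t_obs: np.ndarray, T_null: np.ndarray) -> np.ndarray:
    """Step-down maxT adjusted p-values.

    ``t_obs``: (m,) observed |statistics|; ``T_null``: (B, m) resampled
    |statistics| under the null. Taxa are ranked by decreasing observed
    statistic; the adjusted p at rank r uses the resampled maximum over
    taxa ranked >= r, with monotonicity enforced by a running maximum.
    """
    B, m = T_null.shape
    order = np.argsort(-t_obs, kind="stable")
    T_sorted = T_null[:, order]
    # suffix maxima over ranks r..m-1 for every resample
    suffix_max = np.maximum.accumulate(T_sorted[:, ::-1], axis=1)[:, ::-1]
    p_sorted = (1.0 + (suffix_max >= t_obs[order][None, :] - 1e-12).sum(axis=0)) / (B + 1.0)
    p_sorted = np.maximum.accumulate(p_sorted)
    adj = np.empty(m)
    adj[order] = p_sorted
    return adj


def per_taxon_stepdown(Y: pd.DataFrame, X: pd.DataFrame, term: str,
                       covariates: list[str] | None = None,
                       n_resamples: int = 1000, seed: int = 0,
                       statistic: str = "wald") -> pd.DataFrame:
    """Step-down adjusted per-taxon p-values for one term.

    The null model contains all covariates except ``term`` when
    ``covariates`` is given (default: ``term`` tested against an
    intercept-only null). Returns taxa x [z, raw_p, adj_p].
    """
    Yscr, _ = screen_presence(Y)
    taxa = Yscr.columns.tolist()
    Yarr = Yscr.to_numpy(dtype=float)
    n, m = Yarr.shape
    rng = np.random.default_rng([seed, 104729])

    nuis = [c for c in (covariates or []) if c != term]
    X_null = np.column_stack([np.ones((n, 1))] + [X[c].to_numpy() for c in nuis])
    X_full = np.column_stack([X_null, X[term].to_numpy()])
    term_idx = X_full.shape[1] - 1

    fit_null = fit_cloglog_batch(Yarr, X_null)
    z_obs, _ = _observed_z(Yarr, X_null, X_full, fit_null, statistic, term_idx)

    B = n_resamples
    Z_null = np.empty((B, m))
    for b in range(B):
        perm = rng.permutation(n)
        u_b = _pit_uniforms(Yarr, fit_null.mu, rng)[perm]
        Yb = _reconstruct(u_b, fit_null.mu)
        degen = (Yb.min(axis=0) == Yb.max(axis=0))
        fit_null_b = fit_cloglog_batch(Yb, X_null)
        z_b, _ = _observed_z(Yb, X_null, X_full, fit_null_b, statistic, term_idx)
        Z_null[b] = np.where(degen, 0.0, z_b)

    raw_p = (1.0 + (np.abs(Z_null) >= np.abs(z_obs)[None, :] - 1e-12).sum(axis=0)) / (B + 1.0)
    adj_p = _stepdown_adjust(np.abs(z_obs), np.abs(Z_null))
    return pd.DataFrame({"z": z_obs, "raw_p": raw_p, "adj_p": adj_p},
                        index=pd.Index(taxa, name="taxon"))


# ---------------------------------------------------------------------------
# coefficient clustering and indicator report

def cluster_taxa_by_coefficients(coefficients: pd.DataFrame,
                                 n_clusters: int | None = None,
                                 cut_height: float | None = None
                                 ) -> tuple[pd.Series, list[str]]:
    """Hierarchical (average-linkage, Euclidean) clustering of taxa by
    their coefficient vectors; returns labels and dendrogram leaf order."""
    if coefficients.shape[0] < 2:
        raise ValueError("need at least two taxa to cluster")
    Z = linkage(coefficients.to_numpy(dtype=float), method="average", metric="euclidean")
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        h = cut_height if cut_height is not None else 0.7 * Z[:, 2].max()
        labels = fcluster(Z, t=h, criterion="distance")
    leaves = dendrogram(Z, no_plot=True)["leaves"]
    order = [coefficients.index[i] for i in leaves]
    return pd.Series(labels, index=coefficients.index, name="cluster"), order


def _genus_label(otu_key: str) -> str:
    """Truncate a ';'-joined lineage key to genus (rank 6 of 7)."""
    parts = otu_key.split(";")
    if len(parts) >= 6:
        trimmed = [p for p in parts[:6] if p]
        return ";".join(trimmed) if trimmed else otu_key
    return otu_key


def indicator_report(result: AssociationResult, p_screen: float = 0.10,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Taxa with adjusted p below ``p_screen`` for at least one term.

    One row per (taxon, term) pair passing the screen, with statistic
    magnitude, coefficient sign, a significance flag at ``alpha`` (on
    the step-down adjusted p), and taxonomy truncated to genus.
    """
    rows = []
    screened = {t for t, df in result.per_taxon.items()}
    passing = set()
    for term in screened:
        df = result.per_taxon[term]
        passing |= set(df.index[df["adj_p"] < p_screen])
    for taxon in result.taxa:
        if taxon not in passing:
            continue
        for term, df in result.per_taxon.items():
            row = df.loc[taxon]
            rows.append({
                "taxon": _genus_label(str(taxon)),
                "taxon_key": taxon,
                "term": term,
                "stat": float(row["stat"]),
                "coef_sign": int(row["coef_sign"]),
                "adj_p": float(row["adj_p"]),
                "significant": bool(row["adj_p"] < alpha),
            })
    cols = ["taxon", "taxon_key", "term", "stat", "coef_sign", "adj_p", "significant"]
    return pd.DataFrame(rows, columns=cols)
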