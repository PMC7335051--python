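"""Expression variability and dispersion traits.

Within-sample variability is the coefficient of variation (CV = sd/mean) of
the gated log-scale fluorescence values. Because CV co-varies with mean
expression, dispersion is quantified as CV|mean: the residual of a lowess
regression of CV on mean fitted over all samples of a protein. Bimodal
proteins are additionally described by a two-component Gaussian mixture
(p1, mu1, mu2, sigma1^2, sigma2^2 with mu1 <= mu2), averaged per line,
z-scored and clustered by complete linkage.

Note: CV is computed on log-scale intensities, matching the processing order
of the gating pipeline (whose output FL is a log intensity). The CV of logs
is not the CV of raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import logsumexp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import EventTable, SampleSummary

__all__ = [
    "sample_summary",
    "summarize_samples",
    "CvMeanTrend",
    "fit_cv_mean_trend",
    "dispersion_residuals",
    "GaussianMixture2",
    "Gmm2Fit",
    "fit_gmm2",
    "line_average",
    "LineClusterResult",
    "cluster_lines",
    "kruskal_wallis",
    "spearman_pairs",
    "ttest_pair",
]


def sample_summary(fl: np.ndarray, meta: dict | None = None) -> SampleSummary:
    """Mean, SD (n-1 denominator) and CV = sd/mean of one sample's FL values."""
    fl = np.asarray(fl, dtype=float)
    if fl.size < 2:
        raise ValueError("need at least two cells")
    if not np.isfinite(fl).all():
        raise ValueError("non-finite fluorescence values")
    mean = float(fl.mean())
    if mean <= 0:
        raise ValueError("mean log intensity must be positive for CV to be meaningful")
    sd = float(fl.std(ddof=1))
    meta = meta or {}
    return SampleSummary(
        sample_id=meta.get("sample_id", ""),
        line_id=meta.get("line_id", ""),
        protein=meta.get("protein", ""),
        n_cells=fl.size,
        mean=mean,
        sd=sd,
        cv=sd / mean,
        K=meta.get("K", float("nan")),
        outlier=meta.get("outlier", False),
    )


def summarize_samples(
    tables: Sequence[EventTable],
    k_scores: dict[str, float] | None = None,
    outliers: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-sample summary table for a list of gated event tables."""
    k_scores = k_scores or {}
    outliers = outliers or {}
    rows = []
    for t in tables:
        meta = t.meta()
        meta["K"] = k_scores.get(t.sample_id, float("nan"))
        meta["outlier"] = outliers.get(t.sample_id, False)
        rows.append(sample_summary(t.channel("FL"), meta).as_dict())
    return pd.DataFrame(rows)


class CvMeanTrend:
    """Fitted lowess trend of CV on mean expression for one protein scope.

    Evaluation interpolates linearly between the fitted points and clamps to
    the nearest endpoint outside the fitted mean range (extrapolation is
    flagged by :func:`dispersion_residuals`).
    """

    def __init__(self, means: np.ndarray, fitted: np.ndarray, span: float, protein: str):
        order = np.argsort(means)
        self.means = np.asarray(means, dtype=float)[order]
        self.fitted = np.asarray(fitted, dtype=float)[order]
        self.span = span
        self.protein = protein

    @classmethod
    def fit(
        cls,
        means: np.ndarray,
        cvs: np.ndarray,
        span: float = 0.75,
        robust_iters: int = 3,
        protein: str = "",
    ) -> "CvMeanTrend":
        means = np.asarray(means, dtype=float)
        cvs = np.asarray(cvs, dtype=float)
        if means.size < 10:
            raise ValueError("need at least 10 samples to fit a CV~mean trend")
        smoothed = lowess(cvs, means, frac=span, it=robust_iters, return_sorted=True)
        return cls(smoothed[:, 0], smoothed[:, 1], span=span, protein=protein)

    def predict(self, mean) -> np.ndarray:
        return np.interp(np.asarray(mean, dtype=float), self.means, self.fitted)

    def in_range(self, mean) -> np.ndarray:
        m = np.asarray(mean, dtype=float)
        return (m >= self.means[0]) & (m <= self.means[-1])


def fit_cv_mean_trend(summaries: pd.DataFrame, protein: str | None = None) -> CvMeanTrend:
    """Lowess CV~mean trend over all (non-outlier) samples of one protein."""
    sub = summaries
    if protein is not None:
        sub = sub[sub["protein"] == protein]
    if "outlier" in sub.columns:
        sub = sub[~sub["outlier"].astype(bool)]
    return CvMeanTrend.fit(
        sub["mean"].to_numpy(), sub["cv"].to_numpy(), protein=protein or ""
    )


def dispersion_residuals(summaries: pd.DataFrame, trend: CvMeanTrend) -> pd.DataFrame:
    """Attach CV|mean = observed CV minus the trend's prediction at the mean.

    Means outside the fitted range use nearest-endpoint extrapolation and are
    flagged in the ``extrapolated`` column.
    """
    out = summaries.copy()
    means = out["mean"].to_numpy(dtype=float)
    out["cv_given_mean"] = out["cv"].to_numpy(dtype=float) - trend.predict(means)
    out["extrapolated"] = ~trend.in_range(means)
    return out


@dataclass
class Gmm2Fit:
    """Five-parameter two-component Gaussian mixture, labelled mu1 <= mu2."""

    p1: float
    mu1: float
    mu2: float
    var1: float
    var2: float
    loglik: float
    converged: bool
    n_iter: int = 0

    @property
    def sigma1(self) -> float:
        return float(np.sqrt(self.var1))

    @property
    def sigma2(self) -> float:
        return float(np.sqrt(self.var2))

    def mean(self) -> float:
        """Marginal mean of the mixture."""
        return self.p1 * self.mu1 + (1 - self.p1) * self.mu2

    def variance(self) -> float:
        """Marginal variance of the mixture."""
        m = self.mean()
        return (
            self.p1 * (self.var1 + (self.mu1 - m) ** 2)
            + (1 - self.p1) * (self.var2 + (self.mu2 - m) ** 2)
        )

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.p1 * stats.norm.pdf(x, self.mu1, self.sigma1) + (
            1 - self.p1
        ) * stats.norm.pdf(x, self.mu2, self.sigma2)

    def params(self) -> dict:
        return {
            "p1": self.p1, "mu1": self.mu1, "mu2": self.mu2,
            "sigma1": self.sigma1, "sigma2": self.sigma2,
        }

    def summary(self) -> pd.Series:
        return pd.Series({**self.params(), "loglik": self.loglik, "converged": self.converged})


class GaussianMixture2:
    """EM fit of an unconstrained univariate two-component Gaussian mixture.

    The fit runs a deterministic quantile-split initialisation (components
    seeded from the halves below/above the median) plus ``n_restarts`` random
    initialisations, keeping the best log-likelihood. A variance floor of
    ``1e-6 * var(data)`` blocks the degenerate single-point solutions;
    restarts that collapse onto the floor with a non-finite likelihood are
    discarded.
    """

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        if self.data.size < 100:
            raise ValueError("need at least 100 observations")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite observations")
        if self.data.std() == 0:
            raise ValueError("constant data cannot be fitted")

    def _em(
        self, p1: float, mu: np.ndarray, var: np.ndarray, tol: float, max_iter: int
    ) -> Gmm2Fit | None:
        x = self.data
        n = x.size
        floor = 1e-6 * x.var()
        w = np.array([p1, 1.0 - p1])
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            logpdf = (
                -0.5 * np.log(2 * np.pi * var)[None, :]
                - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
                + np.log(w)[None, :]
            )
            norm = logsumexp(logpdf, axis=1)
            loglik = float(norm.sum())
            resp = np.exp(logpdf - norm[:, None])
            nk = resp.sum(axis=0)
            if (nk < 1e-10).any():
                return None
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            var = np.maximum(var, floor)
            if not np.isfinite(loglik):
                return None
            if abs(loglik - prev) < tol * (abs(loglik) + 1e-12):
                converged = True
                prev = loglik
                break
            prev = loglik
        order = np.argsort(mu)
        w, mu, var = w[order], mu[order], var[order]
        return Gmm2Fit(
            p1=float(w[0]), mu1=float(mu[0]), mu2=float(mu[1]),
            var1=float(var[0]), var2=float(var[1]),
            loglik=float(prev), converged=converged, n_iter=it,
        )

    def _initialisations(self, seed: int, n_restarts: int):
        x = self.data
        median = np.median(x)
        lo, hi = x[x <= median], x[x > median]
        inits = [
            (
                lo.size / x.size,
                np.array([lo.mean(), hi.mean()]),
                np.array([max(lo.var(), 1e-3 * x.var()), max(hi.var(), 1e-3 * x.var())]),
            )
        ]
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            mu = rng.choice(x, size=2, replace=False)
            inits.append((0.5, np.sort(mu.astype(float)), np.full(2, x.var())))
        return inits

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 5,
        tol: float = 1e-8,
        max_iter: int = 500,
    ) -> Gmm2Fit:
        best: Gmm2Fit | None = None
        for p1, mu, var in self._initialisations(seed, n_restarts):
            fit = self._em(p1, mu.copy(), var.copy(), tol=tol, max_iter=max_iter)
            if fit is None:
                continue
            if best is None or fit.loglik > best.loglik:
                best = fit
        if best is None:
            raise RuntimeError("all EM restarts degenerated")
        return best


def fit_gmm2(fl: np.ndarray, seed: int = 0, **kwargs) -> Gmm2Fit:
    """Fit the five-parameter mixture to one sample's expression values."""
    return GaussianMixture2(fl).fit(seed=seed, **kwargs)


def line_average(
    per_sample: pd.DataFrame, value_cols: Sequence[str] | None = None
) -> pd.DataFrame:
    """Average replicate-level statistics per line, with s.e.m. columns.

    Outlier-flagged samples are excluded; lines with no retained samples drop
    out of the result.
    """
    df = per_sample
    if "outlier" in df.columns:
        df = df[~df["outlier"].astype(bool)]
    if value_cols is None:
        value_cols = [
            c for c in df.columns
            if c not in {"sample_id", "line_id", "protein", "replicate",
                         "replicate_index", "batch_id", "outlier", "extrapolated"}
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    grouped = df.groupby("line_id")
    out = grouped[list(value_cols)].mean()
    sem = grouped[list(value_cols)].sem(ddof=1)
    for c in value_cols:
        out[f"{c}_sem"] = sem[c]
    out["n_replicates"] = grouped.size()
    return out


@dataclass
class LineClusterResult:
    """Complete-linkage clustering of lines on z-scored parameters."""

    scaled: pd.DataFrame
    linkage_matrix: np.ndarray
    labels: pd.Series
    k: int

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def cluster_lines(
    param_table: pd.DataFrame, k: int, drop_constant: bool = False
) -> LineClusterResult:
    """Z-score each parameter across lines, then cut a complete-linkage tree.

    ``param_table`` is lines x parameters (no missing values). Scaling uses
    the n-1 SD convention; a constant column raises unless ``drop_constant``.
    """
    if param_table.isna().any().any():
        raise ValueError("parameter table contains missing values")
    if len(param_table) < k:
        raise ValueError("fewer lines than requested clusters")
    sds = param_table.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        if not drop_constant:
            raise ValueError(f"constant parameter columns: {constant}")
        param_table = param_table.drop(columns=constant)
        sds = sds.drop(constant)
    scaled = (param_table - param_table.mean()) / sds
    Z = hierarchy.linkage(scaled.to_numpy(), method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return LineClusterResult(
        scaled=scaled,
        linkage_matrix=Z,
        labels=pd.Series(labels, index=param_table.index, name="cluster"),
        k=k,
    )


def kruskal_wallis(values_by_line: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p on groups-1 df."""
    groups = [np.asarray(g, dtype=float) for g in values_by_line]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def spearman_pairs(
    dispersion_by_protein: pd.DataFrame, min_lines: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (and two-sided p) of per-line dispersion.

    ``dispersion_by_protein`` is lines x proteins of per-line averaged
    CV|mean. Pairs with fewer than ``min_lines`` jointly measured lines are
    left NaN.
    """
    proteins = list(dispersion_by_protein.columns)
    rho = pd.DataFrame(np.nan, index=proteins, columns=proteins)
    pval = pd.DataFrame(np.nan, index=proteins, columns=proteins)
    for i, a in enumerate(proteins):
        rho.loc[a, a], pval.loc[a, a] = 1.0, 0.0
        for b in proteins[i + 1 :]:
            pair = dispersion_by_protein[[a, b]].dropna()
            if len(pair) < min_lines:
                continue
            r, p = stats.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def ttest_pair(reps_a: np.ndarray, reps_b: np.ndarray, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test on replicate-level statistics (Welch default)."""
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per line")
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
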