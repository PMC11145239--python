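"""Differential expression with precision weights and moderated t-statistics.

The pipeline is the classical precision-weighted linear-model analysis of
RNA-seq counts, implemented from first principles:

1. ``log2cpm`` — log2 counts-per-million with a small prior count to avoid
   log of zero: ``log2((count + c) / (library + 2c) * 1e6)`` with c = 0.5.
2. ``voom_transform`` — fit each gene's unweighted linear model, regress the
   quarter-root residual standard deviation on average log2 count with a
   lowess smoother, and convert the fitted trend into per-observation
   precision weights (trend value to the power -4). Low counts are noisy on
   the log scale, so low-expression observations receive small weights.
3. ``fit_moderated`` — weighted least squares per gene; the coefficient of
   the group indicator is the log2 fold change (positive = higher in the
   HV/MV group than in the -V reference).
4. ``ebayes_moderate`` — empirical-Bayes shrinkage of the gene-wise residual
   variances toward a common prior (moment-matching a scaled F on the log
   variances), yielding moderated t-statistics with augmented degrees of
   freedom.
5. ``bh_adjust`` — Benjamini-Hochberg step-up FDR adjustment.

``run_dge`` chains the steps for one contrast (HV vs -V or MV vs -V) and
extracts the signature: genes with q below alpha, tagged "over" when the
log fold change is positive and "under" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .cohort import Cohort, CountMatrix, GROUP_HV, GROUP_MV, GROUP_UNKNOWN
from .errors import ConfigurationError, DataError, ModelError
from .filtering import ExpressionMatrix

CONTRAST_HV = "HV_vs_minusV"
CONTRAST_MV = "MV_vs_minusV"

_MIN_TREND_SD = 1e-3  # floor for the fitted quarter-root sd, keeps weights finite


@dataclass
class DesignInfo:
    """Two-group design with an optional continuous age covariate.

    ``group`` is the 0/1 indicator of the vascularity cohort being contrasted
    against the reference (-V) cohort; the intercept is implicit.
    """

    group: np.ndarray
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        if set(np.unique(self.group)) - {0.0, 1.0}:
            raise ConfigurationError("group indicator must be 0/1")
        if (self.group == 1).sum() < 2 or (self.group == 0).sum() < 2:
            raise ModelError("each cohort of the contrast needs >= 2 samples")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if self.age.shape != self.group.shape:
                raise ConfigurationError("age and group must have equal length")
            if not np.isfinite(self.age).all():
                raise DataError("non-finite age in design")

    @property
    def matrix(self) -> np.ndarray:
        cols = [np.ones_like(self.group), self.group]
        if self.age is not None:
            cols.append(self.age)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ModelError("design matrix is collinear")
        return X

    #: column index of the group (logFC) coefficient
    coef_index: int = 1


@dataclass
class VoomFit:
    logcpm: ExpressionMatrix  # log2cpm scale
    weights: np.ndarray  # (n_genes, n_samples), > 0
    trend_x: np.ndarray  # lowess curve: average log2 count
    trend_y: np.ndarray  # lowess curve: sqrt(residual sd)

    def trend(self, x) -> np.ndarray:
        """Evaluate the fitted mean-variance trend, clamped at the curve ends."""
        y = np.interp(x, self.trend_x, self.trend_y)
        return np.maximum(y, _MIN_TREND_SD)


@dataclass
class GeneFits:
    """Per-gene weighted least-squares summaries."""

    gene_ids: list[str]
    coef: np.ndarray  # group coefficient = logFC
    stderr: np.ndarray  # sampling std error of coef
    stdev_unscaled: np.ndarray  # stderr / sigma
    sigma2: np.ndarray  # weighted residual variance
    df_resid: int
    avg_log2cpm: np.ndarray


@dataclass
class EBayesResult:
    moderated_t: np.ndarray
    p_value: np.ndarray
    df_prior: float
    var_prior: float
    var_post: np.ndarray
    df_total: np.ndarray


@dataclass(frozen=True)
class Signature:
    """Gene set with per-gene direction defining the score system."""

    entries: tuple[tuple[str, str], ...]  # (gene_id, "over" | "under")
    contrast: str

    def __post_init__(self) -> None:
        for gid, direction in self.entries:
            if direction not in ("over", "under"):
                raise ConfigurationError(
                    f"signature direction for {gid!r} must be over/under"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def directions(self) -> dict[str, str]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_id", "direction"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, contrast: str) -> "Signature":
        return cls(
            entries=tuple(zip(df["gene_id"].astype(str), df["direction"])),
            contrast=contrast,
        )


def log2cpm(counts: CountMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with prior count damping.

    ``log2((count + c) / (library_size + 2c) * 1e6)``; the library size is
    the full-gene-set depth carried by the count matrix.
    """
    lib = np.asarray(counts.library_size, dtype=float)
    if (lib <= 0).any():
        raise DataError("zero library size")
    values = np.log2(
        (counts.counts + prior_count) / (lib + 2 * prior_count)[np.newaxis, :] * 1e6
    )
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        scale="log2cpm",
    )


def voom_transform(
    counts: CountMatrix,
    design: DesignInfo,
    prior_count: float = 0.5,
    lowess_span: float = 0.5,
) -> VoomFit:
    """Learn the mean-variance trend and per-observation precision weights.

    Residual standard deviations from unweighted gene-wise fits are regressed
    (quarter-root scale) on average log2 count with a lowess smoother; each
    observation's weight is the inverse fourth power of the trend evaluated
    at its fitted log2 count.
    """
    if counts.n_genes < 10:
        raise ModelError("voom needs at least 10 genes to fit a trend")
    X = design.matrix
    n, p = X.shape
    if n != counts.n_samples:
        raise ConfigurationError("design rows do not match sample count")
    if n - p < 1:
        raise ModelError("no residual degrees of freedom")

    expr = log2cpm(counts, prior_count=prior_count)
    Y = expr.values  # (G, n)
    lib = np.asarray(counts.library_size, dtype=float)

    # unweighted per-gene fits (shared design -> one pseudoinverse)
    pinv = np.linalg.pinv(X)  # (p, n)
    beta = Y @ pinv.T  # (G, p)
    fitted = beta @ X.T  # (G, n)
    resid = Y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))

    # average log2 count of each gene (shift log2cpm back to the count scale)
    mean_log2_lib = np.mean(np.log2(lib + 2 * prior_count))
    sx = Y.mean(axis=1) + mean_log2_lib - np.log2(1e6)
    sy = np.sqrt(sigma)

    smoothed = sm_lowess(sy, sx, frac=lowess_span, it=3, return_sorted=True)
    trend_x, trend_y = smoothed[:, 0], np.maximum(smoothed[:, 1], _MIN_TREND_SD)
    # collapse duplicate x for interpolation
    trend_x, uniq = np.unique(trend_x, return_index=True)
    trend_y = trend_y[uniq]

    fitted_logcount = fitted + (np.log2(lib + 2 * prior_count) - np.log2(1e6))[
        np.newaxis, :
    ]
    trend_at = np.interp(fitted_logcount, trend_x, trend_y)
    trend_at = np.maximum(trend_at, _MIN_TREND_SD)
    weights = trend_at**-4.0
    if not np.isfinite(weights).all() or (weights <= 0).any():
        raise ModelError("non-finite or non-positive voom weights")
    return VoomFit(logcpm=expr, weights=weights, trend_x=trend_x, trend_y=trend_y)


def fit_moderated(voomfit: VoomFit, design: DesignInfo) -> GeneFits:
    """Per-gene weighted least squares; the group coefficient is the logFC."""
    X = design.matrix
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ModelError("residual degrees of freedom must be >= 1")
    Y = voomfit.logcpm.values
    W = voomfit.weights
    k = design.coef_index

    # batched normal equations: A_g = X' diag(w_g) X, b_g = X' diag(w_g) y_g
    A = np.einsum("gs,si,sj->gij", W, X, X)
    b = np.einsum("gs,si,gs->gi", W, X, Y)
    try:
        beta = np.linalg.solve(A, b[..., np.newaxis])[..., 0]
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ModelError("singular weighted design") from exc
    resid = Y - beta @ X.T
    rss = (W * resid**2).sum(axis=1)
    sigma2 = rss / df
    unscaled2 = Ainv[:, k, k]
    stderr = np.sqrt(sigma2 * unscaled2)
    return GeneFits(
        gene_ids=list(voomfit.logcpm.gene_ids),
        coef=beta[:, k],
        stderr=stderr,
        stdev_unscaled=np.sqrt(unscaled2),
        sigma2=sigma2,
        df_resid=df,
        avg_log2cpm=Y.mean(axis=1),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def ebayes_moderate(fits: GeneFits, min_var: float = 1e-12) -> EBayesResult:
    """Empirical-Bayes variance shrinkage and moderated t-statistics.

    The prior degrees of freedom d0 and prior variance s0^2 are estimated by
    moment-matching a scaled F distribution on the log residual variances.
    Posterior variances are the precision-weighted blend
    ``(d0 s0^2 + df s_g^2) / (d0 + df)``; when the gene-wise variances are
    (numerically) identical, d0 diverges and every posterior collapses to
    s0^2 — the documented full-shrinkage limit.
    """
    if len(fits.gene_ids) < 2:
        raise ModelError("empirical Bayes needs >= 2 genes")
    df = float(fits.df_resid)
    s2 = np.maximum(fits.sigma2, min_var)

    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    evar_excess = evar - float(special.polygamma(1, df / 2.0))
    if evar_excess > 0:
        df_prior = 2.0 * _trigamma_inverse(evar_excess)
        var_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
        var_post = (df_prior * var_prior + df * s2) / (df_prior + df)
        df_total = np.full_like(s2, df + df_prior)
    else:
        # no excess spread beyond chi-square sampling noise: infinite prior df,
        # every posterior collapses to the common variance
        df_prior = np.inf
        var_prior = float(s2.mean())
        var_post = np.full_like(s2, var_prior)
        df_total = np.full_like(s2, np.inf)

    t = fits.coef / (np.sqrt(var_post) * fits.stdev_unscaled)
    finite = np.isfinite(df_total)
    p = np.empty_like(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df_total[finite])
    p[~finite] = 2.0 * stats.norm.sf(np.abs(t[~finite]))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return EBayesResult(
        moderated_t=t,
        p_value=p,
        df_prior=float(df_prior),
        var_prior=var_prior,
        var_post=var_post,
        df_total=df_total,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_dge(
    cohort: Cohort,
    contrast: str = CONTRAST_HV,
    alpha: float = 0.01,
    gene_ids: Sequence[str] | None = None,
    include_age: bool = True,
    prior_count: float = 0.5,
    lowess_span: float = 0.5,
) -> tuple[pd.DataFrame, Signature]:
    """Full DE pipeline for one contrast against the -V reference group.

    Returns the per-gene result table (logFC, avg_log2cpm, moderated_t,
    p_value, q_value, significant, neg_log10_q) in the input gene order and
    the significant-gene Signature (direction from the logFC sign). Samples
    from the group not named by the contrast are excluded. ``gene_ids``
    restricts the analysis (typically the keyword + CPM filtered set);
    library sizes remain those of the full matrix.
    """
    if contrast not in (CONTRAST_HV, CONTRAST_MV):
        raise ConfigurationError(f"unknown contrast {contrast!r}")
    target = GROUP_HV if contrast == CONTRAST_HV else GROUP_MV
    groups = {p.patient_id: p.vascular_group for p in cohort.patients}
    if any(g is None for g in groups.values()):
        raise ConfigurationError(
            "vascular groups not assigned; run assign_vascular_groups first"
        )
    keep = [
        s for s in cohort.counts.sample_ids if groups[s] in (target, GROUP_UNKNOWN)
    ]
    indicator = np.array([1.0 if groups[s] == target else 0.0 for s in keep])
    if indicator.sum() == 0:
        raise ConfigurationError(f"contrast group {target} is empty")
    if (indicator == 0).sum() == 0:
        raise ConfigurationError("reference (-V) group is empty")

    counts = cohort.counts.subset_samples(keep)
    if gene_ids is not None:
        counts = counts.subset_genes(gene_ids)
    age = None
    if include_age:
        by_id = {p.patient_id: p.age for p in cohort.patients}
        age = np.array([by_id[s] for s in keep])
        if np.isnan(age).any():
            raise DataError("missing age for a sample in the contrast")
    design = DesignInfo(group=indicator, age=age)

    voomfit = voom_transform(
        counts, design, prior_count=prior_count, lowess_span=lowess_span
    )
    fits = fit_moderated(voomfit, design)
    eb = ebayes_moderate(fits)
    q = bh_adjust(eb.p_value)
    table = pd.DataFrame(
        {
            "gene_id": fits.gene_ids,
            "logFC": fits.coef,
            "avg_log2cpm": fits.avg_log2cpm,
            "moderated_t": eb.moderated_t,
            "p_value": eb.p_value,
            "q_value": q,
            "significant": q < alpha,
        }
    )
    table["neg_log10_q"] = -np.log10(table["q_value"])
    sig = table[table["significant"]]
    entries = tuple(
        (gid, "over" if lfc > 0 else "under")
        for gid, lfc in zip(sig["gene_id"], sig["logFC"])
    )
    return table, Signature(entries=entries, contrast=contrast)
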