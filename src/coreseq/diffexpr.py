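"""Differential expression: CPM filtering, TMM, precision weights, moderated t.

The combined cross-species design is fit as gene-wise weighted linear models
on log2-CPM with mean-variance precision weights, residual variances are
shrunk toward an empirical-Bayes prior (scaled inverse-chi-square, fitted by
moment-matching log variances with digamma/trigamma inversion), and named
contrasts — per-species day contrasts and the species-by-time interaction,
the difference of the two species' pairwise day contrasts — are tested with
moderated t-statistics and Benjamini-Hochberg FDR control.

Design matrices use group-means (cell-means) coding, one indicator column
per species-by-day group, so every contrast is an explicit coefficient
vector over group labels like ``A_d7``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from ._util import ParameterError, logger
from .quantify import CountMatrix, SampleInfo


@dataclass
class DesignMatrix:
    matrix: np.ndarray            # samples x groups indicators
    labels: list[str]             # column labels, e.g. "A_d7"
    samples: list[SampleInfo]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.samples), len(self.labels)):
            raise ValueError("design dimensions inconsistent")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")


def group_means_design(samples: list[SampleInfo]) -> DesignMatrix:
    """One indicator column per (species, day) cell, labelled ``{sp}_d{day}``."""
    cells = sorted({(s.species, s.day) for s in samples})
    labels = [f"{sp}_d{d}" for sp, d in cells]
    X = np.zeros((len(samples), len(cells)))
    for i, s in enumerate(samples):
        X[i, cells.index((s.species, s.day))] = 1.0
    return DesignMatrix(matrix=X, labels=labels, samples=samples)


def contrast_vector(design: DesignMatrix, plus: list[str], minus: list[str]) -> np.ndarray:
    """Coefficient vector +1 on ``plus`` labels and -1 on ``minus`` labels."""
    c = np.zeros(len(design.labels))
    for lab in plus:
        c[design.labels.index(lab)] += 1.0
    for lab in minus:
        c[design.labels.index(lab)] -= 1.0
    return c


def interaction_contrast(design: DesignMatrix, species_a: str, species_b: str,
                         day: int, baseline_day: int = 0) -> np.ndarray:
    """(A_day - A_base) - (B_day - B_base): difference of pairwise contrasts."""
    return contrast_vector(
        design,
        plus=[f"{species_a}_d{day}", f"{species_b}_d{baseline_day}"],
        minus=[f"{species_a}_d{baseline_day}", f"{species_b}_d{day}"],
    )


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_low_expression(counts: CountMatrix, min_cpm: float = 10.0,
                          min_samples: int = 3) -> CountMatrix:
    """Require a CPM floor, judged against the average library size.

    A gene is kept when at least ``min_samples`` samples carry
    ``min_cpm * mean(library size) / 1e6`` or more counts (the study's rule:
    >= 10 CPM based on the average library size, in three samples; four for
    the deeper-replicated per se design).
    """
    if min_samples > len(counts.samples):
        raise ParameterError("min_samples exceeds the number of samples")
    lib = counts.library_sizes()
    thr = min_cpm * lib.mean() / 1e6
    ok = (counts.counts >= thr).sum(axis=1) >= min_samples
    if not ok.any():
        logger.warning("expression filter removed every gene")
    genes = [g for g, k in zip(counts.genes, ok) if k]
    return CountMatrix(genes=genes, samples=counts.samples, counts=counts.counts[ok])


@dataclass
class NormFactors:
    factors: np.ndarray        # per-sample TMM scaling, geometric mean 1
    lib_sizes: np.ndarray

    def effective_lib_sizes(self) -> np.ndarray:
        return self.factors * self.lib_sizes


def tmm_factors(counts: CountMatrix, logratio_trim: float = 0.3,
                sum_trim: float = 0.05, a_cutoff: float = -1e10) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile. Per sample, genes zero in either sample or
    reference are excluded; log-ratios (M) and abundances (A) are doubly
    trimmed (30% on M, 5% on A by default) and the factor is two to the
    precision-weighted mean of the surviving M values, with factors rescaled
    to geometric mean one.
    """
    X = counts.counts.astype(float)
    if X.shape[1] < 2:
        raise ParameterError("TMM needs at least two samples")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ParameterError("sample with zero total counts")
    uq = np.array([np.quantile(X[:, j][X[:, j] > 0] / lib[j], 0.75) if (X[:, j] > 0).any()
                   else 0.0 for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    r, R = X[:, ref], lib[ref]

    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref:
            continue
        x, N = X[:, j], lib[j]
        use = (x > 0) & (r > 0)
        if not use.any():
            logger.warning("sample %s shares no expressed genes with reference; factor 1",
                           counts.sample_ids[j])
            continue
        xs, rs = x[use], r[use]
        M = np.log2((xs / N) / (rs / R))
        A = 0.5 * np.log2((xs / N) * (rs / R))
        keep = np.isfinite(M) & np.isfinite(A) & (A > a_cutoff)
        M, A = M[keep], A[keep]
        xs, rs = xs[keep], rs[keep]
        n = len(M)
        if n == 0:
            continue
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - np.floor(n * sum_trim)
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any():
            continue
        w = (N - xs[sel]) / (N * xs[sel]) + (R - rs[sel]) / (R * rs[sel])
        f = np.sum(M[sel] / w) / np.sum(1.0 / w)
        if not np.isfinite(f):
            f = 0.0
        factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(factors=factors, lib_sizes=lib)


# ---------------------------------------------------------------------------
# precision weights


@dataclass
class VoomFit:
    logcpm: np.ndarray          # genes x samples, log2 CPM with offsets
    weights: np.ndarray         # genes x samples inverse predicted variances
    trend_x: np.ndarray         # lowess knots: mean log2 count
    trend_y: np.ndarray         # lowess values: sqrt residual sd
    design: DesignMatrix
    genes: list[str]

    def __post_init__(self):
        if (self.weights <= 0).any():
            raise ValueError("precision weights must be strictly positive")


def voom_transform(counts: CountMatrix, design: DesignMatrix, factors: NormFactors,
                   span: float = 0.5, weight_floor: float = 1e-6) -> VoomFit:
    """Log2-CPM with mean-variance precision weights.

    logCPM = log2((count + 0.5) / (effective library size + 1) * 1e6). A
    first-pass unweighted fit on the design provides residual standard
    deviations; a lowess of sqrt(sd) on mean log2 count gives the
    mean-variance trend, and the weight of each observation is the predicted
    trend value at its fitted log2 count, raised to the -4th power (inverse
    predicted variance), floored at ``weight_floor``.
    """
    X = design.matrix
    n, p = X.shape
    if counts.counts.shape[1] != n:
        raise ValueError("counts and design sample dimensions differ")
    if n <= p:
        raise ParameterError("no residual degrees of freedom")
    lib_eff = factors.effective_lib_sizes()
    Y = np.log2((counts.counts + 0.5) / (lib_eff + 1.0) * 1e6)

    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T
    fitted = beta @ X.T
    resid = Y - fitted
    dg = n - p
    sigma = np.sqrt((resid**2).sum(axis=1) / dg)

    # mean-variance trend in log2-count units
    sx = Y.mean(axis=1) + np.mean(np.log2(lib_eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=span, return_sorted=True)
    lo_x, lo_y = lo[:, 0], lo[:, 1]

    fitted_count = fitted + (np.log2(lib_eff + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_count, lo_x, lo_y)  # clamped at both ends
    w = np.clip(pred, 1e-12, None) ** -4
    w = np.clip(w, weight_floor, None)
    return VoomFit(logcpm=Y, weights=w, trend_x=lo_x, trend_y=lo_y,
                   design=design, genes=list(counts.genes))


# ---------------------------------------------------------------------------
# gene-wise WLS + empirical Bayes


@dataclass
class ModeratedFits:
    beta: np.ndarray            # genes x coefficients
    cov_unscaled: np.ndarray    # genes x p x p, (X'WX)^-1
    sigma2: np.ndarray          # residual variances s_g^2
    df_residual: float          # d_g
    d0: float                   # prior df (may be inf)
    s0_sq: float                # prior variance
    sigma2_post: np.ndarray     # posterior (moderated) variances
    design: DesignMatrix = None
    genes: list[str] = field(default_factory=list)
    amean: np.ndarray = None    # mean logCPM per gene


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/y (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _fit_inverse_chisq_prior(sigma2: np.ndarray, dg: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to gene variances.

    Under s_g^2 ~ s_0^2 * F(d_g, d_0), log s_g^2 has mean
    log s_0^2 + psi(d_g/2) - log(d_g/2) - psi(d_0/2) + log(d_0/2) and excess
    variance psi'(d_0/2) beyond psi'(d_g/2); digamma/trigamma inversion
    recovers (d_0, s_0^2). All-equal variances give d_0 = inf.
    """
    z = np.log(np.maximum(sigma2, 1e-300))
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    n = len(z)
    if n < 2 or np.allclose(z, z[0]):
        return np.inf, float(np.exp(e.mean()))
    evar = e.var(ddof=1) - special.polygamma(1, dg / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    half_d0 = trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def fit_and_moderate(voom: VoomFit, design: DesignMatrix | None = None,
                     d0_override: float | None = None) -> ModeratedFits:
    """Gene-wise weighted least squares with empirical-Bayes variance shrinkage.

    Per gene: beta = (X'WX)^-1 X'Wy, s_g^2 from weighted residuals with
    d_g = n - p df. The prior (d_0, s_0^2) is fitted across genes and the
    posterior variance is the df-weighted blend
    (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g). ``d0_override`` pins the prior df
    (0 recovers ordinary t; inf fully pools).
    """
    design = design or voom.design
    X = design.matrix
    n, p = X.shape
    Y, W = voom.logcpm, voom.weights
    G = Y.shape[0]
    dg = float(n - p)
    if dg < 1:
        raise ParameterError("at least one residual degree of freedom required")

    XtWX = np.einsum("sp,gs,sq->gpq", X, W, X)
    XtWy = np.einsum("sp,gs,gs->gp", X, W, Y)
    cov = np.linalg.inv(XtWX)
    beta = np.einsum("gpq,gq->gp", cov, XtWy)
    resid = Y - beta @ X.T
    sigma2 = np.einsum("gs,gs->g", W, resid**2) / dg

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = _fit_inverse_chisq_prior(sigma2, dg)
        if d0 == 0:
            s0_sq = float(np.mean(sigma2))
    else:
        d0, s0_sq = _fit_inverse_chisq_prior(sigma2, dg)

    if np.isinf(d0):
        sigma2_post = np.full(G, s0_sq)
    else:
        sigma2_post = (d0 * s0_sq + dg * sigma2) / (d0 + dg)
    return ModeratedFits(beta=beta, cov_unscaled=cov, sigma2=sigma2, df_residual=dg,
                         d0=d0, s0_sq=s0_sq, sigma2_post=sigma2_post, design=design,
                         genes=list(voom.genes), amean=Y.mean(axis=1))


@dataclass
class DEResult:
    genes: list[str]
    logfc: np.ndarray
    ave_expr: np.ndarray
    t: np.ndarray
    p: np.ndarray
    fdr: np.ndarray
    df_total: float
    d0: float
    s0_sq: float
    df_residual: float
    sigma: np.ndarray
    contrast: np.ndarray = None


def apply_contrast(fits: ModeratedFits, contrast: np.ndarray) -> DEResult:
    """Moderated t-test of a coefficient contrast.

    logFC = c'beta; t = logFC / (s_post * sqrt(c' (X'WX)^-1 c)); two-sided p
    from t on d_0 + d_g degrees of freedom.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fits.beta.shape[1],):
        raise ValueError("contrast length must equal the number of design columns")
    if not c.any():
        raise ValueError("contrast vector is identically zero")
    logfc = fits.beta @ c
    var_unscaled = np.einsum("p,gpq,q->g", c, fits.cov_unscaled, c)
    se = np.sqrt(fits.sigma2_post * var_unscaled)
    t = logfc / se
    df = fits.d0 + fits.df_residual
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    fdr = bh_adjust(p)
    return DEResult(genes=list(fits.genes), logfc=logfc, ave_expr=fits.amean,
                    t=t, p=p, fdr=fdr, df_total=df, d0=fits.d0, s0_sq=fits.s0_sq,
                    df_residual=fits.df_residual, sigma=np.sqrt(fits.sigma2),
                    contrast=c)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_table(result: DEResult, annotations: dict[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """Tabulate a contrast, sorted by p-value.

    FC is the signed linear fold change: 2^|logFC| carrying the sign of
    logFC, so logFC of -1 prints as -2. ``annotations`` optionally maps gene
    id to (symbol, description).
    """
    fc = np.sign(result.logfc) * 2.0 ** np.abs(result.logfc)
    fc[result.logfc == 0] = 1.0
    ann = annotations or {}
    sym = [ann.get(g, (g, ""))[0] for g in result.genes]
    name = [ann.get(g, (g, ""))[1] for g in result.genes]
    df = pd.DataFrame(
        dict(FC=fc, gene_symbol=sym, gene_name=name, FDR=result.fdr,
             logFC=result.logfc, AveExpr=result.ave_expr, t=result.t, P=result.p),
        index=pd.Index(result.genes, name="gene"),
    )
    return df.sort_values("P", kind="mergesort")


def run_de(counts: CountMatrix, contrasts: dict[str, np.ndarray] | None = None,
           min_cpm: float = 10.0, min_samples: int = 3,
           ) -> tuple[dict[str, DEResult], ModeratedFits, VoomFit]:
    """Convenience pipeline: filter -> TMM -> precision weights -> moderated t.

    Without an explicit contrast dict, builds the standard set from the
    sample design: per-species day-vs-day-0 contrasts and, when two species
    are present, the species-by-time interaction per later day.
    """
    filtered = filter_low_expression(counts, min_cpm=min_cpm, min_samples=min_samples)
    design = group_means_design(filtered.samples)
    factors = tmm_factors(filtered)
    voom = voom_transform(filtered, design, factors)
    fits = fit_and_moderate(voom)
    if contrasts is None:
        contrasts = standard_contrasts(design)
    results = {name: apply_contrast(fits, c) for name, c in contrasts.items()}
    return results, fits, voom


def standard_contrasts(design: DesignMatrix) -> dict[str, np.ndarray]:
    species = sorted({s.species for s in design.samples})
    days = sorted({s.day for s in design.samples})
    out: dict[str, np.ndarray] = {}
    for sp in species:
        for d in days:
            if d == 0:
                continue
            out[f"{sp}_d{d}_vs_d0"] = contrast_vector(
                design, plus=[f"{sp}_d{d}"], minus=[f"{sp}_d0"])
    if len(species) == 2:
        a, b = species
        for d in days:
            if d == 0:
                continue
            out[f"interaction_d{d}_vs_d0"] = interaction_contrast(design, a, b, d)
    return out


__all__ = [
    "DesignMatrix", "group_means_design", "contrast_vector", "interaction_contrast",
    "filter_low_expression", "NormFactors", "tmm_factors", "VoomFit",
    "voom_transform", "ModeratedFits", "fit_and_moderate", "DEResult",
    "apply_contrast", "bh_adjust", "de_table", "run_de", "standard_contrasts",
    "trigamma_inverse",
]
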