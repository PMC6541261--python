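"""Spearman co-expression networks with scale-free/small-world thresholding.

A threshold on |Spearman rho| turns the gene correlation matrix into a
graph. Rather than fixing the cutoff, a descending grid is scanned and each
candidate graph is scored for scale-free topology (least-squares fit of the
log degree distribution, exponent expected in (1, 3) with a good R^2) and
small-world topology (clustering above, mean path length at or below, the
Erdos-Renyi baselines of equal size and mean degree); the lowest passing
threshold is selected so that the most genes stay in the network.

Because the least-squares check is not a statistically sound test of a
power-law degree distribution, the module also provides a discrete maximum
likelihood fit (Hurwitz-zeta normalization, KS-minimizing tail cutoff) with
a semi-parametric bootstrap goodness-of-fit p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import zeta

from ._util import ParameterError, logger, rng_from_seed


# ---------------------------------------------------------------------------
# correlation and graph construction


def spearman_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman correlation of a genes x samples matrix.

    Ranks (ties averaged) are taken within each gene across samples and
    correlated with Pearson. Genes with zero rank variance (constant across
    samples) get correlation 0 with everything, logged; the diagonal is 1.
    """
    if expr.shape[1] < 3:
        raise ParameterError("need at least 3 samples for rank correlation")
    if expr.isna().any().any():
        raise ParameterError("expression matrix contains missing values")
    ranks = expr.rank(axis=1).to_numpy()
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant genes: correlations set to 0", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=expr.index, columns=expr.index)


@dataclass
class Network:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()], dtype=np.int64)

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\trho\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d.get('rho', float('nan')):.6f}\n")


def network_at_threshold(corr: pd.DataFrame, tau: float, absolute: bool = True) -> Network:
    """Graph with an edge wherever |rho| >= tau (or rho >= tau when signed).

    Genes without a single qualifying partner are excluded from the node set
    (they are "unused" at this threshold).
    """
    if not (0.0 < tau <= 1.0):
        raise ParameterError("tau must lie in (0, 1]")
    M = corr.to_numpy()
    vals = np.abs(M) if absolute else M
    iu, ju = np.triu_indices_from(vals, k=1)
    hit = vals[iu, ju] >= tau
    names = corr.index.to_numpy()
    g = nx.Graph()
    g.add_edges_from(
        (names[i], names[j], {"rho": M[i, j]})
        for i, j in zip(iu[hit], ju[hit])
    )
    return Network(graph=g, threshold=tau)


# ---------------------------------------------------------------------------
# topology diagnostics


def degree_loglog_fit(degrees: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of log p_k on log k over observed degrees.

    Returns (a, c, R^2) where a is the negated slope, so a scale-free graph
    is expected to give a in (1, 3). Requires >= 3 distinct degree values.
    """
    degrees = np.asarray(degrees)
    if (degrees <= 0).any():
        raise ParameterError("degrees must be positive (drop isolated nodes first)")
    k, counts = np.unique(degrees, return_counts=True)
    if len(k) < 3:
        raise ParameterError("need at least 3 distinct degree values for a log-log fit")
    pk = counts / counts.sum()
    res = stats.linregress(np.log(k), np.log(pk))
    return float(-res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class SmallWorldStats:
    mean_cc: float
    mean_path: float
    cc_rand: float
    path_rand: float
    mean_degree: float
    path_rand_defined: bool = True


def smallworld_stats(net: Network) -> SmallWorldStats:
    """Clustering and path length against Erdos-Renyi baselines.

    MeanCC averages the local clustering coefficient over all nodes (degree
    < 2 contributes 0); MeanPath averages shortest-path lengths over
    connected pairs in the largest component. Baselines for a random graph
    of equal n and mean degree kbar: CC_rand = kbar/n, Path_rand =
    ln(n)/ln(kbar) (undefined when kbar <= 1, flagged).
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ParameterError("network is empty")
    mean_cc = float(np.mean(list(nx.clustering(g).values())))
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    mean_path = (nx.average_shortest_path_length(sub)
                 if sub.number_of_nodes() > 1 else 0.0)
    kbar = 2.0 * g.number_of_edges() / n
    cc_rand = kbar / n
    if kbar > 1.0:
        path_rand = float(np.log(n) / np.log(kbar))
        defined = True
    else:
        path_rand = float("nan")
        defined = False
    return SmallWorldStats(mean_cc=mean_cc, mean_path=float(mean_path),
                           cc_rand=cc_rand, path_rand=path_rand,
                           mean_degree=kbar, path_rand_defined=defined)


# ---------------------------------------------------------------------------
# threshold selection


@dataclass
class ThresholdCriteria:
    slope_range: tuple[float, float] = (1.0, 3.0)
    r2_min: float = 0.80
    cc_ratio: float = 2.0      # MeanCC must be >= cc_ratio * CC_rand
    path_ratio: float = 1.0    # MeanPath must be <= path_ratio * Path_rand
    prefer: str = "lowest"     # lowest passing threshold keeps the most genes


REPORT_COLUMNS = ["threshold", "R2", "slope", "MeanCC", "MeanPath",
                  "CC_rand", "Path_rand", "pct_used", "pct_big_comp", "passed"]


@dataclass
class ThresholdReport:
    table: pd.DataFrame
    tau_star: float | None
    status: str

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_grid(start: float = 0.99, stop: float = 0.70, step: float = 0.002) -> np.ndarray:
    """Descending candidate thresholds; the default covers 0.914 exactly."""
    n = int(round((start - stop) / step)) + 1
    return np.round(start - step * np.arange(n), 10)


def select_threshold(
    corr: pd.DataFrame,
    grid: np.ndarray | None = None,
    criteria: ThresholdCriteria | None = None,
    absolute: bool = True,
) -> tuple[float | None, ThresholdReport]:
    """Scan a threshold grid for scale-free, small-world graphs.

    Every grid point is scored; a point passes when the degree-distribution
    exponent lies in ``slope_range`` with R^2 >= ``r2_min``, MeanCC >=
    ``cc_ratio`` * CC_rand, and MeanPath <= ``path_ratio`` * Path_rand. The
    selected threshold is the lowest passing one (configurable to highest),
    maximizing the share of genes kept. The full per-threshold report is
    always returned; with no passing point tau* is None and the status says
    so.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if ((grid <= 0) | (grid >= 1)).any():
        raise ParameterError("grid thresholds must lie in (0, 1)")
    criteria = criteria or ThresholdCriteria()
    n_input = corr.shape[0]
    rows = []
    passing = []
    for tau in grid:
        net = network_at_threshold(corr, float(tau), absolute=absolute)
        n_nodes = net.graph.number_of_nodes()
        row = dict(threshold=float(tau), R2=np.nan, slope=np.nan, MeanCC=np.nan,
                   MeanPath=np.nan, CC_rand=np.nan, Path_rand=np.nan,
                   pct_used=100.0 * n_nodes / n_input, pct_big_comp=np.nan,
                   passed=False)
        if n_nodes >= 3:
            sw = smallworld_stats(net)
            big = max(nx.connected_components(net.graph), key=len)
            row.update(MeanCC=sw.mean_cc, MeanPath=sw.mean_path, CC_rand=sw.cc_rand,
                       Path_rand=sw.path_rand,
                       pct_big_comp=100.0 * len(big) / n_nodes)
            try:
                a, _c, r2 = degree_loglog_fit(net.degrees())
                row.update(slope=a, R2=r2)
            except ParameterError:
                a, r2 = np.nan, np.nan
            lo, hi = criteria.slope_range
            ok = (
                np.isfinite(a) and lo < a < hi
                and np.isfinite(r2) and r2 >= criteria.r2_min
                and sw.mean_cc >= criteria.cc_ratio * sw.cc_rand
                and sw.path_rand_defined
                and sw.mean_path <= criteria.path_ratio * sw.path_rand
            )
            row["passed"] = bool(ok)
            if ok:
                passing.append(float(tau))
        rows.append(row)
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if passing:
        tau_star = min(passing) if criteria.prefer == "lowest" else max(passing)
        status = "ok"
    else:
        tau_star, status = None, "no threshold satisfied the scale-free/small-world criteria"
    return tau_star, ThresholdReport(table=table, tau_star=tau_star, status=status)


# ---------------------------------------------------------------------------
# discrete power-law MLE + bootstrap goodness of fit


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    n_tail: int
    ks: float
    C: float                       # normalization constant 1/zeta(alpha, xmin)
    p_value: float | None = None
    n_boot: int = 0
    boot_alpha: np.ndarray | None = None
    boot_xmin: np.ndarray | None = None
    boot_ks: np.ndarray | None = None
    alpha_ci: tuple[float, float] | None = None
    xmin_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = dict(alpha=self.alpha, xmin=int(self.xmin), n_tail=int(self.n_tail),
                 ks=self.ks, C=self.C, p_value=self.p_value, n_boot=self.n_boot)
        if self.alpha_ci:
            d["alpha_ci"] = list(self.alpha_ci)
        if self.xmin_ci:
            d["xmin_ci"] = list(self.xmin_ci)
        return d


def _mle_alpha(tail: np.ndarray, xmin: int) -> float:
    """Maximize the zeta-normalized discrete power-law likelihood."""
    n = len(tail)
    slog = np.log(tail).sum()

    def nll(alpha: float) -> float:
        return n * np.log(zeta(alpha, xmin)) + alpha * slog

    res = optimize.minimize_scalar(nll, bounds=(1.001, 25.0), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """Max CDF distance between the tail empirical and fitted distributions."""
    n = len(tail)
    k = np.unique(tail)
    ecdf = np.searchsorted(np.sort(tail), k, side="right") / n
    Z = zeta(alpha, xmin)
    model = 1.0 - zeta(alpha, k + 1.0) / Z
    return float(np.max(np.abs(ecdf - model)))


def powerlaw_mle(
    degrees: np.ndarray,
    xmin: int | None = None,
    min_tail: int = 10,
    max_xmin_candidates: int = 80,
) -> PowerLawFit:
    """Discrete power-law fit with KS-selected tail cutoff.

    With ``xmin`` free, every distinct value leaving at least ``min_tail``
    tail observations is a candidate (thinned evenly to at most
    ``max_xmin_candidates``); the cutoff minimizing the KS distance between
    the tail empirical CDF and the fitted law wins, with alpha estimated by
    numeric MLE under the Hurwitz-zeta likelihood at each candidate.
    """
    x = np.asarray(degrees, dtype=np.int64)
    x = x[x >= 1]
    if xmin is not None:
        tail = x[x >= xmin]
        if len(tail) < 2:
            raise ParameterError("degenerate tail above the fixed xmin")
        alpha = _mle_alpha(tail, xmin)
        ks = _ks_distance(tail, alpha, xmin)
        return PowerLawFit(alpha=alpha, xmin=int(xmin), n_tail=len(tail), ks=ks,
                           C=1.0 / zeta(alpha, xmin))
    if len(x) < min_tail:
        raise ParameterError(f"need at least {min_tail} positive observations")
    uniq = np.unique(x)
    xs = np.sort(x)
    tail_sizes = len(xs) - np.searchsorted(xs, uniq, side="left")
    cand = uniq[tail_sizes >= min_tail]
    if len(cand) == 0:
        raise ParameterError("no xmin candidate leaves enough tail observations")
    if len(cand) > max_xmin_candidates:
        idx = np.unique(np.linspace(0, len(cand) - 1, max_xmin_candidates).astype(int))
        cand = cand[idx]
    best: PowerLawFit | None = None
    for xm in cand:
        tail = xs[np.searchsorted(xs, xm, side="left"):]
        alpha = _mle_alpha(tail, int(xm))
        ks = _ks_distance(tail, alpha, int(xm))
        if best is None or ks < best.ks:
            best = PowerLawFit(alpha=alpha, xmin=int(xm), n_tail=len(tail), ks=ks,
                               C=1.0 / zeta(alpha, int(xm)))
    return best


def powerlaw_bootstrap(
    degrees: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    min_tail: int = 10,
    max_xmin_candidates: int = 80,
) -> PowerLawFit:
    """Semi-parametric bootstrap goodness-of-fit for the power-law tail.

    Each replicate draws n values: with probability n_below/n an empirical
    resample of the below-xmin data, otherwise a draw from the fitted law;
    the full fit (free xmin) is repeated and its KS recorded. The p-value is
    the fraction of replicate KS statistics at or above the observed one;
    95% percentile intervals for alpha and xmin come from the replicates.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    from .simulate import simulate_powerlaw_degrees

    x = np.asarray(degrees, dtype=np.int64)
    x = x[x >= 1]
    obs = powerlaw_mle(x, min_tail=min_tail, max_xmin_candidates=max_xmin_candidates)
    rng = rng_from_seed(seed)
    below = x[x < obs.xmin]
    n = len(x)
    p_below = len(below) / n

    b_alpha = np.empty(n_boot)
    b_xmin = np.empty(n_boot, dtype=np.int64)
    b_ks = np.empty(n_boot)
    for b in range(n_boot):
        n_lo = int(rng.binomial(n, p_below)) if p_below > 0 else 0
        parts = []
        if n_lo:
            parts.append(rng.choice(below, size=n_lo, replace=True))
        if n - n_lo:
            sub = int(rng.integers(0, 2**31 - 1))
            parts.append(simulate_powerlaw_degrees(obs.alpha, obs.xmin, n - n_lo, seed=sub))
        sample = np.concatenate(parts)
        try:
            fit = powerlaw_mle(sample, min_tail=min_tail,
                               max_xmin_candidates=max_xmin_candidates)
        except ParameterError:
            fit = powerlaw_mle(sample, xmin=obs.xmin)
        b_alpha[b], b_xmin[b], b_ks[b] = fit.alpha, fit.xmin, fit.ks

    p = float(np.mean(b_ks >= obs.ks))
    return PowerLawFit(
        alpha=obs.alpha, xmin=obs.xmin, n_tail=obs.n_tail, ks=obs.ks, C=obs.C,
        p_value=p, n_boot=n_boot, boot_alpha=b_alpha, boot_xmin=b_xmin, boot_ks=b_ks,
        alpha_ci=(float(np.percentile(b_alpha, 2.5)), float(np.percentile(b_alpha, 97.5))),
        xmin_ci=(float(np.percentile(b_xmin, 2.5)), float(np.percentile(b_xmin, 97.5))),
    )


__all__ = [
    "spearman_matrix", "Network", "network_at_threshold", "degree_loglog_fit",
    "SmallWorldStats", "smallworld_stats", "ThresholdCriteria", "ThresholdReport",
    "REPORT_COLUMNS", "default_grid", "select_threshold", "PowerLawFit",
    "powerlaw_mle", "powerlaw_bootstrap",
]
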