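"""Regulator/target-centered subnetworks and factor-plot summaries.

Given gene lists exported from a pathway analysis (transcriptional
regulators and their downstream targets), each listed gene present in the
thresholded co-expression network becomes the center of a star-closure
subnetwork: the center plus its direct neighbors that are themselves listed,
with all induced edges. Symbol matching is case-insensitive because gene
symbol casing differs between species conventions (Dmd vs DMD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import FormatError
from .coexpression import Network
from .quantify import SampleInfo


@dataclass
class RegulatorSet:
    genes: set[str]                       # uppercased symbols
    roles: dict[str, set[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError("regulator/target set is empty")
        self.genes = {g.upper() for g in self.genes}

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes


def load_regulator_targets(
    paths,
    symbol_column: str = "symbol",
    roles: list[str] | None = None,
) -> RegulatorSet:
    """Union gene symbols from one or more TSV exports.

    Each file needs a ``symbol_column``; an optional per-file role label
    ("regulator"/"target") annotates its genes. Duplicates (including
    case-variant duplicates) collapse to one entry.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    roles = roles or [""] * len(paths)
    genes: set[str] = set()
    role_map: dict[str, set[str]] = {}
    for path, role in zip(paths, roles):
        df = pd.read_csv(path, sep="\t")
        if symbol_column not in df.columns:
            raise FormatError(f"{path}: missing required column '{symbol_column}'")
        for sym in df[symbol_column].dropna().astype(str):
            up = sym.upper()
            genes.add(up)
            if role:
                role_map.setdefault(up, set()).add(role)
    return RegulatorSet(genes=genes, roles=role_map,
                        source=";".join(str(p) for p in paths))


@dataclass
class Subnetwork:
    center: str
    members: list[str]
    edges: list[tuple[str, str]]
    flagged: bool = False          # meets the minimum-size cutoff

    @property
    def size(self) -> int:
        return len(self.members)


def extract_subnetwork(net: Network, center: str, allowed: RegulatorSet) -> Subnetwork:
    """Star-closure subnetwork: the center plus its allowed direct neighbors.

    Members are the center and every neighbor whose symbol is in ``allowed``
    (case-insensitive); edges are all parent-network edges among members, so
    every non-center member is adjacent to the center by construction.
    """
    g = net.graph
    lookup = {str(n).upper(): n for n in g.nodes}
    node = lookup.get(center.upper())
    if node is None:
        raise KeyError(f"center gene {center!r} is not in the network")
    members = [node] + sorted(nb for nb in g.neighbors(node) if str(nb) in allowed)
    mset = set(members)
    edges = sorted(
        (u, v) for u, v in g.edges(mset) if u in mset and v in mset
    )
    return Subnetwork(center=node, members=members, edges=edges)


def enumerate_subnetworks(net: Network, allowed: RegulatorSet,
                          min_size: int = 10) -> list[Subnetwork]:
    """One subnetwork per allowed gene present in the network.

    Sorted by size descending (then by center for determinism); those with
    ``min_size`` or more members are flagged as of particular interest.
    """
    out = []
    for node in net.graph.nodes:
        if str(node) in allowed:
            sn = extract_subnetwork(net, str(node), allowed)
            sn.flagged = sn.size >= min_size
            out.append(sn)
    return sorted(out, key=lambda s: (-s.size, s.center))


@dataclass
class FactorPlotData:
    table: pd.DataFrame    # gene, species, day, mean, ci_half, ci_lo, ci_hi, n

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def factor_plot_data(expr: pd.DataFrame, genes: list[str],
                     samples: list[SampleInfo]) -> FactorPlotData:
    """Group means of log2(expression + 1) with 95% t-based intervals.

    ``expr`` holds natural-scale expression (genes x samples, columns
    matching sample ids). Per gene and (species, day) cell: mean of
    log2(x + 1), with CI half-width t(0.975, n-1) * s / sqrt(n). Cells with
    a single sample get an undefined (NaN) interval and are flagged via n.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    ids = [s.sample_id for s in samples]
    sub = np.log2(expr.loc[genes, ids].to_numpy(dtype=float) + 1.0)
    groups: dict[tuple[str, int], list[int]] = {}
    for j, s in enumerate(samples):
        groups.setdefault((s.species, s.day), []).append(j)
    rows = []
    for gi, gene in enumerate(genes):
        for (sp, day), idx in sorted(groups.items()):
            vals = sub[gi, idx]
            n = len(vals)
            m = float(vals.mean())
            if n >= 2:
                half = float(stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n))
            else:
                half = float("nan")
            rows.append(dict(gene=gene, species=sp, day=day, mean=m, ci_half=half,
                             ci_lo=m - half, ci_hi=m + half, n=n))
    return FactorPlotData(table=pd.DataFrame(rows))


def plot_factor_lines(data: FactorPlotData, ax=None):
    """Line plot of group means with CI bars, one line per gene and species."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    for (gene, sp), gdf in data.table.groupby(["gene", "species"]):
        gdf = gdf.sort_values("day")
        ax.errorbar(gdf["day"], gdf["mean"], yerr=gdf["ci_half"],
                    label=f"{gene} ({sp})", capsize=3, marker="o")
    ax.set_xlabel("day")
    ax.set_ylabel("mean log2(expression + 1)")
    ax.legend(fontsize="small")
    return ax


__all__ = [
    "RegulatorSet", "load_regulator_targets", "Subnetwork", "extract_subnetwork",
    "enumerate_subnetworks", "FactorPlotData", "factor_plot_data", "plot_factor_lines",
]
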