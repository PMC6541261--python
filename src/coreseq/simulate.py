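"""Synthetic data generators for every pipeline input.

Each generator is a pure function of its parameters and a seed, and records
its ground truth in a :class:`SimTruth` so downstream stages can be checked
against known answers: divergent ortholog pairs with multi-HSP alignments,
negative-binomial count matrices with species-by-time interaction effects,
planted co-expression modules, and discrete power-law degree samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import zeta

from ._util import ParameterError, child_seed, rng_from_seed

BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset.

    ortholog_pairs : true (species A gene id, species B gene id) pairs
    isoforms       : gene id -> list of (transcript id, length in bp),
                     covering both species' genes
    de_genes       : gene id -> planted interaction log2 fold change
                     (0 for non-DE genes)
    network_edges  : gene id pairs planted as co-expressed
    seed           : seed the dataset was generated from
    """

    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    isoforms: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    network_edges: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    # planted per-gene expected counts keyed "species:day" (count fixtures only)
    group_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def transcript_to_gene(self) -> dict[str, str]:
        return {tid: g for g, isos in self.isoforms.items() for tid, _ in isos}

    def transcript_lengths(self) -> dict[str, int]:
        return {tid: ln for isos in self.isoforms.values() for tid, ln in isos}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["isoforms"] = {g: [list(t) for t in v] for g, v in self.isoforms.items()}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            ortholog_pairs=[tuple(p) for p in d["ortholog_pairs"]],
            isoforms={g: [(t, int(ln)) for t, ln in v] for g, v in d["isoforms"].items()},
            de_genes={g: float(x) for g, x in d["de_genes"].items()},
            network_edges=[tuple(p) for p in d["network_edges"]],
            seed=int(d["seed"]),
            group_means=d.get("group_means", {}),
        )


# ---------------------------------------------------------------------------
# transcriptomes


def simulate_ortholog_transcriptomes(
    n_genes: int,
    isoforms_per_gene: tuple[int, int] = (1, 3),
    mean_len: int = 1000,
    divergence: float = 0.05,
    indel_rate: float = 0.0,
    seed: int = 0,
):
    """Simulate a de novo assembly (species A) and a reference (species B).

    Each gene has one ancestral sequence. Species B emits it verbatim as a
    single reference transcript; species A emits 1..k isoform copies carrying
    substitutions at the given per-base rate (replacement base drawn uniformly
    from all four, so back-substitution occurs at rate 1/4) and optional
    single-base indels. Returns (records_A, records_B, truth) where records
    are lists of (id, sequence) tuples.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if not (0.0 <= divergence < 0.3):
        raise ParameterError("divergence must lie in [0, 0.3)")
    if not (0.0 <= indel_rate < 0.1):
        raise ParameterError("indel_rate must lie in [0, 0.1)")
    lo, hi = isoforms_per_gene
    if lo < 1 or hi < lo:
        raise ParameterError("isoforms_per_gene must be (lo, hi) with 1 <= lo <= hi")

    rng = rng_from_seed(seed)
    records_a: list[tuple[str, str]] = []
    records_b: list[tuple[str, str]] = []
    truth = SimTruth(seed=seed)

    for g in range(1, n_genes + 1):
        length = int(rng.integers(max(200, mean_len // 2), mean_len * 3 // 2 + 1))
        ancestral = rng.choice(BASES, size=length)
        gene_a = f"SIM_DN{g}_c0_g1"
        tid_b = f"NM_{g:06d}.1"
        records_b.append((tid_b, "".join(ancestral)))
        truth.isoforms[tid_b] = [(tid_b, length)]

        n_iso = int(rng.integers(lo, hi + 1))
        iso_list = []
        for k in range(1, n_iso + 1):
            seq = ancestral.copy()
            hit = rng.random(length) < divergence
            if hit.any():
                seq[hit] = rng.choice(BASES, size=int(hit.sum()))
            seq = _apply_indels(seq, indel_rate, rng)
            tid = f"{gene_a}_i{k}"
            records_a.append((tid, "".join(seq)))
            iso_list.append((tid, len(seq)))
        truth.isoforms[gene_a] = iso_list
        truth.ortholog_pairs.append((gene_a, tid_b))

    return records_a, records_b, truth


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    out = []
    ins = rng.random(len(seq)) < rate / 2
    dele = rng.random(len(seq)) < rate / 2
    for i, base in enumerate(seq):
        if dele[i]:
            continue
        out.append(base)
        if ins[i]:
            out.append(rng.choice(BASES))
    if not out:  # pathological all-deleted case
        out = [seq[0]]
    return np.array(out)


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# BLAST tables

_OUTFMT6 = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def simulate_blast_tables(
    truth: SimTruth,
    split_prob: float = 0.5,
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate forward (A->B) and reverse (B->A) tabular BLAST hit tables.

    True-pair alignments cover most of each isoform and are optionally split
    into 2-3 HSPs; decoy hits to a random wrong subject are added at
    ``decoy_rate`` with bitscores strictly below 0.8x the true pair's total,
    so reciprocal-best-hit truth stays unambiguous. A random subset of pairs
    is reported on the subject minus strand (sstart > send). Coordinates are
    1-based inclusive. Returns (forward, reverse) DataFrames in outfmt-6
    column order.
    """
    if not truth.ortholog_pairs:
        raise ParameterError("truth has no ortholog pairs")
    if not (0.0 <= split_prob <= 1.0) or not (0.0 <= decoy_rate <= 1.0):
        raise ParameterError("split_prob and decoy_rate must lie in [0, 1]")

    rng = rng_from_seed(seed)
    lengths = truth.transcript_lengths()
    fwd_rows: list[dict] = []
    rev_rows: list[dict] = []
    b_transcripts = [b for _, b in truth.ortholog_pairs]

    for gene_a, tid_b in truth.ortholog_pairs:
        len_b = lengths[tid_b]
        minus = bool(rng.random() < 0.2)
        iso_entries = truth.isoforms[gene_a]
        for tid_a, len_a in iso_entries:
            span = int(min(len_a, len_b) * rng.uniform(0.85, 0.98))
            span = max(span, 50)
            q0 = int(rng.integers(1, max(2, len_a - span + 1)))
            s0 = int(rng.integers(1, max(2, len_b - span + 1)))
            pident = float(np.clip(rng.normal(95.0, 1.5), 80.0, 100.0))
            pieces = _split_alignment(span, split_prob, rng)
            total_bits = 0.0
            hsps = []
            off = 0
            for plen in pieces:
                bits = round(1.8 * plen * pident / 100.0, 1)
                total_bits += bits
                hsps.append((q0 + off, q0 + off + plen - 1, s0 + off, s0 + off + plen - 1, plen, bits))
                off += plen + int(rng.integers(1, 8))  # gap between HSPs
            # clamp pieces that ran past either end, keeping coords consistent
            clamped = []
            for qs, qe, ss, se, plen, bits in hsps:
                if qs > len_a or ss > len_b:
                    continue
                plen = min(plen, len_a - qs + 1, len_b - ss + 1)
                if plen < 20:
                    continue
                clamped.append((qs, qs + plen - 1, ss, ss + plen - 1, plen, bits))
            hsps = clamped
            for qs, qe, ss, se, plen, bits in hsps:
                ev = _bits_to_evalue(bits)
                mism = int(round(plen * (1 - pident / 100)))
                srow_s, srow_e = (se, ss) if minus else (ss, se)
                fwd_rows.append(
                    dict(qseqid=tid_a, sseqid=tid_b, pident=round(pident, 2), length=plen,
                         mismatch=mism, gapopen=0, qstart=qs, qend=qe,
                         sstart=srow_s, send=srow_e, evalue=ev, bitscore=bits)
                )
                rev_rows.append(
                    dict(qseqid=tid_b, sseqid=tid_a, pident=round(pident, 2), length=plen,
                         mismatch=mism, gapopen=0, qstart=ss, qend=se,
                         sstart=(qe, qs)[0] if minus else qs,
                         send=(qe, qs)[1] if minus else qe,
                         evalue=ev, bitscore=bits)
                )
            # decoys: strictly below 0.8x the true total bitscore
            if rng.random() < decoy_rate and len(b_transcripts) > 1:
                wrong = tid_b
                while wrong == tid_b:
                    wrong = b_transcripts[int(rng.integers(len(b_transcripts)))]
                dbits = round(total_bits * rng.uniform(0.3, 0.75), 1)
                dlen = max(40, int(span * rng.uniform(0.2, 0.5)))
                dlen = min(dlen, len_a, lengths[wrong])
                dq = int(rng.integers(1, max(2, len_a - dlen + 1)))
                ds = int(rng.integers(1, max(2, lengths[wrong] - dlen + 1)))
                fwd_rows.append(
                    dict(qseqid=tid_a, sseqid=wrong, pident=82.0, length=dlen,
                         mismatch=int(dlen * 0.18), gapopen=0, qstart=dq, qend=dq + dlen - 1,
                         sstart=ds, send=ds + dlen - 1,
                         evalue=_bits_to_evalue(dbits), bitscore=dbits)
                )

    fwd = pd.DataFrame(fwd_rows, columns=_OUTFMT6)
    rev = pd.DataFrame(rev_rows, columns=_OUTFMT6)
    return fwd, rev


def _split_alignment(span: int, split_prob: float, rng: np.random.Generator) -> list[int]:
    if span < 120 or rng.random() >= split_prob:
        return [span]
    n_pieces = int(rng.integers(2, 4))
    cuts = np.sort(rng.choice(np.arange(40, span - 40), size=n_pieces - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [span]])
    pieces = np.diff(bounds)
    # gaps between HSPs eat into the span; shrink pieces slightly
    return [max(30, int(p) - 5) for p in pieces]


def _bits_to_evalue(bits: float) -> float:
    # rough Karlin-Altschul shape: E ~ K m n 2^-S; only the ordering matters here
    return float(min(10.0, 1e3 * 2.0 ** (-bits / 2)))


def write_blast_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# alignments


def simulate_alignments(
    core,
    reads_per_gene: int = 50,
    off_target_frac: float = 0.0,
    read_len: int = 75,
    seed: int = 0,
    side: str = "A",
    transcript_lengths: dict[str, int] | None = None,
) -> str:
    """Simulate single-end SAM records against one species side of a CORE set.

    Exactly ``round(reads_per_gene * (1 - off_target_frac))`` reads per
    ortholog pair start (and end) inside that pair's merged intervals; the
    remainder are placed wholly outside every interval of their transcript.
    Per-pair in-target truth counts are recorded in ``@CO`` header lines.
    Returns the SAM text.
    """
    from .regions import CoreRegionSet  # local import to avoid cycle

    if not isinstance(core, CoreRegionSet):
        raise TypeError("core must be a CoreRegionSet")
    intervals = core.intervals_a if side == "A" else core.intervals_b
    if not intervals:
        raise ParameterError("core region set is empty on the requested side")
    if not (0.0 <= off_target_frac <= 1.0):
        raise ParameterError("off_target_frac must lie in [0, 1]")

    lengths = dict(transcript_lengths or {})
    by_pair: dict[str, list[tuple[str, int, int]]] = {}
    for tid, start, end, pair_id, _strand in intervals:
        by_pair.setdefault(pair_id, []).append((tid, start, end))
        lengths.setdefault(tid, end)  # fall back: interval end bounds the length
    by_tid: dict[str, list[tuple[int, int]]] = {}
    for tid, start, end, _pid, _s in intervals:
        by_tid.setdefault(tid, []).append((start, end))

    for tid, ln in lengths.items():
        if read_len > ln:
            raise ParameterError(f"read_len {read_len} exceeds transcript {tid} length {ln}")

    rng = rng_from_seed(seed)
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    for tid in sorted(lengths):
        header.append(f"@SQ\tSN:{tid}\tLN:{lengths[tid]}")

    n_in = int(round(reads_per_gene * (1.0 - off_target_frac)))
    n_out = reads_per_gene - n_in
    body: list[str] = []
    truth_counts: dict[str, int] = {}
    ridx = 0
    for pair_id in sorted(by_pair):
        placed_in = 0
        ivs = by_pair[pair_id]
        fit_in = [(tid, s, e) for tid, s, e in ivs if e - s >= read_len]
        for i in range(n_in):
            if not fit_in:
                break
            tid, s, e = fit_in[i % len(fit_in)]
            pos = int(rng.integers(s, e - read_len + 1))
            body.append(_sam_line(f"r{ridx}", tid, pos, read_len, rng))
            ridx += 1
            placed_in += 1
        truth_counts[pair_id] = placed_in
        for i in range(n_out):
            tid, s, e = ivs[i % len(ivs)]
            pos = _place_outside(by_tid[tid], lengths[tid], read_len, rng)
            if pos is None:
                continue
            body.append(_sam_line(f"r{ridx}", tid, pos, read_len, rng))
            ridx += 1
    header.append("@CO\ttruth_in_target\t" + json.dumps(truth_counts, sort_keys=True))
    return "\n".join(header + body) + "\n"


def _place_outside(ivs: list[tuple[int, int]], length: int, read_len: int,
                   rng: np.random.Generator) -> int | None:
    """A start so that [pos, pos+read_len) intersects no interval, or None."""
    merged = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    gaps = []
    prev = 0
    for s, e in merged:
        if s - prev >= read_len:
            gaps.append((prev, s - read_len))
        prev = e
    if length - prev >= read_len:
        gaps.append((prev, length - read_len))
    if not gaps:
        return None
    g = gaps[int(rng.integers(len(gaps)))]
    return int(rng.integers(g[0], g[1] + 1))


def _sam_line(qname: str, tid: str, pos0: int, read_len: int, rng: np.random.Generator) -> str:
    seq = "".join(rng.choice(BASES, size=read_len))
    return "\t".join(
        [qname, "0", tid, str(pos0 + 1), "60", f"{read_len}M", "*", "0", "0", seq,
         "I" * read_len]
    )


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    n_genes: int = 2000,
    groups: Sequence[tuple[str, int]] = (("A", 0), ("A", 7), ("A", 14), ("B", 0), ("B", 7), ("B", 14)),
    n_rep: int = 4,
    dispersion: float = 0.1,
    frac_de: float = 0.0,
    interaction_lfc: float = 2.0,
    seed: int = 0,
    base_log2_range: tuple[float, float] = (4.0, 11.0),
):
    """Simulate a gene x sample NB count matrix with a species-by-time design.

    The default design mirrors a two-species wound time course: both species
    at days 0, 7, 14 with ``n_rep`` replicates each. DE genes carry
    ``interaction_lfc`` on the species-by-time interaction only (species A,
    days > 0); species and day main effects are drawn per gene so group means
    differ even for null genes. Variance follows var = mu + phi * mu^2;
    phi = 0 gives Poisson counts. Per-sample library scale factors vary
    within a 2x band. Returns (CountMatrix, SimTruth).
    """
    from .quantify import CountMatrix, SampleInfo  # local import to avoid cycle

    if n_rep < 2:
        raise ParameterError("n_rep must be >= 2")
    if dispersion < 0:
        raise ParameterError("dispersion must be >= 0")
    species = sorted({sp for sp, _ in groups})
    days = sorted({d for _, d in groups})
    if len(species) < 2 or 0 not in days or len(days) < 2:
        raise ParameterError("groups must include both species at day 0 and at least one later day")

    rng = rng_from_seed(seed)
    genes = [f"Gene{i:05d}" for i in range(1, n_genes + 1)]
    base = 2.0 ** rng.uniform(*base_log2_range, size=n_genes)
    sp_eff = rng.normal(0.0, 0.3, size=n_genes)        # log2 species offset
    day_eff = {d: rng.normal(0.0, 0.3, size=n_genes) for d in days if d != 0}

    truth = SimTruth(seed=seed)
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    lfc = np.zeros(n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[de_idx] = interaction_lfc * signs
    truth.de_genes = {g: float(x) for g, x in zip(genes, lfc)}

    samples: list[SampleInfo] = []
    cols: list[np.ndarray] = []
    spA = species[0]  # interaction effect applies to the first species
    for sp, day in groups:
        mu_group = base.copy()
        if sp == spA:
            mu_group = mu_group * 2.0 ** sp_eff
        if day != 0:
            mu_group = mu_group * 2.0 ** day_eff[day]
            if sp == spA:
                mu_group = mu_group * 2.0 ** lfc
        key = f"{sp}:{day}"
        for g, m in zip(genes, mu_group):
            truth.group_means.setdefault(g, {})[key] = float(m)
        for rep in range(1, n_rep + 1):
            scale = float(rng.uniform(0.7, 1.4))
            mu = mu_group * scale
            if dispersion > 0:
                shape = 1.0 / dispersion
                lam = rng.gamma(shape, mu / shape)
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(mu)
            cols.append(counts.astype(np.int64))
            samples.append(SampleInfo(sample_id=f"{sp.lower()}{day}_{rep}", species=sp,
                                      day=day, replicate=rep))
    mat = np.column_stack(cols)
    return CountMatrix(genes=genes, samples=samples, counts=mat), truth


# ---------------------------------------------------------------------------
# co-expression fixtures


def simulate_coexpression(
    n_modules: int,
    module_sizes: Sequence[int],
    within_r: float = 0.92,
    n_background: int = 50,
    n_samples: int = 23,
    n_hubs: int = 0,
    seed: int = 0,
):
    """Simulate an expression matrix with planted co-expression modules.

    Genes within a module load on a shared latent factor with the loading
    calibrated (via the Gaussian rank-correlation identity
    rho_pearson = 2 sin(pi rho_s / 6)) so pairwise Spearman correlation is
    approximately ``within_r``. Optional hub genes load on several module
    factors, linking modules at correlations just below ``within_r``.
    Background genes are independent noise. ``n_samples`` defaults to the
    23-column design of the combined two-species matrix this fixture mimics.
    Returns (DataFrame genes x samples, SimTruth with planted edges).
    """
    if not (0.0 < within_r < 1.0):
        raise ParameterError("within_r must lie in (0, 1)")
    if n_samples < 10:
        raise ParameterError("n_samples must be >= 10")
    if len(module_sizes) != n_modules:
        raise ParameterError("module_sizes must have n_modules entries")

    rng = rng_from_seed(seed)
    pearson_target = 2.0 * np.sin(np.pi * within_r / 6.0)
    w = np.sqrt(pearson_target)

    rows = []
    names = []
    truth = SimTruth(seed=seed)
    factors = rng.normal(size=(n_modules, n_samples))
    gidx = 0
    for m, size in enumerate(module_sizes):
        members = []
        for _ in range(size):
            name = f"M{m:03d}_G{gidx:04d}"
            gidx += 1
            eps = rng.normal(size=n_samples)
            rows.append(w * factors[m] + np.sqrt(1 - w**2) * eps)
            names.append(name)
            members.append(name)
        truth.network_edges.extend(
            (members[i], members[j]) for i in range(size) for j in range(i + 1, size)
        )
    for h in range(n_hubs):
        k = min(3, n_modules)
        picked = rng.choice(n_modules, size=k, replace=False)
        latent = factors[picked].sum(axis=0) / np.sqrt(k)
        eps = rng.normal(size=n_samples)
        rows.append(w * latent + np.sqrt(1 - w**2) * eps)
        names.append(f"HUB_{h:03d}")
    for b in range(n_background):
        rows.append(rng.normal(size=n_samples))
        names.append(f"BG_{b:04d}")

    expr = pd.DataFrame(np.array(rows), index=names,
                        columns=[f"s{j:02d}" for j in range(n_samples)])
    return expr, truth


# ---------------------------------------------------------------------------
# power-law degrees


def simulate_powerlaw_degrees(alpha: float, xmin: int, n: int, seed: int = 0) -> np.ndarray:
    """Draw n i.i.d. values from the discrete power law p(k) = k^-alpha / zeta(alpha, xmin).

    Inverse-CDF sampling: the CDF is tabulated exactly (Hurwitz-zeta
    normalization) up to a large cap; the far tail beyond the cap (total mass
    well under 1e-3 for any alpha > 1.5) falls back on the asymptotic
    zeta(alpha, k) ~ k^(1-alpha)/(alpha-1) inversion.
    """
    if alpha <= 1.0:
        raise ParameterError("alpha must exceed 1 (non-normalizable otherwise)")
    if xmin < 1:
        raise ParameterError("xmin must be >= 1")
    if n < 1:
        raise ParameterError("n must be >= 1")

    rng = rng_from_seed(seed)
    Z = zeta(alpha, xmin)
    cap = 100_000
    ks = np.arange(xmin, xmin + cap, dtype=np.float64)
    cdf = np.cumsum(ks**-alpha) / Z
    u = rng.random(n)
    out = np.searchsorted(cdf, u) + xmin
    over = u > cdf[-1]
    if over.any():
        tail = ((1.0 - u[over]) * Z * (alpha - 1.0)) ** (1.0 / (1.0 - alpha))
        out[over] = np.ceil(tail).astype(np.int64)
    return out.astype(np.int64)


__all__ = [
    "SimTruth",
    "simulate_ortholog_transcriptomes",
    "simulate_blast_tables",
    "simulate_alignments",
    "simulate_counts",
    "simulate_coexpression",
    "simulate_powerlaw_degrees",
    "write_fasta",
    "write_blast_tsv",
    "child_seed",
]
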