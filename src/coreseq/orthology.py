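"""Reciprocal-best-hit orthology from tabular BLAST output.

Hits are local alignments (HSPs) between a de novo assembly (species A,
Trinity-style ``..._gN_iK`` transcript ids) and a reference transcriptome
(species B). Orthology is called at the gene level on the de novo side:
several A isoforms may hit one reference transcript, and a pair is accepted
when the best forward hit and the best reverse hit agree on the same Trinity
gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
import pandas as pd

from ._util import FormatError, logger

_ISOFORM_SUFFIX = re.compile(r"_i\d+$")


@dataclass(frozen=True)
class HSP:
    """One BLAST high-scoring segment pair, 1-based inclusive coordinates.

    ``sstart > send`` encodes a minus-strand subject alignment.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.qstart > self.qend:
            raise ValueError(f"HSP {self.query_id}->{self.subject_id}: qstart > qend")
        if self.aln_len < 1:
            raise ValueError("HSP alignment length must be >= 1")
        if self.evalue < 0 or self.bitscore <= 0:
            raise ValueError("HSP evalue must be >= 0 and bitscore > 0")


@dataclass
class HitTable:
    hsps: list[HSP]
    direction: str  # "forward" (A->B) or "reverse" (B->A)

    def __len__(self) -> int:
        return len(self.hsps)


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    isoforms_a: list[str]
    transcript_b: str
    best_bitscore: float
    best_evalue: float
    shared_reference: bool = False  # gene_b also claimed by another Trinity gene


@dataclass
class OrthologTable:
    pairs: list[OrthologPair] = field(default_factory=list)
    evalue_cutoff: float = 1e-5

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_id(self, pair: OrthologPair) -> str:
        return f"{pair.gene_a}~{pair.gene_b}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(gene_a=p.gene_a, gene_b=p.gene_b, transcript_b=p.transcript_b,
                     isoforms_a=",".join(p.isoforms_a), bitscore=p.best_bitscore,
                     evalue=p.best_evalue)
                for p in self.pairs
            ],
            columns=["gene_a", "gene_b", "transcript_b", "isoforms_a", "bitscore", "evalue"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t")
        pairs = [
            OrthologPair(gene_a=r.gene_a, gene_b=r.gene_b,
                         isoforms_a=str(r.isoforms_a).split(","),
                         transcript_b=r.transcript_b, best_bitscore=float(r.bitscore),
                         best_evalue=float(r.evalue))
            for r in df.itertuples()
        ]
        return cls(pairs=pairs)


def parse_blast_tabular(path, direction: str = "forward") -> HitTable:
    """Parse a 12-column tabular (outfmt 6) BLAST file.

    Comment lines starting with ``#`` are skipped; row order is preserved.
    Malformed rows raise :class:`FormatError` naming the line number.
    """
    hsps: list[HSP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hsps.append(
                    HSP(
                        query_id=fields[0], subject_id=fields[1],
                        pct_identity=float(fields[2]), aln_len=int(fields[3]),
                        qstart=int(fields[6]), qend=int(fields[7]),
                        sstart=int(fields[8]), send=int(fields[9]),
                        evalue=float(fields[10]), bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return HitTable(hsps=hsps, direction=direction)


def hit_table_from_frame(df: pd.DataFrame, direction: str = "forward") -> HitTable:
    """Build a HitTable from an outfmt-6-shaped DataFrame (fixtures path)."""
    hsps = [
        HSP(query_id=str(r.qseqid), subject_id=str(r.sseqid), pct_identity=float(r.pident),
            aln_len=int(r.length), qstart=int(r.qstart), qend=int(r.qend),
            sstart=int(r.sstart), send=int(r.send), evalue=float(r.evalue),
            bitscore=float(r.bitscore))
        for r in df.itertuples()
    ]
    return HitTable(hsps=hsps, direction=direction)


def trinity_gene_of(transcript_id: str) -> str:
    """Strip a trailing Trinity ``_i<digits>`` isoform suffix, if present."""
    return _ISOFORM_SUFFIX.sub("", transcript_id)


def best_hit_per_query(
    hits: HitTable, evalue_cutoff: float = 1e-5
) -> dict[str, tuple[str, float, float]]:
    """Best subject per query after discarding HSPs with evalue above cutoff.

    A subject's score is the *sum* of its HSP bitscores for that query (one
    HSP understates split alignments). Ties break by min evalue, then max
    total alignment length, then lexicographically smallest subject id.
    Returns query_id -> (subject_id, summed_bitscore, best_evalue); queries
    with no surviving hit are absent.
    """
    agg: dict[str, dict[str, list[float]]] = {}
    for h in hits.hsps:
        if h.evalue > evalue_cutoff:
            continue
        per_subj = agg.setdefault(h.query_id, {})
        rec = per_subj.setdefault(h.subject_id, [0.0, float("inf"), 0])
        rec[0] += h.bitscore
        rec[1] = min(rec[1], h.evalue)
        rec[2] += h.aln_len

    best: dict[str, tuple[str, float, float]] = {}
    for q, per_subj in agg.items():
        ranked = sorted(
            per_subj.items(),
            key=lambda kv: (-kv[1][0], kv[1][1], -kv[1][2], kv[0]),
        )
        subj, (bits, ev, _len) = ranked[0]
        best[q] = (subj, bits, ev)
    return best


def reciprocal_best_hits(
    forward: HitTable,
    reverse: HitTable,
    evalue_cutoff: float = 1e-5,
    subject_gene_map: dict[str, str] | None = None,
) -> OrthologTable:
    """Gene-level reciprocal-best-hit orthologs.

    A pair (gene A, gene B) is accepted iff some isoform of gene A has its
    best forward hit on a transcript of gene B and that transcript's best
    reverse hit lands on *any* isoform of the same gene A. ``isoforms_a``
    collects every isoform whose best hit is that transcript. When several
    reference transcripts reciprocate with one Trinity gene, the
    highest-scoring one is kept. A reference gene claimed by more than one
    Trinity gene is kept but flagged ``shared_reference``.

    ``subject_gene_map`` maps reference transcript ids to gene labels;
    without it the transcript id itself is the gene label.
    """
    q_ids = {h.query_id for h in forward.hsps} | {h.subject_id for h in reverse.hsps}
    s_ids = {h.subject_id for h in forward.hsps} | {h.query_id for h in reverse.hsps}
    overlap = q_ids & s_ids
    if overlap:
        raise ValueError(
            f"query/subject id namespaces overlap between species ({sorted(overlap)[:3]}...)"
        )

    fwd_best = best_hit_per_query(forward, evalue_cutoff)
    rev_best = best_hit_per_query(reverse, evalue_cutoff)
    gene_map = subject_gene_map or {}

    # candidate (gene_a, transcript_b): isoforms whose best hit is transcript_b
    candidates: dict[tuple[str, str], list[tuple[str, float, float]]] = {}
    for iso, (tb, bits, ev) in fwd_best.items():
        candidates.setdefault((trinity_gene_of(iso), tb), []).append((iso, bits, ev))

    accepted: dict[str, list[tuple[str, list, float, float]]] = {}
    for (ga, tb), isolist in candidates.items():
        if tb not in rev_best:
            continue
        back_iso = rev_best[tb][0]
        if trinity_gene_of(back_iso) != ga:
            continue
        bits = max(b for _, b, _ in isolist)
        ev = min(e for _, _, e in isolist)
        accepted.setdefault(ga, []).append((tb, sorted(i for i, _, _ in isolist), bits, ev))

    pairs: list[OrthologPair] = []
    claimed_b: dict[str, int] = {}
    for ga in sorted(accepted):
        tb, isos, bits, ev = sorted(
            accepted[ga], key=lambda r: (-r[2], r[3], r[0])
        )[0]
        gb = gene_map.get(tb, tb)
        claimed_b[gb] = claimed_b.get(gb, 0) + 1
        pairs.append(OrthologPair(gene_a=ga, gene_b=gb, isoforms_a=isos,
                                  transcript_b=tb, best_bitscore=bits, best_evalue=ev))
    for p in pairs:
        if claimed_b[p.gene_b] > 1:
            p.shared_reference = True
            logger.warning("reference gene %s claimed by %d Trinity genes",
                           p.gene_b, claimed_b[p.gene_b])
    return OrthologTable(pairs=pairs, evalue_cutoff=evalue_cutoff)


__all__ = [
    "HSP",
    "HitTable",
    "OrthologPair",
    "OrthologTable",
    "parse_blast_tabular",
    "hit_table_from_frame",
    "trinity_gene_of",
    "best_hit_per_query",
    "reciprocal_best_hits",
]
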