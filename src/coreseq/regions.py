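"""Common orthologous regions (COREs): paired BED interval sets from HSPs.

For every accepted ortholog pair, the HSPs linking its reciprocated isoforms
to the paired reference transcript are isolated and converted to species-
specific intervals — query coordinates on the de novo side, subject
coordinates on the reference side. Intervals are merged per (transcript,
pair) on each side independently and written as BED6, which downstream
alignment filtering consumes. The same ortholog table also yields the
gene-transcript map that drives gene-level counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field


from ._util import logger
from .orthology import HSP, HitTable, OrthologTable

# (transcript_id, start, end, pair_id, strand) in 0-based half-open coords
BedInterval = tuple[str, int, int, str, str]


@dataclass
class CoreRegionSet:
    intervals_a: list[BedInterval] = field(default_factory=list)
    intervals_b: list[BedInterval] = field(default_factory=list)
    pair_index: dict[str, tuple[str, str]] = field(default_factory=dict)

    def side(self, which: str) -> list[BedInterval]:
        if which not in ("A", "B"):
            raise ValueError("side must be 'A' or 'B'")
        return self.intervals_a if which == "A" else self.intervals_b

    def by_transcript(self, which: str) -> dict[str, list[tuple[int, int]]]:
        """Merged interval union per transcript on one side."""
        out: dict[str, list[tuple[int, int]]] = {}
        for tid, start, end, _pid, _s in self.side(which):
            out.setdefault(tid, []).append((start, end))
        return {tid: merge_intervals(ivs) for tid, ivs in out.items()}

    def write_bed(self, which: str, path) -> None:
        with open(path, "w") as fh:
            for tid, start, end, pid, strand in sorted(self.side(which)):
                fh.write(f"{tid}\t{start}\t{end}\t{pid}\t0\t{strand}\n")

    @staticmethod
    def read_bed(path_a, path_b) -> "CoreRegionSet":
        def load(path):
            out = []
            with open(path) as fh:
                for line in fh:
                    f = line.rstrip("\n").split("\t")
                    out.append((f[0], int(f[1]), int(f[2]), f[3], f[5]))
            return out

        core = CoreRegionSet(intervals_a=load(path_a), intervals_b=load(path_b))
        for tid, s, e, pid, _ in core.intervals_a + core.intervals_b:
            if pid not in core.pair_index and "~" in pid:
                ga, gb = pid.split("~", 1)
                core.pair_index[pid] = (ga, gb)
        return core


@dataclass
class GeneTranscriptMap:
    """Many-to-one transcript id -> gene label mapping."""

    rows: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def gene_of(self, transcript_id: str) -> str | None:
        return self.rows.get(transcript_id)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.rows):
                fh.write(f"{tid}\t{self.rows[tid]}\n")

    @classmethod
    def read_tsv(cls, path) -> "GeneTranscriptMap":
        rows = {}
        with open(path) as fh:
            for line in fh:
                tid, gene = line.rstrip("\n").split("\t")
                rows[tid] = gene
        return cls(rows=rows)


def hsp_to_bed_intervals(hsp: HSP) -> tuple[tuple[int, int], tuple[int, int, str]]:
    """Convert one HSP's 1-based inclusive coords to 0-based half-open BED.

    Returns ((qstart0, qend0), (sstart0, send0, strand)); strand is '-' iff
    the subject coordinates were reported descending.
    """
    if hsp.qend < hsp.qstart:
        raise ValueError("invalid HSP: qend < qstart")
    q = (hsp.qstart - 1, hsp.qend)
    strand = "-" if hsp.sstart > hsp.send else "+"
    s = (min(hsp.sstart, hsp.send) - 1, max(hsp.sstart, hsp.send), strand)
    return q, s


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sorted union; overlapping or book-ended intervals are coalesced."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


def build_core_beds(orthologs: OrthologTable, forward_hits: HitTable) -> CoreRegionSet:
    """Derive the paired CORE interval sets from accepted orthologs.

    Only HSPs connecting an accepted isoform to its pair's reference
    transcript contribute. Merging is per (transcript, pair) and per species
    side independently; subject-side intervals from different isoforms of one
    pair are merged together, since counting is gene-level.
    """
    wanted: dict[tuple[str, str], str] = {}
    for p in orthologs.pairs:
        pid = orthologs.pair_id(p)
        for iso in p.isoforms_a:
            wanted[(iso, p.transcript_b)] = pid

    raw_a: dict[tuple[str, str], list[tuple[int, int]]] = {}
    raw_b: dict[tuple[str, str], list[tuple[int, int]]] = {}
    strands: dict[tuple[str, str], str] = {}
    seen_pairs: set[str] = set()
    for h in forward_hits.hsps:
        pid = wanted.get((h.query_id, h.subject_id))
        if pid is None:
            continue
        (q0, q1), (s0, s1, strand) = hsp_to_bed_intervals(h)
        raw_a.setdefault((h.query_id, pid), []).append((q0, q1))
        raw_b.setdefault((h.subject_id, pid), []).append((s0, s1))
        strands[(h.subject_id, pid)] = strand
        seen_pairs.add(pid)

    core = CoreRegionSet()
    for p in orthologs.pairs:
        pid = orthologs.pair_id(p)
        if pid not in seen_pairs:
            raise ValueError(f"ortholog pair {pid} has no HSPs in the forward hit table")
        core.pair_index[pid] = (p.gene_a, p.gene_b)
    for (tid, pid), ivs in sorted(raw_a.items()):
        for s, e in merge_intervals(ivs):
            core.intervals_a.append((tid, s, e, pid, "+"))
    for (tid, pid), ivs in sorted(raw_b.items()):
        for s, e in merge_intervals(ivs):
            core.intervals_b.append((tid, s, e, pid, strands[(tid, pid)]))
    return core


def build_gene_transcript_map(
    orthologs: OrthologTable,
    all_transcripts: list[str] | None = None,
    augment: bool = False,
) -> GeneTranscriptMap:
    """Map de novo transcripts to gene labels for counting.

    Ortholog isoforms map to the reference gene label (combined mode). With
    ``augment`` (per se mode), every remaining transcript in
    ``all_transcripts`` maps to its Trinity gene so the whole assembly is
    quantified. A transcript claimed by two reference genes resolves to the
    higher-bitscore pair, with a warning.
    """
    from .orthology import trinity_gene_of

    rows: dict[str, str] = {}
    claim_bits: dict[str, float] = {}
    for p in orthologs.pairs:
        for iso in p.isoforms_a:
            if iso in rows and rows[iso] != p.gene_b:
                logger.warning(
                    "transcript %s claimed by %s and %s; keeping higher bitscore",
                    iso, rows[iso], p.gene_b,
                )
                if p.best_bitscore <= claim_bits[iso]:
                    continue
            rows[iso] = p.gene_b
            claim_bits[iso] = p.best_bitscore
    if augment and all_transcripts:
        for tid in all_transcripts:
            if tid not in rows:
                rows[tid] = trinity_gene_of(tid)
    return GeneTranscriptMap(rows=rows)


def core_coverage(core: CoreRegionSet, which: str) -> dict[str, set[int]]:
    """Per-transcript set of covered base positions (testing/diagnostics)."""
    cov: dict[str, set[int]] = {}
    for tid, s, e, _pid, _strand in core.side(which):
        cov.setdefault(tid, set()).update(range(s, e))
    return cov


__all__ = [
    "BedInterval",
    "CoreRegionSet",
    "GeneTranscriptMap",
    "hsp_to_bed_intervals",
    "merge_intervals",
    "build_core_beds",
    "build_gene_transcript_map",
    "core_coverage",
]
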