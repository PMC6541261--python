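"""CORE-restricted alignment filtering and gene-level counting.

Alignments against a species' transcriptome are kept only where their
aligned reference span overlaps that transcript's CORE intervals, so that
only homologous sequence contributes to counts on either species' side.
Retained primary records are then collapsed to gene-level counts through the
gene-transcript map, and the two species' columns are joined on shared
reference gene labels into the combined cross-species matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from ._util import logger
from .orthology import OrthologTable
from .regions import CoreRegionSet, GeneTranscriptMap


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    species: str
    day: int
    replicate: int


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with sample design factors."""

    genes: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match genes x samples")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        keys = {(s.species, s.day, s.replicate) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("duplicate (species, day, replicate) sample keys")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.sample_ids)

    def write_tsv(self, counts_path, samples_path=None) -> None:
        self.to_frame().to_csv(counts_path, sep="\t", index_label="gene")
        if samples_path is not None:
            pd.DataFrame(
                [dict(sample_id=s.sample_id, species=s.species, day=s.day,
                      replicate=s.replicate) for s in self.samples]
            ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(samples_path, sep="\t")
        samples = [
            SampleInfo(sample_id=str(r.sample_id), species=str(r.species),
                       day=int(r.day), replicate=int(r.replicate))
            for r in meta.itertuples()
        ]
        order = [s.sample_id for s in samples]
        df = df[order]
        return cls(genes=list(df.index), samples=samples,
                   counts=df.to_numpy(dtype=np.int64))


@dataclass
class FilterSummary:
    kept: int = 0
    dropped_unmapped: int = 0
    dropped_secondary: int = 0
    dropped_no_region: int = 0
    dropped_low_overlap: int = 0

    @property
    def total(self) -> int:
        return (self.kept + self.dropped_unmapped + self.dropped_secondary
                + self.dropped_no_region + self.dropped_low_overlap)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def filter_alignments(
    alignments: Iterable[pysam.AlignedSegment] | str,
    core: CoreRegionSet,
    side: str = "A",
    min_overlap: int = 1,
    min_overlap_frac: float = 0.0,
) -> tuple[list[pysam.AlignedSegment], FilterSummary]:
    """Keep primary mapped records overlapping a transcript's CORE intervals.

    A record is kept when its aligned reference span (from the CIGAR:
    M/D/N/=/X consume reference) overlaps the union of its transcript's
    intervals by at least ``min_overlap`` bases *and* at least
    ``min_overlap_frac`` of the span length. Unmapped, secondary and
    supplementary records are dropped; records on transcripts absent from
    the BED side are dropped and counted, not an error. ``alignments`` may
    be a SAM/BAM path or an iterable of records; input order is irrelevant.
    """
    regions = core.by_transcript(side)
    summary = FilterSummary()
    kept: list[pysam.AlignedSegment] = []
    own = None
    if isinstance(alignments, str):
        own = pysam.AlignmentFile(alignments, check_sq=False)
        records: Iterator[pysam.AlignedSegment] = own.fetch(until_eof=True)
    else:
        records = iter(alignments)
    try:
        for rec in records:
            if rec.is_unmapped:
                summary.dropped_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                summary.dropped_secondary += 1
                continue
            if rec.is_paired:
                warnings.warn("paired-end record treated as single-end", stacklevel=2)
            ivs = regions.get(rec.reference_name)
            if ivs is None:
                summary.dropped_no_region += 1
                continue
            start, end = rec.reference_start, rec.reference_end
            span = end - start
            ov = sum(max(0, min(end, e) - max(start, s)) for s, e in ivs)
            if ov >= min_overlap and (span == 0 or ov / span >= min_overlap_frac):
                summary.kept += 1
                kept.append(rec)
            else:
                summary.dropped_low_overlap += 1
    finally:
        if own is not None:
            own.close()
    return kept, summary


def count_genes(
    records: Iterable[pysam.AlignedSegment],
    gene_map: GeneTranscriptMap,
) -> tuple[dict[str, int], int]:
    """Collapse retained records to gene-level counts via the map.

    Returns (gene -> count, n_unmapped_transcript) where the second item
    tallies records whose reference transcript has no gene label.
    """
    counts: dict[str, int] = {}
    orphans = 0
    for rec in records:
        gene = gene_map.gene_of(rec.reference_name)
        if gene is None:
            orphans += 1
            continue
        counts[gene] = counts.get(gene, 0) + 1
    if orphans:
        logger.info("%d records on transcripts without a gene label were excluded", orphans)
    return counts, orphans


def combine_species_counts(
    columns_a: list[tuple[SampleInfo, dict[str, int]]],
    columns_b: list[tuple[SampleInfo, dict[str, int]]],
    orthologs: OrthologTable | None = None,
) -> CountMatrix:
    """Join per-sample gene count columns from both species.

    The row universe is the intersection of gene labels observed on both
    sides (restricted to ortholog gene labels when a table is given); genes
    present on only one side are dropped with a log entry. Columns are
    ordered species A samples first.
    """
    ids = [s.sample_id for s, _ in columns_a + columns_b]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids across species columns")
    genes_a = set().union(*(set(c) for _, c in columns_a)) if columns_a else set()
    genes_b = set().union(*(set(c) for _, c in columns_b)) if columns_b else set()
    shared = genes_a & genes_b
    if orthologs is not None:
        shared &= {p.gene_b for p in orthologs.pairs}
    for g in sorted((genes_a | genes_b) - shared):
        logger.info("gene %s present on one side only; dropped from combined matrix", g)
    genes = sorted(shared)
    cols = []
    samples = []
    for s, c in columns_a + columns_b:
        cols.append([c.get(g, 0) for g in genes])
        samples.append(s)
    mat = np.array(cols, dtype=np.int64).T if genes else np.zeros((0, len(samples)), dtype=np.int64)
    return CountMatrix(genes=genes, samples=samples, counts=mat)


def truth_counts_from_sam(path: str) -> dict[str, int]:
    """Recover the per-pair planted in-target counts from simulated SAM headers."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for co in fh.header.get("CO", []):
            if co.startswith("truth_in_target\t"):
                return json.loads(co.split("\t", 1)[1])
    return {}


__all__ = [
    "SampleInfo",
    "CountMatrix",
    "FilterSummary",
    "filter_alignments",
    "count_genes",
    "combine_species_counts",
    "truth_counts_from_sam",
]
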