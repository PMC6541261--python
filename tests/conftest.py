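import numpy as np
import pytest

from coreseq import simulate
from coreseq.orthology import hit_table_from_frame, reciprocal_best_hits


@pytest.fixture(scope="session")
def ortholog_fixture():
    """50-gene divergent transcriptome pair with split/decoy BLAST tables."""
    fa_a, fa_b, truth = simulate.simulate_ortholog_transcriptomes(
        n_genes=50, isoforms_per_gene=(1, 3), divergence=0.05, seed=7)
    fwd_df, rev_df = simulate.simulate_blast_tables(
        truth, split_prob=0.5, decoy_rate=0.2, seed=3)
    fwd = hit_table_from_frame(fwd_df, "forward")
    rev = hit_table_from_frame(rev_df, "reverse")
    return dict(fa_a=fa_a, fa_b=fa_b, truth=truth, fwd_df=fwd_df, rev_df=rev_df,
                fwd=fwd, rev=rev)


@pytest.fixture(scope="session")
def ortholog_table(ortholog_fixture):
    return reciprocal_best_hits(ortholog_fixture["fwd"], ortholog_fixture["rev"])


def brute_force_rbh(fwd, rev, evalue_cutoff=1e-5):
    """Independent exhaustive reciprocal-best-hit oracle over two hit tables.

    Aggregates summed bitscores per (query, subject) by direct dict scans and
    enforces gene-level reciprocity with explicit loops, sharing no code with
    the package's implementation path.
    """
    from coreseq.orthology import trinity_gene_of

    def best_map(table):
        scores = {}
        for h in table.hsps:
            if h.evalue > evalue_cutoff:
                continue
            key = (h.query_id, h.subject_id)
            bits, ev, ln = scores.get(key, (0.0, float("inf"), 0))
            scores[key] = (bits + h.bitscore, min(ev, h.evalue), ln + h.aln_len)
        best = {}
        for (q, s), (bits, ev, ln) in scores.items():
            cur = best.get(q)
            cand = (-bits, ev, -ln, s)
            if cur is None or cand < cur[0]:
                best[q] = (cand, s)
        return {q: v[1] for q, v in best.items()}

    fbest, rbest = best_map(fwd), best_map(rev)
    pairs = set()
    for iso, tb in fbest.items():
        back = rbest.get(tb)
        if back is not None and trinity_gene_of(back) == trinity_gene_of(iso):
            pairs.add((trinity_gene_of(iso), tb))
    return pairs


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: probability a positive outranks a negative."""
    from scipy.stats import rankdata

    r = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = r[labels.astype(bool)].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
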