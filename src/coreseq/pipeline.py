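"""End-to-end pipeline orchestration with a resumable manifest.

Stages run in dependency order — simulate -> orthologs -> core-bed ->
filter-count -> de -> network -> subnet — writing every artifact type the
modules define. A JSON manifest records each stage's parameter hash and
output hashes; re-running with unchanged inputs skips completed stages, and
a corrupted or missing intermediate triggers a re-run of its stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexpr, metrics, orthology, quantify, regions, simulate, subnetwork
from ._util import child_seed, logger


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_params(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()


DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "coreseq_out",
    "simulate": {
        "n_genes": 50, "divergence": 0.05, "split_prob": 0.5, "decoy_rate": 0.2,
        "reads_per_gene": 50, "off_target_frac": 0.3, "read_len": 75,
        "n_count_genes": 2000, "n_rep": 4, "dispersion": 0.1,
        "frac_de": 0.1, "interaction_lfc": 2.0,
    },
    "orthologs": {"evalue_cutoff": 1e-5},
    "filter_count": {"min_overlap": 1, "min_overlap_frac": 0.0},
    "de": {"min_cpm": 10.0, "min_samples": 3},
    "network": {"grid_start": 0.99, "grid_stop": 0.70, "grid_step": 0.002,
                "n_boot": 200, "max_genes": 400},
    "subnet": {"min_size": 10},
}


class Pipeline:
    """Stage runner over a config dict (see DEFAULT_CONFIG for the schema)."""

    def __init__(self, config: dict | str | Path):
        if not isinstance(config, dict):
            with open(config) as fh:
                config = yaml.safe_load(fh)
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, val in (config or {}).items():
            if isinstance(val, dict) and key in merged:
                merged[key].update(val)
            else:
                merged[key] = val
        self.config = merged
        self.outdir = Path(merged["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists() else {})

    # -- manifest bookkeeping ------------------------------------------------

    def _stage_done(self, stage: str, params: dict, outputs: list[Path]) -> bool:
        rec = self.manifest.get(stage)
        if rec is None or rec.get("params") != _hash_params(params):
            return False
        for out in outputs:
            if not out.exists() or _hash_file(out) != rec["outputs"].get(out.name):
                logger.warning("stage %s: artifact %s missing or changed; re-running",
                               stage, out.name)
                return False
        return True

    def _record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.manifest[stage] = {
            "params": _hash_params(params),
            "outputs": {o.name: _hash_file(o) for o in outputs},
            "seed": self.config["seed"],
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def _run_stage(self, stage: str, params: dict, outputs: list[str], fn) -> list[Path]:
        paths = [self.outdir / o for o in outputs]
        if self._stage_done(stage, params, paths):
            logger.info("stage %s: up to date, skipped", stage)
            return paths
        logger.info("stage %s: running", stage)
        fn(paths)
        self._record(stage, params, paths)
        return paths

    # -- stages --------------------------------------------------------------

    def run(self) -> dict[str, list[Path]]:
        arts: dict[str, list[Path]] = {}
        seed = int(self.config["seed"])
        sim = self.config["simulate"]

        def stage_simulate(paths):
            fa_a, fa_b, truth = simulate.simulate_ortholog_transcriptomes(
                n_genes=sim["n_genes"], divergence=sim["divergence"],
                seed=child_seed(seed, "transcriptomes"))
            simulate.write_fasta(fa_a, paths[0])
            simulate.write_fasta(fa_b, paths[1])
            paths[2].write_text(truth.to_json())
            fwd, rev = simulate.simulate_blast_tables(
                truth, split_prob=sim["split_prob"], decoy_rate=sim["decoy_rate"],
                seed=child_seed(seed, "blast"))
            simulate.write_blast_tsv(fwd, paths[3])
            simulate.write_blast_tsv(rev, paths[4])
            cm, cm_truth = simulate.simulate_counts(
                n_genes=sim["n_count_genes"], n_rep=sim["n_rep"],
                dispersion=sim["dispersion"], frac_de=sim["frac_de"],
                interaction_lfc=sim["interaction_lfc"],
                seed=child_seed(seed, "counts"))
            cm.write_tsv(paths[5], paths[6])
            paths[7].write_text(cm_truth.to_json())

        arts["simulate"] = self._run_stage(
            "simulate", sim,
            ["speciesA.fasta", "speciesB.fasta", "truth_transcriptomes.json",
             "blast_fwd.tsv", "blast_rev.tsv", "counts.tsv", "samples.tsv",
             "truth_counts.json"],
            stage_simulate)

        def stage_orthologs(paths):
            fwd = orthology.parse_blast_tabular(arts["simulate"][3], "forward")
            rev = orthology.parse_blast_tabular(arts["simulate"][4], "reverse")
            table = orthology.reciprocal_best_hits(
                fwd, rev, evalue_cutoff=self.config["orthologs"]["evalue_cutoff"])
            table.write_tsv(paths[0])

        arts["orthologs"] = self._run_stage(
            "orthologs", self.config["orthologs"], ["orthologs.tsv"], stage_orthologs)

        def stage_core_bed(paths):
            fwd = orthology.parse_blast_tabular(arts["simulate"][3], "forward")
            rev = orthology.parse_blast_tabular(arts["simulate"][4], "reverse")
            table = orthology.reciprocal_best_hits(
                fwd, rev, evalue_cutoff=self.config["orthologs"]["evalue_cutoff"])
            core = regions.build_core_beds(table, fwd)
            core.write_bed("A", paths[0])
            core.write_bed("B", paths[1])
            truth = simulate.SimTruth.from_json(arts["simulate"][2].read_text())
            gmap = regions.build_gene_transcript_map(
                table, all_transcripts=sorted(truth.transcript_to_gene()), augment=False)
            gmap.write_tsv(paths[2])
            sam = simulate.simulate_alignments(
                core, reads_per_gene=sim["reads_per_gene"],
                off_target_frac=sim["off_target_frac"], read_len=sim["read_len"],
                seed=child_seed(seed, "alignments"), side="A",
                transcript_lengths=truth.transcript_lengths())
            paths[3].write_text(sam)

        arts["core_bed"] = self._run_stage(
            "core_bed", {**self.config["orthologs"], **sim},
            ["core_A.bed", "core_B.bed", "gene_transcript_map.tsv", "reads_A.sam"],
            stage_core_bed)

        def stage_filter_count(paths):
            core = regions.CoreRegionSet.read_bed(arts["core_bed"][0], arts["core_bed"][1])
            gmap = regions.GeneTranscriptMap.read_tsv(arts["core_bed"][2])
            kept, summary = quantify.filter_alignments(
                str(arts["core_bed"][3]), core, side="A",
                min_overlap=self.config["filter_count"]["min_overlap"],
                min_overlap_frac=self.config["filter_count"]["min_overlap_frac"])
            counts, _orphans = quantify.count_genes(kept, gmap)
            pd.Series(counts, name="count").rename_axis("gene").to_csv(paths[0], sep="\t")
            paths[1].write_text(summary.to_json())

        arts["filter_count"] = self._run_stage(
            "filter_count", self.config["filter_count"],
            ["core_counts_A.tsv", "filter_summary.json"], stage_filter_count)

        def stage_de(paths):
            cm = quantify.CountMatrix.read_tsv(arts["simulate"][5], arts["simulate"][6])
            results, fits, voom = diffexpr.run_de(
                cm, min_cpm=self.config["de"]["min_cpm"],
                min_samples=self.config["de"]["min_samples"])
            for (name, res), path in zip(sorted(results.items()), paths[:-1]):
                diffexpr.de_table(res).to_csv(path, sep="\t")
            logcpm = pd.DataFrame(voom.logcpm, index=voom.genes,
                                  columns=[s.sample_id for s in voom.design.samples])
            logcpm.to_csv(paths[-1], sep="\t", index_label="gene")

        de_outputs = ["de_A_d14_vs_d0.tsv", "de_A_d7_vs_d0.tsv", "de_B_d14_vs_d0.tsv",
                      "de_B_d7_vs_d0.tsv", "de_interaction_d14_vs_d0.tsv",
                      "de_interaction_d7_vs_d0.tsv", "logcpm.tsv"]
        arts["de"] = self._run_stage("de", self.config["de"], de_outputs, stage_de)

        def stage_network(paths):
            netcfg = self.config["network"]
            logcpm = pd.read_csv(arts["de"][-1], sep="\t", index_col=0)
            if len(logcpm) > netcfg["max_genes"]:
                keep = logcpm.var(axis=1).nlargest(netcfg["max_genes"]).index
                logcpm = logcpm.loc[keep]
            corr = coexpression.spearman_matrix(logcpm)
            grid = coexpression.default_grid(netcfg["grid_start"], netcfg["grid_stop"],
                                             netcfg["grid_step"])
            tau, report = coexpression.select_threshold(corr, grid)
            report.write_tsv(paths[1])
            if tau is None:
                tau_used = float(grid[-1])
                status = report.status
            else:
                tau_used, status = tau, "ok"
            net = coexpression.network_at_threshold(corr, tau_used)
            net.write_edge_tsv(paths[0])
            degs = net.degrees()
            fitinfo: dict = {"threshold": tau_used, "status": status}
            if len(degs) >= 10:
                try:
                    fit = coexpression.powerlaw_bootstrap(
                        degs, n_boot=netcfg["n_boot"], seed=child_seed(seed, "boot"))
                    fitinfo.update(fit.to_dict())
                except Exception as exc:  # degenerate degree vectors
                    fitinfo["powerlaw_error"] = str(exc)
            paths[2].write_text(json.dumps(fitinfo, indent=1, sort_keys=True))

        arts["network"] = self._run_stage(
            "network", self.config["network"],
            ["network_edges.tsv", "threshold_report.tsv", "powerlaw_fit.json"],
            stage_network)

        def stage_subnet(paths):
            edges = pd.read_csv(arts["network"][0], sep="\t")
            import networkx as nx

            g = nx.Graph()
            g.add_edges_from(zip(edges["gene_a"].astype(str), edges["gene_b"].astype(str)))
            if g.number_of_nodes() == 0:
                paths[0].write_text("center\tsize\tflagged\tmembers\n")
                return
            net = coexpression.Network(graph=g, threshold=0.0)
            rng = np.random.default_rng(child_seed(seed, "subnet"))
            nodes = sorted(map(str, g.nodes))
            picked = rng.choice(len(nodes), size=min(25, len(nodes)), replace=False)
            allowed = subnetwork.RegulatorSet(genes={nodes[i] for i in picked})
            subs = subnetwork.enumerate_subnetworks(
                net, allowed, min_size=self.config["subnet"]["min_size"])
            with open(paths[0], "w") as fh:
                fh.write("center\tsize\tflagged\tmembers\n")
                for sn in subs:
                    fh.write(f"{sn.center}\t{sn.size}\t{int(sn.flagged)}\t"
                             + ",".join(map(str, sn.members)) + "\n")

        arts["subnet"] = self._run_stage(
            "subnet", self.config["subnet"], ["subnetworks.tsv"], stage_subnet)

        def stage_metrics(paths):
            truth = simulate.SimTruth.from_json(arts["simulate"][2].read_text())
            lens = list(truth.transcript_lengths().values())
            rng = np.random.default_rng(child_seed(seed, "metrics"))
            expr = rng.lognormal(3.0, 1.5, size=len(lens))
            table = metrics.exn50(expr, lens)
            table.to_csv(paths[0], sep="\t", index=False)
            paths[1].write_text(json.dumps({"n50": metrics.n50(lens)}))

        arts["metrics"] = self._run_stage(
            "metrics", {}, ["exn50.tsv", "assembly_metrics.json"], stage_metrics)
        return arts


def run_pipeline(config: dict | str | Path) -> dict[str, list[Path]]:
    return Pipeline(config).run()


__all__ = ["Pipeline", "run_pipeline", "DEFAULT_CONFIG"]
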