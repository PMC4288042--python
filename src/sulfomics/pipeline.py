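"""Pipeline orchestration: simulate → profile → train → bin → curate →
abundance, with the energetics stage independent of the rest.

A single config object drives every stage; all defaults mirror the
module-level defaults.  Reruns with an identical config are bit-identical
— every random choice descends from the one global seed, and each output
file carries the tool version, the seed and a parameter digest in its
header.  The run summary is recomputable from the stage outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import abundance as ab
from . import curation, energetics, esom, io, kmer, synthetic

__all__ = ["PipelineConfig", "run", "load_config"]

log = logging.getLogger("sulfomics.pipeline")


@dataclass
class PipelineConfig:
    seed: int = 42
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "profile", "som", "bin", "curate", "abundance", "energetics"]
    )
    # simulate
    mislabel_rate: float = 0.1
    fragment_median: float = 4000.0
    fragment_sigma: float = 0.5
    min_contig_length: int = 2500
    depth_sigma: float = 0.3
    total_reads: int = 5_000_000
    # profile
    window: int = 5000
    collapse_rc: bool = True
    standardize: bool = False
    # som
    epochs: int = 20
    rate_start: float = 0.5
    rate_end: float = 0.05
    radius_end: float = 1.0
    toroidal: bool = True
    # bin extraction
    threshold_quantile: float = 0.6
    connectivity: int = 8
    # curation
    gc_window: float = 0.05
    cov_band: float = 3.0
    min_vote_fraction: float = 0.5
    # abundance
    abundance_rank: str = "class"
    # energetics
    pH: float = 7.0
    temperature: float = 298.15

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected to catch typos."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _modal_taxon(gene_calls, rank: str) -> str:
    attr = "best_hit_taxon_class" if rank == "class" else "best_hit_taxon_genus"
    votes: dict[str, int] = {}
    for g in gene_calls:
        votes[getattr(g, attr)] = votes.get(getattr(g, attr), 0) + 1
    return max(sorted(votes), key=lambda t: votes[t]) if votes else ""


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages in dependency order.

    Returns the machine-readable summary (also written to summary.json).
    Stage failures propagate with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.to_dict()
    t0 = time.time()
    summary: dict = {"seed": config.seed, "params_digest": io.params_digest(params), "stages": {}}

    sample = None
    matrix = meta = None
    grid = None
    assignment = None

    stage = "simulate"
    try:
        if stage in config.stages:
            log.info("[%s] mislabel=%.3g fragment_median=%g", stage, config.mislabel_rate, config.fragment_median)
            sample = synthetic.simulate_community(
                synthetic.default_models(),
                seed=config.seed,
                fragment_median=config.fragment_median,
                fragment_sigma=config.fragment_sigma,
                min_length=config.min_contig_length,
                depth_sigma=config.depth_sigma,
                mislabel_rate=config.mislabel_rate,
                total_reads=config.total_reads,
            )
            io.write_fasta(sample.contigs, outdir / "contigs.fasta")
            io.write_gff3(sample.gene_calls, outdir / "genes.gff3", seed=config.seed, params=params)
            io.write_truth(sample.truth, outdir / "truth.tsv", seed=config.seed)
            summary["stages"][stage] = {
                "n_contigs": len(sample.contigs),
                "n_genes": len(sample.gene_calls),
                "total_bp": sum(len(c) for c in sample.contigs),
            }

        stage = "profile"
        if stage in config.stages:
            if sample is None:
                raise RuntimeError("profile stage requires the simulate stage (or load contigs via the CLI)")
            log.info("[%s] window=%d collapse_rc=%s", stage, config.window, config.collapse_rc)
            matrix, meta = kmer.profile_matrix(
                sample.contigs,
                window=config.window,
                min_length=config.min_contig_length,
                collapse_rc=config.collapse_rc,
                standardize=config.standardize,
            )
            feats = pd.DataFrame(
                matrix, columns=kmer.feature_names(collapse_rc=config.collapse_rc), index=meta.index
            )
            io.write_tsv(
                pd.concat([meta, feats], axis=1), outdir / "profiles.tsv",
                seed=config.seed, params=params,
            )
            summary["stages"][stage] = {"n_windows": int(matrix.shape[0]), "n_features": int(matrix.shape[1])}

        stage = "som"
        if stage in config.stages:
            if matrix is None:
                raise RuntimeError("som stage requires profiles")
            log.info("[%s] epochs=%d", stage, config.epochs)
            grid = esom.train(
                matrix,
                epochs=config.epochs,
                rate_start=config.rate_start,
                rate_end=config.rate_end,
                radius_end=config.radius_end,
                toroidal=config.toroidal,
                seed=config.seed,
            )
            np.savetxt(outdir / "weights.tsv", grid.weights.reshape(-1, grid.dim), delimiter="\t")
            np.savetxt(outdir / "umatrix.tsv", esom.umatrix(grid, config.connectivity), delimiter="\t")
            summary["stages"][stage] = {
                "rows": grid.rows,
                "cols": grid.cols,
                "qe_initial": grid.qe_history[0],
                "qe_final": grid.qe_history[-1],
            }

        stage = "bin"
        if stage in config.stages:
            if grid is None or matrix is None:
                raise RuntimeError("bin stage requires a trained map")
            log.info("[%s] threshold_quantile=%.2f", stage, config.threshold_quantile)
            table = esom.bmus(grid, matrix)
            assignment = esom.extract_bins(
                grid,
                table,
                window_contigs=meta["contig_id"],
                threshold_quantile=config.threshold_quantile,
                connectivity=config.connectivity,
                window_ids=list(meta["window_id"]),
            )
            rows = [
                {
                    "window_id": wid,
                    "contig_id": cid,
                    "bin_id": assignment.window_bins[wid] if assignment.window_bins[wid] is not None else "NA",
                }
                for wid, cid in zip(meta["window_id"], meta["contig_id"])
            ]
            io.write_tsv(pd.DataFrame(rows), outdir / "bins.tsv", seed=config.seed, params=params)
            info = {"n_bins": len(assignment.bins)}
            if sample is not None:
                assigned = [c for c, b in assignment.contig_bins.items() if b is not None]
                info["ari_vs_truth"] = float(
                    adjusted_rand_score(
                        [sample.truth[c] for c in assigned],
                        [assignment.contig_bins[c] for c in assigned],
                    )
                )
                info["n_assigned_contigs"] = len(assigned)
            summary["stages"][stage] = info

        stage = "curate"
        if stage in config.stages:
            if assignment is None or sample is None:
                raise RuntimeError("curate stage requires bins and the community")
            log.info("[%s] gc_window=%.3f cov_band=%.1fx", stage, config.gc_window, config.cov_band)
            by_contig = {c.contig_id: c for c in sample.contigs}
            genes_by_contig: dict[str, list] = {}
            for g in sample.gene_calls:
                genes_by_contig.setdefault(g.contig_id, []).append(g)
            bin_rows = []
            reports = []
            for bin_id, cids in sorted(assignment.bins.items()):
                bin_genes = [g for c in cids for g in genes_by_contig.get(c, [])]
                target = _modal_taxon(bin_genes, "class")
                kept, vote_report = curation.majority_vote_filter(
                    sorted(cids), sample.gene_calls, target, rank="class",
                    threshold=config.min_vote_fraction,
                )
                gc = {c: kmer.gc_content(by_contig[c].sequence) for c in kept}
                depth = {c: by_contig[c].depth for c in kept}
                kept2, cov_report = curation.gc_coverage_filter(
                    sorted(kept), gc, depth, gc_window=config.gc_window, cov_band=config.cov_band
                )
                vote_report["bin_id"] = bin_id
                cov_report["bin_id"] = bin_id
                reports.extend([vote_report, cov_report])
                if not kept2:
                    continue
                stats = curation.assembly_stats(
                    [by_contig[c] for c in sorted(kept2)],
                    n_genes=sum(len(genes_by_contig.get(c, [])) for c in kept2),
                )
                comp, dup = curation.completeness(
                    [g for c in kept2 for g in genes_by_contig.get(c, [])],
                    curation.DEFAULT_MARKER_SET,
                )
                bin_rows.append(
                    {
                        "bin_id": bin_id,
                        "target_taxon": target,
                        "n_scaffolds": stats.n_scaffolds,
                        "total_bp": stats.total_bp,
                        "longest": stats.longest,
                        "n50": stats.n50,
                        "gc_percent": round(stats.gc_percent, 2),
                        "n_genes": stats.n_genes,
                        "completeness_percent": round(comp, 1),
                        "duplicated_markers": dup,
                    }
                )
            io.write_tsv(pd.DataFrame(bin_rows), outdir / "bin_stats.tsv", seed=config.seed, params=params)
            io.write_tsv(pd.concat(reports, ignore_index=True) if reports else pd.DataFrame(),
                         outdir / "curation_report.tsv", seed=config.seed, params=params)
            summary["stages"][stage] = {"bins": bin_rows}

        stage = "abundance"
        if stage in config.stages:
            if sample is None:
                raise RuntimeError("abundance stage requires the community")
            log.info("[%s] rank=%s", stage, config.abundance_rank)
            hits = synthetic.simulate_hit_table(
                sample.gene_calls, mislabel_rate=0.0,
                seed=np.random.SeedSequence(config.seed).spawn(1)[0],
            )
            io.write_hit_table(hits, outdir / "hits.tsv", seed=config.seed)
            surviving = ab.filter_hits_functional(ab.best_hits(hits))
            table = ab.abundance_table(surviving, sample.total_reads, rank=config.abundance_rank)
            io.write_tsv(table, outdir / "abundance.tsv", seed=config.seed, params=params)
            summary["stages"][stage] = {
                "n_hits": len(hits),
                "n_surviving": len(surviving),
                "n_groups": int(len(table)),
            }

        stage = "energetics"
        if stage in config.stages:
            log.info("[%s] pH=%.1f T=%.2fK", stage, config.pH, config.temperature)
            table = energetics.equations_table(pH=config.pH, temperature=config.temperature)
            io.write_tsv(table, outdir / "energetics.tsv", seed=config.seed, params=params)
            summary["stages"][stage] = {
                r["label"]: round(r["delta_g_prime_kj"], 2) for _, r in table.iterrows()
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["runtime_s"] = round(time.time() - t0, 2)
    blob = json.dumps({k: v for k, v in summary.items() if k != "runtime_s"}, sort_keys=True)
    summary["digest"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
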