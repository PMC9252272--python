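"""Pipeline orchestration: one YAML config drives the full analysis.

Stage order follows the analysis itself: simulate (or load calls) ->
cluster -> phylogeny + bootstrap -> branch events -> occupancy spectrum ->
optional CNV profiling.  Every stage writes plain-text artifacts into the
output directory, and a reproducibility manifest records the config hash,
the seed, per-stage counts, and a checksum of every file written —
re-running with an identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ancestral_events import branch_event_table, family_branch_heatmap_matrix
from .core import DolloTraceError, GenomeConfig, parse_region
from .cnv_profile import cnv_pipeline
from .dollo_phylo import bootstrap_support, heuristic_search
from .formats_io import (
    read_te_bed,
    write_newick,
    write_presence_matrix,
    write_te_bed,
    write_window_table,
)
from .locus_clustering import cluster_pipeline
from .occupancy_models import (
    burst_fraction_statistic,
    occupancy_spectrum,
    restrict_matrix,
)
from .synthetic_data import (
    default_genome,
    emit_sample_beds,
    recovery_config,
    simulate_depth,
    simulate_evolution,
)

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(DolloTraceError):
    """A stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def record_file(self, label: str, path: Path) -> None:
        self.checksums[label] = _sha256(path)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "version": self.version,
                    "stages": self.stages,
                    "checksums": self.checksums,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def run_pipeline(config_path, outdir) -> Path:
    """Execute the full analysis described by a YAML run config.

    The config either names a ``simulate`` preset or an ``inputs`` section
    pointing at BED files and a genome config.  Returns the output
    directory; a ``manifest.json`` inside it records reproducibility
    metadata.
    """
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(config_path) as fh:
        raw_text = fh.read()
    config = yaml.safe_load(raw_text) or {}
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config_hash=hashlib.sha256(raw_text.encode()).hexdigest(),
        seed=seed,
        version=__version__,
    )

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # ------------------------------------------------------------ inputs
    sim_truth = None
    if "simulate" in config:
        sim_spec = config["simulate"] or {}

        def do_simulate():
            sim = recovery_config(
                n_taxa=int(sim_spec.get("n_taxa", 12)),
                gains_per_branch=float(sim_spec.get("gains_per_branch", 30.0)),
                fn_rate=float(sim_spec.get("fn_rate", 0.0)),
                fp_rate=float(sim_spec.get("fp_rate", 0.0)),
                seed=seed,
            )
            truth = simulate_evolution(sim)
            bed_paths = emit_sample_beds(truth, sim, outdir / "beds")
            write_newick(truth.tree, outdir / "truth.nwk", include_support=False)
            truth.gains.to_csv(outdir / "truth_events.tsv", sep="\t", index_label="branch")
            write_presence_matrix(truth.truth_matrix(), outdir / "truth_matrix.tsv")
            manifest.record_file("truth.nwk", outdir / "truth.nwk")
            manifest.record_file("truth_events.tsv", outdir / "truth_events.tsv")
            manifest.record_file("truth_matrix.tsv", outdir / "truth_matrix.tsv")
            for sample, path in bed_paths.items():
                manifest.record_file(f"beds/{sample}.bed", path)
            manifest.stages["simulate"] = {
                "n_samples": len(sim.samples),
                "n_true_loci": len(truth.loci),
            }
            calls = {
                sample: read_te_bed(path, sample)
                for sample, path in bed_paths.items()
            }
            return sim.genome, calls, truth

        genome, calls_by_sample, sim_truth = stage("simulate")(do_simulate)
    elif "inputs" in config:
        inputs = config["inputs"]

        def do_load():
            bed_dir = Path(inputs["beds"])
            if not bed_dir.is_dir():
                raise FileNotFoundError(f"BED directory not found: {bed_dir}")
            genome = (
                GenomeConfig.from_yaml(inputs["genome"])
                if "genome" in inputs
                else default_genome()
            )
            calls = {
                p.stem: read_te_bed(p, p.stem) for p in sorted(bed_dir.glob("*.bed"))
            }
            if not calls:
                raise FileNotFoundError(f"no .bed files in {bed_dir}")
            manifest.stages["load"] = {"n_samples": len(calls)}
            return genome, calls

        genome, calls_by_sample = stage("load")(do_load)
    else:
        raise PipelineError(
            "stage 'inputs' failed: config needs a 'simulate' or 'inputs' section"
        )

    # ----------------------------------------------------------- cluster
    def do_cluster():
        matrix, loci, stats = cluster_pipeline(calls_by_sample, genome)
        write_presence_matrix(matrix, outdir / "matrix.tsv")
        write_te_bed(
            [l.calls[0] for l in loci], outdir / "loci.bed", detail="locus"
        )
        manifest.record_file("matrix.tsv", outdir / "matrix.tsv")
        manifest.record_file("loci.bed", outdir / "loci.bed")
        manifest.stages["cluster"] = stats
        return matrix

    matrix = stage("cluster")(do_cluster)

    # ------------------------------------------------------------- phylo
    phylo_spec = config.get("phylo", {}) or {}

    def do_phylo():
        replicates = int(phylo_spec.get("replicates", 50))
        n_bootstrap = int(phylo_spec.get("bootstrap", 100))
        tree, length = heuristic_search(matrix, replicates=replicates, seed=seed)
        if n_bootstrap > 0:
            tree = bootstrap_support(
                matrix, tree, replicates=n_bootstrap, seed=seed + 1
            )
        write_newick(tree, outdir / "tree.nwk")
        manifest.record_file("tree.nwk", outdir / "tree.nwk")
        manifest.stages["phylo"] = {
            "tree_length": length,
            "search_replicates": replicates,
            "bootstrap_replicates": n_bootstrap,
        }
        return tree

    tree = stage("phylo")(do_phylo)

    # ------------------------------------------------------------ events
    def do_events():
        table = branch_event_table(tree, matrix)
        table.to_frame().to_csv(outdir / "branch_events.tsv", sep="\t")
        heatmap = family_branch_heatmap_matrix(table)
        heatmap.to_csv(outdir / "heatmap.tsv", sep="\t", index_label="family")
        manifest.record_file("branch_events.tsv", outdir / "branch_events.tsv")
        manifest.record_file("heatmap.tsv", outdir / "heatmap.tsv")
        manifest.stages["events"] = {
            "total_gains": table.total_gains,
            "total_losses": table.total_losses,
        }
        return table

    stage("events")(do_events)

    # --------------------------------------------------------- occupancy
    occ_spec = config.get("occupancy", {}) or {}

    def do_occupancy():
        region = parse_region(occ_spec["region"]) if "region" in occ_spec else None
        restricted = restrict_matrix(matrix, region=region) if region else matrix
        spectrum = occupancy_spectrum(restricted, region=region)
        spectrum.to_frame().to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
        manifest.record_file("spectrum.tsv", outdir / "spectrum.tsv")
        manifest.stages["occupancy"] = {
            "n_loci": spectrum.n_loci,
            "burst_fraction": burst_fraction_statistic(spectrum),
        }

    stage("occupancy")(do_occupancy)

    # --------------------------------------------------------------- cnv
    cnv_spec = config.get("cnv")
    if cnv_spec and sim_truth is not None:

        def do_cnv():
            sim_cfg = recovery_config(
                n_taxa=len(matrix.samples), seed=seed
            )  # only genome/ploidy/seed are used for depth
            tables = simulate_depth(
                sim_cfg,
                mean_count=float(cnv_spec.get("mean_count", 100.0)),
                samples=matrix.samples[:1],
            )
            cnv_dir = outdir / "cnv"
            cnv_dir.mkdir(exist_ok=True)
            counts = {}
            for sample, table in tables.items():
                called, segments = cnv_pipeline(table, ploidy=sim_cfg.ploidy)
                path = cnv_dir / f"{sample}.cnv.tsv"
                write_window_table(called, path)
                manifest.record_file(f"cnv/{sample}.cnv.tsv", path)
                counts[sample] = {
                    "n_windows": int(len(called)),
                    "n_segments": int(len(segments)),
                }
            manifest.stages["cnv"] = counts

        stage("cnv")(do_cnv)

    manifest.write(outdir / "manifest.json")
    return outdir
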