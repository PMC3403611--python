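"""End-to-end workflow: seeds -> calibrate -> score -> subnet -> k-core -> enrich.

Stage order mirrors the study design: integrate the expression screens into
seed genes, calibrate phi with the causative genes held out, add them to the
seeds, score and take the top fraction, build the confidence-floored
subnetwork, decompose and partition it, then run enrichment, overlap and
abundance summaries.  Every stage writes its output; a run log records the
parameters and counts, and identical (config, seed) reruns produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import __version__, io
from . import enrich as enrich_mod
from . import network as network_mod
from .config import PipelineConfig
from .expression import assemble_seeds, de_table, harmonize_platforms
from .prioritize import (
    build_activity_vector,
    calibrate_phi,
    default_phi_grid,
    katz_score_direct,
    select_top_fraction,
)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _float_fmt(x: float) -> str:
    return f"{x:.10g}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest of output paths and key counts."""
    config.validate()
    config.preflight()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "counts": {}, "parameters": config.to_dict(),
                      "version": __version__}

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with _stage("read_inputs"):
        net = io.read_weighted_network(config.network_path)
        platforms = []
        probe_maps = {}
        for p in config.expression:
            ds = io.read_expression(p.values, p.groups, p.platform_id)
            platforms.append(ds)
            if p.probe_map:
                probe_maps[p.platform_id] = io.read_probe_map(p.probe_map)
        omim = io.read_gene_list(config.omim_path)
        proteomics = io.read_gene_list(config.proteomics_path)
        loci = io.read_loci(config.loci_path)
        collection = io.read_gmt(config.gmt_path)

    with _stage("expression_screen"):
        harmonized = harmonize_platforms(platforms, probe_maps)
        de_genes: set[str] = set()
        for ds in harmonized:
            tab = de_table(ds, fdr_level=config.fdr_level,
                           low=config.fold_low, high=config.fold_high)
            path = out / f"de_{ds.platform_id}.tsv"
            tab.to_csv(path, sep="\t", index=False, float_format="%.10g")
            manifest["outputs"][f"de_{ds.platform_id}"] = str(path)
            de_genes |= set(tab.loc[tab["selected"], "gene"])
        manifest["counts"]["de_genes"] = len(de_genes)

    with _stage("assemble_seeds"):
        seeds = assemble_seeds(omim, proteomics, de_genes)
        seeds_path = out / "seeds.tsv"
        seeds.as_frame().to_csv(seeds_path, sep="\t", index=False)
        manifest["outputs"]["seeds"] = str(seeds_path)
        manifest["counts"]["seed_union"] = len(seeds.union)

    with _stage("calibrate_phi"):
        cal_seeds = (seeds.proteomics | seeds.microarray) - seeds.omim
        grid = default_phi_grid(config.phi_grid_min, config.phi_grid_max,
                                config.phi_grid_points)
        cal = calibrate_phi(net, cal_seeds, seeds.omim, loci, grid=grid,
                            n_candidates=config.n_candidates)
        cal_path = out / "calibration.tsv"
        cal.as_frame().to_csv(cal_path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"]["calibration"] = str(cal_path)
        manifest["counts"]["phi_star"] = cal.phi_star
        manifest["counts"]["mean_r_ratio_at_phi_star"] = float(min(cal.mean_r_ratio))

    with _stage("score"):
        activity = build_activity_vector(net, seeds.union)
        manifest["counts"]["seeds_in_network"] = activity.n_seeds_in_network
        manifest["counts"]["seeds_missing_from_network"] = len(activity.missing)
        score = katz_score_direct(net, activity.x, cal.phi_star)
        scores_path = out / "scores.tsv"
        score.as_frame().to_csv(scores_path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"]["scores"] = str(scores_path)

    with _stage("select_top"):
        top = select_top_fraction(score, q=config.top_fraction,
                                  denominator=config.top_denominator)
        top_path = out / "top_genes.txt"
        io.write_gene_list(top, top_path)
        manifest["outputs"]["top_genes"] = str(top_path)
        manifest["counts"]["top_genes"] = len(top)

    with _stage("subnetwork"):
        sub = network_mod.extract_subnetwork(net, top, weight_floor=config.weight_floor,
                                             prune_isolated=config.prune_isolated)
        edges_path = out / "subnet_edges.tsv"
        io.write_subnetwork_edges(sub, edges_path)
        manifest["outputs"]["subnet_edges"] = str(edges_path)
        manifest["counts"]["subnet_nodes"] = sub.n_nodes
        manifest["counts"]["subnet_edges"] = sub.n_edges

    with _stage("k_core"):
        dec = network_mod.k_core_decompose(sub)
        part = network_mod.partition_core_periphery(
            dec, k_outer_max=config.k_outer_max, k_medium_max=config.k_medium_max
        )
        tags = {"seed": set(seeds.union), "omim": set(seeds.omim)}
        drug_targets: set[str] = set()
        if config.drug_targets_path:
            drug_targets = set(io.read_gene_list(config.drug_targets_path))
            tags["drug_target"] = drug_targets
        layers_tab = network_mod.layer_composition(dec, tags)
        layers_path = out / "core_layers.tsv"
        layers_tab.to_csv(layers_path, sep="\t")
        manifest["outputs"]["core_layers"] = str(layers_path)
        manifest["counts"]["kmax"] = dec.kmax

        import pandas as pd

        nodes = sorted(sub.nodes)
        node_tab = pd.DataFrame(
            {
                "gene": nodes,
                "core_number": [dec.core_number[v] for v in nodes],
                "partition": [part.label_of(v) for v in nodes],
                "is_seed": [v in seeds.union for v in nodes],
                "is_drug_target": [v in drug_targets for v in nodes],
            }
        )
        nodes_path = out / "subnet_nodes.tsv"
        node_tab.to_csv(nodes_path, sep="\t", index=False)
        manifest["outputs"]["subnet_nodes"] = str(nodes_path)
        graphml_path = out / "subnet.graphml"
        io.write_graphml(sub, graphml_path, node_tab.set_index("gene"))
        manifest["outputs"]["graphml"] = str(graphml_path)

    with _stage("enrichment"):
        query = sub.nodes if config.enrich_query == "subnetwork" else top
        records = enrich_mod.enrich(query, collection, background=net.genes,
                                    alpha=config.alpha)
        enr_path = out / "enrichment.tsv"
        enrich_mod.records_frame(records).to_csv(enr_path, sep="\t", index=False,
                                                 float_format="%.10g")
        manifest["outputs"]["enrichment"] = str(enr_path)
        manifest["counts"]["significant_terms"] = sum(r.significant for r in records)
        if records:
            manifest["counts"]["top_term"] = records[0].term_id

    with _stage("overlap"):
        if config.reference_network_path:
            reference = io.read_gene_list(config.reference_network_path)
            result = enrich_mod.overlap_subnetwork(
                sub, reference, inner_core_genes=part.inner, seed_genes=seeds.union
            )
            ov_path = out / "overlap.tsv"
            enrich_mod.records_frame(result.composition_tests.values()).to_csv(
                ov_path, sep="\t", index=False, float_format="%.10g"
            )
            manifest["outputs"]["overlap"] = str(ov_path)
            manifest["counts"]["overlap_nodes"] = len(result.overlap_nodes)

    with _stage("abundance"):
        if config.abundance_path:
            table = io.read_abundance_table(config.abundance_path)
            summary = enrich_mod.abundance_distribution(sub, table)
            ab_path = out / "abundance.tsv"
            summary.as_frame().to_csv(ab_path, sep="\t", index=False, float_format="%.10g")
            manifest["outputs"]["abundance"] = str(ab_path)
            manifest["counts"]["abundance_coverage"] = round(summary.coverage, 10)
            manifest["counts"]["detected_fraction"] = round(summary.detected_fraction, 10)

    with _stage("run_log"):
        log_path = out / "run.yaml"
        with open(log_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        manifest["outputs"]["run_log"] = str(log_path)

    return manifest
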