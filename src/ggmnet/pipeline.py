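"""End-to-end orchestration: filter -> log -> sampled Pcor/PCC -> edge
selection -> network stats -> MCL modules, with optional enrichment,
cross-species conservation and module-profile stages, under a single
flat config with one global seed.

Stage seeds are derived from the global seed by stable hashing of stage
names, so adding a stage never perturbs the randomness of earlier ones.
Every run writes its intermediate artifacts plus a manifest recording the
config and headline counts; reruns with the same config and seed reproduce
every artifact byte for byte (manifests differ only in the timestamp
field).
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import preprocessing as prep
from . import estimation as est
from . import network as netmod
from . import enrichment as enr
from . import conservation as cons
from . import profiles as prof

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration.  Defaults are the
    published full-compendium settings."""

    expression_path: str = ""
    out_dir: str = "ggmnet_out"
    # preprocessing
    min_max_fpkm: float = 20.0
    # sampled estimation
    n_iterations: int = 25_000
    subset_size: int = 2_000
    # edge selection
    pcor_threshold: float = 0.035
    pcc_threshold: float = 0.35
    # clustering
    inflation: float = 1.5
    min_module_size: int = 5
    # optional stage inputs (empty string = stage skipped)
    annotations_path: str = ""
    motif: str = ""
    promoters_path: str = ""
    partner_network_path: str = ""
    homolog_map_path: str = ""
    sample_groups_path: str = ""
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class PipelineStageError(RuntimeError):
    """An error inside one pipeline stage, named so failures localize."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: global seed mixed with a CRC of the stage name."""
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline described by ``config`` and return the manifest.

    Mandatory stages: read, filter, log transform, sampled Pcor + PCC, edge
    selection, network stats, MCL.  Enrichment, motif, conservation and
    profile stages run when their inputs are configured.  All artifacts and
    the manifest land in ``config.out_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "counts": {}}
    t0 = time.time()

    def run_stage(name: str, fn):
        start = time.time()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineStageError(name, exc) from exc
        manifest["stages"][name] = round(time.time() - start, 3)
        logger.info("stage %-12s %.2fs", name, time.time() - start)
        return result

    matrix = run_stage("read", lambda: prep.read_expression_matrix(config.expression_path))
    kept = run_stage(
        "filter", lambda: prep.filter_low_expression(matrix, config.min_max_fpkm)
    )
    manifest["counts"]["genes_input"] = matrix.n_genes
    manifest["counts"]["genes_kept"] = kept.n_genes
    logged = run_stage("log", lambda: prep.log_transform(kept))

    plan = est.SamplingPlan(
        n_iterations=config.n_iterations,
        subset_size=config.subset_size,
        seed=stage_seed(config.seed, "pcor"),
    )
    assoc = run_stage("pcor", lambda: est.sampled_pcor_estimation(logged, plan))
    manifest["counts"]["pair_coverage"] = round(assoc.coverage, 6)
    run_stage(
        "write_pairs",
        lambda: est.write_pair_associations(assoc, out / "pair_associations.tsv"),
    )

    params = est.EdgeSelectionParams(
        pcor_threshold=config.pcor_threshold, pcc_threshold=config.pcc_threshold
    )
    net = run_stage("edges", lambda: est.select_edges(assoc, params))
    manifest["counts"]["n_positive_edges"] = net.graph["n_positive_edges"]
    manifest["counts"]["n_negative_edges"] = net.graph["n_negative_edges"]
    manifest["counts"]["n_edges"] = net.number_of_edges()
    run_stage("write_edges", lambda: est.write_edge_list(net, out / "edges.tsv"))

    if net.number_of_nodes() >= 3:
        stats = run_stage("stats", lambda: netmod.network_stats(net))
        manifest["counts"]["n_network_genes"] = stats.n_nodes
        manifest["counts"]["clustering_coefficient"] = round(
            stats.clustering_coefficient, 6
        )
        manifest["counts"]["random_expected_c"] = round(stats.random_expected_c, 8)
    else:
        manifest["counts"]["n_network_genes"] = net.number_of_nodes()

    mcl_params = netmod.MCLParams(
        inflation=config.inflation, min_module_size=config.min_module_size
    )
    modules = run_stage("mcl", lambda: netmod.mcl_cluster(net, mcl_params))
    manifest["counts"]["n_modules"] = modules.n_modules
    manifest["counts"]["n_retained_module_genes"] = len(modules.assignments)
    manifest["counts"]["n_small_module_genes"] = len(modules.small_module_genes)
    run_stage("write_modules", lambda: netmod.write_modules(modules, out / "modules.tsv"))

    universe = set(net.nodes)
    if config.annotations_path:
        def _go():
            ann = enr.read_annotations(config.annotations_path)
            frames = []
            for mid in sorted(modules.module_sizes):
                genes = modules.genes_in_module(mid) & universe
                if not genes:
                    continue
                res = enr.go_enrichment(genes, universe, ann)
                res.insert(0, "module_id", mid)
                frames.append(res)
            if frames:
                import pandas as pd

                table = pd.concat(frames, ignore_index=True)
                enr.write_enrichment(table, out / "go_enrichment.tsv")
                return table
            return None

        table = run_stage("go", _go)
        if table is not None:
            manifest["counts"]["n_enrichment_rows"] = len(table)

    if config.motif and config.promoters_path:
        def _motif():
            from .synthetic import read_promoters_fasta
            import pandas as pd

            promoters = read_promoters_fasta(config.promoters_path)
            hits = enr.scan_promoters(promoters, config.motif)
            prom_universe = universe & set(hits)
            rows = []
            for mid in sorted(modules.module_sizes):
                genes = modules.genes_in_module(mid) & prom_universe
                if not genes:
                    continue
                res = enr.motif_enrichment(genes, hits, prom_universe)
                rows.append(
                    {"module_id": mid, "motif": config.motif, "k": res.k,
                     "n": res.n, "p0": res.p0, "p_value": res.p_value}
                )
            table = pd.DataFrame(rows)
            table.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
            return table

        run_stage("motif", _motif)

    if config.partner_network_path and config.homolog_map_path:
        def _conserve():
            partner = netmod.build_network(est.read_edge_list(config.partner_network_path))
            homologs = cons.read_homolog_map(config.homolog_map_path)
            flags = cons.conserved_interactions(net, partner, homologs)
            report = cons.module_conservation(flags, modules)
            cons.write_conservation_report(
                report, out / "conservation_genes.tsv", out / "conservation_modules.tsv"
            )
            return report

        report = run_stage("conserve", _conserve)
        manifest["counts"]["network_wide_percent_conserved"] = round(
            report.network_wide_percent, 4
        )

    if config.sample_groups_path:
        def _profiles():
            groups = prof.read_sample_groups(config.sample_groups_path)
            profile = prof.module_mean_expression(logged, modules, groups)
            prof.write_module_profile(
                profile, out / "module_means.tsv", out / "module_relative.tsv"
            )
            return profile

        run_stage("profiles", _profiles)

    # bookkeeping identities
    c = manifest["counts"]
    assert c["n_edges"] == c["n_positive_edges"] + c["n_negative_edges"]
    assert c["n_network_genes"] == (
        c["n_retained_module_genes"] + c["n_small_module_genes"]
    )
    manifest["elapsed_seconds"] = round(time.time() - t0, 3)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.yml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
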