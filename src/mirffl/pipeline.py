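"""End-to-end pipeline orchestration from a single seeded configuration.

Runs simulate -> differential expression -> interaction filtering ->
network assembly and motif ranking -> survival -> enrichment, writing
every intermediate table under ``output_dir`` and a JSON manifest with
per-stage bookkeeping (up/down DE counts, node/edge totals per role and
type, the top-ranked motif, survival statistics). Stages can be toggled
individually; a disabled stage's inputs are read back from ``output_dir``
when a later stage needs them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .diffexpr import FoldChangeRule, collapse_duplicates, de_summary, run_de, top_k_table, volcano_table
from .enrichment import ora
from .filtering import calibrate_pairs, common_mirnas, filter_mir_edges, filter_tf_edges, split_mir_table
from .network import (
    assemble_network, degree_centrality, enumerate_ffls, motif_table,
    network_summary, rank_motifs, write_edge_list,
)
from .survival import covariate_scan, km_estimate, log_rank, median_split
from .synthetic import (
    PlantedMotif, gene_ids, generate_expression, generate_gene_sets,
    generate_methylation, generate_regulatory_tables, generate_survival,
    mirna_ids, tf_ids,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""


@dataclass
class PipelineConfig:
    """All stage parameters, thresholds at their standard defaults."""

    seed: int = 0
    output_dir: str = "mirffl_out"

    # synthetic cohort
    n_tfs: int = 30
    n_genes: int = 150
    n_mirnas: int = 60
    n_case: int = 30
    n_control: int = 30
    frac_de: float = 0.2
    effect: float = 0.75
    sd: float = 0.4

    # differential expression
    p_thresh: float = 0.05
    fc_rule: str = "band:0.5,1.0"
    adjust: str = "none"
    t_variant: str = "welch"

    # regulatory tables and filtering
    edge_prob: float = 0.04
    pass_prob: float = 0.5
    extra_degree: int = 30
    tf_p_thresh: float = 0.05
    mir_score_thresh: float = 0.95
    require_de_tfs: bool = False
    calibration_mode: str = "fixed_point"
    ffl_support: bool = False

    # network ranking
    rank_rule: str = "sum"
    normalized_centrality: bool = False

    # survival / methylation
    surv_n: int = 200
    baseline_rate: float = 0.02
    log_hr: float = 1.0
    censor_rate: float = 0.01
    invert_hr: bool = True
    n_cpg: int = 50
    meth_alpha: float = 2.0
    meth_beta: float = 5.0

    # enrichment
    n_gene_sets: int = 20
    gene_set_size: int = 25
    n_enriched_sets: int = 2
    top_k: int = 10

    # stage toggles
    run_simulate: bool = True
    run_de: bool = True
    run_filter: bool = True
    run_network: bool = True
    run_survival: bool = True
    run_enrich: bool = True

    def stage_seeds(self, n: int = 8) -> list[int]:
        state = np.random.SeedSequence(self.seed).generate_state(n)
        return [int(s % (2**31)) for s in state]


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """List every out-of-domain parameter with its documented domain."""
    diags: list[str] = []

    def check(ok: bool, name: str, domain: str) -> None:
        if not ok:
            diags.append(f"{name}={getattr(config, name)!r} outside its domain {domain}")

    c = config
    check(0 < c.p_thresh <= 1, "p_thresh", "(0, 1]")
    check(0 < c.tf_p_thresh <= 1, "tf_p_thresh", "(0, 1]")
    check(0 <= c.mir_score_thresh <= 1, "mir_score_thresh", "[0, 1]")
    check(0 <= c.frac_de <= 1, "frac_de", "[0, 1]")
    check(0 <= c.edge_prob <= 1, "edge_prob", "[0, 1]")
    check(0 <= c.pass_prob <= 1, "pass_prob", "[0, 1]")
    check(c.sd > 0, "sd", "(0, inf)")
    check(c.effect >= 0, "effect", "[0, inf)")
    check(c.baseline_rate > 0, "baseline_rate", "(0, inf)")
    check(c.censor_rate > 0, "censor_rate", "(0, inf)")
    check(c.meth_alpha > 0, "meth_alpha", "(0, inf)")
    check(c.meth_beta > 0, "meth_beta", "(0, inf)")
    check(c.n_case >= 2 and c.n_control >= 2, "n_case", ">= 2 per group")
    check(c.surv_n >= 10, "surv_n", ">= 10")
    check(c.extra_degree >= 0, "extra_degree", ">= 0")
    check(c.top_k >= 1, "top_k", ">= 1")
    check(c.adjust in {"none", "bh"}, "adjust", "{none, bh}")
    check(c.t_variant in {"welch", "pooled"}, "t_variant", "{welch, pooled}")
    check(c.rank_rule in {"sum", "max"}, "rank_rule", "{sum, max}")
    check(c.calibration_mode in {"fixed_point", "single_pass"}, "calibration_mode",
          "{fixed_point, single_pass}")
    try:
        FoldChangeRule.parse(c.fc_rule)
    except ValueError as exc:
        diags.append(f"fc_rule={c.fc_rule!r} unparsable: {exc}")
    return diags


def _planted_motif(config: PipelineConfig) -> PlantedMotif:
    return PlantedMotif(
        tf=tf_ids(config.n_tfs)[0],
        gene=gene_ids(config.n_genes)[0],
        mirna=mirna_ids(config.n_mirnas)[0],
        extra_degree=config.extra_degree,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    The manifest is also written to ``output_dir/manifest.json``; it is a
    pure function of the configuration (including the seed), so identical
    configs give byte-identical manifests.
    """
    diags = validate_config(config)
    if diags:
        raise PipelineError("invalid configuration: " + "; ".join(diags))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {"seed": config.seed, "config": dataclasses.asdict(config), "stages": {}}
    state: dict = {}

    stages = [
        ("simulate", config.run_simulate, _stage_simulate),
        ("de", config.run_de, _stage_de),
        ("filter", config.run_filter, _stage_filter),
        ("network", config.run_network, _stage_network),
        ("survival", config.run_survival, _stage_survival),
        ("enrich", config.run_enrich, _stage_enrich),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            continue
        logger.info("pipeline stage %s (seed=%d)", name, config.seed)
        try:
            manifest["stages"][name] = fn(config, out, seeds, state)
        except Exception as exc:
            _write_manifest(manifest, out)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# -- stages -------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path, seeds: list[int], state: dict) -> dict:
    planted = _planted_motif(cfg)
    genes, mirnas = gene_ids(cfg.n_genes), mirna_ids(cfg.n_mirnas)
    mrna_expr, mrna_truth = generate_expression(
        cfg.n_genes, cfg.n_case, cfg.n_control, cfg.frac_de, cfg.effect, cfg.sd,
        seed=seeds[0], feature_names=genes, forced_de=(planted.gene,),
    )
    mirna_expr, mirna_truth = generate_expression(
        cfg.n_mirnas, cfg.n_case, cfg.n_control, cfg.frac_de, cfg.effect, cfg.sd,
        seed=seeds[1], feature_names=mirnas, forced_de=(planted.mirna,),
    )
    tf_gene, mir_targets, _ = generate_regulatory_tables(
        cfg.n_tfs, cfg.n_genes, cfg.n_mirnas, cfg.edge_prob, planted,
        pass_prob=cfg.pass_prob, seed=seeds[2],
    )
    surv_expr = generate_survival(
        cfg.surv_n, cfg.baseline_rate, cfg.log_hr, covariate=None,
        censor_rate=cfg.censor_rate, seed=seeds[3],
    )
    meth = generate_methylation(cfg.n_cpg, cfg.surv_n, cfg.meth_alpha, cfg.meth_beta, seed=seeds[4])
    surv_meth = generate_survival(
        cfg.surv_n, cfg.baseline_rate, cfg.log_hr,
        covariate=meth.iloc[0].to_numpy(), censor_rate=cfg.censor_rate, seed=seeds[5],
    )
    true_de_genes = sorted(mrna_truth.loc[mrna_truth["is_de"], "feature_id"])
    gene_sets = generate_gene_sets(
        genes, cfg.n_gene_sets, cfg.gene_set_size, seed=seeds[6],
        enriched_from=true_de_genes, n_enriched=cfg.n_enriched_sets,
    )

    io.write_expression_tsv(mrna_expr, out / "mrna_expression.tsv")
    io.write_series_matrix(mirna_expr, out / "mirna_expression_series_matrix.txt", seed=cfg.seed)
    io.write_table(mrna_truth, out / "mrna_truth.csv")
    io.write_table(mirna_truth, out / "mirna_truth.csv")
    io.write_table(tf_gene, out / "tf_gene_interactions.csv")
    io.write_table(mir_targets, out / "mir_target_interactions.csv")
    io.write_table(surv_expr, out / "survival_expression.csv")
    io.write_table(surv_meth, out / "survival_methylation.csv")
    io.write_methylation(meth, out / "methylation.tsv")
    io.write_gmt(gene_sets, out / "gene_sets.gmt")

    state.update(
        mrna_expr=mrna_expr, mirna_expr=mirna_expr, mrna_truth=mrna_truth,
        mirna_truth=mirna_truth, tf_gene=tf_gene, mir_targets=mir_targets,
        surv_expr=surv_expr, surv_meth=surv_meth, meth=meth,
        gene_sets=gene_sets, planted=planted,
    )
    return {
        "n_mrna_features": cfg.n_genes,
        "n_mirna_features": cfg.n_mirnas,
        "n_samples": cfg.n_case + cfg.n_control,
        "n_tf_gene_rows": int(len(tf_gene)),
        "n_mir_target_rows": int(len(mir_targets)),
        "planted_motif": {"tf": planted.tf, "gene": planted.gene, "mirna": planted.mirna,
                          "extra_degree": planted.extra_degree},
    }


def _require(state: dict, key: str, out: Path, loader, filename: str):
    if key not in state:
        path = out / filename
        if not path.exists():
            raise PipelineError(f"missing input {key!r}: run the producing stage or provide {path}")
        state[key] = loader(path)
    return state[key]


def _stage_de(cfg: PipelineConfig, out: Path, seeds: list[int], state: dict) -> dict:
    summary = {}
    for kind, expr_key, filename in (
        ("mrna", "mrna_expr", "mrna_expression.tsv"),
        ("mirna", "mirna_expr", "mirna_expression_series_matrix.txt"),
    ):
        expr = _require(state, expr_key, out, io.read_expression, filename)
        expr = collapse_duplicates(expr)
        results = run_de(expr, cfg.p_thresh, cfg.fc_rule, cfg.adjust, cfg.t_variant)
        io.write_table(results, out / f"de_{kind}.csv")
        io.write_table(volcano_table(results), out / f"volcano_{kind}.csv")
        io.write_table(top_k_table(results, cfg.top_k), out / f"top_{kind}.csv")
        state[f"de_{kind}"] = results
        summary[kind] = de_summary(results)
    state["de_gene_ids"] = set(
        state["de_mrna"].loc[state["de_mrna"]["is_de"], "feature_id"]
    )
    state["universe"] = set(state["de_mrna"]["feature_id"])
    return summary


def _stage_filter(cfg: PipelineConfig, out: Path, seeds: list[int], state: dict) -> dict:
    tf_gene = _require(state, "tf_gene", out, io.read_tf_edges, "tf_gene_interactions.csv")
    mir_targets = _require(state, "mir_targets", out, io.read_mir_edges, "mir_target_interactions.csv")
    allowed = state.get("de_gene_ids")
    tf_kept = filter_tf_edges(tf_gene, cfg.tf_p_thresh, allowed_genes=allowed)
    if cfg.require_de_tfs and allowed is not None:
        tf_kept = tf_kept[tf_kept["tf"].isin(allowed)].reset_index(drop=True)
    mir_kept = filter_mir_edges(mir_targets, cfg.mir_score_thresh)
    mir_gene, mir_tf = split_mir_table(mir_kept)
    common = common_mirnas(mir_gene, mir_tf)
    tf_cal, mg_cal, mt_cal = calibrate_pairs(
        tf_kept, mir_gene, mir_tf, mode=cfg.calibration_mode, ffl_support=cfg.ffl_support
    )
    for name, table in (("tf_gene_calibrated", tf_cal), ("mir_gene_calibrated", mg_cal),
                        ("mir_tf_calibrated", mt_cal)):
        io.write_table(table, out / f"{name}.csv")
    state.update(tf_cal=tf_cal, mg_cal=mg_cal, mt_cal=mt_cal)
    return {
        "tf_edges_in": int(len(tf_gene)),
        "tf_edges_filtered": int(len(tf_kept)),
        "mir_edges_in": int(len(mir_targets)),
        "mir_edges_filtered": int(len(mir_kept)),
        "common_mirnas": int(len(common)),
        "tf_gene_calibrated": int(len(tf_cal)),
        "mir_gene_calibrated": int(len(mg_cal)),
        "mir_tf_calibrated": int(len(mt_cal)),
    }


def _stage_network(cfg: PipelineConfig, out: Path, seeds: list[int], state: dict) -> dict:
    tf_cal = _require(state, "tf_cal", out, io.read_tf_edges, "tf_gene_calibrated.csv")
    mg_cal = _require(state, "mg_cal", out, io.read_mir_edges, "mir_gene_calibrated.csv")
    mt_cal = _require(state, "mt_cal", out, io.read_mir_edges, "mir_tf_calibrated.csv")
    net = assemble_network(tf_cal, mg_cal, mt_cal)
    summary = network_summary(net)
    cent = degree_centrality(net, normalized=cfg.normalized_centrality)
    ffls = enumerate_ffls(net)
    ranked = rank_motifs(ffls, cent, rule=cfg.rank_rule)
    write_edge_list(net, out / "network_edges.tsv")
    io.write_table(motif_table(ranked), out / "motif_ranking.csv")
    result = dict(summary)
    result["n_ffls"] = len(ranked)
    if ranked:
        top = ranked[0]
        result["top_motif"] = {"tf": top.tf, "gene": top.gene, "mirna": top.mirna,
                               "motif_score": top.motif_score}
        planted = state.get("planted")
        if planted is not None:
            result["planted_recovered"] = bool(
                (top.tf, top.gene, top.mirna) == (planted.tf, planted.gene, planted.mirna)
            )
    state["ranked_motifs"] = ranked
    return result


def _stage_survival(cfg: PipelineConfig, out: Path, seeds: list[int], state: dict) -> dict:
    surv_expr = _require(state, "surv_expr", out, io.read_survival, "survival_expression.csv")
    result: dict = {}
    groups = median_split(surv_expr)
    res = log_rank(surv_expr, groups, invert_hr=cfg.invert_hr)
    for label in ("high", "low"):
        curve = km_estimate(surv_expr[(groups == label).to_numpy()])
        io.write_table(
            pd.DataFrame(
                {"time": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
            ),
            out / f"km_expression_{label}.csv",
        )
    result["expression"] = {
        "chi2": res.chi2, "p_value": res.p_value, "hr": res.hr,
        "n_high": res.n_high, "n_low": res.n_low, "inverted": res.inverted,
    }
    meth = _require(state, "meth", out, io.read_methylation, "methylation.tsv")
    surv_meth = _require(state, "surv_meth", out, io.read_survival, "survival_methylation.csv")
    scan = covariate_scan(meth, surv_meth, invert_hr=cfg.invert_hr)
    io.write_table(scan, out / "cpg_scan.csv")
    if len(scan):
        top = scan.iloc[0]
        result["methylation_top_cpg"] = {
            "feature_id": str(top["feature_id"]), "p_value": float(top["p_value"]),
            "hr": float(top["hr"]),
        }
    result["n_cpg_scanned"] = int(len(scan))
    return result


def _stage_enrich(cfg: PipelineConfig, out: Path, seeds: list[int], state: dict) -> dict:
    gene_sets = _require(state, "gene_sets", out, io.read_gmt, "gene_sets.gmt")
    if "de_gene_ids" not in state or "universe" not in state:
        raise PipelineError("enrich stage requires the de stage's gene list")
    table = ora(state["de_gene_ids"], state["universe"], gene_sets,
                p_thresh=cfg.p_thresh, top_k=cfg.top_k)
    io.write_table(table, out / "enrichment.csv")
    return {
        "n_sets": len(gene_sets),
        "n_reported": int(len(table)),
        "top_sets": list(table["set_name"].head(5)),
    }
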