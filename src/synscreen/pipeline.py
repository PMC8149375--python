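"""Configuration and end-to-end orchestration of the pipeline stages.

``run_pipeline`` chains the stages on synthetic data with planted truth:
simulate screen -> fit dose-response metrics -> nominate hits -> synergy
matrices -> count / phospho interaction models -> KS enrichment ->
heat-diffusion integration.  Every stage writes its artifacts as
deterministic TSV/CSV under the output directory, and a run log records the
seed and parameters, so two runs with the same configuration are
byte-identical.

Demo problem sizes here are deliberately small; the generators' own defaults
carry the full study design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io
from .dose_response import metrics_table
from .enrichment import AnnotationSet, RankedList, gsea_preranked, ksea, regulon_enrichment
from .errors import SchemaError, SynscreenError
from .interaction import lrt_interaction, rank_by_interaction
from .network import InputThresholds, diffuse, linker_subnetwork, select_inputs
from .nomination import CriterionConfig, criterion_votes, hsa_filter, nominate, rank_classification
from .simulate import (CountSimConfig, ScreenSimConfig, simulate_counts,
                       simulate_dose_matrix, simulate_phospho, simulate_screen)
from .synergy import bliss_excess, combination_index, fit_median_effect, rank_synergy

__all__ = ["PipelineConfig", "run_pipeline", "make_kinase_sets", "make_regulons"]


@dataclass
class PipelineConfig:
    """Umbrella configuration; section dicts override stage defaults."""

    seed: int = 0
    screen: dict = field(default_factory=lambda: {
        "n_drugs": 60, "n_cell_lines": 4, "n_sensitizers": 4})
    criteria: dict = field(default_factory=dict)
    synergy: dict = field(default_factory=lambda: {
        "n_synergy": 2, "n_null": 1, "excess": 0.15, "noise_sd": 0.0})
    counts: dict = field(default_factory=lambda: {
        "n_genes": 300, "n_reps": 3, "frac_interaction": 0.1,
        "beta_dc_magnitude": 1.5})
    phospho: dict = field(default_factory=lambda: {
        "n_peptides": 400, "n_kinases": 8, "set_size": 20, "shift": 1.5,
        "B": 200, "min_hits": 3})
    regulon: dict = field(default_factory=lambda: {
        "n_regulons": 6, "targets_per_regulon": 20, "B": 200})
    integration: dict = field(default_factory=lambda: {
        "restart": 0.15, "size_factor": 1.0,
        "mr_q_max": 0.25, "mr_score_min": 2.0, "ksea_q_max": 0.25})
    network_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise SchemaError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)


def make_kinase_sets(n_kinases: int, set_size: int) -> dict[str, list[str]]:
    """Synthetic kinase-substrate sets with disjoint substrates."""
    return {
        f"K{i:02d}": [f"sub_k{i:02d}_{j:03d}" for j in range(set_size)]
        for i in range(n_kinases)
    }


def make_regulons(
    truth: pd.DataFrame, n_regulons: int, targets_per_regulon: int, seed: int,
) -> tuple[dict[str, AnnotationSet], str]:
    """Regulons over the simulated genes, one planted active regulator.

    The active regulator's positive targets are the genes with the largest
    planted interaction coefficients and its negative targets the most
    negative ones, so its regulon concentrates at both ends of the
    interaction-ranked list with consistent signs.  The remaining regulons
    draw random genes.  Returns (regulons, active regulator name).
    """
    rng = np.random.default_rng(seed)
    by_beta = truth["beta_dc"].sort_values(kind="mergesort")
    half = targets_per_regulon // 2
    pos = list(by_beta.index[-half:])
    neg = list(by_beta.index[:targets_per_regulon - half])
    modes = {g: 1 for g in pos} | {g: -1 for g in neg}
    regulons = {"MR_active": AnnotationSet("MR_active", tuple(pos + neg), modes)}
    genes = np.array(truth.index)
    for i in range(1, n_regulons):
        name = f"MR_rand{i:02d}"
        members = rng.choice(genes, size=targets_per_regulon, replace=False)
        regulons[name] = AnnotationSet(name, tuple(members))
    return regulons, "MR_active"


def _demo_network(
    ksea_table: pd.DataFrame, mr_table: pd.DataFrame, seed: int,
) -> nx.Graph:
    """Small deterministic network joining the enrichment hits.

    The strongest kinase and regulator are bridged by a dedicated linker
    node; every other kinase/regulator hangs off a background ring.
    """
    rng = np.random.default_rng(seed)
    kinases = list(ksea_table.index)
    regulators = list(mr_table.index)
    g = nx.Graph()
    background = [f"bg{i:02d}" for i in range(12)]
    nx.add_cycle(g, background)
    top_k = ksea_table["nks"].abs().idxmax()
    top_r = mr_table["nks"].abs().idxmax()
    g.add_edge(top_k, "linker_hub")
    g.add_edge("linker_hub", top_r)
    for node in kinases + regulators:
        if node in (top_k, top_r):
            continue
        g.add_edge(node, background[int(rng.integers(len(background)))])
    return g


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, writing artifacts under ``out_dir``.

    Returns a summary dict of the headline quantities.  Any stage failure is
    re-raised with the stage name prepended.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "simulate-screen"
    try:
        screen_cfg = ScreenSimConfig(seed=config.seed, **config.screen)
        sim = simulate_screen(screen_cfg)
        io.write_dose_table(
            [s for pair in sim.pairs.values() for s in pair], out / "dose_table.csv")
        io.write_tsv(sim.truth.set_index("drug_id"), out / "screen_truth.tsv")

        stage = "fit-screen"
        metrics = metrics_table(list(sim.pairs.values()))
        io.write_tsv(metrics.set_index(["drug_id", "cell_line"]), out / "metrics.tsv")

        stage = "nominate"
        crit = CriterionConfig(**config.criteria)
        hsa_rows = []
        for (drug, line), (single, combo) in sim.pairs.items():
            passed, _ = hsa_filter(single.inhibition, sim.anchor_inhibition,
                                   combo.inhibition, crit)
            hsa_rows.append({"drug_id": drug, "cell_line": line, "hsa_pass": passed})
        hsa_df = pd.DataFrame(hsa_rows).set_index(["drug_id", "cell_line"])
        io.write_tsv(hsa_df, out / "hsa.tsv")
        votes = criterion_votes(metrics, crit)
        io.write_tsv(votes, out / "votes.tsv")
        nominated = nominate(votes, crit)
        io.write_tsv(nominated, out / "nominated.tsv")
        io.write_tsv(rank_classification(metrics), out / "heatmap_labels.tsv")
        summary["n_nominated"] = len(nominated)
        summary["nominated"] = list(nominated.index)

        stage = "synergy"
        syn_cfg = dict(config.synergy)
        excess = syn_cfg.get("excess", 0.15)
        noise = syn_cfg.get("noise_sd", 0.0)
        results = {}
        rows = []
        jobs = [(f"combo_syn{i}", "bliss_synergy") for i in range(syn_cfg.get("n_synergy", 2))]
        jobs += [(f"combo_null{i}", "bliss_null") for i in range(syn_cfg.get("n_null", 1))]
        for i, (name, mode) in enumerate(jobs):
            # Dm above the dose ranges keeps fa away from 1 so every CI cell
            # stays defined even after the planted excess is added
            params = {"anchor": {"Dm": 3e-6, "m": 1.2}, "drug": {"Dm": 1e-5, "m": 1.0}}
            matrix, _ = simulate_dose_matrix(
                mode, params, excess=excess if mode == "bliss_synergy" else 0.0,
                seed=config.seed + i, noise_sd=noise, combination_id=name)
            io.write_dose_matrix(matrix, out / f"matrix_{name}.csv")
            _, mean_excess = bliss_excess(matrix)
            fit_a = fit_median_effect(matrix.anchor_doses, matrix.anchor_alone)
            fit_d = fit_median_effect(matrix.drug_doses, matrix.drug_alone)
            ci = combination_index(matrix, fit_a, fit_d)
            results[name] = [ci]
            rows.append({"combination": name, "mode": mode,
                         "mean_bliss_excess": mean_excess,
                         "n_ci_synergistic": ci.n_synergistic,
                         "n_ci_defined": ci.n_defined, "mean_ci": ci.mean_ci})
        ranking = rank_synergy(results)
        io.write_tsv(pd.DataFrame(rows).set_index("combination"), out / "synergy_summary.tsv")
        summary["synergy_ranking"] = [r[0] for r in ranking]

        stage = "interaction"
        count_cfg = CountSimConfig(seed=config.seed, **config.counts)
        counts, design, truth = simulate_counts(count_cfg)
        io.write_tsv(counts, out / "counts.tsv")
        io.write_tsv(design, out / "design.tsv")
        lrt = lrt_interaction(counts, design)
        io.write_tsv(lrt, out / "interaction_rna.tsv")
        ranked_scores = rank_by_interaction(lrt)
        io.write_rnk(RankedList.from_scores(ranked_scores), out / "interaction.rnk")
        summary["n_interaction_genes"] = int(lrt["better_explained_by_full"].sum())

        stage = "enrich"
        ph = dict(config.phospho)
        kin_sets = make_kinase_sets(ph.get("n_kinases", 8), ph.get("set_size", 20))
        planted_kinase = sorted(kin_sets)[0]
        fc, _ = simulate_phospho(ph.get("n_peptides", 400), kin_sets,
                                 planted_kinase, ph.get("shift", 1.5),
                                 seed=config.seed)
        ksea_table = ksea(fc, kin_sets, min_hits=ph.get("min_hits", 3),
                          B=ph.get("B", 200), seed=config.seed)
        io.write_tsv(ksea_table, out / "ksea.tsv")
        reg = dict(config.regulon)
        regulons, active = make_regulons(truth, reg.get("n_regulons", 6),
                                         reg.get("targets_per_regulon", 20),
                                         seed=config.seed)
        io.write_gmt(regulons, out / "regulons.gmt")
        mr_table = regulon_enrichment(ranked_scores, regulons,
                                      B=reg.get("B", 200), seed=config.seed)
        io.write_tsv(mr_table, out / "master_regulators.tsv")
        gsea_table = gsea_preranked(
            ranked_scores,
            {name: list(s.members) for name, s in regulons.items()},
            B=reg.get("B", 200), seed=config.seed)
        io.write_tsv(gsea_table, out / "gsea.tsv")
        summary["top_kinase"] = str(ksea_table["nks"].abs().idxmax())
        summary["top_regulator"] = str(mr_table["nks"].abs().idxmax())

        stage = "integrate"
        integ = dict(config.integration)
        if config.network_path is not None:
            net_path = Path(config.network_path)
            if not net_path.exists():
                raise SchemaError(f"network file not found: {net_path}")
            g = io.read_edge_list(net_path)
        else:
            g = _demo_network(ksea_table, mr_table, config.seed)
            io.write_sif(g, out / "network.sif")
        thresholds = InputThresholds(
            mr_q_max=integ.get("mr_q_max", 0.05),
            mr_score_min=integ.get("mr_score_min", 5.0),
            ksea_q_max=integ.get("ksea_q_max", 0.05))
        upstream, downstream = select_inputs(mr_table, ksea_table,
                                             thresholds=thresholds)
        up_heats = diffuse(g, upstream, restart=integ.get("restart", 0.15))
        down_heats = diffuse(g, downstream, restart=integ.get("restart", 0.15))
        sub, node_table = linker_subnetwork(
            g, up_heats, down_heats, upstream, downstream,
            size_factor=integ.get("size_factor", 1.0))
        io.write_sif(sub, out / "subnetwork.sif")
        io.write_tsv(node_table, out / "subnetwork_nodes.tsv")
        summary["linkers"] = list(
            node_table.index[node_table["role"] == "linker"])
    except SynscreenError as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc

    with open(out / "run_log.yaml", "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(
            {"seed": config.seed, "config": dataclasses.asdict(config),
             "summary": {k: v for k, v in summary.items()
                         if isinstance(v, (int, float, str, list))}},
            fh, sort_keys=True)
    return summary
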