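"""End-to-end orchestration: simulate/load -> potency -> differential
expression -> UFG selection -> MVR models -> network propagation ->
pathway enrichment, with a run summary.

Every threshold actually applied is logged and recorded in the run
manifest, because the stage counts the pipeline reports are threshold
definitions in disguise.  Each stage writes a TSV intermediate; with
``resume=True`` a stage whose output already exists is reloaded instead of
recomputed, and resumed runs equal single-pass runs.
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

from . import core_io, diffexpr, mvr, network, potency, synthetic_data, ufg_select

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("ufgpanel")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    out_dir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    # used when simulate is False
    expression_path: str | None = None
    potency_path: str | None = None
    top_conc: dict = field(default_factory=dict)
    alias_path: str | None = None
    # generator overrides (simulate=True)
    synth: dict = field(default_factory=dict)
    graph: dict = field(default_factory=dict)
    # stage thresholds
    alpha_primary: float = 0.05
    alpha_strict: float = 0.0025
    fc_min_log2: float = 1.0
    alpha_regression: float = 0.05
    moderation: str = "auto"
    restart: float = 0.5
    k_subnetwork: int = 100
    p_max: float = 0.05
    q_max: float = 0.1
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage(path: Path, resume: bool, compute, reader=None):
    if resume and path.exists():
        log.info("resuming %s", path.name)
        return (reader or (lambda p: pd.read_csv(p, sep="\t")))(path)
    return compute()


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Run every stage and return the run directory.

    Writes stage TSVs, a JSON run summary mirroring the narrative counts
    (significant genes per threshold, unique genes, UFGs per drug, model
    calibration, enriched pathways) and a manifest.  Any stage error aborts
    with a stage-tagged message.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "thresholds": {
        "alpha_primary": config.alpha_primary,
        "alpha_strict": config.alpha_strict,
        "fc_min_log2": config.fc_min_log2,
        "alpha_regression": config.alpha_regression,
        "p_max": config.p_max,
        "q_max": config.q_max,
    }}

    # ---- stage: inputs -----------------------------------------------------
    try:
        if config.simulate:
            synth_cfg = synthetic_data.SynthConfig(**{"seed": config.seed, **config.synth})
            expr, pot, truth = synthetic_data.simulate_panel(synth_cfg)
            if not (resume and (out / "expression.tsv").exists()):
                core_io.write_expression_matrix(expr, out / "expression.tsv")
                core_io.write_potency_table(pot, out / "ic50.tsv")
                (out / "planted_truth.json").write_text(
                    json.dumps(dataclasses.asdict(truth), indent=2, sort_keys=True)
                )
        else:
            alias = core_io.read_alias_map(config.alias_path) if config.alias_path else None
            expr = core_io.read_expression_matrix(config.expression_path, alias)
            pot = core_io.read_potency_table(config.potency_path, config.top_conc)
            truth = None
        panel = core_io.PanelStudy(expr, pot)
        expr, pot = panel.joint()
    except Exception as err:
        raise RuntimeError(f"[inputs] {err}") from err

    drugs = pot.drugs
    summary["n_lines"] = len(panel.lines)
    summary["n_genes"] = len(expr.genes)

    # ---- stage: potency ----------------------------------------------------
    try:
        pot_summary = potency.summarize_potency(pot)
        pot_summary.reset_index().to_csv(out / "potency_summary.tsv", sep="\t", index=False)
        assignments = {d: potency.assign_quartiles(pot, d) for d in drugs}
        venn = {}
        if len(drugs) == 3:
            for side in ("top", "bottom"):
                counts = potency.quartile_overlap(list(assignments.values()), side)
                venn[side] = {"|".join(k): v for k, v in counts.items()}
        summary["quartile_size"] = assignments[drugs[0]].q
        summary["venn"] = venn
        summary["censored_per_drug"] = {
            d: int(pot.censored.loc[d].sum()) for d in drugs
        }
    except Exception as err:
        raise RuntimeError(f"[potency] {err}") from err

    # ---- stage: differential expression ------------------------------------
    try:
        def compute_de():
            log.info("differential expression, moderation=%s", config.moderation)
            tabs = [
                diffexpr.diffexpr_table(expr, assignments[d], config.moderation)
                for d in drugs
            ]
            de = pd.concat(tabs, ignore_index=True)
            de.to_csv(out / "diffexpr.tsv", sep="\t", index=False)
            return de

        de = _stage(out / "diffexpr.tsv", resume, compute_de)
        summary["significant"] = {
            d: {
                str(alpha): diffexpr.count_significant(de, d, alpha)[0]
                for alpha in (config.alpha_primary, config.alpha_strict)
            }
            for d in drugs
        }
    except Exception as err:
        raise RuntimeError(f"[diffexpr] {err}") from err

    # ---- stage: UFG selection ----------------------------------------------
    try:
        tables = {d: de[de["drug"] == d].copy() for d in drugs}
        unique_sets = ufg_select.drug_unique_genes(tables, config.alpha_strict)
        summary["unique_genes"] = {d: len(unique_sets[d]) for d in drugs}

        def compute_ufg():
            log.info(
                "UFG cascade: alpha_strict=%g fc_min_log2=%g alpha_regression=%g",
                config.alpha_strict, config.fc_min_log2, config.alpha_regression,
            )
            u = ufg_select.select_ufgs(
                tables, panel, config.alpha_strict, config.fc_min_log2,
                config.alpha_regression,
            )
            u.to_csv(out / "ufgs.tsv", sep="\t", index=False)
            return u

        def read_ufg(p):
            u = pd.read_csv(p, sep="\t")
            return u if len(u) else pd.DataFrame(columns=ufg_select.UFG_COLUMNS)

        ufgs = _stage(out / "ufgs.tsv", resume, compute_ufg, read_ufg)
        summary["ufgs_per_drug"] = {
            d: int((ufgs["cognate_drug"] == d).sum()) for d in drugs
        }
    except Exception as err:
        raise RuntimeError(f"[ufg] {err}") from err

    # ---- stage: MVR models -------------------------------------------------
    try:
        mvr_rows, quartile_rows = [], []
        ensembles = {}
        for d in drugs:
            genes = sorted(ufgs.loc[ufgs["cognate_drug"] == d, "gene"])
            if not genes:
                continue
            models = mvr.fit_univariate_models(genes, panel, d)
            noncog = [o for o in drugs if o != d]
            ensemble, specific = mvr.prioritize_subset(
                models, panel, d, noncog, config.alpha_regression
            )
            ensembles[d] = ensemble
            mvr_rows.append(
                {
                    "drug": d,
                    "n_ufgs": len(genes),
                    "subset_size": len(ensemble.members),
                    "subset_genes": ",".join(ensemble.genes),
                    "drug_specific": specific,
                    "calibration_slope": ensemble.calibration.slope,
                    "calibration_r_squared": ensemble.calibration.r_squared,
                    "calibration_p": ensemble.calibration.p,
                }
            )
            predicted = ensemble.predict(expr)
            measured = np.log10(pot.drug_ic50(d))
            qp = mvr.quartile_mean_prediction(predicted, measured, assignments[d])
            qp.insert(0, "drug", d)
            quartile_rows.append(qp)
        mvr_summary = pd.DataFrame(
            mvr_rows,
            columns=[
                "drug", "n_ufgs", "subset_size", "subset_genes", "drug_specific",
                "calibration_slope", "calibration_r_squared", "calibration_p",
            ],
        )
        mvr_summary.to_csv(out / "mvr_summary.tsv", sep="\t", index=False)
        if quartile_rows:
            pd.concat(quartile_rows, ignore_index=True).to_csv(
                out / "quartile_prediction.tsv", sep="\t", index=False
            )
        summary["mvr"] = mvr_rows
    except Exception as err:
        raise RuntimeError(f"[mvr] {err}") from err

    # ---- stage: network propagation + enrichment ---------------------------
    try:
        net_summaries = {}
        for d in drugs:
            genes = sorted(ufgs.loc[ufgs["cognate_drug"] == d, "gene"])
            if not genes:
                continue
            # graph larger than the k=100 subnetwork, or enrichment is vacuous
            graph_cfg = synthetic_data.GraphConfig(
                **{
                    "seed": config.seed,
                    "seed_genes": tuple(genes),
                    "n_modules": 12,
                    "module_size": 25,
                    **config.graph,
                }
            )
            graph, pathways = synthetic_data.simulate_graph_and_pathways(graph_cfg)
            result = network.rwr_propagate(graph, genes, restart=config.restart)
            members, sub = network.top_k_subnetwork(graph, result, config.k_subnetwork)
            network.write_edge_list(sub, out / f"subnetwork_{d}.tsv")
            enr = network.hypergeometric_enrichment(
                set(members), pathways, set(graph.nodes)
            )
            kept = network.filter_pathways(enr, config.p_max, config.q_max)
            enr.to_csv(out / f"enrichment_{d}.tsv", sep="\t", index=False)
            net_summaries[d] = {
                "seeds_used": len(result.seeds_used),
                "seeds_dropped": len(result.seeds_dropped),
                "subnetwork_size": len(members),
                "enriched_pathways": int(len(kept)),
            }
        summary["network"] = net_summaries
    except Exception as err:
        raise RuntimeError(f"[network] {err}") from err

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    core_io.write_manifest(out, dataclasses.asdict(config), seed=config.seed)
    log.info("run complete: %s", out)
    return out
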