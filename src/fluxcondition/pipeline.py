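"""End-to-end orchestration: from model + expression + interactions to
consensus reactions, subsystem clustergram, enrichment and hub genes.

The experimental design has five diet groups sampled at two timepoints.
Group 2 (ad libitum + overnight fast) is the control; its replicates
from both days are pooled into a single control condition, giving eight
non-control condition columns (group 1 and groups 3–5, each at days 4
and 14) plus the control.  For every condition the pipeline builds a
GIMME and an E-flux condition-specific model, computes the deterministic
minimum-L1 flux state, and hands the two reactions × conditions flux
tables to the comparison stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .analysis import FLUX_EPS, fba
from .comparison import (
    ClusterResult,
    ConsensusSet,
    ProjectiveDecompositionResult,
    active_reactions,
    cluster_subsystems,
    consensus_active_set,
    projective_decompose,
    subsystem_flux_table,
)
from .enrichment import EnrichmentRow, GeneSetCollection, fisher_enrichment
from .integration import (
    GIMME_REQUIRED_FRACTION,
    GIMME_THRESHOLD_PERCENTILE,
    ExpressionMatrix,
    eflux,
    gimme,
    gimme_threshold,
    reaction_expression,
)
from .model import (
    MetabolicModel,
    find_dead_end_metabolites,
    model_stats,
    read_ortholog_map,
    translate_genes,
)
from .network import (
    DEFAULT_HUB_COUNT,
    DEFAULT_SCORE_THRESHOLD,
    NetworkMetrics,
    build_graph,
    degree_and_betweenness,
    identify_hubs,
    read_edge_list,
)

__all__ = ["PipelineConfig", "PipelineResult", "condition_cells", "analyze", "run_pipeline"]

logger = logging.getLogger(__name__)

CONTROL_LABEL = "group2_fast"


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    Parameter provenance: eps_flux (1e-6), score_threshold (>0.7) and fdr
    (0.05) follow the published cutoffs of the analysis this mirrors;
    the GIMME threshold mode, required fraction, control pooling and hub
    count are package conventions.
    """

    sbml: Optional[str] = None
    expression: Optional[str] = None
    metadata: Optional[str] = None
    ortholog_map: Optional[str] = None
    edge_list: Optional[str] = None
    output_dir: str = "fluxcondition_out"

    eps_flux: float = FLUX_EPS
    gimme_threshold_mode: str = "percentile"  # or "absolute"
    gimme_threshold_value: float = GIMME_THRESHOLD_PERCENTILE
    required_fraction: float = GIMME_REQUIRED_FRACTION
    control_group: int = 2
    control_label: str = CONTROL_LABEL
    flux_table_method: str = "eflux"  # which table feeds the subsystem stage
    # |mean flux change| (mmol/gDW/h) above which a subsystem counts as altered
    altered_cutoff: float = 0.5
    fdr: float = 0.05
    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    hub_k: int = DEFAULT_HUB_COUNT
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    model: MetabolicModel
    unmapped_genes: List[str]
    dead_ends: List[str]
    condition_labels: List[str]
    gimme_fluxes: pd.DataFrame
    eflux_fluxes: pd.DataFrame
    gimme_inconsistency: Dict[str, float]
    gimme_counts: pd.Series
    eflux_counts: pd.Series
    consensus: ConsensusSet
    subsystem_table: pd.DataFrame
    decomposition: ProjectiveDecompositionResult
    clustering: ClusterResult
    altered_subsystems: List[str]
    enrichment: List[EnrichmentRow]
    network_metrics: Optional[NetworkMetrics]
    hubs: List[str]
    timings: Dict[str, float] = field(default_factory=dict)


def condition_cells(
    expr: ExpressionMatrix, control_group: int = 2, control_label: str = CONTROL_LABEL
) -> List[Tuple[str, int, Optional[int]]]:
    """Condition columns: one per non-control (group, day) cell plus a
    single pooled control (both days of the control group)."""
    meta = expr.sample_meta
    cells: List[Tuple[str, int, Optional[int]]] = [(control_label, control_group, None)]
    for group in sorted(meta["group"].unique()):
        if group == control_group:
            continue
        for day in sorted(meta.loc[meta["group"] == group, "day"].unique()):
            cells.append((f"group{group}_day{day}", int(group), int(day)))
    return cells


def analyze(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    edges: Optional[pd.DataFrame] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    cfg = config or PipelineConfig()
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    dead_ends = find_dead_end_metabolites(model)
    timings["diagnostics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cells = condition_cells(expr, cfg.control_group, cfg.control_label)
    rxn_ids = [r.id for r in model.reactions]
    gimme_cols: Dict[str, pd.Series] = {}
    eflux_cols: Dict[str, pd.Series] = {}
    inconsistency: Dict[str, float] = {}
    for label, group, day in cells:
        gene_means = expr.condition_mean(group, day)
        rxn_expr = reaction_expression(model, gene_means)
        if cfg.gimme_threshold_mode == "percentile":
            thr = gimme_threshold(rxn_expr, cfg.gimme_threshold_value)
        else:
            thr = cfg.gimme_threshold_value
        cond_g, dist_g = gimme(
            model, rxn_expr, thr, cfg.required_fraction, condition=label
        )
        gimme_cols[label] = pd.Series(dist_g.fluxes)
        inconsistency[label] = cond_g.inconsistency
        cond_e = eflux(model, rxn_expr, condition=label)
        dist_e = fba(cond_e.apply(model), minimize_l1=True)
        if not dist_e.optimal:
            raise RuntimeError(f"E-flux FBA for {label} is {dist_e.status}")
        eflux_cols[label] = pd.Series(dist_e.fluxes)
    gimme_fluxes = pd.DataFrame(gimme_cols).loc[rxn_ids]
    eflux_fluxes = pd.DataFrame(eflux_cols).loc[rxn_ids]
    timings["condition_models"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    g_counts = active_reactions(gimme_fluxes, cfg.eps_flux)
    e_counts = active_reactions(eflux_fluxes, cfg.eps_flux)
    consensus = consensus_active_set(g_counts, e_counts, len(cells), cfg.eps_flux)
    table = eflux_fluxes if cfg.flux_table_method == "eflux" else gimme_fluxes
    sub_table = subsystem_flux_table(model, consensus, table, cfg.control_label)
    # rows/columns indistinguishable from zero at flux precision cannot be
    # RMS-normalized (a condition identical to control gives a zero column)
    nonzero = sub_table.loc[
        (sub_table.abs().max(axis=1) >= cfg.eps_flux),
        (sub_table.abs().max(axis=0) >= cfg.eps_flux),
    ]
    decomposition = projective_decompose(nonzero)
    clustering = cluster_subsystems(decomposition.core)
    # altered = subsystems whose mean |flux| moved materially from control
    # in at least one condition (judged on the unnormalized table; the
    # normalized core serves visualisation and clustering)
    altered = sorted(
        sub_table.index[(sub_table.abs() >= cfg.altered_cutoff).any(axis=1)]
    )
    timings["flux_comparison"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    subsystem_genes: Dict[str, set] = {}
    for rxn in model.reactions:
        if rxn.subsystem and not rxn.gpr.empty:
            subsystem_genes.setdefault(rxn.subsystem, set()).update(rxn.gpr.genes())
    collection = GeneSetCollection.from_dict(subsystem_genes, model.genes)
    query: set = set()
    for sub in altered:
        query |= subsystem_genes.get(sub, set())
    enrichment = fisher_enrichment(query, collection) if query else []
    timings["enrichment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    metrics: Optional[NetworkMetrics] = None
    hubs: List[str] = []
    if edges is not None:
        graph = build_graph(edges, cfg.score_threshold)
        metrics = degree_and_betweenness(graph)
        hubs = identify_hubs(metrics, cfg.hub_k)
    timings["network"] = time.perf_counter() - t0

    return PipelineResult(
        model=model,
        unmapped_genes=[],
        dead_ends=dead_ends,
        condition_labels=[c[0] for c in cells],
        gimme_fluxes=gimme_fluxes,
        eflux_fluxes=eflux_fluxes,
        gimme_inconsistency=inconsistency,
        gimme_counts=g_counts,
        eflux_counts=e_counts,
        consensus=consensus,
        subsystem_table=sub_table,
        decomposition=decomposition,
        clustering=clustering,
        altered_subsystems=altered,
        enrichment=enrichment,
        network_metrics=metrics,
        hubs=hubs,
        timings=timings,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs per config, run :func:`analyze`, write the report bundle."""
    from .sbml_io import read_sbml

    for attr in ("sbml", "expression", "metadata"):
        path = getattr(config, attr)
        if path is None:
            raise ValueError(f"config is missing required path {attr!r}")
        if not Path(path).exists():
            raise FileNotFoundError(f"{attr} file not found: {path}")
    for attr in ("ortholog_map", "edge_list"):
        path = getattr(config, attr)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{attr} file not found: {path}")

    model = read_sbml(config.sbml)
    unmapped: List[str] = []
    if config.ortholog_map:
        model, unmapped = translate_genes(model, read_ortholog_map(config.ortholog_map))
    expr = ExpressionMatrix.read_tsv(config.expression, config.metadata)
    edges = read_edge_list(config.edge_list) if config.edge_list else None

    result = analyze(model, expr, edges, config)
    result.unmapped_genes = unmapped
    _write_bundle(result, config)
    return result


def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats = model_stats(result.model).as_dict()
    pd.Series(stats).to_csv(out / "model_stats.tsv", sep="\t", header=False)
    (out / "dead_ends.txt").write_text("\n".join(result.dead_ends) + "\n")
    result.gimme_fluxes.to_csv(out / "gimme_fluxes.tsv", sep="\t", index_label="reaction")
    result.eflux_fluxes.to_csv(out / "eflux_fluxes.tsv", sep="\t", index_label="reaction")
    counts = pd.DataFrame({"gimme": result.gimme_counts, "eflux": result.eflux_counts})
    counts.to_csv(out / "active_counts.tsv", sep="\t", index_label="reaction")
    pd.Series(result.consensus.reactions).to_csv(
        out / "consensus_reactions.tsv", sep="\t", index=False, header=["reaction"]
    )
    result.subsystem_table.to_csv(out / "subsystem_flux.tsv", sep="\t", index_label="subsystem")
    result.decomposition.core.to_csv(
        out / "normalized_core.tsv", sep="\t", index_label="subsystem"
    )
    (out / "subsystem_tree.nwk").write_text(result.clustering.newick + "\n")
    _plot_clustergram(result, out / "clustergram.png")
    pd.DataFrame(
        [dataclasses.asdict(row) for row in result.enrichment]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if result.network_metrics is not None:
        pd.Series(result.network_metrics.degree, name="degree").to_csv(
            out / "node_degree.tsv", sep="\t", index_label="gene"
        )
        eb = result.network_metrics.edge_betweenness
        pd.DataFrame(
            [(a, b, v) for (a, b), v in sorted(eb.items())],
            columns=["gene_a", "gene_b", "edge_betweenness"],
        ).to_csv(out / "edge_betweenness.tsv", sep="\t", index=False)
        (out / "hubs.txt").write_text("\n".join(result.hubs) + "\n")
    manifest = {
        "package_version": _pkg_version,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "conditions": result.condition_labels,
        "n_consensus": len(result.consensus),
        "altered_subsystems": result.altered_subsystems,
        "hubs": result.hubs,
        "timings_s": {k: round(v, 4) for k, v in result.timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _plot_clustergram(result: PipelineResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    core = result.decomposition.core.loc[result.clustering.order]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.4 * len(core))))
    im = ax.imshow(core.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(core.index)), core.index, fontsize=8)
    ax.set_xticks(range(len(core.columns)), core.columns, rotation=45, ha="right", fontsize=8)
    fig.colorbar(im, ax=ax, label="normalized flux change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
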