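"""Synthetic fixtures with known ground truth.

Three generators emulate the study's three data layers:

* :func:`generate_toy_gem` — a ~40-reaction, 3-compartment liver-like
  GEM (glycolysis/gluconeogenesis, TCA cycle, pentose phosphate pathway,
  fatty-acid oxidation, oxidative phosphorylation, transports, exchanges,
  a biomass objective and one deliberately dead-ended side branch), small
  enough for exhaustive LP oracles yet rich enough to carry every
  pipeline stage;
* :func:`generate_expression` — a 5-group × 2-day × n-replicate log2
  expression matrix with pathway-localised diet-restriction effects and
  Gaussian log-scale noise, mirroring the feeding design (group 1
  ad libitum, 2 ad libitum + overnight fast = control, 3/4/5 = −15/−30/
  −60% food, sampled at days 4 and 14);
* :func:`generate_interactions` — a scored gene-interaction edge list
  with planted high-degree hub genes.

Each generator returns its ground truth alongside the data so that
recovery tests can check the pipeline finds what was planted.
All randomness flows through a seed parameter; the same seed reproduces
byte-identical outputs.  Synthetic gene ids are namespaced ``SYNG…`` to
avoid collision with real symbol spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .gpr import parse_gpr
from .integration import ExpressionMatrix
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyGemSpec",
    "ToyGemTruth",
    "ExpressionSimSpec",
    "generate_toy_gem",
    "generate_expression",
    "generate_interactions",
    "DEFAULT_EFFECTS",
    "DEFAULT_HUB_GENES",
]

GLY = "Glycolysis/gluconeogenesis"
TCA = "TCA cycle"
PPP = "Pentose phosphate pathway"
FAO = "Fatty acid oxidation"
OXPHOS = "Oxidative phosphorylation"
TRANSPORT = "Transport"
EXCHANGE = "Exchange"
BIOMASS_SS = "Biomass"
PURINE = "Purine metabolism"

# id, stoichiometry, lb, ub, gpr, subsystem
_REACTIONS: List[tuple] = [
    # exchanges (negative flux = uptake)
    ("EX_glc_e", {"glc_e": -1}, -10.0, 1000.0, "", EXCHANGE),
    ("EX_fa_e", {"fa_e": -1}, -6.0, 1000.0, "", EXCHANGE),
    ("EX_o2_e", {"o2_e": -1}, -20.0, 0.0, "", EXCHANGE),
    ("EX_co2_e", {"co2_e": -1}, 0.0, 1000.0, "", EXCHANGE),
    # lactate is secretion-only in the growth medium; uptake is what the
    # gluconeogenesis function task forces
    ("EX_lac_e", {"lac_e": -1}, 0.0, 1000.0, "", EXCHANGE),
    # transports
    ("GLCt", {"glc_e": -1, "glc_c": 1}, -1000.0, 1000.0, "SYNG0001", TRANSPORT),
    ("FAt", {"fa_e": -1, "fa_c": 1}, 0.0, 1000.0, "SYNG0002", TRANSPORT),
    ("O2t", {"o2_e": -1, "o2_c": 1}, 0.0, 1000.0, "", TRANSPORT),
    ("O2tm", {"o2_c": -1, "o2_m": 1}, 0.0, 1000.0, "", TRANSPORT),
    ("CO2t", {"co2_c": -1, "co2_e": 1}, 0.0, 1000.0, "", TRANSPORT),
    ("CO2tm", {"co2_m": -1, "co2_c": 1}, -1000.0, 1000.0, "", TRANSPORT),
    ("LACt", {"lac_e": -1, "lac_c": 1}, -1000.0, 1000.0, "SYNG0003", TRANSPORT),
    ("PYRtm", {"pyr_c": -1, "pyr_m": 1}, 0.0, 1000.0, "SYNG0004", TRANSPORT),
    ("OAAtm", {"oaa_m": -1, "oaa_c": 1}, -1000.0, 1000.0, "SYNG0005", TRANSPORT),
    ("ATPtm", {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1}, -1000.0, 1000.0,
     "SYNG0006", TRANSPORT),
    ("NADHS", {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1}, 0.0, 1000.0,
     "(SYNG0007 and SYNG0008)", TRANSPORT),
    ("FAtm", {"fa_c": -1, "atp_c": -1, "fa_m": 1, "adp_c": 1}, 0.0, 1000.0,
     "SYNG0009", TRANSPORT),
    # glycolysis / gluconeogenesis
    ("HEX", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, 0.0, 40.0,
     "(SYNG0101 or SYNG0102)", GLY),
    ("PGI", {"g6p_c": -1, "f6p_c": 1}, -40.0, 40.0, "SYNG0103", GLY),
    ("PFK", {"f6p_c": -1, "atp_c": -1, "t3p_c": 2, "adp_c": 1}, 0.0, 40.0,
     "(SYNG0104 and SYNG0105)", GLY),
    ("GAPD", {"t3p_c": -1, "nad_c": -1, "adp_c": -1, "pep_c": 1, "nadh_c": 1, "atp_c": 1},
     0.0, 40.0, "SYNG0106", GLY),
    ("PYK", {"pep_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1}, 0.0, 40.0,
     "(SYNG0107 or SYNG0108)", GLY),
    ("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1}, -40.0, 40.0,
     "SYNG0109", GLY),
    ("FBP", {"t3p_c": -2, "f6p_c": 1}, 0.0, 40.0, "SYNG0110", GLY),
    ("G6PASE", {"g6p_c": -1, "glc_c": 1}, 0.0, 40.0, "SYNG0111", GLY),
    ("PEPCK", {"oaa_c": -1, "atp_c": -1, "pep_c": 1, "adp_c": 1}, 0.0, 40.0,
     "SYNG0112", GLY),
    ("GNG1", {"pep_c": -1, "nadh_c": -1, "atp_c": -1, "t3p_c": 1, "nad_c": 1, "adp_c": 1},
     0.0, 40.0, "SYNG0113", GLY),
    # TCA cycle (lumped)
    ("PDH", {"pyr_m": -1, "nad_m": -1, "accoa_m": 1, "co2_m": 1, "nadh_m": 1}, 0.0, 40.0,
     "(SYNG0201 and SYNG0202 and SYNG0203)", TCA),
    ("PC", {"pyr_m": -1, "co2_m": -1, "atp_m": -1, "oaa_m": 1, "adp_m": 1}, 0.0, 40.0,
     "SYNG0204", TCA),
    ("CS", {"accoa_m": -1, "oaa_m": -1, "cit_m": 1}, 0.0, 40.0, "SYNG0205", TCA),
    ("ACONT", {"cit_m": -1, "nad_m": -1, "akg_m": 1, "co2_m": 1, "nadh_m": 1}, 0.0, 40.0,
     "SYNG0206", TCA),
    ("AKGD", {"akg_m": -1, "nad_m": -1, "adp_m": -1, "oaa_m": 1, "co2_m": 1, "nadh_m": 1,
              "atp_m": 1}, 0.0, 40.0, "(SYNG0207 and SYNG0208)", TCA),
    # oxidative phosphorylation + maintenance
    ("ETC", {"nadh_m": -1, "o2_m": -0.5, "adp_m": -2, "nad_m": 1, "atp_m": 2}, 0.0, 1000.0,
     "(SYNG0301 and SYNG0302)", OXPHOS),
    # non-growth maintenance demand dominates the liver's ATP budget
    ("ATPM", {"atp_c": -1, "adp_c": 1}, 25.0, 1000.0, "", OXPHOS),
    # pentose phosphate pathway
    ("G6PDH", {"g6p_c": -1, "nadp_c": -2, "p5p_c": 1, "co2_c": 1, "nadph_c": 2}, 0.0, 40.0,
     "SYNG0401", PPP),
    ("TKT", {"p5p_c": -3, "f6p_c": 2, "t3p_c": 1}, -40.0, 40.0,
     "(SYNG0402 or SYNG0403)", PPP),
    # fatty-acid oxidation (one lumped C8 beta-oxidation)
    ("BOX", {"fa_m": -1, "nad_m": -4, "accoa_m": 4, "nadh_m": 4}, 0.0, 8.0,
     "(SYNG0501 and SYNG0502)", FAO),
    # deliberately dead-ended side branch (prpp_c has no consumer)
    ("PRPPS_D", {"p5p_c": -1, "atp_c": -1, "prpp_c": 1, "adp_c": 1}, 0.0, 40.0,
     "SYNG0601", PURINE),
    # biomass
    ("BIOMASS", {"g6p_c": -3, "p5p_c": -2, "pyr_c": -5, "oaa_c": -3, "accoa_m": -5,
                 "atp_c": -5, "nadph_c": -6, "biomass_c": 1, "adp_c": 5, "nadp_c": 6},
     0.0, 1000.0, "", BIOMASS_SS),
    ("DM_biomass", {"biomass_c": -1}, 0.0, 1000.0, "", EXCHANGE),
]

#: reactions that must carry flux whenever the model grows on glucose —
#: the constitutive main carbon path used by recovery tests
CONSTITUTIVE_REACTIONS = [
    "EX_glc_e", "EX_o2_e", "EX_co2_e",
    "GLCt", "O2t", "O2tm", "CO2t", "CO2tm", "PYRtm", "ATPtm",
    "HEX", "PGI", "PFK", "GAPD", "PYK",
    "ETC", "ATPM", "G6PDH", "TKT",
    "BIOMASS", "DM_biomass",
]

#: planted hub genes: hexokinase-, GAPDH- and pyruvate-kinase-like
DEFAULT_HUB_GENES = ["SYNG0101", "SYNG0106", "SYNG0107"]


@dataclass(frozen=True)
class ToyGemSpec:
    model_id: str = "toyLiver"
    seed: int = 0


@dataclass(frozen=True)
class ToyGemTruth:
    dead_end_metabolites: List[str]
    blocked_reactions: List[str]
    constitutive_reactions: List[str]
    biomass_reaction: str
    pathway_genes: Dict[str, List[str]]


def generate_toy_gem(spec: ToyGemSpec = ToyGemSpec()) -> Tuple[MetabolicModel, ToyGemTruth]:
    """Build the toy liver GEM; deterministic given the spec."""
    met_ids = sorted({m for _, stoich, *_ in _REACTIONS for m in stoich})
    metabolites = [
        Metabolite(id=m, name=m.rsplit("_", 1)[0], compartment=m.rsplit("_", 1)[1])
        for m in met_ids
    ]
    reactions = [
        Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                 gpr=parse_gpr(gpr), subsystem=subsystem)
        for rid, stoich, lb, ub, gpr, subsystem in _REACTIONS
    ]
    model = MetabolicModel(
        id=spec.model_id,
        metabolites=metabolites,
        reactions=reactions,
        compartments=sorted({m.compartment for m in metabolites}),
        objective_reaction_id="BIOMASS",
    )
    model.validate()
    pathway_genes: Dict[str, List[str]] = {}
    for rxn in model.reactions:
        if rxn.subsystem:
            pathway_genes.setdefault(rxn.subsystem, [])
            for g in sorted(rxn.gpr.genes()):
                if g not in pathway_genes[rxn.subsystem]:
                    pathway_genes[rxn.subsystem].append(g)
    truth = ToyGemTruth(
        dead_end_metabolites=["prpp_c"],
        blocked_reactions=["PRPPS_D"],
        constitutive_reactions=list(CONSTITUTIVE_REACTIONS),
        biomass_reaction="BIOMASS",
        pathway_genes={k: sorted(v) for k, v in pathway_genes.items()},
    )
    return model, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

#: diet-restriction effects: (group, day) -> subsystem -> linear multiplier.
#: Early restriction is buffered by glycogen (small day-4 effects); by day
#: 14 glycolysis is progressively suppressed and fatty-acid oxidation
#: induced with restriction severity, with a milder PPP decrease.
DEFAULT_EFFECTS: Dict[Tuple[int, int], Dict[str, float]] = {
    (3, 4): {GLY: 0.9},
    (3, 14): {GLY: 0.7, FAO: 1.25},
    (4, 4): {GLY: 0.7, FAO: 1.25},
    (4, 14): {GLY: 0.45, FAO: 1.5, PPP: 0.8},
    (5, 4): {GLY: 0.5, FAO: 1.5, PPP: 0.7},
    (5, 14): {GLY: 0.25, FAO: 2.0, PPP: 0.5},
}


@dataclass(frozen=True)
class ExpressionSimSpec:
    replicates: int = 5
    noise_sd: float = 0.25  # log2 scale
    baseline_low: float = 10.8  # log2 intensity range of baselines
    baseline_high: float = 12.0
    effects: Dict[Tuple[int, int], Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    )
    groups: Tuple[int, ...] = (1, 2, 3, 4, 5)
    days: Tuple[int, ...] = (4, 14)
    seed: int = 0


def generate_expression(
    spec: ExpressionSimSpec, model: MetabolicModel
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the diet-restriction expression matrix for a model's genes.

    Per gene: a fixed baseline log2 intensity drawn once, shifted by
    log2(multiplier) of its pathway's effect in each (group, day) cell,
    plus i.i.d. Gaussian noise per sample.  Returns the matrix and the
    true effect table (gene, group, day, multiplier) for recovery tests.
    """
    genes = model.genes
    if not genes:
        raise ValueError("model has no genes to simulate expression for")
    gene_subsystem: Dict[str, str] = {}
    for rxn in model.reactions:
        for g in rxn.gpr.genes():
            gene_subsystem.setdefault(g, rxn.subsystem)
    for cell, effects in spec.effects.items():
        unknown = set(effects) - {r.subsystem for r in model.reactions}
        if unknown:
            raise ValueError(f"effects for {cell} name unknown pathways: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    baseline = {g: rng.uniform(spec.baseline_low, spec.baseline_high) for g in genes}

    columns: Dict[str, np.ndarray] = {}
    meta_rows = []
    truth_rows = []
    for group in spec.groups:
        for day in spec.days:
            effects = spec.effects.get((group, day), {})
            with np.errstate(divide="ignore"):
                # multiplier 0 (complete silencing) maps to -inf log2 intensity
                shift = np.array(
                    [np.log2(effects.get(gene_subsystem[g], 1.0)) for g in genes]
                )
            for g_i, gene in enumerate(genes):
                mult = effects.get(gene_subsystem[gene], 1.0)
                if mult != 1.0:
                    truth_rows.append((gene, group, day, mult))
            base = np.array([baseline[g] for g in genes])
            for rep in range(1, spec.replicates + 1):
                sample = f"g{group}_d{day}_r{rep}"
                noise = rng.normal(0.0, spec.noise_sd, size=len(genes))
                columns[sample] = base + shift + noise
                meta_rows.append({"sample": sample, "group": group, "day": day,
                                  "replicate": rep})
    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows, columns=["gene", "group", "day", "multiplier"])
    return ExpressionMatrix(values, meta), truth


# ---------------------------------------------------------------------------
# Interaction network simulation
# ---------------------------------------------------------------------------


def generate_interactions(
    model: MetabolicModel,
    planted_hubs: Optional[List[str]] = None,
    seed: int = 0,
    n_background_edges: int = 120,
    hub_degree: int = 15,
    max_background_degree: int = 6,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Scored gene-interaction edge list with guaranteed hub structure.

    Planted hubs each receive ``hub_degree`` confident edges
    (score > threshold); background edges get Uniform(0.5, 1) scores but
    any that would push a non-hub's confident degree past
    ``max_background_degree`` are demoted below the threshold.  As long
    as ``hub_degree > max_background_degree + len(planted_hubs)`` every
    planted hub out-ranks every other node after threshold filtering.
    """
    genes = model.genes
    hubs = DEFAULT_HUB_GENES if planted_hubs is None else list(planted_hubs)
    stray = [h for h in hubs if h not in genes]
    if stray:
        raise ValueError(f"planted hubs not in model gene list: {stray}")
    rng = np.random.default_rng(seed)
    edges: Dict[Tuple[str, str], float] = {}
    confident_deg: Dict[str, int] = {g: 0 for g in genes}

    def add(a: str, b: str, score: float) -> None:
        key = (a, b) if a < b else (b, a)
        prev = edges.get(key)
        if prev is None or score > prev:
            if prev is not None and prev > threshold:
                confident_deg[a] -= 1
                confident_deg[b] -= 1
            edges[key] = score
            if score > threshold:
                confident_deg[a] += 1
                confident_deg[b] += 1

    non_hubs = [g for g in genes if g not in hubs]
    for hub in hubs:
        partners = rng.choice(len(non_hubs), size=min(hub_degree, len(non_hubs)),
                              replace=False)
        for p in partners:
            add(hub, non_hubs[p], float(rng.uniform(0.75, 0.99)))
    for _ in range(n_background_edges):
        i, j = rng.choice(len(genes), size=2, replace=False)
        a, b = genes[i], genes[j]
        score = float(rng.uniform(0.5, 1.0))
        if score > threshold:
            for node in (a, b):
                if node not in hubs and confident_deg[node] >= max_background_degree:
                    score = float(rng.uniform(0.5, threshold - 0.01))
                    break
        add(a, b, score)
    rows = [(a, b, s) for (a, b), s in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
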