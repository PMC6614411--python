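"""Core genome-scale metabolic model (GEM) data structures.

A :class:`MetabolicModel` holds reactions, metabolites, GPR rules,
subsystem labels and flux bounds — everything a constraint-based analysis
needs.  The stoichiometric matrix S is derived on demand; fluxes are in
mmol·gDW⁻¹·h⁻¹ and the biomass objective in h⁻¹, the conventional units
of flux balance analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from .gpr import GPR

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "OrthologMap",
    "ModelValidationError",
    "ModelStats",
    "model_stats",
    "translate_genes",
    "find_dead_end_metabolites",
    "read_ortholog_map",
]

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """An invariant of the model structure is violated."""


@dataclass(frozen=True)
class Metabolite:
    """A compartment-localised chemical species."""

    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative
    = consumed).  A reaction with exactly one participating metabolite is
    a boundary (exchange/demand/sink) reaction.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPR = field(default_factory=GPR)
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        """Reversibility is defined purely by the bounds."""
        return self.lower_bound < 0 < self.upper_bound

    @property
    def boundary(self) -> bool:
        return len(self.stoichiometry) <= 1


@dataclass
class MetabolicModel:
    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    compartments: List[str] = field(default_factory=list)
    objective_reaction_id: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self._met_index: Dict[str, int] = {}
        for i, met in enumerate(self.metabolites):
            if met.id in self._met_index:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            self._met_index[met.id] = i
        self._rxn_index: Dict[str, int] = {}
        for j, rxn in enumerate(self.reactions):
            if rxn.id in self._rxn_index:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            self._rxn_index[rxn.id] = j

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def genes(self) -> List[str]:
        """Union of all GPR leaves, sorted (the model's gene list)."""
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.gpr.genes()
        return sorted(out)

    @property
    def subsystems(self) -> List[str]:
        return sorted({r.subsystem for r in self.reactions if r.subsystem})

    # -- derived structures ----------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites × reactions)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[self._met_index[met_id], j] = coeff
        return S

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- editing (copy-on-write helpers) ---------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            compartments=list(self.compartments),
            objective_reaction_id=self.objective_reaction_id,
            name=self.name,
        )

    def with_bounds(self, new_bounds: Mapping[str, Tuple[float, float]]) -> "MetabolicModel":
        """A copy with the given reactions' bounds replaced."""
        out = self.copy()
        for rxn_id, (lb, ub) in new_bounds.items():
            j = out._rxn_index[rxn_id]
            out.reactions[j] = replace(out.reactions[j], lower_bound=lb, upper_bound=ub)
        return out

    def with_reactions_added(self, extra: Iterable[Reaction]) -> "MetabolicModel":
        out = self.copy()
        known = set(out._met_index)
        for rxn in extra:
            missing = [m for m in rxn.stoichiometry if m not in known]
            for met_id in missing:
                out.metabolites.append(Metabolite(id=met_id, compartment=_compartment_of(met_id)))
                known.add(met_id)
            out.reactions.append(rxn)
        out._index()
        return out

    def validate(self) -> None:
        """Check structural invariants, raising on the first violation."""
        comps = set(self.compartments)
        for met in self.metabolites:
            if comps and met.compartment not in comps:
                raise ModelValidationError(
                    f"metabolite {met.id}: compartment {met.compartment!r} not declared"
                )
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id}: unknown metabolite {met_id!r}"
                    )
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {rxn.id}: empty stoichiometry")
        if self.objective_reaction_id is not None and (
            self.objective_reaction_id not in self._rxn_index
        ):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )


def _compartment_of(met_id: str) -> str:
    """Compartment from a BiGG-style suffix ('glc_c' -> 'c')."""
    if "_" in met_id:
        return met_id.rsplit("_", 1)[1]
    return "c"


@dataclass(frozen=True)
class ModelStats:
    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_compartments: int
    n_subsystems: int

    def as_dict(self) -> Dict[str, int]:
        return {
            "n_reactions": self.n_reactions,
            "n_metabolites": self.n_metabolites,
            "n_genes": self.n_genes,
            "n_compartments": self.n_compartments,
            "n_subsystems": self.n_subsystems,
        }


def model_stats(model: MetabolicModel) -> ModelStats:
    """Summary counts of a model's deduplicated components."""
    compartments = set(model.compartments) | {m.compartment for m in model.metabolites}
    return ModelStats(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
        n_compartments=len(compartments) if model.metabolites or model.compartments else 0,
        n_subsystems=len(model.subsystems),
    )


# ---------------------------------------------------------------------------
# Orthology translation
# ---------------------------------------------------------------------------

OrthologMap = Dict[str, List[str]]


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV (source_gene, target_gene).

    Repeated source rows accumulate into a 1:many mapping; a row with an
    empty second column records an explicit "no ortholog".
    """
    mapping: OrthologMap = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            src = parts[0].strip()
            tgt = parts[1].strip() if len(parts) > 1 else ""
            targets = mapping.setdefault(src, [])
            if tgt and tgt not in targets:
                targets.append(tgt)
    return mapping


def translate_genes(
    model: MetabolicModel, mapping: OrthologMap
) -> Tuple[MetabolicModel, List[str]]:
    """Rewrite GPR gene leaves through an ortholog map.

    1:1 mappings rename the leaf; 1:many mappings expand it into an OR
    over the targets (any functional ortholog can stand in for the source
    gene); unmapped leaves are kept and reported.  Reactions, metabolites
    and bounds are untouched.
    """
    unmapped: set[str] = set()

    def rewrite(gene: str):
        targets = mapping.get(gene)
        if not targets:
            unmapped.add(gene)
            return gene
        if len(targets) == 1:
            return targets[0]
        return ("or", list(targets))

    new_reactions = [replace(r, gpr=r.gpr.map_genes(rewrite)) for r in model.reactions]
    out = MetabolicModel(
        id=model.id,
        metabolites=list(model.metabolites),
        reactions=new_reactions,
        compartments=list(model.compartments),
        objective_reaction_id=model.objective_reaction_id,
        name=model.name,
    )
    return out, sorted(unmapped)


# ---------------------------------------------------------------------------
# Structural diagnostics (no LP needed)
# ---------------------------------------------------------------------------


def find_dead_end_metabolites(model: MetabolicModel) -> List[str]:
    """Metabolites that are only ever produced or only ever consumed.

    A reversible reaction (lb < 0 < ub) counts as both producer and
    consumer of every participant.  Boundary reactions are genuine
    producers/consumers, so an exchanged metabolite is never a dead end.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions:
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff == 0:
                continue
            forward_ok = rxn.upper_bound > 0
            backward_ok = rxn.lower_bound < 0
            if coeff > 0:
                if forward_ok:
                    produced.add(met_id)
                if backward_ok:
                    consumed.add(met_id)
            else:
                if forward_ok:
                    consumed.add(met_id)
                if backward_ok:
                    produced.add(met_id)
    return sorted(produced ^ consumed)
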