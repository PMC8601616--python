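"""Metabolic model representation and condition-specific flux spaces.

A genome-scale metabolic model (GEM) is held as a stoichiometric matrix
``S`` (metabolites x reactions) together with per-reaction bounds in
mmol gDW^-1 h^-1 and annotation (subsystem, gene rule, compartments).
A :class:`FluxSpace` pairs a model with a named constraint condition and
defines the steady-state flux polytope ``{v : S v = 0, lb <= v <= ub}``.

SBML input/output is delegated to cobrapy; the in-memory containers here
are deliberately plain (NumPy arrays plus id lists) because every
downstream stage (FVA, expectation propagation, PCA) consumes the raw
matrix rather than a reaction-object API.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSpace",
    "read_model",
    "write_model",
    "add_release_reactions",
    "apply_default_bounds",
    "block_reactions",
    "DEFAULT_REVERSIBLE_BOUNDS",
    "DEFAULT_IRREVERSIBLE_BOUNDS",
]

#: Default flux bounds (mmol gDW^-1 h^-1) imposed on every reversible /
#: irreversible reaction when a flux space is defined.
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str

    @property
    def display_name(self) -> str:
        return f"{self.name} [{self.compartment}]"


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str
    subsystem: str
    reversible: bool
    gene_rule: str
    equation: str


@dataclass
class MetabolicModel:
    """Stoichiometric model: ``S`` is metabolites x reactions, dense float."""

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        n_met, n_rxn = len(self.metabolites), len(self.reactions)
        if self.S.shape != (n_met, n_rxn):
            raise ValueError(
                f"S has shape {self.S.shape}, expected ({n_met}, {n_rxn})"
            )
        if self.lb.shape != (n_rxn,) or self.ub.shape != (n_rxn,):
            raise ValueError("bounds must be per-reaction vectors")
        if np.any(self.lb > self.ub):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ValueError(f"lb > ub for reaction {bad!r}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reaction ids")
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            raise ValueError("duplicate metabolite ids")

    # -- convenience ------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite id {metabolite_id!r}") from None

    @property
    def exchange_flags(self) -> np.ndarray:
        """Boolean per reaction: touches exactly one (non-boundary) metabolite."""
        return np.count_nonzero(self.S, axis=0) == 1

    def reactions_of_metabolite(self, metabolite_id: str) -> list[str]:
        i = self.metabolite_index(metabolite_id)
        return [self.reactions[j].id for j in np.flatnonzero(self.S[i])]

    def metabolites_of_reaction(self, reaction_id: str) -> list[str]:
        j = self.reaction_index(reaction_id)
        return [self.metabolites[i].id for i in np.flatnonzero(self.S[:, j])]

    def reaction_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "name": [r.name for r in self.reactions],
                "subsystem": [r.subsystem for r in self.reactions],
                "reversible": [r.reversible for r in self.reactions],
                "gene_rule": [r.gene_rule for r in self.reactions],
                "equation": [r.equation for r in self.reactions],
                "lb": self.lb,
                "ub": self.ub,
                "exchange": self.exchange_flags,
            }
        )

    def metabolite_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite_id": self.metabolite_ids,
                "name": [m.name for m in self.metabolites],
                "compartment": [m.compartment for m in self.metabolites],
            }
        )

    def summary(self) -> dict:
        return {
            "model_id": self.model_id,
            "n_reactions": self.n_reactions,
            "n_metabolites": self.n_metabolites,
            "n_reversible": int(sum(r.reversible for r in self.reactions)),
            "n_exchange": int(self.exchange_flags.sum()),
            "compartments": sorted({m.compartment for m in self.metabolites}),
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass
class FluxSpace:
    """A model plus a named constraint condition.

    ``applied_overrides`` maps reaction id -> (lb, ub) and is applied on
    top of the model's default-rule bounds; ``lb``/``ub`` hold the
    effective bounds of the polytope {S v = 0, lb <= v <= ub}.
    """

    model: MetabolicModel
    condition_label: str
    applied_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lb is None:
            self.lb = self.model.lb.copy()
        if self.ub is None:
            self.ub = self.model.ub.copy()
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        for rid, (lo, hi) in self.applied_overrides.items():
            j = self.model.reaction_index(rid)  # raises KeyError if unknown
            if lo > hi:
                raise ValueError(f"override lb > ub for reaction {rid!r}")
            self.lb[j], self.ub[j] = lo, hi
        if np.any(self.lb > self.ub):
            raise ValueError("lb > ub after applying overrides")

    @property
    def S(self) -> np.ndarray:
        return self.model.S

    @property
    def reaction_ids(self) -> list[str]:
        return self.model.reaction_ids


# ---------------------------------------------------------------------------
# SBML input / output (cobrapy-backed)
# ---------------------------------------------------------------------------

def _equation_text(cobra_reaction) -> str:
    return cobra_reaction.build_reaction_string(use_metabolite_names=False)


def read_model(path) -> MetabolicModel:
    """Read an SBML file (L2 or L3+fbc) into a :class:`MetabolicModel`.

    Subsystem defaults to ``"unassigned"`` when the annotation is absent;
    the chemical equation text is rendered from the stoichiometry.
    """
    import logging

    from cobra.io import read_sbml_model

    # flux-space analysis needs no objective; silence cobra's complaint
    # about objective-free SBML during the read
    sbml_log = logging.getLogger("cobra.io.sbml")
    level = sbml_log.level
    sbml_log.setLevel(logging.CRITICAL)
    try:
        cm = read_sbml_model(str(path))
    finally:
        sbml_log.setLevel(level)
    if len(cm.reactions) == 0:
        raise ValueError(f"model {cm.id!r} contains no reactions")

    metabolites = [
        Metabolite(m.id, m.name or m.id, m.compartment or "unassigned")
        for m in cm.metabolites
    ]
    met_index = {m.id: i for i, m in enumerate(cm.metabolites)}
    n_met, n_rxn = len(metabolites), len(cm.reactions)
    S = np.zeros((n_met, n_rxn))
    reactions = []
    lb = np.zeros(n_rxn)
    ub = np.zeros(n_rxn)
    for j, r in enumerate(cm.reactions):
        for met, coef in r.metabolites.items():
            S[met_index[met.id], j] = coef
        reactions.append(
            Reaction(
                id=r.id,
                name=r.name or r.id,
                subsystem=r.subsystem or "unassigned",
                reversible=r.lower_bound < 0,
                gene_rule=r.gene_reaction_rule or "",
                equation=_equation_text(r),
            )
        )
        lb[j], ub[j] = r.lower_bound, r.upper_bound
    return MetabolicModel(cm.id or "model", metabolites, reactions, S, lb, ub)


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (for SBML export and oracle cross-checks)."""
    import cobra

    cm = cobra.Model(model.model_id)
    mets = []
    for m in model.metabolites:
        cm_met = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        mets.append(cm_met)
    cm.add_metabolites(mets)
    rxns = []
    for j, r in enumerate(model.reactions):
        cr = cobra.Reaction(
            r.id, name=r.name,
            lower_bound=float(model.lb[j]), upper_bound=float(model.ub[j]),
        )
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for j, r in enumerate(model.reactions):
        coeffs = {
            mets[i]: float(model.S[i, j]) for i in np.flatnonzero(model.S[:, j])
        }
        cm.reactions.get_by_id(r.id).add_metabolites(coeffs)
    # subsystems persist in SBML as group annotations
    by_subsystem: dict[str, list] = {}
    for r in model.reactions:
        if r.subsystem and r.subsystem != "unassigned":
            by_subsystem.setdefault(r.subsystem, []).append(
                cm.reactions.get_by_id(r.id))
    groups = []
    for idx, (name, members) in enumerate(sorted(by_subsystem.items())):
        g = cobra.core.Group(f"g{idx + 1}", name=name, members=members,
                             kind="partonomy")
        groups.append(g)
    if groups:
        cm.add_groups(groups)
    return cm


def write_model(model: MetabolicModel, path) -> None:
    """Write the model as SBML L3+fbc via cobrapy."""
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# Model edits and condition construction
# ---------------------------------------------------------------------------

def add_release_reactions(
    model: MetabolicModel,
    metabolite_ids: list[str],
    cytosol: str = "c",
    extracellular: str = "e",
) -> MetabolicModel:
    """Add one irreversible release reaction per cytosolic metabolite.

    Each new reaction ``EXC_OUT_<metabolite id>`` moves the metabolite
    from the cytosolic to the extracellular compartment (stoichiometry
    -1 cytosol / +1 extracellular); an extracellular counterpart species
    is created when the model lacks one with the same name.
    """
    metabolites = list(model.metabolites)
    met_by_id = {m.id: i for i, m in enumerate(metabolites)}
    S_cols = []
    new_reactions = []
    new_rows = 0
    existing_rids = set(model.reaction_ids)

    for mid in metabolite_ids:
        if mid not in met_by_id:
            raise KeyError(f"unknown metabolite id {mid!r}")
        met = metabolites[met_by_id[mid]]
        if met.compartment != cytosol:
            raise ValueError(
                f"metabolite {mid!r} is in compartment {met.compartment!r}, "
                f"not the cytosol ({cytosol!r})"
            )
        rid = f"EXC_OUT_{mid}"
        if rid in existing_rids:
            raise ValueError(f"reaction id {rid!r} already exists")
        existing_rids.add(rid)
        # find or create the extracellular counterpart by name
        target = next(
            (
                i
                for i, m in enumerate(metabolites)
                if m.name == met.name and m.compartment == extracellular
            ),
            None,
        )
        if target is None:
            new_met = Metabolite(f"{mid}_{extracellular}", met.name, extracellular)
            if new_met.id in {m.id for m in metabolites}:
                raise ValueError(f"metabolite id {new_met.id!r} already exists")
            metabolites.append(new_met)
            target = len(metabolites) - 1
            new_rows += 1
        col = {met_by_id[mid]: -1.0, target: 1.0}
        S_cols.append(col)
        new_reactions.append(
            Reaction(
                id=rid,
                name=f"{met.name} release ({cytosol} -> {extracellular})",
                subsystem="Extracellular transport",
                reversible=False,
                gene_rule="",
                equation=f"{mid} --> {metabolites[target].id}",
            )
        )

    n_met = len(metabolites)
    n_old = model.n_reactions
    S = np.zeros((n_met, n_old + len(new_reactions)))
    S[: model.n_metabolites, :n_old] = model.S
    for k, col in enumerate(S_cols):
        for i, coef in col.items():
            S[i, n_old + k] = coef
    lb = np.concatenate([model.lb, np.zeros(len(new_reactions))])
    ub = np.concatenate([model.ub, np.full(len(new_reactions), 1000.0)])
    return MetabolicModel(
        model.model_id,
        metabolites,
        list(model.reactions) + new_reactions,
        S,
        lb,
        ub,
    )


def apply_default_bounds(
    model: MetabolicModel, condition_label: str = "default"
) -> FluxSpace:
    """Impose the default flux-space bounds on every reaction.

    Reversible reactions get (-1000, 1000) and irreversible ones
    (0, 1000) mmol gDW^-1 h^-1, exchange reactions included regardless
    of their original (typically closed) bounds. Reversibility is taken
    from the reaction flag, not the stored bounds. Idempotent.
    """
    reversible = np.array([r.reversible for r in model.reactions])
    lb = np.where(reversible, DEFAULT_REVERSIBLE_BOUNDS[0], DEFAULT_IRREVERSIBLE_BOUNDS[0])
    ub = np.where(reversible, DEFAULT_REVERSIBLE_BOUNDS[1], DEFAULT_IRREVERSIBLE_BOUNDS[1])
    return FluxSpace(model, condition_label, {}, lb=lb, ub=ub)


def block_reactions(
    space: FluxSpace, reaction_ids: list[str], condition_label: str
) -> FluxSpace:
    """Close the listed reactions (lb = ub = 0) under a new condition label."""
    overrides = dict(space.applied_overrides)
    for rid in reaction_ids:
        space.model.reaction_index(rid)  # KeyError on unknown id
        overrides[rid] = (0.0, 0.0)
    lb, ub = space.lb.copy(), space.ub.copy()
    for rid, (lo, hi) in overrides.items():
        j = space.model.reaction_index(rid)
        lb[j], ub[j] = lo, hi
    return FluxSpace(space.model, condition_label, overrides, lb=lb, ub=ub)
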