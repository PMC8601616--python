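"""Flux variability analysis and blocked-reaction removal.

Preprocessing tightens a condition-specific flux polytope before moment
approximation: every reaction's attainable flux range [vmin, vmax] is
found by two linear programs (FVA), reactions incapable of carrying any
flux (blocked) are dropped, and the surviving reactions' bounds are
replaced by their FVA ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_core import FluxSpace, MetabolicModel, Metabolite, Reaction

__all__ = [
    "FvaResult",
    "ReducedFluxSpace",
    "run_fva",
    "remove_blocked",
    "nullspace_dimension",
    "BLOCKED_TOL",
]

#: Reactions whose FVA range and endpoints all fall below this value
#: (mmol gDW^-1 h^-1) are treated as blocked.
BLOCKED_TOL = 1e-6

# HiGHS primal/dual feasibility tolerances for the FVA linear programs.
_LP_OPTIONS = {"primal_feasibility_tolerance": 1e-9,
               "dual_feasibility_tolerance": 1e-9}


@dataclass
class FvaResult:
    reaction_ids: list[str]
    vmin: np.ndarray
    vmax: np.ndarray

    def range_of(self, reaction_id: str) -> tuple[float, float]:
        i = self.reaction_ids.index(reaction_id)
        return float(self.vmin[i]), float(self.vmax[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": self.reaction_ids, "vmin": self.vmin, "vmax": self.vmax}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ReducedFluxSpace:
    """FluxSpace restricted to unblocked reactions, bounds = FVA ranges."""

    model: MetabolicModel
    condition_label: str
    lb: np.ndarray
    ub: np.ndarray
    removed_reaction_ids: list[str] = field(default_factory=list)

    @property
    def S(self) -> np.ndarray:
        return self.model.S

    @property
    def reaction_ids(self) -> list[str]:
        return self.model.reaction_ids

    @property
    def n_reactions(self) -> int:
        return self.model.n_reactions


def _solve_lp(c, S, lb, ub):
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options=_LP_OPTIONS,
    )
    if res.status == 2:
        raise ValueError("flux polytope is infeasible")
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return res


def run_fva(space: FluxSpace) -> FvaResult:
    """Per-reaction flux minima/maxima over {S v = 0, lb <= v <= ub}.

    Each reaction is minimised and maximised in a separate LP (HiGHS);
    the result does not depend on reaction order.
    """
    S, lb, ub = space.S, space.lb, space.ub
    n = S.shape[1]
    vmin = np.empty(n)
    vmax = np.empty(n)
    for j in range(n):
        if lb[j] == ub[j]:  # fixed reaction: no LP needed
            vmin[j] = vmax[j] = lb[j]
            continue
        c = np.zeros(n)
        c[j] = 1.0
        vmin[j] = _solve_lp(c, S, lb, ub).x[j]
        c[j] = -1.0
        vmax[j] = _solve_lp(c, S, lb, ub).x[j]
    # clip tiny LP round-off outside the box
    vmin = np.clip(vmin, lb, ub)
    vmax = np.clip(vmax, lb, ub)
    vmin, vmax = np.minimum(vmin, vmax), np.maximum(vmin, vmax)
    return FvaResult(list(space.reaction_ids), vmin, vmax)


def remove_blocked(
    space: FluxSpace, fva: FvaResult, tol: float = BLOCKED_TOL
) -> ReducedFluxSpace:
    """Drop blocked reactions and tighten bounds to the FVA ranges.

    A reaction is blocked when |vmin| < tol and |vmax| < tol, i.e. it can
    carry no flux anywhere in the polytope. Retained reactions have their
    box bounds replaced by [vmin, vmax].
    """
    if fva.reaction_ids != list(space.reaction_ids):
        raise ValueError("FVA result does not cover this flux space")
    blocked = (np.abs(fva.vmin) < tol) & (np.abs(fva.vmax) < tol)
    keep = ~blocked
    model = space.model
    removed = [rid for rid, b in zip(model.reaction_ids, blocked) if b]

    reduced_model = MetabolicModel(
        model.model_id,
        list(model.metabolites),
        [r for r, k in zip(model.reactions, keep) if k],
        model.S[:, keep],
        fva.vmin[keep],
        fva.vmax[keep],
    )
    return ReducedFluxSpace(
        reduced_model,
        space.condition_label,
        fva.vmin[keep].copy(),
        fva.vmax[keep].copy(),
        removed_reaction_ids=removed,
    )


def nullspace_dimension(space: ReducedFluxSpace, sv_cutoff: float = 1e-10) -> int:
    """Dimension of {v : S v = 0}: n_reactions - rank(S).

    The rank uses a singular-value cutoff of ``sv_cutoff`` relative to the
    largest singular value.
    """
    S = space.S
    if S.size == 0:
        return space.n_reactions
    sv = np.linalg.svd(S, compute_uv=False)
    rank = int(np.sum(sv > sv_cutoff * sv[0])) if sv[0] > 0 else 0
    return space.n_reactions - rank


def removal_log(space: ReducedFluxSpace) -> pd.DataFrame:
    return pd.DataFrame({"removed_reaction_id": space.removed_reaction_ids})
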