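"""Synthetic models and loading matrices with analytically known behaviour.

These generators make every pipeline stage testable without external
model downloads:

* chain model — a single linear pathway whose steady-state flux space is
  a segment: the uniform distribution has mean 1/2 and variance 1/12 on
  every reaction, the analytic oracle for the moment approximation.
* triangle model — one branch point (inflow v1, outflows v2 and v3) whose
  flux space is the unit triangle {v2, v3 >= 0, v2 + v3 <= 1}:
  E[v2] = 1/3, Var[v2] = 1/18, Cov(v2, v3) = -1/36, E[v1] = 2/3.
* planted loading matrices — two conditions sharing common components
  plus condition-specific super-Gaussian (Laplace-weight) components at
  known column indices, used to test source recovery in the comparison
  stage. Laplace weights are used because their excess kurtosis (3)
  clears the retention bound of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decompose import LoadingMatrix
from .model_core import MetabolicModel, Metabolite, Reaction

__all__ = [
    "make_chain_model",
    "make_triangle_model",
    "make_star_model",
    "make_planted_loadings",
    "PlantedLoadings",
]

# analytic uniform-polytope moments of the fixtures
CHAIN_MEAN = 0.5
CHAIN_VARIANCE = 1.0 / 12.0
TRIANGLE_MEAN_BRANCH = 1.0 / 3.0
TRIANGLE_VAR_BRANCH = 1.0 / 18.0
TRIANGLE_COV_BRANCHES = -1.0 / 36.0
TRIANGLE_MEAN_INFLOW = 2.0 / 3.0


def make_chain_model(length: int = 2) -> MetabolicModel:
    """Linear pathway in -> M1 -> ... -> M(length-1) -> out, bounds [0, 1].

    At steady state all fluxes are equal, so the polytope is a segment and
    the null space is one-dimensional for any length.
    """
    if length < 2:
        raise ValueError("chain length must be >= 2")
    metabolites = [
        Metabolite(f"m{i}", f"intermediate {i}", "c") for i in range(1, length)
    ]
    reactions = []
    S = np.zeros((length - 1, length))
    for j in range(length):
        if j > 0:
            S[j - 1, j] -= 1.0
        if j < length - 1:
            S[j, j] += 1.0
        reactions.append(
            Reaction(
                id=f"v{j + 1}",
                name=f"chain step {j + 1}",
                subsystem="Chain pathway",
                reversible=False,
                gene_rule="",
                equation=(
                    f"m{j} --> m{j + 1}" if 0 < j < length - 1
                    else (f"--> m1" if j == 0 else f"m{length - 1} -->")
                ),
            )
        )
    return MetabolicModel(
        f"chain{length}",
        metabolites,
        reactions,
        S,
        np.zeros(length),
        np.ones(length),
    )


def make_triangle_model() -> MetabolicModel:
    """Branch point: v1 produces one metabolite consumed by v2 and v3.

    All bounds [0, 1]; at steady state v1 = v2 + v3, so the uniform
    distribution lives on the unit triangle in (v2, v3).
    """
    metabolites = [Metabolite("m1", "branch metabolite", "c")]
    S = np.array([[1.0, -1.0, -1.0]])
    reactions = [
        Reaction("v1", "inflow", "Branch pathway", False, "", "--> m1"),
        Reaction("v2", "outflow A", "Branch pathway", False, "", "m1 -->"),
        Reaction("v3", "outflow B", "Branch pathway", False, "", "m1 -->"),
    ]
    return MetabolicModel(
        "triangle", metabolites, reactions, S, np.zeros(3), np.ones(3)
    )


def make_star_model(n_in: int = 10, n_out: int = 10) -> MetabolicModel:
    """Hub metabolite with ``n_in`` inflows and ``n_out`` outflows.

    The steady-state polytope has dimension ``n_in + n_out - 1``, making
    this the smallest fixture family whose covariance supports a
    multi-component PCA/ICA exercise. Upper bounds are staggered between
    0.8 and 1.2 so the reactions are distinguishable: a perfectly
    symmetric star gives every reaction an identical loading profile,
    which degenerates any loading-magnitude filter.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("need at least one inflow and one outflow")
    n = n_in + n_out
    metabolites = [Metabolite("hub", "hub metabolite", "c")]
    S = np.zeros((1, n))
    S[0, :n_in] = 1.0
    S[0, n_in:] = -1.0
    reactions = [
        Reaction(f"in{j + 1}", f"inflow {j + 1}", "Star inflow", False, "",
                 "--> hub")
        for j in range(n_in)
    ] + [
        Reaction(f"out{j + 1}", f"outflow {j + 1}", "Star outflow", False, "",
                 "hub -->")
        for j in range(n_out)
    ]
    return MetabolicModel(
        f"star{n_in}x{n_out}", metabolites, reactions, S,
        np.zeros(n), np.round(np.linspace(0.8, 1.2, n), 6),
    )


@dataclass
class PlantedLoadings:
    """Ground truth bundle for the planted-source comparison fixture."""

    condition1: LoadingMatrix
    condition2: LoadingMatrix
    sources: np.ndarray              # n_reactions x n_sources Laplace vectors
    shared_source_indices: list[int]
    specific_columns: dict[str, list[tuple[int, int]]]
    # condition label -> [(column index in that condition, source index)]


def make_planted_loadings(
    n_reactions: int = 300,
    sources: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_columns: int = 8,
) -> PlantedLoadings:
    """Two loading matrices with planted super-Gaussian components.

    Source 0 is shared between the conditions; the remaining sources are
    assigned alternately as condition-1- and condition-2-specific. Each
    planted source occupies one column (plus Gaussian observation noise of
    sd ``noise_sd``); the other columns are low-variance Gaussian filler,
    so the planted columns are both super-Gaussian and high-variance.
    Deterministic for a fixed seed.
    """
    if sources > n_reactions:
        raise ValueError("cannot plant more sources than reactions")
    if sources < 1:
        raise ValueError("need at least one source")
    rng = np.random.default_rng(seed)
    # Sparse Laplace-weight sources: varimax-rotated loading columns are
    # concentrated on few reactions, and sparsity keeps the components
    # strongly super-Gaussian even after the low-loading row filter.
    support = rng.random(size=(n_reactions, sources)) < 0.25
    Z = support * rng.laplace(scale=1.0, size=(n_reactions, sources))
    Z /= Z.std(axis=0)  # unit variance; excess kurtosis ~ 6/0.25 - 3

    shared = [0]
    spec1 = [i for i in range(1, sources) if i % 2 == 1]
    spec2 = [i for i in range(1, sources) if i % 2 == 0]

    reaction_ids = [f"r{i + 1}" for i in range(n_reactions)]
    specific_columns: dict[str, list[tuple[int, int]]] = {}

    def build(label: str, specific: list[int]) -> LoadingMatrix:
        # Every column is a linear mixture of this condition's sources, so
        # the signal subspace has exactly `sources` dimensions overall; the
        # first columns are (near-)pure copies of each planted source, the
        # rest are weaker random mixtures.
        planted = shared + specific
        m = len(planted)
        k = max(n_columns, m)
        W = rng.uniform(-0.6, 0.6, size=(k, m))
        cols = []
        for slot, src in enumerate(planted):
            W[slot] = 0.0
            W[slot, slot] = 1.0
            if src in specific:
                cols.append((slot, src))
        L = Z[:, planted] @ W.T + noise_sd * rng.standard_normal((n_reactions, k))
        specific_columns[label] = cols
        frac = np.full(k, 1.0 / k)
        return LoadingMatrix(
            reaction_ids=list(reaction_ids),
            loadings=L,
            variance_fraction=frac,
            rotated=True,
            condition_label=label,
        )

    lm1 = build("condition1", spec1)
    lm2 = build("condition2", spec2)
    return PlantedLoadings(lm1, lm2, Z, shared, specific_columns)
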