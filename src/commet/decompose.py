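"""PCA of the flux covariance, varimax rotation and module extraction.

The flux covariance matrix is decomposed into eigenvector loadings; the
leading components explaining 99.9% of the variance are varimax-rotated
so each rotated component concentrates on few reactions, and a module is
the set of reactions whose absolute loadings reach at least half of the
component's maximum absolute loading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LoadingMatrix",
    "Module",
    "pca_covariance",
    "select_components",
    "varimax_rotate",
    "extract_module",
    "global_modules",
    "VARIANCE_THRESHOLD",
    "MODULE_LOADING_FRACTION",
]

#: Cumulative-variance threshold for retaining components.
VARIANCE_THRESHOLD = 0.999
#: A reaction joins a module when |loading| >= this fraction of the
#: component's maximal |loading| (inclusive).
MODULE_LOADING_FRACTION = 0.5


@dataclass
class LoadingMatrix:
    reaction_ids: list[str]
    loadings: np.ndarray            # reactions x components
    variance_fraction: np.ndarray   # per component, sums to <= 1
    rotated: bool = False
    condition_label: str = ""
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, float)
        self.variance_fraction = np.asarray(self.variance_fraction, float)
        if self.loadings.shape[0] != len(self.reaction_ids):
            raise ValueError("loadings rows must match reaction ids")
        if self.loadings.shape[1] > self.loadings.shape[0]:
            raise ValueError("more components than reactions")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings,
            index=pd.Index(self.reaction_ids, name="reaction_id"),
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class Module:
    component: int          # 0-based component index
    condition_label: str
    members: list[tuple[str, float]] = field(default_factory=list)

    @property
    def reaction_ids(self) -> list[str]:
        return [rid for rid, _ in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


def _sign_convention(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-absolute entry is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def pca_covariance(
    cov: np.ndarray,
    condition_label: str = "",
    sym_tol: float = 1e-6,
    reaction_ids: list[str] | None = None,
) -> LoadingMatrix:
    """Eigendecomposition of a flux covariance matrix.

    Eigenvector columns are sorted by eigenvalue descending; numerically
    negative eigenvalues are clipped to zero before the variance fractions
    (eigenvalue / trace) are formed. Asymmetry beyond ``sym_tol`` (relative
    to the largest entry) is an error.
    """
    cov = np.asarray(cov, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    scale = max(np.max(np.abs(cov)), 1.0)
    if np.max(np.abs(cov - cov.T)) > sym_tol * scale:
        raise ValueError("covariance matrix is not symmetric")
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0.0, None)
    total = w.sum()
    frac = w / total if total > 0 else np.zeros_like(w)
    V = _sign_convention(V)
    rids = reaction_ids or [f"r{i + 1}" for i in range(cov.shape[0])]
    if len(rids) != cov.shape[0]:
        raise ValueError("reaction_ids length must match the covariance size")
    return LoadingMatrix(list(rids), V, frac, rotated=False,
                         condition_label=condition_label, eigenvalues=w)


def select_components(lm: LoadingMatrix, threshold: float = VARIANCE_THRESHOLD) -> int:
    """Smallest k whose cumulative variance fraction reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(lm.variance_fraction)
    if cum.size == 0:
        return 0
    target = min(threshold, cum[-1])  # trace round-off keeps threshold 1 attainable
    hits = np.flatnonzero(cum >= target - 1e-12)
    return int(hits[0]) + 1


def _varimax(L: np.ndarray, tol: float = 1e-8, max_sweeps: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Raw varimax (no Kaiser row normalisation) by pairwise rotations.

    Each sweep visits every column pair and applies the planar rotation
    angle that exactly maximises the pair's varimax criterion (Kaiser's
    closed form), so the criterion is nondecreasing; convergence when the
    largest angle of a sweep drops below ``tol``. The pairwise scheme also
    rotates through saddle points (e.g. the perfectly mixed two-component
    case) where gradient-based ascent stalls. Returns (rotated loadings,
    orthogonal rotation matrix).
    """
    p, k = L.shape
    R = np.eye(k)
    if k < 2:
        return L.copy(), R
    Lr = L.copy()
    for _ in range(max_sweeps):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = Lr[:, i], Lr[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = float(u @ u - v @ v)
                D = 2.0 * float(u @ v)
                num = D - 2.0 * A * B / p
                den = C - (A**2 - B**2) / p
                theta = 0.25 * np.arctan2(num, den)
                if abs(theta) <= tol:
                    continue
                max_angle = max(max_angle, abs(theta))
                c, s = np.cos(theta), np.sin(theta)
                G = np.array([[c, -s], [s, c]])
                Lr[:, [i, j]] = Lr[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        if max_angle <= tol:
            break
    return Lr, R


def varimax_rotate(lm: LoadingMatrix, k: int | None = None) -> LoadingMatrix:
    """Varimax-rotate the first ``k`` components (all retained ones).

    Rotation is orthogonal, so row communalities over the k components are
    preserved; the rotated flag is set and component variance fractions are
    recomputed from the rotated column variances of the implied scores.
    """
    if k is None:
        k = lm.n_components
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > lm.n_components:
        raise ValueError("k exceeds the number of components")
    block = lm.loadings[:, :k]
    if lm.eigenvalues is not None:
        # rotate variance-scaled loadings so rotated columns carry variance
        scaled = block * np.sqrt(np.clip(lm.eigenvalues[:k], 0.0, None))
        rotated_scaled, R = _varimax(scaled)
        col_var = np.sum(rotated_scaled**2, axis=0)
        total = np.sum(np.clip(lm.eigenvalues, 0.0, None))
        frac = col_var / total if total > 0 else np.zeros(k)
        rotated = _sign_convention(rotated_scaled)
    else:
        rotated, R = _varimax(block)
        rotated = _sign_convention(rotated)
        frac = lm.variance_fraction[:k]
    return LoadingMatrix(
        list(lm.reaction_ids),
        rotated,
        frac,
        rotated=True,
        condition_label=lm.condition_label,
    )


def extract_module(lm: LoadingMatrix, component: int) -> Module:
    """Reactions whose |loading| is at least half the component maximum."""
    if not 0 <= component < lm.n_components:
        raise IndexError(f"component {component} out of range")
    col = lm.loadings[:, component]
    peak = np.max(np.abs(col))
    if peak == 0:
        raise ValueError(f"component {component} has all-zero loadings")
    mask = np.abs(col) >= MODULE_LOADING_FRACTION * peak
    members = [
        (lm.reaction_ids[i], float(col[i])) for i in np.flatnonzero(mask)
    ]
    return Module(component, lm.condition_label, members)


def global_modules(
    lm: LoadingMatrix,
) -> tuple[list[Module], set[str], dict[str, int]]:
    """All modules of a rotated loading matrix, their union and counts.

    Returns (modules, union of member reaction ids, per-reaction module
    membership count over all components).
    """
    if not lm.rotated:
        raise ValueError("global modules require a rotated loading matrix")
    modules = [extract_module(lm, c) for c in range(lm.n_components)]
    union: set[str] = set()
    counts: dict[str, int] = {}
    for mod in modules:
        for rid in mod.reaction_ids:
            union.add(rid)
            counts[rid] = counts.get(rid, 0) + 1
    return modules, union, counts


def modules_to_frame(modules: list[Module], subsystems: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for mod in modules:
        for rid, loading in mod.members:
            rows.append(
                {
                    "component": mod.component + 1,
                    "condition": mod.condition_label,
                    "reaction_id": rid,
                    "loading": loading,
                    "subsystem": (subsystems or {}).get(rid, "unassigned"),
                }
            )
    return pd.DataFrame(rows, columns=["component", "condition", "reaction_id", "loading", "subsystem"])


def write_modules(modules: list[Module], tsv_path=None, json_path=None, subsystems=None) -> None:
    frame = modules_to_frame(modules, subsystems)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "component": m.component + 1,
                "condition": m.condition_label,
                "members": [{"reaction_id": r, "loading": l} for r, l in m.members],
            }
            for m in modules
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
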