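"""Condition comparison: which rotated components are distinct?

The rotated loading matrices of the two conditions are concatenated
column-wise, reactions with low loadings everywhere are dropped, and the
remaining matrix is treated as a set of mixed signals over reactions.
Independent component analysis (symmetric fastICA, pow3 nonlinearity)
is then used in three stages:

1. a bootstrapped stability scan over candidate component numbers N:
   for each N the decomposition is repeated from random initial
   conditions, the pooled estimates are clustered (average linkage on
   1 - |corr|) and each cluster receives an icasso-style stability index
   Iq = mean intra-cluster |corr| - mean between-cluster |corr|;
2. the optimal N is read off by 2-means clustering of all stability
   values into a high- and a low-stability line over cluster rank and
   locating the rank where the two lines cross;
3. ICA is re-run many times at the optimal N; components whose excess
   kurtosis is outside (-1, 1) (clearly non-Gaussian) are assigned to the
   source column with the largest absolute mixing weight, accumulating a
   per-column estimation frequency. The knee of the sorted frequency
   curve (maximum distance above the endpoint chord) selects the distinct
   columns, each traced back to its condition and component.

All randomness derives from explicit seeds; repeated executions with the
same master seed are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kurtosis as _kurtosis
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .decompose import LoadingMatrix

__all__ = [
    "CombinedLoadings",
    "StabilityScan",
    "DistinctFeatures",
    "concat_and_filter",
    "stability_scan",
    "choose_optimal_n",
    "final_ica",
    "knee_select",
    "compare_conditions",
]

DEFAULT_N_RANGE = range(2, 91)
DEFAULT_SCAN_RUNS = 100
DEFAULT_FINAL_RUNS = 9000
DEFAULT_KURTOSIS_BOUND = 1.0


@dataclass
class CombinedLoadings:
    reaction_ids: list[str]          # retained rows (post low-loading filter)
    matrix: np.ndarray               # reactions x (k1 + k2)
    provenance: list[tuple[str, int]]  # per column: (condition, component idx)
    cutoff: float
    n_removed_reactions: int

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class StabilityScan:
    profiles: dict[int, np.ndarray]  # N -> per-cluster Iq, sorted descending
    runs: int
    nonlinearity: str
    seed: int
    nonconverged: dict[int, int] = field(default_factory=dict)

    @property
    def n_values(self) -> list[int]:
        return sorted(self.profiles)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"n": n, "cluster_rank": r + 1, "stability": s}
            for n in self.n_values
            for r, s in enumerate(self.profiles[n])
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DistinctFeatures:
    optimal_n: int
    frequencies: np.ndarray          # per input column, counts over runs
    kurtosis_retained: int           # total retained ICs over all runs
    runs: int
    kurtosis_bound: float
    provenance: list[tuple[str, int]]
    seed: int
    selected_columns: list[int] | None = None
    knee_index: int | None = None

    def selection_frame(self) -> pd.DataFrame:
        cols = self.selected_columns or []
        return pd.DataFrame(
            [
                {
                    "column": c,
                    "condition": self.provenance[c][0],
                    "component": self.provenance[c][1] + 1,
                    "frequency": int(self.frequencies[c]),
                }
                for c in cols
            ],
            columns=["column", "condition", "component", "frequency"],
        )

    def selected_per_condition(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.selected_columns or []:
            label = self.provenance[c][0]
            counts[label] = counts.get(label, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# concatenation and low-loading filter
# ---------------------------------------------------------------------------

def concat_and_filter(lm1: LoadingMatrix, lm2: LoadingMatrix) -> CombinedLoadings:
    """Concatenate two rotated loading matrices and drop low-loading rows.

    Rows are the union of reaction ids (zero-filled where a reaction is
    absent from one condition). With m_r the maximum absolute loading of
    row r over all columns, the cutoff is median(m) + mean(|m - mean(m)|)
    and rows with m < cutoff are removed.
    """
    if not (lm1.rotated and lm2.rotated):
        raise ValueError("both loading matrices must be rotated")
    ids = list(lm1.reaction_ids)
    seen = set(ids)
    ids += [r for r in lm2.reaction_ids if r not in seen]
    pos = {r: i for i, r in enumerate(ids)}

    k1, k2 = lm1.n_components, lm2.n_components
    M = np.zeros((len(ids), k1 + k2))
    for i, r in enumerate(lm1.reaction_ids):
        M[pos[r], :k1] = lm1.loadings[i]
    for i, r in enumerate(lm2.reaction_ids):
        M[pos[r], k1:] = lm2.loadings[i]

    m = np.max(np.abs(M), axis=1)
    cutoff = float(np.median(m) + np.mean(np.abs(m - np.mean(m))))
    keep = m >= cutoff
    if not keep.any():
        raise ValueError("no reactions survive the low-loading cutoff")

    provenance = [(lm1.condition_label or "condition1", j) for j in range(k1)]
    provenance += [(lm2.condition_label or "condition2", j) for j in range(k2)]
    return CombinedLoadings(
        [ids[i] for i in np.flatnonzero(keep)],
        M[keep],
        provenance,
        cutoff,
        int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# bootstrapped stability scan
# ---------------------------------------------------------------------------

def _run_fastica(X: np.ndarray, n: int, seed: int, max_iter: int = 1000):
    """One symmetric pow3 fastICA run; returns (sources, mixing, converged)."""
    ica = FastICA(
        n_components=n,
        algorithm="parallel",
        fun="cube",
        whiten="unit-variance",
        random_state=seed,
        max_iter=max_iter,
        tol=1e-4,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    return S, ica.mixing_, converged


def _cluster_stability(components: np.ndarray, n_clusters: int) -> np.ndarray:
    """icasso-style Iq for average-linkage clusters on 1 - |corr|."""
    C = np.abs(np.corrcoef(components))
    np.fill_diagonal(C, 1.0)
    D = np.clip(1.0 - C, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    iq = []
    for lab in range(1, labels.max() + 1):
        inside = labels == lab
        if not inside.any():
            continue
        intra = C[np.ix_(inside, inside)].mean()
        outside = ~inside
        between = C[np.ix_(inside, outside)].mean() if outside.any() else 0.0
        iq.append(intra - between)
    iq = np.sort(np.asarray(iq))[::-1]
    return iq


def stability_scan(
    cl: CombinedLoadings,
    n_range=DEFAULT_N_RANGE,
    runs: int = DEFAULT_SCAN_RUNS,
    seed: int = 0,
    bootstrap: bool = True,
) -> StabilityScan:
    """Per-candidate-N stability profiles from repeated fastICA runs.

    For each N, fastICA is run ``runs`` times from random initial
    conditions, each run fitted on a bootstrap resample of the reactions
    (icasso's combined randinit-and-bootstrap mode) and its components
    evaluated on the full data so runs are comparable; the pooled
    estimates are clustered into N groups and each group's stability
    index recorded (sorted descending). Bootstrapping matters: components
    that merely fit sample-specific noise reappear at different
    orientations in every resample and score low, whereas with a fixed
    dataset random restarts alone converge to the same spurious optima.
    Runs that fail outright (solver error or non-finite output) are
    logged and excluded; runs that merely hit the iteration cap still
    contribute their estimates — their scatter is precisely what lowers
    the stability of an ill-chosen N.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs per N")
    n_values = [int(n) for n in n_range]
    if max(n_values) >= cl.n_columns:
        raise ValueError("max(n_range) must be below the column count")
    X = cl.matrix
    n_rows = X.shape[0]
    profiles: dict[int, np.ndarray] = {}
    nonconv: dict[int, int] = {}
    rng = np.random.default_rng(seed)
    for n in n_values:
        run_seeds = rng.integers(0, 2**31 - 1, size=runs)
        pool = []
        not_converged = 0
        for rs in run_seeds:
            run_rng = np.random.default_rng(int(rs))
            if bootstrap:
                rows = run_rng.integers(0, n_rows, size=n_rows)
                X_fit = X[rows]
            else:
                X_fit = X
            try:
                ica = FastICA(
                    n_components=n, algorithm="parallel", fun="cube",
                    whiten="unit-variance", random_state=int(rs),
                    max_iter=1000, tol=1e-4,
                )
                ok = True
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", ConvergenceWarning)
                    ica.fit(X_fit)
                    if any(issubclass(w.category, ConvergenceWarning)
                           for w in caught):
                        ok = False
                S = ica.transform(X)
            except Exception:
                not_converged += 1
                continue
            if not np.all(np.isfinite(S)):
                not_converged += 1
                continue
            pool.append(S.T)
            if not ok:
                not_converged += 1
        if not pool:  # every run failed at this N; leave it out of the scan
            nonconv[n] = not_converged
            continue
        comps = np.vstack(pool)
        profiles[n] = _cluster_stability(comps, n)
        if not_converged:
            nonconv[n] = not_converged
    return StabilityScan(profiles, runs, "pow3", seed, nonconv)


def _two_means_1d(values: np.ndarray) -> np.ndarray:
    """Exact 1-D 2-means: boolean mask of the high-mean group."""
    order = np.argsort(values)
    v = values[order]
    n = v.size
    csum = np.cumsum(v)
    total = csum[-1]
    best, best_split = np.inf, 1
    for split in range(1, n):
        m1 = csum[split - 1] / split
        m2 = (total - csum[split - 1]) / (n - split)
        ss = np.sum((v[:split] - m1) ** 2) + np.sum((v[split:] - m2) ** 2)
        if ss < best:
            best, best_split = ss, split
    high = np.zeros(n, bool)
    high[order[best_split:]] = True
    return high


def choose_optimal_n(scan: StabilityScan) -> int:
    """Optimal component number from the 2-means two-line intersection.

    All per-cluster stability values (across every scanned N, indexed by
    their rank within the sorted profile) are split into a high- and a
    low-stability group by exact 1-D 2-means. Per cluster rank the two
    groups' occupancy curves are formed (the fraction of that rank's
    values belonging to each group); the curves cross at the rank where
    the high-stability group stops holding the majority, and the optimal
    N is the last rank before the crossing.
    """
    if len(scan.profiles) < 3:
        raise ValueError("scan must cover at least 3 values of N")
    ranks, values = [], []
    for n, prof in scan.profiles.items():
        for r, s in enumerate(prof, start=1):
            ranks.append(r)
            values.append(s)
    ranks = np.asarray(ranks)
    values = np.asarray(values)
    if np.isclose(values.max(), values.min()):
        raise ValueError(
            "degenerate 2-means clustering: all stability values are equal")
    high = _two_means_1d(values)
    if high.all() or not high.any():
        raise ValueError("degenerate 2-means clustering (one empty group)")

    optimal = 0
    for r in range(1, int(ranks.max()) + 1):
        at_r = ranks == r
        if not at_r.any():
            break
        if np.mean(high[at_r]) <= 0.5:
            break
        optimal = r
    if optimal == 0:
        raise ValueError("high-stability line never dominates; no optimal N")
    return optimal


# ---------------------------------------------------------------------------
# high-replication ICA with kurtosis filter
# ---------------------------------------------------------------------------

def final_ica(
    cl: CombinedLoadings,
    n: int,
    runs: int = DEFAULT_FINAL_RUNS,
    kurtosis_bound: float = DEFAULT_KURTOSIS_BOUND,
    seed: int = 0,
) -> DistinctFeatures:
    """Estimation frequencies from repeated fastICA at the chosen N.

    Each run uses the explicit seed ``seed + run_index``. Components with
    excess (Fisher) kurtosis outside (-kurtosis_bound, kurtosis_bound) are
    retained and assigned to the input column carrying their largest
    absolute mixing weight (ties to the lower column index); the per-column
    assignment counts over all runs are the estimation frequencies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    X = cl.matrix
    freq = np.zeros(cl.n_columns, dtype=int)
    retained_total = 0
    for run in range(runs):
        try:
            S, A, _ = _run_fastica(X, n, seed + run)
        except Exception:  # failed run: logged by omission, never fatal
            continue
        kurt = _kurtosis(S, axis=0, fisher=True)
        for j in np.flatnonzero(np.abs(kurt) >= kurtosis_bound):
            col = int(np.argmax(np.abs(A[:, j])))
            freq[col] += 1
            retained_total += 1
    return DistinctFeatures(
        optimal_n=n,
        frequencies=freq,
        kurtosis_retained=retained_total,
        runs=runs,
        kurtosis_bound=kurtosis_bound,
        provenance=list(cl.provenance),
        seed=seed,
    )


def knee_select(features: DistinctFeatures) -> DistinctFeatures:
    """Select the columns at or left of the knee of the sorted curve.

    Frequencies are sorted descending and the point of maximal distance to
    the chord joining the first and last points located. When that point
    lies above the chord (concave plateau-then-cliff curve) it is the last
    point of the plateau and selection includes it; when it lies below
    (convex curve) it is the first point after the drop and selection stops
    just before it. A flat or strictly linear curve has no knee: the
    selection is left empty with a warning.
    """
    freq = features.frequencies
    if freq.size == 0:
        raise ValueError("no frequencies to select from")
    order = np.argsort(-freq, kind="stable")
    y = freq[order].astype(float)
    m = y.size
    if m == 1:
        features.selected_columns = [int(order[0])] if y[0] > 0 else []
        features.knee_index = 0 if y[0] > 0 else None
        return features
    x = np.arange(m, dtype=float)
    chord = y[0] + (y[-1] - y[0]) * x / (m - 1)
    dist = y - chord
    idx = int(np.argmax(np.abs(dist)))
    if abs(dist[idx]) <= 1e-12:
        warnings.warn("frequency curve is flat/linear; no knee found",
                      RuntimeWarning, stacklevel=2)
        features.selected_columns = []
        features.knee_index = None
        return features
    knee = idx if dist[idx] > 0 else idx - 1
    if knee < 0:
        warnings.warn("frequency curve drops immediately; empty selection",
                      RuntimeWarning, stacklevel=2)
        features.selected_columns = []
        features.knee_index = None
        return features
    features.knee_index = knee
    features.selected_columns = [int(c) for c in order[: knee + 1]]
    return features


def compare_conditions(
    lm1: LoadingMatrix,
    lm2: LoadingMatrix,
    n_range=DEFAULT_N_RANGE,
    scan_runs: int = DEFAULT_SCAN_RUNS,
    final_runs: int = DEFAULT_FINAL_RUNS,
    kurtosis_bound: float = DEFAULT_KURTOSIS_BOUND,
    seed: int = 0,
) -> tuple[CombinedLoadings, StabilityScan, DistinctFeatures]:
    """Full comparison stage: filter, scan, optimal N, final ICA, knee."""
    cl = concat_and_filter(lm1, lm2)
    scan = stability_scan(cl, n_range=n_range, runs=scan_runs, seed=seed)
    n_opt = choose_optimal_n(scan)
    features = final_ica(
        cl, n_opt, runs=final_runs, kurtosis_bound=kurtosis_bound, seed=seed
    )
    return cl, scan, knee_select(features)
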