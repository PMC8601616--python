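"""Per-reaction differential flux statistics between two conditions.

For each reaction present in both conditions the change in its flux
distribution is scored as

    z_i = (E2[v_i] - E1[v_i]) / sqrt(Var2[v_i] + Var1[v_i])

and converted to a two-sided Gaussian p-value, p = 2 (1 - Phi(|z|)).
Reactions unblocked in only one condition cannot be scored and are
reported with a membership flag instead. No multiple-testing correction
is applied; the significance call is the raw p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .flux_approx import FluxMoments

__all__ = ["DifferentialFluxResult", "flux_zscores", "significant_reactions"]


@dataclass
class DifferentialFluxResult:
    table: pd.DataFrame
    condition1: str
    condition2: str

    @property
    def shared(self) -> pd.DataFrame:
        return self.table[self.table["flag"] == "both"]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def flux_zscores(
    m1: FluxMoments,
    m2: FluxMoments,
    label1: str = "condition1",
    label2: str = "condition2",
) -> DifferentialFluxResult:
    """Z-scores and two-sided Gaussian p-values on the shared reactions.

    Reactions present in only one condition get flag ``condition1_only`` /
    ``condition2_only`` with z and p left empty. A zero pooled variance
    with equal means gives z = 0 by convention; with unequal means the
    reaction is flagged ``degenerate`` and p underflows to 0.
    """
    ids1, ids2 = set(m1.reaction_ids), set(m2.reaction_ids)
    shared = [rid for rid in m1.reaction_ids if rid in ids2]
    if not shared:
        raise ValueError("the two conditions share no reactions")

    i1 = {r: i for i, r in enumerate(m1.reaction_ids)}
    i2 = {r: i for i, r in enumerate(m2.reaction_ids)}
    rows = []
    for rid in shared:
        e1, v1 = m1.mean[i1[rid]], m1.variance[i1[rid]]
        e2, v2 = m2.mean[i2[rid]], m2.variance[i2[rid]]
        pooled = v1 + v2
        flag = "both"
        if pooled <= 0:
            if e1 == e2:
                z = 0.0
            else:
                z = np.inf if e2 > e1 else -np.inf
                flag = "degenerate"
        else:
            z = (e2 - e1) / np.sqrt(pooled)
        p = 2.0 * norm.sf(abs(z))
        rows.append(
            {
                "reaction_id": rid,
                "mean1": e1,
                "sd1": np.sqrt(max(v1, 0.0)),
                "mean2": e2,
                "sd2": np.sqrt(max(v2, 0.0)),
                "z": z,
                "p": p,
                "flag": flag,
            }
        )
    for rid in m1.reaction_ids:
        if rid not in ids2:
            i = i1[rid]
            rows.append(
                {"reaction_id": rid, "mean1": m1.mean[i],
                 "sd1": np.sqrt(max(m1.variance[i], 0.0)), "mean2": np.nan,
                 "sd2": np.nan, "z": np.nan, "p": np.nan,
                 "flag": "condition1_only"}
            )
    for rid in m2.reaction_ids:
        if rid not in ids1:
            i = i2[rid]
            rows.append(
                {"reaction_id": rid, "mean1": np.nan, "sd1": np.nan,
                 "mean2": m2.mean[i], "sd2": np.sqrt(max(m2.variance[i], 0.0)),
                 "z": np.nan, "p": np.nan, "flag": "condition2_only"}
            )
    return DifferentialFluxResult(pd.DataFrame(rows), label1, label2)


def significant_reactions(
    result: DifferentialFluxResult, alpha: float = 0.05
) -> list[str]:
    """Reaction ids with p < alpha, sorted by ascending p (ties by id)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    scored = result.table.dropna(subset=["p"])
    hits = scored[scored["p"] < alpha]
    hits = hits.sort_values(["p", "reaction_id"], kind="mergesort")
    return hits["reaction_id"].tolist()
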