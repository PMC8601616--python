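"""End-to-end orchestration of the eight-stage workflow.

Per condition: constraint application -> FVA preprocessing -> moment
approximation -> PCA -> varimax rotation -> module extraction; then the
condition pair is compared (differential z-scores and the ICA comparison
stage) and the module networks exported. Every run writes a manifest
(parameters, seeds, package version, per-stage wall time) and
content-keyed stage artefacts, so editing a downstream parameter never
triggers upstream recompute.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import (DEFAULT_FINAL_RUNS, DEFAULT_KURTOSIS_BOUND,
                      DEFAULT_SCAN_RUNS)
from .decompose import (VARIANCE_THRESHOLD, global_modules, pca_covariance,
                        select_components, varimax_rotate, write_modules)
from .diffstats import flux_zscores, significant_reactions
from .flux_approx import EpConfig, ep_moments, sample_moments
from .model_core import apply_default_bounds, block_reactions, read_model
from .preprocess import BLOCKED_TOL, nullspace_dimension, remove_blocked, run_fva
from .network import build_reaction_graph, export_graph

__all__ = ["RunConfig", "ConditionSpec", "run_commet", "load_config"]

log = logging.getLogger("commet")

STAGES = [
    "constraints",
    "preprocess",
    "moments",
    "pca",
    "rotation",
    "modules",
    "compare",
    "network",
]


@dataclass
class ConditionSpec:
    label: str
    blocked_reactions: list[str] = field(default_factory=list)
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class RunConfig:
    model_path: str
    conditions: list[ConditionSpec]
    output_dir: str = "commet_out"
    blocked_tol: float = BLOCKED_TOL
    method: str = "ep"                     # "ep" | "sampling"
    n_samples: int = 100_000
    ep: EpConfig = field(default_factory=EpConfig)
    pca_threshold: float = VARIANCE_THRESHOLD
    n_range: tuple[int, int] = (2, 90)
    scan_runs: int = DEFAULT_SCAN_RUNS
    final_runs: int = DEFAULT_FINAL_RUNS
    kurtosis_bound: float = DEFAULT_KURTOSIS_BOUND
    alpha: float = 0.05
    seed: int = 0
    release_metabolites: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need at least two named conditions")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if not 0 < self.pca_threshold <= 1:
            raise ValueError("pca_threshold must lie in (0, 1]")
        if self.method not in {"ep", "sampling"}:
            raise ValueError(f"unknown method {self.method!r}")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (validation errors before compute)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "model" not in raw:
        raise ValueError("config must be a mapping with a 'model' entry")
    if "conditions" not in raw or not raw["conditions"]:
        raise ValueError("config must define a 'conditions' section")
    conditions = []
    for entry in raw["conditions"]:
        conditions.append(
            ConditionSpec(
                label=entry["label"],
                blocked_reactions=list(entry.get("block", [])),
                bound_overrides={
                    rid: (float(b[0]), float(b[1]))
                    for rid, b in (entry.get("bounds") or {}).items()
                },
            )
        )
    ep_raw = raw.get("ep", {})
    cfg = RunConfig(
        model_path=raw["model"],
        conditions=conditions,
        output_dir=raw.get("output_dir", "commet_out"),
        blocked_tol=float(raw.get("blocked_tol", BLOCKED_TOL)),
        method=raw.get("method", "ep"),
        n_samples=int(raw.get("n_samples", 100_000)),
        ep=EpConfig(
            max_iterations=int(ep_raw.get("max_iterations", 1000)),
            precision=float(ep_raw.get("precision", 1e-5)),
            beta=float(ep_raw.get("beta", 1e8)),
        ),
        pca_threshold=float(raw.get("pca_threshold", VARIANCE_THRESHOLD)),
        n_range=tuple(raw.get("n_range", (2, 90))),
        scan_runs=int(raw.get("scan_runs", DEFAULT_SCAN_RUNS)),
        final_runs=int(raw.get("final_runs", DEFAULT_FINAL_RUNS)),
        kurtosis_bound=float(raw.get("kurtosis_bound", DEFAULT_KURTOSIS_BOUND)),
        alpha=float(raw.get("alpha", 0.05)),
        seed=int(raw.get("seed", 0)),
        release_metabolites=list(raw.get("release_metabolites", [])),
    )
    cfg.validate()
    return cfg


def _stage_key(name: str, payload: dict) -> str:
    blob = json.dumps({"stage": name, **payload}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Cache:
    """Content-keyed stage cache: artefacts stored under their input hash."""

    def __init__(self, root: Path):
        self.root = root
        self.root.mkdir(parents=True, exist_ok=True)

    def path(self, name: str, key: str) -> Path:
        return self.root / f"{name}-{key}.npz"

    def load(self, name: str, key: str):
        p = self.path(name, key)
        if p.exists():
            with np.load(p, allow_pickle=True) as z:
                return {k: z[k] for k in z.files}
        return None

    def store(self, name: str, key: str, **arrays) -> None:
        np.savez(self.path(name, key), **arrays)


def run_commet(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest.

    Any stage failure aborts with the stage name in the raised error;
    artefacts of completed stages are retained in the output directory.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _Cache(out / "cache")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "blocked_tol": config.blocked_tol,
            "method": config.method,
            "ep": vars(config.ep),
            "pca_threshold": config.pca_threshold,
            "n_range": list(config.n_range),
            "scan_runs": config.scan_runs,
            "final_runs": config.final_runs,
            "kurtosis_bound": config.kurtosis_bound,
            "alpha": config.alpha,
        },
        "stages": {},
        "conditions": {},
    }

    def timed(stage: str):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s started", stage)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                status = "failed" if exc else "completed"
                manifest["stages"].setdefault(stage, {})
                manifest["stages"][stage]["status"] = status
                manifest["stages"][stage]["seconds"] = round(dt, 3)
                log.info("stage %s %s in %.2fs", stage, status, dt)
                if exc:
                    _write_manifest(out, manifest)
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
                return False
        return _T()

    # stage A: constraints -> condition flux spaces
    with timed("constraints"):
        model = read_model(config.model_path)
        if config.release_metabolites:
            from .model_core import add_release_reactions
            model = add_release_reactions(model, config.release_metabolites)
        base = apply_default_bounds(model)
        spaces = []
        for cond in config.conditions:
            space = base
            if cond.bound_overrides:
                from .model_core import FluxSpace
                space = FluxSpace(model, cond.label,
                                  dict(cond.bound_overrides),
                                  lb=base.lb.copy(), ub=base.ub.copy())
            # blocking wins over capacity overrides: it is the perturbation
            space = block_reactions(space, cond.blocked_reactions, cond.label)
            spaces.append(space)

    per_condition = {}
    # stages B-E per condition
    for cond, space in zip(config.conditions, spaces):
        cinfo: dict = {}
        with timed("preprocess"):
            key = _stage_key("preprocess", {
                "model": config.model_path, "label": cond.label,
                "blocked": cond.blocked_reactions,
                "overrides": cond.bound_overrides,
                "tol": config.blocked_tol,
                "release": config.release_metabolites,
            })
            fva = run_fva(space)
            reduced = remove_blocked(space, fva, tol=config.blocked_tol)
            fva.write_tsv(out / f"fva_{cond.label}.tsv")
            (out / f"removed_{cond.label}.txt").write_text(
                "\n".join(reduced.removed_reaction_ids) + "\n")
            cinfo["n_removed"] = len(reduced.removed_reaction_ids)
            cinfo["n_retained"] = reduced.n_reactions
            cinfo["nullspace_dim"] = nullspace_dimension(reduced)

        with timed("moments"):
            mkey = _stage_key("moments", {
                "upstream": key, "method": config.method,
                "ep": vars(config.ep), "n_samples": config.n_samples,
                "seed": config.seed,
            })
            cached = cache.load("moments", mkey)
            if cached is not None:
                from .flux_approx import FluxMoments
                moments = FluxMoments(
                    [str(r) for r in cached["reaction_ids"]],
                    cached["mean"], cached["variance"], cached["covariance"],
                    str(cached["method"]),
                )
            elif config.method == "ep":
                moments = ep_moments(reduced, config.ep)
            else:
                moments = sample_moments(
                    reduced, n_samples=config.n_samples, seed=config.seed)
            cache.store("moments", mkey,
                        reaction_ids=np.array(moments.reaction_ids),
                        mean=moments.mean, variance=moments.variance,
                        covariance=moments.covariance,
                        method=np.array(moments.method))
            moments.write_tsv(out / f"moments_{cond.label}.tsv")

        with timed("pca"):
            lm = pca_covariance(moments.covariance, cond.label,
                                reaction_ids=list(moments.reaction_ids))
            k = select_components(lm, config.pca_threshold)
            cinfo["n_components"] = k

        with timed("rotation"):
            rotated = varimax_rotate(lm, k)
            rotated.write_tsv(out / f"loadings_{cond.label}.tsv")

        with timed("modules"):
            mods, union, counts = global_modules(rotated)
            subsys = {r.id: r.subsystem for r in reduced.model.reactions}
            write_modules(mods, out / f"modules_{cond.label}.tsv",
                          out / f"modules_{cond.label}.json", subsys)
            cinfo["n_modules"] = len(mods)
            cinfo["module_union"] = len(union)
            cinfo["module_sizes"] = [m.size for m in mods]
        per_condition[cond.label] = {
            "space": space, "reduced": reduced, "moments": moments,
            "rotated": rotated, "modules": mods, "union": union,
            "counts": counts,
        }
        manifest["conditions"][cond.label] = cinfo

    # pairwise stages (first two conditions, as in the reference analysis)
    c1, c2 = config.conditions[0].label, config.conditions[1].label
    with timed("compare"):
        diff = flux_zscores(per_condition[c1]["moments"],
                            per_condition[c2]["moments"], c1, c2)
        diff.write_tsv(out / f"zscores_{c1}_vs_{c2}.tsv")
        sig = significant_reactions(diff, config.alpha)
        manifest["n_significant"] = len(sig)

        from .compare import (choose_optimal_n, concat_and_filter, final_ica,
                              knee_select, stability_scan)
        cl = concat_and_filter(per_condition[c1]["rotated"],
                               per_condition[c2]["rotated"])
        scan = stability_scan(
            cl, n_range=range(config.n_range[0], config.n_range[1] + 1),
            runs=config.scan_runs, seed=config.seed)
        scan.write_tsv(out / "stability_scan.tsv")
        features = None
        try:
            n_opt = choose_optimal_n(scan)
        except ValueError as exc:
            # a legitimate method outcome on structureless data: report it,
            # leave the selection empty, and keep the stage artefacts
            log.warning("no stable component number found: %s", exc)
            manifest["optimal_n"] = None
            manifest["n_selected_features"] = 0
            manifest["selected_per_condition"] = {}
            import pandas as pd
            pd.DataFrame(columns=["column", "condition", "component",
                                  "frequency"]).to_csv(
                out / "distinct_features.tsv", sep="\t", index=False)
        else:
            features = knee_select(final_ica(
                cl, n_opt, runs=config.final_runs,
                kurtosis_bound=config.kurtosis_bound, seed=config.seed))
            features.selection_frame().to_csv(out / "distinct_features.tsv",
                                              sep="\t", index=False)
            manifest["optimal_n"] = features.optimal_n
            manifest["n_selected_features"] = len(
                features.selected_columns or [])
            manifest["selected_per_condition"] = \
                features.selected_per_condition()

    with timed("network"):
        from .decompose import extract_module
        sig_set = set(sig)
        graphs = {}
        for label in (c1, c2):
            g = build_reaction_graph(per_condition[label]["modules"],
                                     per_condition[label]["reduced"].model,
                                     significant=sig_set)
            export_graph(g, out / f"reaction_graph_{label}")
            graphs[label] = g
            manifest["conditions"][label]["graph_nodes"] = g.number_of_nodes()
            manifest["conditions"][label]["graph_edges"] = g.number_of_edges()
        # distinct-modules network from the selected features
        distinct_mods = []
        selected = (features.selected_columns or []) if features else []
        for col in selected:
            label, comp = features.provenance[col]
            rotated = per_condition[label]["rotated"]
            distinct_mods.append(extract_module(rotated, comp))
        if distinct_mods:
            gd = build_reaction_graph(
                distinct_mods, per_condition[c1]["reduced"].model
                if all(m.condition_label == c1 for m in distinct_mods)
                else _merged_model(per_condition, c1, c2),
                significant=sig_set)
            export_graph(gd, out / "distinct_modules_graph")
            manifest["distinct_graph_nodes"] = gd.number_of_nodes()
            manifest["distinct_graph_edges"] = gd.number_of_edges()

    _write_manifest(out, manifest)
    return manifest


def _merged_model(per_condition, c1, c2):
    """Model covering the union of both reduced reaction sets.

    The reduced models share the parent model's metabolites; the first
    condition's model is used when it already covers the union, otherwise
    reactions present only in the second are appended.
    """
    m1 = per_condition[c1]["reduced"].model
    m2 = per_condition[c2]["reduced"].model
    ids1 = set(m1.reaction_ids)
    extra = [j for j, rid in enumerate(m2.reaction_ids) if rid not in ids1]
    if not extra:
        return m1
    from .model_core import MetabolicModel

    met_index = {m.id: i for i, m in enumerate(m1.metabolites)}
    S_extra = np.zeros((m1.n_metabolites, len(extra)))
    for k, j in enumerate(extra):
        for i in np.flatnonzero(m2.S[:, j]):
            S_extra[met_index[m2.metabolites[i].id], k] = m2.S[i, j]
    return MetabolicModel(
        m1.model_id,
        list(m1.metabolites),
        list(m1.reactions) + [m2.reactions[j] for j in extra],
        np.hstack([m1.S, S_extra]),
        np.concatenate([m1.lb, m2.lb[extra]]),
        np.concatenate([m1.ub, m2.ub[extra]]),
    )


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
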