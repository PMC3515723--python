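"""End-to-end orchestration: simulate → extract → connect → compare → map → associate.

Each stage writes plain-text tables (TSV) and NIfTI volumes under the run
directory, plus a machine-readable JSON summary and a checksum manifest, so
a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from . import connectivity as conn
from . import maps as vmaps
from . import roi_signals as roi
from . import synthetic as syn

__all__ = [
    "RunConfig",
    "run_pipeline",
    "task_performance_check",
    "load_run_config",
    "PipelineError",
]

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """Stage failure wrapper carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    out_dir: str = "petconn_run"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    data_dir: str | None = None  # use existing simulate output instead
    use_replicates: str = "average"
    smooth_fwhm_mm: float = 0.0  # analysis-time smoothing
    edges: list | None = None  # list of [a, b]; default: all region pairs
    comparisons: list = field(default_factory=list)
    forming_threshold_p: float = 0.001
    n_permutations: int = 500
    run_maps: bool = True
    association_session: str | None = None
    association_method: str = "residual_product"
    default_direction: str = "increase"

    def stage_seed(self, stage_index: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage_index])


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def synthetic_config_from_dict(overrides: dict, seed: int) -> syn.SyntheticConfig:
    overrides = dict(overrides)
    if "regions" in overrides:
        overrides["regions"] = [
            syn.RegionSpec(
                name=r["name"], center_mm=tuple(r["center_mm"]),
                extent_mm=float(r["extent_mm"]), shape=r.get("shape", "sphere"),
            )
            for r in overrides["regions"]
        ]
    for key in ("grid_shape", "sessions", "conditions", "brain_center_mm",
                "brain_semiaxes_mm", "response_edge"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    if "session_edge_corr" in overrides:
        overrides["session_edge_corr"] = {
            k: np.asarray(v, dtype=float)
            for k, v in overrides["session_edge_corr"].items()
        }
    overrides.setdefault("seed", seed)
    return syn.SyntheticConfig(**overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_checksums(out_dir: Path) -> Path:
    rows = []
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != "checksums.tsv":
            rows.append((str(p.relative_to(out_dir)), _sha256(p)))
    dest = out_dir / "checksums.tsv"
    pd.DataFrame(rows, columns=["path", "sha256"]).to_csv(dest, sep="\t", index=False)
    return dest


def load_data(data_dir):
    """Load a simulate-style directory: manifest.tsv, clinical.tsv, masks/, volumes."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    clinical = pd.read_csv(data_dir / "clinical.tsv", sep="\t")
    volumes = {}
    for row in manifest.itertuples(index=False):
        key = (row.participant, row.session, row.condition, row.replicate)
        volumes[key] = roi.read_volume(data_dir / row.path, scan_key=key)
    masks = []
    mask_dir = data_dir / "masks"
    brain = None
    for p in sorted(mask_dir.glob("*.nii*")):
        name = p.name.split(".nii")[0]
        m = roi.read_mask(p, name)
        if name == "whole_brain":
            brain = m
        else:
            masks.append(m)
    if brain is None:
        raise FileNotFoundError(f"no whole_brain mask found in {mask_dir}")
    return manifest, volumes, masks, brain, clinical


def _comparison_plan(config: RunConfig, sessions, edges):
    if config.comparisons:
        plan = []
        for item in config.comparisons:
            pair = tuple(item["pair"])
            directions = {
                tuple(k.split("-")): v for k, v in item.get("directions", {}).items()
            }
            for e in edges:
                directions.setdefault(tuple(e), item.get("direction",
                                                         config.default_direction))
            plan.append((pair, directions))
        return plan
    plan = []
    for a, b in itertools.combinations(sessions, 2):
        plan.append(((a, b), {tuple(e): config.default_direction for e in edges}))
    return plan


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the JSON-serializable summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }

    # ---- stage 1: obtain data -------------------------------------------
    try:
        if config.data_dir is not None:
            manifest, volumes, roi_masks, brain_mask, clinical = load_data(
                config.data_dir
            )
            ground_truth = None
        else:
            syn_cfg = synthetic_config_from_dict(config.synthetic, config.seed)
            cohort = syn.generate_cohort(syn_cfg, out_dir=out_dir / "data")
            manifest, volumes, clinical = (
                cohort.manifest, cohort.volumes, cohort.clinical,
            )
            roi_masks, brain_mask = cohort.masks[:-1], cohort.masks[-1]
            ground_truth = cohort.ground_truth
        region_names = [m.name for m in roi_masks]
        sessions = list(dict.fromkeys(manifest["session"]))
        summary["stages"]["simulate"] = {
            "n_scans": len(manifest), "regions": region_names, "sessions": sessions,
        }
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # ---- stage 2: smooth + extract --------------------------------------
    try:
        if config.smooth_fwhm_mm > 0:
            volumes = {
                k: roi.smooth_volume(v, config.smooth_fwhm_mm)
                for k, v in volumes.items()
            }
        stacks_cond = roi.stack_scans(manifest, volumes, "session_condition",
                                      config.use_replicates)
        stacks_comb = roi.stack_scans(manifest, volumes, "session_combined",
                                      config.use_replicates)
        table_comb = pd.concat(
            [roi.eigenvariate_table(s, roi_masks, brain_mask)
             for s in stacks_comb.values()],
            ignore_index=True,
        )
        table_cond = pd.concat(
            [roi.eigenvariate_table(s, roi_masks, brain_mask)
             for s in stacks_cond.values()],
            ignore_index=True,
        )
        table_comb.to_csv(out_dir / "eigenvariates_combined.tsv", sep="\t", index=False)
        table_cond.to_csv(out_dir / "eigenvariates_conditions.tsv", sep="\t", index=False)
        summary["stages"]["extract"] = {
            "smooth_fwhm_mm": config.smooth_fwhm_mm,
            "use_replicates": config.use_replicates,
            "n_units_combined": {s: int(st.n_units) for s, st in stacks_comb.items()},
        }
    except Exception as exc:
        raise PipelineError("extract", str(exc)) from exc

    # ---- stage 3: connectivity ------------------------------------------
    try:
        edges = config.edges or [
            list(e) for e in itertools.combinations(region_names, 2)
        ]
        graphs = {}
        long_tables = []
        for sess in sessions:
            g = conn.build_graph(table_comb, region_names, sess, "combined")
            graphs[sess] = g
            conn.write_matrix_table(
                g, out_dir / f"connectivity_{sess}_combined.tsv", region_names
            )
            long_tables.append(conn.graph_long_table(g))
            for cond in dict.fromkeys(manifest["condition"]):
                gc = conn.build_graph(table_cond, region_names, sess, cond)
                long_tables.append(conn.graph_long_table(gc))
        edge_table = pd.concat(long_tables, ignore_index=True)
        edge_table.to_csv(out_dir / "edges.tsv", sep="\t", index=False)
        summary["stages"]["connect"] = {
            "n_edges": int(edge_table.shape[0]),
            "effective_n": {
                s: {f"{a}-{b}": int(graphs[s].edges[a, b]["estimate"].n)
                    for a, b in graphs[s].edges}
                for s in sessions
            },
        }
    except Exception as exc:
        raise PipelineError("connect", str(exc)) from exc

    # ---- stage 4: session comparisons -----------------------------------
    try:
        plan = _comparison_plan(config, sessions, edges)
        rows = []
        for (sa, sb), directions in plan:
            results = cmp.compare_graphs(graphs[sa], graphs[sb], directions)
            for r in results:
                rows.append(
                    dict(region_a=r.edge[0], region_b=r.edge[1],
                         session_a=sa, session_b=sb, direction=r.direction,
                         z_stat=r.z_stat, p=r.p_one_sided, p_adjusted=r.p_adjusted,
                         n_a=r.n_A, n_b=r.n_B)
                )
        comparison_table = pd.DataFrame(rows)
        comparison_table.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
        summary["stages"]["compare"] = {
            "n_tests": len(rows),
            "families": [f"{sa}->{sb}" for (sa, sb), _ in plan],
        }
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    # ---- stage 5: voxelwise maps ----------------------------------------
    try:
        if config.run_maps:
            import nibabel as nib

            map_summaries = {}
            map_rng = config.stage_seed(5)
            for (sa, sb), _ in plan:
                stack_A, stack_B = stacks_comb[sa], stacks_comb[sb]
                n_pairs = min(stack_A.n_units, stack_B.n_units)
                thr = vmaps.forming_threshold_from_p(
                    config.forming_threshold_p, n_pairs
                )
                cm = vmaps.cluster_fdr(
                    stack_A, stack_B, forming_threshold=thr,
                    n_permutations=config.n_permutations,
                    seed=int(map_rng.integers(2 ** 31)),
                    brain_mask=brain_mask,
                )
                nib.Nifti1Image(
                    np.nan_to_num(cm.t_map).astype(np.float32), stack_A.affine
                ).to_filename(str(out_dir / f"tmap_{sa}_vs_{sb}.nii.gz"))
                vmaps.cluster_table(cm).to_csv(
                    out_dir / f"clusters_{sa}_vs_{sb}.tsv", sep="\t", index=False
                )
                map_summaries[f"{sa}->{sb}"] = {
                    "forming_threshold": thr,
                    "n_permutations": cm.n_permutations,
                    "exhaustive": cm.exhaustive,
                    "n_clusters": len(cm.clusters),
                }
            summary["stages"]["map"] = map_summaries
        else:
            summary["stages"]["map"] = "skipped"
    except Exception as exc:
        raise PipelineError("map", str(exc)) from exc

    # ---- stage 6: response association ----------------------------------
    try:
        assoc_session = config.association_session or sessions[min(1, len(sessions) - 1)]
        clinical_prepared = cmp.prepare_clinical(clinical)
        scores = cmp.participant_edge_scores(
            table_comb, [tuple(e) for e in edges], assoc_session,
            method=config.association_method,
        )
        assoc = cmp.response_association(clinical_prepared, scores, assoc_session)
        assoc_table = pd.DataFrame(
            [dict(region_a=a.edge[0], region_b=a.edge[1], session=a.session,
                  r=a.r_assoc, r_squared=a.r_squared, p=a.p, n=a.n)
             for a in assoc]
        )
        assoc_table.to_csv(out_dir / "association.tsv", sep="\t", index=False)
        summary["stages"]["associate"] = {
            "session": assoc_session, "method": config.association_method,
            "n_edges": len(assoc),
        }
    except Exception as exc:
        raise PipelineError("associate", str(exc)) from exc

    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_checksums(out_dir)
    logger.info("pipeline complete: %s", out_dir)
    return summary


def task_performance_check(table: pd.DataFrame, value_column: str = "value") -> dict:
    """One-way repeated-measures ANOVA across sessions with Bonferroni pairwise t.

    ``table`` needs participant, session, and the value column. Participants
    missing any session are dropped listwise (count logged). Utility only.
    """
    from scipy import stats as sps
    from statsmodels.stats.anova import AnovaRM

    sessions = list(dict.fromkeys(table["session"]))
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    wide = table.pivot_table(index="participant", columns="session",
                             values=value_column, aggfunc="mean")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("task_performance_check: dropped %d incomplete participants",
                    dropped)
    if len(complete) < 2:
        raise ValueError("need at least 2 complete participants")
    long = complete.reset_index().melt(
        id_vars="participant", var_name="session", value_name=value_column
    )
    fit = AnovaRM(long, depvar=value_column, subject="participant",
                  within=["session"]).fit()
    F = float(fit.anova_table["F Value"].iloc[0])
    p = float(fit.anova_table["Pr > F"].iloc[0])
    pairs = list(itertools.combinations(sessions, 2))
    k = len(pairs)
    pairwise = {}
    for a, b in pairs:
        t, pt = sps.ttest_rel(complete[a], complete[b])
        pairwise[f"{a} vs {b}"] = dict(
            t=float(t), p=float(pt), p_bonferroni=min(1.0, float(pt) * k)
        )
    return dict(F=F, p=p, n_complete=len(complete), n_dropped=dropped,
                pairwise=pairwise)
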