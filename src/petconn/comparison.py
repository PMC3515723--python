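"""Between-session comparison of edge connectivity and clinical association.

Fisher z-difference tests with directional normal tails, step-up
false-discovery-rate adjustment across the edge family, and the
participant-level association between connectivity and treatment response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityEstimate

__all__ = [
    "SessionComparison",
    "AssociationResult",
    "compare_connections",
    "normal_tail_p",
    "adjust_pvalues",
    "compare_graphs",
    "prepare_clinical",
    "participant_edge_scores",
    "response_association",
]

DIRECTIONS = ("increase", "decrease")


@dataclass(frozen=True)
class SessionComparison:
    """One edge, one ordered session pair, one tested direction."""

    z_stat: float
    p_one_sided: float
    direction: str
    n_A: int
    n_B: int
    edge: tuple = ()
    pair: tuple = ()
    p_adjusted: float | None = None


@dataclass(frozen=True)
class AssociationResult:
    edge: tuple
    session: str
    r_assoc: float
    r_squared: float
    p: float
    n: int


def normal_tail_p(z_stat: float, direction: str) -> float:
    """Exact standard-normal tail in the tested direction."""
    z_stat = float(z_stat)
    if not np.isfinite(z_stat):
        raise ValueError(f"z_stat must be finite, got {z_stat}")
    if direction == "increase":
        return float(stats.norm.sf(z_stat))
    if direction == "decrease":
        return float(stats.norm.cdf(z_stat))
    raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def compare_connections(
    z_A: float, n_A: int, z_B: float, n_B: int, direction: str
) -> SessionComparison:
    """Fisher z-difference test of session B against session A.

    z_stat = (z_B - z_A) / sqrt(1/(n_A-3) + 1/(n_B-3)); the one-sided p is
    the upper normal tail for direction 'increase' (B > A) and the lower
    tail for 'decrease' (B < A).
    """
    n_A, n_B = int(n_A), int(n_B)
    if n_A <= 3 or n_B <= 3:
        raise ValueError(f"both samples need n > 3, got n_A={n_A}, n_B={n_B}")
    se = np.sqrt(1.0 / (n_A - 3) + 1.0 / (n_B - 3))
    z_stat = float((float(z_B) - float(z_A)) / se)
    return SessionComparison(
        z_stat=z_stat,
        p_one_sided=normal_tail_p(z_stat, direction),
        direction=direction,
        n_A=n_A,
        n_B=n_B,
    )


def adjust_pvalues(p_list) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted.tolist()


def compare_graphs(graph_A, graph_B, directions: dict, adjust: bool = True) -> list[SessionComparison]:
    """Compare every edge listed in ``directions`` between two graphs.

    ``directions`` maps an (a, b) region pair to 'increase' or 'decrease';
    the listed edges form one adjustment family.
    """
    pair = (graph_A.graph.get("session", "A"), graph_B.graph.get("session", "B"))
    results = []
    for edge, direction in directions.items():
        a, b = edge
        est_A: ConnectivityEstimate = graph_A.edges[a, b]["estimate"]
        est_B: ConnectivityEstimate = graph_B.edges[a, b]["estimate"]
        cmp = compare_connections(est_A.z, est_A.n, est_B.z, est_B.n, direction)
        results.append(replace(cmp, edge=(a, b), pair=pair))
    if adjust and results:
        adj = adjust_pvalues([r.p_one_sided for r in results])
        results = [replace(r, p_adjusted=a) for r, a in zip(results, adj)]
    return results


def prepare_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Attach the response column (baseline minus week-six score) once."""
    required = {"participant", "bprs_psychosis_baseline", "bprs_psychosis_week6"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table is missing columns: {sorted(missing)}")
    out = clinical.copy()
    out["response"] = out["bprs_psychosis_baseline"] - out["bprs_psychosis_week6"]
    return out


def participant_edge_scores(
    table: pd.DataFrame,
    edges,
    session: str,
    covariate_column: str = "global",
    method: str = "residual_product",
) -> pd.DataFrame:
    """Per-participant connectivity surrogate for each edge at one session.

    'residual_product': residualize both region signals on the covariate
    across all units of the session, standardize the residuals, and average
    each participant's product of the two — a single-participant analogue of
    the group partial correlation. 'loo_z': the group Fisher z recomputed
    with the participant's units left out (sign-flipped so larger values
    mean the participant pulls the edge up).
    """
    from .connectivity import fisher_z, partial_corr

    sub = table[table["session"] == session]
    if len(sub) < 4:
        raise ValueError(f"need at least 4 units at session {session!r}")
    participants = sorted(sub["participant"].unique())
    out = pd.DataFrame(index=pd.Index(participants, name="participant"))
    cov = sub[covariate_column].to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(cov), cov])

    def _std_resid(col):
        v = sub[col].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        resid = v - design @ coef
        sd = resid.std()
        if sd == 0:
            raise ValueError(f"zero residual variance for region {col!r}")
        return resid / sd

    for a, b in edges:
        name = f"{a}-{b}"
        if method == "residual_product":
            prod = _std_resid(a) * _std_resid(b)
            out[name] = pd.Series(prod, index=sub["participant"].to_numpy()).groupby(
                level=0
            ).mean().reindex(participants)
        elif method == "loo_z":
            z_all = fisher_z(partial_corr(sub[a], sub[b], sub[covariate_column]))
            vals = []
            for p in participants:
                keep = sub["participant"] != p
                if keep.sum() < 4:
                    raise ValueError("too few units for leave-one-out")
                z_loo = fisher_z(
                    partial_corr(sub.loc[keep, a], sub.loc[keep, b],
                                 sub.loc[keep, covariate_column])
                )
                vals.append(z_all - z_loo)
            out[name] = vals
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def response_association(
    clinical: pd.DataFrame,
    per_participant_edge_z: pd.DataFrame,
    session: str,
) -> list[AssociationResult]:
    """Pearson association of treatment response with each edge's scores."""
    if "response" not in clinical.columns:
        clinical = prepare_clinical(clinical)
    merged = per_participant_edge_z.join(
        clinical.set_index("participant")["response"], how="inner"
    )
    results = []
    for col in per_participant_edge_z.columns:
        sub = merged[[col, "response"]].dropna()
        if len(sub) < 4:
            raise ValueError(f"fewer than 4 participants with data for edge {col!r}")
        x = sub[col].to_numpy(dtype=float)
        y = sub["response"].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"zero variance in association inputs for edge {col!r}")
        r, p = stats.pearsonr(x, y)
        results.append(
            AssociationResult(edge=tuple(col.split("-")), session=session,
                              r_assoc=float(r), r_squared=float(r) ** 2,
                              p=float(p), n=len(sub))
        )
    return results
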