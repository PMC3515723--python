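"""Edge-level functional connectivity between region signals.

Partial correlations controlling for the whole-brain covariate, Fisher
r-to-z, and per-edge significance via the t transform with df = n - 3.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConnectivityEstimate",
    "partial_corr",
    "fisher_z",
    "connection_pvalue",
    "estimate_edge",
    "build_graph",
    "graph_long_table",
    "write_matrix_table",
]


@dataclass(frozen=True)
class ConnectivityEstimate:
    """One edge at one session/condition: partial r, Fisher z, n, df, p."""

    edge: tuple
    session: str
    condition: str
    r: float
    z: float
    n: int
    df: int
    p_two_sided: float


def _residualize(v: np.ndarray, covariate: np.ndarray, label: str) -> np.ndarray:
    design = np.column_stack([np.ones_like(covariate), covariate])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ coef
    scale = max(1.0, float(np.abs(v).max()))
    if float(np.sqrt((resid ** 2).mean())) <= 1e-12 * scale:
        raise ValueError(
            f"input {label!r} has zero residual variance after removing the covariate"
        )
    return resid


def partial_corr(x, y, covariate) -> float:
    """Pearson correlation of x and y after regressing each on the covariate.

    Equivalent to the closed form
    ``(r_xy - r_xc*r_yc) / sqrt((1 - r_xc^2) (1 - r_yc^2))``.
    """
    x, y, c = (np.asarray(v, dtype=float) for v in (x, y, covariate))
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValueError("x, y, covariate must be 1-D arrays of equal length")
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(c).all()):
        raise ValueError("inputs must be finite")
    rx = _residualize(x, c, "x")
    ry = _residualize(y, c, "y")
    return float(np.corrcoef(rx, ry)[0, 1])


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r) = 0.5*ln((1+r)/(1-r))."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    return float(np.arctanh(r))


def connection_pvalue(r: float, n: int) -> float:
    """Two-sided p for a partial correlation on n units with one covariate.

    Uses t = r*sqrt(df/(1-r^2)) with df = n - 3 against Student's t.
    """
    n = int(n)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    r = float(r)
    if abs(r) > 1:
        raise ValueError(f"correlation out of range: {r}")
    df = n - 3
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: p-value degenerates to 0", RuntimeWarning)
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def estimate_edge(x, y, covariate, edge=("x", "y"), session="", condition="") -> ConnectivityEstimate:
    """Full per-edge record from raw signal vectors."""
    n = len(np.asarray(x))
    r = partial_corr(x, y, covariate)
    return ConnectivityEstimate(
        edge=tuple(edge), session=session, condition=condition,
        r=r, z=fisher_z(r), n=n, df=n - 3, p_two_sided=connection_pvalue(r, n),
    )


def build_graph(
    table: pd.DataFrame,
    regions,
    session: str,
    condition: str = "combined",
    covariate_column: str = "global",
) -> nx.Graph:
    """Connectivity graph over all unordered region pairs for one key.

    ``table`` is an eigenvariate table (unit keys + one column per region +
    the covariate column). ``condition='combined'`` uses every unit of the
    session; a named condition filters to it. Per-edge n counts the units
    with no missing value in either region or the covariate.
    """
    regions = list(regions)
    sub = table[table["session"] == session]
    if condition != "combined":
        sub = sub[sub["condition"] == condition]
    if len(sub) < 4:
        raise ValueError(
            f"need at least 4 analysis units for session={session!r} "
            f"condition={condition!r}, got {len(sub)}"
        )
    graph = nx.Graph(session=session, condition=condition)
    graph.add_nodes_from(regions)
    for a, b in itertools.combinations(regions, 2):
        cols = sub[[a, b, covariate_column]].dropna()
        if len(cols) < 4:
            raise ValueError(f"fewer than 4 complete units for edge ({a}, {b})")
        est = estimate_edge(cols[a], cols[b], cols[covariate_column],
                            edge=(a, b), session=session, condition=condition)
        graph.add_edge(a, b, estimate=est)
    return graph


def graph_long_table(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for a, b, attrs in graph.edges(data=True):
        e: ConnectivityEstimate = attrs["estimate"]
        rows.append(dict(region_a=e.edge[0], region_b=e.edge[1],
                         session=e.session, condition=e.condition,
                         r=e.r, z=e.z, n=e.n, df=e.df, p=e.p_two_sided))
    return pd.DataFrame(rows).sort_values(["region_a", "region_b"]).reset_index(drop=True)


def write_matrix_table(graph: nx.Graph, path, regions=None) -> None:
    """Lower-triangle matrix layout, 'r p=..' per cell, one row per region."""
    regions = list(regions) if regions is not None else list(graph.nodes)
    with open(path, "w") as fh:
        fh.write("Area\t" + "\t".join(regions) + "\n")
        for i, a in enumerate(regions):
            cells = []
            for j, b in enumerate(regions):
                if j > i:
                    cells.append("")
                elif j == i:
                    cells.append("1.000")
                else:
                    e: ConnectivityEstimate = graph.edges[a, b]["estimate"]
                    cells.append(f"{e.r:.3f} p={e.p_two_sided:.3f}")
            fh.write(a + "\t" + "\t".join(cells) + "\n")
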