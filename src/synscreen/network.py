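"""Heat-diffusion integration of kinase and regulator evidence.

Two node sets summarize the omics stages: *upstream* kinases (inferred by
KSEA, plus directly measured kinases with significant interaction effects)
and *downstream* transcriptional master regulators (regulon enrichment).
Each set seeds a restart-based random walk (personalized PageRank) over a
reference interaction network; nodes heated by **both** walks are linkers
that tie the signalling evidence to the transcriptional evidence, and the
induced subgraph over inputs plus top linkers is the integrated network.

The walk iterates h = r * p + (1 - r) * W h with restart probability ``r``
and the degree-normalized (column-stochastic) adjacency W, so the total
heat equals the seeded mass and a dense linear solve provides an exact
oracle for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, NumericalError, SchemaError

__all__ = [
    "InputThresholds", "select_inputs", "diffuse", "linker_subnetwork",
]


@dataclass(frozen=True)
class InputThresholds:
    """Selection thresholds for diffusion input nodes.

    Downstream master regulators need q below ``mr_q_max`` and |enrichment
    score| at least ``mr_score_min``; upstream KSEA kinases need q at most
    ``ksea_q_max``; directly measured kinases enter at the residue-specific
    q cut-offs (a permissive tyrosine cut and a stringent serine/threonine
    cut, reflecting the very different sizes of the two datasets).
    """

    mr_q_max: float = 0.05
    mr_score_min: float = 5.0
    ksea_q_max: float = 0.05
    measured_py_q_max: float = 0.5
    measured_pst_q_max: float = 0.01


def select_inputs(
    mr_results: pd.DataFrame,
    ksea_results: pd.DataFrame,
    measured_results: pd.DataFrame | None = None,
    thresholds: InputThresholds | None = None,
    score_col: str = "nks",
) -> tuple[dict[str, float], dict[str, float]]:
    """Threshold the enrichment tables into weighted input node sets.

    Returns ``(upstream, downstream)`` maps node -> signed weight.  Inferred
    nodes are weighted by their enrichment score; measured kinases by their
    interaction coefficient ``beta_dc`` (``measured_results`` needs columns
    ``q_value``, ``beta_dc`` and ``residue_type`` in {"pY", "pST"}).
    """
    t = thresholds or InputThresholds()
    for df, cols, label in [
        (mr_results, {"q_value", score_col}, "mr_results"),
        (ksea_results, {"q_value", score_col}, "ksea_results"),
    ]:
        missing = cols - set(df.columns)
        if missing:
            raise SchemaError(f"{label} missing columns: {sorted(missing)}")

    mr = mr_results.dropna(subset=["q_value", score_col])
    keep = (mr["q_value"] < t.mr_q_max) & (mr[score_col].abs() >= t.mr_score_min)
    downstream = {str(i): float(s) for i, s in mr.loc[keep, score_col].items()}

    ks = ksea_results.dropna(subset=["q_value", score_col])
    keep = ks["q_value"] <= t.ksea_q_max
    upstream = {str(i): float(s) for i, s in ks.loc[keep, score_col].items()}

    if measured_results is not None and len(measured_results):
        missing = {"q_value", "beta_dc", "residue_type"} - set(measured_results.columns)
        if missing:
            raise SchemaError(f"measured_results missing columns: {sorted(missing)}")
        meas = measured_results.dropna(subset=["q_value", "beta_dc"])
        qmax = meas["residue_type"].map(
            {"pY": t.measured_py_q_max, "pST": t.measured_pst_q_max})
        for node, beta in meas.loc[meas["q_value"] <= qmax, "beta_dc"].items():
            upstream.setdefault(str(node), float(beta))

    if not upstream or not downstream:
        raise SchemaError(
            "diffusion inputs are empty "
            f"(upstream={len(upstream)}, downstream={len(downstream)})")
    return upstream, downstream


def _walk_matrix(g: nx.Graph, nodes: list[str]) -> np.ndarray:
    """Column-stochastic degree-normalized adjacency; isolated nodes keep
    their heat (identity column)."""
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    deg = a.sum(axis=0)
    w = np.zeros_like(a)
    nz = deg > 0
    w[:, nz] = a[:, nz] / deg[nz]
    idx = np.nonzero(~nz)[0]
    w[idx, idx] = 1.0
    return w


def diffuse(
    g: nx.Graph,
    seeds: dict[str, float],
    restart: float = 0.15,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> dict[str, float]:
    """Restart-walk stationary heats from weighted seed nodes.

    Seed magnitudes |weight| form the personalization vector (signs carry
    direction labels, not heat).  Iterates to ``tol`` in L1; the heat total
    equals the seeded mass.  Raises on empty seeds or non-convergence.
    """
    if not seeds:
        raise ConfigError("diffuse requires at least one seed node")
    if not (0 < restart < 1):
        raise ConfigError(f"restart must be in (0, 1), got {restart}")
    nodes = sorted(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    missing = [n for n in seeds if n not in index]
    if missing:
        warnings.warn(f"dropping {len(missing)} seed nodes absent from the network")
    p = np.zeros(len(nodes))
    for n, wgt in seeds.items():
        if n in index:
            p[index[n]] = abs(float(wgt))
    if p.sum() == 0:
        raise ConfigError("all seed nodes are absent from the network")
    w = _walk_matrix(g, nodes)
    h = p.copy()
    for _ in range(max_iter):
        h_next = restart * p + (1.0 - restart) * (w @ h)
        resid = float(np.abs(h_next - h).sum())
        h = h_next
        if resid < tol:
            return {n: float(h[index[n]]) for n in nodes}
    raise NumericalError(f"diffusion did not converge: residual {resid:.3e} "
                         f"after {max_iter} iterations")


def linker_subnetwork(
    g: nx.Graph,
    up_heats: dict[str, float],
    down_heats: dict[str, float],
    upstream: dict[str, float],
    downstream: dict[str, float],
    size_factor: float = 1.0,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Extract the agreement subnetwork between the two heat fields.

    Every node's linker score is min(upstream heat, downstream heat) -- heat
    received from *both* evidence sources.  The top
    ``round(size_factor * (|upstream| + |downstream|))`` non-input nodes with
    positive score become linkers; the result is the induced subgraph over
    input nodes plus linkers, with a node table carrying scores, roles and
    the direction sign of each input's weight.
    """
    if size_factor <= 0:
        raise ConfigError("size_factor must be positive")
    inputs = set(upstream) | set(downstream)
    scores = {
        n: min(up_heats.get(n, 0.0), down_heats.get(n, 0.0)) for n in g.nodes()
    }
    k = int(round(size_factor * (len(upstream) + len(downstream))))
    candidates = sorted(
        ((n, s) for n, s in scores.items() if n not in inputs and s > 0),
        key=lambda t: (-t[1], t[0]),
    )
    linkers = [n for n, _ in candidates[:k]]
    if not linkers:
        warnings.warn("no node receives heat from both sources; "
                      "returning the inputs-only subnetwork")
    keep = [n for n in g.nodes() if n in inputs or n in set(linkers)]
    sub = g.subgraph(keep).copy()
    rows = []
    for n in sorted(keep):
        role = ("upstream" if n in upstream else
                "downstream" if n in downstream else "linker")
        weight = upstream.get(n, downstream.get(n, 0.0))
        rows.append({"node": n, "role": role, "linker_score": scores[n],
                     "direction": int(np.sign(weight))})
    table = pd.DataFrame(rows).set_index("node")
    return sub, table
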