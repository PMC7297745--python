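"""Time-aggregated contact networks and their summary metrics.

A contact network aggregates bouts over a window into a weighted graph whose
nodes are individuals and whose edge weights count in-contact timesteps
("contact frequency" at the grid resolution).  Body-contact networks are
undirected; the visual-field network — individual j appearing inside
individual i's visual polygon — is directed i -> j and is never symmetrized.

Metrics follow the usual connectivity summaries for such networks: density,
node degree (distinct partners), contact duration (bout lengths, in
timesteps), per-capita sum contacts (total in-contact timesteps incident to a
node), daily degree (distinct partners per UTC calendar day), and, for
directed networks, the instantaneous out-degree time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import (
    BOUT_COLUMNS,
    POINT_PART,
    _series_from_fixes,
    detect_contacts,
    extract_bouts,
    pairwise_distances,
)
from .geometry import PART_COL
from .io import TIME_COL
from .preprocess import GridSpec

SECONDS_PER_DAY = 86_400


@dataclass
class ContactNetwork:
    """Weighted time-aggregated contact graph plus its bout records."""

    graph: nx.Graph | nx.DiGraph
    directed: bool
    window: tuple[int, int] | None = None
    bouts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BOUT_COLUMNS))
    label: str | None = None

    def edge_records(self) -> list[dict]:
        """Edge list rows (weights already aggregated; one row per edge)."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            if not self.directed and str(v) < str(u):
                u, v = v, u
            rows.append(
                {
                    "from_id": u,
                    "to_id": v,
                    "from_part": data.get("part_a", ""),
                    "to_part": data.get("part_b", ""),
                    "directed": self.directed,
                    "weight": data["weight"],
                }
            )
        return rows


def build_network(
    bouts: pd.DataFrame,
    window: tuple[int, int] | None = None,
    directed: bool = False,
    nodes=None,
    label: str | None = None,
) -> ContactNetwork:
    """Aggregate bouts into a weighted network.

    Edge weight is the sum of ``n_timesteps`` over all bouts of the dyad (and
    part-pair label).  For undirected part-asymmetric networks (head to
    posterior), the i-head/j-posterior and j-head/i-posterior bouts accumulate
    into the single undirected (i, j) edge.  ``nodes`` optionally supplies the
    full node set so individuals without contacts appear as isolates.
    """
    graph = nx.DiGraph() if directed else nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    sub = bouts
    if window is not None:
        sub = bouts[(bouts["start_time"] >= window[0]) & (bouts["end_time"] <= window[1])]
    for row in sub.itertuples():
        u, v = row.id_a, row.id_b
        if graph.has_edge(u, v):
            graph[u][v]["weight"] += int(row.n_timesteps)
        else:
            graph.add_edge(u, v, weight=int(row.n_timesteps), part_a=row.part_a, part_b=row.part_b)
    return ContactNetwork(graph=graph, directed=directed, window=window, bouts=sub, label=label)


def build_visual_network(
    polygons: pd.DataFrame,
    positions: pd.DataFrame,
    spth: float,
    grid: GridSpec,
    max_gap: int = 0,
) -> ContactNetwork:
    """Directed network of individuals appearing in others' visual fields.

    Edge i -> j gains one unit of weight for every timestep at which the
    distance from j's point location to i's visual-field polygon is at most
    ``spth``.  ``polygons`` is the oriented visual-polygon series (one part);
    ``positions`` the planar fix table on the same grid.
    """
    parts = polygons[PART_COL].unique()
    if len(parts) != 1:
        raise ValueError("visual polygon series must contain exactly one part")
    visual_part = parts[0]
    combined = pd.concat(
        [polygons, _series_from_fixes(positions)], ignore_index=True
    )
    dist = pairwise_distances(combined, [(visual_part, POINT_PART)], directed=True)
    flags = detect_contacts(dist, spth)
    bouts = extract_bouts(flags, grid, max_gap=max_gap)
    return build_network(
        bouts,
        window=(grid.start, grid.end),
        directed=True,
        nodes=sorted(positions["id"].unique()),
        label="visual",
    )


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return 0.0, 0.0
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def network_metrics(
    net: ContactNetwork,
    n_timesteps_total: int | None = None,
    grid: GridSpec | None = None,
) -> dict:
    """Summary connectivity metrics for a contact network.

    Returns a dict with density, mean/SD node degree (distinct partners),
    mean/SD contact duration (bout lengths, timesteps), mean/SD per-capita sum
    contacts (incident edge weight per node), mean/SD daily degree (distinct
    partners per UTC calendar day), and for directed networks the mean/SD of
    the instantaneous out-degree across nodes and timesteps (requires
    ``grid``).  An empty network reports zeros along with ``n_nodes``.
    """
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    possible = n * (n - 1) if net.directed else n * (n - 1) / 2
    density = m / possible if possible else 0.0

    if net.directed:
        degrees = [g.out_degree(v) for v in g.nodes]
        strengths = [g.out_degree(v, weight="weight") for v in g.nodes]
    else:
        degrees = [g.degree(v) for v in g.nodes]
        strengths = [g.degree(v, weight="weight") for v in g.nodes]
    deg_mean, deg_sd = _mean_sd(degrees)
    str_mean, str_sd = _mean_sd(strengths)
    dur_mean, dur_sd = _mean_sd(net.bouts["n_timesteps"]) if len(net.bouts) else (0.0, 0.0)

    metrics = {
        "n_nodes": n,
        "n_edges": m,
        "density": float(density),
        "degree_mean": deg_mean,
        "degree_sd": deg_sd,
        "contact_duration_mean": dur_mean,
        "contact_duration_sd": dur_sd,
        "per_capita_sum_contacts_mean": str_mean,
        "per_capita_sum_contacts_sd": str_sd,
    }

    if len(net.bouts):
        daily: dict[tuple, set] = {}
        for row in net.bouts.itertuples():
            for day in range(
                int(row.start_time) // SECONDS_PER_DAY,
                int(row.end_time) // SECONDS_PER_DAY + 1,
            ):
                daily.setdefault((row.id_a, day), set()).add(row.id_b)
                if not net.directed:
                    daily.setdefault((row.id_b, day), set()).add(row.id_a)
        metrics["daily_degree_mean"], metrics["daily_degree_sd"] = _mean_sd(
            len(v) for v in daily.values()
        )
    else:
        metrics["daily_degree_mean"] = metrics["daily_degree_sd"] = 0.0

    if net.directed and grid is not None:
        counts = np.zeros((n, grid.n_slots), dtype=int)
        index = {v: i for i, v in enumerate(sorted(g.nodes))}
        for row in net.bouts.itertuples():
            k0 = (int(row.start_time) - grid.start) // grid.interval
            k1 = (int(row.end_time) - grid.start) // grid.interval
            counts[index[row.id_a], k0 : k1 + 1] += 1
        metrics["out_degree_series_mean"] = float(counts.mean())
        metrics["out_degree_series_sd"] = float(counts.std(ddof=1))
    return metrics
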