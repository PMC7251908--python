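"""Receptor-ligand cell-pair interaction networks between cell types.

An interaction links one cell expressing a ligand to another expressing the
matching receptor.  For a pair (L, R) and an ordered (sender, receiver) cell
type pair the raw edge weight is the number of such cell pairs:

    count = (# sender cells expressing L) x (# receiver cells expressing R)

"Expressing" means normalized expression above a threshold (0 by default,
i.e. any expression).  Self-type edges are allowed.  For drawing, node sizes
are cell counts scaled by 1/20 and edge widths are pair counts scaled by
1/4,000,000; edges whose sender type expresses the ligand in more than 10%
of its cells carry a draw flag (a reporting filter only -- it never changes
the counts).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .signatures import _as_frame

__all__ = [
    "InteractionNetwork",
    "expressing_fraction",
    "count_pairs",
    "export_network",
    "import_network",
    "to_networkx",
    "NODE_SCALE",
    "EDGE_SCALE",
]

NODE_SCALE = 1.0 / 20.0
EDGE_SCALE = 1.0 / 4_000_000.0

EDGE_COLUMNS = ["sender", "receiver", "ligand", "receptor", "count", "scaled_weight", "draw_flag"]


@dataclass
class InteractionNetwork:
    edges: pd.DataFrame  # EDGE_COLUMNS
    nodes: pd.DataFrame  # cell_type, n_cells, scaled_size
    expressing_fractions: pd.DataFrame = field(default_factory=pd.DataFrame)  # type x gene


def expressing_fraction(X, cell_types: pd.Series, gene: str, threshold: float = 0.0) -> pd.Series:
    """Fraction of cells of each type with expression of ``gene`` above
    ``threshold``."""
    frame = _as_frame(X)
    if gene not in frame.columns:
        raise KeyError(f"gene {gene!r} not present in the expression matrix")
    expressed = frame[gene] > threshold
    types = pd.Series(cell_types, index=frame.index)
    return expressed.groupby(types, observed=True).mean().rename(gene)


def count_pairs(
    X,
    cell_types: pd.Series,
    pairs: pd.DataFrame,
    threshold: float = 0.0,
    draw_fraction: float = 0.10,
) -> InteractionNetwork:
    """Count ligand-receptor cell pairs between every ordered cell-type pair.

    ``pairs`` needs columns ligand/receptor; pairs whose genes are absent
    from the matrix are skipped with a warning; edges with zero pairs are
    omitted.
    """
    frame = _as_frame(X)
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 cells to form pairs")
    types = pd.Series(cell_types, index=frame.index).astype(str)
    type_names = sorted(types.unique())
    n_cells = types.value_counts().reindex(type_names)
    if len(pairs) == 0:
        warnings.warn("empty ligand-receptor pair table; network has no edges")
    genes = sorted(set(pairs.get("ligand", [])) | set(pairs.get("receptor", [])))
    present = [g for g in genes if g in frame.columns]
    # expressing-cell counts and fractions per type for every pair gene
    n_expr = pd.DataFrame(0, index=type_names, columns=present, dtype=int)
    frac = pd.DataFrame(0.0, index=type_names, columns=present)
    for gene in present:
        expressed = frame[gene] > threshold
        counts = expressed.groupby(types, observed=True).sum().reindex(type_names, fill_value=0)
        n_expr[gene] = counts.astype(int)
        frac[gene] = counts / n_cells
    records = []
    for _, row in pairs.iterrows():
        ligand, receptor = row["ligand"], row["receptor"]
        if ligand not in frame.columns or receptor not in frame.columns:
            warnings.warn(f"pair {ligand}:{receptor} skipped; gene absent from matrix")
            continue
        for sender in type_names:
            nl = int(n_expr.loc[sender, ligand])
            if nl == 0:
                continue
            for receiver in type_names:
                nr = int(n_expr.loc[receiver, receptor])
                if nr == 0:
                    continue
                count = nl * nr
                records.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "ligand": ligand,
                        "receptor": receptor,
                        "count": count,
                        "scaled_weight": count * EDGE_SCALE,
                        "draw_flag": bool(frac.loc[sender, ligand] > draw_fraction),
                    }
                )
    edges = pd.DataFrame(records, columns=EDGE_COLUMNS)
    nodes = pd.DataFrame(
        {
            "cell_type": type_names,
            "n_cells": n_cells.to_numpy(),
            "scaled_size": n_cells.to_numpy() * NODE_SCALE,
        }
    )
    return InteractionNetwork(edges=edges, nodes=nodes, expressing_fractions=frac)


def export_network(network: InteractionNetwork, directory: str | Path) -> tuple[Path, Path]:
    """Write edges.csv and nodes.json; returns their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edges_path = directory / "edges.csv"
    nodes_path = directory / "nodes.json"
    try:
        network.edges.to_csv(edges_path, index=False)
        nodes_path.write_text(
            json.dumps(network.nodes.to_dict(orient="records"), indent=2)
        )
    except OSError as exc:
        raise OSError(f"cannot export network under {directory}: {exc}") from exc
    return edges_path, nodes_path


def import_network(directory: str | Path) -> InteractionNetwork:
    directory = Path(directory)
    edges = pd.read_csv(directory / "edges.csv")
    if list(edges.columns) != EDGE_COLUMNS:
        raise ValueError(f"{directory}/edges.csv: unexpected columns {list(edges.columns)}")
    nodes = pd.DataFrame(json.loads((directory / "nodes.json").read_text()))
    return InteractionNetwork(edges=edges, nodes=nodes)


def to_networkx(network: InteractionNetwork) -> nx.MultiDiGraph:
    """Render the network as a networkx MultiDiGraph (one edge per pair)."""
    graph = nx.MultiDiGraph()
    for _, node in network.nodes.iterrows():
        graph.add_node(node["cell_type"], n_cells=int(node["n_cells"]), size=node["scaled_size"])
    for _, edge in network.edges.iterrows():
        graph.add_edge(
            edge["sender"],
            edge["receiver"],
            key=f"{edge['ligand']}:{edge['receptor']}",
            ligand=edge["ligand"],
            receptor=edge["receptor"],
            count=int(edge["count"]),
            weight=float(edge["scaled_weight"]),
            draw=bool(edge["draw_flag"]),
        )
    return graph
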