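"""STRING-style PPI edge lists: parsing, confidence thresholding, cluster extraction.

Edges carry the STRING combined-score convention (integer 0-1000; 400 =
"medium confidence" 0.4). Cluster extraction induces the subgraph on a seed
set of proteins (typically the differentially expressed symbols), enumerates
connected components and ranks them by edge density, then mean combined
score, then size — surfacing the most interconnected module rather than the
largest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

#: Packaged synthetic fixture edge list over the 17 DE protein symbols.
FIXTURE_EDGES = "ppi_17de_synthetic.tsv"


def fixture_path() -> Path:
    """Path of the packaged synthetic PPI fixture edge list."""
    return Path(resources.files("tmtdea").joinpath("data", FIXTURE_EDGES))


def load_edges(path) -> nx.Graph:
    """Parse a protein-links TSV (protein1, protein2, combined_score) into a graph.

    Reciprocal/duplicate rows are merged keeping the maximum score; self-loops
    are dropped with a warning; a malformed score raises with its line number.
    Lines starting with '#' are comments.
    """
    g = nx.Graph()
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = {name: i for i, name in enumerate(fields)}
                for col in ("protein1", "protein2", "combined_score"):
                    if col not in header:
                        raise ValueError(f"{path}: missing column {col!r}")
                continue
            a = fields[header["protein1"]]
            b = fields[header["protein2"]]
            try:
                score = int(fields[header["combined_score"]])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed combined_score") from exc
            if not 0 <= score <= 1000:
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], score)
            else:
                g.add_edge(a, b, score=score)
    return g


def filter_edges(net: nx.Graph, min_conf: float = 0.4) -> nx.Graph:
    """Retain edges with combined_score >= round(min_conf * 1000); keep all nodes."""
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError("min_conf must be in [0, 1]")
    threshold = round(min_conf * 1000)
    out = nx.Graph()
    out.add_nodes_from(net.nodes)
    out.add_edges_from(
        (a, b, d) for a, b, d in net.edges(data=True) if d["score"] >= threshold
    )
    return out


@dataclass(frozen=True)
class Cluster:
    """One connected component of the induced DE subgraph."""

    members: tuple[str, ...]
    density: float
    mean_score: float
    n_edges: int

    @property
    def size(self) -> int:
        return len(self.members)


def extract_clusters(net: nx.Graph, seed_nodes) -> list[Cluster]:
    """Connected components of the subgraph induced on ``seed_nodes``, ranked.

    Ranking is by edge density (edges / possible edges; a clique of any size
    >= 2 has density 1, a singleton 0), then mean combined score, then size,
    all descending. Seed names absent from the network are reported via a
    warning, not fatal.
    """
    seed_nodes = set(seed_nodes)
    if not seed_nodes:
        raise ValueError("seed node set is empty")
    missing = seed_nodes - set(net.nodes)
    if missing:
        logger.warning("seed nodes not in network: %s", sorted(missing))
    sub = net.subgraph(seed_nodes & set(net.nodes))
    clusters = []
    for comp in nx.connected_components(sub):
        cg = sub.subgraph(comp)
        scores = [d["score"] for _, _, d in cg.edges(data=True)]
        clusters.append(
            Cluster(
                members=tuple(sorted(comp)),
                density=nx.density(cg) if len(comp) > 1 else 0.0,
                mean_score=float(sum(scores) / len(scores)) if scores else 0.0,
                n_edges=cg.number_of_edges(),
            )
        )
    clusters.sort(key=lambda c: (-c.density, -c.mean_score, -c.size, c.members))
    return clusters
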