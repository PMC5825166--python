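"""Cα contact networks and communicability centrality.

Residue-residue communication is modelled on an undirected, unweighted
graph whose nodes are Cα atoms, with an edge whenever the Cα-Cα distance
is at most 5 Å. Communicability (subgraph) centrality of a node is the
factorial-weighted count of closed walks through it — the corresponding
diagonal entry of exp(A) — computed here from the eigendecomposition of
the symmetric adjacency matrix. Centralities are z-scored within a domain
so that the tethered and isolated members can be compared on a common
scale; a residue is flagged when its normalized centrality differs by
more than 1.5 between the pair members.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .structure_io import ResidueMapping, Structure

__all__ = [
    "ContactNetwork",
    "CentralityProfile",
    "build_network",
    "communicability_centrality",
    "normalize_centrality",
    "centrality_profile",
    "centrality_difference",
]


@dataclass
class ContactNetwork:
    """Cα contact graph: node i is residue i of the source structure."""

    adjacency: np.ndarray      # symmetric 0/1, zero diagonal
    cutoff: float

    def __post_init__(self):
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with no self-edges")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class CentralityProfile:
    raw: np.ndarray
    normalized: np.ndarray


def build_network(s: Structure | np.ndarray, cutoff: float = 5.0) -> ContactNetwork:
    """Build the Cα contact network at an inclusive distance cutoff.

    Accepts a Structure or an N x 3 Cα coordinate array. An edge exists
    iff the Cα-Cα distance is <= cutoff (5 Å by default).
    """
    coords = s if isinstance(s, np.ndarray) else s.ca_coords()
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("structure has no CA atoms")
    d = squareform(pdist(coords))
    adj = (d <= cutoff).astype(float)
    np.fill_diagonal(adj, 0.0)
    return ContactNetwork(adjacency=adj, cutoff=cutoff)


def communicability_centrality(g: ContactNetwork) -> np.ndarray:
    """Raw communicability centrality: diag(exp(A)).

    Equal to sum_k (A^k)_ii / k!, the factorial-weighted number of closed
    walks at node i; always >= 1 because the length-0 walk counts.
    Computed spectrally: with A = V diag(w) V^T, the score is
    sum_j V_ij^2 exp(w_j).
    """
    w, v = np.linalg.eigh(g.adjacency)
    return (v**2) @ np.exp(w)


def normalize_centrality(raw: np.ndarray) -> np.ndarray:
    """Within-domain z-score; all-zero when the spread is zero."""
    raw = np.asarray(raw, float)
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def centrality_profile(g: ContactNetwork) -> CentralityProfile:
    raw = communicability_centrality(g)
    return CentralityProfile(raw=raw, normalized=normalize_centrality(raw))


def centrality_difference(
    md: CentralityProfile,
    id_: CentralityProfile,
    mapping: ResidueMapping,
    threshold: float = 1.5,
) -> list[tuple[int, int]]:
    """Mapped residue pairs whose normalized centralities differ by > threshold.

    The comparison is strict: an absolute difference of exactly the
    threshold is not flagged. Returned as (index in MD, index in ID)
    pairs. Raises if the mapping addresses residues outside either
    profile.
    """
    flagged = []
    for ia, ib in mapping.pairs:
        if ia >= md.normalized.size or ib >= id_.normalized.size:
            raise IndexError(
                f"mapped pair ({ia}, {ib}) outside centrality profiles"
            )
        if abs(md.normalized[ia] - id_.normalized[ib]) > threshold:
            flagged.append((ia, ib))
    return flagged
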