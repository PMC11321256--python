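"""Set memberships (the hypergraph layer) and within-set interaction graphs.

A community of S species is organized into G overlapping sets; each species
belongs to exactly K of them, chosen uniformly at random.  Two species can
interact only inside sets they share, so the expected number of shared sets
per pair — the *order* H = K^2/G — controls how many distinct interaction
events a pair can accrue.  This module owns the membership sampling, the
order bookkeeping, and the per-set interaction graphs (Erdos-Renyi or
preferential-attachment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import networkx as nx
import numpy as np

from ._rng import as_generator

logger = logging.getLogger(__name__)

__all__ = [
    "SetMembership",
    "WithinSetGraph",
    "sample_membership",
    "expected_order",
    "empirical_order",
    "sample_within_set_edges",
    "sample_scale_free_edges",
]


@dataclass(frozen=True)
class SetMembership:
    """S x G binary incidence of species over sets.

    ``incidence[i, g] == 1`` iff species ``i`` belongs to set ``g``.  Every
    row sums to exactly ``sets_per_species`` (K).
    """

    incidence: np.ndarray
    sets_per_species: int

    def __post_init__(self):
        inc = np.asarray(self.incidence, dtype=np.int8)
        if inc.ndim != 2:
            raise ValueError("incidence must be a 2-D table")
        if not np.isin(inc, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        rows = inc.sum(axis=1)
        if not (rows == self.sets_per_species).all():
            bad = int(np.flatnonzero(rows != self.sets_per_species)[0])
            raise ValueError(
                f"species {bad} belongs to {int(rows[bad])} sets, "
                f"expected K={self.sets_per_species}"
            )
        object.__setattr__(self, "incidence", inc)

    @property
    def n_species(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_sets(self) -> int:
        return self.incidence.shape[1]

    def members_of(self, set_id: int) -> np.ndarray:
        """Species indices belonging to set ``set_id`` (0-based)."""
        return np.flatnonzero(self.incidence[:, set_id])

    def sets_of(self, species: int) -> np.ndarray:
        """Set indices containing ``species`` (0-based)."""
        return np.flatnonzero(self.incidence[species, :])


@dataclass(frozen=True)
class WithinSetGraph:
    """Interaction graph restricted to the members of one set.

    Edges are unordered pairs of member species; self-loops and edges
    leaving the member list are invalid.
    """

    set_id: int
    members: tuple
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        members = tuple(int(m) for m in self.members)
        mem = set(members)
        edges = frozenset(tuple(sorted((int(u), int(v)))) for u, v in self.edges)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on species {u}")
            if u not in mem or v not in mem:
                raise ValueError(f"edge ({u},{v}) leaves the member list of set {self.set_id}")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def average_degree(self) -> float:
        return 2 * len(self.edges) / len(self.members) if self.members else 0.0

    @property
    def connectivity(self) -> float:
        m = len(self.members)
        return len(self.edges) / (m * (m - 1) / 2) if m > 1 else 0.0


def sample_membership(S: int, G: int, K: int, seed=None) -> SetMembership:
    """Assign each of S species to K of G sets, uniformly without replacement.

    Choices are independent across species, so set sizes are random with
    mean S*K/G.  Empty or singleton sets are allowed; they simply carry no
    interactions.
    """
    if S < 2:
        raise ValueError(f"need at least 2 species, got S={S}")
    if not 1 <= K <= G:
        raise ValueError(f"need 1 <= K <= G, got K={K}, G={G}")
    rng = as_generator(seed)
    # argpartition of iid uniform keys yields a uniform K-subset per row
    keys = rng.random((S, G))
    chosen = np.argpartition(keys, K - 1, axis=1)[:, :K]
    incidence = np.zeros((S, G), dtype=np.int8)
    incidence[np.arange(S)[:, None], chosen] = 1
    return SetMembership(incidence=incidence, sets_per_species=K)


def expected_order(K: int, G: int) -> float:
    """Expected number of sets shared by two random species: H = K^2/G."""
    if not 1 <= K <= G:
        raise ValueError(f"need 1 <= K <= G, got K={K}, G={G}")
    return K**2 / G


def empirical_order(membership: SetMembership) -> float:
    """Mean number of shared sets over all unordered species pairs.

    Over random memberships its expectation equals ``expected_order(K, G)``.
    """
    S = membership.n_species
    if S < 2:
        raise ValueError("empirical order needs at least 2 species")
    inc = membership.incidence.astype(np.int64)
    shared = inc @ inc.T
    total = (shared.sum() - np.trace(shared)) / 2  # upper triangle
    return float(total / (S * (S - 1) / 2))


def sample_within_set_edges(
    members: Sequence[int], C: float, seed=None, set_id: int = 0
) -> WithinSetGraph:
    """Erdos-Renyi edges among the members: each pair present independently with probability C."""
    if not 0 <= C <= 1:
        raise ValueError(f"connectivity must lie in [0, 1], got C={C}")
    rng = as_generator(seed)
    members = tuple(int(m) for m in members)
    m = len(members)
    if m < 2:
        return WithinSetGraph(set_id=set_id, members=members, edges=frozenset())
    iu, ju = _triu_pairs(m)
    mask = rng.random(iu.size) < C
    arr = np.asarray(members)
    edges = frozenset(zip(arr[iu[mask]].tolist(), arr[ju[mask]].tolist()))
    return WithinSetGraph(set_id=set_id, members=members, edges=edges)


def sample_scale_free_edges(
    members: Sequence[int],
    *,
    average_degree: float | None = None,
    connectivity: float | None = None,
    seed=None,
    set_id: int = 0,
) -> WithinSetGraph:
    """Preferential-attachment (Barabasi-Albert) graph over the members.

    The target is either an average degree ``k`` or a connectivity ``C``
    (converted via k = C*(m-1) for m members).  A Barabasi-Albert graph on
    m nodes with attachment count a has exactly a*(m-a) edges, i.e. average
    degree 2a(m-a)/m, so the real-valued attachment count solving that for
    k is rounded stochastically; the realized average degree is then
    unbiased for the target (up to the floor of one attachment per node).
    Degree distributions are heavy-tailed for large member counts.
    """
    members = tuple(int(m) for m in members)
    m = len(members)
    if m < 2:
        raise ValueError(f"preferential attachment needs at least 2 members, got {m}")
    if (average_degree is None) == (connectivity is None):
        raise ValueError("give exactly one of average_degree or connectivity")
    if connectivity is not None:
        if not 0 <= connectivity <= 1:
            raise ValueError(f"connectivity must lie in [0, 1], got C={connectivity}")
        target_k = connectivity * (m - 1)
    else:
        target_k = float(average_degree)
    if target_k >= m:
        raise ValueError(f"target average degree {target_k} unachievable with {m} members")
    if target_k < 0:
        raise ValueError(f"target average degree must be nonnegative, got {target_k}")
    rng = as_generator(seed)
    # 2a(m-a)/m = k  =>  a = (m - sqrt(m^2 - 2km))/2; stochastic rounding
    disc = m * m - 2 * target_k * m
    a = (m - np.sqrt(disc)) / 2 if disc >= 0 else m / 2
    lo = int(np.floor(a))
    m_pa = lo + int(rng.random() < a - lo)
    m_pa = max(1, min(m_pa, m - 1))
    g = nx.barabasi_albert_graph(m, m_pa, seed=int(rng.integers(2**31)))
    # random relabelling so hubs are not biased toward low species indices
    order = rng.permutation(members)
    edges = frozenset((int(order[u]), int(order[v])) for u, v in g.edges())
    return WithinSetGraph(set_id=set_id, members=members, edges=edges)


@lru_cache(maxsize=None)
def _triu_pairs(m: int):
    """Cached upper-triangle pair indices for an m-member set."""
    return np.triu_indices(m, k=1)
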