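"""Community-matrix ensembles over set-structured and unstructured systems.

The linearized dynamics near a feasible equilibrium X* are
dx/dt = diag(X*) J x = M x, so the community matrix M is the Jacobian row-
scaled by the equilibrium abundances.  Off-diagonal strengths are bivariate
draws built from N(0, sigma^2) and its folded variants, placed per set with
probability C (or on per-set graph edges for the degree-heterogeneous and
local-symmetric flavors) and summed over sets: M_ij = sum_g M^g_ij.  The
diagonal is the self-regulation -d, overwritten after the sum and scaled by
abundances last.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._rng import as_generator
from .structure import (
    SetMembership,
    _triu_pairs,
    sample_scale_free_edges,
)

logger = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_TYPES",
    "FLAVORS",
    "ABUNDANCE_DISTS",
    "EnsembleConfig",
    "InteractionPair",
    "CommunityMatrix",
    "AbundanceVector",
    "sample_pair",
    "sample_pairs",
    "build_set_structured",
    "build_unstructured",
    "build_heterogeneous_set_structured",
    "build_heterogeneous_unstructured",
    "build_local_symmetric",
    "sample_abundances",
    "apply_abundances",
]

INTERACTION_TYPES = ("random", "exploitative", "mutualistic", "competitive", "mixed")
FLAVORS = ("er_within_set", "scale_free_within_set", "local_symmetric")
ABUNDANCE_DISTS = ("unit", "uniform", "lognormal", "halfnormal")


@dataclass(frozen=True)
class EnsembleConfig:
    """All scalar parameters of one ensemble.

    Parameters
    ----------
    n_species : int
        Community size S.
    connectivity : float
        Probability C that a within-set (or global, for unstructured
        systems) species pair interacts.
    strength_sd : float
        Scale sigma of the N(0, sigma^2) interaction-strength draws.
    n_sets, sets_per_species : int
        G and K of the set structure; the order is H = K^2/G.
    interaction_type : str
        One of ``random``, ``exploitative`` (+/-), ``mutualistic`` (+/+),
        ``competitive`` (-/-), or ``mixed`` (type drawn per pair).
    self_regulation : float
        d > 0; every diagonal entry is -d before abundance scaling.  Only
        the ratio d/sigma enters the stability criteria.
    flavor : str
        ``er_within_set`` places edges independently with probability C;
        ``scale_free_within_set`` uses a preferential-attachment graph per
        set at connectivity C; ``local_symmetric`` uses per-set
        preferential-attachment graphs at a fixed average degree k.
    average_degree : float, optional
        The per-set average degree k (local_symmetric flavor only).
    abundance_dist, abundance_params :
        Equilibrium-abundance distribution; ``unit`` fixes X* = 1.
    """

    n_species: int
    connectivity: float
    strength_sd: float
    n_sets: int
    sets_per_species: int
    interaction_type: str = "random"
    self_regulation: float = 1.0
    flavor: str = "er_within_set"
    average_degree: Optional[float] = None
    abundance_dist: str = "unit"
    abundance_params: tuple = ()

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError(f"need at least 2 species, got S={self.n_species}")
        if not 0 <= self.connectivity <= 1:
            raise ValueError(f"connectivity must lie in [0, 1], got C={self.connectivity}")
        if self.strength_sd <= 0:
            raise ValueError(f"strength_sd must be positive, got sigma={self.strength_sd}")
        if self.self_regulation <= 0:
            raise ValueError(f"self_regulation must be positive, got d={self.self_regulation}")
        if not 1 <= self.sets_per_species <= self.n_sets:
            raise ValueError(
                f"need 1 <= K <= G, got K={self.sets_per_species}, G={self.n_sets}"
            )
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        if self.flavor not in FLAVORS:
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.abundance_dist not in ABUNDANCE_DISTS:
            raise ValueError(f"unknown abundance distribution {self.abundance_dist!r}")
        if self.flavor == "local_symmetric" and self.average_degree is None:
            raise ValueError("local_symmetric flavor requires average_degree")

    @property
    def order(self) -> float:
        """H = K^2/G."""
        return self.sets_per_species**2 / self.n_sets

    def with_sets(self, n_sets: int) -> "EnsembleConfig":
        return replace(self, n_sets=n_sets)


@dataclass(frozen=True)
class InteractionPair:
    """One bivariate interaction draw (M_ij^g, M_ji^g)."""

    forward: float
    backward: float


@dataclass(frozen=True)
class CommunityMatrix:
    """S x S real matrix with a role tag.

    Roles: ``set_structured`` (M), ``unstructured`` (M-hat), ``per_set``
    (M^g), ``jacobian`` (J, before abundance scaling).
    """

    values: np.ndarray
    role: str = "set_structured"
    config: Optional[EnsembleConfig] = None

    _ROLES = ("set_structured", "unstructured", "per_set", "jacobian")

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"community matrix must be square, got shape {vals.shape}")
        if self.role not in self._ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        object.__setattr__(self, "values", vals)

    @property
    def n_species(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AbundanceVector:
    """Strictly positive equilibrium abundances X*."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("abundances must be a 1-D vector")
        if not (vals > 0).all():
            raise ValueError("all equilibrium abundances must be strictly positive")
        object.__setattr__(self, "values", vals)


# ---------------------------------------------------------------------------
# interaction strengths


def sample_pairs(interaction_type: str, sd: float, n: int, seed=None):
    """Vectorized bivariate strength draws: two length-n arrays (forward, backward).

    random       both ~ N(0, sd^2), independent.
    exploitative one is +|N(0, sd^2)|, the other -|N(0, sd^2)| with
                 independent magnitudes; which side is positive is a fair
                 coin per pair.
    mutualistic  both +|N(0, sd^2)|, independent.
    competitive  both -|N(0, sd^2)|, independent.
    mixed        the type itself is drawn uniformly per pair from the four
                 above, then strengths are sampled accordingly.
    """
    if sd <= 0:
        raise ValueError(f"strength sd must be positive, got {sd}")
    rng = as_generator(seed)
    if interaction_type == "random":
        return rng.normal(0.0, sd, n), rng.normal(0.0, sd, n)
    if interaction_type == "mutualistic":
        return np.abs(rng.normal(0.0, sd, n)), np.abs(rng.normal(0.0, sd, n))
    if interaction_type == "competitive":
        return -np.abs(rng.normal(0.0, sd, n)), -np.abs(rng.normal(0.0, sd, n))
    if interaction_type == "exploitative":
        a = np.abs(rng.normal(0.0, sd, n))
        b = np.abs(rng.normal(0.0, sd, n))
        coin = rng.random(n) < 0.5
        return np.where(coin, a, -a), np.where(coin, -b, b)
    if interaction_type == "mixed":
        kinds = rng.integers(0, 4, n)
        fwd = np.empty(n)
        bwd = np.empty(n)
        for k, name in enumerate(("random", "exploitative", "mutualistic", "competitive")):
            sel = kinds == k
            f, b = sample_pairs(name, sd, int(sel.sum()), rng)
            fwd[sel], bwd[sel] = f, b
        return fwd, bwd
    raise ValueError(f"unknown interaction type {interaction_type!r}")


def sample_pair(interaction_type: str, sd: float, seed=None) -> InteractionPair:
    """Single bivariate strength draw; see :func:`sample_pairs`."""
    fwd, bwd = sample_pairs(interaction_type, sd, 1, seed)
    return InteractionPair(forward=float(fwd[0]), backward=float(bwd[0]))


# ---------------------------------------------------------------------------
# builders


def _check_dims(config: EnsembleConfig, membership: SetMembership):
    if membership.n_species != config.n_species or membership.n_sets != config.n_sets:
        raise ValueError(
            f"membership shape ({membership.n_species}, {membership.n_sets}) inconsistent "
            f"with config (S={config.n_species}, G={config.n_sets})"
        )
    if membership.sets_per_species != config.sets_per_species:
        raise ValueError(
            f"membership K={membership.sets_per_species} inconsistent with "
            f"config K={config.sets_per_species}"
        )


def _place(M, rows, cols, config, rng):
    """Accumulate one bivariate draw per (row, col) pair into M, symmetric slots."""
    fwd, bwd = sample_pairs(config.interaction_type, config.strength_sd, rows.size, rng)
    M[rows, cols] += fwd
    M[cols, rows] += bwd


def _finalize(M, config: EnsembleConfig, role: str, rng) -> CommunityMatrix:
    """Overwrite the diagonal with -d, then apply abundance scaling if configured."""
    np.fill_diagonal(M, -config.self_regulation)
    if config.abundance_dist != "unit":
        ab = sample_abundances(
            config.abundance_dist, M.shape[0], rng, params=config.abundance_params
        )
        M = ab.values[:, None] * M
    return CommunityMatrix(values=M, role=role, config=config)


def build_set_structured(
    config: EnsembleConfig, membership: SetMembership, seed=None
) -> CommunityMatrix:
    """Set-structured community matrix M = sum_g M^g with ER edges per set.

    For every set g and every unordered member pair, an interaction pair is
    placed with probability C, independently across sets — a pair sharing h
    sets interacts Binomial(h, C) times, so the expected interaction count
    per pair is T = C*K^2/G.
    """
    if config.flavor != "er_within_set":
        raise ValueError(f"build_set_structured requires er_within_set flavor, got {config.flavor!r}")
    _check_dims(config, membership)
    rng = as_generator(seed)
    S = config.n_species
    M = np.zeros((S, S))
    children = rng.spawn(membership.n_sets)
    for g, child in enumerate(children):
        members = membership.members_of(g)
        m = members.size
        if m < 2:
            continue
        iu, ju = _triu_pairs(m)
        mask = child.random(iu.size) < config.connectivity
        if not mask.any():
            continue
        _place(M, members[iu[mask]], members[ju[mask]], config, child)
    return _finalize(M, config, "set_structured", rng)


def build_unstructured(config: EnsembleConfig, seed=None) -> CommunityMatrix:
    """Unstructured (set-free) community matrix M-hat: one ER placement at connectivity C."""
    rng = as_generator(seed)
    S = config.n_species
    M = np.zeros((S, S))
    iu, ju = _triu_pairs(S)
    mask = rng.random(iu.size) < config.connectivity
    if mask.any():
        _place(M, iu[mask], ju[mask], config, rng)
    return _finalize(M, config, "unstructured", rng)


def build_heterogeneous_set_structured(
    config: EnsembleConfig, membership: SetMembership, seed=None
) -> CommunityMatrix:
    """Set-structured matrix with a preferential-attachment graph per set at connectivity C."""
    if config.flavor != "scale_free_within_set":
        raise ValueError(
            f"build_heterogeneous_set_structured requires scale_free_within_set flavor, "
            f"got {config.flavor!r}"
        )
    _check_dims(config, membership)
    rng = as_generator(seed)
    S = config.n_species
    M = np.zeros((S, S))
    children = rng.spawn(membership.n_sets)
    for g, child in enumerate(children):
        members = membership.members_of(g)
        if members.size < 2:
            logger.info("set %d has %d member(s); skipped", g, members.size)
            continue
        graph = sample_scale_free_edges(
            members, connectivity=config.connectivity, seed=child, set_id=g
        )
        if not graph.edges:
            continue
        edges = np.asarray(sorted(graph.edges))
        _place(M, edges[:, 0], edges[:, 1], config, child)
    return _finalize(M, config, "set_structured", rng)


def build_heterogeneous_unstructured(config: EnsembleConfig, seed=None) -> CommunityMatrix:
    """Unstructured matrix whose edges come from one global preferential-attachment graph."""
    rng = as_generator(seed)
    S = config.n_species
    M = np.zeros((S, S))
    graph = sample_scale_free_edges(
        range(S), connectivity=config.connectivity, seed=rng, set_id=0
    )
    if graph.edges:
        edges = np.asarray(sorted(graph.edges))
        _place(M, edges[:, 0], edges[:, 1], config, rng)
    return _finalize(M, config, "unstructured", rng)


def build_local_symmetric(
    config: EnsembleConfig, membership: SetMembership, seed=None
):
    """Paired matrices where each set's graph and the unstructured graph share average degree k.

    Every set carries a preferential-attachment graph of average degree k,
    so a species in K sets accrues about K*k neighbours and the overall
    average degree of the set-structured system exceeds k — its complexity
    is higher than the matched unstructured system, which gets a single
    preferential-attachment graph at average degree k.

    Returns
    -------
    (CommunityMatrix, CommunityMatrix)
        The set-structured and the matched unstructured matrix.
    """
    if config.flavor != "local_symmetric":
        raise ValueError(
            f"build_local_symmetric requires local_symmetric flavor, got {config.flavor!r}"
        )
    _check_dims(config, membership)
    k = config.average_degree
    expected_size = config.n_species * config.sets_per_species / config.n_sets
    if k >= expected_size:
        raise ValueError(
            f"average degree k={k} must be below the expected set size "
            f"S*K/G={expected_size:g}"
        )
    rng = as_generator(seed)
    S = config.n_species
    M = np.zeros((S, S))
    children = rng.spawn(membership.n_sets)
    for g, child in enumerate(children):
        members = membership.members_of(g)
        if members.size < 2:
            logger.info("set %d has %d member(s); skipped", g, members.size)
            continue
        # small sets cannot reach k; the attachment count is clamped to m-1
        target = min(k, members.size - 1)
        graph = sample_scale_free_edges(
            members, average_degree=target, seed=child, set_id=g
        )
        if not graph.edges:
            continue
        edges = np.asarray(sorted(graph.edges))
        _place(M, edges[:, 0], edges[:, 1], config, child)
    structured = _finalize(M, config, "set_structured", rng)

    Mu = np.zeros((S, S))
    graph = sample_scale_free_edges(range(S), average_degree=k, seed=rng, set_id=0)
    if graph.edges:
        edges = np.asarray(sorted(graph.edges))
        _place(Mu, edges[:, 0], edges[:, 1], config, rng)
    unstructured = _finalize(Mu, config, "unstructured", rng)
    return structured, unstructured


# ---------------------------------------------------------------------------
# equilibrium abundances


def sample_abundances(dist: str, S: int, seed=None, params: tuple = ()) -> AbundanceVector:
    """Sample a strictly positive equilibrium-abundance vector X*.

    ``unit`` gives all ones; ``uniform`` takes (low, high) with low > 0
    (default (0.75, 1.25)); ``lognormal`` takes (mean, sd) of log-abundance
    (default (0, 0.25)); ``halfnormal`` takes a scale (default 1.0).  The
    half-normal is truncated away from zero at 1e-6 to keep the equilibrium
    feasible.
    """
    rng = as_generator(seed)
    if dist == "unit":
        return AbundanceVector(np.ones(S))
    if dist == "uniform":
        low, high = params if params else (0.75, 1.25)
        if low <= 0 or high <= low:
            raise ValueError(f"uniform abundances need 0 < low < high, got ({low}, {high})")
        return AbundanceVector(rng.uniform(low, high, S))
    if dist == "lognormal":
        mean, sd = params if params else (0.0, 0.25)
        if sd <= 0:
            raise ValueError(f"lognormal sd must be positive, got {sd}")
        return AbundanceVector(rng.lognormal(mean, sd, S))
    if dist == "halfnormal":
        (scale,) = params if params else (1.0,)
        if scale <= 0:
            raise ValueError(f"halfnormal scale must be positive, got {scale}")
        vals = np.abs(rng.normal(0.0, scale, S))
        return AbundanceVector(np.maximum(vals, 1e-6))
    raise ValueError(f"unknown abundance distribution {dist!r}")


def apply_abundances(jacobian: CommunityMatrix, abundances: AbundanceVector) -> CommunityMatrix:
    """Row-scale a Jacobian by equilibrium abundances: M = diag(X*) J."""
    J = jacobian.values
    X = abundances.values
    if X.shape[0] != J.shape[0]:
        raise ValueError(
            f"abundance length {X.shape[0]} does not match matrix size {J.shape[0]}"
        )
    return CommunityMatrix(
        values=X[:, None] * J, role=jacobian.role, config=jacobian.config
    )
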