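"""Monte-Carlo experiments: stability sweeps, critical-ratio detection,
perturbation dynamics, and stable-proportion estimation.

The central quantity is DeltaStability = stability(set-structured) -
stability(unstructured) for parameter-matched pairs.  Sweeping the number of
sets G at fixed K traces DeltaStability as a function of the order ratio
K^2/G; the zero crossing of its mean estimates the critical ratio, predicted
to sit at 1 for random, exploitative, and mutualistic interactions and below
1 for competitive ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

from ._rng import as_generator
from .ensemble import (
    AbundanceVector,
    CommunityMatrix,
    EnsembleConfig,
    build_heterogeneous_set_structured,
    build_heterogeneous_unstructured,
    build_local_symmetric,
    build_set_structured,
    build_unstructured,
)
from .stability import leading_real_part
from .structure import sample_membership

logger = logging.getLogger(__name__)

__all__ = [
    "SweepPoint",
    "SweepResult",
    "DynamicsResult",
    "StableProportions",
    "build_pair",
    "delta_stability",
    "sweep_over_G",
    "zero_crossings",
    "find_critical_ratio",
    "simulate_dynamics",
    "proportion_stable",
]


@dataclass(frozen=True)
class SweepPoint:
    """Mean and spread of DeltaStability at one value of G."""

    n_sets: int
    ratio: float  # K^2/G
    mean_delta: float
    sd_delta: float
    n_replicates: int

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("a sweep point needs at least one replicate")
        if self.sd_delta < 0:
            raise ValueError("sd_delta must be nonnegative")


@dataclass(frozen=True)
class SweepResult:
    """Sweep points in ascending ratio order plus the interpolated critical ratio."""

    points: tuple
    critical_ratio: Optional[float] = None

    def __post_init__(self):
        pts = tuple(sorted(self.points, key=lambda p: p.ratio))
        object.__setattr__(self, "points", pts)
        if self.critical_ratio is not None and pts:
            lo, hi = pts[0].ratio, pts[-1].ratio
            if not lo <= self.critical_ratio <= hi:
                raise ValueError(
                    f"critical ratio {self.critical_ratio} outside swept range [{lo}, {hi}]"
                )

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points])

    @property
    def mean_deltas(self) -> np.ndarray:
        return np.array([p.mean_delta for p in self.points])


def build_pair(config: EnsembleConfig, seed=None, common_random_numbers: bool = False):
    """Build one parameter-matched (set-structured, unstructured) matrix pair.

    The pair shares all scalar parameters (S, C, sigma, d, interaction type)
    but draws interactions independently; with ``common_random_numbers`` the
    two builders consume identically seeded streams, reducing the variance
    of the stability difference.
    """
    rng = as_generator(seed)
    s_membership, s_struct, s_unstruct = rng.integers(2**31, size=3)
    if common_random_numbers:
        s_unstruct = s_struct
    membership = sample_membership(
        config.n_species, config.n_sets, config.sets_per_species, int(s_membership)
    )
    if config.flavor == "er_within_set":
        ms = build_set_structured(config, membership, int(s_struct))
        mu = build_unstructured(config, int(s_unstruct))
    elif config.flavor == "scale_free_within_set":
        ms = build_heterogeneous_set_structured(config, membership, int(s_struct))
        mu = build_heterogeneous_unstructured(config, int(s_unstruct))
    else:  # local_symmetric
        ms, mu = build_local_symmetric(config, membership, int(s_struct))
    return ms, mu


def delta_stability(
    config: EnsembleConfig,
    n_replicates: int,
    seed=None,
    common_random_numbers: bool = False,
) -> SweepPoint:
    """Mean and sd of stability(set-structured) - stability(unstructured) over replicates."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = as_generator(seed)
    deltas = np.empty(n_replicates)
    for r in range(n_replicates):
        ms, mu = build_pair(config, rng, common_random_numbers=common_random_numbers)
        deltas[r] = (
            leading_real_part(mu).leading_real - leading_real_part(ms).leading_real
        )
    return SweepPoint(
        n_sets=config.n_sets,
        ratio=config.order,
        mean_delta=float(deltas.mean()),
        sd_delta=float(deltas.std(ddof=1)) if n_replicates > 1 else 0.0,
        n_replicates=n_replicates,
    )


def sweep_over_G(
    config: EnsembleConfig,
    G_values: Sequence[int],
    n_replicates: int,
    seed=None,
    common_random_numbers: bool = False,
) -> SweepResult:
    """DeltaStability profile over a grid of set counts G (ratio K^2/G descends as G ascends)."""
    G_values = [int(g) for g in G_values]
    K = config.sets_per_species
    for g in G_values:
        if g < K:
            raise ValueError(f"every G must be >= K={K}, got G={g}")
    rng = as_generator(seed)
    points = []
    for g, child in zip(G_values, rng.spawn(len(G_values))):
        pt = delta_stability(
            config.with_sets(g), n_replicates, child,
            common_random_numbers=common_random_numbers,
        )
        logger.info(
            "G=%d ratio=%.4f mean_delta=%.5f sd=%.5f", g, pt.ratio, pt.mean_delta, pt.sd_delta
        )
        points.append(pt)
    result = SweepResult(points=tuple(points))
    if len(points) >= 2:
        crit = find_critical_ratio(result)
    else:
        crit = points[0].ratio if points and points[0].mean_delta == 0 else None
    return SweepResult(points=result.points, critical_ratio=crit)


def zero_crossings(points: Sequence[SweepPoint]) -> list:
    """All linearly interpolated zero crossings of mean_delta vs ratio, ascending."""
    pts = sorted(points, key=lambda p: p.ratio)
    crossings = []
    for a, b in zip(pts[:-1], pts[1:]):
        ya, yb = a.mean_delta, b.mean_delta
        if ya == 0.0:
            crossings.append(a.ratio)
        elif ya * yb < 0:
            crossings.append(a.ratio + (b.ratio - a.ratio) * (-ya) / (yb - ya))
    if pts and pts[-1].mean_delta == 0.0:
        crossings.append(pts[-1].ratio)
    return crossings


def find_critical_ratio(sweep) -> Optional[float]:
    """Zero crossing of mean DeltaStability vs ratio, nearest to 1 when several exist.

    Accepts a :class:`SweepResult` or a sequence of points; returns None when
    mean_delta never changes sign.
    """
    points = sweep.points if isinstance(sweep, SweepResult) else tuple(sweep)
    if len(points) < 2:
        raise ValueError("critical-ratio detection needs at least 2 sweep points")
    crossings = zero_crossings(points)
    if not crossings:
        return None
    if len(crossings) > 1:
        logger.info("multiple zero crossings found: %s", crossings)
    return min(crossings, key=lambda r: abs(r - 1.0))


# ---------------------------------------------------------------------------
# dynamics


@dataclass(frozen=True)
class DynamicsResult:
    """Abundance trajectories X* + x(t) on a fixed time grid."""

    time_grid: np.ndarray
    trajectories: np.ndarray  # (S, len(time_grid))
    converged: bool
    overflowed: bool = False
    initial_state: np.ndarray = None


def simulate_dynamics(
    M,
    abundances: AbundanceVector,
    perturbation_scale: float = 0.1,
    horizon: float = 50.0,
    n_steps: int = 200,
    seed=None,
) -> DynamicsResult:
    """Integrate the linearized dynamics dx/dt = Mx after a random perturbation.

    The initial displacement x(0) has entries uniform in
    [-perturbation_scale*X_i*, +perturbation_scale*X_i*]; the same seed
    therefore produces a bit-identical perturbation across paired systems.
    Propagation uses the matrix exponential on the fixed grid (exact for the
    linear system).  ``converged`` means the final ||x|| fell below 1e-2 of
    the initial one; a non-finite trajectory is truncated at the overflow
    point and flagged, not raised.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    if n_steps < 2:
        raise ValueError(f"need at least 2 time steps, got {n_steps}")
    vals = getattr(M, "values", M)
    vals = np.asarray(vals, dtype=float)
    X = abundances.values
    if X.shape[0] != vals.shape[0]:
        raise ValueError("abundance length does not match matrix size")
    rng = as_generator(seed)
    x0 = rng.uniform(-1.0, 1.0, X.shape[0]) * perturbation_scale * X
    ts = np.linspace(0.0, horizon, n_steps)
    dt = ts[1] - ts[0]
    propagator = expm(vals * dt)
    traj = np.empty((X.shape[0], n_steps))
    traj[:, 0] = X + x0
    x = x0
    overflowed = False
    last = n_steps - 1
    with np.errstate(over="ignore", invalid="ignore"):
        for j in range(1, n_steps):
            x = propagator @ x
            if not np.isfinite(x).all():
                overflowed = True
                last = j - 1
                logger.warning("trajectory overflowed at t=%.3f; truncated", ts[j])
                break
            traj[:, j] = X + x
    if overflowed:
        ts = ts[: last + 1]
        traj = traj[:, : last + 1]
        converged = False
    else:
        with np.errstate(over="ignore"):
            norm0 = np.linalg.norm(x0)
            converged = bool(np.linalg.norm(x) < norm0 * 1e-2) if norm0 > 0 else True
    return DynamicsResult(
        time_grid=ts,
        trajectories=traj,
        converged=converged,
        overflowed=overflowed,
        initial_state=X + x0,
    )


@dataclass(frozen=True)
class StableProportions:
    """Fractions of asymptotically stable draws per system kind."""

    set_structured: float
    unstructured: float
    n_communities: int


def proportion_stable(config: EnsembleConfig, n_communities: int, seed=None) -> StableProportions:
    """Fraction of draws with Re(lambda_1) < 0 for matched structured/unstructured ensembles."""
    if n_communities < 1:
        raise ValueError("need at least one community")
    rng = as_generator(seed)
    stable_s = 0
    stable_u = 0
    for _ in range(n_communities):
        ms, mu = build_pair(config, rng)
        stable_s += leading_real_part(ms).is_stable
        stable_u += leading_real_part(mu).is_stable
    return StableProportions(
        set_structured=stable_s / n_communities,
        unstructured=stable_u / n_communities,
        n_communities=n_communities,
    )
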