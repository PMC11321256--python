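"""Spectral stability and closed-form stability criteria.

A linearized community dx/dt = Mx is asymptotically stable iff the largest
real part among the eigenvalues of M, Re(lambda_1), is negative; the scalar
-Re(lambda_1) is used as the stability score.  Random-matrix theory gives
closed-form criteria of the form  lhs(S, C, H) < d/sigma  per interaction
type, where H = K^2/G is the order of the set structure; the unstructured
criteria are the same formulas with H := 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "StabilityResult",
    "CriterionResult",
    "leading_real_part",
    "F",
    "criterion",
    "expected_interaction_times",
]

# Below this expected interaction count the competitive closed form is an
# extrapolation outside its derivation regime and is flagged, not trusted.
COMPETITIVE_VALIDITY_FLOOR = 0.1


@dataclass(frozen=True)
class StabilityResult:
    """Leading eigenvalue real part and the derived stability score."""

    leading_real: float

    @property
    def stability(self) -> float:
        return -self.leading_real

    @property
    def is_stable(self) -> bool:
        return self.leading_real < 0


def leading_real_part(M) -> StabilityResult:
    """Largest real part of the full nonsymmetric spectrum of M.

    Accepts a :class:`~setstab.ensemble.CommunityMatrix` or a square array.
    No symmetrization is applied; ties at exactly zero count as unstable.
    """
    vals = getattr(M, "values", M)
    vals = np.asarray(vals, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {vals.shape}")
    if not np.isfinite(vals).all():
        raise ValueError("community matrix contains non-finite entries")
    eig = np.linalg.eigvals(vals)
    return StabilityResult(leading_real=float(eig.real.max()))


def F(x: float, S: int) -> float:
    """Bulk-edge factor of the competitive criterion.

    F(x) = sqrt(S*x*(1 - 2x/pi)) * (1 + 2(1-x)/(pi - 2x)), defined for
    0 <= x < pi/2 (the radical and denominator fail beyond).
    """
    if x < 0:
        raise ValueError(f"F is defined for nonnegative x, got {x}")
    if x >= math.pi / 2:
        raise ValueError(f"F is undefined for x >= pi/2, got x={x}")
    return math.sqrt(S * x * (1 - 2 * x / math.pi)) * (1 + 2 * (1 - x) / (math.pi - 2 * x))


@dataclass(frozen=True)
class CriterionResult:
    """One evaluated stability criterion: predicted stable iff lhs < rhs = d/sigma."""

    lhs: float
    rhs: float
    interaction_type: str
    structured: bool
    warning: Optional[str] = None

    @property
    def predicted_stable(self) -> bool:
        return self.lhs < self.rhs


def criterion(
    interaction_type: str,
    S: int,
    C: float,
    H: float,
    d: float,
    sd: float,
    structured: bool = True,
) -> CriterionResult:
    """Evaluate the closed-form stability criterion for one interaction type.

    The structured criteria depend on the order H = K^2/G only through the
    product C*H; the unstructured column is the same formula with H := 1,
    so both reduce to each other at H = 1.

    lhs per type (structured column):
        random        sqrt(S*C*H)
        mutualistic   (S-1)*C*H*sqrt(2/pi)
        exploitative  sqrt(S*C*H)*(1 - 2/pi)
        competitive   F(C*H) + C*H*sqrt(2/pi)
    """
    if sd <= 0 or d <= 0:
        raise ValueError("d and sigma must be positive")
    if not 0 <= C <= 1:
        raise ValueError(f"connectivity must lie in [0, 1], got C={C}")
    if H < 0:
        raise ValueError(f"order H must be nonnegative, got {H}")
    h_eff = H if structured else 1.0
    t = C * h_eff  # expected interaction count per pair
    rhs = d / sd
    warning = None
    if interaction_type == "random":
        lhs = math.sqrt(S * t)
    elif interaction_type == "mutualistic":
        lhs = (S - 1) * t * math.sqrt(2 / math.pi)
    elif interaction_type == "exploitative":
        lhs = math.sqrt(S * t) * (1 - 2 / math.pi)
    elif interaction_type == "competitive":
        lhs = F(t, S) + t * math.sqrt(2 / math.pi)
        if t < COMPETITIVE_VALIDITY_FLOOR:
            warning = (
                f"competitive criterion is an approximation that degrades for "
                f"C*H << 1 (here C*H={t:g})"
            )
    else:
        raise ValueError(f"no closed-form criterion for interaction type {interaction_type!r}")
    return CriterionResult(
        lhs=lhs, rhs=rhs, interaction_type=interaction_type,
        structured=structured, warning=warning,
    )


def expected_interaction_times(C: float, K: int, G: int) -> float:
    """Expected number of interaction events between two species: T = C*K^2/G."""
    if not 0 <= C <= 1:
        raise ValueError(f"connectivity must lie in [0, 1], got C={C}")
    if not 1 <= K <= G:
        raise ValueError(f"need 1 <= K <= G, got K={K}, G={G}")
    return C * K**2 / G
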