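"""Log-scale relative effects (log OR, log RR, log HR) from arm-level summaries.

All estimates are returned as :class:`EffectEstimate`, a log-scale point value
with a variance and a ``derivation`` tag recording how it was obtained.  Binary
endpoints use the standard 2x2 formulas with an optional continuity correction;
hazard ratios not reported directly can be reconstructed from a two-sided
log-rank p-value and the total event count (the Tierney approach) or
back-calculated from a reported confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError

__all__ = [
    "EffectEstimate",
    "logor_from_counts",
    "logrr_from_counts",
    "loghr_from_logrank",
    "loghr_from_ci",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A relative treatment effect on the log scale.

    Attributes
    ----------
    measure:
        One of ``"logHR"``, ``"logOR"``, ``"logRR"``.
    value:
        Log-scale point estimate (e.g. ln of the hazard ratio).
    variance:
        Sampling variance of ``value``; strictly positive.
    derivation:
        Provenance tag: ``reported``, ``counts``, ``logrank_p`` or
        ``ci_backcalc``.
    """

    measure: str
    value: float
    variance: float
    derivation: str = "reported"

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValidationError(f"variance must be positive, got {self.variance}")
        if not math.isfinite(self.value):
            raise ValidationError("effect value must be finite")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def _validated_cells(e1: float, n1: float, e0: float, n0: float, cc: float):
    for e, n in ((e1, n1), (e0, n0)):
        if n < 1:
            raise ValidationError(f"arm total must be >= 1, got {n}")
        if not 0 <= e <= n:
            raise ValidationError(f"events must lie in [0, n], got e={e}, n={n}")
    if (e1 == n1 and e0 == n0) or (e1 == 0 and e0 == 0):
        raise ValidationError(
            "degenerate 2x2 table: both arms all-events or both all-zero"
        )
    a, b = e1, n1 - e1  # events / non-events, arm 1
    c, d = e0, n0 - e0
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + cc for x in (a, b, c, d))
    if min(a, b, c, d) == 0:
        raise ValidationError("degenerate 2x2 table even after continuity correction")
    return a, b, c, d


def logor_from_counts(
    e1: int, n1: int, e0: int, n0: int, cc: float = 0.5
) -> EffectEstimate:
    """Log odds ratio of arm 1 versus arm 0 from event counts.

    When any cell of the 2x2 table is zero, the continuity constant ``cc``
    is added to all four cells before applying the formula.
    """
    a, b, c, d = _validated_cells(e1, n1, e0, n0, cc)
    value = math.log((a * d) / (c * b))
    variance = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectEstimate("logOR", value, variance, "counts")


def logrr_from_counts(
    e1: int, n1: int, e0: int, n0: int, cc: float = 0.5
) -> EffectEstimate:
    """Log risk ratio of arm 1 versus arm 0 from event counts."""
    a, b, c, d = _validated_cells(e1, n1, e0, n0, cc)
    m1, m0 = a + b, c + d
    value = math.log((a / m1) / (c / m0))
    variance = 1 / a - 1 / m1 + 1 / c - 1 / m0
    if variance <= 0:  # both arms all-events after correction
        raise ValidationError("risk-ratio variance is not positive")
    return EffectEstimate("logRR", value, variance, "counts")


def loghr_from_logrank(
    p_two_sided: float,
    total_events: int,
    alloc_ratio: float = 1.0,
    direction: int = 1,
) -> EffectEstimate:
    """Reconstruct a log hazard ratio from a log-rank p-value.

    Uses the approximation ``V = events * R / (1 + R)^2`` for the variance of
    the log-rank ``O - E`` statistic under allocation ratio ``R``; the signed
    ``O - E`` is recovered from the two-sided p-value, and
    ``logHR = (O - E) / V`` with variance ``1 / V``.  The p-value carries no
    sign, so ``direction`` (+1 or -1) must state which arm is favoured.
    """
    if not 0 < p_two_sided < 1:
        raise ValidationError("p-value must lie strictly in (0, 1)")
    if total_events < 1:
        raise ValidationError("total_events must be >= 1")
    if alloc_ratio <= 0:
        raise ValidationError("allocation ratio must be positive")
    if direction not in (-1, 1):
        raise ValidationError("direction must be +1 or -1")
    R = alloc_ratio
    V = total_events * R / (1 + R) ** 2
    z = stats.norm.isf(p_two_sided / 2.0)
    o_minus_e = direction * z * math.sqrt(V)
    return EffectEstimate("logHR", o_minus_e / V, 1.0 / V, "logrank_p")


def loghr_from_ci(
    hr: float, lo: float, hi: float, level: float = 0.95
) -> EffectEstimate:
    """Log hazard ratio and variance back-calculated from a reported CI."""
    if not (0 < lo <= hr <= hi):
        raise ValidationError("require 0 < lo <= hr <= hi")
    if not 0 < level < 1:
        raise ValidationError("coverage level must lie in (0, 1)")
    if lo == hi:
        raise ValidationError("degenerate interval gives zero variance")
    z = stats.norm.isf((1 - level) / 2.0)
    se = (math.log(hi) - math.log(lo)) / (2 * z)
    return EffectEstimate("logHR", math.log(hr), se * se, "ci_backcalc")
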