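"""Direct-versus-indirect agreement around closed loops of the network.

For each triangle A-B-C with direct pairwise estimates d_AB, d_AC, d_BC the
inconsistency factor ("ratio of odds ratios" on the log scale) is

    RoR = | d_AB - (d_AC - d_BC) |,   SE = sqrt(v_AB + v_AC + v_BC),

with a normal-approximation z statistic and 95% CI (truncated at zero on the
absolute-value scale).  Loop-level heterogeneity tau^2 is estimated by
restricted maximum likelihood on the loop's pairwise estimates under a
common-tau^2 assumption and plugged into the inverse-variance weights of the
direct estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .effect_measures import EffectEstimate
from .errors import ValidationError
from .nma_model import pairwise_estimate
from .trial_data import TreatmentNetwork, TrialRecord, enumerate_triangles

__all__ = [
    "LoopAssessment",
    "direct_estimate",
    "loop_inconsistency",
    "reml_tau2",
    "loop_reml_tau2",
    "network_inconsistency_report",
]

logger = logging.getLogger(__name__)


@dataclass
class LoopAssessment:
    loop: tuple[str, str, str]
    ror: float
    se: float
    z: float
    ci95: tuple[float, float]
    tau2_loop: float


def direct_estimate(
    estimates: list[EffectEstimate], tau2: float = 0.0
) -> EffectEstimate:
    """Inverse-variance pooled direct estimate with weights 1/(v_i + tau2)."""
    if not estimates:
        raise ValidationError("no estimates to pool")
    w = np.array([1.0 / (e.variance + tau2) for e in estimates])
    y = np.array([e.value for e in estimates])
    return EffectEstimate(
        estimates[0].measure, float(np.sum(w * y) / np.sum(w)), float(1.0 / np.sum(w)),
        "counts" if all(e.derivation == "counts" for e in estimates) else "reported",
    )


def loop_inconsistency(
    ab: EffectEstimate, ac: EffectEstimate, bc: EffectEstimate,
    tau2_loop: float = 0.0,
    loop: tuple[str, str, str] = ("A", "B", "C"),
) -> LoopAssessment:
    """Bucher-style inconsistency of one triangular loop.

    ``ab``, ``ac``, ``bc`` are the direct estimates of A vs B, A vs C and
    B vs C on a common log-scale measure; the indirect A-vs-B estimate is
    ``ac - bc`` by consistency.
    """
    if not (ab.measure == ac.measure == bc.measure):
        raise ValidationError("loop estimates must share one measure")
    diff = ab.value - (ac.value - bc.value)
    se = math.sqrt(ab.variance + ac.variance + bc.variance)
    ror = abs(diff)
    z = ror / se
    half = 1.959963984540054 * se
    ci = (max(0.0, ror - half), ror + half)
    return LoopAssessment(loop, ror, se, z, ci, tau2_loop)


def _restricted_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


def reml_tau2(effects: list[EffectEstimate], tau2_max: float = 10.0) -> float:
    """Between-study variance by restricted maximum likelihood.

    Maximizes the restricted log-likelihood of the one-mean random-effects
    model by bounded one-dimensional optimization on [0, tau2_max].
    """
    if len(effects) < 2:
        raise ValidationError("REML needs at least 2 estimates")
    y = np.array([e.value for e in effects])
    v = np.array([e.variance for e in effects])
    res = optimize.minimize_scalar(
        _restricted_nll, bounds=(0.0, tau2_max), args=(y, v), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    # the bounded optimizer never lands exactly on 0; snap when the boundary
    # is at least as good
    if _restricted_nll(0.0, y, v) <= res.fun:
        tau2 = 0.0
    return tau2


def _grouped_restricted_nll(
    tau2: float, groups: list[tuple[np.ndarray, np.ndarray]]
) -> float:
    """Restricted NLL with a separate mean per comparison, common tau2."""
    total = 0.0
    for y, v in groups:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        total += 0.5 * (
            np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )
    return total


def loop_reml_tau2(
    edge_estimates: dict[tuple[str, str], list[EffectEstimate]],
    tau2_max: float = 10.0,
) -> float:
    """Common-tau2 REML across the loop's comparisons (one mean per edge)."""
    groups = [
        (np.array([e.value for e in ests]), np.array([e.variance for e in ests]))
        for ests in edge_estimates.values()
    ]
    if sum(len(y) for y, _ in groups) <= len(groups):
        return 0.0  # no within-comparison replication to estimate tau2 from
    res = optimize.minimize_scalar(
        _grouped_restricted_nll, bounds=(0.0, tau2_max), args=(groups,),
        method="bounded", options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    if _grouped_restricted_nll(0.0, groups) <= res.fun:
        tau2 = 0.0
    return tau2


def network_inconsistency_report(
    network: TreatmentNetwork,
    trials: list[TrialRecord],
    endpoint: str,
) -> list[LoopAssessment]:
    """One loop assessment per evaluable triangle of the network.

    A triangle is evaluable when all three edges have at least one trial
    providing direct evidence for the endpoint; others are skipped with a
    logged reason.  Loop heterogeneity is REML-estimated on the union of the
    loop's per-trial estimates (when >= 2) and plugged into the pooling
    weights.
    """
    assessments = []
    for tri in enumerate_triangles(network):
        a, b, c = tri
        edge_estimates: dict[tuple[str, str], list[EffectEstimate]] = {}
        ok = True
        for pair in ((a, b), (a, c), (b, c)):
            ests = []
            for t in trials:
                if pair[0] in t.treatments and pair[1] in t.treatments:
                    try:
                        ests.append(pairwise_estimate(t, pair[0], pair[1], endpoint))
                    except ValidationError as exc:
                        logger.warning(
                            "loop %s: trial %s unusable for %s: %s",
                            tri, t.study_id, endpoint, exc,
                        )
            if not ests:
                logger.warning(
                    "skipping loop %s: no direct evidence on edge %s", tri, pair
                )
                ok = False
                break
            edge_estimates[pair] = ests
        if not ok:
            continue
        tau2 = loop_reml_tau2(edge_estimates)
        ab = direct_estimate(edge_estimates[(a, b)], tau2)
        ac = direct_estimate(edge_estimates[(a, c)], tau2)
        bc = direct_estimate(edge_estimates[(b, c)], tau2)
        assessments.append(loop_inconsistency(ab, ac, bc, tau2, tri))
    return assessments
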