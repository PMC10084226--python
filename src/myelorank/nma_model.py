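"""Contrast-based Bayesian random-effects network meta-analysis.

The model is the standard consistency (Lu-Ades) formulation.  For trial *i*
with baseline arm :math:`b_i` and :math:`m_i` non-baseline arms, the observed
log-scale contrasts :math:`y_i` are

.. math::

    y_i \\sim N(\\delta_i, S_i), \\qquad
    \\delta_i \\sim N(X_i d, \\Sigma_\\tau),

where :math:`S_i` is the within-trial covariance (off-diagonals carry the
shared baseline-arm variance in multi-arm trials), :math:`d` are the basic
parameters (log relative effects versus the reference treatment, with
:math:`d_{ref} = 0`), and :math:`\\Sigma_\\tau` has diagonal :math:`\\tau^2`
and off-diagonal :math:`\\tau^2/2` — the exchangeable random-effects
structure that keeps every pairwise contrast's heterogeneity variance equal
to :math:`\\tau^2`.  Consistency (:math:`d_{bk} = d_{ref,k} - d_{ref,b}`) is
built into the design matrices.

Priors are vague by default: :math:`d_k \\sim N(0, 10^2)` on the log scale
and :math:`\\tau \\sim U(0, 5)`.  Sampling is Metropolis-within-Gibbs:
conjugate normal updates for :math:`d` and :math:`\\delta`, and a shrinkage
slice update for :math:`\\tau` on its bounded support.  Convergence is
monitored with split-\\ :math:`\\hat R` on the retained draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effect_measures import (
    EffectEstimate,
    loghr_from_ci,
    loghr_from_logrank,
    logor_from_counts,
    logrr_from_counts,
)
from .errors import ValidationError
from .trial_data import TrialRecord

__all__ = [
    "ContrastData",
    "NMAConfig",
    "PosteriorSamples",
    "ENDPOINT_MEASURES",
    "to_contrasts",
    "pairwise_estimate",
    "fit_nma",
    "relative_effects",
]

logger = logging.getLogger(__name__)

#: Effect measure per endpoint: survival endpoints are synthesized on the
#: log hazard-ratio scale, response endpoints as log odds ratios, and the
#: grade 3-4 adverse-event endpoint as a log risk ratio.
ENDPOINT_MEASURES = {
    "PFS": "logHR",
    "OS": "logHR",
    "ORR": "logOR",
    "CR": "logOR",
    "safety": "logRR",
}


@dataclass
class ContrastData:
    """Observed contrasts of one trial: baseline arm, y vector, covariance."""

    study_id: str
    baseline: str
    treatments: tuple[str, ...]  # non-baseline arms, trial order
    y: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        m = len(self.treatments)
        if self.y.shape != (m,) or self.S.shape != (m, m):
            raise ValidationError("contrast dimensions do not match arm count")
        if not np.allclose(self.S, self.S.T):
            raise ValidationError("within-trial covariance must be symmetric")
        if np.linalg.eigvalsh(self.S).min() <= 0:
            raise ValidationError(
                f"within-trial covariance for {self.study_id} is not "
                "positive-definite"
            )


@dataclass
class NMAConfig:
    """Sampler configuration.

    ``iterations`` is the per-chain draw count including warm-up
    (``burn_in`` draws are discarded).  ``prior_d_sd`` is the SD of the
    normal prior on each basic parameter; ``prior_tau_upper`` the upper
    bound of the uniform prior on the heterogeneity SD.
    """

    iterations: int = 30_000
    burn_in: int = 10_000
    chains: int = 4
    seed: int = 0
    prior_d_sd: float = 10.0
    prior_tau_upper: float = 5.0

    def __post_init__(self) -> None:
        if not self.burn_in < self.iterations:
            raise ValidationError("burn_in must be smaller than iterations")
        if self.chains < 2:
            raise ValidationError("at least 2 chains are required")
        if self.prior_d_sd <= 0 or self.prior_tau_upper <= 0:
            raise ValidationError("prior scales must be positive")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws of the basic parameters d and heterogeneity tau."""

    endpoint: str
    reference: str
    treatments: tuple[str, ...]  # all treatments, reference included
    draws: np.ndarray  # (chains, kept, K-1 + 1); last column = tau
    param_names: tuple[str, ...]
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def tau_draws(self) -> np.ndarray:
        return self.draws[:, :, -1].reshape(-1)

    def d_full_draws(self) -> np.ndarray:
        """Draws of d for every treatment (reference column fixed at 0).

        Returns an array of shape (total draws, #treatments), columns in
        ``self.treatments`` order.
        """
        flat = self.draws[:, :, :-1].reshape(-1, len(self.treatments) - 1)
        full = np.zeros((flat.shape[0], len(self.treatments)))
        j = 0
        for k, t in enumerate(self.treatments):
            if t == self.reference:
                continue
            full[:, k] = flat[:, j]
            j += 1
        return full

    def to_frame(self) -> pd.DataFrame:
        """All retained draws as one column per parameter."""
        return pd.DataFrame(
            self.draws.reshape(-1, self.draws.shape[-1]), columns=self.param_names
        )


def _survival_effect(summary, measure: str) -> EffectEstimate:
    if summary.stat_type == "loghr_se":
        return EffectEstimate(measure, summary.value1, summary.value2**2, "reported")
    if summary.stat_type == "pvalue_events":
        p = abs(summary.value1)
        direction = -1 if summary.value1 < 0 else 1
        return loghr_from_logrank(p, int(round(summary.value2)), 1.0, direction)
    if summary.stat_type == "hr_ci":
        lo, hi = summary.value1, summary.value2
        return loghr_from_ci(math.sqrt(lo * hi), lo, hi)
    raise ValidationError(
        f"stat_type {summary.stat_type!r} is not a survival summary"
    )


def pairwise_estimate(
    trial: TrialRecord, t1: str, t2: str, endpoint: str
) -> EffectEstimate:
    """Within-trial relative effect of ``t1`` versus ``t2`` for one endpoint.

    For count endpoints the 2x2 formula is applied directly; for survival
    endpoints the arms' log-HRs versus the trial baseline are differenced
    (variances added; the shared-baseline covariance is not removable from
    summary data and is conservatively ignored).
    """
    measure = ENDPOINT_MEASURES[endpoint]
    arms = {a.treatment: a for a in trial.arms}
    if t1 not in arms or t2 not in arms:
        raise ValidationError(f"trial {trial.study_id} lacks {t1} or {t2}")
    s1 = arms[t1].endpoint_summaries.get(endpoint)
    s2 = arms[t2].endpoint_summaries.get(endpoint)
    if measure in ("logOR", "logRR"):
        if s1 is None or s2 is None or "events_total" not in (
            s1.stat_type,
            s2.stat_type,
        ):
            raise ValidationError(
                f"trial {trial.study_id} lacks count data for {endpoint}"
            )
        fn = logor_from_counts if measure == "logOR" else logrr_from_counts
        return fn(
            int(s1.value1), int(s1.value2), int(s2.value1), int(s2.value2)
        )
    baseline = trial.arms[0].treatment
    if t2 == baseline and s1 is not None:
        return _survival_effect(s1, measure)
    if t1 == baseline and s2 is not None:
        e = _survival_effect(s2, measure)
        return EffectEstimate(measure, -e.value, e.variance, e.derivation)
    if s1 is None or s2 is None:
        raise ValidationError(
            f"trial {trial.study_id} lacks survival data for {t1} vs {t2}"
        )
    e1, e2 = _survival_effect(s1, measure), _survival_effect(s2, measure)
    return EffectEstimate(
        measure, e1.value - e2.value, e1.variance + e2.variance, "reported"
    )


def to_contrasts(
    trials: list[TrialRecord],
    endpoint: str,
    baseline_var_share: float = 0.0,
) -> list[ContrastData]:
    """Build per-trial contrast vectors and covariances for one endpoint.

    The first listed arm is the baseline.  For count endpoints the
    off-diagonal covariance of a multi-arm trial is the baseline arm's
    variance contribution (``1/e_b + 1/(n_b - e_b)`` for odds ratios,
    ``1/e_b - 1/n_b`` for risk ratios).  For survival endpoints reported as
    HRs the baseline share is not recoverable from summaries;
    ``baseline_var_share`` (default 0) is used instead.

    Trials with no usable summary for the endpoint are dropped with a
    logged warning.
    """
    if endpoint not in ENDPOINT_MEASURES:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    measure = ENDPOINT_MEASURES[endpoint]
    out: list[ContrastData] = []
    for trial in trials:
        base = trial.arms[0]
        others = trial.arms[1:]
        try:
            y = []
            var = []
            if measure in ("logOR", "logRR"):
                cells = []
                for arm in trial.arms:
                    s = arm.endpoint_summaries.get(endpoint)
                    if s is None or s.stat_type != "events_total":
                        raise ValidationError("missing counts")
                    cells.append((s.value1, s.value2))
                # trial-wide continuity correction keeps the shared baseline
                # term consistent across contrasts (covariance stays PD)
                if any(e == 0 or e == n for e, n in cells):
                    cells = [(e + 0.5, n + 1.0) for e, n in cells]
                eb, nb = cells[0]
                if measure == "logOR":
                    share = 1.0 / eb + 1.0 / (nb - eb)
                else:
                    share = 1.0 / eb - 1.0 / nb
                fn = logor_from_counts if measure == "logOR" else logrr_from_counts
                for ek, nk in cells[1:]:
                    est = fn(ek, nk, eb, nb)
                    y.append(est.value)
                    var.append(est.variance)
            else:
                share = baseline_var_share
                for arm in others:
                    s = arm.endpoint_summaries.get(endpoint)
                    if s is None:
                        raise ValidationError("missing survival summary")
                    est = _survival_effect(s, measure)
                    y.append(est.value)
                    var.append(est.variance)
        except ValidationError as exc:
            logger.warning(
                "dropping trial %s for endpoint %s: %s", trial.study_id, endpoint, exc
            )
            continue
        m = len(y)
        S = np.full((m, m), share, dtype=float)
        np.fill_diagonal(S, var)
        out.append(
            ContrastData(
                trial.study_id,
                base.treatment,
                tuple(a.treatment for a in others),
                np.array(y),
                S,
            )
        )
    return out


def _slice_sample_tau(logf, tau0: float, upper: float, rng) -> float:
    """One shrinkage slice-sampling update of tau on (0, upper)."""
    log_y = logf(tau0) + math.log(rng.uniform())
    lo, hi = 1e-12, upper
    for _ in range(100):
        prop = rng.uniform(lo, hi)
        if logf(prop) >= log_y:
            return prop
        if prop < tau0:
            lo = prop
        else:
            hi = prop
    return tau0


def fit_nma(
    data: list[ContrastData],
    config: NMAConfig | None = None,
    reference: str | None = None,
    endpoint: str = "",
) -> PosteriorSamples:
    """Fit the random-effects consistency model by MCMC.

    Parameters
    ----------
    data:
        Per-trial contrasts (see :func:`to_contrasts`).
    config:
        Sampler settings; defaults to 4 chains of 30,000 iterations with the
        first 10,000 discarded.
    reference:
        Reference treatment for the basic parameters; defaults to ``"MP"``
        when present, otherwise the first treatment in sorted order.

    Raises an error if the evidence network over ``data`` is disconnected
    (naming the components).  A convergence warning (split-R-hat >= 1.05) is
    recorded on the result rather than raised.
    """
    if config is None:
        config = NMAConfig()
    if not data:
        raise ValidationError("no contrast data supplied")

    treatments = sorted({c.baseline for c in data} | {t for c in data for t in c.treatments})
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(treatments)
    for c in data:
        for t in c.treatments:
            g.add_edge(c.baseline, t)
    if not nx.is_connected(g):
        comps = [sorted(cc) for cc in nx.connected_components(g)]
        raise ValidationError(f"evidence network is disconnected: {comps}")

    if reference is None:
        reference = "MP" if "MP" in treatments else treatments[0]
    if reference not in treatments:
        raise ValidationError(f"reference {reference!r} is not in the network")
    free = [t for t in treatments if t != reference]
    idx = {t: j for j, t in enumerate(free)}
    K = len(free)

    # per-trial design matrices; trials are batched by contrast dimension m
    # so the delta updates run through numpy's batched linear algebra
    def design_matrix(c: ContrastData) -> np.ndarray:
        m = len(c.treatments)
        X = np.zeros((m, K))
        for r, t in enumerate(c.treatments):
            if t != reference:
                X[r, idx[t]] = 1.0
        if c.baseline != reference:
            X[:, idx[c.baseline]] -= 1.0
        return X

    total_m = sum(len(c.treatments) for c in data)
    by_m: dict[int, list[ContrastData]] = {}
    for c in data:
        by_m.setdefault(len(c.treatments), []).append(c)

    groups = []  # (m, P, y (n,m), Sinv (n,m,m), X (n,m,K), XtP (n,K,m))
    M = np.zeros((K, K))
    for m, cs in sorted(by_m.items()):
        P = np.eye(m) - np.ones((m, m)) / (m + 1)  # ((I+J)/2)^{-1} / 2
        y = np.stack([c.y for c in cs])
        Sinv = np.stack([np.linalg.inv(c.S) for c in cs])
        X = np.stack([design_matrix(c) for c in cs])
        XtP = 2.0 * np.einsum("nmk,ml->nkl", X, P)  # (n, K, m)
        M += np.einsum("nkm,nml->kl", XtP, X)
        groups.append((m, P, y, Sinv, X, XtP))

    kept = config.iterations - config.burn_in
    n_param = K + 1
    all_draws = np.empty((config.chains, kept, n_param))
    prior_prec = 1.0 / config.prior_d_sd**2
    upper = config.prior_tau_upper
    eyeK = np.eye(K)

    ss = np.random.SeedSequence(config.seed)
    for chain, child in enumerate(ss.spawn(config.chains)):
        rng = np.random.default_rng(child)
        d = rng.normal(0.0, 0.1, K)
        tau = min(0.5, upper / 2.0)
        deltas = [y.copy() for (_, _, y, _, _, _) in groups]
        for it in range(config.iterations):
            tau2 = tau * tau
            # --- delta | y, d, tau (conjugate normal, batched per m) ---
            for gi, (m, P, y, Sinv, X, XtP) in enumerate(groups):
                xd = X @ d
                if m == 1:
                    sinv = Sinv[:, 0, 0]
                    prec = sinv + 1.0 / tau2
                    mean = (sinv * y[:, 0] + xd[:, 0] / tau2) / prec
                    deltas[gi][:, 0] = mean + rng.standard_normal(len(y)) / np.sqrt(prec)
                else:
                    Q = Sinv + (2.0 / tau2) * P
                    rhs = np.einsum("nml,nl->nm", Sinv, y) + (2.0 / tau2) * xd @ P
                    mean = np.linalg.solve(Q, rhs[..., None])[..., 0]
                    L = np.linalg.cholesky(Q)
                    z = rng.standard_normal((len(y), m, 1))
                    deltas[gi] = mean + np.linalg.solve(
                        np.swapaxes(L, 1, 2), z
                    )[..., 0]
            # --- d | delta, tau (conjugate normal) ---
            b = np.zeros(K)
            for (m, P, y, Sinv, X, XtP), delta in zip(groups, deltas):
                b += np.einsum("nkm,nm->k", XtP, delta)
            A = M / tau2 + prior_prec * eyeK
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b / tau2)
            d = mean + np.linalg.solve(L.T, rng.standard_normal(K))
            # --- tau | delta, d (slice on bounded support) ---
            Qres = 0.0
            for (m, P, y, Sinv, X, XtP), delta in zip(groups, deltas):
                r = delta - X @ d
                Qres += 2.0 * float(np.einsum("nm,ml,nl->", r, P, r))
            Qres = max(Qres, 1e-300)

            def logf(t: float, _q=Qres) -> float:
                return -total_m * math.log(t) - 0.5 * _q / (t * t)

            tau = _slice_sample_tau(logf, tau, upper, rng)
            if it >= config.burn_in:
                all_draws[chain, it - config.burn_in, :K] = d
                all_draws[chain, it - config.burn_in, K] = tau

    param_names = tuple(f"d[{t}]" for t in free) + ("tau",)
    rhat = _split_rhat(all_draws, param_names)
    converged = all(v < 1.05 for v in rhat.values() if np.isfinite(v))
    if not converged:
        logger.warning(
            "split-R-hat >= 1.05 for %s",
            [k for k, v in rhat.items() if not v < 1.05],
        )
    return PosteriorSamples(
        endpoint=endpoint,
        reference=reference,
        treatments=tuple(treatments),
        draws=all_draws,
        param_names=param_names,
        rhat=rhat,
        converged=converged,
    )


def _split_rhat(draws: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    """Split-R-hat per parameter (each chain halved, rank-free version)."""
    chains, kept, _ = draws.shape
    half = kept // 2
    out = {}
    for j, n in enumerate(names):
        x = draws[:, : 2 * half, j].reshape(2 * chains, half)
        mch = x.mean(axis=1)
        b = half * mch.var(ddof=1)
        w = x.var(axis=1, ddof=1).mean()
        if w <= 0:
            out[n] = 1.0 if b <= 0 else math.inf
            continue
        var_hat = (half - 1) / half * w + b / half
        out[n] = float(math.sqrt(var_hat / w))
    return out


def relative_effects(
    samples: PosteriorSamples, reference: str | None = None
) -> pd.DataFrame:
    """Relative effects of every treatment versus ``reference``.

    Differences of basic parameters are formed per draw and exponentiated,
    so re-referencing is exact; the table reports the posterior median and
    the 2.5/97.5 percentile credible interval on the ratio scale.
    """
    if reference is None:
        reference = samples.reference
    if reference not in samples.treatments:
        raise ValidationError(f"unknown reference {reference!r}")
    full = samples.d_full_draws()
    ref_col = samples.treatments.index(reference)
    diff = full - full[:, [ref_col]]
    ratio = np.exp(diff)
    point = np.median(ratio, axis=0)
    lo, hi = np.percentile(ratio, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "treatment": samples.treatments,
            "reference": reference,
            "point": point,
            "lower": lo,
            "upper": hi,
        }
    )
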