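"""Synthetic trial networks with known truth, plus the published-table fixture.

Two generators live here:

* :func:`simulate_trialset` draws multi-arm randomized trials from a
  consistency model with between-trial heterogeneity (SD ``tau``), the
  half-correlation structure between contrasts sharing a baseline arm, and
  endpoint-specific observation noise (binomial counts for response/safety
  endpoints, normal log-HR noise with variance ``4 / events`` for survival
  endpoints — the equal-allocation log-rank approximation).
* :func:`simulate_profiled_network` builds a :class:`SimulationTruth` whose
  treatments fall into planted groups with correlated endpoint-effect
  vectors, for end-to-end recovery testing of the SUCRA-profile clustering.

:func:`table1_fixture` reconstructs the structure of the 27 published
first-line trials (study ids, years, arm labels, per-trial enrolment and the
most frequent grade 3-4 adverse event).  The table prints no per-arm sizes
and no effect estimates, so arm sizes are split equally (remainder to the
first arm) and endpoint summaries are filled synthetically from a seeded,
plausible truth — the fixture is structurally faithful and numerically
synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .trial_data import ArmRecord, EndpointSummary, TrialRecord

__all__ = [
    "SimulationTruth",
    "TrialDesign",
    "simulate_trialset",
    "simulate_profiled_network",
    "table1_fixture",
    "TABLE1_STRUCTURE",
]

#: (study_id, year, arm labels as printed, total enrolment, most frequent
#: grade 3-4 adverse event) for the 27 published trials.
TABLE1_STRUCTURE: tuple[tuple[str, int, str, int, str], ...] = (
    ("Facon/IFM 99-06", 2007, "MPT/MP", 321, "Neutropenia"),
    ("Palumbo (2008)", 2008, "MPTT/MP", 331, "Cytopenia"),
    ("Hulin/IFM 01/01", 2009, "MPT/MP", 229, "Neutropenias"),
    ("Waage", 2009, "MPTT/MP", 357, "Neutropenia"),
    ("Ludwig", 2009, "TD/MP", 288, "Infections/Leukopenia"),
    ("Beksac", 2010, "MPTT/MP", 115, "Cytopenia"),
    ("Wijermans/Hovon49", 2010, "MPTT/MP", 344, "Infections"),
    ("Mateos/Vista", 2010, "VMP/MP", 682, "Neutropenia"),
    ("Palumbo (2010)", 2010, "VMPT/VMP", 511, "Neutropenia"),
    ("Morgan/MRC myeloma IX", 2011, "CTD/MP", 849, "Cytopenia/Infections"),
    ("Sacchi", 2011, "MPT/MP", 118, "Neutropenia"),
    ("Palumbo/MM-015", 2012, "MPRR/MPR/MP", 459, "Neutropenia"),
    ("San Miguel", 2013, "VMPS/VMP", 106, "Neutropenia"),
    ("Mateos/GEM2005", 2014, "VMP/VTP", 260, "Neutropenia"),
    ("Hungria", 2015, "MPTT/TD/CTD", 82, "Neutropenia/Neuropathy"),
    ("Keith Stewart/E1A06", 2015, "MPRR/MPTT", 298, "Neutropenia"),
    ("Niesvizky/UPFRONT", 2015, "VD/VTD/VMP", 502, "Neuropathy"),
    ("Magarotto", 2016, "MPR/CPR/RD9", 662, "Neutropenia"),
    ("Zweegman", 2016, "MPRR/MPTT", 637, "Neutropenia"),
    ("Durie/SWOGS0777", 2016, "VRD/RD", 471, "Neutropenia"),
    ("Facon/FIRST", 2018, "MPT/RD/RD18", 1623, "Neutropenia/Infections"),
    ("Mateos/ALCYONE", 2018, "VMPDr/VMP", 706, "Neutropenia"),
    ("Facon/MAIA", 2018, "DrRD/RD", 737, "Neutropenia"),
    ("Usmani/Keynote185", 2018, "PRD/RD", 301, "Neutropenia"),
    ("Facon/CLARION", 2019, "KMP/VMP", 955, "Neutropenia"),
    ("Facon/Tourmaline-MM2", 2021, "IRD/RD", 705, "Neutropenia"),
    ("Puig/CLARIDEX", 2021, "ClRD/RD", 286, "Infections"),
)

SURVIVAL_ENDPOINTS = ("PFS", "OS")
BINARY_ENDPOINTS = ("ORR", "CR", "safety")

#: Typical first-line control-arm rates: overall response ~50%, complete
#: response ~15%, grade 3-4 adverse event of interest ~30%.
DEFAULT_BASELINE_RISKS = {"ORR": 0.50, "CR": 0.15, "safety": 0.30}


@dataclass
class SimulationTruth:
    """Ground truth for a simulated network.

    ``d_true[endpoint]`` holds the log-scale effect of each treatment versus
    the first treatment (the reference, whose entry is 0) on the endpoint's
    modelling scale (log HR for PFS/OS, log OR for ORR/CR, log RR for
    safety).
    """

    treatments: tuple[str, ...]
    d_true: dict[str, np.ndarray]
    tau_true: dict[str, float]
    endpoint_corr: np.ndarray | None = None
    group_plan: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for ep, d in self.d_true.items():
            d = np.asarray(d, dtype=float)
            if d.shape != (len(self.treatments),):
                raise ValidationError(f"d_true[{ep}] has wrong length")
            if not math.isclose(d[0], 0.0, abs_tol=1e-12):
                raise ValidationError("reference treatment effect must be 0")
            self.d_true[ep] = d
        if self.endpoint_corr is not None:
            ev = np.linalg.eigvalsh(np.asarray(self.endpoint_corr))
            if ev.min() < -1e-10:
                raise ValidationError("endpoint_corr must be positive semi-definite")


@dataclass
class TrialDesign:
    """Shape of the simulated trial set."""

    n_trials: int = 30
    three_arm_prob: float = 0.2
    n_per_arm: tuple[int, int] = (100, 300)
    baseline_risks: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RISKS)
    )
    event_fraction: float = 0.6  # survival events per enrolled patient
    baseline_logit_sd: float = 0.3  # between-trial spread of control risks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_per_arm[0] < 1:
            raise ValidationError("counts must be positive")
        if not 0 <= self.three_arm_prob <= 1:
            raise ValidationError("three_arm_prob must lie in [0, 1]")


def _contrast_re(rng, deltas: np.ndarray, tau: float) -> np.ndarray:
    """Trial random effects around true contrasts, correlation 1/2."""
    m = len(deltas)
    if tau == 0.0:
        return deltas.copy()
    cov = np.full((m, m), tau * tau / 2.0)
    np.fill_diagonal(cov, tau * tau)
    return rng.multivariate_normal(deltas, cov, method="cholesky")


def _fill_summaries(
    rng,
    arm_labels: list[str],
    arm_ns: list[int],
    d_index: dict[str, int],
    truth: SimulationTruth,
    baseline_risks: dict[str, float],
    event_fraction: float,
    baseline_logit_sd: float,
) -> list[ArmRecord]:
    """Draw endpoint summaries for one trial's arms from the truth."""
    base, others = arm_labels[0], arm_labels[1:]
    summaries: list[dict[str, EndpointSummary]] = [dict() for _ in arm_labels]
    for ep, d in truth.d_true.items():
        tau = truth.tau_true.get(ep, 0.0)
        deltas = np.array([d[d_index[t]] - d[d_index[base]] for t in others])
        eff = _contrast_re(rng, deltas, tau)
        if ep in SURVIVAL_ENDPOINTS:
            for j, t in enumerate(others):
                events = max(2, int(round(event_fraction * (arm_ns[0] + arm_ns[j + 1]))))
                se = 2.0 / math.sqrt(events)
                obs = eff[j] + rng.normal(0.0, se)
                summaries[j + 1][ep] = EndpointSummary("loghr_se", obs, se)
        else:
            p0 = baseline_risks[ep]
            logit0 = math.log(p0 / (1 - p0)) + rng.normal(0.0, baseline_logit_sd)
            pb = 1.0 / (1.0 + math.exp(-logit0))
            if ep == "safety":  # risk-ratio scale
                probs = np.clip(pb * np.exp(eff), 1e-4, 0.99)
            else:  # odds-ratio scale
                probs = 1.0 / (1.0 + np.exp(-(logit0 + eff)))
            e_base = int(rng.binomial(arm_ns[0], pb))
            summaries[0][ep] = EndpointSummary("events_total", e_base, arm_ns[0])
            for j, t in enumerate(others):
                e = int(rng.binomial(arm_ns[j + 1], probs[j]))
                summaries[j + 1][ep] = EndpointSummary(
                    "events_total", e, arm_ns[j + 1]
                )
    return [
        ArmRecord(t, n, s) for t, n, s in zip(arm_labels, arm_ns, summaries)
    ]


def simulate_trialset(truth: SimulationTruth, design: TrialDesign) -> list[TrialRecord]:
    """Draw a connected set of randomized trials from the truth.

    The first ``K - 1`` trials follow a random spanning tree over the
    treatments so the evidence network is always connected; remaining trials
    compare uniformly sampled treatment pairs (or triples with probability
    ``three_arm_prob``).  Output is byte-identical for identical seeds.
    """
    rng = np.random.default_rng(design.seed)
    trts = list(truth.treatments)
    K = len(trts)
    if K < 2:
        raise ValidationError("need at least 2 treatments")
    if design.n_trials < K - 1:
        raise ValidationError(
            f"{design.n_trials} trials cannot connect {K} treatments"
        )
    d_index = {t: i for i, t in enumerate(trts)}
    order = list(rng.permutation(K))
    trials: list[TrialRecord] = []
    for i in range(design.n_trials):
        if i < K - 1:  # spanning-tree edge
            new = order[i + 1]
            old = order[int(rng.integers(0, i + 1))]
            chosen = [trts[old], trts[new]]
        else:
            size = 3 if (rng.uniform() < design.three_arm_prob and K >= 3) else 2
            chosen = [trts[j] for j in rng.choice(K, size=size, replace=False)]
        ns = [int(rng.integers(design.n_per_arm[0], design.n_per_arm[1] + 1))
              for _ in chosen]
        arms = _fill_summaries(
            rng, chosen, ns, d_index, truth,
            design.baseline_risks, design.event_fraction, design.baseline_logit_sd,
        )
        quality = tuple(bool(b) for b in rng.uniform(size=5) < 0.8)
        trials.append(
            TrialRecord(f"SIM{i + 1:03d}", 2010 + i % 12, tuple(arms), quality)
        )
    return trials


def simulate_profiled_network(
    groups: dict[str, int] | list[int],
    separation: float = 1.0,
    jitter: float = 0.05,
    tau: float = 0.1,
    endpoint_corr_strength: float = 0.8,
    seed: int = 0,
) -> SimulationTruth:
    """Truth with planted regimen groups sharing endpoint-effect profiles.

    ``groups`` maps treatments to group ids (or gives group sizes, in which
    case treatments are named ``T01``, ``T02``, ...).  Treatments in one
    group share their endpoint-effect vector up to ``jitter``; consecutive
    group centres differ by ``separation`` on the benefit axis, which is
    mapped onto every endpoint's scale with correlation
    ``endpoint_corr_strength`` between endpoints.
    """
    if isinstance(groups, dict):
        plan = dict(groups)
    else:
        plan = {}
        i = 0
        for g, size in enumerate(groups):
            for _ in range(size):
                i += 1
                plan[f"T{i:02d}"] = g
    group_ids = sorted(set(plan.values()))
    if len(group_ids) < 2:
        raise ValidationError("need at least 2 planted groups")
    if separation <= 0:
        raise ValidationError("separation must be positive")
    rng = np.random.default_rng(seed)
    trts = tuple(plan)
    endpoints = SURVIVAL_ENDPOINTS + BINARY_ENDPOINTS
    # benefit sign per endpoint scale: better = lower logHR/logRR, higher logOR
    sign = {"PFS": -1.0, "OS": -1.0, "ORR": 1.0, "CR": 1.0, "safety": -1.0}
    rho = endpoint_corr_strength
    corr = np.full((len(endpoints), len(endpoints)), rho)
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(endpoints)))
    d_true = {ep: np.zeros(len(trts)) for ep in endpoints}
    for k, t in enumerate(trts):
        benefit = plan[t] * separation
        noise = L @ rng.normal(0.0, jitter, len(endpoints))
        for j, ep in enumerate(endpoints):
            d_true[ep][k] = sign[ep] * benefit + noise[j]
    # re-express versus the first treatment so the reference effect is 0
    for ep in endpoints:
        d_true[ep] = d_true[ep] - d_true[ep][0]
    return SimulationTruth(
        treatments=trts,
        d_true=d_true,
        tau_true={ep: tau for ep in endpoints},
        endpoint_corr=corr,
        group_plan=plan,
    )


def _fixture_truth(seed: int) -> tuple[dict[str, np.ndarray], list[str]]:
    """Plausible per-regimen truth for the structural fixture.

    A latent benefit score increases with the era of the regimen (modern
    antibody-containing triplets beat classic melphalan doublets) plus a
    seeded perturbation; it is mapped onto each endpoint's scale.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for _, _, arms, _, _ in TABLE1_STRUCTURE:
        for a in arms.split("/"):
            if a not in labels:
                labels.append(a)
    first_year = {}
    for sid, year, arms, _, _ in TABLE1_STRUCTURE:
        for a in arms.split("/"):
            first_year.setdefault(a, year)
    benefit = {
        a: 0.05 * (first_year[a] - 2007) + float(rng.normal(0.0, 0.25))
        for a in labels
    }
    benefit["MP"] = 0.0  # classic doublet anchors the scale
    sign = {"PFS": -1.0, "OS": -1.0, "ORR": 1.0, "CR": 1.0, "safety": -1.0}
    scale = {"PFS": 0.8, "OS": 0.5, "ORR": 1.0, "CR": 1.0, "safety": 0.3}
    d_true = {}
    for ep in SURVIVAL_ENDPOINTS + BINARY_ENDPOINTS:
        d = np.array(
            [sign[ep] * scale[ep] * benefit[a] + float(rng.normal(0, 0.1))
             for a in labels]
        )
        d_true[ep] = d - d[0]
    return d_true, labels


def table1_fixture(seed: int = 20101) -> list[TrialRecord]:
    """The 27-trial structural fixture with synthetic endpoint summaries.

    Study ids, years, arm labels and total enrolment follow the published
    table; per-arm sizes split the printed total equally across arms with
    the remainder given to the first arm.  Endpoint summaries are drawn from
    a seeded plausible truth (the table prints none), so analyses of the
    fixture exercise the published network structure, not the published
    effect estimates.
    """
    d_true, labels = _fixture_truth(seed)
    truth = SimulationTruth(
        treatments=tuple(labels),
        d_true={ep: d.copy() for ep, d in d_true.items()},
        tau_true={ep: 0.1 for ep in d_true},
    )
    d_index = {t: i for i, t in enumerate(labels)}
    rng = np.random.default_rng(seed + 1)
    trials: list[TrialRecord] = []
    for sid, year, arms_s, total, _ae in TABLE1_STRUCTURE:
        arm_labels = arms_s.split("/")
        k = len(arm_labels)
        base_n, rem = divmod(total, k)
        ns = [base_n + (rem if j == 0 else 0) for j in range(k)]
        arms = _fill_summaries(
            rng, arm_labels, ns, d_index, truth,
            DEFAULT_BASELINE_RISKS, 0.6, 0.3,
        )
        quality = tuple(bool(b) for b in rng.uniform(size=5) < 0.8)
        trials.append(TrialRecord(sid, year, tuple(arms), quality))
    return trials
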