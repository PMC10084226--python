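"""Trial ingestion, treatment canonicalization, and the evidence network.

The input dialect is a long-format UTF-8 CSV with columns
``study_id, year, treatment, n, endpoint, stat_type, value1, value2`` — one
row per (arm, endpoint summary).  Supported ``stat_type`` values:

``loghr_se``
    value1 = log hazard ratio of this arm versus the trial's first-listed
    (baseline) arm, value2 = its standard error.  Baseline arms carry no
    ``loghr_se`` rows.
``events_total``
    value1 = event count in this arm, value2 = arm total at risk.
``pvalue_events``
    value1 = signed two-sided log-rank p-value (negative sign means this arm
    is favoured over the baseline, i.e. logHR < 0), value2 = total events in
    the comparison.
``hr_ci``
    value1/value2 = lower/upper bound of a 95% CI for the hazard ratio versus
    baseline; the point estimate is taken as the geometric mean of the bounds.

Arms are ordered by first appearance within a study; the first arm is the
trial baseline for contrast construction.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from .effect_measures import EffectEstimate
from .errors import FormatError, ValidationError

__all__ = [
    "ArmRecord",
    "TrialRecord",
    "TreatmentNetwork",
    "QualityScore",
    "EndpointSummary",
    "ENDPOINTS",
    "DEFAULT_MERGE_MAP",
    "read_trials",
    "write_trials",
    "canonicalize_treatments",
    "build_network",
    "enumerate_triangles",
    "quality_score",
    "funnel_points",
]

logger = logging.getLogger(__name__)

#: Endpoints analysed, in canonical column order.
ENDPOINTS = ("PFS", "OS", "ORR", "CR", "safety")

REQUIRED_COLUMNS = (
    "study_id",
    "year",
    "treatment",
    "n",
    "endpoint",
    "stat_type",
    "value1",
    "value2",
)

STAT_TYPES = ("loghr_se", "events_total", "pvalue_events", "hr_ci")

#: Bortezomib/thalidomide/prednisone is pooled with VTD (both are
#: bortezomib-thalidomide + steroid schedules).
DEFAULT_MERGE_MAP = {"VTP": "VTD"}

# Display aliases: the same regimen is typeset differently across source
# tables (RD vs Rd, VMPDr vs DrVMP, ...).  Keys are punctuation-stripped
# upper-case forms, values the canonical display label.  Maintenance variants
# (MPT-T, MPR-R, Rd18, Rd9) remain distinct regimens.
_ALIASES = {
    "MP": "MP",
    "MPT": "MPT",
    "MPTT": "MPT-T",
    "MPR": "MPR",
    "MPRR": "MPR-R",
    "TD": "TD",
    "VD": "VD",
    "RD": "Rd",
    "RD18": "Rd18",
    "RD9": "Rd9",
    "VMP": "VMP",
    "VMPT": "VMPT",
    "VMPS": "VMPS",
    "VTD": "VTD",
    "VTP": "VTP",
    "VRD": "VRD",
    "CTD": "CTD",
    "CPR": "CPR",
    "KMP": "KMP",
    "IRD": "IRD",
    "VMPDR": "DrVMP",
    "DRVMP": "DrVMP",
    "DRRD": "DrRd",
    "PRD": "PRd",
    "CLRD": "ClRd",
}


def _normalize(label: str) -> str:
    """Case-insensitive, punctuation-stripped key for a treatment label."""
    return re.sub(r"[^0-9A-Za-z]", "", label).upper()


def canonical_label(label: str) -> str:
    """Resolve a raw treatment label to its canonical display form."""
    key = _normalize(label)
    return _ALIASES.get(key, key)


@dataclass(frozen=True)
class EndpointSummary:
    """One arm-level summary for one endpoint (see module docstring)."""

    stat_type: str
    value1: float
    value2: float

    def __post_init__(self) -> None:
        if self.stat_type not in STAT_TYPES:
            raise ValidationError(f"unknown stat_type {self.stat_type!r}")
        if self.stat_type == "events_total":
            e, t = self.value1, self.value2
            if not (t >= 1 and 0 <= e <= t):
                raise ValidationError(
                    f"events/total must satisfy 0 <= events <= total, got {e}/{t}"
                )


@dataclass(frozen=True)
class ArmRecord:
    """One randomized arm: treatment label, size and endpoint summaries."""

    treatment: str
    n: int
    endpoint_summaries: dict[str, EndpointSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"arm size must be >= 1, got {self.n}")


@dataclass(frozen=True)
class TrialRecord:
    """A randomized trial with >= 2 arms; the first arm is the baseline."""

    study_id: str
    year: int
    arms: tuple[ArmRecord, ...]
    quality_items: tuple[bool, bool, bool, bool, bool] = (True,) * 5

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValidationError(f"trial {self.study_id} has < 2 arms")
        labels = [a.treatment for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValidationError(
                f"duplicate treatment label within trial {self.study_id}"
            )

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(a.treatment for a in self.arms)

    @property
    def total_n(self) -> int:
        return sum(a.n for a in self.arms)


@dataclass(frozen=True)
class QualityScore:
    study_id: str
    score: int


@dataclass
class TreatmentNetwork:
    """Evidence network: nodes weighted by patients, edges by trial counts."""

    graph: nx.Graph
    connected: bool

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def node_weights(self) -> dict[str, int]:
        return {t: self.graph.nodes[t]["n"] for t in self.graph.nodes}

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        return {
            tuple(sorted((u, v))): d["trials"]
            for u, v, d in self.graph.edges(data=True)
        }

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Node and edge tables ready for CSV export / plotting."""
        nodes = pd.DataFrame(
            {"treatment": self.nodes, "n": [self.node_weights[t] for t in self.nodes]}
        )
        edges = pd.DataFrame(
            [(u, v, m) for (u, v), m in sorted(self.edges.items())],
            columns=["treatment_a", "treatment_b", "trials"],
        )
        return nodes, edges


def read_trials(path) -> list[TrialRecord]:
    """Read trials from the long-format CSV dialect.

    Rows are grouped by ``study_id`` preserving arm order of first
    appearance; counts are parsed as integers.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    trials: list[TrialRecord] = []
    for study_id, grp in df.groupby("study_id", sort=False):
        arms: list[ArmRecord] = []
        seen: set[str] = set()
        for treatment, arm_rows in grp.groupby("treatment", sort=False):
            if treatment in seen:
                raise ValidationError(
                    f"duplicate (study_id, treatment) = ({study_id}, {treatment})"
                )
            seen.add(treatment)
            if arm_rows["n"].nunique() > 1:
                raise ValidationError(
                    f"duplicate (study_id, treatment) = ({study_id}, {treatment}) "
                    "with conflicting n"
                )
            n = int(arm_rows["n"].iloc[0])
            if n <= 0:
                raise ValidationError(f"non-positive n for {study_id}/{treatment}")
            summaries = {}
            for _, row in arm_rows.iterrows():
                if pd.isna(row["endpoint"]) or pd.isna(row["stat_type"]):
                    continue
                ep = str(row["endpoint"])
                if ep in summaries:
                    raise ValidationError(
                        f"duplicate (study_id, treatment) = ({study_id}, "
                        f"{treatment}): endpoint {ep} listed twice"
                    )
                summaries[ep] = EndpointSummary(
                    str(row["stat_type"]), float(row["value1"]), float(row["value2"])
                )
            arms.append(ArmRecord(str(treatment), n, summaries))
        trials.append(
            TrialRecord(str(study_id), int(grp["year"].iloc[0]), tuple(arms))
        )
    return trials


def write_trials(trials: list[TrialRecord], path) -> None:
    """Write trials in the long-format CSV dialect read by :func:`read_trials`."""
    rows = []
    for t in trials:
        for arm in t.arms:
            if not arm.endpoint_summaries:
                rows.append(
                    (t.study_id, t.year, arm.treatment, arm.n, "", "", "", "")
                )
            for ep, s in arm.endpoint_summaries.items():
                rows.append(
                    (t.study_id, t.year, arm.treatment, arm.n,
                     ep, s.stat_type, s.value1, s.value2)
                )
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


def canonicalize_treatments(
    trials: list[TrialRecord],
    merge_map: dict[str, str] | None = None,
    drop_invalid: bool = False,
) -> list[TrialRecord]:
    """Rewrite treatment labels to canonical form and apply regimen merges.

    Labels are matched case-insensitively with punctuation stripped, then
    ``merge_map`` (default: pool VTP into VTD) is applied.  A merge that
    would leave two identically-labelled arms inside one trial raises a
    :class:`ValidationError`, or drops the trial with a warning when
    ``drop_invalid`` is true.
    """
    if merge_map is None:
        merge_map = DEFAULT_MERGE_MAP
    merge = {
        _normalize(canonical_label(k)): canonical_label(v)
        for k, v in merge_map.items()
    }
    out: list[TrialRecord] = []
    for t in trials:
        new_arms = []
        for arm in t.arms:
            label = canonical_label(arm.treatment)
            label = merge.get(_normalize(label), label)
            new_arms.append(replace(arm, treatment=label))
        labels = [a.treatment for a in new_arms]
        if len(set(labels)) != len(labels):
            if drop_invalid:
                logger.warning(
                    "dropping trial %s: merge produced duplicate arms", t.study_id
                )
                continue
            raise ValidationError(
                f"merge produced duplicate arms within trial {t.study_id}"
            )
        out.append(replace(t, arms=tuple(new_arms)))
    return out


def build_network(trials: list[TrialRecord]) -> TreatmentNetwork:
    """Build the evidence network from (canonicalized) trials.

    Node weight is the total number of patients randomized to the regimen
    across trials; edge multiplicity is the number of trials containing both
    regimens.  A disconnected network is flagged, not rejected.
    """
    g = nx.Graph()
    for t in trials:
        for arm in t.arms:
            if arm.treatment in g:
                g.nodes[arm.treatment]["n"] += arm.n
            else:
                g.add_node(arm.treatment, n=arm.n)
        for u, v in itertools.combinations(t.treatments, 2):
            if g.has_edge(u, v):
                g[u][v]["trials"] += 1
            else:
                g.add_edge(u, v, trials=1)
    connected = nx.is_connected(g) if len(g) else True
    if not connected:
        logger.warning(
            "evidence network is disconnected (%d components)",
            nx.number_connected_components(g),
        )
    return TreatmentNetwork(graph=g, connected=connected)


def enumerate_triangles(network: TreatmentNetwork) -> list[tuple[str, str, str]]:
    """All mutually-adjacent node triples, lexicographically ordered."""
    g = network.graph
    triangles = set()
    # enumerate_all_cliques yields cliques by increasing size; every triangle
    # (including those inside larger cliques) appears at size 3
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) == 3:
            triangles.add(tuple(sorted(clique)))
        elif len(clique) > 3:
            break
    return sorted(triangles)


def quality_score(trial: TrialRecord) -> QualityScore:
    """Cochrane-style study quality: one point per satisfied item.

    The five items are method of randomization, allocation concealment,
    blinding, withdrawal/dropout reporting, and adequacy of follow-up.
    """
    if len(trial.quality_items) != 5:
        raise ValidationError("exactly 5 quality items expected")
    return QualityScore(trial.study_id, int(sum(bool(x) for x in trial.quality_items)))


def funnel_points(
    estimates: list[EffectEstimate],
) -> list[tuple[float, float]]:
    """Funnel-plot coordinates for one pairwise comparison.

    Each effect is centered on the fixed-effect (inverse-variance) pooled
    value; the pairs (centered effect, standard error) are returned for
    plotting with SE on an inverted axis.
    """
    if not estimates:
        raise ValidationError("need at least one estimate")
    measures = {e.measure for e in estimates}
    if len(measures) > 1:
        raise ValidationError(f"mixed measures in funnel input: {measures}")
    weights = [1.0 / e.variance for e in estimates]
    pooled = sum(w * e.value for w, e in zip(weights, estimates)) / sum(weights)
    return [(e.value - pooled, e.se) for e in estimates]
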