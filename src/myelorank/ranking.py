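"""Treatment hierarchies from posterior draws: rankograms and SUCRA.

For each retained draw the treatments are ranked on their effect versus the
common reference (the reference itself enters at d = 0); rank 1 is best
after applying the endpoint's direction (lower log-HR is better for
survival, higher log-OR better for response, lower log-RR better for
toxicity — so the safety SUCRA is already oriented "higher = safer").
SUCRA for treatment *i* among *a* treatments is the average of its
cumulative rank probabilities over ranks 1..a-1; 1 means certainly best,
0 certainly worst, and the SUCRAs always sum to a/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .nma_model import PosteriorSamples

__all__ = [
    "ENDPOINT_DIRECTIONS",
    "RankSummary",
    "rank_probabilities",
    "cumulative_ranking",
    "sucra",
    "rank_summary",
    "mean_sucra_chart",
]

#: better-is direction per endpoint.
ENDPOINT_DIRECTIONS = {
    "PFS": "lower",
    "OS": "lower",
    "ORR": "higher",
    "CR": "higher",
    "safety": "lower",
}


@dataclass
class RankSummary:
    """Rank-probability matrix, cumulative curves and SUCRA for one endpoint."""

    endpoint: str
    direction: str
    treatments: tuple[str, ...]
    rank_probability: np.ndarray | None = None  # (a, a): P(trt i has rank j+1)
    cumulative: np.ndarray | None = None
    sucra: np.ndarray | None = None

    def to_frame(self, which: str = "rank_probability") -> pd.DataFrame:
        mat = getattr(self, which)
        if mat is None:
            raise ValidationError(f"{which} not filled yet")
        a = len(self.treatments)
        return pd.DataFrame(
            mat, index=list(self.treatments), columns=[f"rank_{j+1}" for j in range(a)]
        )


def rank_probabilities(
    samples: PosteriorSamples, direction: str
) -> RankSummary:
    """Tally, per retained draw, which rank each treatment occupies.

    Ties within a draw (measure zero in continuous models) are broken by
    stable treatment order so the result is deterministic.
    """
    if direction not in ("lower", "higher"):
        raise ValidationError(f"direction must be 'lower' or 'higher', got {direction!r}")
    full = samples.d_full_draws()  # (N, a), reference column = 0
    if full.shape[0] < 1000:
        raise ValidationError("need at least 1000 retained draws for ranking")
    key = full if direction == "lower" else -full
    a = key.shape[1]
    # stable argsort: rank 1 = best; ties resolved by treatment order
    order = np.argsort(key, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(key.shape[0])[:, None]
    ranks[rows, order] = np.arange(a)[None, :]
    counts = np.zeros((a, a), dtype=float)
    for j in range(a):
        counts[j] = np.bincount(ranks[:, j], minlength=a)
    counts /= key.shape[0]
    return RankSummary(
        endpoint=samples.endpoint,
        direction=direction,
        treatments=samples.treatments,
        rank_probability=counts,
    )


def cumulative_ranking(summary: RankSummary) -> RankSummary:
    """Fill the row-wise cumulative rank probabilities (rankogram CDF)."""
    if summary.rank_probability is None:
        raise ValidationError("rank_probability must be filled first")
    summary.cumulative = np.cumsum(summary.rank_probability, axis=1)
    return summary


def sucra(summary: RankSummary) -> RankSummary:
    """Fill SUCRA: mean cumulative rank probability over ranks 1..a-1."""
    if summary.cumulative is None:
        raise ValidationError("cumulative must be filled first")
    a = len(summary.treatments)
    if a == 1:
        summary.sucra = np.ones(1)
    else:
        summary.sucra = summary.cumulative[:, : a - 1].mean(axis=1)
    return summary


def rank_summary(samples: PosteriorSamples, direction: str) -> RankSummary:
    """Convenience: rank probabilities, cumulative curves and SUCRA in one go."""
    return sucra(cumulative_ranking(rank_probabilities(samples, direction)))


def mean_sucra_chart(summaries: dict[str, RankSummary]) -> pd.DataFrame:
    """Assemble the SUCRA-per-endpoint chart with its unweighted mean.

    Rows are treatments sorted by descending mean SUCRA (ties broken by
    label); columns are the endpoints in the supplied order plus
    ``mean_sucra``.
    """
    endpoints = list(summaries)
    sets = {ep: set(s.treatments) for ep, s in summaries.items()}
    universe = sets[endpoints[0]]
    for ep, trts in sets.items():
        if trts != universe:
            diff = sorted(universe ^ trts)
            raise ValidationError(
                f"treatment sets differ across endpoints (endpoint {ep}): {diff}"
            )
    cols = {}
    for ep, s in summaries.items():
        if s.sucra is None:
            raise ValidationError(f"SUCRA not filled for endpoint {ep}")
        cols[ep] = pd.Series(s.sucra, index=list(s.treatments))
    chart = pd.DataFrame(cols)
    chart["mean_sucra"] = chart[endpoints].mean(axis=1)
    # sort by label first so the stable sort breaks mean-SUCRA ties by label
    chart = chart.sort_index().sort_values(
        by="mean_sucra", ascending=False, kind="stable"
    )
    chart.index.name = "treatment"
    return chart
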