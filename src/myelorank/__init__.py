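"""myelorank: Bayesian network meta-analysis and SUCRA-profile clustering
of first-line regimens for transplant-ineligible multiple myeloma.

The analytic chain: trial summaries -> evidence network -> random-effects
consistency model (MCMC) per endpoint -> rank probabilities and SUCRA ->
loop inconsistency / heterogeneity diagnostics -> PCA + k-medoids grouping
of the regimen SUCRA profiles.
"""

from importlib import resources as _resources

from .errors import FormatError, MyelorankError, ValidationError
from .effect_measures import (
    EffectEstimate,
    loghr_from_ci,
    loghr_from_logrank,
    logor_from_counts,
    logrr_from_counts,
)
from .trial_data import (
    ENDPOINTS,
    ArmRecord,
    EndpointSummary,
    QualityScore,
    TreatmentNetwork,
    TrialRecord,
    build_network,
    canonicalize_treatments,
    enumerate_triangles,
    funnel_points,
    quality_score,
    read_trials,
    write_trials,
)
from .nma_model import (
    ContrastData,
    NMAConfig,
    PosteriorSamples,
    fit_nma,
    pairwise_estimate,
    relative_effects,
    to_contrasts,
)
from .ranking import (
    ENDPOINT_DIRECTIONS,
    RankSummary,
    cumulative_ranking,
    mean_sucra_chart,
    rank_probabilities,
    rank_summary,
    sucra,
)
from .inconsistency import (
    LoopAssessment,
    direct_estimate,
    loop_inconsistency,
    loop_reml_tau2,
    network_inconsistency_report,
    reml_tau2,
)
from .profiling import (
    ClusterResult,
    SucraProfile,
    assemble_profile,
    choose_k,
    mean_silhouette,
    pam_cluster,
    pca_scores,
    profile_and_cluster,
)
from .synthetic import (
    SimulationTruth,
    TrialDesign,
    simulate_profiled_network,
    simulate_trialset,
    table1_fixture,
)

__version__ = "0.1.0"


def fixture_csv_path():
    """Path to the packaged long-format CSV copy of the structural fixture."""
    return _resources.files("myelorank") / "data" / "table1_synthetic.csv"
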