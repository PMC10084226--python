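"""Group the regimens by their SUCRA profiles: PCA + partitioning around medoids.

Reads the mean-SUCRA chart written by 03_rank_sucra.py, reduces the
treatments x endpoints matrix by correlation PCA, clusters the regimens on
the leading components (>= 80% explained variance) by PAM, and writes the
component scores, loadings and group assignments.  Both the
silhouette-chosen k and the fixed three-group partition are reported.
"""

from pathlib import Path

import pandas as pd

import myelorank as mr

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    chart = pd.read_csv(OUT / "sucra_chart.csv", index_col=0)
    auto = mr.profile_and_cluster(chart, seed=0)
    widths = {k: round(v, 3) for k, v in auto.silhouette.items()}
    print(f"silhouette-chosen k = {auto.k} (mean widths: {widths})")
    print("explained variance by PC:", auto.explained_variance.round(3))

    fixed = mr.profile_and_cluster(chart, k=3, seed=0)
    groups: dict[int, list[str]] = {}
    for t, g in fixed.assignments.items():
        groups.setdefault(g, []).append(t)
    for g in sorted(groups):
        medoid = fixed.medoids[g]
        print(f"group {g + 1} (medoid {medoid}): {', '.join(sorted(groups[g]))}")

    scores = pd.DataFrame(
        fixed.scores,
        index=list(fixed.treatments),
        columns=[f"PC{j + 1}" for j in range(fixed.scores.shape[1])],
    )
    scores["cluster"] = [fixed.assignments[t] for t in fixed.treatments]
    scores["is_medoid"] = [t in fixed.medoids for t in fixed.treatments]
    scores.index.name = "treatment"
    scores.to_csv(OUT / "pca_pam_scores.csv")
    loadings = pd.DataFrame(
        fixed.loadings,
        index=list(mr.ENDPOINTS),
        columns=[f"PC{j + 1}" for j in range(fixed.loadings.shape[1])],
    )
    loadings.index.name = "endpoint"
    loadings.to_csv(OUT / "pca_loadings.csv")


if __name__ == "__main__":
    main()
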