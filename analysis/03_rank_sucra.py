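"""Assemble the mean-SUCRA ranking chart across the five endpoints.

Reads the per-endpoint SUCRA vectors written by 02_fit_nma.py, builds the
treatments x endpoints chart with its unweighted mean (the overall ranking
criterion), and writes it sorted from best to worst.
"""

from pathlib import Path

import pandas as pd

import myelorank as mr

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cols = {}
    for ep in mr.ENDPOINTS:
        s = pd.read_csv(OUT / f"sucra_{ep}.csv", index_col=0)["sucra"]
        cols[ep] = s
    chart = pd.DataFrame(cols)
    chart["mean_sucra"] = chart[list(mr.ENDPOINTS)].mean(axis=1)
    chart = chart.sort_index().sort_values("mean_sucra", ascending=False, kind="stable")
    chart.index.name = "treatment"
    chart.to_csv(OUT / "sucra_chart.csv")
    print("mean-SUCRA ranking (top 5):")
    print(chart.head(5).round(3).to_string())
    print(f"SUCRA column sums (should each be a/2 = {len(chart) / 2}):")
    print(chart[list(mr.ENDPOINTS)].sum().round(3).to_string())


if __name__ == "__main__":
    main()
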