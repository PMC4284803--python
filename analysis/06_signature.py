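#!/usr/bin/env python
"""Build and evaluate the tumour/normal lncRNA biomarker signature.

Per marker: paired t-test on ΔCt and a ROC curve (positive class =
tumour, score = ΔCt). Markers with AUC > 0.7 form the signature, whose
joint performance is the pooled out-of-fold AUC of a tenfold
patient-grouped cross-validated logistic regression. Tumour-tissue ΔCt
of the selected markers is hierarchically clustered for the heatmap.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from p53lnc.signature import (
    cluster_samples,
    crossval_signature,
    marker_statistics,
    read_ct_table,
    roc_auc,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM, FIG = ROOT / "sim", ROOT / "figures"
SEED = 20160503


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    cohort = read_ct_table(SIM / "cohort_ct.tsv")
    stats = marker_statistics(cohort)
    stats.to_csv(ROOT / "marker_statistics.tsv", sep="\t", index=False)
    n_sig = int(stats["significant"].sum())
    print(f"{len(cohort.patients)} patients, {len(cohort.markers)} markers; "
          f"{n_sig} significantly shifted (paired t, P<0.01)")

    result = crossval_signature(cohort, k=10, seed=SEED)
    print(f"selected (AUC>0.7): {result.selected}")
    print(f"tenfold pooled CV AUC = {result.pooled_auc:.3f}")
    (ROOT / "signature.json").write_text(
        json.dumps(
            {
                "per_marker_auc": result.per_marker_auc,
                "selected": result.selected,
                "pooled_cv_auc": result.pooled_auc,
                "k": result.k,
                "seed": result.seed,
            },
            indent=1,
        )
    )

    fig, ax = plt.subplots(figsize=(4.2, 4))
    pooled = roc_auc(result.pooled_scores, result.pooled_labels)
    ax.plot(pooled.fpr, pooled.tpr, label=f"signature (AUC {pooled.auc:.3f})")
    tum, nor = cohort.tissue_matrix("tumour"), cohort.tissue_matrix("normal")
    for m in result.selected:
        r = roc_auc(
            np.r_[tum[m].to_numpy(), nor[m].to_numpy()],
            np.r_[np.ones(len(tum)), np.zeros(len(nor))],
        )
        ax.plot(r.fpr, r.tpr, lw=0.8, alpha=0.6, label=f"{m} ({r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(FIG / "roc_curves.png", dpi=150)

    if result.selected:
        matrix = tum[result.selected].T  # markers x patients
        rows, cols = cluster_samples(matrix)
        ordered = matrix.loc[rows, cols]
        fig, ax = plt.subplots(figsize=(7, 2.5))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_yticks(range(len(rows)), rows, fontsize=7)
        ax.set_xticks([])
        ax.set_xlabel("patients (clustered)")
        fig.colorbar(im, label="tumour ΔCt")
        fig.tight_layout()
        fig.savefig(FIG / "signature_clustering.png", dpi=150)
        pd.DataFrame({"marker_order": pd.Series(rows)}).to_csv(
            ROOT / "clustering_rows.tsv", sep="\t", index=False
        )


if __name__ == "__main__":
    main()
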