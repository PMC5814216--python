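"""Discover radiomic consensus clusters and select the cluster count.

Standardizes the radiomic matrix, runs consensus clustering (500 resamples,
80% patient subsampling, Pearson geometry) over k = 2..6, selects k by the
PAC statistic, and writes assignments, the consensus matrix, the PAC curve
and a similarity heatmap.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from radgbm.subtyping import consensus_cluster, pearson_similarity, standardize


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/cohort")
    ap.add_argument("--resamples", type=int, default=500)
    args = ap.parse_args()

    out = Path(args.outdir)
    features = pd.read_csv(out / "radiomic_matrix.tsv", sep="\t",
                           index_col="patient_id")
    z = standardize(features)
    result = consensus_cluster(z, k_range=(2, 3, 4, 5, 6),
                               n_resamples=args.resamples,
                               subsample_fraction=0.8, seed=args.seed)
    result.assignments.to_csv(out / "cluster_assignments.tsv", sep="\t",
                              index_label="patient_id")
    result.consensus_matrix.to_csv(out / "consensus_matrix.tsv", sep="\t",
                                   index_label="patient_id")
    result.stability_curve.rename("pac").to_csv(out / "pac_curve.tsv", sep="\t",
                                                index_label="k")

    labels = result.labels()
    order = labels.sort_values().index
    sim = pearson_similarity(z).loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sim.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_title(f"Patient similarity (Pearson), ordered by cluster (k={result.k_selected})")
    fig.colorbar(im, ax=ax, label="r")
    fig.savefig(out / "similarity_heatmap.png", dpi=120, bbox_inches="tight")

    print(f"PAC per k: {result.stability_curve.round(3).to_dict()}")
    print(f"selected k = {result.k_selected}")
    sizes = labels.value_counts().sort_index()
    print("cluster sizes:", ", ".join(f"{k}: n={v}" for k, v in sizes.items()))
    print(f"written to {out}/ (assignments, consensus matrix, PAC curve, heatmap)")


if __name__ == "__main__":
    main()
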