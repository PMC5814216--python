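"""Radiogenomic association screens and the cluster survival contrast.

Runs the Spearman screen of radiomic features against ssGSEA pathway scores
(|rho| > 0.6, p < 0.05, BH adjustment), per-gene mutation/CNV linear
regressions, Mann-Whitney feature contrasts between clusters, and the
Kaplan-Meier / log-rank comparison of cluster survival. Writes tables and a
KM plot.
"""

import argparse
import itertools
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from radgbm import association as assoc


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results/cohort")
    args = ap.parse_args()

    out = Path(args.outdir)
    features = pd.read_csv(out / "radiomic_matrix.tsv", sep="\t",
                           index_col="patient_id")
    scores = pd.read_csv(out / "ssgsea_scores.tsv", sep="\t", index_col="gene_set")
    clusters = pd.read_csv(out / "cluster_assignments.tsv", sep="\t",
                           index_col="patient_id")
    k_col = "3" if "3" in clusters.columns else clusters.columns[-1]
    labels = clusters[k_col].reindex(features.index)
    mutations = pd.read_csv(out / "mutations.tsv", sep="\t", index_col="gene")
    cnv = pd.read_csv(out / "cnv_log2.tsv", sep="\t", index_col="gene")
    survival = pd.read_csv(out / "survival.tsv", sep="\t")

    screen = assoc.spearman_screen(features, scores, rho_min=0.6, p_max=0.05)
    screen.to_csv(out / "pathway_associations.tsv", sep="\t", index=False)

    mw_rows = []
    for feat in features.columns:
        for a, b in itertools.combinations(sorted(labels.unique()), 2):
            u, p = assoc.mannwhitney_test(
                features[feat], labels[labels == a].index, labels[labels == b].index
            )
            mw_rows.append((feat, f"{a}v{b}", u, p))
    mw = pd.DataFrame(mw_rows, columns=["radiomic_feature", "contrast", "U", "p_value"])
    mw["adjusted_p"] = assoc.bh_adjust(mw["p_value"].to_numpy())
    mw.to_csv(out / "cluster_feature_tests.tsv", sep="\t", index=False)

    var_rows = []
    for kind, mat in (("mutation", mutations), ("cnv", cnv)):
        for gene in mat.index:
            indicator = mat.loc[gene, features.index]
            for feat in features.columns:
                r = assoc.variant_effect_regression(features[feat], indicator)
                var_rows.append((kind, gene, feat, r["coefficient"], r["p_value"],
                                 r["testable"]))
    var = pd.DataFrame(var_rows, columns=["kind", "gene", "radiomic_feature",
                                          "coefficient", "p_value", "testable"])
    ok = var["testable"]
    var["adjusted_p"] = np.nan
    var.loc[ok, "adjusted_p"] = assoc.bh_adjust(var.loc[ok, "p_value"].to_numpy())
    var.to_csv(out / "variant_associations.tsv", sep="\t", index=False)

    survival["group"] = labels.reindex(survival["patient_id"]).to_numpy()
    km = assoc.km_logrank(survival)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for g in sorted(survival["group"].unique()):
        sub = survival[survival["group"] == g]
        KaplanMeierFitter().fit(sub["time"], sub["event"],
                                label=f"cluster {g} (n={len(sub)})").plot(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank p = {km['logrank_p']:.3g}")
    fig.savefig(out / "km_by_cluster.png", dpi=120, bbox_inches="tight")

    print(f"Spearman screen: {len(screen)} feature~pathway hits "
          f"({int((screen['adjusted_p'] <= 0.01).sum())} at adjusted p <= 0.01) "
          f"of {screen.attrs['n_tested']} pairs")
    print(f"Mann-Whitney: {int((mw['adjusted_p'] <= 0.01).sum())} "
          f"cluster-contrast hits at adjusted p <= 0.01")
    n_var = int((var["adjusted_p"].dropna() <= 0.01).sum())
    print(f"mutation/CNV regressions: {n_var} hits at adjusted p <= 0.01 "
          f"({int((~var['testable']).sum())} untestable)")
    for g, s in km["groups"].items():
        print(f"cluster {g}: median OS {s['median']:.1f} months "
              f"(95% CI {s['ci_low']:.1f}-{s['ci_high']:.1f}), "
              f"{s['events']}/{s['n']} events")
    print(f"log-rank chi2 {km['logrank_stat']:.2f}, p = {km['logrank_p']:.3g}")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
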