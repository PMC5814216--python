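"""Transcriptomic characterisation of the radiomic clusters.

Trains a ClaNC balanced nearest-centroid signature on the cluster labels
(size chosen by stratified CV), scores every gene set per patient with
ssGSEA, and tests signature-gene over-representation in each set (Fisher,
BH-adjusted). Writes the signature, CV curve, score matrix and enrichment
table.
"""

import argparse
from pathlib import Path

import pandas as pd

from radgbm import signatures as sig
from radgbm.association import bh_adjust


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/cohort")
    ap.add_argument("--sizes", type=int, nargs="+", default=[5, 10, 20, 30])
    args = ap.parse_args()

    out = Path(args.outdir)
    expr = pd.read_csv(out / "expression_log2.tsv", sep="\t", index_col="gene")
    expr.attrs["transform"] = "log"
    clusters = pd.read_csv(out / "cluster_assignments.tsv", sep="\t",
                           index_col="patient_id")
    k_col = clusters.columns[-1] if "3" not in clusters.columns else "3"
    labels = clusters[k_col].astype(str).reindex(expr.columns)
    gene_sets = sig.read_gmt(out / "gene_sets.gmt")

    curve, chosen = sig.clanc_cv(expr, labels, args.sizes, n_folds=5,
                                 seed=args.seed)
    model = sig.clanc_train(expr, labels, chosen)
    pd.DataFrame(
        [(c, g) for c in model.class_labels for g in model.selected_genes[c]],
        columns=["cluster", "gene"],
    ).to_csv(out / "clanc_signature.tsv", sep="\t", index=False)
    curve.rename("cv_error").to_csv(out / "clanc_cv_curve.tsv", sep="\t",
                                    index_label="genes_per_class")

    scores = sig.ssgsea(expr, gene_sets, alpha=0.25)
    scores.to_csv(out / "ssgsea_scores.tsv", sep="\t", index_label="gene_set")

    rows = []
    universe = list(expr.index)
    for c in model.class_labels:
        for name, members in gene_sets.items():
            res = sig.fisher_ora(model.selected_genes[c], members, universe,
                                 set_name=name)
            rows.append((c, name, res.overlap, res.statistic, res.p_value))
    ora = pd.DataFrame(rows, columns=["cluster", "gene_set", "overlap",
                                      "odds_ratio", "p_value"])
    ora["adjusted_p"] = bh_adjust(ora["p_value"].to_numpy())
    ora.to_csv(out / "cluster_set_enrichment.tsv", sep="\t", index=False)

    print(f"ClaNC CV error by signature size: {curve.round(3).to_dict()}")
    print(f"chosen signature: {chosen} genes per class "
          f"({chosen * len(model.class_labels)} total)")
    hits = ora[ora["adjusted_p"] <= 0.01]
    print(f"{len(hits)} cluster/gene-set enrichments at adjusted p <= 0.01:")
    for _, r in hits.iterrows():
        print(f"  cluster {r['cluster']} ~ {r['gene_set']}: overlap {r['overlap']}, "
              f"OR {r['odds_ratio']:.1f}, adj p {r['adjusted_p']:.2e}")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
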