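"""Generate the synthetic 65-patient radiogenomic cohort and write it out.

Writes the omics tables (expression, mutations, CNV, survival), the gene-set
collection (GMT), the ground-truth subtype labels, and — as an IO example —
one patient's imaging volumes as NIfTI. Imaging for the full cohort is not
persisted: downstream drivers re-derive it deterministically from the seed.
"""

import argparse
from pathlib import Path

import nibabel as nib
import numpy as np

from radgbm.signatures import write_gmt
from radgbm.synth import default_config, simulate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/cohort")
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=args.seed)
    cohort = simulate_cohort(cfg, keep_imaging=True)

    cohort.expression.to_csv(out / "expression_log2.tsv", sep="\t", index_label="gene")
    cohort.mutations.to_csv(out / "mutations.tsv", sep="\t", index_label="gene")
    cohort.cnv.to_csv(out / "cnv_log2.tsv", sep="\t", index_label="gene")
    cohort.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
    cohort.truth.subtype_labels.to_csv(out / "true_subtypes.tsv", sep="\t",
                                       index_label="patient_id")
    write_gmt(cohort.gene_sets, out / "gene_sets.gmt")

    # one example subject as NIfTI (the format the map stage consumes)
    p = cohort.patients[0]
    affine = np.diag([*p.spacing, 1.0])
    nii = out / "example_patient"
    nii.mkdir(exist_ok=True)
    for name, arr in (("t1ce", p.t1ce), ("t2flair", p.t2flair),
                      ("dwi_b0", p.dwi_b0), ("dwi_b1000", p.dwi_b1000)):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
                 nii / f"{name}.nii")
    dsc = np.moveaxis(p.dsc.data, 0, -1)  # x,y,z,t on disk
    nib.save(nib.Nifti1Image(dsc.astype(np.float32), affine), nii / "dsc.nii")
    for name, roi in p.rois.items():
        nib.save(nib.Nifti1Image(roi.voxels.astype(np.uint8), affine),
                 nii / f"mask_{name}.nii")

    counts = cohort.truth.subtype_labels.value_counts()
    print(f"cohort of {cfg.n_patients} patients (seed {args.seed})")
    print("planted subtypes:", ", ".join(f"{k}: n={v}" for k, v in counts.items()))
    print(f"expression: {cohort.expression.shape[0]} genes; "
          f"mutations/CNV: {cohort.mutations.shape[0]} genes; "
          f"{len(cohort.gene_sets)} gene sets")
    print(f"median follow-up time {np.median(cohort.survival['time']):.1f} months, "
          f"{int(cohort.survival['event'].sum())} events")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
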