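"""End-to-end orchestration: cohort -> maps -> features -> clusters -> omics.

The stages mirror the analysis workflow: (1) simulate or load a cohort,
(2) compute physiologic maps per patient, (3) extract the 82-feature
radiomic matrix, (4) consensus-cluster patients, (5) derive transcriptomic
signatures (ClaNC, ssGSEA), (6) run association screens (Spearman,
Mann-Whitney, mutation/CNV regression) and the survival contrast, and
(7) render a plain-text report. Every run writes a manifest recording the
seed, the resolved parameters and a checksum per output file, so a re-run
with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import signatures as sig
from .maps import (
    PerfusionMapSet,
    compute_adc,
    correct_leakage,
    fit_gamma_variate_batch,
    normalize_relative,
    perfusion_indices_batch,
    signal_to_relaxation,
)
from .radiomics import extract_patient_features, feature_registry, subtract_exclusions
from .subtyping import consensus_cluster, standardize
from .synth import CohortConfig, SyntheticCohort, default_config, simulate_cohort

__all__ = [
    "PipelineConfig",
    "compute_patient_maps",
    "patient_feature_vector",
    "cohort_feature_matrix",
    "run_pipeline",
    "report",
]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    cohort: CohortConfig | None = None
    k_range: tuple = (2, 3, 4, 5, 6)
    n_resamples: int = 500
    subsample_fraction: float = 0.8
    fixed_k: int | None = None  # bypass PAC selection when set
    clanc_sizes: tuple = (5, 10, 20, 30)
    clanc_folds: int = 5
    ssgsea_alpha: float = 0.25
    rho_min: float = 0.6
    p_max: float = 0.05
    adj_p_max: float = 0.01
    leakage_correction: bool = True
    stages: tuple = (
        "simulate", "maps", "extract", "cluster", "signatures", "associate", "report",
    )

    def validate(self):
        if not 0 < self.p_max <= 1 or not 0 < self.adj_p_max <= 1:
            raise ValueError("p-value thresholds must lie in (0, 1]")
        if not 0 <= self.rho_min < 1:
            raise ValueError("rho_min must lie in [0, 1)")
        if not 0.5 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0.5, 1]")


# --------------------------------------------------------------------------
# per-patient map computation


def compute_patient_maps(patient, leakage_correction: bool = True) -> dict:
    """ADC and perfusion index maps for one patient, reference-normalised.

    DSC fitting runs only on voxels inside the FLAIR ROI or the reference
    region (elsewhere there is no bolus to fit). Returns the five maps
    keyed by registry source name plus diagnostics (clamp count, fit
    failure fraction).
    """
    rois = patient.rois
    ref_mask = rois["reference"].voxels
    interest = rois["t2flair"].voxels | ref_mask

    adc, n_clamped = compute_adc(
        patient.dwi_b0, patient.dwi_b1000, b=max(patient.b_values)
    )
    radc = normalize_relative(adc, ref_mask)

    times = patient.dsc.times
    idx = np.flatnonzero(interest.ravel())
    curves = signal_to_relaxation(patient.dsc, mask=interest).T  # voxels x time
    if leakage_correction:
        ref_rows = ref_mask.ravel()[idx]
        reference_curve = curves[ref_rows].mean(axis=0)
        curves, _k2 = correct_leakage(curves, reference_curve, times)
    fit = fit_gamma_variate_batch(curves, times)
    cbv_v, cbf_v, mtt_v, ttp_v = perfusion_indices_batch(fit)

    shape = patient.dwi_b0.shape
    full = {}
    for name, vals in (("cbv", cbv_v), ("cbf", cbf_v), ("mtt", mtt_v), ("ttp", ttp_v)):
        m = np.full(np.prod(shape), np.nan)
        m[idx] = vals
        full[name] = m.reshape(shape)
    quality = np.zeros(np.prod(shape), dtype=bool)
    quality[idx] = fit["converged"]
    quality = quality.reshape(shape)

    perfusion = PerfusionMapSet(
        rcbv=normalize_relative(full["cbv"], ref_mask),
        rcbf=normalize_relative(full["cbf"], ref_mask),
        mtt=full["mtt"],
        ttp=full["ttp"],
        fit_quality=quality,
    )
    n_roi = int(interest.sum())
    n_failed = n_roi - int(fit["converged"].sum())
    return {
        "maps": {
            "rADC": radc,
            "rCBF": perfusion.rcbf,
            "rCBV": perfusion.rcbv,
            "MTT": perfusion.mtt,
            "TTP": perfusion.ttp,
        },
        "perfusion": perfusion,
        "diagnostics": {
            "adc_clamped": n_clamped,
            "fit_failed": n_failed,
            "fit_failed_frac": n_failed / max(n_roi, 1),
        },
    }


def patient_feature_vector(patient, leakage_correction: bool = True) -> pd.Series:
    """Maps + exclusion-subtracted ROIs -> the 82-feature vector."""
    computed = compute_patient_maps(patient, leakage_correction=leakage_correction)
    rois = patient.rois
    t1 = subtract_exclusions(rois["t1ce"], rois["necrosis"], rois["vessels"])
    t2 = subtract_exclusions(rois["t2flair"], rois["necrosis"], rois["vessels"])
    vec = extract_patient_features(computed["maps"], {"T1CE": t1, "T2FLAIR": t2})
    vec.name = patient.patient_id
    return vec


def cohort_feature_matrix(config: CohortConfig | None = None,
                          cohort: SyntheticCohort | None = None,
                          leakage_correction: bool = True):
    """Patients x 82 radiomic matrix for a whole cohort.

    When called with a config (no cohort), imaging is simulated and
    discarded patient by patient, keeping memory flat across seeds.
    Returns ``(matrix, cohort_without_imaging_or_cohort)``.
    """
    if cohort is not None:
        rows = [patient_feature_vector(p, leakage_correction) for p in cohort.patients]
        return pd.DataFrame(rows), cohort
    if config is None:
        config = default_config()
    from .synth import draw_labels, simulate_patient_imaging  # local: streaming path

    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients + 5)
    labels = draw_labels(config, np.random.default_rng(children[0]))
    by_name = {p.name: p for p in config.profiles}
    rows = []
    for i, pid in enumerate(labels.index):
        rng = np.random.default_rng(children[1 + i])
        patient, _truth = simulate_patient_imaging(config, by_name[labels.loc[pid]], pid, rng)
        rows.append(patient_feature_vector(patient, leakage_correction))
    lean = simulate_cohort(config, keep_imaging=False)
    return pd.DataFrame(rows), lean


# --------------------------------------------------------------------------
# full run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None):
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("cohort",)
        },
        "outputs": {},
        "stages": {},
    }

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "simulate"
    try:
        cohort_cfg = config.cohort or default_config(seed=config.seed)
        features, cohort = cohort_feature_matrix(
            cohort_cfg, leakage_correction=config.leakage_correction
        )
        stage = "extract"
        _write_tsv(features, outdir / "radiomic_matrix.tsv", index_label="patient_id")
        record("radiomic_matrix", outdir / "radiomic_matrix.tsv")
        _write_tsv(
            pd.DataFrame([vars(s) for s in feature_registry()]),
            outdir / "feature_registry.tsv",
        )
        record("feature_registry", outdir / "feature_registry.tsv")
        manifest["stages"]["extract"] = {
            "n_patients": int(features.shape[0]),
            "n_features": int(features.shape[1]),
            "n_missing": int(features.isna().sum().sum()),
        }

        stage = "cluster"
        z = standardize(features)
        consensus = consensus_cluster(
            z,
            k_range=config.k_range,
            n_resamples=config.n_resamples,
            subsample_fraction=config.subsample_fraction,
            seed=config.seed,
        )
        k_used = config.fixed_k or consensus.k_selected
        clusters = consensus.labels(k_used)
        _write_tsv(consensus.assignments, outdir / "cluster_assignments.tsv",
                   index_label="patient_id")
        record("cluster_assignments", outdir / "cluster_assignments.tsv")
        _write_tsv(consensus.consensus_matrix, outdir / "consensus_matrix.tsv",
                   index_label="patient_id")
        record("consensus_matrix", outdir / "consensus_matrix.tsv")
        manifest["stages"]["cluster"] = {
            "k_selected": int(consensus.k_selected),
            "k_used": int(k_used),
            "pac_curve": {int(k): float(v) for k, v in consensus.stability_curve.items()},
            "cluster_sizes": {int(k): int(v) for k, v in
                              clusters.value_counts().sort_index().items()},
        }

        stage = "signatures"
        expr = cohort.expression
        expr.attrs["transform"] = "log"
        cluster_labels = clusters.astype(str)
        curve, chosen = sig.clanc_cv(
            expr, cluster_labels, config.clanc_sizes,
            n_folds=config.clanc_folds, seed=config.seed,
        )
        model = sig.clanc_train(expr, cluster_labels, chosen)
        model.cv_curve = curve
        scores = sig.ssgsea(expr, cohort.gene_sets, alpha=config.ssgsea_alpha)
        _write_tsv(scores, outdir / "ssgsea_scores.tsv", index_label="gene_set")
        record("ssgsea_scores", outdir / "ssgsea_scores.tsv")
        signature_df = pd.DataFrame(
            [(c, g) for c in model.class_labels for g in model.selected_genes[c]],
            columns=["cluster", "gene"],
        )
        _write_tsv(signature_df, outdir / "clanc_signature.tsv")
        record("clanc_signature", outdir / "clanc_signature.tsv")
        manifest["stages"]["signatures"] = {
            "clanc_genes_per_class": int(chosen),
            "clanc_cv_curve": {int(s): float(v) for s, v in curve.items()},
            "n_gene_sets": int(scores.shape[0]),
        }

        stage = "associate"
        pathway_screen = assoc.spearman_screen(
            features, scores, rho_min=config.rho_min, p_max=config.p_max
        )
        _write_tsv(pathway_screen, outdir / "pathway_associations.tsv")
        record("pathway_associations", outdir / "pathway_associations.tsv")

        # signature-gene enrichment per cluster against the gene-set collection
        ora_rows = []
        universe = list(expr.index)
        for c in model.class_labels:
            for set_name, members in cohort.gene_sets.items():
                res = sig.fisher_ora(model.selected_genes[c], members, universe,
                                     set_name=set_name)
                ora_rows.append(
                    (c, set_name, res.overlap, res.statistic, res.p_value)
                )
        ora = pd.DataFrame(
            ora_rows, columns=["cluster", "gene_set", "overlap", "odds_ratio", "p_value"]
        )
        ora["adjusted_p"] = assoc.bh_adjust(ora["p_value"].to_numpy())
        _write_tsv(ora, outdir / "cluster_set_enrichment.tsv")
        record("cluster_set_enrichment", outdir / "cluster_set_enrichment.tsv")

        variant_rows = []
        for kind, mat in (("mutation", cohort.mutations), ("cnv", cohort.cnv)):
            for gene in mat.index:
                indicator = mat.loc[gene, features.index]
                for feat in features.columns:
                    res = assoc.variant_effect_regression(features[feat], indicator)
                    variant_rows.append(
                        (kind, gene, feat, res["coefficient"], res["p_value"],
                         res["testable"], res["n_used"])
                    )
        variants = pd.DataFrame(
            variant_rows,
            columns=["kind", "gene", "radiomic_feature", "coefficient", "p_value",
                     "testable", "n_used"],
        )
        testable = variants["testable"]
        adj = np.full(len(variants), np.nan)
        if testable.any():
            adj[testable.to_numpy()] = assoc.bh_adjust(
                variants.loc[testable, "p_value"].to_numpy()
            )
        variants["adjusted_p"] = adj
        _write_tsv(variants, outdir / "variant_associations.tsv")
        record("variant_associations", outdir / "variant_associations.tsv")

        surv = cohort.survival.copy()
        surv["group"] = clusters.reindex(surv["patient_id"]).to_numpy()
        km = assoc.km_logrank(surv)
        km["groups"] = {int(g): s for g, s in km["groups"].items()}
        _write_tsv(surv, outdir / "survival_by_cluster.tsv")
        record("survival_by_cluster", outdir / "survival_by_cluster.tsv")
        manifest["stages"]["associate"] = {
            "n_pathway_hits": int(len(pathway_screen)),
            "n_pathway_hits_adj": int((pathway_screen["adjusted_p"] <= config.adj_p_max).sum()),
            "n_enriched_sets": int((ora["adjusted_p"] <= config.adj_p_max).sum()),
            "n_variant_hits_adj": int(
                (variants["adjusted_p"].dropna() <= config.adj_p_max).sum()
            ),
            "n_untestable_variants": int((~variants["testable"]).sum()),
            "survival": km,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    if "report" in config.stages:
        text = report(manifest)
        (outdir / "report.md").write_text(text)
    return manifest


def report(manifest: dict) -> str:
    """Render a human-readable run summary from a manifest."""
    lines = ["# Radiogenomic pipeline report", ""]
    lines.append(f"Seed: {manifest.get('seed')}")
    stages = manifest.get("stages", {})
    missing = [s for s in ("extract", "cluster", "signatures", "associate")
               if s not in stages]
    if missing:
        lines.append(f"Missing stage outputs: {', '.join(missing)}")
    if "extract" in stages:
        ex = stages["extract"]
        lines += [
            "",
            "## Radiomic matrix",
            f"- {ex['n_patients']} patients x {ex['n_features']} features "
            f"({ex['n_patients'] * ex['n_features']} values, {ex['n_missing']} missing)",
        ]
    if "cluster" in stages:
        cl = stages["cluster"]
        sizes = ", ".join(f"cluster {k}: n={v}" for k, v in cl["cluster_sizes"].items())
        lines += [
            "",
            "## Consensus clusters",
            f"- selected k = {cl['k_selected']} (used k = {cl['k_used']})",
            f"- {sizes}",
            "- PAC per k: "
            + ", ".join(f"{k}: {v:.3f}" for k, v in cl["pac_curve"].items()),
        ]
    if "signatures" in stages:
        sg = stages["signatures"]
        lines += [
            "",
            "## Transcriptomic signatures",
            f"- ClaNC signature: {sg['clanc_genes_per_class']} genes per class",
            f"- ssGSEA scored {sg['n_gene_sets']} gene sets",
        ]
    if "associate" in stages:
        asx = stages["associate"]
        lines += [
            "",
            "## Associations",
            f"- Spearman screen hits (|rho| and p thresholds): {asx['n_pathway_hits']}"
            f" ({asx['n_pathway_hits_adj']} at adjusted p threshold)",
            f"- enriched gene sets (ORA, adjusted p): {asx['n_enriched_sets']}",
            f"- mutation/CNV regression hits (adjusted p): {asx['n_variant_hits_adj']}"
            f" ({asx['n_untestable_variants']} untestable records)",
        ]
        km = asx.get("survival", {})
        if km:
            lines += ["", "## Survival by cluster"]
            for g, s in km.get("groups", {}).items():
                lines.append(
                    f"- {g}: n={s['n']}, events={s['events']}, "
                    f"median {s['median']:.1f} months "
                    f"(95% CI {s['ci_low']:.1f}-{s['ci_high']:.1f})"
                )
            lines.append(
                f"- log-rank chi-square {km['logrank_stat']:.2f}, p = {km['logrank_p']:.3g}"
            )
    if not lines[-1] == "":
        lines.append("")
    return "\n".join(lines)
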