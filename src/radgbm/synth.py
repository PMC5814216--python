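"""Synthetic radiogenomic cohort generator with known ground truth.

Emulates a 65-patient glioblastoma cohort in which three latent subtypes are
expressed jointly across every data channel the downstream pipeline consumes:

* imaging — nested tumor geometry (contrast-enhancing sphere inside a larger
  FLAIR-hyperintense ellipsoid, with a necrotic core and a vessel rod to
  exercise mask subtraction), DWI at b = 0/1000 s/mm^2 around a planted ADC
  map, and a DSC bolus-passage time series built from planted per-voxel
  gamma-variate parameters;
* transcriptome — log-scale expression with disjoint marker-gene blocks
  shifted per subtype;
* genome — sparse per-gene Bernoulli mutations and Gaussian log2 copy-number
  around subtype-specific means;
* outcome — exponential survival with subtype-specific hazards and
  independent uniform censoring.

The three default profiles mimic the qualitative radiology of the GBM
transcriptional subtypes: a hyperperfused/low-ADC profile (mesenchymal-like,
worst prognosis), a hypoperfused/high-ADC profile, and an intermediate
profile with the largest tumor volume. Their displacements live along three
different feature families (perfusion, diffusion, size) with comparable
standardized magnitudes, so no pair of subtypes is a priori closer than any
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import DynamicSeries, gamma_variate, _cumtrapz
from .radiomics import ROIMask

__all__ = [
    "GammaParams",
    "SubtypeProfile",
    "DscParams",
    "CohortConfig",
    "PatientImaging",
    "GroundTruth",
    "SyntheticCohort",
    "default_profiles",
    "default_config",
    "simulate_cohort",
    "simulate_patient_imaging",
    "simulate_dwi_pair",
    "simulate_dsc_series",
    "simulate_expression",
    "simulate_mutations",
    "simulate_cnv",
    "simulate_survival",
    "make_gene_sets",
]


@dataclass(frozen=True)
class GammaParams:
    """Gamma-variate bolus parameters of one tissue class."""

    k_amp: float
    t0: float
    alpha_g: float
    beta_g: float

    def __post_init__(self):
        if self.k_amp < 0 or self.alpha_g <= 0 or self.beta_g <= 0 or self.t0 < 0:
            raise ValueError(f"invalid gamma-variate parameters {self}")


@dataclass
class SubtypeProfile:
    """Generative description of one latent tumor subtype."""

    name: str
    prevalence: float
    perfusion_params: dict  # tissue -> GammaParams; tissues: enhancing/edema/normal
    adc_mean: float  # mm^2/s inside enhancing tumor
    tumor_radius_mm: float  # radius of the enhancing sphere
    marker_block: list  # gene ids up-shifted in this subtype
    expression_delta: float  # log2 mean shift of the marker block
    mutation_rates: dict  # gene -> Bernoulli probability
    cnv_segments: dict  # gene -> log2 copy-number mean
    hazard: float  # exponential survival rate, 1/month

    def validate(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"profile {self.name}: prevalence outside [0,1]")
        if self.adc_mean <= 0:
            raise ValueError(f"profile {self.name}: adc_mean must be positive")
        if self.tumor_radius_mm <= 0:
            raise ValueError(f"profile {self.name}: tumor_radius_mm must be positive")
        if self.hazard <= 0:
            raise ValueError(f"profile {self.name}: hazard must be positive")
        for tissue in ("enhancing", "edema", "normal"):
            if tissue not in self.perfusion_params:
                raise ValueError(f"profile {self.name}: missing {tissue} perfusion params")


@dataclass(frozen=True)
class DscParams:
    tr: float = 1.72  # s
    te: float = 0.035  # s
    n_timepoints: int = 50
    s0: float = 100.0

    def __post_init__(self):
        if self.n_timepoints < 10:
            raise ValueError("dsc_params: need >=10 timepoints")
        if self.tr <= 0 or self.te <= 0 or self.s0 <= 0:
            raise ValueError("dsc_params: TR, TE, S0 must be positive")


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 65
    profiles: list = field(default_factory=lambda: default_profiles())
    grid_shape: tuple = (32, 32, 32)
    voxel_spacing: tuple = (2.0, 2.0, 5.0)  # mm
    dsc_params: DscParams = field(default_factory=DscParams)
    b_values: tuple = (0.0, 1000.0)  # s/mm^2
    noise_sd: dict = field(
        default_factory=lambda: {
            "dsc": 1.0,  # signal units (S0 = 100)
            "dwi": 5.0,  # signal units (S0 = 1000)
            "adc_voxel": 8e-5,  # mm^2/s voxelwise ADC texture
            "k_voxel": 0.15,  # lognormal sd of voxelwise amplitude jitter
            "patient_perfusion": 0.13,  # lognormal sd of per-patient amplitude
            "patient_adc": 0.06,
            "patient_radius": 0.10,
        }
    )
    n_genes: int = 1000
    expression_baseline: float = 3.0  # log2 units
    expression_noise_sd: float = 1.0
    censoring_rate: float = 0.292  # 1 - 0.708 expired
    seed: int = 0

    def validate(self):
        if self.n_patients < len(self.profiles):
            raise ValueError("n_patients: fewer patients than profiles")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing: all spacings must be positive")
        prev = sum(p.prevalence for p in self.profiles)
        if abs(prev - 1.0) > 1e-9:
            raise ValueError(f"profiles: prevalences sum to {prev}, expected 1")
        blocks = [set(p.marker_block) for p in self.profiles]
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                if blocks[i] & blocks[j]:
                    raise ValueError("profiles: marker blocks must be disjoint")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate: must be in [0, 1)")
        if self.n_genes < sum(len(b) for b in blocks):
            raise ValueError("n_genes: smaller than the union of marker blocks")
        for p in self.profiles:
            p.validate()


@dataclass
class PatientImaging:
    """All simulated volumes and masks for one subject, on a shared grid."""

    patient_id: str
    t1ce: np.ndarray
    t2flair: np.ndarray
    dwi_b0: np.ndarray
    dwi_b1000: np.ndarray
    b_values: tuple
    dsc: DynamicSeries
    rois: dict  # t1ce / t2flair / necrosis / vessels / reference -> ROIMask
    spacing: tuple


@dataclass
class GroundTruth:
    subtype_labels: pd.Series  # patient_id -> profile name
    voxel_params: dict  # patient_id -> dict of planted tissue-level parameters
    marker_genes: dict  # profile name -> list of genes
    true_hazards: dict  # profile name -> rate


@dataclass
class SyntheticCohort:
    patients: list
    expression: pd.DataFrame  # genes x patients, log2 scale
    mutations: pd.DataFrame  # genes x patients, 0/1
    cnv: pd.DataFrame  # genes x patients, log2 copy number
    survival: pd.DataFrame  # patient_id, time, event, group
    truth: GroundTruth
    gene_sets: dict  # set name -> list of genes


_NORMAL_PERFUSION = GammaParams(k_amp=7.0, t0=15.0, alpha_g=2.0, beta_g=2.0)
MUTATION_PANEL = [
    "EGFR", "NF1", "PTEN", "TP53", "IDH1", "ATRX",
    "PDGFRA", "RB1", "PIK3CA", "CDKN2A", "MDM2", "CDK4",
]
_BACKGROUND_MUTATION_RATE = 0.05


def _marker_block(start: int, size: int = 30) -> list:
    return [f"G{i:04d}" for i in range(start, start + size)]


def default_profiles() -> list:
    """The three default subtypes (see module docstring for rationale)."""
    normal = _NORMAL_PERFUSION
    # amplitude derived from a target CBV ratio to normal tissue, so the
    # blood-volume contrast is controlled independently of the transit time:
    # CBV = K * beta^(alpha+1) * Gamma(alpha+1), normal CBV = 7 * 2^3 * 2 = 112
    cbv_normal = 112.0

    def mk(cbv_ratio, beta):
        k = cbv_ratio * cbv_normal / (beta**3 * 2.0)  # alpha fixed at 2
        return GammaParams(k_amp=k, t0=15.0, alpha_g=2.0, beta_g=beta)
    # Axes are balanced so that no pair of subtypes is a priori closer than
    # any other in standardized feature space: hyper and hypo sit at opposite
    # ends of the perfusion/diffusion axes while sharing a short transit
    # time and small volume; the bulky subtype is intermediate on
    # perfusion/diffusion but owns the transit-time and volume axes.
    return [
        SubtypeProfile(
            name="hyperperfused",
            prevalence=0.35,
            perfusion_params={"enhancing": mk(2.2, 2.15), "edema": mk(1.5, 2.15), "normal": normal},
            adc_mean=1.00e-3,
            tumor_radius_mm=8.0,
            marker_block=_marker_block(0),
            expression_delta=2.0,
            mutation_rates={"NF1": 0.45, "PTEN": 0.35, "TP53": 0.30},
            cnv_segments={"NF1": -0.8, "CDKN2A": -0.8},
            hazard=np.log(2) / 9.5,
        ),
        SubtypeProfile(
            name="hypoperfused",
            prevalence=0.30,
            perfusion_params={"enhancing": mk(1.0, 2.15), "edema": mk(1.0, 2.15), "normal": normal},
            adc_mean=1.55e-3,
            tumor_radius_mm=8.0,
            marker_block=_marker_block(30),
            expression_delta=2.0,
            mutation_rates={"TP53": 0.50, "IDH1": 0.30, "PDGFRA": 0.25, "ATRX": 0.30},
            cnv_segments={"PDGFRA": 0.8, "CDK4": 0.6},
            hazard=np.log(2) / 17.0,
        ),
        SubtypeProfile(
            name="bulky-intermediate",
            prevalence=0.35,
            perfusion_params={"enhancing": mk(1.8, 2.9), "edema": mk(1.45, 2.9), "normal": normal},
            adc_mean=1.20e-3,
            tumor_radius_mm=12.5,
            marker_block=_marker_block(60),
            expression_delta=2.0,
            mutation_rates={"EGFR": 0.60, "PTEN": 0.25},
            cnv_segments={"EGFR": 1.2, "CDKN2A": -1.0},
            hazard=np.log(2) / 13.0,
        ),
    ]


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    cfg = CohortConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# imaging primitives


def simulate_dwi_pair(adc_truth, s0, b_values=(0.0, 1000.0), noise_sd=0.0, rng=None):
    """Two DWI volumes S_b = s0 * exp(-b * ADC), with additive Gaussian noise.

    With ``noise_sd=0`` the pair inverts exactly under ``compute_adc``.
    """
    adc_truth = np.asarray(adc_truth, dtype=float)
    if np.any(adc_truth < 0):
        raise ValueError("adc_truth must be non-negative everywhere")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    rng = np.random.default_rng(rng)
    vols = []
    for b in b_values:
        s = s0 * np.exp(-b * adc_truth)
        if noise_sd > 0:
            s = s + rng.normal(0.0, noise_sd, size=s.shape)
            s = np.maximum(s, 1e-3)  # keep log-ratio defined
        vols.append(s)
    return tuple(vols)


def simulate_dsc_series(
    true_params: dict,
    dsc_params: DscParams = DscParams(),
    recirculation: bool = False,
    leakage_k2: float = 0.0,
    noise_sd: float = 0.0,
    baseline_window: slice | None = None,
    rng=None,
) -> DynamicSeries:
    """A DSC signal series from planted per-voxel gamma-variate parameters.

    ``true_params`` holds arrays ``k_amp, t0, alpha_g, beta_g`` of a common
    spatial shape. The relaxation curve is the first-pass gamma variate,
    plus an optional delayed/broadened recirculation bump, minus an optional
    ``leakage_k2 * cumint(mean first-pass curve)`` T1-leakage droop; the
    signal is ``S0 * exp(-TE * dR2*)``. The noiseless series is exactly
    invertible by ``signal_to_relaxation``.
    """
    k = np.asarray(true_params["k_amp"], dtype=float)
    t0 = np.broadcast_to(np.asarray(true_params["t0"], dtype=float), k.shape)
    al = np.broadcast_to(np.asarray(true_params["alpha_g"], dtype=float), k.shape)
    be = np.broadcast_to(np.asarray(true_params["beta_g"], dtype=float), k.shape)
    times = np.arange(dsc_params.n_timepoints) * dsc_params.tr
    horizon = times[-1]
    active = k > 0
    if np.any(active):
        needed = (t0 + 5.0 * al * be)[active].max()
        if needed > horizon:
            raise ValueError(
                f"time window too short: need {needed:.1f}s, have {horizon:.1f}s"
            )
    shape = k.shape
    act = active.reshape(-1)
    kf, t0f, alf, bef = (x.reshape(-1) for x in (k, t0, al, be))
    # bolus curves only where amplitude is non-zero; elsewhere the signal is flat
    curves = np.zeros((k.size, len(times)))
    if act.any():
        curves[act] = gamma_variate(
            times[None, :], kf[act, None], t0f[act, None], alf[act, None], bef[act, None]
        )
        if recirculation:
            curves[act] += gamma_variate(
                times[None, :],
                0.15 * kf[act, None],
                (t0f + 2.0 * alf * bef)[act, None],
                alf[act, None],
                (2.0 * bef)[act, None],
            )
        if leakage_k2 != 0.0:
            ref = curves[act].mean(axis=0)
            curves[act] -= leakage_k2 * _cumtrapz(ref, times)[None, :]
    signal = dsc_params.s0 * np.exp(-dsc_params.te * curves)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        noise = rng.standard_normal(signal.shape, dtype=np.float32) * noise_sd
        signal = np.maximum(signal + noise, 1e-3)
    data = signal.reshape(shape + (len(times),))
    data = np.moveaxis(data, -1, 0)  # time-first
    if baseline_window is None:
        t0_min = float(t0[active].min()) if np.any(active) else times[len(times) // 4]
        n_base = max(2, int(t0_min / dsc_params.tr) - 1)
        baseline_window = slice(0, n_base)
    return DynamicSeries(data=data, tr=dsc_params.tr, te=dsc_params.te,
                         baseline_window=baseline_window)


# --------------------------------------------------------------------------
# geometry


def _ellipsoid_mask(grid_shape, spacing, center_mm, radii_mm) -> np.ndarray:
    coords = [np.arange(n) * d for n, d in zip(grid_shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    rx, ry, rz = radii_mm
    cx, cy, cz = center_mm
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0


def simulate_patient_imaging(config: CohortConfig, profile: SubtypeProfile,
                             patient_id: str, rng) -> tuple:
    """One subject's volumes, masks and the planted voxel-level truth.

    Returns ``(PatientImaging, truth_dict)`` where the truth dict records
    the jittered tissue-level parameters and the planted ADC map.
    """
    ns = config.noise_sd
    shape = config.grid_shape
    spacing = config.voxel_spacing
    fov = [n * d for n, d in zip(shape, spacing)]

    radius = profile.tumor_radius_mm * rng.lognormal(0.0, ns["patient_radius"])
    center = np.array([fov[0] / 2, fov[1] / 2, fov[2] / 2])
    center[:2] += rng.uniform(-2.0, 2.0, size=2)

    t1_mask = _ellipsoid_mask(shape, spacing, center, (radius, radius, radius))
    t2_radii = (1.6 * radius, 1.6 * radius, 1.25 * radius)
    t2_mask = _ellipsoid_mask(shape, spacing, center, t2_radii) | t1_mask
    necrosis = _ellipsoid_mask(shape, spacing, center, (0.4 * radius,) * 3)
    vessels = np.zeros(shape, dtype=bool)
    vx = int(round((center[0] + 0.8 * radius) / spacing[0]))
    vy = int(round(center[1] / spacing[1]))
    vz = int(round(center[2] / spacing[2]))
    if 0 <= vx < shape[0]:
        vessels[vx, max(vy - 1, 0): vy + 1, max(vz - 1, 0): vz + 2] = True
        vessels &= t2_mask
    reference = np.zeros(shape, dtype=bool)
    reference[10:22, 10:22, 3:6] = True  # normal tissue, axially clear of tumor

    # planted ADC: normal background, subtype-specific tumor core, edema between
    adc_patient = profile.adc_mean * rng.lognormal(0.0, ns["patient_adc"])
    adc = np.full(shape, 0.80e-3)
    adc[t2_mask] = 0.5 * (adc_patient + 0.80e-3)  # edema: halfway to normal
    adc[t1_mask] = adc_patient
    adc = np.maximum(adc + rng.normal(0.0, ns["adc_voxel"], size=shape), 1e-5)
    dwi_b0, dwi_b1000 = simulate_dwi_pair(
        adc, s0=1000.0, b_values=config.b_values, noise_sd=ns["dwi"], rng=rng
    )

    # planted perfusion: tissue-level params with per-patient and per-voxel jitter
    amp_jitter = rng.lognormal(0.0, ns["patient_perfusion"])
    t0_jitter = rng.uniform(-1.0, 1.0)
    tissue_params = {}
    for tissue in ("normal", "edema", "enhancing"):
        base = profile.perfusion_params[tissue]
        tissue_params[tissue] = GammaParams(
            k_amp=base.k_amp * amp_jitter,
            t0=base.t0 + t0_jitter,
            alpha_g=base.alpha_g,
            beta_g=base.beta_g,
        )
    k_map = np.zeros(shape)
    t0_map = np.zeros(shape)
    al_map = np.full(shape, 2.0)
    be_map = np.full(shape, 2.0)
    active = t2_mask | reference
    for tissue, mask in (
        ("normal", reference & ~t2_mask),
        ("edema", t2_mask & ~t1_mask),
        ("enhancing", t1_mask),
    ):
        p = tissue_params[tissue]
        k_map[mask] = p.k_amp
        t0_map[mask] = p.t0
        al_map[mask] = p.alpha_g
        be_map[mask] = p.beta_g
    k_map[active] *= rng.lognormal(0.0, ns["k_voxel"], size=int(active.sum()))

    dsc = simulate_dsc_series(
        {"k_amp": k_map, "t0": t0_map, "alpha_g": al_map, "beta_g": be_map},
        dsc_params=config.dsc_params,
        noise_sd=ns["dsc"],
        baseline_window=slice(0, 7),
        rng=rng,
    )

    t1ce = np.where(t1_mask & ~necrosis, 200.0, 100.0)
    t2flair = np.where(t2_mask, 180.0, 100.0)
    patient = PatientImaging(
        patient_id=patient_id,
        t1ce=t1ce,
        t2flair=t2flair,
        dwi_b0=dwi_b0.astype(np.float32),
        dwi_b1000=dwi_b1000.astype(np.float32),
        b_values=config.b_values,
        dsc=DynamicSeries(dsc.data.astype(np.float32), dsc.tr, dsc.te, dsc.baseline_window),
        rois={
            "t1ce": ROIMask(t1_mask, "T1CE", spacing),
            "t2flair": ROIMask(t2_mask, "T2FLAIR", spacing),
            "necrosis": ROIMask(necrosis, "T1CE", spacing),
            "vessels": ROIMask(vessels, "T1CE", spacing),
            "reference": ROIMask(reference, "T1CE", spacing),
        },
        spacing=spacing,
    )
    truth = {
        "radius_mm": radius,
        "adc_tumor": adc_patient,
        "tissue_params": tissue_params,
        "adc_map": adc.astype(np.float32),
    }
    return patient, truth


# --------------------------------------------------------------------------
# omics and outcome


def _gene_universe(n_genes: int) -> list:
    return [f"G{i:04d}" for i in range(n_genes)]


def simulate_expression(labels, profiles, n_genes=1000, baseline_mean=3.0,
                        noise_sd=1.0, seed=None) -> pd.DataFrame:
    """Log2-scale genes x patients matrix with marker blocks shifted per subtype.

    Every gene carries a patient-independent baseline offset (gene-to-gene
    heterogeneity); genes in a subtype's marker block gain that profile's
    ``expression_delta`` in that subtype's patients only.
    """
    labels = pd.Series(labels)
    by_name = {p.name: p for p in profiles}
    blocks = [set(p.marker_block) for p in profiles]
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if blocks[i] & blocks[j]:
                raise ValueError("marker blocks overlap")
    genes = _gene_universe(n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for p in profiles:
        missing = [g for g in p.marker_block if g not in gene_idx]
        if missing:
            raise ValueError(f"marker genes outside the gene universe: {missing[:5]}")
    rng = np.random.default_rng(seed)
    gene_offsets = rng.normal(0.0, 1.0, size=n_genes)
    values = baseline_mean + gene_offsets[:, None] + rng.normal(
        0.0, noise_sd, size=(n_genes, len(labels))
    )
    for j, pid in enumerate(labels.index):
        prof = by_name[labels.loc[pid]]
        rows = [gene_idx[g] for g in prof.marker_block]
        values[rows, j] += prof.expression_delta
    return pd.DataFrame(values, index=genes, columns=list(labels.index))


def simulate_mutations(labels, profiles, seed=None) -> pd.DataFrame:
    """Binary somatic-mutation matrix over the driver panel (genes x patients)."""
    labels = pd.Series(labels)
    by_name = {p.name: p for p in profiles}
    rng = np.random.default_rng(seed)
    out = np.zeros((len(MUTATION_PANEL), len(labels)), dtype=int)
    for j, pid in enumerate(labels.index):
        rates = by_name[labels.loc[pid]].mutation_rates
        for i, gene in enumerate(MUTATION_PANEL):
            p = rates.get(gene, _BACKGROUND_MUTATION_RATE)
            out[i, j] = int(rng.random() < p)
    return pd.DataFrame(out, index=MUTATION_PANEL, columns=list(labels.index))


def simulate_cnv(labels, profiles, sd=0.25, seed=None) -> pd.DataFrame:
    """Gene-level log2 copy-number matrix around subtype-specific means."""
    labels = pd.Series(labels)
    by_name = {p.name: p for p in profiles}
    rng = np.random.default_rng(seed)
    out = np.zeros((len(MUTATION_PANEL), len(labels)))
    for j, pid in enumerate(labels.index):
        segs = by_name[labels.loc[pid]].cnv_segments
        for i, gene in enumerate(MUTATION_PANEL):
            out[i, j] = rng.normal(segs.get(gene, 0.0), sd)
    return pd.DataFrame(out, index=MUTATION_PANEL, columns=list(labels.index))


def simulate_survival(labels, profiles, censoring_rate=0.0, seed=None) -> pd.DataFrame:
    """Exponential survival times (months) with independent censoring.

    The censoring time is an independent exponential with rate
    ``lam * c/(1-c)`` (c = ``censoring_rate``), so each patient is censored
    with probability exactly c while censoring stays non-informative and
    Kaplan-Meier estimates remain unbiased. The observed time is
    min(event, censor).
    """
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must be in [0, 1)")
    labels = pd.Series(labels)
    by_name = {p.name: p for p in profiles}
    for p in profiles:
        if p.hazard <= 0:
            raise ValueError(f"profile {p.name}: hazard must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in labels.index:
        lam = by_name[labels.loc[pid]].hazard
        t_event = rng.exponential(1.0 / lam)
        if censoring_rate > 0:
            lam_c = lam * censoring_rate / (1.0 - censoring_rate)
            t_cens = rng.exponential(1.0 / lam_c)
        else:
            t_cens = np.inf
        event = t_event <= t_cens
        rows.append((pid, min(t_event, t_cens), bool(event), labels.loc[pid]))
    df = pd.DataFrame(rows, columns=["patient_id", "time", "event", "group"])
    df["time"] = np.maximum(df["time"], 1e-6)
    return df


def make_gene_sets(profiles, n_genes=1000, n_random_sets=20, set_size=30, seed=None) -> dict:
    """Marker-block pathways plus random decoy sets, GMT-style."""
    rng = np.random.default_rng(seed)
    genes = _gene_universe(n_genes)
    sets = {f"PATHWAY_{p.name.upper().replace('-', '_')}": list(p.marker_block)
            for p in profiles}
    for i in range(n_random_sets):
        sets[f"RANDOM_SET_{i:02d}"] = sorted(
            rng.choice(genes, size=set_size, replace=False).tolist()
        )
    return sets


# --------------------------------------------------------------------------
# cohort assembly


def draw_labels(config: CohortConfig, rng) -> pd.Series:
    """Subtype labels with the configured composition, in random order.

    Prevalences are realised exactly (largest-remainder apportionment of
    n_patients) rather than by iid draws: the generator's job is to plant a
    cohort with the stated composition, and iid sampling would add a
    composition lottery on top of every downstream analysis.
    """
    names = [p.name for p in config.profiles]
    prev = np.array([p.prevalence for p in config.profiles], dtype=float)
    prev = prev / prev.sum()
    n = config.n_patients
    counts = np.floor(prev * n).astype(int)
    remainder = prev * n - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    lab = np.repeat(names, counts)
    rng.shuffle(lab)
    ids = [f"P{i:03d}" for i in range(n)]
    return pd.Series(lab, index=ids, name="subtype")


def simulate_cohort(config: CohortConfig | None = None, keep_imaging: bool = True) -> SyntheticCohort:
    """Generate the full multi-modal cohort; deterministic given config.seed."""
    if config is None:
        config = default_config()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients + 5)
    labels = draw_labels(config, np.random.default_rng(children[0]))
    by_name = {p.name: p for p in config.profiles}

    patients = []
    voxel_params = {}
    for i, pid in enumerate(labels.index):
        rng = np.random.default_rng(children[1 + i])
        patient, truth = simulate_patient_imaging(config, by_name[labels.loc[pid]], pid, rng)
        voxel_params[pid] = truth
        if keep_imaging:
            patients.append(patient)

    n = config.n_patients
    expression = simulate_expression(
        labels, config.profiles, n_genes=config.n_genes,
        baseline_mean=config.expression_baseline,
        noise_sd=config.expression_noise_sd, seed=children[n + 1],
    )
    mutations = simulate_mutations(labels, config.profiles, seed=children[n + 2])
    cnv = simulate_cnv(labels, config.profiles, seed=children[n + 3])
    survival = simulate_survival(
        labels, config.profiles, censoring_rate=config.censoring_rate,
        seed=children[n + 4],
    )
    gene_sets = make_gene_sets(config.profiles, n_genes=config.n_genes, seed=config.seed)
    truth = GroundTruth(
        subtype_labels=labels,
        voxel_params=voxel_params,
        marker_genes={p.name: list(p.marker_block) for p in config.profiles},
        true_hazards={p.name: p.hazard for p in config.profiles},
    )
    return SyntheticCohort(patients, expression, mutations, cnv, survival, truth, gene_sets)
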