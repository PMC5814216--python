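# Methods

`radgbm` re-implements a radiogenomic analysis of glioblastoma as a tested
pipeline: physiologic MR maps are computed per patient, 82 first-order
radiomic features are extracted from two tumor ROIs, patients are grouped by
consensus clustering of the standardized feature matrix, and the resulting
imaging subtypes are characterised against transcriptome, mutation/CNV and
survival data. Because the cohort this style of analysis was developed on is
not publicly available, the package ships a synthetic cohort generator with
known ground truth; every downstream stage is validated against what the
generator planted.

## Physiologic maps

**ADC.** The apparent diffusion coefficient is computed from a two-point DWI
acquisition as `ADC = ln(S_b0 / S_b1000) / b` (mm²/s, b in s/mm²). Noise can
push `S_b1000` above `S_b0`; such voxels are clamped to 0 and counted. The
map is reported relative to normal tissue (rADC, below).

**DSC perfusion.** The dynamic susceptibility signal is converted to the
relaxation-rate change `ΔR2*(t) = −ln(S(t)/S_base)/TE`, with `S_base` the
mean over a pre-bolus baseline window. The first-pass bolus is modelled by
the gamma-variate function

    C(t) = K (t − t0)^α exp(−(t − t0)/β),   t > t0,

fitted per voxel by least squares. To avoid recirculation the fit window
ends at the first post-peak sample below 20% of the peak. Initialisation is
by log-linearisation (given t0, `ln C` is linear in `ln K`, α, 1/β; t0
starts at the last sample before the curve exceeds 10% of peak), followed by
a Levenberg–Marquardt refinement with box constraints (K > 0, α ∈ [1e-3,
50], β ∈ [1e-3, 1e4], 0 ≤ t0 < t_peak). The refinement is vectorised across
all voxels of a patient (batched 4×4 normal equations, per-voxel damping and
an active set), which makes whole-cohort fitting a few seconds per subject;
`scipy.optimize.least_squares` on single curves serves as an independent
cross-check in the tests. A voxel is flagged non-converged when its peak
fails an SNR gate (peak ≥ 3× a noise floor estimated from the baseline
scatter or, for curves with no flat baseline, from second differences) or
when the fitted model explains less than half of the windowed signal energy;
such voxels are excluded from downstream histograms.

Perfusion indices are defined in closed form on the fitted curve — no
arterial input function or deconvolution is used, matching the *relative*
units of the feature registry:

* CBV = K β^(α+1) Γ(α+1) (area under the curve),
* MTT = β (α + 1) (first moment about t0 over area, seconds),
* TTP = t0 + αβ (time of peak, seconds),
* CBF = CBV / MTT (central volume principle).

**Leakage correction.** Contrast extravasation adds a T1-driven droop so the
tail of `ΔR2*` does not return to baseline. The two-parameter linear model
(Boxerman-style) `curve ≈ k1·ref − k2·∫ref` is fitted against the
whole-tissue mean curve; the corrected curve adds back `k2·∫ref`. With no
leak the estimated k2 is ~0 and the correction is a no-op.

**Relative normalisation.** CBV, CBF and ADC maps are divided by their
median over a user-supplied normal-tissue reference mask (the generator
always emits one), giving rCBV/rCBF/rADC with reference median exactly 1.
The median is used rather than the mean for robustness to fit failures.

## Radiomic features

The registry holds exactly 82 named features: 12 size features (voxel
count, total in-plane area in cm², volume in mL — on the contrast-enhancing
T1CE ROI and the T2FLAIR hyperintensity ROI, plus the same three
restricted to ADC-valid voxels of each ROI) and 70 histogram features
(mean, median, SD, 5th/95th percentiles and quartiles of rCBF, rCBV, MTT,
TTP and rADC over each ROI). Naming follows the `{MAP}n{T1|T2}_{STAT}`
convention of the clinical registry the table mirrors (one historical typo,
`T2FALIR_VOL`, is preserved so exported tables are column-compatible).

Conventions chosen where the registry is silent: "area" is the total
in-plane area summed over slices (count·dx·dy), so volume = area·dz for
uniform slices; percentiles interpolate linearly between order statistics
(inclusive endpoints); SD uses the n−1 denominator; the ADC-restricted size
rows count ROI voxels with a valid ADC value, which differs from the plain
mask rows only when voxels were invalidated. Necrotic-core and vessel masks
are subtracted from both ROIs before extraction (set difference; an ROI that
empties is an error). Voxels with failed perfusion fits are excluded
list-wise per feature family, with the missing fraction flagged when it
exceeds 50%.

## Consensus subtypes

Features are z-scored across patients (constant columns dropped with a
warning). Patient similarity is the Pearson correlation of standardized
feature vectors. Consensus clustering draws 500 resamples of 80% of
patients without replacement, clusters each resample at every candidate
k ∈ {2..6}, and records consensus(i, j) = co-clusterings / co-samplings.
Final labels at each k cut an average-linkage tree on `1 − consensus`.

The per-resample clusterer is k-means with a **single random
initialisation**, run on row-standardized patient vectors; in that space
squared Euclidean distance is proportional to `1 − r`, so this is k-means
under Pearson geometry. The weakness of a single init is deliberate: the
consensus machinery infers the cluster count from how *unstable* a
mismatched k is. A deterministic agglomerative clusterer (available as
`inner="average"`) resolves k=2 on three-cluster data the same way in every
resample, making the over-merged solution look perfectly stable and
defeating stability-based selection of k; with single-init k-means the
2-cut of three clusters flips between the possible merges and the ambiguity
is visible in the consensus matrix.

The cluster count is selected by the proportion of ambiguous clustering,
PAC(k) = fraction of off-diagonal consensus entries in (0.1, 0.9); the
smallest k attains ties. On the default synthetic cohort this yields
PAC(3) = 0 with PAC(2) ≈ 0.1–0.5 and PAC(k ≥ 4) ≈ 0.15–0.22, selecting
k = 3. A fixed-k mode is available in the pipeline configuration.

## Transcriptomic machinery

**Units.** RPKM[g,s] = 10⁹·counts/(length·library size); log2(x+1) corrects
the skew (double transformation is refused via a tag on the matrix).

**ClaNC.** For gene g and class c, `d[g,c] = (mean_c − overall mean) /
(m_c (s_g + s0))` with `m_c = sqrt(1/n_c − 1/n)`, pooled within-class SD
`s_g`, and shrinkage offset `s0` = median pooled SD. Genes are assigned
greedily to classes in decreasing |d| under an exact per-class quota, no
gene serving two classes. Prediction is the class minimising the
standardized squared distance over that class's own signature genes (ties:
first class in model order). The signature size is the smallest candidate
attaining the minimum stratified-CV misclassification.

**ssGSEA.** Per sample, genes are ranked by expression descending (ties
broken by gene id). With weights `(N − position)^α` (α = 0.25 by default)
normalised over the gene set, the score is the sum over all ranks of
`P_in − P_out`, where `P_in` is the weighted in-set CDF and `P_out` the
uniform out-of-set ECDF. Scores are rank-based, hence invariant to any
monotone per-sample transformation. Optional min–max normalisation across
the score matrix is off by default.

**ORA.** Over-representation of a gene list in a set is the one-sided
hypergeometric tail P(overlap ≥ observed); the odds ratio uses a 0.5
continuity correction when a 2×2 cell is zero. Multiple sets are adjusted
by Benjamini–Hochberg within the analysis family.

## Association statistics

Spearman screening uses midranks with the t-approximation for p; records
are kept at |rho| > 0.6 and p < 0.05 with BH adjustment computed over all
tested pairs; constant vectors are skipped and counted. The Mann–Whitney U
test is exact (full enumeration) when the combined n ≤ 12 with no ties,
otherwise normal with tie and continuity corrections. Mutation/CNV effects
are ordinary least squares of the phenotype on the indicator, with a
two-sided t-test on the slope; a constant indicator or a binary indicator
with fewer than 3 carriers is reported untestable rather than tested.
Multiple-testing adjustment is BH within each analysis family. Survival is
compared by Kaplan–Meier medians with Greenwood-based CIs (via lifelines)
and the k-group log-rank test.

## Synthetic cohort

The generator plants three latent subtypes jointly across imaging,
expression, mutations/CNV and survival for 65 patients on a 32³ grid with
2×2×5 mm voxels. DSC acquisition constants are TR = 1.72 s, TE = 35 ms, 50
volumes; DWI uses b = 0/1000 s/mm². Tumor geometry is a contrast-enhancing
sphere nested in a FLAIR ellipsoid (in-plane radius 1.6×, axial 1.25×) with
a necrotic core (0.4× radius) and a small vessel rod to exercise mask
subtraction; a normal-tissue reference box sits in axially clear slices.
Normal tissue has CBV 112 (arbitrary units), MTT 6 s, t0 = 15 s, ADC
0.80×10⁻³ mm²/s.

Default profiles (values are ratios to normal CBV, enhancing tissue):

| profile | CBV ratio | β (s) | ADC (10⁻³) | radius (mm) | median OS target |
|---|---|---|---|---|---|
| hyperperfused | 2.2 | 2.15 | 1.00 | 8.0 | 9.5 months |
| hypoperfused | 1.0 | 2.15 | 1.55 | 8.0 | 17 months |
| bulky-intermediate | 1.8 | 2.90 | 1.20 | 12.5 | 13 months |

The hyper- and hypoperfused profiles sit at opposite ends of the
perfusion/diffusion axes while sharing a short transit time and small
volume; the bulky profile is intermediate on perfusion/diffusion and owns
the transit-time and volume axes. This balances the three centered subtype
displacement vectors in standardized feature space (measured norms ≈
7.4/9.9/7.7) so that no pair of subtypes is a priori closer than any other —
the planted structure is three comparable clusters, not a two-level
hierarchy. Prevalences (0.35/0.30/0.35) are realised as an exact cohort
composition (largest-remainder apportionment, shuffled order): the
generator's contract is to plant the stated composition, and iid draws
would add a composition lottery on top of every downstream analysis.

Noise: Gaussian on DSC signal (sd 1 at S0 = 100) and DWI signal (sd 5 at
S0 = 1000); voxel-level lognormal jitter on bolus amplitude (sd 0.15) and
Gaussian ADC texture (sd 8×10⁻⁵); patient-level lognormal jitter on
perfusion amplitude (sd 0.13), ADC (0.06) and radius (0.10); bolus arrival
jitter ±1 s. Expression is Gaussian on the log scale (gene baseline offsets
sd 1, residual sd 1) with disjoint 30-gene marker blocks shifted by +2 per
subtype; gene sets comprise the three marker pathways plus 20 random decoy
sets. Mutations are independent Bernoulli draws over a 12-gene driver panel
with subtype-specific rates (background 0.05); CNV is Gaussian (sd 0.25)
around subtype-specific log2 means. Survival is exponential with
subtype-specific hazards and independent exponential censoring tuned to a 29.2% censoring probability (Kaplan-Meier stays unbiased).

What the generator does **not** emulate: brain anatomy, bias fields,
motion, partial-volume mixtures of subtypes, positional CNV structure,
library-size effects in expression, or informative censoring. Passing
tests therefore demonstrate the *machinery* — map computation, feature
extraction, cluster recovery, signature detection, calibrated tests — under
known ground truth, not performance on clinical data.

## Numerical and design choices

* Gamma-variate fits: tolerance 1e-12 relative cost improvement, ≤60 LM
  iterations; flat or sub-SNR curves return non-converged rather than
  raising; all-zero curves score no indices.
* The DSC fit runs only on voxels inside the FLAIR ROI or the reference
  region; elsewhere there is no bolus to fit and the maps are NaN.
* PAC thresholds (0.1, 0.9); ties in k-selection and in CV-size selection
  break to the smallest candidate; BH caps at 1 and preserves input order.
* Problem sizes in the test and acceptance studies: 65-patient cohorts on
  32³ grids; 500 resamples for the headline consensus run and 150 for the
  20-seed recovery study; 5000 replicates for type-I-error calibration;
  100 replicates for power checks. These sizes keep each study's Monte
  Carlo error well inside the asserted margins.
* All randomness flows from a single seed through `numpy.random.SeedSequence`
  spawns (one child per patient plus one per omics table), so cohorts are
  bitwise reproducible and patient-level simulation is order-independent.

## Known limitations

* Perfusion indices are relative; no AIF means no absolute CBF/CBV, exactly
  as in the registry being mirrored.
* The recirculation guard is a window cutoff, not a second-bolus fit; very
  early recirculation would bias β upward.
* ClaNC's greedy quota assignment is the standard approximation, not an
  optimal balanced selection.
* The Mann–Whitney exact path enumerates all label arrangements and is
  limited to combined n ≤ 12.
* `standardize` drops near-constant columns by a relative tolerance
  (1e-12), which silently removes features that are genuinely constant
  across a cohort.
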