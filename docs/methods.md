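# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `maldilip`. Empirical statements here (recovery rates,
calibration bounds, segmentation agreement) are exactly the ones computed
by the test suite; nothing is claimed beyond what the tests measure.

## Spectrum model and preprocessing

A profile spectrum is a strictly increasing *m/z* axis with non-negative
intensities. The default acquisition model covers *m/z* 100–1200 at 0.01 Da
spacing; peaks are Gaussian with σ(m/z) = m/z / (2.355·R) at a resolving
power R = 15,000, a plausible value for a reflectron TOF at lipid masses.

**SNIP baseline.** The baseline is the fixed point of iterative symmetric
clipping, `b_i(k) = min(v_i, (v_{i−k}+v_{i+k})/2)` for k = 1..K, applied by
default in the log-log-sqrt (LLS) compressed domain and back-transformed.
K defaults to 100 (1 Da reach at the default grid); the imaging path uses
K = 20, matching a "peak width 20" convolution setting. The estimate never
exceeds the input, so the clipped residual is non-negative — a property
the tests assert. Two practical notes: (i) the LLS compression is intended
for spectra with peaks; on a steep peak-free ramp it leaves a visible
residual, so the linear-space variant (`lls=False`) is exposed and used
when the pure clipping behavior is wanted; (ii) baseline subtraction runs
*before* smoothing, because polynomial smoothing of a spiky spectrum rings
below the baseline and the SNIP lower envelope would lock onto those
artificial dips (we measured a ~60% baseline underestimate in that order).

**Smoothing.** Savitzky–Golay, order 3, half-window 5 bins. An 11-bin
window sits near the peak FWHM at the default grid/resolution; wider
windows (e.g. 21 bins) attenuate narrow low-mass peaks more than twofold
and merge neighbors ~0.1 Da apart, which measurably degrades fold-change
recovery. Both parameters are exposed.

**Lock-mass recalibration.** One multiplicative factor per spectrum,
`lock/observed`, from the most intense peak within ±0.5 Da of the lock
mass (PC(34:1) [M+H]⁺ 760.5851 positive, PI(38:4) [M−H]⁻ 885.5499
negative). Multiplicative rather than additive correction was chosen
because TOF calibration errors scale with *m/z* to first order; it also
preserves relative peak spacing exactly. A simulated +300 ppm drift is
reduced below the 0.05% relative-error bound for ≥99% of well-ionized
truth peaks (asserted in the acceptance suite). A spectrum without a
detectable lock peak is left unchanged and flagged, not dropped.

**Alignment and normalization.** Spectra are warped onto the most intense
local maxima of the total average spectrum (monotone piecewise-linear
shift, constant extrapolation beyond the outermost anchors; spectra with
fewer than two matched anchors keep an identity warp with a warning), then
TIC-normalized to unit total intensity. Sum = 1 was chosen as the TIC
target; any constant target differs only by a global scale, to which all
downstream statistics are invariant (asserted).

**Peak detection and feature quantification.** Peaks are local maxima
rising `snr × noise` above the local median, with noise = 1.4826·MAD in
200-bin blocks, linearly interpolated; SNR defaults to 3. Features are
defined once, on the total average spectrum, and each sample contributes
its maximum intensity within ±1·10⁻⁴ (relative) of every consensus
position. Defining features per sample and binning afterwards
(`build_feature_matrix`, greedy single-linkage within 0.05% — also
provided) makes weak peaks flicker in and out of individual replicates
and inflates replicate CVs roughly fivefold; consensus extraction cannot
drop a feature in a subset of samples. The extraction window is
deliberately tighter than the annotation tolerance: it needs to cover
only the post-recalibration apex error, and widening it lets neighboring
peaks bleed into a feature and shear fold changes toward 1.

**Replicate QC.** Per feature, CV = sd/mean across technical replicates of
each biological sample, averaged over samples (cells with zero mean are
excluded and counted); the gate requires mean CV < 0.50. A failed gate
warns and flags but does not abort the run.

## Differential statistics

Lipid intensities are not normal (the Kolmogorov–Smirnov gate against a
normal with sample moments is provided), so group comparison is by rank
tests: two-sided Wilcoxon rank-sum for two groups (exact U distribution
when n₁+n₂ ≤ 12 without ties, otherwise normal approximation with tie and
continuity corrections) and Kruskal–Wallis with tie correction for more
(χ² p by default; exact enumeration over all group assignments available
and intended for total n ≲ 10). Technical replicates are averaged per
biological sample before testing, so n is the number of biological
samples. Fold change is the ratio of group means with a pseudocount of
half the smallest nonzero matrix value; the significance rule is raw
p < α together with the symmetric fold-change criterion
max(FC, 1/FC) > threshold (α and the threshold are per-contrast settings,
typically 0.05 or 0.01 and 2.0). Raw p drives the calls; BH-adjusted
values are reported alongside as a clearly labeled extension. Exact paths
are verified against full enumeration oracles for every configuration
with total n ≤ 8, and the hypergeometric pathway p against subset
enumeration for universes ≤ 12.

Hierarchical clustering uses 1 − Spearman ρ with average linkage
(constant items get undefined correlations set to distance 1, with a
warning); PCA is a column-centered (optionally unit-variance) SVD with
the sign of each component fixed by its largest-|loading| element.

## Imaging

An MSI cube is a pixel grid sharing one *m/z* axis. Ion-density maps sum
intensity within ±0.2 Da of the target (the "minimal interval width");
"medium denoising" is mapped to a 3×3 median filter, which removes
single-pixel speckle (the vendor meaning is undocumented). The skyline
projection is the per-bin maximum over pixels.

Segmentation is bisecting k-means under correlation distance
d(u,v) = 1 − Pearson(u,v) on TIC-normalized pixel spectra: recursively,
the leaf with the largest within-cluster distance sum is split by 2-means
(k-means++ seeding, 10 restarts, best within-distance sum kept,
deterministic given the seed), recording per split the inter-centroid
correlation distance and the number of spectra. Splitting the most
heterogeneous leaf (rather than the largest) matters: on the synthetic
ovary layout, count-based selection cuts the big homogeneous stroma on
noise before the small lumens separate (ARI 0.63 vs 1.00). Stopping is by
leaf count and/or a minimum split distance; recorded distances lie in
[0, 2] but are *not* guaranteed monotone along root-to-leaf paths.
Correlation distance makes the segmentation invariant to per-pixel gain,
as a per-pixel rescaling test asserts.

## Annotation

Observed peaks are matched to theoretical adducted m/z within ±0.05%
**of the theoretical mass** (the observed-based ratio differs in the 4th
decimal); positive mode considers [M+H]⁺, [M+Na]⁺, [M+K]⁺ and negative
mode [M−H]⁻, [M+Cl]⁻, all singly charged, with the charged-species mass
convention (proton 1.007276 Da; chloride 34.969402 Da, electron included).
The reference database has two tiers — a public tier and a
tissue-specific tier of lipids identified in bovine follicular fluid and
cells; when candidates from both tiers match a peak, only tissue-specific
candidates are retained, ordered by |Δm/z|. Ambiguous species ("PC or
PE") are stored as separate records and surface as ranked alternatives.

Isotopologue flagging precedes annotation and is database-free: peak P is
flagged as the +k isotopologue of earlier unflagged peak Q if their
spacing matches k·1.003355 Da within 0.025 Da (absolute — pair spacing
within one spectrum is differential and far more accurate than the
absolute calibration; the window also covers apex quantization on the
0.01 Da grid) and the intensity ratio P/Q stays under a generic-lipid
ceiling 0.011·(m/z/14) + 0.05, a crude carbon-count proxy that only gates
flagging. A +2 flag additionally requires a +1 flag on the same parent:
for CHNOP lipids the M+1 always dominates the M+2, so an isolated 2-Da
spacing is a distinct compound (typically a homolog differing by one
double bond), not an isotopologue. Isotope envelopes themselves come from
nucleon-aggregated convolution of per-element isotope distributions,
normalized to the monoisotopic peak.

On calibrated synthetic cohorts, top-1 annotation accuracy is 100% for
truth peaks that are resolvable — no other truth peak within 0.12 Da, the
effective merge radius after smoothing — and every resolvable, detected
M+1 peak is flagged. Truly isobaric pairs at 0.05% tolerance (e.g. an SM
[M+H]⁺ 4 mDa from a CE [M+K]⁺) are not resolvable by mass alone at TOF
accuracy, by any method.

## Pathway enrichment

For a query of annotated lipids against a pathway membership table:
enrichment factor = hits / (pathway size × query/universe ratio), p-value
= hypergeometric upper tail (one-sided Fisher). The universe size is an
explicit input — published tables print only the ratio, which is why the
bundled summary table for the large-vs-small follicle contrast carries a
shared background rate r ≈ 1/310 recoverable by least squares across its
rows; the membership fixture shipped with the package is synthetic
(placeholder compound identifiers, sizes matching the summary totals).
The topology-based "impact" column is pass-through metadata: computing it
requires a pathway-graph algorithm outside this package's scope.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with full provenance (every peak's lipid, adduct, isotope index and
region recorded):

- **Peaks**: area-normalized Gaussians at each adduct m/z, scaled by
  abundance × adduct weight ([M+H]⁺ 1.0, [M+Na]⁺ 0.3, [M+K]⁺ 0.15;
  [M−H]⁻ 1.0, [M+Cl]⁻ 0.25) × isotope envelope.
- **Nuisance**: exponential-decay chemical baseline (amplitude 5, decay
  300 Da), half-normal additive noise floor (σ 0.05), log-normal
  multiplicative effects — biological CV 30% per sample×lipid, technical
  CV 20% per replicate×lipid, 20% per-spectrum gain — and a uniform
  calibration drift within ±100 ppm (±300 ppm in the calibration tests).
  The biological/technical CVs were set so cohorts sit comfortably inside
  the <50% replicate-CV QC regime, as the real acquisitions did.
- **Designs**: presets `follicle-size` (large vs small follicles, 24
  biological samples per arm, technical triplicates), `ff-fractions`
  (four depleted fluid fractions, n = 6), `ev-types` (cells, apoptotic
  bodies, microvesicles, exosomes, n = 6), `null` (no planted effects).
  Planted two-group contrasts put half the differential lipids up in each
  arm — as in the real tables, where regulation runs in both directions —
  which also keeps group TICs comparable under normalization. Panels
  always include the polarity's lock-mass lipid.
- **MSI**: a 32×32 ovary-like layout (stroma, follicle wall, one large
  and two small lumens), each region a panel sharing a lipid backbone
  plus region-specific species; pixels get per-lipid log-normal factors
  (CV 25%) and the additive floor. The cube *m/z* axis is 400–900 at
  0.1 Da — imaging acquisitions are summarized coarser than profiling.
- A feature-level cohort simulator bypasses the spectral layer for pure
  statistical calibration (e.g. 1000-feature null panels, which could
  not exist as resolvable peaks in one spectrum).

What the simulator does **not** model — and what passing tests therefore
do not show about real data: ionization suppression and matrix effects,
chimeric/overlapping peak shapes beyond simple Gaussian summation,
detector saturation, batch effects, missingness mechanisms other than
falling below the SNR threshold, and biological correlation between
lipids. Recovery figures on synthetic cohorts are upper bounds.

## Problem sizes used by the test suite

Desk-scale versions of the study conditions keep the suite fast while
preserving the contrasts: the spectral end-to-end recovery test runs the
full `follicle-size` design (300 lipids, 50 differential at FC 2.5,
24 + 24 biological samples × 3 replicates on the full 110,001-bin axis);
statistical calibration runs at 300–1000 features; the segmentation
acceptance cube is 32×32 pixels; oracle sweeps cover every test layout
with total n ≤ 8 and hypergeometric tables with universe ≤ 12. A lipid
counts as recovered end-to-end if any of its adduct ions is called
significant — with ~2700 truth peaks in 1100 Da some individual ions are
unavoidably confounded by overlap, including differential lipids of
opposite direction sharing an apex.

## Known limitations

- Singly charged adducts only; no in-source fragments, no MS/MS evidence,
  no retention time; annotation beyond TOF mass accuracy is out of reach.
- The lock-mass model corrects a single multiplicative drift; higher-order
  calibration residuals are left to the alignment warp.
- Exact Kruskal–Wallis enumeration is factorial in total n; it is a
  verification tool, not a large-n method.
- The isotope-flagging ceiling is a heuristic; lipids with unusual
  composition (halogenated, sulfur-rich) need a database-aware envelope.
- imzML input requires the binary `.ibd` companion and is exercised only
  through the optional pyimzml path; the tested cube interface is the
  long-format CSV dialect.
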