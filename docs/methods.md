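# Methods

This note documents the models, numerical choices and limitations behind
`honeyscreen`, in the order the pipeline runs.

## Formula arithmetic and isotope patterns

Molecular formulas are element→count maps over a declared support set
(C, H, N, O, S, P, Cl, Na, K), round-tripping through Hill-order text.
Monoisotopic masses use IUPAC lightest-isotope masses shipped as a
versioned plain-text table (`data/isotopes.tsv`); the [M−H]⁻ ion mass
subtracts a hydrogen atom and adds the electron mass (0.000549 Da) —
without the electron term the ion m/z is wrong in the fourth decimal,
which matters at the 4-d.p. reporting convention of QToF screening work.

Theoretical isotope patterns are computed by polynomial convolution of
per-element isotope distributions, exponentiated per atom count, then
aggregated into nominal-mass-shift peaks (M, M+1, M+2, …) with
abundance-weighted mean masses.  This aggregation matches how centroided
QToF data presents isotopologues; fine structure within a nominal shift
is deliberately not resolved.  Peaks below a prune threshold (default
1e-4 relative to the base peak, applied after normalisation) are
dropped.  For small formulas the convolution is exactly equivalent to
exhaustive isotopologue enumeration; the test suite verifies agreement
to 1e-6 relative abundance for formulas up to 12 atoms.

Pattern agreement is scored two ways on vectors aligned by nominal shift
from the theoretical base mass (peaks missing on either side count as
zero-abundance):

* **dot** — cosine similarity in [0, 1];
* **msigma_like** — 1000 × RMS deviation of base-peak-normalised
  abundances.  The vendor mSigma statistic is proprietary; this
  surrogate is transparent, has the same ordering semantics (lower is
  better), and the conventional ≤ 50 acceptance threshold is applied to
  it.  Surrogate values are not numerically comparable to vendor values.

Mass errors follow the convention measured − theoretical (reported in
mDa and ppm with a shared sign).  Published instrument reports sometimes
use the opposite sign; callers comparing against such sources should
compare magnitudes.

## DIA runs, EICs and peak detection

A run holds two retention-time-ordered centroid spectrum lists: a
low-collision-energy channel (precursor scans, 4 eV) and a
high-collision-energy channel (fragment scans, 25 eV), the structure of
broadband-CID data-independent acquisition.  mzML I/O is self-contained
and centroid-only: the writer emits uncompressed little-endian float64
arrays with standard PSI-MS cvParam accessions, the reader handles
uncompressed or zlib-compressed 32/64-bit floats, assigns channels from
the collision-energy metadata (falling back to ms level) and rejects
profile-mode spectra.  Round trips preserve centroids to float
precision.

EICs sum centroids within a ± tolerance window (default 5 mDa) per
low-energy scan.  Peak detection is a deliberately simple apex/valley
detector — this package does not reproduce published wavelet-based
pickers, and feature tables for chemometrics come from the synthetic
generator or external CSV:

* apices are local maxima; boundaries descend to the surrounding valley
  or to a baseline floor at 0.1 % of the apex height (the floor stops
  the bounds from crawling along flat nonzero baselines);
* noise is 1.4826 × the median absolute deviation of the off-peak
  signal, floored at 1 count; peaks below a signal-to-noise ratio of 3
  are discarded;
* areas are trapezoids over the bounds, in counts × minutes.

Fragment spectra for a peak average the high-energy scans inside the
peak bounds (clustered on the m/z axis at the matching tolerance),
subtract the average of flanking background windows (default 0.2 min per
side, configurable since the appropriate window is scenario-specific)
and clip negatives to zero.

## Screening

**Targets** (reference standard in hand) are confirmed only when all
four criteria hold: |Δt_R| < 0.2 min, precursor mass error < 5 mDa,
isotopic-fit surrogate ≤ 50, and ≥ 2 qualifier ions matched in the
background-subtracted fragment spectrum (5 mDa).  Quantification inverts
the matrix-matched calibration line on the peak area and multiplies by
the extract-to-honey dilution factor (default 0.2: 1 g of honey
reconstituted to 0.2 mL of extract, so 1 mg/L in extract = 0.2 mg/kg in
honey).  Responses at or below the intercept return a below-LOD sentinel
rather than a negative concentration.

**Calibration and validation.**  Curves are ordinary least squares of
response on concentration (≥ 4 distinct levels; the study design uses
0.25–5.0 mg/L).  Recovery% is the mean spiked response over the
matrix-matched reference at the same concentration; matrix effect% is
100 × (matrix slope / solvent slope − 1); LOD and LOQ use the
residual-standard-deviation method (3.3 and 10 × s_y/x / slope), which
fixes LOQ/LOD = 10/3.3 by construction.

**Suspects** (formula known, standard absent) pass through the threshold
chain height > 1000 counts, area > 2000 (both strict inequalities, taken
literally), mass error < 5 mDa, isotopic fit ≤ 50, |t_R −
t_R,predicted| < 1.8 min.  The 1.8-min window originates as an observed
property of a QSRR retention-time model and is promoted here to a
configurable screening parameter.  MS/MS similarity is the cosine of
square-root-transformed intensities over m/z-matched fragment pairs
(unmatched peaks contribute zeros); the square-root transform is common
practice to de-emphasise base-peak dominance.  When the reference is a
bare fragment list, the pass criterion is ≥ 3 matched fragments — the
"three matched fragments" fallback is read as *at least three*, the
stricter of its plausible readings.

Peaks claimed by several isomeric suspects are assigned to the candidate
with the strongest fragment evidence (more matched fragments, then the
larger matched fraction of the expected list).  This reproduces
diagnostic-fragment isomer discrimination: an isomer pair sharing a
formula is split by the fragment only one of them produces.

**Confidence levels** follow the widely used tiered scheme: 1 —
confirmed by reference standard; 2a — library MS/MS match (≥ 0.7 cosine
or the three-fragment rule) plus formula and retention-time
plausibility; 3 — tentative candidate with in-silico/fragment evidence
only; 4 — unequivocal molecular formula; 5 — exact mass of interest.
Ties resolve to the weaker level.  Candidate fragment lists supplied
with a local database count as in-silico evidence (level 3 ceiling);
only a genuine library spectrum supports 2a.

## Non-target feature handling

Feature tables are samples × features matrices with `"m/z_tR"` column
ids (4/2 d.p.) and per-sample roles (sample / blank / QC) and class
labels.  Blank subtraction is a transparent fold-change rule — a feature
survives iff mean(samples) ≥ 5 × mean(blanks) — standing in for more
elaborate blank-removal methods; the fold is configurable.  QC filtering
removes features whose pooled-QC replicate RSD exceeds 30 % (no
community-standard threshold exists; 30 % is a common metabolomics
choice).  Both filters are idempotent and commute.

Annotation retrieves candidates from a local CSV compound list within
±2 mDa of the [M−H]⁻ m/z (ordered by |error|, ties by name), filters by
the 1.8-min predicted-retention-time window, optionally checks the
isotopic fit of a measured pattern, scores fragments against the
candidate's fragment list or a library spectrum, and assigns a
confidence level.  The package ships no compound database; any CSV with
name, formula, monoisotopic mass, optional predicted t_R and fragments
is accepted, and the tests build a toy database of literature honey
phenolics.

## Chemometrics

Scaling options are autoscale (x−μ)/s, Pareto (x−μ)/√s and Vast
(x−μ)/s · (μ/s).  Vast multiplies the autoscaled column by its inverse
coefficient of variation, down-weighting high-CV features; on data where
strong shared nuisance variance loads on uninformative features this is
what lets class structure reach the leading PLS components.
Zero-variance columns are dropped with a warning.  Scaling statistics
are always estimated on training data only and applied to held-out
samples — refitted inside every cross-validation fold to avoid leakage.

PLS-DA is NIPALS PLS1 on −1/+1 dummy-coded classes (centred response):
per component, the weight vector w ∝ Xᵀy is normalised to unit length,
scores t = Xw, Y-loading q = tᵀy/tᵀt, X is deflated by t pᵀ and y by
q t.  SSY_c = q_c² t_cᵀt_c is the Y sum of squares explained by
component c, and Σ_c SSY_c = SSY_total.  The decision threshold is 0 on
the coded scale.  The number of components is a parameter (default 2);
when selecting it by cross-validation, ties should go to fewer
components.

VIP is computed in the standard weight-normalised square-root form

    VIP_i = √( I · Σ_c w_ic² SSY_c / SSY_total ),

the only form under which the mean of squared VIP scores is identically
1 (a property the implementation asserts to 1e-9), making VIP > 1 the
natural significance cut-off.  Printed variants of the formula that
divide by the component count or omit the radical do not satisfy this
normalisation and are treated as typesetting variants of the standard
form.

Kennard–Stone selection is the classical deterministic max-min
algorithm: the first two picks are the pair at maximum Euclidean
distance, each further pick maximises its minimum distance to the
selected set, ties break to the lowest sample index.  The selected
points form the external test set, matching the study design this
package emulates (the algorithm itself is agnostic).  Leave-one-out
cross-validation refits scaling and model per fold; folds that would
leave a class unrepresented are skipped with a warning.  ROC curves
sweep the unique score thresholds; AUC is the trapezoid over
(1−specificity, sensitivity).

All chemometrics code is deterministic given input order; randomness is
confined to the synthetic-data module.

## Synthetic data: what it emulates, and what it does not

The generator mirrors a two-country honey study: 51 samples (26 + 25 per
origin) × 408 features, one procedural blank, five pooled-QC
injections.  On the log-intensity scale each feature has a log-normal
baseline (mean log intensity ≈ log 10⁴, SD 1 across features) and
within-class noise of σ_w = 0.25 log units.  Ten marker features carry a
between-class mean shift of 3 σ_w (the `effect` parameter, in units of
the within-class SD).  All non-marker features load on one shared
nuisance factor — per-sample scores drawn uniform on ±√3 (unit
variance), loadings 6 σ_w × U(0.5, 1.5).

Two design choices deserve comment.  The nuisance factor is *bounded*
(uniform rather than Gaussian): it models batch/drift-like shared
variation, and boundedness keeps Kennard–Stone-selected test samples —
which are by construction the most extreme points — inside the training
range, so external-set performance measures the classifier rather than
extrapolation.  The loading scale (6 σ_w) is set so the scaling methods
separate qualitatively: Vast-scaled PLS-DA achieves 0 leave-one-out and
external error across seeds, while autoscaling (external error ≈ 0.09)
and Pareto scaling (≈ 0.25) visibly degrade — the behaviour this
pipeline exists to demonstrate.  Under this design the ten injected
markers occupy the top VIP ranks and the 11-sample Kennard–Stone test
set is classified perfectly in ≥ 95 % of seeded replicates.

Blanks carry 15 contaminant features at sample-level intensity (the rest
near zero), so the fold-change rule removes exactly the contaminants;
QCs are noisy replicates of the grand mean (5 % CV) except for 10
deliberately unstable features (σ = 1 log unit) that the RSD filter
removes.

Simulated DIA runs place each compound's [M−H]⁻ isotope pattern under a
Gaussian elution profile (SD 0.05 min) sampled at 2 Hz per channel, with
declared fragments co-eluting in the high-energy channel at 40 % of the
precursor height plus a 20 % residual precursor, and an optional random
centroid noise floor.  Isotope patterns are computed on the deprotonated
ion formula (one H removed, electron mass added) — the same convention
the screening side uses when extracting measured patterns, so the two
sides of the isotopic-fit comparison are exactly consistent.

What the generator does **not** emulate: real honey matrix chemistry and
ionisation suppression, retention-time drift and batch effects beyond QC
noise, correlated marker blocks (markers are independent), adducts and
in-source fragments in the feature table, or heavy-tailed feature-wise
noise.  Passing tests therefore demonstrate correctness of the
algorithms under the declared statistical structure, not performance on
real instrument data; with real data the thresholds (similarity 0.7,
5/2 mDa, VIP 1.0, …) are the tunable surface.

## Numerical and degenerate-input conventions

* Screening inequalities are strict exactly where stated ("more than
  1000 / more than 2000"); the rt and similarity thresholds are strict
  (<) and the isotopic-fit threshold inclusive (≤), matching their
  phrasing.
* Candidate and qualifier matching tolerances are in mDa throughout
  screening; annotation uses 2 mDa retrieval.
* A calibration response below the intercept quantifies as a below-LOD
  sentinel, never negative.
* Tables without blanks or with < 3 QC injections pass through the
  respective filter unchanged, with a warning.
* Kennard–Stone with n = 1 returns the lower-indexed member of the
  maximum-distance pair; duplicated points resolve deterministically by
  the lowest-index tie rule.
* The LOO error denominator counts only evaluated folds (skipped
  singleton-class folds are excluded and reported as unassigned).

## Problem sizes used in the shipped checks

The test suite and acceptance script run the study-scale design
directly (51 × 408 feature tables; 40-sample leave-one-out; 20
replicates for marker recovery) and keep simulated DIA runs to 1–3-min
gradients at 2 Hz, which makes the complete suite run in seconds on a
single CPU while exercising every stage at the emulated study's real
dimensions.
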