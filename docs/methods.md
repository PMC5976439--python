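# Methods

## The kinetic picture

An ISWI-family remodeler repositions a nucleosome along DNA in alternating
phases: long *pauses* at a fixed position and short *translocation* events
that move the nucleosome by several base pairs. In the single-molecule FRET
geometry used here, a donor on histone H3 and an acceptor on the nearer DNA
end give an end-positioned nucleosome a high FRET efficiency (~0.95 for the
proximally labeled H3, ~0.57 for the distal one); sliding away from the end
lowers FRET. The package treats everything downstream of the extracted
two-channel intensity traces: image-level spot finding and registration are
out of scope.

## Trajectory simulator

`simulate_trajectory` draws a continuous-time kinetic path and samples it at
the camera frame rate (default 7.4 Hz, 100 ms exposure):

- **Pause durations** are exponential with index-dependent means
  (`wait_mean_s`, `p1_mean_s`, `p2plus_mean_s`; defaults 20/10/10 s). A
  single-exponential dwell is the minimal model consistent with reporting
  only mean durations; no multi-exponential structure is imposed.
- **Translocation distances** are drawn around the configured means
  (defaults 8 bp for the first step, 5 bp afterwards; normal with SD 2 /
  1.5 bp, truncated at one elementary step) and realized as successive
  elementary sub-steps (`substep_bp`, default 1 bp, valid range 1–2 bp) at a
  constant speed. The speed is not experimentally constrained; the default
  (40 bp/s) makes translocation phases last ~1–2 frames, i.e. short
  relative to pauses, which is what the observed trajectories look like.
  Position is clamped to the calibrated range; reaching the far end of the
  calibration puts the trace in an absorbing final pause.
- **Backtracking** (direction reversal) occurs per translocation with
  probability `backtrack_prob` (default 0.05 — observed but unquantified
  experimentally; treat it as an order-of-magnitude placeholder).
- **Labeling stoichiometry**: each H3 copy carries a donor independently
  with probability `labeled_fraction` (default 1/3, the 2:1
  unlabeled:labeled mixing), giving both/proximal/distal/none classes with
  probabilities 1/9, 2/9, 2/9, 4/9. Distal-label FRET is modeled as a fixed
  scale factor 0.6 of the proximal curve (0.57/0.95 at bp = 0).
- **Photophysics**: per-dye donor + sensitized acceptor emission is
  conserved (no gamma mismatch by default; corrections are exposed in
  `compute_fret`). Dyes bleach with exponential lifetimes (default mean
  600 s per dye — multi-minute lifetimes are realistic under
  Trolox/glucose-oxidase imaging buffers), blink as a Poisson process of
  dark intervals (default 0.005 s⁻¹, mean 0.3 s), and both channels carry
  additive Gaussian noise (`noise_sd`, default 0.05 of the per-dye
  intensity). After acceptor bleaching the donor recovers its full
  emission.

What the simulator does **not** emulate: spectral crosstalk, non-exponential
photobleaching, intensity drift, multi-enzyme (dimer) kinetics, or any
dependence of pause exit on nucleosome position. Passing recovery tests
therefore demonstrate that the analysis chain is unbiased under the stated
kinetic model, not that it is robust to every artifact of real recordings.

## Calibration

The FRET↔bp map is a strictly decreasing anchor table interpolated with a
shape-preserving monotone cubic (PCHIP); the inverse is the PCHIP of the
reversed table, exact at anchors and within ~0.05 bp of a true inverse
between them on the default curve. Extrapolation is refused (optionally
clamped). The default curve is Förster-shaped — `E = 1/(1 + (r/R0)^6)` with
dye separation linear in bp — normalized to E(0) = 0.95 and E(20) = 0.10.
It is a stand-in with the right shape and endpoints, not a measured curve;
analyses of real data should load the experimentally determined anchor
table (`CalibrationCurve.from_csv`). All analysis logic is curve-agnostic,
which is why correctness is established by simulator/analyzer round trips
that share one curve.

## QC rules

- `no_signal`: median total intensity over the early window below 10% of
  the trace's peak total (an unlabeled nucleosome; judged early so a
  mid-trace bleach does not trigger it).
- Two-step donor bleaching (two labeled H3) excludes the trace. A donor
  bleach is a drop in *total* intensity of ≥40% of the pre-step level that
  never recovers; an acceptor bleach is an acceptor-channel step to below
  8% of the locally detected total while the total is unchanged (the donor
  reclaims the transferred energy). Remodeling redistributes intensity
  between channels at constant total and never reaches background, and
  blinks recover, so neither is misread as bleaching. Step positions come
  from the exact DP changepoint fit with a BIC-type penalty.
- Fitted initial FRET strictly below 0.775 excludes the trace (distally
  labeled population); exactly 0.775 is kept. The threshold applies to the
  uncorrected proximity ratio, matching the default FRET estimator.
- Retained traces are truncated at the earliest bleach; segments from the
  first backtracking event (a pause level more than `tolerance = 0.05`
  FRET above the preceding pause level — above the noise at the default
  frame rate) onward are removed.

## Segmentation

A Gaussian-emission HMM with a *fixed* sticky transition matrix (diagonal
0.995, off-diagonal uniform) is fit per trace by EM; only emissions and the
initial-state distribution are learned. The stickiness penalizes short
excursions so blinks and noise spikes do not become states; frames whose
total intensity is below 30% of the trace median (blinks) are additionally
masked out of the fit. Initialization is deterministic — emission means
evenly spaced over the data range (range-covering, so a short-lived level
such as a brief wait pause cannot be absorbed into a neighboring state),
variances from a robust first-difference noise estimate — making fits
reproducible with no hidden randomness. The number of states (up to
`max_states = 12`) is selected by BIC with early stopping after two
consecutive increases. Viterbi paths are cleaned by merging runs shorter
than `min_dwell_frames = 3`.

Runs of a constant state become pauses at the state's emission mean;
adjacent runs closer than `translocation_min_dbp = 1` bp (the smallest
physical step; ties merge) are merged into one pause with a
duration-weighted level. Transitions become translocation segments spanning
one frame period and are marked censored — at 7.4 Hz a translocation faster
than one frame has no measurable duration, and the analysis quantifies
pauses, not translocation speed. The final pause of every trace (and the
last pause before a truncation) is censored.

The test oracle `oracle_segment` computes the globally optimal
least-squares piecewise-constant fit by dynamic programming (identical to
exhaustive enumeration over changepoint placements, and cross-checked
against a literal full scan in the tests). Oracle-agreement tests compare
changepoint *placements* at the HMM's selected changepoint count: the
sticky prior deliberately suppresses 1–2-frame dwells that an unpenalized
least-squares fit keeps, so model-selection differences on such dwells are
by design, not error.

## Pause and step statistics

Censored pauses are excluded from duration means by default: their observed
duration is a lower bound and including them biases means downward. (This
choice slightly biases the other way — long pauses are more likely to be
cut — but with dye lifetimes several-fold longer than pause means the
residual bias is a few percent.) Bootstrap errors resample *trajectories*
with replacement (1000 replicates by default, seeded); reported errors are
the SDs of the resampled statistics, and ECDF bands are pointwise ±1
bootstrap SD. Step sizes are differences of `fret_to_bp` at consecutive
pause levels, positive away from the labeled end; levels outside the
calibrated FRET range are flagged and excluded from distributions (the
range test uses the anchored range, so a wait level a noise-width above the
top anchor is flagged — the conversion itself clamps). Datasets with fewer
than 100 trajectories are summarized with a warning, mirroring the
customary minimum of ≥100 traces pooled from ≥3 experiments.

## Ensemble fits

All models are fit by trust-region (`scipy.optimize.least_squares`, `trf`)
nonlinear least squares with nonnegativity bounds on rates, f_fast ∈ [0,1],
and tight tolerances (1e-14), so noiseless generating data are recovered to
≲1e-6 relative error. Standard errors come from the Jacobian at the
optimum; replicate-level SEMs can be computed by fitting replicates
separately. Titrations are analyzed in two stages matching the experimental
workflow: per-concentration single-exponential fits with y0 and plateau p
shared across the series (one global least-squares problem), then the
cooperative binding model on the per-series k_obs. Degenerate inputs are
flagged rather than silently fit: a flat series reports k_obs = 0 with a
`zero_amplitude` flag; a flat competition series is `non_identifiable`; a
two-phase fit whose rate ratio is below 3 (or whose fast fraction hits 0 or
1) also reports the constrained single-exponential fit with an AIC
comparison. Two-phase output is normalized so k_fast ≥ k_slow. The ATPase
initial rate is the OLS slope over points with Pi ≤ 10% of total ATP,
expanding to the first three points (flagged) when fewer than two qualify;
the synthetic ATPase time course is linear at the configured rate until 10%
of ATP is consumed and then approaches the total exponentially with
matching slope at the joint.

## Crosslinking-MS domain quantification

CSMs are classified target vs decoy by a linear SVM (standardized features,
class-balanced hinge loss, C = 1) on the five search-output features; the
decision function is the signed margin, so "SVM score greater than 1" is
one margin unit. Residue pairs (order-canonicalized) are scored by their
best CSM and retained iff SVM score > 1 (strict), score difference > 5
(strict) and fractional spectral count ≥ 1 — alternate localizations of
ambiguous-only spectra carry fractional counts below one and are therefore
not reported on their own. FDR is the standard construction for a decoy
database holding `decoy_multiplicity` (default 10) randomized copies of
each target sequence: decoy passes divided by the multiplicity, then by
target passes; specificity is 1 − decoy pass fraction.

Fractional counting awards each spectrum exactly one count split equally
over its k candidate residue pairs. Domain aggregation uses 1-based
inclusive boundaries (histones numbered without the initiator methionine;
SNF2h numbering offset +2 from the UniProt entry). The printed H4 boundary
list ("H4 tail: 25–102") is internally inconsistent with the other
histones' tail/core splits; the package uses tail 1–24 / core 25–102.
Intra- vs intermolecular crosslinks of identical chains are
indistinguishable (octamer symmetry, 2:1 enzyme:nucleosome stoichiometry),
so matrices are symmetric over canonical domain pairs. The differential
matrix floors counts at a pseudocount of 1, takes log2(B/A), sets exactly-
zero ratios to NA, and centers the remaining cells so that the median over
unique (upper-triangle) non-NA cells is 0 — NA cells are excluded from the
median, i.e. centering happens after NA assignment. Cells with no
crosslinks in either condition are flagged separately (`no_data`).

## Problem sizes and numerical choices

The recovery suites use 300 trajectories of 1110 frames (150 s at 7.4 Hz)
for the end-to-end pause/step test — enough that the standard error of an
exponential mean (~6%) sits well inside the 15% acceptance band — and 300
trajectories of 200 frames for the static-cluster test; the XL-MS
enrichment test uses 20 000 CSMs per condition so that per-domain-pair
Poisson noise (~0.2 log2 units at the enriched cell) is small against the
±0.5 band. All simulations, fits and bootstraps take explicit integer
seeds; there is no hidden global random state.

## Known limitations

- Pause labels are positional (order of appearance); a missed short pause
  shifts later labels, which inflates label-wise means slightly at the
  default frame rate (~10% for p1 under the default conditions, inside the
  documented tolerance, but not zero).
- Translocation speed is not estimated — phases faster than one frame are
  censored by construction.
- The bleach detector assumes step-like, irreversible bleaching and roughly
  constant total intensity; slow intensity drift would need detrending
  first.
- Kaplan–Meier handling of censored pauses is exposed in principle by the
  censoring flags but no survival estimator is built in; means simply
  exclude censored dwells.
- The SVM score scale depends on the training set; the margin-1 threshold
  is calibrated by construction of the classifier, not against the original
  search engine's score distribution.
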