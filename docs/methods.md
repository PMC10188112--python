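# Methods

## Locomotor model and bout parameters

The raw signal is Δ pixels: per well and frame transition, the number of
camera pixels whose grey value changed beyond the tracker's sensitivity
threshold. That threshold is an acquisition setting applied upstream; this
package treats the series as already thresholded, and its own activity
predicate is *value strictly greater than the activity floor* (default 0).
A bout is a maximal run of same-state frames; by construction active and
inactive bouts alternate and tile each epoch exactly, which the tests
assert as a conservation identity.

Timing runs on the Zeitgeber clock (ZT 0 = lights-ON) with a 14 h:10 h
light:dark schedule by default. Epoch boundaries land on frame
round((boundary_zt − start_zt) × 3600 × fps) with half-up rounding, and
ranges are half-open, so a lights-transition frame belongs to the epoch it
starts. By default only complete epochs contribute to parameter averages;
truncated epochs at the recording edges can be included with the
`use="all"` switch, since whether such partial epochs should count is a
genuine analysis choice rather than something this package can decide.

Nine parameters summarize each epoch. Six are per-bout statistics of the
active bouts (length in seconds; mean, standard deviation, total, minimum
and maximum of the Δ-pixel values composing the bout), reduced to one
epoch value by an **unweighted mean across bouts** — not by pooling frames.
The reduction is a deliberate convention: the parameters are defined
per bout, and the unweighted mean keeps a long bout from dominating the
epoch. The per-bout standard deviation uses the population denominator
(n), so a single-frame bout contributes 0 rather than an undefined value.
The remaining three are the active-bout count, total time active as a
percentage of epoch frames, and the mean inactive-bout length. Bouts
truncated by epoch boundaries enter as-is (no censoring): deterministic,
and at realistic bout lengths the truncation bias is negligible relative
to between-larva variance. Epochs with no active bout report the six
active-bout measures as missing — never 0 — and missingness propagates
through all downstream stages (Z-scoring, distances, correlations) by
exclusion, never by zero-filling.

Day values average each parameter over all complete day epochs, night
values over night epochs: 18 measures per larva, in a fixed canonical
order (nine day measures, then nine night), so fingerprints and libraries
interoperate by column name.

## Fingerprints, distances, matching

Z-scores are referenced to the within-plate control group:
z = (x − μ_ref)/σ_ref per measure, with σ_ref the *sample* standard
deviation (denominator n − 1; the choice of denominator is a convention,
documented here because nothing downstream forces it). Measures with zero
reference variance are flagged and reported missing for all larvae. Group
summaries report per-measure mean ± SEM (sd/√n over non-missing members);
SEM for a single member is reported missing rather than 0.

The Euclidean distance √(Σ z²) over non-missing measures quantifies
phenotype strength; because Z-scoring centres the controls, the control
centroid is the origin. Distances computed over different measure subsets
are not comparable, so the output carries the measure count used.
Correlations are Pearson, pairwise-complete over shared non-missing
measures, with a minimum-overlap requirement (default 5) and an undefined
result (zero variance) reported as missing.

Library ranking sorts conditions by r descending, ties broken by condition
name. Clustering uses correlation distance 1 − r with average linkage
(UPGMA). Both choices are configurable; they are the conventional
clustergram defaults for Z-profile data, where the profile *shape* rather
than its magnitude carries the signal. The agglomeration is written here
rather than delegated, for one reason: deterministic, permutation-invariant
tie-breaking. Among pairs at the minimal distance (relative tolerance
1e−12) the pair with the lexicographically smallest (min leaf name,
max leaf name) key merges first, which makes the tree invariant to input
row order even under exact ties — index-based tie rules cannot give that.
The implementation uses Lance–Williams updates and is tested for exact
agreement both with a brute-force oracle that recomputes every
inter-cluster distance as the mean over leaf pairs, and with scipy's UPGMA
on tie-free inputs.

## Peak statistics

Per peak and per direction ("significant in condition X" = X's intensity
distribution stochastically greater), two one-tailed tests:

* **Wilcoxon rank-sum.** Exact null distribution for tie-free samples with
  total n ≤ 12 (configurable cutoff); otherwise the normal approximation
  with tie correction and continuity correction. On matrices above the
  cutoff the p-values are computed by a vectorized implementation (ranks
  and tie terms are label-independent and computed once; rank sums under
  relabelings are a single matrix product), tested for exact agreement
  with the scalar path.
* **One-tailed KS.** D = sup of the signed ECDF difference in the stated
  direction, clamped at 0; p from the one-sided asymptotic bound
  exp(−2 D² n_e), n_e = nm/(n+m), clamped to (0, 1]. Exact small-sample KS
  p-values are out of scope; the bound is conservative, and the combined
  call is dominated by the Wilcoxon threshold in practice.

A peak is significant in a direction when the raw p-values pass the
thresholds — defaults 0.001 (Wilcoxon) and 0.01 (KS), both required
("both" rule). The conjunction is the conservative reading of a two-test
filter and is configurable ("either" is the alternative). No
multiple-testing correction is applied at this filtering step; the
permutation null is what controls the overall claim.

The permutation null shuffles condition labels over cells (group sizes
preserved, each peak's value multiset untouched — asserted), recounts
significant peaks per shuffle (a peak significant in both directions
counts once), and reports the add-one empirical p-value
(1 + #{null ≥ observed})/(1 + n_shuffles), whose floor is 1/(1+n_shuffles).
The add-one form is the standard validity-preserving estimator for
permutation tests. Empirical p-values from this construction are discrete
and conservative — on null data the observed count is usually 0 and p = 1 —
so the calibration test checks *super-uniformity* (no excess of small
p-values, one-sided KS) rather than two-sided uniformity, which any valid
discrete p-value would fail. Calibration of the Wilcoxon tail itself is
checked by pooling per-direction rejections at p < 0.001 across null
matrices against the exact binomial 99% interval.

Bulk region classification consumes a (ratio, FDR) table from an external
differential analysis: up at FDR < 0.01 and ratio > 1, down at FDR < 0.01
and ratio < 1, "unaffected" controls at FDR > 0.95 with ratio strictly
inside (0.995, 1.005), else none. All comparisons are strict, classes are
disjoint by construction.

## Interval conventions

Coordinates are 0-based half-open everywhere; BED io is lossless. Overlap
means ≥ 1 shared base — abutting intervals do not overlap, including at
promoter and peak boundaries. The Tn5 shift moves + strand read starts by
+4 and − strand read ends by −5; a read the shift would collapse is an
error, not silently dropped. Effective fragments satisfy mapq ≥ 30
(standing in for "uniquely mapped"; no separate uniqueness test) and
insert ≤ 100 bp; drops are counted by reason, with mapq checked first. RPM
coverage is overlap count × 10⁶ / total effective fragments.
Condition-specific peaks are high-threshold calls in one condition with no
overlapping low-threshold call in the other — overlap, not interval
identity. Promoters are [max(0, TSS − 1 kb), TSS + 1 kb), strand-symmetric;
for − strand gene spans the TSS is the 3′-most coordinate (end − 1). The
closed-versus-half-open status of the original windows is unknowable from
the conventions at hand; half-open is used consistently and documented.

## Synthetic data: what it does and does not emulate

`simulate_plate` generates an alternating renewal process per well:
exponential bout durations (inactive mean per epoch type, divided by the
group's bout-rate factor; active mean shared), gamma(shape 2) per-frame
amplitudes with mean amplitude_scale × group epoch factor, bouts truncated
at epoch boundaries, each epoch restarting inactive. Defaults: 1 Hz
sampling (keeps tests in seconds; the 25 Hz acquisition rate is a config
value), 48 h duration, mean inactive bout 3 s by day and 12 s by night,
mean active bout 2 s, amplitude scale 10 Δ-pixel units — chosen once as
plausible magnitudes for binned larval locomotor data. The process
reproduces exactly the statistics the pipeline measures (bout counts,
lengths, amplitudes, time active) with analytically controllable group
effects, which is what makes planted-effect recovery a meaningful test. It
deliberately omits circadian ramping within epochs, light-transition
startle responses, developmental drift across days, and inter-larva
baseline heterogeneity (exposed as config, not asserted) — so passing
tests demonstrate the pipeline's correctness and sensitivity under the
stated model, not distributional realism of any particular rig.

`simulate_library` draws i.i.d. standard-normal Z-scores per condition ×
measure; a planted mimic is the query plus additive Gaussian noise in
Z-space, which fixes its expected Pearson r at 1/√(1 + σ²) in closed form
(σ = 0.3 gives r ≈ 0.96, far above the max-of-199-null-rows ceiling at 18
measures — hence the ≥ 95% rank-1 recovery requirement). Real compound
libraries have correlated measures and dose structure; none of that is
claimed.

`simulate_peak_matrix` draws negative-binomial counts (shape = dispersion,
default 2; per-peak baseline means log-normal around 10) with the second
condition's mean multiplied by the effect size at planted peaks. The
rank/ECDF tests are distribution-free, so NB margins (rather than
zero-inflated mixtures) suffice for calibration; sensitivity numbers are
specific to this generative choice.

## Problem sizes

The test suite runs in about two minutes: the bout oracle covers 1000
random traces up to 10⁴ frames; planted-effect recovery uses 48 wells per
group at 1 Hz for 48 h; drug matching 100 library draws of 200 conditions;
null calibration 100 matrices of 200 peaks × (50+50) cells with
1000-shuffle permutation nulls each. `scripts/acceptance.py` re-runs the
same measurements at 500 traces, 50 library draws and 20 null matrices,
sizes at which every reported rate is stable to a few percent across
seeds.

## Known limitations

* The one-sided KS p-value is an asymptotic bound; at very small cell
  counts the Wilcoxon exact path carries the inference.
* Sleep-specific metrics (sleep-bout criteria, latency), stimulus-response
  assays and behavioral-state models are out of scope; the nine parameters
  are the complete measure set.
* Distances over differing missing-measure subsets are flagged, not
  reweighted; there is no imputation anywhere.
* The clustergram helper returns the tree (JSON/scipy linkage); heatmap
  rendering beyond that is left to the caller.
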