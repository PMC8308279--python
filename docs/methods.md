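# Methods

## Model and procedure

The pipeline reproduces the comparative-call analysis used by classic
Affymetrix MAS5-style workflows, followed by a dose-consistency consensus.

**Detection.** For one probe set on one chip with probe pairs
(PM_i, MM_i), the discrimination scores R_i = (PM_i − MM_i)/(PM_i + MM_i)
are tested against the offset τ (default 0.015) with a one-sided Wilcoxon
signed-rank test of H1: median(R) > τ. Scores exactly equal to τ are
dropped; if all are dropped, p = 1 and the call is absent. Buckets: present
p < 0.04, marginal 0.04 ≤ p < 0.06, absent p ≥ 0.06.

**Change.** For a (control, CR) chip pair the per-pair differences
d_i = log2(max(PM_exp,i − MM_exp,i, 1)) − log2(max(PM_base,i − MM_base,i, 1))
are tested one-sided (p near 0 ⇒ increase). The floor of 1.0 on the
background-adjusted value guards the logarithm against non-positive
differences; it plays the role the ideal-mismatch correction plays on real
chips. The change test uses the **mid-p** tail,
p = P(W⁺ > w) + ½·P(W⁺ = w), so that swapping the two chips maps p exactly
to 1 − p and an identical pair sits at exactly 0.5 (all-zero differences
return 0.5 by convention). Detection uses the plain tail P(W⁺ ≥ w), whose
extreme value for n uniformly positive scores is 1/2ⁿ. Change buckets as
printed: increase p ≤ 0.0025, marginal increase 0.0025 < p ≤ 0.003, no
change 0.003 < p < 0.997, marginal decrease 0.997 ≤ p < 0.998, decrease
p ≥ 0.998; boundary values belong to the bucket their inequality states.

**Exact null.** Both tests condition on the observed magnitude ranks
(mid-ranks for ties) and use the exact distribution of the positive rank
sum over all 2ⁿ sign assignments, computed by dynamic programming on
doubled (integer) ranks — equivalent to full enumeration at O(n·Σranks)
cost. The exact path is used up to n = 25 observations; above that a normal
approximation with implicit tie correction is used (continuity correction
½ for the plain tail, none for mid-p). With the default 11 probe pairs the
exact path is always taken. The p-value granularity at n = 11 is 1/2¹²,
comfortably below the 0.0025 increase threshold.

**Signal log ratio.** The SLR is the one-step Tukey biweight of the per-pair
d_i: centre t = median, scale s = MAD, u_i = (d_i − t)/(c·s + ε) with c = 5
and ε = 10⁻⁴ (published MAS5 constants, overridable), weights
w_i = (1 − u_i²)² for |u_i| < 1 else 0. For constant vectors all weights are
1 and the SLR is exact, so a uniform k-fold change yields exactly log2(k).

**Consensus.** A probe is informative in a condition iff neither chip of
the pair is absent (marginal detection is *not* excluded — only 'absent'
is) and the change call is a firm increase/decrease. For adipose, which is
hybridized in duplicate, both chip pairs must independently give the same
firm direction. "CR responsive" probes have the same informative direction
in *every* condition of a tissue; this is read as all four levels **and**
both durations (the published per-tissue overlap counts span both duration
columns), with a per-duration intersection available via
`cr_responsive(..., duration=...)` and the CLI flag `--per-duration`.

**Cross-tissue commonality.** A probe whose informative entries over the 36
conditions all share one direction gets a commonality record with that
direction and the count of informative conditions; probes mixing both
directions are excluded from commonality ranking (every published
commonality row is single-direction). Conditions absent from a tissue's
design (intestine has only four) count as non-informative, never as
penalties. The up/down inclusion thresholds (20 and 19 of 36 in the source
analysis) are exposed as the `min_conditions` parameter rather than fixed.

**Enrichment.** One-sided hypergeometric upper tail
P(X ≥ k | N, K, n) per category (equivalently Fisher's exact test for
over-representation), Benjamini–Hochberg step-up across all tested
categories, significance at adjusted p < α (default 10⁻⁴). The default
universe is the caller's informative-gene background; no default annotation
database ships with the package — categories come from a user GMT. A
two-sided variant sums all table probabilities not exceeding the observed
one and sits behind a flag.

**Meta concordance.** A study gene is *concordant* when at least one
reference reports it and every reporting reference matches the study
direction, *conflicting* when any reporting reference disagrees, otherwise
*not found*; the three labels partition the input. "Overlap with the
meta-analyses" is reported both as concordant-only and as
concordant + conflicting (`ConcordanceSummary.overlapping`), since a
direction-conflicting gene does overlap without agreeing.

## Synthetic data

The generator emulates the pooled-RNA study design: per tissue×duration one
control chip and four CR chips (duplicated throughout for adipose,
replicates sharing condition means with independent noise), 36 CR
conditions in total, one chip per condition by design — the pooled design
has no biological replicates, and the pipeline's dose-consistency filter is
precisely the mitigation for that.

Intensity model: per tissue, probe-set baselines log2-normal
(mean 9, sd 1.5); per-probe affinities N(0, 0.8) on the log2 scale, fixed
across chips; chip-level noise N(0, noise_sd) on log2 PM. MM is the
realized PM times `mm_fraction` (default 0.5) with its own independent
multiplicative jitter of the same sd. Tying MM to the realized PM keeps
`noise_sd` meaningful on the background-adjusted log2(PM−MM) scale (the
per-pair change difference then has sd 2·noise_sd); with MM noise fully
independent of PM the effective noise of log2(PM−MM) is amplified ≈2.2×,
which silently changes what a given noise level means. The jitter still
makes discrimination scores vary probe to probe.

Planted structure: disjoint blocks of probe sets get a signed log2 shift of
`effect_slr_at_30` (default 1.5) scaled per level by `dose_scaling`
(default 0.25/0.5/0.8/1.0 for 5/10/20/30%, a saturating dose response) in
every condition of their tissue; "common" blocks carry the shift in all
five tissues. Because the shift multiplies PM and MM alike, the expected
SLR equals the planted shift exactly in the noiseless limit, which the
tests verify. Defaults (200 probe sets of 11 pairs, 12 responsive probes
per direction per tissue, 5 common per direction, noise sd 0.1) give a
desk-scale study — about 55 chips and 2,200 probe-set intensities — that a
full pipeline run processes in seconds; the parameter-recovery study in the
acceptance script uses five such simulations at noise sd 0.05.

What the generator does **not** emulate: probe-sequence affinity structure,
spatial artifacts, batch or scan-date effects, cross-hybridization,
saturation, and inter-chip intensity scale differences. Passing
parameter-recovery tests therefore demonstrates the correctness of the
filtering and consensus logic under the stated noise model, not performance
on real chip data.

## Numerical choices and degenerate inputs

- Zero differences are dropped before ranking (signed-rank convention);
  all-dropped inputs resolve deterministically (detection: p = 1/absent;
  change: p = 0.5/no change).
- Tied magnitudes get mid-ranks; doubling ranks makes them integers so the
  exact DP is free of floating-point rank issues.
- Detection p is non-increasing when any single score is raised, *provided
  magnitudes stay tie-free*; exact magnitude ties can break monotonicity
  because mid-ranking conditions the null on a different rank multiset (a
  four-score counterexample exists). The property test restricts itself to
  tie-free configurations.
- Ranking and commonality tie-breaks are lexicographic by probe-set id, so
  every ordering is deterministic under input shuffling.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical output
  files.
- No inter-chip scaling or normalization is applied before comparison
  calls; the package exposes none, and comparisons assume chips are on a
  common intensity scale (true for the synthetic generator, a caveat for
  real data).

## Known limitations

- Binary CEL/CDF parsing is out of scope; inputs are plain TSV intensity
  tables.
- The probe-level analysis deliberately applies no false-discovery control;
  FDR enters only in category enrichment, mirroring the conservative
  call-and-intersect design.
- Missing probes on a referenced chip are an error (strict mode only); a
  permissive treat-as-absent mode is not implemented.
- Real annotation (GO/DAVID) content is user-supplied; published annotation
  p-values depend on database versions and are not reproduced.
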