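# Methods

## The estimand and the estimator

For a probe pair whose MM probe differs from the consensus at probe position
*i* (1 = 5' terminus of the written sequence, 25 = 3', the surface-attached
end), the discrimination statistic is log2(PM/MM_i). Intensities enter on
the linear scale; within each tissue the replicate arrays' log2 intensities
are averaged, giving one PM and one MM value per tissue. The per-pair
estimate is the Chip coefficient (PM vs MM) of the additive two-factor
linear model

    log2 I ~ intercept + Tissue + Chip

fitted to the 2 × T per-tissue means. Under the balanced design used
throughout (every tissue present on both platforms with equal replicate
counts) this coefficient reduces in closed form to the across-tissue mean of
per-tissue PM−MM differences. The implementation computes both routes — the
closed form, and the coefficient via the pseudo-inverse of the shared design
matrix applied to all pairs at once — and asserts their agreement to 1e-10
for every pair; the test suite additionally cross-checks the coefficient
against an independent statsmodels OLS fit on small instances. The
"one-way ANOVA with the variables Tissue and Chip" phrasing this model
operationalizes is internally contradictory (two variables); the additive
two-factor model is the reading under which the stated per-tissue averaging
then grand mean is exact.

## Probe matching

Alignment is semi-global: the probe aligns end-to-end while consensus
overhangs are free. Scores are match +1, mismatch −1, gap open 5, gap
extend 0.5 (first gap column costs open + extend). This scale guarantees
that for a 25-mer one substitution (score 23) always beats any gapped
alternative (≤ 25 − 5.5), so on indel-free data the optimum is the
minimum-Hamming window. The optimal score is obtained from Biopython's
`PairwiseAligner` (free end deletions on the probe row); the reported
placement comes from a vectorized ungapped window scan whenever the ungapped
optimum attains that score — which also realizes the declared tie-break
(leftmost start, then fewest gaps) exactly. Gapped optima, which arise only
for adversarial inputs outside the study design, fall back to the
PairwiseAligner alignment chosen deterministically by (start, gap count)
among the first 64 optimal alignments. Correctness is anchored to an
independent pure-Python sliding-window Hamming oracle in the tests, not to
any particular aligner implementation.

A probeset is kept iff its probes' alignment starts strictly increase with
probe order ("sequential") and every probe is fully aligned with zero gaps
("complete"); the discard log records the first violated criterion, checked
in that order. A pair is called iff the query probe has exactly one
mismatch and the PM design contains a probe exactly matching the aligned
consensus window; zero-mismatch probes become controls, ≥2-mismatch probes
are dropped. When the window matches PM probes on several probesets, a
candidate sharing the query's probeset wins (smallest probe id); otherwise a
unique candidate is accepted and a genuine conflict raises an ambiguity
error. The mismatch type is written PM base → MM base; since the PM probe
equals the consensus window, the PM base is the consensus base.

## Preprocessing

Quantile normalization is applied within replicate groups — by default the
pair of arrays sharing (platform, tissue); a per-platform global grouping
exists for sensitivity analysis. Each column's sorted values are replaced
by the across-column mean of order statistics; tied values in a column share
the average of the reference quantiles over their rank span (the common
convention; the choice is not externally fixed). With ties the
sorted-columns-identical and idempotence properties hold only approximately;
for tie-free columns (continuous intensities) they are exact, and the suite
asserts idempotence to 1e-12.

## Summaries

* **Position profile**: per position, n / mean / median / MAD / IQR of the
  estimates. MAD is the raw median absolute deviation (no 1.4826 constant —
  it would cancel in the spread regression's R² anyway); IQR quartiles use
  linear interpolation of order statistics (type 7). Positions with no
  pairs carry n = 0 and NaN summaries.
* **Spread regression**: OLS of MAD on median over positions with data
  (≥ 3 required). A constant-MAD input returns slope 0, R² 0 as the defined
  limit.
* **Type × group summary**: positions binned into 5' end (1–8), center
  (9–17), 3' end (18–25); per-(type, group) means, per-type frequencies,
  and two-sided pooled-variance Student's t-tests for the three group
  contrasts (Welch available behind a flag). No multiple-testing
  correction is applied anywhere; raw p-values are reported. A contrast
  with a cell of fewer than 2 estimates is marked unavailable and logged.
* **Percent contrasts**: ratio-scale form 100·(1 − 2^(Δmean)) for "percent
  decrease of PM/MM", and the percent-higher-on-log2-scale form
  100·(mean_other/mean_ref − 1) for group comparisons.
* **Control comparison**: identical-probe control differences (design A −
  design B, same estimator) form a single sample without a mismatch
  position; each position's estimates are tested against that full sample
  with the pooled t-test. Positions where either sample has < 2 values are
  skipped and logged.

## Cross-study machinery

Study vectors carry 12 per-type values and a declared direction:
"discrimination" (log2(PM/MM) convention, larger = less stable duplex) or
"stability". Correlation harmonizes everything to the stability scale and
reports Spearman and Pearson with two-sided p-values at N = 12; Spearman
p-values use the t-approximation by default, with a seeded permutation
option (exhaustive when the resample budget exceeds the permutation count).
Because a published correlation may have been computed on ranks, Pearson is
also reported on ranks, labeled separately. Notation conversion maps PM→MM
to duplex (probe, target) form: probe base = MM base, target base =
complement of the PM base (U for RNA targets); the inverse is provided and
round-trips. The stability list places the most stable type at position 1;
under Watson-Crick rules positions 1–6 should be the six types disrupting
an A·T pair and 7–12 those disrupting a C·G pair, and `flag_outliers` flags
violations of that block rule. Ties in the stability order break by type
name for determinism.

## The synthetic generator

The generator emulates the cross-species study structure: per probeset a
random uniform-composition consensus; design A probes as exact 25-mer
windows tiled left-to-right (strictly increasing starts); design B probes
as copies that are unchanged (control fraction, default 0.2), singly
substituted (position and admissible type drawn from configurable
distributions, default uniform), or doubly substituted at distinct positions
(multi-mismatch fraction, default 0.05 — fodder for the exclusion filter).
Intensities follow

    log2 I = baseline + probe affinity + tissue effect − δ·[single-mismatch B probe] + ε

with affinity ~ N(0, 1.0) shared between paired probes, five fixed tissue
offsets (−0.7…0.8 log2 units), baseline 9.0 log2 units, ε ~ N(0, noise_sd),
and linear intensities floored at 2^−10. Multi-mismatch probes get a fixed
penalty of twice the mean of δ; they never reach the estimator. The default
penalty surface δ(i, type) is separable: a unimodal positional profile
peaking at position 12 with a slightly slower decay on the 5' flank
(quadratic half-widths 13 vs 12), times per-type multipliers that separate
the classes (A·T-pair types 0.70–0.82, C·G-pair types 1.08–1.25, strongest
on C-A, G-A, C-G, weakest on A-C, A-G, A-T), scaled to a 1.0 log2-unit
peak. The magnitudes are choices, not measurements: no public value fixes
the arrays' noise level, so noise_sd defaults to 0.3 log2 units (a
realistic replicate scatter for probe-level data) and recovery checks are
phrased as within-standard-error and rank/shape properties rather than
fixed tolerances.

What the generator does *not* emulate: sequence-dependent affinity (GC
content, nearest-neighbor stacking), optical background, cross-
hybridization, indels, strandedness complications (probes are generated
sense-consistent; the matcher compares probes as written and does not
reverse-complement by default). Passing tests therefore demonstrate the
pipeline's correctness and calibration under the stated model, not the
biophysics of real hybridization.

Randomness: one integer seed per `SimulationTruth`; design generation and
intensity simulation derive independent child streams from it, so identical
seed + config gives byte-identical artifacts end-to-end (asserted for the
full pipeline).

## Problem sizes and numerical choices

The study-scale recovery experiment uses 2,500 probesets × 5 probes on
60-base consensus sequences — 12,500 single-mismatch pairs, ~500 per
position, matching the published dataset's per-position order of magnitude —
with 5 tissues × 2 replicates and noise 0.3; it completes in seconds. The
type-I calibration of the control comparison uses 1,000 null replications of
20-vs-20 samples. The closed-form/linear-model identity is checked on
1,000 random balanced instances at tolerance 1e-10. The demo analysis run
uses 500 probesets × 11 probes (a typical probeset size) on 120-base
consensus sequences.

## Known limitations

* The aligner's leftmost-start tie-break is exact for ungapped optima; for
  the rare gapped optimum the deterministic choice among enumerated optimal
  alignments is a convention, not a guarantee of global leftmost-ness.
* The estimator requires a complete balanced layout (every tissue on both
  platforms); missing cells abort rather than rebalance.
* Exhaustive permutation p-values for Spearman at N = 12 are infeasible
  (12! pairings); the permutation option is exact only for smaller N and
  Monte-Carlo above.
* Published per-study effect vectors are not shipped; the cross-study
  driver generates clearly-labeled synthetic example vectors, so its
  correlations illustrate the machinery only.
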