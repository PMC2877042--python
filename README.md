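# xsmm — single-base mismatch effects on short-oligonucleotide microarrays

Short-oligonucleotide expression arrays (Affymetrix-style GeneChips) probe
each transcript with 25-mer probes. A single base difference between probe
and target — a SNP, or a species difference when samples from one organism
are hybridized to another organism's array — weakens the duplex and lowers
the measured signal, by an amount that depends strongly on *where* on the
probe the mismatch sits and on *which* base pair is disrupted. `xsmm`
implements, as a tested reusable pipeline, the analysis used to quantify
these effects from paired array designs:

1. **Probe matching** — each probe of a query design is aligned to its
   probeset's consensus transcript with a semi-global aligner (probe
   end-to-end, free consensus end gaps). Probesets whose probes do not align
   sequentially and completely are discarded; probes with exactly one
   mismatch to the consensus become MM probes, the other design's probe that
   exactly matches the aligned consensus window is the PM probe, and probes
   identical in both designs become controls.
2. **Preprocessing** — quantile normalization within replicate groups
   (the pair of arrays sharing platform and tissue).
3. **Effect estimation** — for each PM/MM pair the discrimination statistic
   log2(PM/MM_i), where *i* ∈ 1..25 is the mismatch position, is the Chip
   (PM vs MM) coefficient of an additive Tissue + Chip linear model on
   replicate-averaged log2 intensities; under the balanced design this
   equals the across-tissue mean of per-tissue PM−MM differences (both
   routes are computed and asserted equal).
4. **Summaries** — the 25-position profile (n, mean, median, MAD, IQR), the
   MAD-on-median spread regression, the 12 mismatch types × 3 position
   groups (5' end = 1–8, center = 9–17, 3' end = 18–25) table with pooled
   Student's t-tests, and per-position tests against identical-probe
   controls.
5. **Cross-study comparison** — harmonization of per-type effect vectors
   across studies (PM→MM vs duplex notation, discrimination vs stability
   direction), Spearman/Pearson correlation at N = 12, stability orders,
   A·T/C·G pair-class consolidation, and Watson-Crick block-rule outlier
   flagging.

Because real two-species array data needs proprietary binary inputs, the
package ships a first-class synthetic generator (`xsmm.synthetic_data`) that
emulates the study design — two probe designs sharing consensus transcripts,
5 tissues × 2 replicates per platform, substitutions spread over all 25
positions and 12 types, an identical-probe control fraction — under a
generative intensity model with a known penalty surface δ(position, type),
so every stage is testable against ground truth.

## Worked example

Run the numbered drivers from the repository root (each is a thin script
over the library; outputs go to `results/analysis/`):

```
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/03_match_probes.py
python analysis/04_effect_stats.py
python analysis/05_cross_study.py
```

The matching stage reports perfect recovery of the planted mismatches:

```
match: 4120 pairs, 1126 controls, 254 multi-mismatch dropped, 0 probesets discarded
(position, type) agreement with ledger: 100.0%
```

and the statistics stage prints the headline effects:

```
positional mean peaks at position 11
PM/MM ratio decrease peak -> position 1: 20.2%
PM/MM ratio decrease peak -> position 25: 31.3%
MAD on median regression: slope 0.180, R^2 0.790
center group exceeds both flanks for 12/12 types
max p vs identical-probe controls across positions: 1.04e-210
```

The positional mean of log2(PM/MM_i) is unimodal with its peak near the
probe center (true peak 12; the estimate lands within one position), the
PM/MM ratio loses ~20% moving from the peak to the 5' end and ~30% to the
3' end, spread tracks location across positions, and every mismatch type
discriminates more in the center group than at either flank — while
identical-probe control differences are indistinguishable from zero by
comparison. The same pipeline is driveable from a single config via the
`xsmm` CLI (`xsmm run --config config.yaml`, plus `simulate / normalize /
match / analyze / crossstudy` subcommands).

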