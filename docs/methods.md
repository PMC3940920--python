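# Methods

## Setting and data model

The package analyzes cycle-threshold (Ct) matrices from qRT-PCR miRNA
panels run on serum. A Ct value is the PCR cycle at which amplification
crosses a fixed signal; lower Ct means higher abundance, and one cycle is a
two-fold difference, so all modeling is done on the cycle (log2) scale.
Cells with no amplification ("Undetermined", empty, "NA", ">40" — the token
set is configurable) are *censored*: they carry no Ct and never enter any
mean. A finite Ct above 40 cycles (configurable) is also treated as
censored on read, since such values are not quantitative.

Assay names carry the field's arm convention: a `-3p`/`-5p` suffix names
the mature strand's side of the precursor hairpin, and legacy names
(e.g. miR-451) carry no arm information. Arm calls are therefore a total,
deterministic function of the name; the optional miRBase-style GFF3 join
contributes display-only genomic locations and never affects computation.

## Expression calling and QC

A cell is *expressed* when its Ct is finite and ≤ 37 cycles (inclusive).
The *global set* is every assay expressed in at least one cohort sample.

Hemolysis releases erythrocyte miR-451 into serum. With both markers on
the panel the check is ΔCt(miR-23a − miR-451) > 7 cycles; with miR-451
alone, a Ct more than 5 cycles below the cohort median. The two thresholds
are distinct, configurable knobs: the two-marker delta has an established
working range, while the single-marker rule compares within-cohort and
needs a tighter bound to catch a ~6-cycle shift. Spike-in QC flags samples
whose spike-in Ct deviates more than 2.0 cycles from the cohort median — a
conventional qPCR tolerance; the spike-in is synthetic and non-human, so
deviations are technical. QC failures are flags, not exclusions: dropping
samples is an explicit configuration switch, since a cohort in which every
sample passes is the expected case.

## Global-mean ΔCt normalization

Each sample is centered on the mean Ct of the global-set assays expressed
in *that* sample:

    ΔCt(a, s) = Ct(a, s) − mean{ Ct(m, s) : m ∈ global set, expressed in s }

with linear relative quantity 2^(−ΔCt). The global set is defined
cohort-wide but each sample's mean can only average the cells that exist in
it; this is the only self-consistent treatment of censoring. Spike-ins are
excluded from the global set (they are technical, not biological, signal).
Two exact invariants are property-tested: the per-sample mean of ΔCt over
included assays is 0 (within 1e−9), and adding a constant to all of one
sample's Ct values leaves its ΔCt unchanged.

## Dual-reference fold changes and ranking

Group profiles aggregate the mean of ΔCt over expressing members — the
geometric mean on the linear scale, the standard ΔΔCt convention (an
arithmetic-linear alternative is available). The case-vs-group fold is
2^(−(ΔCt_case − mean ΔCt_group)), so swapping arguments inverts the fold
exactly. A marker is called overexpressed when its fold is ≥ 2.0
(inclusive) against *both* the control and the other-tumor reference
groups; assays not expressed in the case are never called, whatever the
group values, since overexpression requires a defined case level. Called
markers are ranked by fold vs controls, descending, ties broken
alphabetically. Published marker tables often reference both the case and
the comparison group to controls; `fold_vs_other_from_referenced` recovers
the direct case-vs-group fold as the ratio of the two printed columns.

Note one compositional property of global-mean centering: the case's own
spiked markers lower its sample mean by Σ log2(fold)/n, so every estimated
case fold is attenuated by the same factor (about 0.86 under the default
simulation; exact to 1e−9 in the zero-noise test). This is inherent to the
normalization, not an estimator defect, and it also suppresses false
positive calls.

## Strand-bias analysis

For a marker list, each assay falls in exactly one class: *no arm info*
(no suffix), *missing sister* (arm named but no opposite-arm probe on the
platform), or *informative* by arm. Only informative markers are counted:
an apparent arm excess among assays whose sister probe is absent could
reflect platform content rather than biology. The -3p count among n
informative markers is tested with an exact binomial test computed in
exact rational arithmetic (math.comb with Fractions): one-sided
P(X ≥ k) for the -3p-excess alternative (the default, since that is the
directional hypothesis the RNase IIIb mechanism motivates), or the
two-sided minimum-likelihood sum. Reports always state sidedness and the
null probability. The implementation is verified against exhaustive
enumeration of all 2^n outcomes for every n ≤ 20 and cross-checked against
an independent library implementation.

The two analyses that use arms answer different questions and are separate
operations: the discovery-list test uses the overexpressed list itself as
its universe, while the per-sample arm-fraction summary uses the
platform-wide dual-probe universe (percentages of each sample's expressed
members, summing to 100 where defined).

On printed counts of interest, the one-sided values are 0.0214 for 21/30
and 0.0107 for 9/10 (two-sided: 0.0428 and 0.0215). Reported "exact
binomial" p-values in the motivating literature for these counts (0.013,
0.0098) match neither convention exactly; sidedness is therefore an
exposed parameter rather than something tuned to reproduce a printed
number.

## Housekeeper selection and monitoring

Housekeeper candidates must be expressed in **all** cohort samples;
stability is the SD of globally normalized ΔCt across samples (not raw Ct,
so loading offsets do not masquerade as instability), and the k = 3 lowest
SDs win, ties alphabetical. Targeted-panel levels are then
ΔCt vs the arithmetic mean of housekeeper Ct (geometric mean of linear
levels, the standard multi-reference convention), referenced to a
configurable comparator sample — the comparator maps to exactly 1.0 —
and ordered by day offsets taken from the sample sheet, never assumed.
Marker–marker association uses ordinary least squares
(scipy.stats.linregress) with a two-sided p for zero slope; a flat
response returns slope 0, r 0, p 1 rather than NaN.

## Synthetic cohort generator

The generator emulates the study design the pipeline assumes, with
defaults chosen as that design's stated structure:

| parameter | default | meaning |
|---|---|---|
| n_assays | 741 | human assays on the platform (plus one spike-in row) |
| n_control / n_other_tumor | 20 / 32 | reference groups; with the index case, 53 discovery samples |
| n_relatives | 2 | mutation-carrier relatives, generated as controls |
| longitudinal_days | −11, −2, +3, +12 | case samples relative to treatment start (day −11 is the diagnostic/index sample; −2 and +3 are plumbing defaults between the printed anchors) |
| baseline_ct_range | Uniform(22, 35) | per-assay serum abundance |
| sample_shift_sd / noise_sd | 0.5 / 0.5 cycles | loading offsets and Gaussian cycle-scale technical noise |
| detection_limit / censor_limit | 37 / 40 cycles | expression-call threshold; censoring bound |
| spike_set_size | 45 | case-only overexpressed markers |
| spike_fold_range | 3.4–40.3 | log-uniform programmed folds (the span of the motivating marker table) |
| frac_informative_spiked / frac_3p_spiked | 30/45, 0.7 | arm composition of the spike set (21 -3p / 9 -5p / 14 no-arm / 1 missing-sister) |
| pair_prob | 1/3 | hairpins carrying both arm probes, giving a ~0.5 dual-probe platform fraction |
| flare_profile | 1.0, 1.6, 2.2, 0.25 | per-day multiplier on spiked levels: rising pre-treatment, an on-treatment flare, then a trough below baseline at day +12 |

Ct(a, s) = baseline(a) + shift(s) − log2(spike fold × flare) + noise, with
values above the censor limit written as "Undetermined". Other-tumor
samples receive small disjoint spike sets of their own (3 assays each,
2–8-fold) so the dual-reference filter is genuinely exercised; relatives
carry no spike effect, modeling the observation that a germline mutation
alone produces no serum signal. The named control assays (miR-451,
miR-23a, the three housekeepers, cel-miR-39-3p) get fixed baselines, and
housekeepers/spike-in get reduced technical noise so that stability
selection has a programmed answer. Hemolysis (−6 cycles on miR-451) and
spike-in failures (+3.5 cycles) are injected only into explicitly listed
samples. The per-assay arm-suffix distribution applies to unpaired
hairpins; paired hairpins are drawn with `pair_prob`, because independent
per-assay suffix draws could not produce sister-probe pairs. Everything is
deterministic given the seed, and `truth.json` carries spikes, folds,
arms, baselines, shifts and the flare profile — enough to recompute every
expected output analytically.

What the generator does **not** emulate: plate/batch effects, inter-run
calibration, sequence-level cross-hybridization, isomiRs, non-Gaussian
outliers, and any real biological covariance between miRNAs. Passing
recovery tests therefore demonstrates the pipeline's correctness under its
own assumptions, not clinical performance on real serum.

## Problem sizes and numerical choices

Recovery statistics use 20 default-size cohorts (741 × 58); test size and
power of the arm test use 2000 and 1000 simulated 30-marker lists;
regression recovery uses 500 replicates of 12-point fits — sizes at which
the binomial/Monte-Carlo error is well below the asserted margins.
Boundary conventions are inclusive everywhere a threshold is stated
(Ct ≤ 37 expressed, fold ≥ 2.0 called). Fold-change ties in ranking break
alphabetically for determinism. Undefined quantities propagate as NaN and
never satisfy a call criterion. The exact binomial p is computed in
rational arithmetic and converted to float only on return, so oracle
equivalence holds to machine precision.

## Known limitations

- The measured case-vs-control fold is attenuated by the compositional
  factor described above; with hundreds of assays and tens of spikes the
  factor is ~0.9, but on small panels it would be material.
- The linear-scale marker–marker regression is noise-sensitive at high
  folds (cycle noise is multiplicative on the linear scale); with the
  default 0.5-cycle noise, r between two proportional markers over a
  six-sample series varies widely across seeds. Log-scale regression of
  the same series would be more stable but is not what the monitoring
  convention reports.
- Hemolysis thresholds are conventions, not calibrated to any measured
  erythrocyte panel; both are configurable.
- The single index case is a fundamental design limit: no variance
  estimate exists for the case side of any fold change, so no per-marker
  significance is attached to the discovery screen (and no multiple-testing
  correction is applied).
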