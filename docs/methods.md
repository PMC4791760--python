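# Methods

This note documents the models and procedures implemented in `dsdseq`, the
assumptions behind them, the parameters that matter, and what the synthetic
cohort generator does and does not emulate.

## Panel geometry and windows

Coordinates are 0-based half-open throughout (BED convention), so interval
length is `end − start`; the reported size of a duplication bounded by
ChrX:30322539–30749577 is 427,038 bp by this arithmetic. Target regions
shorter than 100 bp are padded to 100 bp about their center before merging
of overlaps; an odd padding deficit puts the extra base on the end side
(a deterministic tie-break), and padding clipped at coordinate 0 shifts
entirely to the right. Depth analysis tiles each target with 30-bp windows
at 25-bp steps. Targets shorter than 30 bp are padded equally from both ends
and yield one window; for longer targets only full-length windows are
emitted — a sub-window tail is dropped rather than emitted short, so every
window's GC fraction is computed over the same length. The span of *k*
consecutive windows is (k−1)·25 + 30, hence 130 bp at the five-window
calling minimum.

## GC-bias correction

Capture and amplification depress coverage at extreme GC. Correction is per
sample: window depth is LOWESS-regressed on window GC (span 0.3, i.e. 30 %
of windows per local fit, 2 robustness iterations — the span is a smoothing
choice exposed in config; smaller spans track noise, larger ones flatten
genuine bias), the sample's mean window depth serves as baseline, and each
window's depth is divided by `fitted/baseline` clamped below at 0.1. The
clamp prevents explosive corrections in the sparse GC tails; clamped windows
are flagged low-confidence and excluded from dosage baselines downstream.
The correction redistributes depth along the GC axis without rescaling the
sample (mean depth is preserved to within a few percent), and it is fully
deterministic.

## Sex-chromosome dosage and karyotype

The autosomal baseline (chrATO) is the mean corrected depth over all
autosomal windows after discarding both 5 % quantile tails — a symmetric
trim that removes windows sitting on CNVs or capture dropouts. Dosage
ratios are marker-window means over this baseline, using only windows from
the 40 designated chrX genes and 6 chrY genes; restricting to uniquely
mapping marker genes avoids pseudoautosomal and X/Y-homologous targets
whose depth is ambiguous.

Classification is nearest-centroid in (chrX/chrATO, chrY/chrATO). The
default centroid table uses empirical targeted-capture cluster means — one
X copy 0.5134, two X copies 1.0188, one Y copy 0.4160, null Y 0.0031 — with
XXX (1.53) and XYY (0.83) extrapolated linearly. The one-Y value sits well
below the theoretical 0.5 because chrY capture/mapping efficiency is
systematically lower; keeping the empirical value, and giving the simulator
a matching per-chromosome capture-efficiency parameter, makes the default
classifier self-consistent with default simulations. A call is `ambiguous`
when the nearest centroid is farther than 0.15 or the two best distances
differ by less than 0.05; both limits are config-overridable. Whole-
chromosome dosage only — mosaicism and partial rearrangements are out of
scope.

## Batch QC

A sample is compared, chromosome by chromosome, against the median corrected
profile of the *other* samples in the batch (leave-one-out, so an aberrant
sample does not drag its own reference). Pearson correlation is used; a
constant profile, for which r is undefined, scores 0. The sample fails QC
when its mean correlation over chromosomes is below 0.6, or when more than
four chromosomes correlate below 4/5 of the other samples' mean level for
that chromosome. Batches of fewer than three samples cannot define a
reference and skip QC with a recorded warning.

## Negative-binomial calibration and HMM copy-number calling

Corrected depths of one window across the batch are modelled as negative
binomial with variance μ + μ²/size; the method-of-moments fit is
size = m²/(v − m), falling back to Poisson when v ≤ m. Windows with zero
batch coverage are masked and never reach calling. Per-window ratios
(corrected depth over batch mean) feed a hidden Markov model with states
copy number 0–4. The emission for state CN at a window is the window's NB
density evaluated at the observed corrected count with mean scaled by
CN/expected copies; the zero-copy state keeps a small residual mean (2.5 %
of the window mean) because truly deleted windows still collect mismapped
reads. Expected copies come from the karyotype call for chrX/chrY (1 or 2)
and are 2 on autosomes. Transitions stay in the current state with
probability 0.98 and switch uniformly otherwise; the initial distribution is
uniform. Decoding is exact Viterbi.

The stay probability was set from the emission arithmetic: at 300× and NB
size 30, a heterozygous duplication (ratio 1.5) contributes ≈ 2.6 log units
of evidence per window, so the minimal five-window event carries ≈ 13 units;
two transitions must cost less than that (2·ln((1−0.98)/4) ≈ −10.6) or
minimal events can never be called. The five-consecutive-window segmentation
rule is what controls false calls (no false positives observed in 100
simulated clean samples). Segments report the window-bounded (inner)
interval and outer bounds extended to the flanking normal windows, since the
true breakpoint can lie anywhere between the terminal base inside the event
and the adjacent non-CNV base. Events smaller than 130 bp are below the
design's resolution and are intentionally not reportable.

## SRY detection in XX samples

The module consumes a per-base depth table over the *SRY* target — produced
upstream by realigning XX samples to a chrY-free reference, extracting
unmapped read pairs and remapping them to chrY — and summarizes it as
breadth (fraction of bases at ≥ 10×) and mean depth. A sample is called
positive when breadth ≥ 0.9. True positives show the entire gene covered at
~100×+, while negative samples show only sparse sub-1× mismapping noise, so
the call is far from both thresholds in practice; the thresholds are
deliberately conservative and configurable. Applying the check to a non-XX
karyotype is refused, since XY/XXY samples carry SRY constitutively.

## Variant triage

Steps 1–3 are pure predicates and commute: coverage (depth ≥ 8 and
quality ≥ 30; boundaries kept — the cascade excludes strictly-below
records), frequency (every recorded population AF ≤ 0.05; absent
frequencies count as unobserved so novel variants survive), and region
(intronic/UTR/synonymous discarded unless splice-site or a catalogued HGMD
mutation). Step 4 accepts a variant when at least one inheritance model
fits every typed family member: autosomal recessive (affected homozygous,
typed parents heterozygous), X-linked (one-X individuals hemizygous if
affected, allele from a carrier mother or de novo), de novo (both typed
parents reference), or dominant (all affected carry, no unaffected does).
Hemizygosity is judged from the *dosage karyotype* when available rather
than reported sex — a 46,XY phenotypic female is genetically hemizygous.
Compound-heterozygote candidates pair any two surviving heterozygous
variants in one gene; phase is unknown, and a trans configuration is
required only when both parents are typed. Parental origin is reported as
mat/pat/de novo/untyped.

Survivors are classified by a deliberately small three-way rule: Pathogenic
when the nucleotide or protein change matches a curated known-pathogenic
set; Likely pathogenic for novel protein-truncating changes with consistent
segregation; otherwise VUS. This is a surrogate for full guideline-based
interpretation (evidence-code engines are out of scope) that reproduces the
standard triage pattern for panels of this kind. Phenotype matching is a
free-text report concern, not a computed filter.

## Synthetic cohort generator

The generator emulates, at the count level, everything the pipeline reads:
`count ~ NB(mean_depth · copies/2 · gc_bias(gc) · capture_eff, size)` per
window, with defaults mean depth 300×, NB size 30, multiplicative GC bias
`exp(1.0·(gc − 0.5))` (a monotone ±~28 % swing over the panel's 0.25–0.75 GC
range), chromosome capture efficiencies chrX 1.02 / chrY 0.832 (so one Y
copy ≈ 0.416 of baseline, matching the default centroids), and per-window
probe efficiencies drawn once from a lognormal (σ = 0.35) stream fixed by
the panel design, not the run seed. The probe-level term matters: without
shared window-to-window structure, GC-corrected profiles would be pure
noise and the correlation-based QC could not distinguish good samples from
bad — real capture data always carries strong probe-level structure. The
toy panel spans a fictitious mini-genome (six autosomes, coordinates
< 10 Mb, 40 X-marker and 6 Y-marker genes) so fixtures stay tiny.

The 45-sample validation cohort is 17 XX, 24 XY, 3 XXY and 1 XO. Variant
scenarios generate VCF/PED pairs with recorded truth (an X-linked
two-brother family, a de novo truncating case, plus common noise variants
that the frequency step must remove), and a 21-proband triage cohort is
composed as 6 catalogued-pathogenic, 2 novel-truncating, 3 novel-missense
and 10 unresolved families. Everything is seeded: identical config and seed
give byte-identical outputs.

What the generator does **not** emulate: read-level artifacts (mapping
quality, duplicates, strand bias), GC bias that varies between samples in
*shape* (only amplitude via the shared curve), mosaicism, partial-chromosome
events, relatedness between cohort samples, and realistic variant-site
noise (genotyping error). Passing tests therefore demonstrate the
correctness and calibration of the analysis given its modelled inputs, not
robustness to every artifact of real capture sequencing.

## Problem sizes and numerical choices

The test suite and acceptance script run on the toy panel (696 windows,
batches of 8–16 samples, cohorts of 45), where the full suite completes in
about two minutes. Duplication-recall simulations use a 14-window
(two-target) event in a 12-sample batch over 100 seeds; recall of minimal
five-window events is inherently lower (the 130-bp floor is the detection
limit, not the high-power point). LOWESS is deterministic; Viterbi ties are
broken toward the lower state index via argmax, though ties have measure
zero with continuous emissions. NB pmfs are evaluated at integer-rounded
corrected counts.
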