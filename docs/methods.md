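# Methods

This note documents the models and procedures implemented in
`vocalgwas`, the defaults chosen where the design was open, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Source-filter synthesis

Synthetic voiced audio follows the classical source-filter model. The
glottal source is an impulse train produced by phase accumulation
along a prescribed f₀ contour (constant, linear drift, or sinusoidal
vibrato), shaped by a one-pole decaying exponential with a 50 Hz
cutoff — the textbook −6 dB/oct glottal spectrum that formant-analysis
pre-emphasis at 50 Hz is designed to flatten. Placing the source pole
at 50 Hz (rather than inside the F₁ region) matters: a source pole
near 300 Hz is indistinguishable from a low first formant and corrupts
F₁ estimation. The vocal-tract filter is a cascade of second-order
resonators, one per formant target, with unity DC gain and default
bandwidths 80/90/120/130 Hz for F₁–F₄. White Gaussian noise is added
at a configurable SNR, default 50 dB, emulating a sound-attenuated
booth with professional condenser microphones; formant tracking of
back-vowel F₃/F₄ degrades below roughly 45 dB because those peaks sit
40–60 dB below the F₁ region.

Default vowel templates (F₁, F₂ in Hz) are generic cardinal values for
the five Icelandic monophthongs: [i] (300, 2200), [ɛ] (550, 1800),
[a] (750, 1300), [ɔ] (500, 900), [u] (350, 800), with F₃/F₄ at
2500/3500 Hz. The elicitation battery per speaker comprises one
reading proxy (default 25 s concatenation of randomized vowel
segments under a drifting f₀ contour — no attempt at linguistic
fidelity), two tokens of each vowel, one ~4 s sustained [a], and two
tokens of each of two word proxies (16 labeled segments). Every
generator returns its exact ground truth (f₀ contour, formant centers)
and is bit-reproducible given its seed.

What the generator does **not** emulate: consonants, coarticulation
and prosody; jitter/shimmer and voice-quality variation; microphone
transfer functions and room acoustics; speech pathology. Passing
recovery tests on this material therefore demonstrates estimator
correctness on idealized voiced speech, not robustness to real-world
recording variability.

## Cohort model

Speakers are adults (ages clipped-normal, mean 54.1, SD 14.7, range
18–93; 56% female). Voice pitch baselines: males flat at 124.0 Hz
until 60, rising 0.6 Hz/yr after; females fall 0.8 Hz/yr from
223.3 Hz (at 25) to ~195 Hz at 60, flat thereafter. Within-sex
residual SD defaults to 19 Hz, the scale at which a 0.11 SD effect on
the standardized trait corresponds to ~2.1 Hz per allele. The planted
causal variant acts additively on the Hz scale and is centered at the
population mean dosage so the stated baselines remain population
medians. Relatedness comes from sib-pair pedigree blocks: parental
haplotypes are drawn at the founder allele frequency and transmitted
by Mendelian sampling, giving an expected kinship coefficient of 0.25
between sibs. The kinship matrix defaults to the pedigree expectation
(φ convention: 0.5 diagonal) for deterministic test expectations; an
empirical genotype-based estimate (VanRaden GRM/2) is available. The
mixed model uses K only up to proportionality, so the convention is
inert.

## Acoustic estimation

**Pitch.** Sliding-window analysis with sex-specific ranges (60–220 /
100–300 Hz) and windows (60/40 ms); the hop is window − 10 ms (the
"overlap" read literally as shared duration; configurable). Each
Hann-windowed frame's autocorrelation is normalized by the window's
own autocorrelation (Boersma-style), and candidate peaks are local
maxima above a voicing threshold of 0.45. Candidates are scored with
an octave cost of 0.05 per octave below the range ceiling, which
suppresses subharmonic (half-f₀) errors without a dynamic-programming
path search; the winner is refined by parabolic interpolation and
clamped to the search range. Contour refinement is exactly:
linear interpolation of interior gaps → 5-point running median
(nearest-edge padding) → removal of values beyond 3 scaled MADs
(×1.4826) from the contour median. When the MAD is zero (majority of
frames identical), the rule's strict limit applies: any deviation from
the median is removed. Summaries are the median, sample SD (ddof 1)
and Fisher–Pearson skewness g₁ = m₃/m₂^{3/2} of retained values; fewer
than 3 values yields a missing-measure marker, not an exception.

**Formants.** The signal is resampled to twice the sex-specific
ceiling (10/11 kHz), pre-emphasized once as a whole with coefficient
exp(−2π·50/fs) (per-frame pre-emphasis creates boundary spikes that
bias the pole fit), and analyzed in Gaussian windows every 10 ms. The
stated 25 ms window is the effective duration; the physical window is
twice that, following Praat's convention for Gaussian tapers. Burg
linear prediction of order 10 yields pole candidates; those with
bandwidth < 400 Hz and frequency in (50 Hz, ceiling) are sorted
ascending into F₁…F₅. Summaries (median/SD of F₁–F₄) use only frames
whose linear RMS intensity is at least half the utterance maximum,
each formant summarized over the frames where it is present.

**Known bias.** With a periodic source, the spectrum samples the
vocal-tract envelope only at harmonics, so LPC pulls low formants
toward the nearest strong harmonic. For close vowels at female pitches
([i] with F₁ = 300 Hz at f₀ ≈ 200 Hz) this produces a systematic
+25–40 Hz (up to ~10% relative) F₁ overestimate that no tested
variation of SNR, window, or model order removes; it reproduces the
well-documented error-proneness of automatic formant measurement at
high pitch. F₂/F₃ recover within 5% across all templates and both
sexes, and f₀ recovers within 0.1 Hz. The acceptance suite asserts
the stricter 5% bound for all three formants and is expected to fail
on female close-vowel F₁; the regular test suite asserts the measured
envelope (F₁ ≤ 12%, F₂/F₃ ≤ 5%).

**Silence trimming** replaces forced-alignment segmentation: 10 ms
frame RMS is compared to the loudest frame; edge silence below
−25 dB is always removed, internal pauses only when longer than
100 ms.

## Phenotype catalog

The default manifest enumerates 66 measures: 3 pitch statistics
(median, SD, skew) × 5 tasks (reading, vowels, words, sustained [a],
and the across-task global average); median and SD of F₁–F₄ for each
of the five vowels and for the all-vowel average; and VSA4, FCR, VTL.
The catalog column count is printed in the manifest and is
configuration-driven — the enumeration is a documented default, not a
claim about any particular study's measure list. QC removes manually
flagged speakers first, then speakers with < 70% of manifest measures
present (completeness percentages are reported against the
post-manual denominator). Measures are log-transformed (skew, which
can be negative, stays raw), adjusted within sex by OLS on age, BMI,
height and microphone indicators (missing covariates exclude the
speaker from that measure; no imputation; age enters linearly by
default with an optional quadratic), and inverse-normal transformed
within sex with the Blom offset 3/8 (offsets 0 and 0.5 also
supported). Per-sex INT makes the sexes separately standard-normal, so
pooled association analysis is scale-free.

## Correlation scan

Pearson correlation (point-biserial for case-control) on the
pairwise-complete intersection, two-sided P from the t transform,
95% CI by Fisher z. Results with intersection ≤ 100, degenerate
variance, or no case/control mix are suppressed but recorded. The
Bonferroni threshold divides α by the full grid size. Per-sex effects
are compared on the Fisher-z scale with SE 1/√(n−3); the
heterogeneity P uses z = (b_m − b_f)/√(se_m² + se_f²), equivalent to
a two-stratum Cochran Q. Combined-sex r is computed on the pooled
per-sex-standardized values rather than meta-analyzed across strata.

## Mixed-model association

For each trait, REML estimates of (σ²_g, σ²_e) are obtained by
profiling the likelihood over h = σ²_g/(σ²_g + σ²_e) on the eigenbasis
of K (bounded scalar minimization, tolerance 1e-8); K is
eigendecomposed once and reused, and diagonal K short-circuits the
rotation, so identity kinship reproduces OLS exactly rather than
approximately. Per-variant tests reuse the null variance components
(EMMA/score-style approximation — standard practice, vastly cheaper,
negligible bias at polygenic effect sizes) but compute an exact
per-variant GLS slope, SE and t-based P with a per-variant residual
variance. Monomorphic or collinear variants are skipped with a
reason. Hardy-Weinberg/imputation-quality filters are consumed as
input flags, not recomputed; no principal-component adjustment is
applied (the simulated population is homogeneous). Coordinates are
1-based (GRCh38 convention).

## Fine-mapping and colocalization

Wakefield ABFs are computed in log space with prior variance W = 0.04
(prior SD 0.2 on the SD-unit effect scale; configurable). Posteriors
are normalized over the region under a one-causal-variant assumption;
the credible set is the smallest posterior-sorted prefix with
cumulative mass ≥ 0.95, which is optimal because the posterior-mass
maximizing subset of any size is always the top-k prefix. Ties are
broken by stable sort order. Colocalization is a pure LD-overlap
lookup: external records whose variant has r² > 0.8 with the lead are
reported with their effect directions; no statistical colocalization
model is fitted.

## Fixed-derived scan

Biallelic SNVs only. The ancestral state requires all three outgroups
present and identical; any missing outgroup call excludes the site
(conservative: no call without a confident ancestral state). The
human allele must differ at frequency strictly above 0.9999 and the
impact annotation (consumed, VEP-style, never computed) must be high
or moderate. Archaic genotypes are classified per genome as
homozygous-fixed, carries-ancestral, or missing. Gene summaries take
BED intervals (0-based half-open), convert internally to 1-based
(p ∈ (start, end]), count calls per gene, bucket intergenic calls
separately, and report the fraction of genes with at least one call.

## Problem sizes and numerical choices

The end-to-end demo runs 100–200 speakers with ~60–500 variants and a
3–8 s reading proxy; the calibration suites use 2000 null variants at
n = 500, 100 effect-recovery replicates at n = 2000 (kinship
eigendecomposition computed once and shared), and 100 fuzzed
alignment fixtures. These sizes make the full validation run in about
a minute on one CPU while keeping Monte-Carlo error small relative to
the asserted bounds. All randomness flows from explicit seeds;
rerunning any stage with the same configuration is bit-identical.

## Limitations

- Formant F₁ of close vowels at high f₀ is biased upward (see above);
  vowel-space metrics inherit this bias in a speaker-independent way.
- The reading-task proxy has no linguistic content; pitch statistics
  from it are realistic, but nothing downstream should be interpreted
  as modeling real read speech.
- The 66-measure manifest is a documented default, not a replication
  of any specific study's measure list.
- Heritability-style summary statistics (LD-score methods), eQTL/pQTL
  measurement, imputation and variant calling are out of scope;
  annotations and external association tables are consumed as inputs.
- Jitter, shimmer, harmonics-to-noise ratio and other voice-quality
  measures are not implemented.
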