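# vocalgwas

Tools for studying the genetics of the human voice: acoustic
phenotyping of speech recordings (voice pitch, vowel formants,
vowel-space metrics), phenotype QC and normalization, phenome-wide
correlation scanning, kinship-aware mixed-model GWAS with
annotation-weighted significance, credible-set fine-mapping, and a
scan for human-fixed derived coding variants against primate
outgroups. A synthetic-data module generates every input with known
ground truth, so the whole pipeline can be exercised and validated end
to end without any external data.

The package is aimed at researchers who want a transparent, testable
reference implementation of this analysis path — from WAV files to
credible sets — at desk scale.

## What it computes

**Acoustics.** Fundamental frequency f₀ (voice pitch) is tracked with
a windowed normalized autocorrelation using sex-specific search ranges
(60–220 Hz male, 100–300 Hz female) and window lengths (60/40 ms);
contours are refined by interpolation, a 5-point running median and
MAD outlier removal, and summarized as median, SD and skew. Formants
F₁–F₅ are estimated by Burg linear prediction (order 10) after
resampling to twice the sex-specific ceiling (5000/5500 Hz) with 50 Hz
pre-emphasis, 25 ms effective windows every 10 ms, and summarized over
frames whose intensity exceeds half the utterance maximum.

**Vowel space.** Quadrilateral vowel space area (VSA4) from the
corner vowels [i, a, ɔ, u]; formant centralization ratio
FCR = (F₂ᵤ + F₂ₐ + F₁ᵢ + F₁ᵤ) / (F₂ᵢ + F₁ₐ); apparent vocal tract
length from formant spacing, VTL = c / (2 ΔF) with c = 353 m/s, where
ΔF is the through-origin regression of Fₙ on (2n − 1)/2.

**Phenotype table.** QC cascade (manual flags, then ≥ 70%
completeness), per-sex adjustment of log measures for age, BMI, height
and microphone, and rank-based inverse normal transformation
Φ⁻¹((rank − 3/8)/(n + 1/4)).

**Association.** The mixed model y = Xβ + u + e with
u ~ N(0, σ²_g K) for kinship matrix K, fitted by REML on the
eigenbasis of K; per-variant GLS tests reuse the null variance
components. Significance is weighted by annotation: 2.5×10⁻⁷
(loss-of-function), 5.0×10⁻⁸ (moderate), 4.5×10⁻⁹ (low), 2.3×10⁻⁹
(DNase-hypersensitivity-site), 7.5×10⁻¹⁰ (remaining). Effects in SD
units convert to Hz per allele via the trait's residual SD; the
homozygote effect is twice the per-allele effect.

**Fine-mapping.** Wakefield approximate Bayes factors
ABF = √(V/(V+W))·exp(z²W/(2(V+W))) with V = SE², prior W = 0.04;
normalized ABFs are posterior probabilities and the 95% credible set
is the smallest posterior-sorted prefix reaching 0.95, with r² to the
lead variant attached.

**Comparative genomics.** A site is human-fixed derived when
chimpanzee, bonobo and macaque agree on the ancestral allele, the
human allele differs at frequency > 99.99%, and the impact is
high/moderate; calls are checked against archaic genomes and
summarized per gene.

## Worked example

Run the full synthetic study (100 speakers in sib pairs, 60 variants,
a planted 25 Hz-per-allele pitch variant) from Python:

```python
from vocalgwas import RunConfig, run_all

cfg = RunConfig(n_speakers=100, n_variants=60, causal_effect_hz=25.0,
                seed=11, reading_duration=3.0, vowel_duration=0.4,
                sustained_duration=2.0, n_library_traits=6)
res = run_all(cfg, "demo_run")

a = res["assoc"]
top = a.loc[a[~a["skipped"]]["p"].idxmin()]
print(top["variant"], top["beta"], top["p"], top["beta_hz"])
cs = res["credible_set"]
print(cs.lead, cs.size, cs.mass)
```

This prints (numbers from the run above):

```
var00030 beta=0.897 se=0.113 p=3.63e-12 beta_hz=26.78 sig: True
credible set: 1 variants, mass 1.000 lead var00030
fixed calls: 7
```

`var00030` is the planted causal variant: the scan recovers it as the
strongest association (0.90 SD per allele on the inverse-normal scale,
equivalent to 26.8 Hz given the cohort's 29.9 Hz within-sex residual
SD — consistent with the planted 25 Hz), it is genome-wide significant
under the weighted thresholds, the 95% credible set contains exactly
that variant, and the alignment scan returns exactly the 7 planted
fixed-derived sites. The same pipeline is available from the shell:

```bash
vocalgwas run-all --out demo_run --seed 11
vocalgwas fixedscan --alignment demo_run/alignment.tsv --out calls.tsv
```

The null-model fit is a statsmodels-style object:

```python
from vocalgwas import KinshipMixedLM
fit = KinshipMixedLM(y, X, kinship=K).fit()
print(fit.summary())      # variance components + fixed effects
res = fit.test_variants(dosages)   # per-variant beta, se, p
```

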