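# aacsia

Amino acid compound-specific stable isotope analysis (AA-CSIA) for
food-web ecology: essential amino acid δ¹³C fingerprinting, amino-acid
based trophic position estimation, isotope-gradient statistics, and
multivariate habitat discrimination, with a seeded forward simulator
that lets every stage be tested against known ground truth.

## Who this is for

Ecologists and biogeochemists working with per-amino-acid δ¹³C/δ¹⁵N
measurements of consumers (zooplankton, planktivores) who want to ask:
what primary producers support this consumer, what is its trophic
position, and do assemblages from different habitats (e.g. nearshore
reef vs offshore surface vs offshore deep) carry distinct isotopic
profiles?

## The model

**Fingerprinting.** Essential amino acids (EAAs: Ile, Leu, Lys, Phe,
Thr, Val) pass from producer to consumer with minimal carbon isotope
fractionation, so the *pattern* of a consumer's δ¹³C_EAA values traces
its basal carbon source. Within each sample the values are
mean-centered,

δ¹³C_j,centered = δ¹³C_j − (1/n) Σᵢ δ¹³Cᵢ,

removing the sample-specific baseline while preserving the relative
pattern (the producer "fingerprint"). Consumers are classified against
producer endmember fingerprints by linear discriminant analysis with
shared-covariance Gaussian posteriors.

**Trophic position.** Source amino acids (Phe, Lys) record the δ¹⁵N
baseline; trophic amino acids (Glx, Ala) enrich per trophic step.
Trophic position is

TP = ((δ¹⁵N_trophic − δ¹⁵N_source) − β) / TDF + 1,

with shipped presets Glx–Phe (β = 3.4‰, TDF = 7.6‰; metazoan transfer)
and Ala–Phe (β = 3.2‰, TDF = 4.5‰; includes protistan grazing steps).
Custom (trophic AA, source AA, β, TDF) quadruples are accepted as data.

**Statistics.** Ordinary least-squares regressions of isotope metrics
on ln(distance from shore) with Benjamini–Hochberg correction per
family; Shapiro–Wilk/Levene-gated group comparisons (ANOVA + Tukey or
Kruskal–Wallis + BH-corrected Dunn; Welch t or Mann–Whitney U for two
groups); one-factor PERMANOVA on Euclidean distances with a
betadisper-style dispersion companion test and BH-corrected pairwise
contrasts; Fisher LDA with loadings, between-group variance
proportions, and leave-one-out cross-validation.

## Worked example

`examples/03_gradient_statistics.py` simulates the default
three-habitat scenario and runs the gradient and group statistics:

```
d15N_Phe ~ ln(distance): slope -0.853 permil per ln km, adj R2 0.954, p 3.14e-27 (n=40)
TP comparison path: anova_tukey, omnibus p 1.28e-22
  reef vs offshore_surface: p_adj 5.13e-12
  reef vs offshore_deep: p_adj 0
  offshore_surface vs offshore_deep: p_adj 3.67e-13
```

The negative slope is the nearshore ¹⁵N enrichment decaying with
ln(distance) over surface waters; the pairwise Tukey tests recover the
reef < offshore surface < offshore deep food-chain-length ordering
built into the scenario. `examples/02_fingerprint_classification.py`
shows producer-source assignment (reef consumers resolve to their
diatom diet, offshore surface consumers to prasinophytes), and
`examples/04_full_pipeline.py` runs everything at once:

```
             block  n   pseudo_f       r2     p  dispersion_p
       carbon_only 56 307.694833 0.920705 0.001         0.623
   carbon_nitrogen 56 293.365308 0.917153 0.001         0.530
carbon_nitrogen_tp 56 287.717368 0.915663 0.001         0.572
```

Each feature block separates the three habitats (p = 0.001 is the
smallest attainable p at 999 permutations) with non-significant
dispersion, i.e. location rather than spread drives the separation.

## Command line

A thin CLI wraps the library:

```bash
aacsia simulate --seed 5 --out sim/            # dataset + truth table
aacsia analyze --input sim/dataset.csv --out report/
aacsia fingerprint --input sim/dataset.csv --out fp.tsv
aacsia tp --input sim/dataset.csv --params GlxPhe
```

All report tables are TSVs whose header line records the seed and a
configuration hash; identical configuration and seed reproduce them
byte for byte.

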