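# Methods

This note documents the models and numerical conventions behind each
module, what the synthetic generator does and does not emulate, and the
design choices made where the underlying workflow left the details open.

## Study design being modelled

Two treatment arms (a D1-specific and a D2-specific dopamine agonist,
`SKF` and `LY`) against a shared control. Transcripts are measured on
two-channel cDNA arrays in a common-reference design: each treatment
sample is hybridised against one pooled control, so each array yields
per-spot log2 ratios M that are directly comparable across arrays and
differential expression is a one-class test of M against zero. Proteins
are measured by iTRAQ 4-plex (control = label 114, LY = 115, SKF = 117):
each identified spectrum (PSM) carries three reporter intensities whose
ratios estimate protein-level fold changes. The cross-omics link is purely
sequence-based: regulated ESTs are translated and locally aligned against
the regulated proteins.

## Synthetic data generator

Hidden truth per gene: a coding sequence (ATG + random sense codons, no
internal stops; protein length uniform on [80, 160] residues by default),
its standard-genetic-code translation, and log2 effects per treatment and
layer. Exactly `round(n_genes x frac_de)` genes are regulated per layer
and treatment; every effect has fixed magnitude `effect_size_log2`
(default 1.0, i.e. 2-fold — the middle of the 1.1–8.6-fold range such
experiments report) and a random sign. For genes regulated in both layers
the protein sign equals the mRNA sign with probability `concordance_rate`;
this makes sign concordance the single controlled quantity the full
pipeline is asked to recover.

**Arrays.** Four arrays per treatment, the last a dye-reversal (channel
columns swapped); each gene printed in duplicate. Noise is multiplicative
lognormal: per-channel log2 noise of sd `array_noise_sd/sqrt(2)` (so a
spot's log ratio has sd `array_noise_sd`, default 0.2), plus two per-array
distortions the normalization must remove — a global intensity scale
(shifts A) and a treatment-channel gain (shifts M by an array constant).

**PSMs.** Peptides are in-silico tryptic fragments (cleave after K/R
except before P, no missed cleavages, 6–30 residues kept); proteins whose
digest is empty are skipped with a warning. Spectrum counts per protein
are Poisson with mean `spectra_per_protein` (default 14, the
spectra-per-identified-protein depth of the emulated study; after the
confidence and S/N filters a typical protein retains ~4 quantifiable
spectra, matching the "three good spectra = confident" tier convention).
Reporter noise is per-channel lognormal with log2 sd `reporter_cv/sqrt(2)`,
so each reporter *ratio* has log2 sd exactly `reporter_cv` (default 0.3)
and the two treatment ratios of one PSM are correlated 0.5 through the
shared control channel, as in real 4-plex data. Signal-to-noise sums are
lognormal(3.0, 0.8), putting ~16% of spectra under the >9 filter.

**Incorrect identifications.** On top of the T genuine PSMs the generator
draws `Binomial(T, f/(1-f))` decoy PSMs (peptides of reversed sequences)
and, independently, the same expected number of *false-target* PSMs —
incorrect identifications assigned to real proteins with null reporter
ratios. Without the false targets a decoy search would be estimating a
quantity that is identically zero. Correct identifications score
confidence ~ Beta(8,1); incorrect ones score Beta(1,8) with probability
0.85 and Uniform(0.9, 1) otherwise. The high tail is deliberate: the
working threshold of the field is 95% confidence (score 1.301), and a pure
Beta(1,8) would put no incorrect identification above it
(P ≈ 4e-11), making FDR estimation at that threshold vacuous. A hidden
`is_correct` column records the truth for test scoring; no estimator reads
it.

All randomness flows from one master seed through fixed per-table streams
(truth, arrays, PSMs), so adding arrays never perturbs the PSM table and
regeneration is bit-identical.

**What is not modelled:** pooling variance (RNA pools of several animals
vs single-animal iTRAQ labels are treated as one biological unit per
replicate), raw spectra/retention times/SCX fractions, isotope impurity,
print-tip or spatial array artefacts, sequence polymorphism between the
EST and protein databases, and hormone (LH) endpoints. Passing tests
therefore demonstrate statistical correctness of the estimators under the
stated noise model, not robustness to every artefact of real data.

## GPA normalization

Each array is a configuration of points, one per spot, with coordinates
(A, M) = (mean log2 intensity, log2 ratio). Dye-reversal arrays are
re-oriented (channels swapped back) first. Configurations are centred
(translation), scaled to a common Frobenius norm (isotropic scaling), and
then iteratively rotated (orthogonal Procrustes) to the evolving mean
consensus until the consensus residual changes by < 1e-10 (relative;
cap 100 iterations). Doing the scaling once up front makes every
subsequent step a least-squares minimisation, so the consensus residual is
non-increasing — a property the test suite checks on random inputs.

Back-transform: intensities are rebuilt from the aligned (A, M) with a
common A location (grand mean of the original per-array A means) and an M
location chosen so each output array is **median**-centred in M rather
than mean-centred. The mean translation used for alignment absorbs the net
log-ratio of the regulated genes — a real signal component — along with
the dye/gain offset; re-centring every gene by it shifts all unregulated
genes coherently, a bias the sign-flip permutation null cannot represent
(empirically ~3x the nominal false-positive rate at q < 0.05). The robust
location, dominated by unregulated genes, does not have this defect. The
convention is idempotent up to second-order rotation terms (< 1e-3 log2
units on repeat normalization).

## SAM differential expression

Duplicate spots are averaged per array first. For gene i with replicate
log ratios across arrays: d_i = mean_i / (s_i + s0), where s_i is the
standard error and s0 a fudge factor stabilising small-variance genes. s0
defaults to the 5th percentile of the s_i distribution — stable at
desk-scale gene counts — with the coefficient-of-variation minimisation
over an s-percentile grid available as `s0_method="tusher"`. Genes with
fewer than 2 finite replicates are excluded (q = NaN); zero scatter with
s0 = 0 yields d = ±inf, which simply ranks first (deterministic gene-id
tie-break in output ordering).

Null distributions come from sign-flipping whole arrays (the one-class
exchangeability); for each gene the estimated FDR at threshold |d_i| is
`median_b #{|d*_b| >= |d_i|} / #{|d| >= |d_i|}` (median over permutations,
clipped to [0, 1], no pi0 correction — conservative), and the q-value is
the minimum estimated FDR over thresholds at which the gene is still
called, making q monotone non-increasing in |d|. The median (not mean)
over permutations matters: with few arrays a non-negligible fraction of
sign vectors are the identity, which would otherwise leak true signal into
the null. Calibration under the global null and 100% recall at strong
effect are asserted in the acceptance tests. Fold changes are reported in
the signed convention: ratio r maps to +r when r >= 1 and -1/r otherwise,
so |FC| >= 1 always and the boundary r = 1 maps to +1.

## iTRAQ quantitation

Spectrum filter: confidence >= 0.95, signal-to-noise sum strictly > 9,
shared peptides excluded (verbatim strict/inclusive readings of the
workflow's thresholds). Identification scores are -log10(1 - confidence),
so 95% maps to 1.301; the reversed-database FDR at a score threshold is
(decoys above)/(targets above), reported with both counts and flagged
undefined when no target qualifies (it is not assumed monotone in the
threshold).

Aggregation is on the log scale: per-PSM log2(i_label/i114), protein log
ratio = arithmetic mean (symmetric treatment of up/down regulation,
matching the reciprocal fold-change convention), ratio = 2^mean. The error
factor is EF = 2^(t_{0.975, n-1} x SE), reproducing the stated semantics —
the true ratio lies in [ratio/EF, ratio x EF] 95% of the time — and the
p-value is the dual two-sided one-sample t-test (p < 0.05 iff 1 lies
outside the EF interval). Proteins need >= 2 filtered spectra (n = 2 is
tier "reported", n >= 3 "confident"); n < 2 refuses quantitation with a
"peptide signal was too low" reason; zero scatter is guarded (EF = 1,
p = 0, flagged). Selection uses raw p < 0.05 in >= 1 treatment by default;
a Benjamini-Hochberg-adjusted alternative is behind a flag because the
original workflow is ambiguous about whether its p-values were adjusted.
An optional global bias correction (median log-ratio re-centring per
channel, >= 10 proteins required) is off by default.

## Translated matching

Six frames via the standard genetic code (+1..+3 forward, -1..-3 on the
reverse complement; N-codons translate to X). Alignments never cross stop
codons: each frame is split at '*' and segments (>= 4 aa) are aligned
independently. The aligner is full Smith-Waterman with BLOSUM62 and affine
gaps costing 11 + k for a gap of length k (the classic gapped-search
defaults); at desk scale (tens of proteins) this is affordable and exactly
testable — the suite checks it against an independent pure-Python Gotoh DP
and, for tiny inputs, an exhaustive alignment-path enumeration.
Significance uses Karlin-Altschul E = K·m·n·e^(-lambda·S) with the
published gapped BLOSUM62 constants lambda = 0.267, K = 0.041, m the
frame's translated length and n the database residue count;
length/edge-effect corrections are omitted as the thresholds here are
order-of-magnitude decisions (E <= 1e-5 to accept, E <= 1e-8 for
annotation grade). One best hit per EST (highest score; ties break by
accession, then frame order). Internally coordinates are 0-based
half-open.

When several ESTs match one protein they are collapsed only if their
expression profiles are identical — regulated under the same treatments
with the same signs — in which case the largest-|FC| EST survives. Any
difference (an opposite sign, or regulation under different treatments)
keeps all of them, flagged "starred", since they may represent distinct
genes; this is the rule that reproduces the asterisked duplicate rows of
the packaged table, including its same-sign cross-treatment case.

## Pair table and concordance

One row per retained (protein, EST) match; DE proteins without a match
keep empty mRNA fields, and absent fold changes are never imputed. A
treatment's agreement counts only rows where both layers carry a fold
change for that treatment (rows whose two layers are regulated under
different treatments count toward shared-entity totals but no pair count;
starred rows each contribute their own pair). With zero pairs the fraction
is undefined, not 0. The null reference for an observed agreement count is
exact Binomial(n_pairs, 1/2), with a Monte-Carlo sign-resampling
permutation that converges to it. Venn-style totals count each entity once
across treatments; the protein/mRNA overlap equals the shared-entity count
by construction, which the tests assert as an internal consistency check.

The packaged table ships with a recorded sha256; the loader verifies it
and refuses silently edited fixtures. Its known quirk is surfaced, not
fixed: 15 rows carry both an SKF protein and mRNA fold change while the
originally reported denominator was 14 (the numerator, 8 agreements,
matches either way), so `summarize_table1` reports both numbers.

## Problem sizes and determinism

The acceptance checks run at desk scale chosen for statistical power per
unit time: error-factor coverage on 2000 proteins x 5 fixed spectra
(binomial 95% CI half-width ~1%); SAM calibration on 20 repeats of 1000
genes x 4 arrays with 100 sign-flip permutations; decoy FDR on ~3500 PSMs;
end-to-end recovery on 300 genes with 40% regulated per layer at
rho in {0.2, 0.5, 0.8}, pooling both treatments (~60-90 matched pairs per
rate, so the binomial CI separates the three rates). Every stochastic
quantity is seeded; pipeline runs with the same configuration are
byte-identical across the TSV/JSON outputs.

## Known limitations

- The permutation null for SAM with 4 arrays has only 16 sign patterns;
  q-values are coarse at very small replicate counts (mitigated by the
  median-over-permutations estimator).
- Karlin-Altschul parameters are treated as constants; E-values for very
  short segments are approximate (segments < 4 aa are not searched).
- The dedup rule keys on sign/treatment patterns only; it does not model
  quantitative similarity of fold changes.
- GPA idempotence and rotation behaviour are guaranteed only for the
  2-D (A, M) representation used here.
- Raw p-value protein selection reproduces the emulated workflow's
  reported counts but is anti-conservative by construction; the BH option
  exists for calibrated use.
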