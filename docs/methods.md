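# Methods

## Design and model

The data are three omics layers from the same cohort: a log2 miRNA
expression matrix over groups N (adjacent normal, n=5), T (tumor,
n=7) and F1 (first-passage patient-derived xenograft, n=8); protein
differential-expression tables per (contrast, subcellular fraction)
with fractions membrane and cytosolic; and mRNA DE tables per
contrast. The two contrasts are TvN = T − N and F1vT = F1 − T, always
with the first-named group as numerator. Groups are treated as
unpaired independent samples: the cohorts are not fully matched and no
pairing structure is modelled.

Expression is analysed on the log2 scale. Probe/replicate-level values
can be summarized by a one-step Tukey biweight: with median m and
median absolute deviation MAD, distances u_i = (x_i − m)/(c·MAD + eps)
give weights (1 − u_i²)² for |u_i| < 1 and 0 otherwise, and the
summary is the weighted mean (the median when every weight vanishes).
Defaults c = 5, eps = 1e-4. The eps guard means the c→∞ mean limit
holds only when MAD > 0; with MAD = 0 off-median points are simply
discarded, which is the desired robust behaviour for a
constant-with-outlier pattern.

Fold changes are reported as signed linear ratios: FC(Δ) = 2^Δ for
Δ ≥ 0 and −2^(−Δ) otherwise, so the image is (−∞,−1] ∪ [1,∞) and −2
means 2-fold down. Values in the open interval (−1, 1) are rejected by
the I/O layer as a convention violation.

## Moderated statistics

Each feature is fit in a one-way layout over the groups present
(every group needs ≥ 2 samples). The pooled within-group variance s_g²
has d_g = n_total − k degrees of freedom. The empirical-Bayes prior
(d₀, s₀²) is estimated by moment matching on
e_g = log s_g² − ψ(d_g/2) + log(d_g/2): under the scaled-inverse-χ²
prior, var(e) = ψ′(d_g/2) + ψ′(d₀/2) and
mean(e) = log s₀² − ψ(d₀/2) + log(d₀/2), where ψ and ψ′ are the
digamma and trigamma functions. The trigamma inversion is a monotone
bisection in log space on (0, 1e8] with relative tolerance 1e-10;
non-positive excess variance, or solutions beyond the bracket, declare
d₀ infinite with s₀² = exp(mean(e)). Zero variances are excluded from
estimation with a warning and floored at 1e-10 for test statistics (a
flag records which features were floored); if *no* positive variance
exists — possible only for fully noiseless synthetic input — the
analysis falls back to the unmoderated d₀ = 0 limit on the floored
variances.

The moderated t for a contrast with estimate Δ and unscaled variance
v_c (1/n_a + 1/n_b) uses s̃² = (d₀s₀² + d_g s_g²)/(d₀ + d_g) and a
Student-t null with d₀ + d_g df (normal when d₀ is infinite); d₀ = 0
recovers the classical pooled t exactly. The overall moderated F is
the between-group mean square over s̃² with (k−1, d₀+d_g) df (scaled
χ² when d₀ is infinite); d₀ = 0 recovers one-way ANOVA. These
identities, and agreement of the estimated prior and statistics with R
limma to ~1e-6 relative, are asserted in the test suite — limma serves
only as an independent oracle, never as the implementation.

Benjamini–Hochberg adjustment (adj_(i) = min_{j≥i} p_(j)·n/j, capped
at 1) is applied separately per contrast to the t p-values and across
features to the F p-values. The DE cascade keeps |FC| ≥ 1.5
(inclusive), raw p < 0.05 (strict), F-FDR < 0.005 (strict) and feature
ids with the case-sensitive prefix `hsa`; the inclusive/strict split
mirrors how the thresholds are conventionally stated (±1.5 fold,
p < 0.05, FDR < 0.005). Contrast p-values are the moderated two-group
contrasts within the three-group fit; per-contrast BH FDR is also
reported so either the raw-p or the FDR reading can be applied
downstream.

## Priority lists and attribution

Top-k (default 10) up and down lists are ranked by |FC| descending —
the triage is explicitly about changes of greatest magnitude — with
ties broken by ascending p then feature id. The same-direction list is
the intersection of the two filtered DE tables with equal fold-change
sign. The priority universe for integration is the union of the top-k
views and the same-direction list, deduplicated by feature id
(same-direction features carry both contrasts' values and the tag
`both`). Stem-loop (`hsa-mir-…`) and mature (`hsa-miR-…`) ids are
distinct features throughout; no collapsing rule is applied. For
recovery evaluation on synthetic data the universe can instead be
every cascade-passing feature (`k=None`).

Target predictions are filtered to binding probability ≥ 0.95
(threshold attained), 3'UTR binding site, and validated-interaction
evidence. Attribution emits a hit for a (miRNA, gene) prediction and a
protein DE entry of that gene when the two fold changes have strictly
opposite signs; hits are resolved per (contrast, fraction) because
proteins can and do flip sign across fractions. Two matching policies
exist:

* `same` (default): a protein entry is only compared with the miRNA's
  fold change in the entry's own contrast (`both` miRNAs match
  either).
* `any`: entries in either contrast may be attributed; the miRNA fold
  change used is that of the entry's contrast when available,
  otherwise the miRNA's own. The published integration tables this
  package reproduces pair xenograft-contrast miRNAs with proteins
  whose only DE evidence lies in the tumor/normal contrast, so the
  worked example and the acceptance computation use `any`; `same` is
  the stricter default for prospective analyses.

mRNA-concordance elimination then removes hits whose gene has an mRNA
entry in the protein's contrast with the protein's sign (status
`concordant`); opposite-sign entries mark `discordant` and missing
entries `absent`, both retained. Concordance is judged against the
protein's direction, not the miRNA's, because the elimination targets
transcriptionally explained protein changes. Whether elimination runs
before or after the multi-target summary is configurable
(`apply_mrna_filter`); the summary itself counts distinct gene symbols
per miRNA across all contrasts and fractions and reports counts ≥ 2.

## PDX provenance

Peptides are matched as exact substrings against every sequence of the
human and mouse databases (entries joined with a sentinel so matches
cannot span records). A protein with ≥ 1 human-unique and 0
mouse-unique peptides is human-not-murine; the mirror case
murine-not-human; everything else — all-shared evidence or conflicting
species-unique peptides — is ambiguous (the conservative reading). One
human-unique peptide suffices even when all others are shared. No
enzymatic digest, mass tolerance or PSM rescoring is modelled: the
categories are assigned by scrutiny of already-identified peptides.
Isoleucine and leucine are distinct by default with a `merge_il` flag
for the mass-spectrometry convention, since silent I/L folding is
easy to enable but hard to notice. Origin calls restrict the F1vT
protein list to human-not-murine genes; TvN entries (human tissue)
always pass.

## Synthetic data generator

The generator emulates the pipeline's inputs with the cohort sizes of
the study design (5/7/8) and a single seeded NumPy generator with a
fixed draw order, so identical configs are byte-reproducible.
Defaults: 300 miRNAs (10% `mmu-` prefixed), 400 genes, baseline log2
signal N(7, 1), per-observation noise sd 0.3, planted log2 effects
uniform on [0.7, 3.0] with random sign (so the weakest planted effect,
FC ≈ 1.62, clears the 1.5-fold filter), DE fractions 0.15 (TvN) and
0.2 (F1vT) plus 6 same-direction miRNAs shifted with equal sign in
both contrasts. Mouse transcripts receive TvN shifts at the combined
DE rate, giving the species filter real work; a fully null
configuration plants nothing anywhere.

Each planted-DE miRNA regulates 1 + Poisson(2) genes (mean 3, and at
least one, so edge recall is defined for every DE miRNA): the gene's
protein moves opposite to the miRNA with log2 magnitude β·|effect|
(β = 0.8) in one or both fractions, with no mRNA entry — the
post-transcriptional signature. True predictions get probability
U(0.95, 1), 3'UTR, validated. Decoy predictions (default 60) violate
at least one filter rule. Transcriptional decoy genes (default 10% of
genes) are inverse to a planted miRNA (so they enter the hit list)
*and* carry a same-sign mRNA entry, so the concordance filter should
remove them. Planted protein/mRNA p-values are U(1e-6, 0.01) for true
effects and U(0.2, 1) for background; the attribution logic consumes
direction only, so any sub-threshold scheme works. Background protein
and mRNA entries on 30% of null genes have random direction and no
filter-passing prediction pointing at them.

What the generator does not model — probe-level intensities, batch and
hybridization effects, mass-spectrometry missingness, correlated
miRNA families, partial target repression with mRNA decay — bounds
what the passing tests show: they validate the triage logic and its
calibration, not robustness to those real-data phenomena.

At desk scale the defaults give, e.g. (seed 42), 50 TvN and 66 F1vT
cascade-passing miRNAs, planted-edge recall 1.0 over edges whose miRNA
passes the cascade at noise sd 0.3, and elimination of all
transcriptional decoys. Null calibration (no planted effects,
n = 2000 features) yields a raw p < 0.05 fraction of ~0.05 and an
empty cascade in ≥ 19 of 20 seeds; these figures are recomputed by the
test suite. Problem sizes in the tests (300–2000 features, 20
samples, ≤ 20 seeds) were chosen as the smallest that make the
binomial noise on such fractions negligible.

## Numerical and I/O choices

All tables are single-header TSVs with `#` provenance comments; floats
are written with `repr` so rewrites and round-trips are bit-exact
(readers that go through pandas use `float_precision="round_trip"` —
the default pandas float parser is off by one ulp often enough to
break byte-determinism across staged runs). Report rows are sorted by
stringified field tuple, making reruns byte-identical. Readers reject
every type-invariant violation (duplicate ids, unknown groups,
probabilities outside [0,1], fold changes inside (−1,1), non-numeric
cells) rather than coercing.

Known limitations: the published-table fixtures inherit two printing
gaps (two cytosolic protein cells without p-values, one p-value with
an exponent-sign misprint) documented in `mirtriage.published`; the
species filter is a literal prefix test; and the provenance module's
exact-substring matching cannot detect isobaric substitutions beyond
I/L.
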