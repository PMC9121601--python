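# Methods

This note documents the statistical procedures implemented in `regvar`, the
defaults they run with, what the synthetic-data generator does and does not
emulate, and the design choices made where the underlying methodology is
genuinely open.

## LD extraction

r² between two sites is computed from phased haplotypes by direct counting,
in integer-count form to keep perfect LD exact:
r² = (n·n_AB − n_A·n_B)² / (n_A(n−n_A) n_B(n−n_B)), where n is the number
of haplotypes, n_A and n_B the allele-1 counts and n_AB the joint count.
Monomorphic sites have undefined r² and are skipped with a warning.
Unphased genotypes are rejected rather than EM-estimated (`assume_phased`
exists for genuinely phased data coded with `/`): accepting them silently
would change the estimator.

The partner threshold is **strict** (r² > 0.6 by default). At the
degenerate boundary r²_min = 1.0, exact copies of the index column
(r² = 1) are retained, since otherwise the setting would select nothing by
construction. A variant tagging several index SNPs is assigned to the index
with the highest r², ties to the earlier index in input order — an
arbitrary but deterministic rule for overlapping loci. No kilobase window
is applied internally; the caller restricts the panel to the locus of
interest.

## Motif model and exact p-values

PWMs hold per-position base probabilities. Scoring uses log-odds in bits
with a pseudocount: score(i,a) = log2((p(i,a) + pc·bg(a)) / ((1+pc)·bg(a))),
pc = 0.01 by default, which bounds scores away from −∞ while leaving a
background-distributed row at exactly 0 for any pc. The background defaults
to uniform 0.25 and is configurable; a uniform background makes synthetic
results reproducible and is the conventional default when no genome
composition is supplied.

Scores are rounded onto an integer lattice at ε = 10⁻⁴ bits. The null
distribution of the integer score of a random background word is built
exactly by per-column convolution over the lattice (O(w² · span/ε) work,
with an overflow guard that advises a larger ε). Because scanning uses the
same rounded matrix, reported p-values are exact for the matrix actually
scanned. A property test asserts equality with exhaustive 4^w enumeration
for all widths ≤ 6.

Scanning a ±20 bp allele window evaluates every offset on both strands
(reverse-strand hits are mapped back to forward coordinates). A candidate
hit needs p < 0.001 and, by default, must cover the SNP base
(`require_snp_overlap`): an occurrence that does not cover the SNP cannot
differ between alleles and so cannot inform disruption. Whether the original
screening procedure imposed this is not documented; the flag exposes both
behaviours. Ties among candidate hits break by score, then leftmost start,
then '+' strand. Positions containing N contribute score 0
(background-equivalent) — a conservative choice for reference gaps.

## Disruption calls

A (SNP, TF) pair is called **disrupting** when the SNP lies inside a peak
of that TF and exactly one allele has a qualifying motif hit. Both-allele
hits give `motif_retained`, no hits `no_motif`, and no same-TF peak
`no_peak` regardless of motif status — the peak criterion is per-TF, not
pan-TF. Allele-discordance is the operational reading of "binding-
disrupting"; a permissive mode (also call when both alleles hit but
|Δscore| ≥ δ bits, δ = 2) is available but off by default, since a pure
occurrence-plus-peak rule cannot distinguish alleles at all.

## eQTL scan, corrections, consensus

The built-in association model is single-SNP OLS of (log2) expression on
alternate-allele dosage: β = cov(g,y)/var(g), two-sided p from t with n−2
df. Degenerate cases are explicit: zero dosage variance → pair skipped;
constant expression → β = 0, p = 1; a numerically perfect fit → smallest
positive double, flagged. This is deliberately simpler than the
covariate/PEER-adjusted models behind published brain eQTL resources — the
faithful path is to ingest precomputed association tables and apply only
the correction and tally logic; the OLS path exists so the stage is
testable end-to-end on synthetic cohorts and calibrated under the null
(type-I error ≈ nominal, verified at 1000 null scans).

BH-FDR goes through `statsmodels` (verified against a hand step-up oracle),
Bonferroni is min(1, p·m). Two significance rules are supported because
both appear in practice: per-dataset FDR < 0.05 and uncorrected p < 0.01;
the consensus tally (SNPs significant in ≥ k of D datasets) takes either.
Note that when most tested pairs carry true signal, BH within a dataset is
liberal on the few null pairs; the raw-p rule gives the more predictable
false-positive behaviour in the planted-truth tests.

Differential expression is a per-gene Welch t-test on log2 values with
log2FC = mean(case) − mean(control) and BH-FDR across genes — a screening
stand-in, not a reimplementation of any consortium's DE model.

## ASE tests

Per SNP, the allelic read counts are tested with an exact two-sided
binomial test at p₀ = 1/2. The set-level enrichment test asks whether k of
n functional SNPs showing ASE is surprising given a genome-wide proportion
K/N (defaults 571,220 / 46,526,292, the GTEx v8 brain ASE catalogue —
treated as parameters, not computed quantities). Both tests use the
**minimum-likelihood two-sided convention**: p = Σ P(X=j) over all j with
P(X=j) ≤ (1+10⁻⁷)·P(X=k), matching R's `binom.test`. The pmf is computed
by exact products for n ≤ 64 so dyadic cases are bit-exact, and in log
space above that. Per-SNP significance defaults to raw p < 0.05 with
optional BH across SNPs (the significance calls consumed in practice come
precomputed, so no single convention is canonical).

## Synthetic-data generator

The generator emulates the statistical structure of the real inputs, not
their biology:

- **Motifs**: width 6, per-column information 1.5 bits (consensus
  probability solved by bisection). Width 6 is a deliberate choice: at the
  scan defaults (p < 0.001, uniform background) a width-6 consensus scores
  p ≈ 2.4×10⁻⁴ while any single mismatch scores p ≈ 4.6×10⁻³, so the
  planted alternate allele deterministically abolishes the hit. Wider
  high-information motifs leave one-mismatch words significant and make
  single-base "disruption" unrecoverable at that threshold.
- **LD**: partners copy the index haplotype and resample each entry with
  probability m = 1 − √r²_target, giving expected allele correlation
  √r²_target. This is transparent and analytically checkable; it does not
  model recombination maps, demography or allele-frequency spectra. Default
  targets 0.9 (retained) and 0.3 (dropped) span the 0.6 cutoff; at the
  default panel size (100 samples) sampling noise never crosses the cutoff
  in practice.
- **Classes**: disrupting SNPs sit at the maximum-information column of a
  planted in-peak motif with the minimum-probability alternate allele;
  decoys are in-peak-without-motif, motif-without-peak, and plain
  background; index SNPs anchor the LD structure. Placement is verified
  with the production scanner and offending windows resampled, so class
  labels are true by construction and recovery tests are sharp rather than
  probabilistic.
- **eQTL**: five cohorts of 200 samples, β = 1.0 per alt allele at
  MAF 0.3, unit noise; three SNPs share β across all datasets, the others
  are active in exactly one. Dosages are drawn independently per cohort.
- **DE**: 50/50 case/control, shift 0.5 on the consensus target genes,
  σ = 0.2. **ASE**: depth 100, imbalance 0.5 + 0.4 for ASE-true SNPs.

All randomness flows from one `numpy` Generator seeded by the config;
regenerated scenarios and reruns of the pipeline are byte-identical (float
output is fixed-format; the run manifest contains no timestamps).

What passing these tests shows — and does not show: they demonstrate that
each stage implements its stated statistic exactly or at its stated
calibration on data matching the generator's assumptions (independent
haplotypes, 0-order background sequence, single-SNP additive expression
effects, binomial read counts). They do not certify performance on real
genomes, where background composition, overlapping motifs, LD from real
demography, covariate structure and mapping bias all intrude.

## Numerical and scale choices

- Score lattice ε = 10⁻⁴ bits; DP overflow guard at 5×10⁷ cells.
- r² in exact integer arithmetic; clamped at 1.0 against rounding.
- Test-suite problem sizes (1000 LD oracle pairs, 100-seed threshold runs,
  20 recovery scenarios, 1000-replicate calibration loops) were chosen so
  the binomial uncertainty of each asserted rate sits well inside the
  asserted band; the full suite runs in well under a minute.

## Known limitations

- No D′, haplotype blocks, or EM estimation from unphased genotypes.
- 0-order background only; no q-value calibration across genome-scale scans.
- The eQTL OLS ignores covariates and relatedness; cis-window definition,
  trans effects and conditional analyses are out of scope.
- ASE is count-level only: no read realignment, mapping-bias correction or
  haplotype-aware aggregation.
- The enrichment background K/N is an external catalogue constant; its
  sampling uncertainty is not propagated.
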