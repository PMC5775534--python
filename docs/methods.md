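# Methods

This note documents the models, parameter choices and numerical decisions
behind `retrosilence`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Repeat annotation

RepeatMasker reports proviruses as separate fragments (internal segments
and flanking LTRs, often interrupted by short unannotated stretches). We
rebuild element-level units by merging fragments that share chromosome,
strand and repeat name whenever at most 100 bp lie strictly between them
("within 100 bp" read inclusively: a gap of exactly 100 bp merges).
Merging is a sorted sweep; it is equivalent to the transitive closure of
the pairwise gap relation, a fact the tests verify against a brute-force
oracle. Elements spanning strictly more than 5000 bp are full-length
("longer than 5 kb"); exactly 5000 bp is truncated.

A `name_scope` parameter restricts merging to chosen repeat names (e.g.
only IAP-related names) while passing everything else through unmerged; it
exists because fragment-level annotations are ambiguous about whether
internal and LTR fragments should be merged under one umbrella name or
per-name, and both behaviours should be expressible without code changes.
Internally all coordinates are 0-based half-open; RepeatMasker's 1-based
inclusive convention is converted exactly once, at the parser boundary.

## Counting regimes

A read is attributed to the element covering at least 50 % of its aligned
span. The attribution threshold is a package choice: it guarantees a read
is attributed to at most one element, and makes boundary behaviour exact
and testable. Ties between distinct elements at the same locus go to the
longer element, then to the lexicographically smaller name — an arbitrary
but deterministic rule.

Inclusive counting counts every read exactly once through its primary
placement (chosen uniformly at random among equally-best hits upstream, by
the aligner or the simulator). No fractional assignment and no EM
reallocation is attempted: the contract is "one location at random", which
keeps class-level totals unbiased while individual-copy attribution is
meaningless in this regime. Copy-level analysis therefore switches to
unique counting, where multi-mapped reads contribute nothing — unbiased
for well-diverged copies, blind to young identical ones.

RPM uses the total library size, not the assigned-read count. The
detection rule (RPM > 0.25 in at least one sample, strict) and the
activation rule (mean-RPM ratio > 10, strict) are both applied to the
unique-regime copy table. The ratio uses a pseudocount of 0.1 RPM in
numerator and denominator; the value is a package default chosen to be
well below the 0.25 RPM detectability floor, so it prevents division by
zero while perturbing detectable copies by a few percent at most. Whether
"detectable" is assessed before or after pooling replicates, and the
pseudocount itself, are parameters because neither convention is canonical.

## Negative-binomial differential expression

Counts K_ij for feature i in sample j are modelled as NB with mean
s_j μ_ig(j) and dispersion α_i, where s_j are median-of-ratios size
factors (rescaled to geometric mean 1) and g(j) is the condition.

Dispersion estimation at three replicates per condition is the hard part.
The raw per-feature estimate is method-of-moments on normalized counts,
α̂ = max(0, (v − m)/m²), with mean and variance pooled within conditions so
the condition effect does not masquerade as dispersion. A mean–dispersion
trend α(μ) = a₁/μ + a₀ is fitted by least squares over all expressed
features — zero estimates included, since dropping them would condition on
positive noise and bias the trend upward. The final dispersion is the
geometric mean of the raw estimate and the trend, **floored at the trend
value**: with four residual degrees of freedom, below-trend raw estimates
are almost entirely sampling noise, and allowing them to drag the final
dispersion under the trend makes the Wald test anticonservative (measured
type-I error 0.06–0.10 at nominal 0.05 across true dispersions 0.01–0.5;
with the trend floor, 0.03–0.07). This mirrors how empirical-Bayes
shrinkage behaves at small sample sizes, where the prior dominates unless
the data pull upward. The absolute floor is 10⁻⁸; all-zero features are
untestable (NaN, excluded from the BH denominator).

The per-feature GLM (log link, intercept + condition indicator, log s_j
offset) is fitted by IRLS with weights μ/(1 + αμ), convergence at step
max-norm < 10⁻⁸, at most 50 iterations, and the linear predictor clipped
to ±30 to keep exp() finite; non-converged features are flagged and not
called. The Wald p-value uses the normal approximation. The differential
call is |log2FC| > 1 with **raw** p < 0.05, because that is the stated
rule in this analysis tradition; BH-adjusted values are reported alongside
so either convention can be applied downstream. The module approximates
rather than replicates DESeq2: no independent filtering, no LFC shrinkage,
no outlier handling.

## oxBS methylation calling

The chemistry model: unmodified C converts to T with probability equal to
the bisulfite conversion efficiency; 5mC never converts; 5hmC never
converts under BS and converts under oxBS with probability (oxidation
efficiency × conversion efficiency). Hence the BS C-level estimates
5mC + 5hmC, the oxBS C-level estimates 5mC, and 5hmC is the clamped
difference. Clamping at zero is necessary because two independent binomial
estimates are subtracted; under a 5hmC-free truth the unclamped difference
averages zero, which the tests check.

Because amplicon reads span the entire reference, alignment reduces to
ungapped conversion-aware matching: each read is compared against each
amplicon in both orientations, positions that are reference-C are exempt
(they legitimately read C or T), and the best assignment is accepted if at
most 10 % of non-exempt positions mismatch. Reverse-orientation reads are
reverse-complemented into top-strand coordinates before tallying; only
top-strand CpGs are called.

The coverage rule — at least 100 reads, inclusive — is applied per
treatment and per replicate, the strictest reading. No
incomplete-conversion correction is applied; conversion efficiency is a
simulator parameter precisely so its (small) bias can be studied: at the
default efficiencies (0.995 conversion, 0.95 oxidation), 5mC is
overestimated by at most ~0.005 + 0.05 × 5hmC. Cross-replicate
aggregation is the unweighted mean over QC-passing replicates.

## Peak enrichment

The statistic is the number of peaks overlapping each repeat class by at
least 1 bp — a peak spanning several copies of one class counts once; a
peak overlapping two classes counts for both. The null relocates each peak
independently, preserving its length, to a start offset uniform over all
positions (across all mappable regions) where the peak fits wholly; no
inter-peak overlap constraint is imposed, the simplest null consistent
with shuffling over mappable space. Mappable regions are an explicit input
because "mappable" is operationally read-length-dependent and outside this
package's scope. The add-one estimator p = (1 + #{null ≥ obs})/(N + 1)
never returns zero. Because overlap counts are integers, ties make the
estimator mildly conservative when expected overlaps are small; the
calibration tests therefore use scenarios with expected overlaps of ~30,
where the discreteness is negligible.

## The synthetic-data generator

The generator emulates the study design this package serves: several
ERV-like repeat classes, each with copies of high mutual identity (so
reads genuinely multi-map), both truncated and full-length (>5 kb) copies,
three replicates per condition, and an IAP-like class strongly activated
in the depleted condition.

Key defaults and why:

* `inter_copy_divergence = 0.02` substitutions/site — young ERV families
  are a few percent diverged; at 50 bp reads this yields a realistic
  mixture of unique and multi-mapping reads.
* `copy_length_range = (800, 7000)` bp, spread evenly per class, so each
  class contains truncated and full-length copies; the range must span
  5 kb and the config enforces this.
* `background_fraction = 0.9`: the share of reads drawn from non-repeat
  sequence. Real total-RNA libraries are dominated by gene-derived reads;
  this matters quantitatively because RPM is compositional — with a fixed
  library size, activating one class deflates every other feature's RPM.
  At 90 % background a planted 15-fold activation realizes as ~11–13-fold
  in RPM; at low background the same activation would compress below
  tenfold and the copy-level classification could not behave as it does on
  real data.
* `class_fold_changes = {IAPEz: 15}` — "more than tenfold" activation with
  margin for the compositional squeeze above.
* `replicate_cv = 0.1`: lognormal per-replicate wobble on class
  expression, a mild biological-replicate noise level.
* Reads are error-free by default (`error_rate = 0`), keeping acceptance
  surfaces analytic; a uniform substitution rate is available.
* Multi-mapping is defined as *exact-tie* best placements among homologous
  windows of same-class copies; the primary is drawn uniformly and flagged
  non-secondary in the SAM, all other ties are secondary records.
* BS/oxBS defaults (0.995 conversion, 0.95 oxidation, 2 replicates,
  amplicons with 8 CpGs; the IAP-like amplicon hypermethylated at
  5mC 0.4–0.9, others at 0.05–0.3, 5hmC 0–0.1) reflect typical chemistry
  and ERV methylation levels.
* Peaks: 300 peaks of 300 bp, 80 % placed inside copies of the enriched
  class, the rest uniform over the mappable genome (the whole toy
  chromosome).

Every operation draws from its own RNG stream seeded as
`[seed, operation-offset, …]`, so stages can be regenerated independently
and a fixed config reproduces byte-identical FASTA/SAM/FASTQ/BED output.

What the generator does **not** emulate: transcript structure (splicing,
polyadenylation), paired-end reads, quality-score or PCR-duplicate
artefacts, near-tie alignment scores, strand-specific libraries, bottom
strand bisulfite reads, and genomic context effects (nested repeats,
CpG-density variation). Passing tests therefore demonstrate that the
*computational* contracts are correct — counting conservation, regime
ordering, calibration, recovery of planted effects under the stated noise
model — not that any upstream aligner or peak caller behaves well on real
libraries.

## Problem sizes

The bundled demo uses a ~170 kb toy genome (4 classes × 6 copies), six
samples of 30 000 reads, 2 000 BS/oxBS reads per treatment and replicate,
300 peaks and 1 000 shuffles; it completes in well under a minute on one
core. Calibration suites use 1 000 null NB features (3 vs 3) and ~100
permutation p-values from 25 independent null peak sets; these sizes give
standard errors comfortably inside the asserted bands while keeping the
whole test suite around a minute.

## Known limitations

* The NB workflow tests a single two-group contrast; no multi-factor
  designs or likelihood-ratio tests.
* Unique-regime copy expression is biased against young, poorly diverged
  copies by construction (they have no unique reads); this is inherent to
  the regime, not a defect of the implementation.
* The conversion-aware matcher assumes ungapped, full-length amplicon
  reads; it is not a general bisulfite aligner.
* The permutation null treats peaks as independent; clustered peaks
  violate this and would make the test liberal at small N.
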