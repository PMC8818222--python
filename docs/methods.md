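# Methods

This note records the models, conventions and design choices behind
`csfcirc`, in the order data flows through the pipeline.

## Coordinates and the chimeric dialect

Internally every junction is 0-based half-open `[start, end)`, serialized
as `chrom:start|end:strand`. The chimeric-record dialect is 1-based and
column-compatible with STAR's chimeric-junction layout: columns 1–7 are
chromA, posA, strandA, chromB, posB, strandB, junction type; columns 8–9
carry the two anchor lengths and column 10 the read name (extras are
ignored). `posA` is the first base after the donor segment's end and
`posB` the last base before the acceptor's start, both in transcript
orientation; a record is back-splice evidence iff both segments share
chromosome and strand and the acceptor lies upstream of the donor
(`posB < posA` on `+`, reversed on `−`). On `+` the supported circle is
`[posB, posA − 1)`; on `−`, `[posA, posB − 1)`.

The caller's `min_reads` defaults to 1, matching the species definition
(detected ⇔ read count > 0); a stricter ≥ 2 call is a flag. Junctions
that fail exon-boundary annotation are retained as `unannotated` rather
than dropped — the screening stage, not the caller, decides what to keep.
Exon-boundary matching uses `tolerance_nt = 0` by default; a tolerance is
available for junction lists produced by other pipelines, whose boundary
conventions can jitter by a base or two. When both ends match exons of
more than one gene, the lexicographically first gene ID is assigned, so
annotation is deterministic.

## Normalization and FPKM

TMM follows the published definition: M- and A-values over genes nonzero
in both the sample and the reference column (M is undefined at zero),
double rank-based trimming (30% of M, 5% of A — the method's established
defaults; the analysis this mirrors names the method but not its
parameters), weights equal to the inverse asymptotic binomial variance,
factor `2^(weighted mean M)`, and a final rescaling to geometric mean 1.
The reference column is the one whose upper quartile (of counts/library
size) is closest to the mean upper quartile.

FPKM uses the 10⁹ scaling constant. Gene lengths are exon-union lengths
(overlaps merged once). Every circRNA shares one effective length,
`2·(read_length − anchor_size)`: a junction-spanning read can start only
within `read_length − anchor_size` bases on either side of the joint, so
that window is the only unbiased evidence for the circle. The anchor size
defaults to 20 nt and is deliberately surfaced in the configuration — the
published effective lengths of any given dataset depend on it, so
absolute FPKM values are only comparable within one anchor convention.
circRNA FPKM takes its library size and TMM factor from the *linear*
counts of the same sample, never from circ totals, keeping circular and
linear abundance on one scale; the circ/parent ratio is undefined (NaN,
never infinity) where the parent gene's FPKM is zero.

## Profiling statistics

Compartment comparisons use the rank-based family: unpaired rank-sum by
default (compartment availability differs per patient), signed-rank when
explicitly paired on patients with both samples. Exact p-values are used
up to n = 25 when there are no ties, otherwise the normal approximation
with tie/continuity correction. Shared-species counts are reported as
log₂(n + 1); the pseudocount admits zero-overlap pairs. Pearson r carries
the two-sided p from t = r·√(n−2)/√(1−r²). The therapy-line trend test is
Kendall tau-b between value and ordinal line — a stand-in, as no specific
trend test is canonical for three ordered small groups.

## Screening

The cascade is exclusion → tumor recurrence, but the candidate set is an
intersection, so stage order only affects the intermediate counts (a test
asserts order independence of the result). Recurrence counts *distinct
patients* with a detected tissue sample; two tissue samples of one
patient count once. "Detected" throughout means count > 0, the only
definition the species count supports.

Burden dichotomization uses the nearest-rank empirical quantile: the
cutoff is the ⌈(1−q)·n⌉-th order statistic of per-patient burdens
(q = 0.25 by default), with burden ≤ cutoff labelled deficient and
> cutoff abundant. Quantile conventions differ across software and are
generally unrecoverable from a reported cutoff, so the cutoff is also
directly overridable (`--cutoff 7` reproduces a published ≤ 7 / > 7
split). An all-equal burden vector yields a single group and is flagged
degenerate rather than raising. The median split (q = 0.5) is available
through the same parameter.

## Sponge network

The junction probe takes the last 30 nt and first 30 nt of the spliced
circle, reverse-joined, so a binding site that spans the joint cannot
occur on the linear transcript. Circles shorter than 60 nt contribute
their full sequence exactly once (⌊L/2⌋ tail + remainder head); the
`junction_offset` marks the joint.

The duplex scorer is a Gotoh local alignment of the reversed miRNA
against the probe: Watson–Crick +5, G:U wobble +1, mismatch −3, gap open
−9, gap extend −4, with pair scores at miRNA seed positions 2–8 weighted
×4 (gap penalties are not weighted). A perfectly complementary 22-mer
scores 5·15 + 5·7·4 = 215. The duplex "energy" is a per-pair sum (G:C
−3.0, A:U −2.0, G:U −1.0 kcal/mol) over the aligned pairs — a fast
surrogate, not a nearest-neighbor thermodynamic model; swapping in a true
thermodynamic energy is an extension point. Hits require score > 170 and
energy < −30; strict mode additionally demands the whole seed be WC
paired and ungapped. The 170/−30/strict thresholds are honored
numerically, but because the scorer's parameterization stands in for an
external tool's unpublished defaults, the score scale is not calibrated
against that tool. Note one consequence of seed weighting: a single-base
gap (−9) can legitimately out-score a seed mismatch (−3·4), so optimal
alignments of random sequences are gapped more often than intuition
suggests.

miRNA→mRNA prediction is sequence-only seed matching: an edge iff the
reverse complement of miRNA positions 2–8 (7mer-m8) occurs in the 3'UTR,
upgraded to 8mer when the next UTR base is an A. Positions 2–8 are the
single seed convention used everywhere (scoring weight, strict filter,
site matching).

Co-expression edges require |Pearson r| ≥ 0.70 (inclusive) and p < 0.01,
computed on log₂(FPKM + 1) by default — correlations of strongly skewed
abundance data are more stable on the log scale, and the synthetic
generator plants its correlation there; `transform="linear"` gives raw
FPKM. Raw p governs the edge rule, mirroring common practice in this
analysis family; BH q-values are reported alongside to surface the
multiplicity issue without changing the filter. Over-representation is an
upper-tail hypergeometric test on user-supplied gene sets against an
explicit universe, again with BH q-values reported.

## Survival

Overall survival runs from brain-metastasis diagnosis to death from any
cause, censored at last follow-up. The KM estimator keeps individuals
censored at an event time at risk through that time; the median is the
smallest t with Ŝ(t) ≤ 0.5 and is reported as an explicit not-reached
marker (`inf`, printed "NR") when the curve never gets there. Median
follow-up is the reverse-KM median (event indicator flipped). The
log-rank test is the standard observed-vs-expected chi-square with
hypergeometric variance, df = k − 1. Cox models use Efron tie handling
(lifelines' default and that of the R framework this mirrors); sex,
smoking and metastasis are binary indicators, age is continuous.
Univariate mode fits one covariate at a time; multivariate fits them
jointly. The per-candidate scan dichotomizes patients per circRNA by
detection (> 0) or by median FPKM, flags degenerate single-group splits
instead of failing, and reports BH q-values next to raw p.

## Synthetic cohort generator

The generator is the package's test bed: every downstream stage must
recover what it plants. Defaults mirror the emulated study design: 21
patients with 19 CSF / 21 plasma / 15 tissue samples (the default missing
map removes CSF for patients 1 and 20 and tissue for patients 4, 7, 9,
11, 18, 19), read length 150 nt, anchor 20 nt, a ~1 Mb three-chromosome
toy genome, 300 circRNAs of which 12 are true candidates and 60 sit on
the normal-brain exclusion list, CSF species fraction 0.4, CSF abundance
factor 5, true hazard ratio 3 for the circRNA-abundant quarter of
patients, planted co-expression ρ = 0.9 and ctDNA ρ = −0.7.

Counts are negative binomial (dispersion 0.3 in fluids, 0.2 in tissue —
standard RNA-seq overdispersion; no distributional detail is recoverable
from summary figures, so only rank/direction contrasts are meaningful).
CSF heterogeneity is produced by independent per-patient Bernoulli
species masks — one parameter that yields both the species deficit and
the low between-patient overlap. Candidate detection probability is 0.8
in abundant vs 0.15 in deficient patients, which separates the burden
distribution cleanly around the top-25% cutoff. Each stratum of the
screening flowchart is constructed, not sampled: candidates are forced
into ≥ 2 patients' tissue and ≥ 1 CSF; CSF-present non-candidates are
either excluded-list members or confined to ≤ 1 tissue patient, so the
cascade returns exactly the planted set. Planted miRNAs are exact reverse
complements of 22-nt windows centred on candidate probes' joints (score
215, energy ≤ −44 < −30, always junction-spanning); partner-gene 3'UTRs
receive one exact 8mer site. Survival times are exponential with baseline
rate log 2 / 17 months, hazard multiplied by the configured ratio for
abundant patients, censored uniformly on [0, 40] months — the simplest
mechanism compatible with reverse-KM follow-up estimation. ctDNA values
are linear in a Gaussian latent correlated at ρ with log CSF circRNA
abundance.

What the generator does **not** emulate: read-level FASTQ/base-call
noise, sequencing error, batch effects, isoform structure within a gene,
library-preparation differences between biofluid and tissue protocols,
and any real biological pathway structure in the miRNA/mRNA identities.
Passing tests therefore demonstrate the *algorithms* are correct and
calibrated under the stated statistical structure, not that the pipeline
is robust to artifacts of real sequencing data.

## Numerical conventions and degenerate inputs

Fixed seeds make every generator output byte-identical. TMM raises on
all-zero samples and returns factor 1 for identical-composition pairs;
Pearson raises on zero variance; the paired rank test raises when all
differences are zero; the trend test flags constant input; Cox refuses
constant covariates and zero events, and quasi-separated toy instances
(all events in one covariate group) are outside the oracle-equivalence
contract because the partial-likelihood maximum is then numerically
ill-defined. Problem sizes in the test suite and acceptance script (60–300
circRNAs, 8–21 patients, 20–200 Monte-Carlo seeds) were chosen as the
smallest that exercise every code path while keeping Monte-Carlo bands
(±3 points on a 5% rate, 0.1 on a log hazard ratio) comfortably
resolvable.
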