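# Methods

## Scope and data model

`trbrep` analyses TCR-β amplicon repertoires. One sample is a clonotype
table keyed by (CDR3aa, V call, J call) with read counts and frequencies;
a cohort is a set of samples labelled `tumor` or `normal` with optional
clinical covariates (LDH in U/L, NLR as a ratio, ALC in 10⁹/L). All
sequence intervals are 0-based half-open; anchor coordinates point at the
first base of the conserved codon.

## Germline reference

The bundled reference is **synthetic**: 58 V, 2 D and 14 J segments with
IMGT-style names spanning 28 V families (TRBV7 contributes 8 subfamilies,
including TRBV7-6; the pseudogene-style TRBJ2-2p is kept as an ordinary
segment). V segments are 63 nt with the cysteine codon at offset 54
followed by 6 germline bases; J segments are 48 nt with the phenylalanine
codon at offset 9. Sequences are random nucleotides generated once from a
fixed seed (`build_synthetic_reference`), which is sufficient for
amplicon CDR3 work: only segment identity and anchor positions matter
downstream, and it keeps the package free of licensed germline downloads.
Family names derive from the id by truncating the subfamily token
(`TRBV7-6 → TRBV7`); collapsing usage to families conserves totals.

## Read quality control

A read is removed when it has more than 8 ambiguous bases (strict
inequality), or when the fraction of positions with Phred < 30 is **at
least** 0.15. The inclusive reading of the 15% boundary is a documented
choice that makes tests deterministic; a read failing both filters is
counted under the ambiguous-base tally (checked first). Only Phred+33
FASTQ is supported; adaptor trimming, paired-end merging and UMIs are out
of scope (the simulator emits adaptor-free single-end reads).

## Alignment and V(D)J assignment

Segment calls use an in-package local aligner: match +1, mismatch −1,
linear gap −2, `N` mismatches everything. Among maximal-scoring
alignments the smallest read start wins, then the smallest segment start,
then the smallest ends — implemented as two DP passes (a suffix pass
locating the minimal start, then an anchored pass locating the minimal
end), which reproduces a brute-force enumeration over all substring pairs
exactly, tie-breaks included. Kernels are numba-compiled; the pure-Python
oracle lives in the test suite.

Per read, the best V is called first (ties to the lexicographically
smaller id), then the best J aligned against the read suffix beyond the V
alignment, so the J start never precedes the V end. Either best score
below `min_score = 10` is a no-call. At this floor, random 100-nt reads
reach the score threshold for both segments in roughly 13% of cases —
an expected property of local-alignment score statistics against 58
segments — but essentially never yield an in-frame C…F junction
(measured ≈0.1% productive), so junk reads contaminate clonotype tables
at about one read per thousand. Only the forward strand is searched;
reverse-complement search is deliberately not enabled by default.

The CDR3 is anchor-inclusive: from the read position of the V cysteine
codon through the end of the J phenylalanine codon, both located by
mapping the anchor through the alignment path (a gapped or uncovered
anchor voids the junction). The inclusive convention is chosen because it
puts mean junction lengths on the ≈14-aa scale used throughout; the
exclusive reading would shift every length by 2. A junction is productive
iff its length is divisible by 3, its translation is stop-free, and it
starts with C and ends with F. D segments are assigned by longest exact
substring match of at least 5 nt inside the junction (ties and shorter
matches give no call) — D segments are too short for scored alignment to
be reliable.

## Diversity and usage statistics

Diversity indices operate on unique-CDR3aa frequencies (V/J collapsed);
usage statistics operate on read-level calls over the full 58 × 14 = 812
cell gene space. Formulas (the field's standard conventions): Shannon
entropy in natural log; clonality `1 − H/ln R`; Simpson dominance `Σ p²`;
CF100 as the summed top-100 frequencies (tie-invariant, 1.0 when R ≤ 100);
D50 as `k/R` with `k` the minimal top-clonotype count reaching cumulative
frequency 0.5. VDJ combination counts use clonotypes with a non-null
majority D call. CDR3 length distributions default to clonotype weighting
(each unique CDR3aa once; read weighting available), with a Gaussian fit
R² computed against the Normal(mean, sd) mass discretized over integer
lengths. Frequency-region histograms use half-open decade bins
(0, 10⁻⁵, 10⁻⁴, 10⁻³, 10⁻², 1]; a frequency exactly on an edge belongs to
the bin below. Repertoire overlap is the overlap coefficient on unique
CDR3aa sets (shared / smaller), chosen over Jaccard so nested repertoires
score 1.

## Cohort statistics

Group comparisons use the two-sided Mann–Whitney U test: exact null
distribution when the combined sample size is ≤ 12 with no ties,
otherwise the normal approximation with midranks, tie correction and
continuity correction (the 13-vs-9 design sits in the approximation
regime; the exact path exists and is verified against full enumeration).
Usage comparisons run one test per feature across the chosen level
(28 V families, 58 V subfamilies, 14 J segments, or 812 V–J pairs) and
report raw p-values next to Benjamini–Hochberg adjusted ones; the
significance flag follows the uncorrected p < 0.05 convention and the
output metadata notes that choice. Spearman correlations use midranks
with the t-approximation p-value and are computed separately per tissue
group; constant inputs are an error rather than a NaN. J-family
clustering is average-linkage agglomerative clustering of the 14 usage
columns under Euclidean distance (a deterministic choice; the two
top-level clusters come from cutting the final merge, degenerate
all-equal inputs may not split). Paired-sample structure is deliberately
not exploited: the comparison is unpaired throughout.

## Synthetic repertoires

`sample_clones` draws, per clone: V and J from usage vectors
(Dirichlet-sampled skewed base vectors under a fixed internal seed when
not supplied), a junction length from round(Normal(14, 1.5)) clipped to
[8, 24] aa, a junction as C + uniform interior + F with nucleotides from
uniform synonymous-codon back-translation, and a log-normal weight
(sigma 1.5) normalized into frequencies. The anchor codons are copied
from the clone's germline segments so emitted reads align consistently.
With probability 0.7 a ≥ 6 nt D-segment substring is spliced into the
interior (re-translated; splices creating stops are re-rolled and
abandoned after 20 attempts, so the realized embedding fraction is
slightly below 0.7).

`emit_reads` draws multinomial read counts over clone frequencies; each
read is the 36 germline nt upstream of the V anchor, the junction, and
27 germline nt downstream of the J anchor, with independent per-base
substitution errors (default 0.002) and Phred values from
round(Normal(38, 2)) clipped to [2, 40]. A junk fraction (default 1%)
rotates through random-sequence reads, reads with 9 planted N bases, and
reads with 20% of positions at Q20, exercising the no-call path and both
QC filters. Identical seeds give byte-identical FASTQ and tables.

`make_cohort` builds the default two-group template: 13 tumor and 9
normal samples; TRBV16 and TRBV7-6 usage raised +0.05 in tumor (other
segments rescaled); per-sample usage resampled from a Dirichlet around
the group vector (concentration 300, giving realistic between-sample
usage noise of order 0.01); per-sample clone-size sigma mapped
monotonically from a latent diversity driver over [0.8, 2.2]; and
clinical covariates tied to that driver through a Gaussian copula
(Spearman target ρ_s converted to the copula's Pearson parameter by
ρ = 2 sin(πρ_s/6)), defaults LDH (−0.8 tumor / −0.2 normal), NLR
(+0.7 / +0.2), ALC (−0.5 / +0.3), with log-normal marginal scales chosen
to look like clinical-chemistry values. Table mode skips read emission
and annotation and builds clonotype tables directly from the ground
truth — used for statistics-level simulations; read mode writes FASTQ,
metadata, provenance and ground-truth tables plus a params YAML.

### What the generator does and does not emulate

It reproduces the *statistical* structure relevant to the analysis:
group sizes, clonotype-count scale (10³–10⁴ unique CDR3aa per sample),
skewed clone sizes, Gaussian junction lengths around 14 aa, a 58 V / 14 J
usage space with group-specific shifts, and rank-coupled covariates. It
does not model PCR amplification bias, chimeras, sequencing-cycle quality
decay, reverse-strand reads, paired-end structure, or biological
V–J pairing preferences; segment sequences themselves are synthetic.
Passing tests therefore demonstrate correctness of the algorithms under
controlled conditions, not concordance with any patient cohort.

## Numerical and design choices

- Exact/approximate Mann–Whitney switch at combined n ≤ 12 without ties.
- D50's cumulative-frequency threshold uses a 10⁻¹² guard against
  floating-point shortfall at exactly 0.5.
- Clonality of a single-clonotype repertoire is an error at the function
  level and NaN in the aggregated per-sample profile; empty repertoires
  propagate as zero counts with NaN indices so cohort code can proceed.
- Problem sizes used by the default verification runs: the acceptance
  script simulates 5,000 clones at depth 20,000 (error-free); the
  pipeline-closure test uses 2,000 clones at depth 10,000; calibration
  uses 10,000 Mann–Whitney null replicates at n = 9 vs 13, 100 cohort
  replicates for usage-shift power, and 50 for covariate-coupling
  recovery. These sizes were chosen so each property is measured with
  comfortable Monte-Carlo margins.
- The pipeline-closure property is defined for junk-free, error-free
  reads: planted junk exists to exercise QC and no-calls, and random junk
  reads can (rarely, ≈0.1%) produce a spurious productive clonotype, so
  exact table equality is only meaningful without them.

## Known limitations

- No allele-level (\*01/\*02) resolution; segment identity stops at the
  subfamily.
- No clustering of near-identical CDR3s; clonotypes are exact sequences.
- No rarefaction or richness extrapolation (Chao, Hill numbers);
  clonotype counts are depth-dependent.
- Single-end, forward-strand reads only.
- The exact Mann–Whitney path is limited to small, tie-free samples; the
  asymptotic path is mildly conservative at the 13-vs-9 design (measured
  type-I error ≈ 0.049 at α = 0.05).
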