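# Methods

## Primer model and registry

Oligos are modelled over the 15-letter IUPAC alphabet (U is treated as T)
with an explicit structural segmentation: flow-cell adaptor, pad, and a
single 3'-terminal binding region. The built-in registry ships three
one-step Illumina primer systems as packaged TSV data (`region`, `name`,
`conc_umol_per_L`, `sequence`, `role`): the V4 system (515F/806R), the
V1–V2 system (68F/338R) and the modified mixture V1–V2M, which is V1–V2
plus the degenerate forward companion 68F_M. Users can supply their own TSV
in the same dialect.

Segment boundaries are recovered by anchoring: the binding region is the
known reference-primer 3'-terminal substring (515F: `GTGYCAGCMGCCGCGGTAA`;
806R: `GGACTACNVGGGTWTCTAAT`; 68F: `GTNANACATGCAAGTCGRRSG`; 68F_M:
everything 3' of the shared pad; 338R: the printed 19-mer
`AGCTGCCTCCCGTAGGAGT`), the pad is the longest suffix of the remainder
matching a prefix of the corresponding sequencing primer, and the rest is
adaptor. Pad anchoring tolerates one incompatible position because the V4
reverse oligo and its Read2 primer print different pad variants at one
base; validation surfaces this as a `pad-variant` finding rather than a
failure. Validation otherwise checks the two index identities
(Index1 = revcomp(Read2), Index2 = revcomp(Read1)) and degenerate
compatibility of each sequencing primer with the amplification oligo it
reads from; a position where one code's base set contains the other's
(e.g. N in the reverse oligo versus H in Read2) is reported as
`compatible-subset`, not failure — the discrepancy is reported, not
resolved.

## In-silico PCR

Binding sites are ungapped placements on either strand; a position matches
iff the primer code's base set intersects the target code's base set
(reference databases contain occasional ambiguity codes). No indel
alignment is attempted: primer annealing is modelled positionally, which
also keeps the brute-force expansion oracle exact. Coordinates are 0-based
half-open on the + strand everywhere; reverse sites are stored by their
+ strand footprint.

Amplification uses a binary 3'-terminal policy: a site supports extension
iff its mismatch count in the 3'-terminal window of `w` bases is strictly
below `max_mismatch_3prime`. Defaults are `w = 5` and
`max_mismatch_3prime = 2` — i.e. amplification fails with two or more
mismatches in the last five bases — which reproduces clade-dropout
behaviour while staying tunable; the window length is a parameter because
"3' terminus" has no single canonical width. Products are all convergent,
non-overlapping forward×reverse site pairs within length bounds
(`min_length = 50`, `max_length = 2000` by default); for mixtures a site
from any member suffices. All qualifying products are reported — this is a
screening model, not a quantitative PCR-efficiency model, and no "best
product" election or melting-temperature prediction is attempted.

Both `length_16s` (outer primer-to-primer span) and `length_library`
(adding the non-binding adaptor+pad tails of both oligos) are reported on
every product, so either reading of "amplicon length" is checkable.

Rescue-primer design extracts, for each failing reference, the reference's
actual sequence at the best-available binding locus of the base primer
(minimum total, then 3'-window mismatches, either strand), then greedily
clusters these loci under a degeneracy cap: a locus joins the first
existing cluster whose position-wise IUPAC union stays within
`max_degeneracy`, else founds a new cluster while fewer than
`max_extra_oligos` exist, else the reference is reported unrescuable.
Each cluster's union becomes one proposed oligo reusing the base primer's
adaptor+pad. By construction every member reference matches its proposal
with zero mismatches, so coverage of the failing set returns to 1.0 when
the proposals are appended to the mixture.

## Synthetic libraries

The simulator emulates a 2×150 bp paired-end amplicon run. Community
references are mutated copies (per-base substitution probability
`divergence`, default 0.1 — comfortably above the within-species scale so
toy taxa are unambiguous) of a shared random backbone with exact primer
loci planted at fixed positions. Insert lengths default to 253 bp for
V4-style systems (read pairs overlap and merge) and 290 bp otherwise
(pairs cannot overlap at 2×150 after tail truncation, forcing the
concatenation path) — the two regimes a short-read platform must handle.

The dropout configuration plants a fixed 23-nt locus variant
(`DROPOUT_LOCUS_V12`) carrying exactly two mismatches inside the
3'-terminal window of the 68F binding region while remaining amplifiable
by 68F_M (one tolerated 3'-window mismatch) — the mechanism by which a
clade is invisible to the base system and recovered by the mixture. The
synthetic host record plants near-match forward/reverse loci in convergent
orientation with mismatches placed away from the 3' windows, emulating a
mitochondrion-like off-target locus; `n_loci` controls how many distinct
off-target products the host contributes, standing in for the sequence
diversity of real host-derived reads.

Read 1 is the first `read_length` bases of the amplicon top strand, read 2
of the bottom strand. Substitution errors are i.i.d. with per-base
probabilities that follow the (rounded) Phred values emitted in the quality
strings, so expected-error filtering operates on exactly the planted error
process; a flat Q profile corresponds to `error_rate` (default 0.001, Q30)
with an optional linear 3' quality decay to exercise the filter. Only
substitutions are simulated (no indels), matching the ungapped denoising
model downstream; chimera formation and index hopping are not simulated —
chimeric fixtures are constructed explicitly in tests. One root seed
drives named substreams per operation, so identical configurations produce
byte-identical FASTQ.

What passing on these libraries does **not** show: robustness to real
error-profile structure (quality-dependent, position-correlated,
indel-containing), to chimera formation during PCR, to primer-region
sequence variation inside reads, or to compositional effects of real 16S
copy-number variation. The simulator is a contract tester, not an error
model.

## Host subtraction

Full-scale practice maps reads to the host genome with a short-read
aligner and subtracts successfully mapped reads. At package scale the same
contract is implemented as an exact canonical k-mer screen: the host index
is the strand-collapsed set of all k-mers of the host reference (k odd,
11–31, default 21), and a sequence classifies host when the fraction of
its k-mers present in the index reaches `theta` (default 0.5). A pair is
removed when either mate classifies host (conservative, mirroring
subtraction of any successfully mapped read). The CLI accepts an external
read-id list so a real aligner's output can be plugged in for full-scale
runs. False-positive collisions are negligible at k = 21 (≈ n·4⁻²¹ per
k-mer); recall degrades only when the per-read error rate approaches
1/k. The ASV-level host percentage splits concatenated ASVs at the 10-N
spacer and calls the ASV host if any segment classifies host.

## Read-to-ASV pipeline

Filtering truncates a fixed 3' tail (default 10 bases) from each mate and
drops the pair if either mate has > 0 ambiguous bases, expected errors
Σ10^(−Qᵢ/10) > 2, or length < `min_len` (default 50 — a post-truncation
floor the procedure itself does not pin down). Dereplication collapses
identical sequences, tracking abundances and per-position mean qualities.

Denoising is a greedy abundance-skew rule (UNOISE-flavoured) replacing a
learned parametric error model: processing uniques in descending
abundance, a sequence joins the most abundant existing same-length center
within Hamming distance `d_max` (default 2) whose abundance satisfies
`a(u) ≤ a(center)·2^(−α·d)` (α default 2), else founds a center. The ratio
test uses the center's founding abundance, which keeps the procedure
order-deterministic. A unique that neither joins a center nor reaches
`min_abundance` is discarded as a likely many-error read; the library
function defaults to `min_abundance = 1` (so `d_max = 0` is the exact
identity) while the pipeline uses 2, the conventional guard against
singleton artifacts. The contract preserved from learned-error denoisers —
error reads are absorbed into true template sequences — is what the
recovery tests check.

Pairs are merged when the best overlap of ≥ `min_overlap` (default 12)
bases has ≤ `max_overlap_mismatch` (default 0) mismatches, taking the
higher-quality base at conflicts; otherwise read 1 and the reverse
complement of read 2 are concatenated with exactly ten N characters, the
common spacer convention for non-overlapping pairs. These constants are
package choices: the procedure being modelled names the behaviour, not the
numbers.

Bimera flagging is the two-parent exact-segment test: an ASV is chimeric
in a sample when some split point divides it into a prefix of one parent
and a suffix of another, both at least twice as abundant there; the flag
is set on a strict majority of the samples where the ASV occurs. This is
the simplest faithful de novo bimera rule and is verified against an
exhaustive parent-pair × split-point oracle.

Contaminant flagging combines a genus signature list (the packaged list of
common reagent-contaminant genera is an editable placeholder, not a
study-specific curation) with a negative-control prevalence rule: an ASV
present in the controls whose control prevalence is at least its
true-sample prevalence is flagged. The prevalence rule requires actual
occurrence in a control so never-observed ASVs are not flagged vacuously.
This replaces model-based contaminant statistics with a transparent,
exactly testable rule.

## Taxonomy

The classifier is the classical word-based naive Bayes method as a
scikit-learn estimator: 8-mer words; word prior Pᵢ = (nᵢ+0.5)/(N+1);
genus-conditional P(wᵢ|G) = (mᵢ+Pᵢ)/(M+1); a query scores each genus by the
sum of log conditionals over its distinct words. Words absent from the
training vocabulary contribute a per-genus floor probability
(0.5/(N+1))/(M+1) — without this, strands and queries with different
numbers of known words would not be comparable. Both strands are scored
and the better kept, so classification is orientation-free; concatenated
ASVs are split at the N spacer and their word sets unioned. Confidence per
rank is the percentage of 100 bootstrap trials (⌊W/8⌋ words with
replacement) whose winning genus rolls up to the top assignment's taxon at
that rank; assignments require confidence ≥ 80. k = 8, 100 trials, W/8
subsampling and the 80 cutoff are the published defaults of the method.
Species-level calls use the same machinery where training lineages carry a
species field; otherwise the rank reports NA. Rank confidences are monotone
non-increasing from domain to genus by construction of the rollup.

## Community statistics

Alpha indices are computed from their closed forms on unrarefied,
unflagged counts by default (a rarefy-first switch is available via
`rarefaction_curve`); the implemented set — observed richness, Chao1,
Shannon (natural log), Simpson and inverse Simpson — is the conventional
one. Rarefaction subsamples without replacement and is verified against
the hypergeometric expectation E[S] = Σ(1 − C(N−Nᵢ,d)/C(N,d)). Beta
diversity uses presence/absence Jaccard distances ordinated by PCoA
(scikit-bio's eigendecomposition of the double-centred squared-distance
matrix); PERMANOVA is implemented in-package so the permutation count,
p-value formula p = (1+#{F* ≥ F})/(1+n_perm) and seeding are explicit, and
is cross-checked against scikit-bio's statistic in tests.

Differential abundance normalizes counts by median-of-ratios size factors
and reports baseMean (mean normalized count), log₂ fold-change with a
pseudocount of 0.5, and a two-sided Wilcoxon rank-sum p per genus (exact
for group sizes ≤ 10 without ties; tie-corrected normal approximation
otherwise). Significance uses raw p < 0.05 plus a mean relative-abundance
filter of 0.5 % — multiple-testing correction is available
(Benjamini–Hochberg via statsmodels-style flag left to the caller) but off
by default to match the screening character of the ranking. This
normalization approximates shrinkage-based axes well enough for ranking;
it is not a dispersion-modelling differential test. Pearson
reproducibility aligns two profiles on the union of taxa (zeros filled),
converts to relative abundances and reports r (NA for zero-variance
vectors).

## Problem sizes and numerical choices

The test-suite and acceptance runs use 10⁴-pair libraries for host-fraction
recovery, 2×10⁴ pairs for community recovery, 600 reads for classifier
accuracy, 500 random instances for the matcher oracle, and 200 runs of 99
permutations for the PERMANOVA null — sizes chosen so each check's
statistical resolution comfortably exceeds its tolerance. Ties in the
denoiser and classifier argmax resolve deterministically (first index),
which matters only for degenerate constructed inputs. Degenerate cases are
defined explicitly: empty samples give all-zero alpha indices; zero
within-group variance gives an infinite pseudo-F; zero-variance profiles
give NA correlation; sequences shorter than k classify non-host with
fraction 0.

## Known limitations

- The k-mer host screen is exact, not alignment-based: full-scale
  host-percentage figures from real biopsy data depend on aligner
  parameters the screen does not model; the external-id bypass exists for
  that use.
- The denoiser has no quality-aware per-base likelihoods, no pooling
  modes, and merges only equal-length sequences.
- Real printed-figure regressions (off-target coordinates on the human
  mitochondrion, coverage of real clades against SILVA) require
  user-downloaded references and are not run by default; the synthetic
  stand-ins exercise the mechanisms, not the figures.
- Phylogenetic diversity metrics (UniFrac, Faith's PD) are out of scope
  because tree construction is.
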