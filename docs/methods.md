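# Methods

## Scope and model

`sagqc` covers the computational quality control that follows sequencing of
a single-amplified genome (SAG): screening of amplification reactions,
trimming of screening-amplicon Sanger reads, compositional decontamination
of the assembly, marker-based completeness and genome-size estimation, and
report generation. Wet-lab stages (cell sorting, MDA chemistry) and
external-tool stages (read normalization, assembly, annotation, HMM marker
searches, BLAST) are out of scope; the package consumes their outputs
through plain-text interfaces (FASTA, FASTQ, TSV hit tables) and, in
synthetic mode, mocks them with simulators.

## qPCR screening

A standard dilution series of a 16S rRNA plasmid standard is fitted by
ordinary least squares:

    Cq = intercept + slope · log10(copies)

Amplification efficiency is reported by the standard qPCR convention
`10^(−1/slope) − 1` (slope −3.3219 ⇔ perfect doubling, efficiency 1.0).
A curve needs ≥ 3 dilution points spanning more than one concentration and
is flagged invalid when R² < 0.95 or the slope is non-negative; invalid
curves refuse quantification. Reaction quantification inverts the curve,
`copies = 10^((Cq − intercept)/slope)`.

A reaction **passes** when its quantified copy number reaches the detection
threshold and its melt temperature is acceptable. Two conventions here are
deliberate, config-exposed choices because the source protocol wording does
not pin them down:

- the detection-limit comparison is **inclusive** (≥ 100 copies/µl,
  default `threshold=100`);
- the melt-temperature floor has no protocol-given value; the default
  `melt_min=78 °C` is a typical floor for bacterial 16S SYBR amplicons
  (primer dimers and short artifacts dissociate earlier) and should be set
  per assay. Melt exclusion takes precedence over quantity, matching the
  bench practice of discarding dissociation-curve failures before reading
  quantities.

## Sanger read trimming

Per-read rule: take all maximal runs in which every base has Phred quality
strictly greater than `q_min=10`; among those, keep the longest run with
mean quality at least `mean_min=20` (leftmost on ties); discard the read if
the kept run is shorter than `len_min=100` bp. The mean condition is
evaluated per run, not over the whole read — the rule describes one
contiguous stretch, and restricting to maximal >q_min runs keeps the
selection O(n). Reported intervals are 1-based inclusive.

## Tetranucleotide profiles and PCA

Each contig of length ≥ `min_len` (default 1,000 bp — shorter contigs give
noisy 4-mer frequencies; the default matches the fragment scale of typical
SAG assemblies) is summarized by its canonical tetranucleotide frequency
vector: all width-4 windows at step 1, windows containing N skipped, counts
folded onto the lexicographically smaller of each 4-mer and its reverse
complement (contigs are unoriented, so strand-folding is the defensible
choice), normalized by the number of countable windows. This yields
(256 − 16)/2 + 16 = 136 features per contig; rows with zero countable
windows are skipped, not zero-filled, and no pseudocounts are added.

PCA centers columns but does **not** scale to unit variance by default:
frequencies share a scale, and scaling would inflate rare k-mers (a config
flag enables scaling). Components are ordered by decreasing explained
variance; each loading column is oriented so its largest-magnitude entry is
positive, making scores deterministic and testable.

## DBSCAN decontamination

Contigs are clustered in the space of the first `n_components=3` principal
components (the bulk of compositional separation lives in the leading
components; config-exposed) with DBSCAN under the Euclidean metric. The
implementation is local to the package so its semantics are fixed: a core
point has ≥ `min_pts` points (itself included) within `eps`; clusters are
maximal density-connected sets grown from core points in input order;
border points join the first cluster that reaches them (deterministic,
input-order tie-break); unreachable non-core points are noise.
`min_pts` defaults to 4 (≈ 2 × embedding dimension rule of thumb).

When `eps` is not supplied it is chosen from the sorted
min_pts-nearest-neighbour distance curve: the knee (maximum second
difference), accepted when that maximum exceeds 5× the median absolute
second difference, otherwise the 90th percentile of the k-distances. Both
branches are scale-equivariant, so scaling the embedding scales the chosen
eps.

The **main cluster** is the one carrying the largest total base-pair mass
(ties: more contigs, then lowest cluster id) — base pairs rather than contig
count, so many short spurious contigs cannot outvote the genome. Members of
the main cluster are valid; all other clusters and noise points are flagged
as candidate contaminants. A taxonomy refinement step then rescues flagged
contigs whose gene-level taxonomy calls intersect the taxonomic range of the
main cluster (union of taxa called on main-cluster contigs unless given
explicitly): a compositional outlier that annotates like the host is more
likely an atypical region (e.g. a genomic island) than a contaminant. The
classifier behind the calls is pluggable — BLAST-based in a full
deployment, a truth-table mock in synthetic mode; the package does not wrap
BLAST itself. Refinement is monotone: it never demotes a valid contig.
Contigs too short to profile are reported as `unprofiled` and kept by
default (config-exposed policy). When DBSCAN labels every contig as noise
the stage raises instead of guessing — that situation calls for parameter
review, the automated analogue of the manual inspection step in the
original bench workflow; a `--inspect` flag emits the PCA scores and
cluster labels as TSV for that review.

## Completeness and genome size

Completeness is the recovered fraction *f* of a set of ubiquitously
conserved single-copy marker genes (35 COG families). Marker presence is
tallied from a best-hit table restricted to contigs that survived
decontamination; multiplicity is ignored (the estimator counts recovered
set members, not copies) but duplicated markers are surfaced as a warning
since they hint at residual contamination. The genome size estimate is

    G = L / f

with L the total length of valid contigs; at f = 0 the estimate is
undefined and reported as a dash. Because each marker is present exactly
once per genome and markers are (approximately) uniformly placed, the
number recovered is Binomial(35, f), making f̂ unbiased with standard error
√(f(1−f)/35) ≈ 0.08 at f = 0.6 — the estimator is honest but coarse, which
is why reports round completeness to two decimals. The real marker-set
identifiers are supplied by the user as a one-id-per-line file; the package
ships 35 named placeholder slots and, in synthetic mode, pairs them with
generated 30-bp marker tokens found by exact substring scan (the stand-in
for an HMM search; no HMM database at desk scale).

## Assembly statistics

N50/L50 use the standard definition: sort contigs by decreasing length;
L50 is the smallest m whose m largest contigs reach half the total length,
N50 the length of the m-th contig. The half-total comparison is
`2·cumsum ≥ total` on integers, so even totals never hit a float boundary;
when several contigs share the boundary length the minimal m is reported.
GC content is (G+C)/(A+C+G+T) with N excluded from the denominator.
Assembly size is the post-decontamination (valid-contig) total, consistent
with the L used in the size estimate. Report formatting: size estimates in
3-significant-digit scientific notation, completeness to two decimals,
cohort mean N50 rounded to the nearest bp.

## Synthetic data: what it does and does not emulate

Genomes are iid base streams at a target GC (or order-1 Markov chains for
harder compositional cases). Fragmentation draws contig lengths from a
lognormal around the requested mean (σ = 0.5, truncated at 500 bp, matching
the heavy fragmentation of real SAG assemblies) until the requested genome
fraction is covered, then places them without overlap by distributing the
uncovered residue as random gaps — so every contig is an exact substring of
the genome and recovered length is within one contig of f·genome length.
Marker tokens are inserted at uniform positions, making token recovery
Binomial(n_markers, ≈f) under fragmentation, which is exactly the sampling
model the completeness estimator assumes.

Not emulated (no model for them is specified anywhere the package could
follow): MDA amplification bias and chimeras, sequencing error profiles,
real coding sequence and hence real HMM hit noise, and inter-genome
compositional structure beyond GC/Markov-1. Passing tests therefore show
the algorithms implement their definitions and behave correctly under the
assumed sampling model — not that real SAG contaminants are always
separable by tetranucleotide PCA (a real contaminant with host-like
composition will be missed, as it would be in the original workflow).

## Numerical and testing choices

All simulators take explicit integer seeds and share no global state; the
pipeline derives per-SAG seeds from the config seed, so runs are
reproducible byte for byte. Problem sizes in the test suite (genomes of
50–250 kb, 200-seed replications, 5 kb contigs) are chosen so every
statistical check has comfortable power while the whole suite runs in well
under a minute. Statistical tolerances come from the underlying sampling
distributions (e.g. 6σ binomial bands for GC convergence, 2σ-of-mean bands
over 200 replicates for completeness recovery, binomial bounds on per-seed
slope-recovery rates), computed before the tests were run. DBSCAN is
validated against a brute-force density-connectivity oracle and
cross-checked against scikit-learn's implementation; N50/L50 and the
trimming rule are validated against brute-force enumeration oracles; PCA is
checked against an independent eigendecomposition of the covariance matrix.

## Known limitations

- Tetranucleotide separation degrades when host and contaminant have
  similar composition; the taxonomy refinement can only rescue
  false positives, not recover false negatives.
- The completeness estimator is undefined at f = 0 and highly variable at
  small f (a 35-member set cannot resolve completeness below ~3%); size
  estimates at low completeness inherit that variance — visible in
  published cohorts as order-of-magnitude spread among low-completeness
  size estimates.
- `choose_eps` is a heuristic; pathological embeddings (many identical
  points, single cluster plus uniform noise) may need a manual `--eps`.
- Melt-curve modelling, plate layouts and primer trimming are out of scope;
  inputs are assumed pre-trimmed and tabulated.
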