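# Methods

`mitochar` characterizes annotated vertebrate mitochondrial genomes and
re-estimates phylogenies from them. This note documents the models,
conventions, numerical choices and limitations; nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and the characterization table

All coordinates are 1-based, fully closed intervals on the heavy (H)
strand, exactly as mitogenome annotation tables print them. Gene length is
`to − from + 1`. Intergenic nucleotides of row *i* (in table order) are
`from(i) − to(i−1) − 1` over H-strand coordinates regardless of strand;
negative values are overlaps; the first row is 0 by convention; the
circular gap from the last feature back to the first is reported
separately, not as a row value. This is the only convention that
reproduces every printed value of the reference pangolin annotation,
including the 40-bp ATP8/ATP6 overlap and the 27-bp tRNA-Met/ND2 overlap.

The reference annotation itself contains two internal inconsistencies that
we reproduce rather than repair: the control region's printed length
(1,049) disagrees with its coordinates (15,521–16,570 span 1,050 bp) —
lengths are always computed from coordinates — and ND2's start lies inside
tRNA-Met. Both are flagged, neither is an error.

Stop codons follow the vertebrate mitochondrial code (NCBI table 2; stops
TAA/TAG/AGA/AGG, starts ATN). A coding sequence whose length is divisible
by 3 must end on a complete stop; length mod 3 = 1 requires a trailing T
("T--"), mod 3 = 2 a trailing TA ("TA-") — incomplete stops completed to
UAA by polyadenylation of the mRNA. Violations raise an
annotation-inconsistency error naming the gene; a non-ATN start is a
warning only, since other taxa legitimately use GTG and relatives.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); both are scale-invariant and
flip sign exactly under reverse complementation. N bases are excluded from
numerator and denominator. Display rounding is decimal half-up: 2 places
for percentages, 4 for skews.

Provenance matters at the fourth decimal: a skew computed from raw counts
generally differs from one recomputed from percentages that were first
rounded for display. `base_composition` works from counts;
`skews_from_percentages` deliberately takes already-rounded percentages so
published tables can be verified exactly. The package never mixes the two.

Pooled rows (rRNA / PCGs / tRNA) concatenate coding-strand gene sequences;
overlapping genome positions count once per gene occurrence (plain
concatenation), which is the arithmetic that makes the pooled PCG length
the simple sum of the 13 gene lengths (11,396 for the reference plan).

RSCU of a codon is its count divided by the mean count of its synonymous
family; stop codons are tallied separately and excluded; incomplete
trailing codons are dropped; an in-frame internal stop is a warning naming
the gene and codon position, not an error.

## tRNA cloverleaf prediction

Folding is an exhaustive search over canonical arm placements, not a
thermodynamic minimization: the claim being modelled is cloverleaf
*topology*, and a combinatorial criterion admits an exact brute-force
oracle. Geometry bounds (all in one `GeometryBounds` block, widenable):
acceptor stem 6–7 bp; spacer 1–3 nt; DHU stem 3–4 bp with 4–11-nt loop;
spacer 0–2 nt; anticodon stem 4–5 bp with a fixed 7-nt loop holding the
anticodon at loop positions 3–5; variable region 3–23 nt; TψC stem 4–5 bp
with 4–9-nt loop; 0–4 unpaired 3' nt.

A stem placement scores the longest contiguous run of valid pairs (WC A·U,
G·C, plus G·U wobble; T ≡ U) within its aligned halves; bulges and
internal mismatch repair are not modelled. Total score = paired bases over
all arms. A placement counts as DHU-bearing only if the DHU run is ≥ 3
pairs; if no such placement exists the best degenerate placement (DHU arm
absent, an unpaired 4–19-nt stretch instead) is returned — the typical
state of mitochondrial tRNA-Ser(GCU). Ties break on more WC pairs, then
fewer unpaired nucleotides, then leftmost DHU. When an anticodon is given,
only placements spelling it at loop positions 3–5 are searched, and its
absence anywhere in the sequence is a fold failure.

## Alignment

Global Gotoh alignment with affine gaps (gap of length k costs
`gap_open + k·gap_extend`; defaults +2/−1/−4/−1). Progressive multiple
alignment uses a UPGMA guide tree on shared-k-mer distances (k = 6) and
profile–profile alignment with mean-pair column scores (gap and N pairs
score 0). Traceback ties are deterministic: substitution, then gap in the
first profile, then the second. The DP is row-vectorized; memory is still
quadratic, so whole-mitogenome MSA is intentionally out of reach — align
per gene and concatenate (`concatenate_genes` records the partition map).
Percent identity excludes gap/N columns from the denominator by default;
an `exclude_gaps=False` variant counts them as mismatches, since published
similarity figures rarely state their denominator.

## Substitution model and likelihood

GTR with exchangeabilities (AC, AG, AT, CG, CT, GT; GT ≡ 1 during
optimization) and empirical base frequencies (+F, counted from the
alignment; regularized by a pseudocount only if some base is entirely
absent). The rate matrix is scaled to one expected substitution per site
at stationarity. Rate heterogeneity is the Yang-style discrete gamma with
4 equal-probability categories (category rate = mean of its quantile
band), plus an invariant-site point mass at rate 0 with probability
`p_inv`; gamma rates are rescaled by 1/(1−p_inv) so the mixture mean stays
1. Transition matrices come from one eigendecomposition of the
symmetrized reversible matrix.

Likelihood is Felsenstein pruning over unique site patterns with per-node
max-rescaling against underflow; gaps and N are fully missing (partial
likelihood 1 in every state). The value is invariant to taxon order and to
the pruning root (pulley principle); the test suite checks this to 1e-8
and checks exact agreement with a brute-force sum over internal-node
states on small instances.

## Tree search, bootstrap, classification

Search: neighbor joining on Jukes–Cantor-corrected distances (saturated
pairs capped at 5 subst/site, negative NJ branch estimates clamped to 0),
then rounds of coordinate-wise optimization — every branch length, then
the five free exchangeabilities (log-scale), then alpha (log-scale), then
p_inv — each by bounded scalar minimization (Brent, tolerance 1e-6 logL),
followed by NNI hill climbing over all internal edges until no
rearrangement improves the likelihood. Deterministic given input order. A
run that exhausts `max_rounds` without meeting the tolerance returns the
best tree with a warning rather than failing. Coordinate descent on
correlated parameters converges slowly near the optimum; for tight
parameter estimation (e.g. the 100k-site recovery check) allow ~30 rounds.

Branch support is the standard nonparametric bootstrap: sites resampled
with replacement, the pipeline re-run per replicate, support = percent of
replicates containing each original bipartition. Replicates reuse the
model parameters fitted on the original data (topology and branch lengths
re-estimated); this is the usual desk-scale practice and changes supports
negligibly when parameters are well determined. An alignment with no
variable sites yields undefined supports and a warning. No fast bootstrap
approximation is implemented.

Monophyly classification roots the tree on an explicit outgroup (a tip or
a tip set that forms one side of an edge — the rooting choice is the
user's responsibility precisely because published trees often leave it
implicit). A group is monophyletic iff it is exactly a clade's tip set;
otherwise paraphyletic iff the non-group tips inside its minimal spanning
clade form a single clade; otherwise polyphyletic.

## Synthetic data

The generator realizes an ordered gene plan (lengths, strands, intergenic
offsets including negative overlaps, ATN starts, complete/incomplete stop
types, anticodons, per-category composition targets) into a concrete
genome whose characterization reproduces the plan exactly. The default
template is the reference pangolin plan — 38 features, 16,570 bp, every
printed overlap and spacer, one DHU-less tRNA — so the pipeline's corner
cases are exercised by default.

Realization order: (1) PCG start codons and stop bases are written as
locked positions (conflicting locks make the template unrealizable, an
error raised before sampling); (2) tRNA cloverleaves from `generate_trna`
fill their spans' unlocked positions; (3) remaining positions are sampled
from per-category composition targets — on the H strand, so light-strand
gene bodies (ND6) show inverted skews on their coding strand, as real
L-strand genes do; (4) a repair pass resamples free positions of any
in-frame stop codon, checking every PCG frame that covers the position,
until all frames are stop-free. Repair may touch tRNA bases inside a
gene/tRNA overlap, so an in-genome tRNA at an overlap boundary can fold
imperfectly; standalone `generate_trna` output always folds to its
construction truth or an equal-or-better placement. DHU-less tRNAs are
rejection-sampled until the anticodon-constrained fold confirms no DHU
stem; an unconstrained fold may still relocate the anticodon loop and
find one.

Composition defaults are realistic vertebrate-mitogenome values
(per-category A/C/G/T targets around 32–38% A, strongly negative
H-strand GC skew). One seeded `numpy` generator is threaded through all
sampling; (template, seed) determines the output byte-for-byte.

Sequence evolution along a tree is site-independent: each site draws a
rate from the +I+G mixture, then evolves by eigendecomposition-based
transition probabilities down each branch. No indel process is simulated
(alignment tests use engineered indels); no coalescent/ILS simulation.

What a green synthetic test does not establish: the generator emulates
gene order, composition targets, codon structure and foldable tRNAs, but
not real covariation (codon usage bias beyond composition, tRNA modified
bases, replication-origin-distance gradients in skew), so agreement on
synthetic data validates the arithmetic and the inference machinery, not
the biology of any particular genome.

## Known limitations

- Wrap-around (origin-spanning) features are rejected; none occur in the
  reference plan.
- GenBank flat files are not parsed; inputs are FASTA plus the package's
  TSV feature table.
- IUPAC ambiguity codes other than N are rejected at parse time.
- The aligner's quadratic memory limits it to a few kb per block.
- Model selection is out of scope: GTR+F+I+G4 is taken as given.
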