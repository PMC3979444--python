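# Methods

This note documents the models and procedures implemented in peroxevol, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that affect results.

## Curation and typing

Proteins enter as FASTA with optional `id|species|order|type` headers over
the 20-letter alphabet plus X.  Signal peptides are **consumed as an
annotation table** (id, cleavage position), not predicted: secretion-signal
prediction is a separate, well-served problem, and the pipeline only needs
the cleavage point.  All anchor numbering is on the **mature** protein;
configs written against full-length numbering must subtract the
signal-peptide length.

Within-species redundancy removal keeps, among records with identical
species and identical mature sequence, the lexicographically smallest id.
The tie-break is arbitrary but fixed, which makes deduplication idempotent
and independent of input order.  Records flagged as incompletely processed
transcripts are removed via an exclusion list rather than detected
automatically.

Typing reads four anchor columns, located by mapping reference-row mature
positions through the alignment's gap structure: the Mn-binding triad
(E35, E39, D179 of an MnP-type reference) and the catalytic tryptophan
(W171 of a LiP-type reference).  Triad-and-Trp → VP, triad only → MnP, Trp
only → LiP, neither → CII.  A gap at an anchor column counts as absence.
Strict residue identity (E, E, D and W) is the default; a *conservative*
mode accepting E↔D interchange at the triad exists because natural Mn sites
occasionally vary, but it is off by default so the standard shading rule is
reproduced.  The heme filter discards sequences lacking histidine at the
distal/proximal heme-ligand columns — and looks **only** at those columns,
so CII sequences (which lack the substrate-oxidation residues by
definition) stay in the analysis.  Heme-ligand positions are configurable
because no universal numbering exists; the defaults (47, 176 mature) match
the package's synthetic reference.

## Phylogeny

Distances are amino-acid p-distances with pairwise deletion: for each pair,
columns where either row has a gap or X are excluded, and the distance is
mismatches over remaining columns; the valid-column count is kept alongside.
A pair sharing no columns is an error, not a guess.

Neighbor joining is the Saitou–Nei agglomeration on the rate-corrected
criterion Q(i,j) = (n−2)d(i,j) − (r_i + r_j).  Two determinism measures are
deliberate: row sums are accumulated in sorted-value order and r_i + r_j is
grouped before subtraction, making Q bit-identical under input-row
permutation; and ties are broken on the lexicographically smallest pair of
cluster labels (a cluster's label is the smallest leaf name it contains).
Negative branch-length estimates are clamped to zero and flagged.  The tree
is unrooted (trifurcating root).

Bootstrap resamples columns with replacement, rebuilds the NJ tree, and
scores each bipartition of the point-estimate tree by the percentage of
replicates containing it.  A replicate that leaves some pair with no shared
columns is redrawn (at most 100 attempts).  With a fixed seed the whole
procedure is bit-reproducible.

Group delineation takes maximal clades that (a) are pure for one taxonomic
order and (b) meet the support policy — above the *strong* threshold
(default 90) in every available method, or above *member* (default 80) in
every method and above *strong* in at least one.  External ML/MP analyses
are not re-implemented; their per-bipartition supports can be supplied as
tables and then participate in the policy.  The policy is applied to clades
of the NJ topology (the underlying three-method protocol is ambiguous on
this point; applying it to the NJ tree is this package's documented
choice).  Groups are named by the sorted set of LP types they contain, with
Roman numerals when several groups share a type set; leaves in no
qualifying clade are reported as separate LPs.  A species-monophyly index
(fraction of multi-copy species whose copies are monophyletic within a
group) summarizes concerted-like (→1) versus birth-and-death-like (→0)
behavior descriptively; no ancestral-state machinery is attached to it.

The built-in progressive aligner (k-mer-distance NJ guide tree, profile
Gotoh alignment, BLOSUM62, gap open 10 / extend 0.2) exists so the pipeline
runs with no external aligner; for reproducing results derived from a
specific published alignment, supplying that alignment is the recommended
path, since no two progressive aligners agree column-for-column.

## Gene structure

Intron phase is 0/1/2 for introns falling between codons, after the first
nucleotide, or after the second.  **Phase-0 introns anchor to the residue
following the intron**; phases 1 and 2 anchor to the interrupted residue.
The anchoring convention for phase 0 is not universal in the literature;
this package fixes it as stated.  Only introns between the translation
start and stop exist by construction (exon tables span exactly the CDS).

Homologous positions are clustered by single linkage along the alignment
column axis with a window of 2 columns (default), phase-agnostically —
intron sliding can shift both position and phase.  The window value is a
judgment call where the tolerated "minor variation" is not quantified;
2 columns covers one-codon sliding plus one alignment wobble.  A cluster
chaining over more than 6 columns triggers a warning because positional
homology becomes doubtful at that span.  Labels run A…Z, AA, AB, … in
anchor-column order (the 36th label is AJ), and relabelling is invariant
under input permutation.

## Codon site models

The substitution process is the Goldman–Yang codon model on the 61 sense
codons of the universal code: rate i→j is zero unless the codons differ at
one nucleotide, and otherwise π_j, multiplied by κ for transitions and by ω
for nonsynonymous changes.  Codon frequencies default to **F3x4**
(position-specific nucleotide frequencies estimated from the data), the
conventional default for this model family; F61/uniform can be passed
explicitly.  Codons with zero equilibrium frequency are excluded from the
state space (restriction to observed codons).

Site models share κ and branch lengths and differ in the ω mixture: M0 one
ratio; M1a (ω₀<1, ω₁=1); M2a adds ω₂≥1; M3 three free classes — K=3 is
forced by the 4-degree-of-freedom M0-vs-M3 test (5 vs 1 free class
parameters); M7 a Beta(p,q) discretized into 10 equal-probability
categories at their medians (category count configurable); M8 adds one
class with ω_s ≥ 1.  Per-class generators are scaled **jointly** so the
mixture has unit expected rate; branch lengths are therefore in expected
substitutions per codon site.

Likelihoods use Felsenstein pruning vectorized over unique site patterns,
with per-pattern rescaling against underflow; transition matrices come from
one symmetrized eigendecomposition per (κ, ω) and are cheap per branch.
Per-site per-class log-likelihoods are retained for empirical-Bayes use.

Fitting is L-BFGS-B on transformed parameters (log for κ, ω, branch
lengths, beta shapes; logistic for proportions and sub-unity ω; 1+exp for
ω ≥ 1 classes), finite-difference gradients with step 10⁻⁶, and an
objective tolerance of about 10⁻⁶ log-units.  Branch lengths are optimized
under M0 and reused by the other models (full per-model optimization is a
flag); this is the usual speed/robustness trade-off and matters little for
LRTs between models sharing the same tree.  Alternative models are fitted
from **two starts** — a boundary image of their null's optimum (M3 from M0,
M2a from M1a, M8 from M7), which guarantees ℓ(alt) ≥ ℓ(null) up to
optimizer tolerance, and the model's default start, which restores search
power when the optimum is far from the null boundary — keeping the better
optimum.  Additional seed-perturbed restarts (fixed seed list 1, 2, 3) are
available but off by default: on the synthetic surfaces they never changed
an optimum, and they triple cost.  All fits are deterministic.

LRT p-values use the plain chi-square upper tail with df 4/2/2 for
M0–M3 / M1a–M2a / M7–M8, matching standard reporting practice for these
pairs; the boundary-corrected mixture for M7-vs-M8 is available as an
option but is not the default.  A negative 2Δℓ (optimizer failure) is
floored at zero with a warning.  Positively selected sites are flagged by
naive empirical Bayes — posterior class probabilities with MLEs plugged in
— at 0.95 and 0.99; Bayes empirical Bayes is out of scope.

The decision rule is conjunctive: a sequence set is called positively
selected only when the positive-class ω of M3 (its highest class), M2a
(ω₂), or M8 (ω_s) exceeds 1 **and** the corresponding LRT has p < 0.05.
Either a sub-unity ω or a nonsignificant LRT rejects.  Which ω a discrete
model "reports" is taken to be its highest-ω class estimate.

## Synthetic data: what it does and does not emulate

The generators produce data with exactly the statistical structure each
stage assumes: trees are Yule topologies with exponential branch lengths;
codon alignments evolve site-independently under the declared mixture, with
the true class of every site recorded; LP-like proteins are point-mutated
copies (10% per non-anchor site) of a fixed 250-residue reference with
anchors set or ablated per requested type and signal peptides of 17–25
residues prepended; gene models carry GT…AG introns of 50–500 nt (the
fungal scale; length is irrelevant downstream) planted at homologous
mature-codon positions with ±jitter emulating sliding.

Not emulated: insertions/deletions (so alignment is exact and typing
accuracy of 100% reflects anchor logic, not aligner robustness), rate
variation beyond the ω mixture, codon usage bias beyond the chosen π,
intron gain/loss dynamics, or misannotated gene models.  Passing the
round-trip tests therefore certifies the algorithms under their own model
assumptions; performance on real data additionally depends on alignment
quality and annotation accuracy, which these tests do not probe.

Default demo scale is 12 proteins / 4 types and 6–8-taxon codon sets —
large enough for every code path, small enough to iterate on.

## Study conditions of the acceptance surface

The quantities recomputed by `scripts/acceptance.py` use fixed conditions
chosen once: 200 proteins (50 per type) for typing; twelve additive
matrices from random 4–6-taxon trees with branch lengths in [0.1, 1] for
the NJ oracle; a 4-taxon, 3-site, two-class mixture for the enumeration
oracle; ω = 0.5, κ = 2, L = 500, 8 taxa for M0 recovery; 20 null datasets
(M7, L = 200, 6 taxa) for type-I calibration of M7-vs-M8 at α = 0.05
(expected rejections ≤ 1 on average; the tested bound of 3 allows binomial
fluctuation, and the plain chi-square reference is conservative at this
boundary, so counts near zero are typical); a 10-position intron plan with
jitter 2 / window 2 / spacing 12 plus a 36-position plan (labels A–AJ); and
the nine published group summaries for the decision rule.

## Known limitations

- The aligner is a plain progressive method without iterative refinement;
  deep or indel-rich families deserve an external aligner.
- NJ bootstrap on hundreds of taxa is O(reps × n³) in Python and becomes
  slow beyond ~100 sequences.
- Selection fits assume in-frame, stop-free, whole-codon-gapped alignments;
  gapped codon columns are dropped by default (cleandata behavior) and
  ambiguity codes are not modeled.
- Minus-strand GFF3 gene models are not converted; coordinates must be
  supplied on the coding strand.
- The M8 ω_s class is constrained to ω ≥ 1, so "M8 found ω < 1" manifests
  as ω_s pinned near 1 with negligible weight rather than a sub-unity
  estimate.
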