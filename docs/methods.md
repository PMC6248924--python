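# Methods

This package reconstructs, as tested code, the computational analysis
behind the discovery of tandem repeat domains in "giant" bacterial
flagellins: how flagellins are told apart from their FlgL-like relatives,
how the hypervariable central insert and its internal duplication are
found, and how the evolutionary history of that duplication is read off a
pair of phylogenies.  Every stage runs offline on synthetic data with
known ground truth.

## The biological model

A flagellin consists of conserved N- and C-terminal regions that fold
together into the D0/D1 core domains (the polymerising part of the
filament), flanking a hypervariable central insert that faces the
solvent.  Canonical flagellins are ~495 aa (the *Salmonella* FliC
anchor); sequences >800 aa are classed *large* and >1,000 aa *giant*,
both by strict inequality on residue count.  In the Oceanospirillales,
the largest flagellins carry the central insert organised as two tandem
copies of a repeat unit — the Domain-Extension (DE) region — optionally
separated by a further insert (the DE-eXtension, DX) that contains a
conserved ~35-aa glycine-rich stretch.  Intermediate-length relatives
carry a single DE copy.

## Pipeline stages

1. **Family classification.**  Flagellins and the hook–filament junction
   protein FlgL share an N-terminal helical block, so each sequence is
   scored under two profile HMMs (one per family) and classified by the
   bit-score margin: flagellin above +2 bits, FlgL-like below −2 bits,
   ambiguous inside the band.  The band is a design choice (the original
   voting scheme is not specified anywhere); 2 bits is small relative to
   observed margins (hundreds of bits on synthetic families) and exists
   to force a conscious no-call rather than a coin flip.

2. **Insert measurement.**  Dedicated N-core and C-core profile HMMs are
   Viterbi-aligned to each flagellin; the central insert is
   `[end of N-core hit, start of C-core hit)`.  A core hit below 10 bits
   is treated as missing (structured no-call); cores out of order raise,
   because silently measuring such a sequence would poison everything
   downstream.

3. **Tandem repeat seeding.**  Each insert is locally aligned against
   itself with cells within `exclusion_band = 30` of the main diagonal
   forbidden; a strong off-diagonal alignment is an internal duplication.
   The repeat-calling threshold is the shuffled-insert null's 99th
   percentile, computed once per run as the `ceil(0.99 (n+1))`-th order
   statistic of `n = 100` shuffle scores (the null maximum), with calls
   requiring a *strictly* greater score.  By exchangeability this bounds
   the false-call probability at `1/(n+1) < 1%` for any score
   distribution, ties included — an estimator-noise-free guarantee that a
   plug-in empirical quantile does not give.

4. **Iterative DE discovery.**  The tandem copies are pooled (labelled
   `seqid/1half`, `seqid/2half`), aligned, and a profile HMM built,
   calibrated, and scanned over the dataset at E < 0.1.  Novel
   non-overlapping hits (singly-occurring DE copies, `seqid/ins`) are
   pooled and the model rebuilt.  Convergence requires a *confirming*
   round: the loop stops when a round after the first adds nothing, so
   the round that "identifies no additional regions" is always executed
   and reported.  The instance set grows monotonically and the loop is
   bounded by `max_iter = 5` (exhaustion is flagged, not raised).

5. **DX and the glycine-rich region.**  DX is the material strictly
   between exactly two tandem DE copies when at least `min_dx_length =
   20` aa long.  The glycine scan slides an 11-residue window over DX,
   marks windows with glycine fraction ≥ 0.4, merges marked spans, and
   keeps merged intervals ≥ 20 aa.  The defaults make a ~35-aa region at
   60% glycine detectable even after substitutional decay at the
   generator's divergence (0.6·0.8 + 0.05·0.2 ≈ 0.49 ≥ 0.4 at 20%
   divergence); all three knobs are configurable.

6. **Core phylogeny and congruence.**  The D0/D1 core residues (sequence
   minus measured insert) are progressively aligned, columns with > 50%
   gaps trimmed, pairwise distances Poisson-corrected (−ln(1−p), capped
   at 5.0), and a tree built by neighbor joining.  Leaves carry insert
   length and DE-copy count annotations.  For taxa with two DE copies,
   each post-duplication copy set is aligned and NJ-inferred separately;
   Robinson–Foulds distance 0 against the flagellin tree for both copy
   trees is the signature of duplication followed by vertical
   transmission (horizontal transfer of the insert would decouple the
   topologies).

## Profile HMM internals

The HMM core is written here, not delegated: match/insert/delete states
with one node per match column (≤ 50% gaps), Henikoff position-based
sequence weights, emissions mixed with the background at pseudocount
weight 1.0, Laplace-pseudocounted transitions.  Local alignment mode is
configured as: uniform entry `1/L` into any match state; a fixed early
exit probability of 0.1 from every internal match state (learned
continue transitions scaled by 0.9); mandatory exit from the last node;
flanking residues emitted at background frequencies so they cancel in
the log2-odds score.  Delete states exist only strictly inside the model
(no entry/exit through deletes in local mode).  Forward runs in odds
space with per-position rescaling (no per-cell transcendentals); Viterbi
runs in log space with deterministic tie-breaking M > D > I.  Both are
verified against explicit enumeration of every state path on toy models.

Significance is self-contained: a Gumbel is fitted to forward scores of
≥ 100 shuffled database sequences, and `E(x) = N_db · P(score ≥ x)`.
The threshold E < 0.1 follows the screening convention for "no
significant hits".  Note that local-alignment bit maxima of *random*
sequences sit near zero rather than clearly negative (they grow like
log nL); this is why the null checks in the tests are E-value-based, not
sign-based.

Domain scanning is greedy: best hit by Viterbi envelope, interval masked
with `X` (which scores 0 bits against everything), repeat until the
E-value crosses the threshold.  Hits are non-overlapping by construction.

## Pairwise alignment

Affine-gap Smith–Waterman and Needleman–Wunsch (gap of length k costs
`gap_open + (k−1)·gap_extend`), BLOSUM62 with 11/1 by default — the
community standard; no matrix is prescribed by the analysis being
reproduced.  Both kernels run over a dense pair-score matrix, so the
same code serves sequences and alignment profiles (profile columns score
as the mean pairwise substitution score, gaps scoring 0).  Coordinates
are 0-based half-open; tie-breaking is fixed diagonal > up > left, so
outputs are byte-reproducible.  The dot-plot is Dotlet-style: entry
(i, j) sums substitution scores along a truncated diagonal window
(default 15, odd).  Scores are validated against exhaustive enumeration
of all gapped alignments on short reduced-alphabet sequences.

Progressive MSA uses an NJ guide tree on global-alignment identity
distances, midpoint-rooted, merging profiles leaf-to-root.  This is a
deliberate stand-in for statistical aligners: the downstream claims
depend on having a trimmed core alignment, not on any particular
aligner.  Trimming removes columns with gap fraction above 0.5 and
returns an index map back to original columns.

## The synthetic generator

The generator emits the statistical structure the analysis assumes, with
full ground truth.  Ancestral segments (N-core 180 aa, C-core 180 aa,
plain insert 135 aa, DE, DX with a 35-aa glycine region at fraction 0.6)
are drawn once per seed — each from its own sub-seeded stream, so
configs sharing a seed share every equal-length ancestor — and evolved
along a known tree (balanced by default; Yule and star shapes
available).  Per branch of length ℓ (expected substitutions/site,
root-to-leaf total = `divergence`, default 0.2): each site is hit with
probability 1−e^(−ℓ) and replaced by a uniform different residue;
indel events arrive at rate 0.05·ℓ per site with geometric lengths
(mean ≈ 2.9), confined strictly inside segments so planted boundaries
shift but never vanish.  The DE duplication is planted at the root of
every maximal clade whose leaves all carry a tandem model, so the two
copies diverge along the species tree afterwards — the vertical
transmission scenario.

Two presets fix the study geometries: `canonical_preset`
(180+135+180 = 495 aa) and `oceanospirillales_preset`
(180+260+140+260+180 = 1,020 aa for the giant leaves, with half the taxa
giant, a quarter single-DE, a quarter canonical).  FlgL-like decoys share
the first 60 aa of the flagellin N-core ancestor (the shared helical
block that motivates the voting scheme) and are otherwise drawn from a
distinct 250-aa core, evolved at 30% divergence.

What the generator does *not* emulate: realistic amino-acid composition
(backgrounds are uniform), rate heterogeneity across sites, selection,
codon structure, alignment-degrading low-complexity regions, and the
database-scale diversity of real proteomes.  Passing tests therefore
show that the pipeline's logic is correct under its stated model, not
that its thresholds are tuned for UniProt-scale screens.

## Numerical choices and degenerate inputs

- `X` is the only ambiguity code accepted; it scores 0 bits/0 points
  against everything, which keeps all DP well defined and doubles as the
  masking symbol.
- Negative NJ branch lengths are clamped to 0 with the deficit moved to
  the sibling; NJ tie-breaks by the clusters' smallest leaf labels, so
  results are independent of input row order.
- Poisson distances are capped at 5.0 to keep saturated pairs finite.
- Alignments of indistinguishable sequences skip the guide tree (any
  merge order is equivalent).
- Sequence sets with fewer than 3 measurable cores skip tree building;
  congruence needs ≥ 4 tandem taxa.
- All randomness (shuffle nulls, calibrations, the generator) flows from
  explicit integer seeds; identical inputs and seeds give byte-identical
  outputs.

## Problem sizes

The shipped analyses and checks use 8-taxon datasets, 12-sequence
training sets, 100-shuffle nulls and calibrations, 50–100 generator
seeds for the recovery/congruence statistics, and 200+200 held-out
sequences for the classifier — sizes chosen so the complete run is a
desk-scale computation while keeping every Monte-Carlo bound meaningful.

## Known limitations

- The HMM is single-hit local; glocal/multi-hit HMMER parity, Dirichlet
  mixture priors, and posterior decoding are out of scope, and the
  plain-text model serialization is this package's own format.
- "Voting" is a two-model margin rule; multi-model majority voting per
  family would be a configuration extension.
- ML tree inference is intentionally replaced by NJ on corrected
  distances: every downstream claim tested here (clade membership,
  congruence) is topology-level and NJ-recoverable at the simulated
  divergences.
- Homology-group colouring of insert annotations is single-linkage
  clustering of insert alignment scores — a documented stand-in for an
  unspecified published procedure — and is not part of the tested
  surface.
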