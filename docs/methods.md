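# Methods

This note records the models implemented, the defaults and why they are
set where they are, what the synthetic data do and do not emulate, and
the numerical choices a maintainer would want spelled out.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Family identification and classification

A WRKY domain hit is an occurrence of the heptapeptide `WRKYGQK`
(configurable variant list, e.g. `WRKYGKK`, off by default because the
canonical motif is what defines the curated family) followed by a zinc
finger.  The finger patterns are matched as regular expressions with the
spacings that distinguish the two finger types:

* C2H2: `C X{4,5} C X{22,23} H X H`
* C2HC: `C X{7} C X{23} H X C`

The first finger cysteine must begin within **30 residues** after the
heptapeptide and the whole domain is capped at **120 residues** — the
domain is ~60 aa, so these bounds are generous while keeping the regex
search local.  When both patterns match from the same cysteine the more
constrained C2H2 wins; matches are non-overlapping, leftmost-first, so
scanning is deterministic.  A heptapeptide with no finger in range is
reported with finger type `none` and left `unclassified`, mirroring the
manual-curation step of a family census (truncated or mis-annotated
genes).  Group rules: ≥2 complete domains → Group 1; one C2H2 → Group 2;
one C2HC → Group 3.

Subgroups 2a–2e are assigned on the domain tree: a member takes the
subgroup of its nearest labeled reference by patristic distance, ties
broken by the smallest containing clade.  A single-domain protein whose
nearest references are Group-1 C-terminal domains is re-labeled Group 1 —
the case of a two-domain gene that lost (or was mis-annotated at) its
N-terminal domain.

Intron mapping converts protein-offset domain intervals to CDS nucleotide
coordinates (×3) and counts CDS-segment junctions inside them; intron
phase is (CDS nucleotides upstream of the junction) mod 3.

## Phylogeny

The progressive aligner exists to make the pipeline self-contained: guide
order from single-linkage joining on 3-mer distances (index tie-breaks),
profile–profile Needleman–Wunsch with BLOSUM62 expected scores and a
linear gap penalty (−5/column, half the affine open cost — a deliberate
simplification that keeps the DP quadratic and deterministic).  It is not
a general-purpose MSA program and is not claimed to be; for the
near-identical domain copies the synthetic genomes produce, and for the
~60-aa domain rows the pipeline aligns, it is adequate and exactly
reproducible.

Distances use pairwise deletion (columns gapped in either row of a pair
are dropped for that pair), p-distance or Poisson correction
d = −ln(1 − p); Poisson is the default amino-acid model, with p-distance
selectable.  A saturated pair (p = 1) is capped at 1 − 1/(2n) mismatches
rather than made infinite, so bootstrap replicates on noisy data cannot
crash the run.

Neighbor joining is the standard Saitou–Nei Q-criterion algorithm with
the lowest-index pair taken on ties and negative branch lengths clamped
to zero.  On additive matrices the output reproduces the generating
topology and path lengths exactly (property-tested).  Bootstrap support
resamples columns with replacement; one master seed spawns per-replicate
child seeds (`numpy` `SeedSequence`), so results are reproducible and
independent of replicate order.  Group-1 proteins contribute their two
domains as separate rows suffixed `-NTWD`/`-CTWD`, keeping the two
domains' distinct ancestries visible in the domain tree.

## Duplication

Tandem clustering is single linkage over gene ranks (position of a gene
among all genes of its chromosome ordered by start coordinate, strand
ignored) with a maximum gap of **10 genes** — the rank interpretation is
the literal reading of a "10 genes distance" rule.

Microsynteny blocks: for a candidate family pair, homologous gene pairs
between the two 50-gene windows centred on the focal genes are collected
(homologous tandem neighbours within 2 ranks collapse to one
representative; the focal pair itself is excluded from anchors), and the
longest chain strictly monotone in both rank orders — in either
orientation, so inversions are tolerated — is the anchor set.  Blocks
need ≥3 anchors.  Significance: the number of homologous pairs between
two windows of w genes, under a genome-wide homolog density, is a
hypergeometric draw; the block E-value is the upper tail P(X ≥ m) times
the number of window pairs tested (Bonferroni).  E ≤ 0.01 is reported.
This statistic is monotone decreasing in the anchor count
(property-tested); it is this package's choice of collinearity
significance, and the absolute E-values of any particular external tool
are not a comparison target.

Duplication classes use the conventional precedence segmental > tandem >
proximal (family homolog within 10 ranks) > dispersed (any family
homolog) > singleton.

Homology input is pluggable.  The built-in screen
(`infer_homology_pairs`) calls two proteins homologous when the smaller
shares ≥50 % of its 6-mers with the other — a seed heuristic suited to
the synthetic genomes, whose homologs are near-identical copies; for real
proteomes the Smith–Waterman scorer in the orthology module is the
appropriate backend on the candidates this screen returns.

Block Ks summaries compute NG86 Ks per anchor pair, drop saturated pairs
(ps ≥ 3/4) and pairs with Ks > 5 (deep paralogy, uninformative for block
dating), and report mean and sample SD; a single usable pair reports
SD = 0 with the summary flagged defined, and no usable pairs flags the
summary undefined instead of raising.

## Selection

**NG86.** Synonymous sites per codon are the fractions of non-stop
single-nucleotide changes that preserve the amino acid, summed over the
three positions and averaged over the two sequences.  Codons differing at
more than one position average their difference counts over all
mutational pathways that avoid stop codons (all orderings of the single
steps; equal weighting).  Jukes–Cantor correction maps ps and pn to Ks
and Ka; ps or pn ≥ 3/4 sets a saturation flag with NaN distances rather
than raising, because saturated pairs are expected in genome-wide Ks
tables and must be filterable, not fatal.  The implementation is checked
against an independent brute-force enumerator over all 61×61 sense-codon
pairs.

**Codon model.** The substitution process on the 61 sense codons has
rate π_j·κ^[transition]·ω^[nonsynonymous] for single-nucleotide changes
and 0 otherwise.  Codon frequencies are F3x4 estimated from the alignment
(pseudocount 0.5 per nucleotide so every sense codon keeps positive
frequency); equal frequencies (1/61) are selectable and used by the
oracle tests.  The generator is reversible, so P(t) = exp(Qt) comes from
a symmetrized eigendecomposition; transition matrices are clipped at 0
and row-renormalized to absorb round-off.  All matrices share one
normalization: expected substitutions/codon/unit time equals 1 under the
**background** site-class mixture, so a branch length reads as expected
substitutions per codon on background branches.

**Branch-site model A.** Site classes 0 (ω₀ everywhere), 1 (ω₁ = 1
everywhere), 2a (background ω₀, foreground ω₂) and 2b (background 1,
foreground ω₂), with p2a/p2b = p0/p1.  One published description of this
model's class 1 says it evolves neutrally "with ω₁ < 1"; neutral
evolution means ω₁ = 1 and that is what is implemented — the standard
model-A definition.  ω₂ is capped at 999, matching the convention of the
reference codon-ML implementation so fitted values are comparable.
Likelihoods use Felsenstein pruning over compressed site patterns.  The
tree is re-rooted at the foreground branch's parent, so the four classes
share the two background-regime partial likelihoods (ω₀-tree and ω₁-tree)
and differ only in the transition matrix on the foreground edge — a 2×
saving that is exact, not approximate (verified against brute-force state
enumeration).  Per-node rescaling engages only when partials threaten
underflow (max < 1e−120).

**Optimization.** Free parameters are transformed to an unconstrained
scale — log κ, logit ω₀, logit of (ω₂−1)/998, logit of p0+p1, logit of
p0/(p0+p1), log branch-scale — and maximized with L-BFGS-B
(finite-difference gradients) from several deterministic starts,
including the conventional ω₂ = 1.5 initialization, with a Nelder–Mead
fallback if the quasi-Newton runs all fail.  Branch lengths are handled
as the input tree's relative lengths times one free scale factor rather
than 13 free coordinates: the foreground test concerns ω₂, both
hypotheses share the same branch-length treatment, and the scale factor
absorbs overall-rate misspecification; this keeps a full null + 
alternative fit near one second at 8 taxa × 300 codons.  The alternative
is warm-started from the fitted null but never at ω₂ ≈ 1 (a start at the
boundary traps the optimizer there); conversely, when the alternative
wins by more than 1 lnL unit the null is re-polished from the
alternative's parameters, and if the alternative still ends below the
null, the null optimum itself (with ω₂ = 1, which lies inside the
alternative space) is adopted as the alternative fit.  Together these
guards make 2ΔlnL ≥ 0 structural rather than hoped-for.

**LRT.** 2ΔlnL is referred to χ²₁ (the test the workflow prescribes); the
boundary-respecting 50:50 mixture of point-mass-at-0 and χ²₁ is available
via `mixture_null=True`.  Because the plain χ²₁ test is conservative at
this boundary, null-simulation rejection rates land well below the
nominal α (the acceptance suite measures this directly).

## Expression

RPKM = 10⁹·c/(L·len).  Log ratios are log₂((x+ε)/(y+ε)) with ε = 1 RPKM
by default — the analysis is silent on zero handling in general, and a
1-RPKM pseudocount bounds ratios for dropout genes while leaving
moderately expressed genes essentially untouched.  Fold-change calls use
threshold 2: up if any condition reaches ≥ log₂2, down if any reaches
≤ −log₂2; a gene crossing both is classed up (induction-focused reading
that keeps the up/down partition exclusive) and flagged `bidirectional`.
Hierarchical clustering delegates to SciPy (correlation or Euclidean
distance; average or complete linkage), which breaks ties by smallest
cluster index, so leaf order is deterministic for a fixed input order;
constant rows are rejected by name under the correlation metric because
their correlation distance is undefined.  2^(−ΔΔCt): ΔCt per sample is
mean target Ct − mean reference Ct over technical replicates, ΔΔCt
subtracts the control sample, and the reported SE combines both genes'
replicate SEs in quadrature.

## Orthology

Similarity is Smith–Waterman local alignment score (BLOSUM62, gap open
−11 / extend −1, the BLASTP-default costs), symmetrized by the maximum of
the two directions; the alignment engine is Biopython's
`PairwiseAligner`.  Seed orthologs are two-way best hits above a score
floor of 40 (below which short spurious local hits dominate); inparalogs
are same-proteome sequences scoring at least as high to their own seed as
to anything cross-proteome, with confidence = score to seed / seed–seed
score.  Groups are disjoint; every tie breaks by id order.  Bootstrap
confidence estimation and overlapping-group resolution of the full
InParanoid procedure are intentionally out of scope — the two stated
rules are what the pipeline consumes.

## Synthetic data: what it emulates, and what it does not

`generate_annotated_genome` plants: family proteins whose domain
architecture matches their group exactly (two C2H2 domains for Group 1,
one C2H2 for Group 2, one C2HC for Group 3), one intron of phase 2 inside
the (first) domain of every family gene, tandem arrays at specified rank
gaps, and collinear segments sharing a specified number of near-identical
anchor genes around a homologous focal pair.  Background genes are random
proteins screened to contain no `WRKYGQK` (clean negatives).  Members of
a group/subgroup copy one prototype verbatim, so at zero noise every
downstream stage can be held to exact truth-table equality.  Planted
structures are separated by ≥30 ranks — beyond the 25-gene half-window —
so no unplanted family pair's windows capture another block's anchors.

The default study genome for end-to-end tests is 4 chromosomes × 150
genes with 18 family members, two tandem arrays (sizes 3 and 2) and two
segments (8 and 5 anchors).  The genome size matters: block significance
is relative to genome-wide homolog density, and windows of 50 genes in a
toy genome of a few hundred genes are a substantial fraction of all
pairs, which is why the generator defaults are set at this scale.

What passing these tests shows: the algorithms recover exactly what was
planted under their own model assumptions.  What it does not show:
robustness to real-genome phenomena the generator omits — alternative
isoforms, pseudogenes, partial domains, unequal intergenic spacing,
annotation errors, alignment uncertainty, codon-usage heterogeneity, and
expression dispersion beyond log-normal noise.

`simulate_codon_alignment` evolves sites under the same rate matrices the
estimator uses (shared code by design, so recovery tests isolate
optimizer correctness from model mismatch); site classes are drawn from
the stated proportions and the truth vector is returned.  The power
conditions used in the acceptance suite — 8 taxa, 300 codons, foreground
terminal branch 0.5 expected substitutions/codon, ω₀ = 0.2, 24 % of sites
in classes 2a+2b, ω₂ = 5 — were chosen as a regime where the test should
have high power, so that a power shortfall indicates an implementation
defect rather than an information-starved design; calibration runs use
the same tree with ω₂ = 1 and 20 % boundary-class sites.

`simulate_expression_matrix` multiplies log-normal baselines by planted
fold changes with optional log-normal noise (log₂-sd 0.35 in the
sensitivity test, a mid-range value for biological + technical spread on
RPKM).

## Degenerate inputs and edge policies

* FASTA: duplicate ids and empty files are errors; sequences are
  upper-cased; the alphabet is validated.
* GFF3: internal coordinates are 0-based half-open, converted at the I/O
  boundary; CDS with unresolvable parents and overlapping exons are
  errors; ranks are per-chromosome permutations of 0..n−1 by start.
* The fixture tables ship as TSV transcriptions guarded by checksum
  tests; the tandem table's 15 rows / 33 genes and the synteny table's
  61 rows / 57 genes are asserted in the suite.  (The source tables'
  surrounding text contains two internal inconsistencies — a per-group
  tandem count sentence that contradicts the same sentence's own list,
  and per-chromosome counts that sum to one less than the stated mapped
  total; the tables are preserved as printed and neither is "corrected".)
* NG86 refuses length mismatches, frame violations and internal stops;
  terminal stops are trimmed.
* NJ requires ≥3 taxa and a symmetric, zero-diagonal, non-negative
  matrix; bootstrap requires ≥4 rows.
* `likelihood_ratio_test` treats lnL_alt < lnL_null beyond 1e−6 as an
  optimizer failure and raises; the orchestrating `branch_site_lrt`
  prevents that state from arising as described above.

## Known limitations

* The progressive aligner is a determinism-first stand-in, not a
  competitive MSA method; tree inference is NJ only (no ML/MP).
* Branch lengths in the branch-site fit are a scaled copy of the input
  tree's relative lengths, not freely optimized per edge; with a badly
  wrong input shape the fit cannot compensate.
* The block E-value is this package's own hypergeometric formulation;
  anchor counts and E-values from other collinearity tools are not
  expected to match numerically.
* The k-mer homology screen is tuned for near-identical duplicates; real
  proteome-scale homology should come from the alignment-score backend.
* qRT-PCR replicate analysis stops at mean ± SE; no ANOVA layer.
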