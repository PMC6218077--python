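# Methods

`rhodups` re-implements, at desk scale, the inference chain used to decide
how many times the intron-less visual rhodopsin gene (*rh1*) was duplicated
early in teleost evolution, and what was secondarily lost afterwards. This
note records the models, the numerical choices, and what the synthetic data
do and do not establish.

## Substitution model and likelihood engine

Sequence evolution is modelled as GTR+Γ: a general time-reversible rate
matrix Q with six exchangeabilities (order AC, AG, AT, CG, CT; GT ≡ 1) and
stationary frequencies π, scaled so −Σᵢ πᵢ Qᵢᵢ = 1 (branch lengths are
expected substitutions per site). Among-site rate variation uses Yang's
discrete-gamma approximation with k equal-probability categories (default
k = 4), each category represented by its conditional mean under
Gamma(α, α); the category rates are renormalised to average exactly 1.
The mean-of-class (not median) convention matches the default behaviour of
the mainstream ML phylogenetics programs this pipeline mirrors.

Likelihoods are computed by Felsenstein pruning over compressed site
patterns. IUPAC ambiguity codes — including the R/Y states produced by
recoding — enter the leaf conditionals as indicator vectors over their
compatible states, and gaps are treated as fully missing (N). Because an
ambiguity only widens a leaf's state set, recoding can never lower a site
likelihood; this dominance property is asserted in the tests. Partials are
rescaled per pattern at every internal node, so deep trees cannot
underflow. P(t) comes from the symmetrised eigendecomposition of Q, which
is computed once per model instance and cached.

Optimisation is coordinate ascent: per-branch bounded Brent line searches
(branch lengths clamped to [1e-8, 20], xatol 1e-7) interleaved with
L-BFGS-B steps on log-transformed exchangeabilities, frequency log-ratios
and log α, iterated until a full sweep improves log L by less than 1e-4.
Each single-branch line search uses an exact one-dimensional restriction
of the likelihood (outer × P(t) × inner partials, expressed in the
eigenbasis), so a sweep costs one full pruning pass per branch rather than
one per function evaluation. Zero or missing starting branch lengths are
nudged to 1e-5 before optimisation, since impossible patterns have zero
likelihood at t = 0. The engine is exposed statsmodels-style:
`TreeLikelihood(tree, aln, model).fit()` returns a result object with the
fitted tree, model, log-likelihood and a `summary()` table.

## Alignment preparation

The composition screen is the classical contingency chi-squared test of
base-composition homogeneity across taxa, run separately per codon
position on the taxa × {A,C,G,T} count table (ambiguities and gaps
excluded; taxa with no countable base are dropped with a warning). Degrees
of freedom follow the classical convention (n_taxa − 1) × 3. RY recoding
maps A/G→R and C/T→Y at selected codon positions (default {3});
ambiguities wholly within the purines map to R, wholly within the
pyrimidines to Y, and codes spanning both to N, so exactly the
purine/pyrimidine signal survives. The transform is idempotent. Recoded
columns are analysed as IUPAC ambiguities under the 4-state model — no
2-state model — which is how the mainstream ML programs ingest R/Y data.

## Tree search and bootstrap

`ml_search` is a multi-start NNI hill climb. Starting trees are
random-addition trees made constraint-compatible by construction: the
(possibly multifurcating) constraint is resolved at random and
unconstrained taxa are inserted on random edges — taxa outside the
constraint cannot break compatibility because compatibility is evaluated
on bipartitions restricted to shared taxa. Candidate moves get a cheap
local branch-length pass (the five branches around the swapped edge); an
accepted move triggers full branch re-optimisation. Constraint-violating
moves are never accepted, ties between equally likely topologies break on
lexicographic Newick order, and the reported log L is the re-scored value
of the returned tree. Nonparametric bootstrap resamples columns at the
original length, re-searches each pseudo-replicate (seeded, starting from
the best tree), and reports per-bipartition percentages; alignments with
no variation are flagged `no_signal` with support 0.

## RELL and the AU test

Per-site log-likelihoods of each candidate (constrained) best tree form a
sites × trees matrix. RELL resamples round(n·r) site indices with
replacement (implemented as multinomial site weights), credits the argmax
tree per replicate and splits ties equally, so proportions always sum
to 1. The AU test runs RELL at scales r ∈ {0.5, …, 1.4} (1.0 always
included), clamps each bootstrap proportion to [1/(2B), 1 − 1/(2B)],
transforms z = Φ⁻¹(1 − BP), and fits z(r) ≈ d√r + c/√r by weighted least
squares with delta-method binomial weights; au = 1 − Φ(d − c), and np is
the untransformed proportion at r = 1. Trees pinned at the clamp on every
scale are reported at the implied bound and flagged. Default B is 10,000
per scale; desk-scale runs (tests, demo) use 1,000. Under an exchangeable
null (two trees, 100 sites, 500 simulations, B = 1,000) the measured
rejection rate at α = 0.05 is ≈ 0.05, inside the [0.02, 0.10] calibration
band the test suite asserts.

## Reconciliation and the twelve scenarios

LCA reconciliation maps each gene-tree node to the species-tree last
common ancestor of its descendant species; a node is a duplication iff it
maps to the same species node as one of its children. Losses are counted
per gene edge as the species nodes skipped between the parent and child
maps (plus the branch shed at the parent itself when the parent is a
duplication), and each loss is located on the species branch that failed
to inherit the copy. Species absent from the alignment are pruned before
counting by default — absence of evidence is not billed as loss; the
simulator, which knows its ground truth, reconciles against the full
species tree. On small cases the LCA map provably attains the minimum
duplication + loss count over all monotone maps, and the tests verify
this against exhaustive enumeration.

The twelve duplication/loss scenarios are encoded as rooted topologies
over seven observed gene lineages (Elopomorpha *rh1-dso*/*rh1-fwo*,
*Hiodon* *rh1-1*/*rh1-2*, the remaining osteoglossomorph *rh1* group,
Clupeocephala *rh1-A*/*rh1-B*): scenario A places three duplications
(lineage-specific, or teleost-stem + two lineage events), scenario B two
(elopomorph-stem or teleost-stem paired with an
osteoglossomorph+clupeocephalan event, or teleost-stem paired with a
clupeocephalan-stem event — B5/B6), scenario C a single teleost-stem
(genome-duplication) event. Within-family variants are the distinct
assignments of observed lineages to duplication products. Each topology
reconciles to its family's duplication count (3/2/1), and B6 — the
scenario the likelihood ranking favours — implies exactly two secondary
losses of the older paralog, on the clupeocephalan stem and in the
non-*Hiodon* osteoglossomorphs. For hypothesis evaluation the lineage
topologies expand to taxon-level constraints by substituting each tag's
taxa as an unresolved clade; outgroup taxa join the root polytomy
unconstrained. The substitution model is re-optimised under every
constraint by default, with a `shared` flag to fit it once and hold it
fixed (used by the long-running recovery experiments; rankings agreed
under both on trial data).

## Parsimony ancestral states

Characters (presence of the intron-bearing pineal *exo-rh1*, presence of
*rh1* introns, intron-less *rh1* copy number 0/1/2) are unordered and
equally weighted by default; `?` is a leaf compatible with every state.
Reconstruction is Sankoff dynamic programming — identical to Fitch
counting for unordered states, exact on multifurcations — with a
root-to-tip second pass giving the full MPR state set per node. Counting
independent gains (e.g. 1→2 copy-number gains inside the Teleostei) uses
a lexicographic two-part edge cost (10⁶ × changes + focal gains), which
yields the minimum number of focal transitions among all
most-parsimonious reconstructions; transitions are attributed to the
branch above the derived node, and a branch is "inside" a clade iff its
child is a strict descendant of the clade root. An ordered-character flag
(linear 0–1–2 costs) exists but is off. The packaged backbone phylogeny
of jawed vertebrates and the character matrix cover the taxa whose states
the survey establishes; uncertain taxa (bichir, sturgeon, bowfin
*exo-rh1*, …) are coded `?`. On this input the copy-number character
needs four changes overall, of which three are independent 1→2 gains
within the Teleostei (eel-like fishes, *Hiodon*, otocephalans), and the
intron character needs exactly one loss.

## Key sites

Spectral-tuning sites 83, 96, 102, 122, 183, 194, 195, 253, 261, 289,
292, 317 (plus site 210, which separates the "deep-sea" and "freshwater"
eel paralogs as V/C) are addressed in bovine rhodopsin numbering. Queries
are globally aligned to the bundled bovine reference (RHO_BOVIN, P02699,
348 aa) with BLOSUM62, gap open −11 / extend −1, taking the first
(deterministically ordered) optimal alignment; gapped columns drop out of
the coordinate map, and a query mapping fewer than half of the positions
in the 83–317 region is flagged unmappable. Paralog comparisons report
per-site residue pairs, symmetric in their arguments; unmapped sites are
listed as indeterminate and excluded from difference counts.

## Synthetic gene families

The generator defines the study conditions. Species trees are ultrametric
with outgroup-to-tip depth 0.45 substitutions/site: a 12-species tree
(2 outgroup chondrichthyans, 4 elopomorphs, 3 osteoglossomorphs,
3 clupeocephalans) and a compact 6-species tree with one representative
per lineage carrier. A scenario's gene tree is built by expanding its
lineage-level topology: each gene lineage is replaced by the species
subtree of its carriers — by default the observed retention pattern
(*rh1-fwo* kept by anguilliforms, *rh1-2* only by *Hiodon*, *rh1-B* only
by otocephalans), or every descendant species under `full_retention`.
Additional losses are supplied as (lineage, clade) pairs rather than
guessed, since the relative timing of losses is not constrained by the
scenarios. Duplication nodes sit at the midpoint of their species-tree
branch (the scenarios specify only the branch); speciation nodes inherit
species-tree times; a configurable rate multiplier (default 1) scales all
gene-tree branches. Duplication and loss counts in the truth record come
from reconciling the constructed tree against the full species tree, so
the bookkeeping is self-consistent by construction.

Sequences evolve site-independently under the GTR+Γ defaults
(exchangeabilities 1.5/4.0/1.0/1.2/6.0/1.0, π = (0.22, 0.28, 0.24, 0.26),
α = 0.5, k = 4, 996 sites — the length of the real data matrix). The root
is a stationary draw, or optionally a back-translated bovine rhodopsin
coding sequence (`rhodopsin_root_sequence`), which keeps simulated
families recognisably rhodopsin-like so the key-site stage works on
simulator output. Compositional heterogeneity is lineage-specific: with a
third-position override, silent sites evolve 3× faster than the gene-wide
average everywhere, and the clupeocephalan copies (the lineage with
conspicuous third-position bias in real fishes) are re-equilibrated at
the override frequencies — their clade root is redrawn from the override
π and their edges evolve under it. A global π change would be invisible
to the across-taxon homogeneity test; the lineage-specific form yields
detection at position 3 in 20/20 replicates and none at positions 1–2.
Tree topology and sequence evolution consume two independent streams of
the user seed, so either stage can be varied alone; identical seeds
reproduce FASTA output byte for byte.

What the simulations do not emulate: indels and alignment error (the real
matrix was aligned manually), retrotransposition mechanics, synteny,
selection or site-specific amino-acid constraints beyond the gamma rates,
and non-stationarity other than the silent-site bias. Passing tests
therefore demonstrate correctness of the inference machinery under the
generating model, not robustness to real-data violations of it.

## Problem sizes

The test-suite and acceptance experiments use: exact oracles at 4–6 taxa
and 18–60 sites; JC closed-form at 4,000–5,000 sites; AU calibration with
500 null simulations of 100 sites at B = 1,000; scenario recovery with 10
seeds × 2,000 sites on the compact species tree with all 12 constrained
searches per seed (shared model parameters); and the demo at 996 sites.
These sizes keep the full chain exact where exactness is claimed and
Monte-Carlo error small relative to the asserted bands.

## Known limitations

No invariant-sites category, partitioned or codon models; no SPR beyond
the NNI neighbourhood (adequate for ≤ 60 taxa with informative data); no
KH/SH tests; no likelihood-based ancestral states; loss counts depend on
the sampled-species convention described above; and the key-site stage
assumes the query is alignable to bovine rhodopsin over the tuning-site
region.
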