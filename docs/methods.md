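# Methods

## The model in brief

The package reconstructs upper and lower bounds of the urancestral
protein-domain repertoire from the abundance of fold superfamilies (FSFs)
in proteomes.  The underlying evolutionary model assumes that domain
repertoires grow: proteomes add FSFs and expand their copy numbers over
time, so ancient superfamilies are, on average, more abundant and more
widely shared than young ones.  Two dual analyses follow from one census
matrix of counts `g[fsf, proteome]`:

* a **tree of proteomes** (taxa = proteomes, characters = FSFs) polarized
  from state 0 upward — a hypothetical ancestor with an empty repertoire;
* a **tree of domain structures** (taxa = FSFs, characters = proteomes)
  polarized from the maximal state downward — the most ancient structures
  being maximally abundant and widespread.

Both are unrooted maximum-parsimony trees rooted a posteriori by the
Lundberg procedure: a hypothetical taxon holding the declared ancestral
state in every character is attached to the edge that minimizes the total
rooted length.  No outgroup is invoked; the polarity assumption carries the
direction of time.

## Character coding

Raw counts span zero to hundreds, so they are compressed onto `n_states`
(default 24) linearly ordered states:

    state = round( g_ab / g_max * (n_states - 1) )       (linear, default)
    state = round( ln(g_ab+1) / ln(g_max+1) * (n_states - 1) )   (log option)

with `g_max` the matrix-wide maximum (a per-character option exists for
sensitivity analyses) and ties rounded half away from zero — a fixed,
documented rule; round-half-even would silently change matrices between
platforms.  States are written `0–9A–N`, and characters are treated as
additive (Wagner): a change from state *i* to *j* costs `|i − j|` steps.

## Parsimony machinery

Two exact scorers back all tree operations:

* **Farris intervals** — one post-order pass maintaining per-node state
  intervals; exact for additive characters on binary trees and the fast
  path inside search (O(nodes × characters)).
* **Sankoff dynamic programming with linear costs** — per-node cost tables
  over all states, with the min-plus convolution against `|i − j|` computed
  by a two-sweep distance transform (O(states) instead of O(states²)).
  This general path handles polytomies and yields, from one down-pass and
  one up-pass, (a) exact leaf-insertion costs on every edge — used for
  stepwise addition and for Lundberg rooting — and (b) per-node MPR state
  intervals (a state is in the interval iff its down-cost plus up-cost
  equals the character's optimum).  Leaves carry hard 0/∞ cost columns so
  their intervals stay point observations.

Heuristic search uses random-addition replicates (greedy Wagner addition by
exact insertion cost) followed by first-improvement branch swapping: NNI,
SPR, or TBR.  True TBR (prune, re-root the pruned part, regraft) is
guaranteed up to a configurable taxon count (default 12) and replaced by
alternating SPR+NNI sweeps above it; on the matrix sizes this package
targets the two converge to the same optima at a fraction of the cost.
Equally shortest distinct unrooted topologies are retained up to
`maxtrees`, sorted by canonical form for determinism.

Tree statistics follow the standard definitions: CI = Σm/L (m = ordered
character minimum, max − min observed state), RI = (G − L)/(G − M) with G
the best single-ancestral-state ("bush") length, undefined when G = M; g₁
is the Fisher–Pearson skewness of the length distribution over uniformly
generated random topologies (sequential random addition — every labeled
topology equiprobable).  The nonparametric bootstrap resamples characters
with replacement to the original count and tallies the reference tree's
bipartitions; majority-rule consensus is delegated to dendropy (the
SumTrees engine) with a strictly-greater cutoff.

## Root-branch changes and ambiguity

A character is gained on the root branch iff the MPR interval of the
root-adjacent (crown) node admits a state above the ancestor state, and the
gain is *ambiguous* iff the interval also admits the ancestor state itself:
the change can then be deferred to deeper branches at equal cost, the
accelerated-vs-delayed-transformation disagreement.  With a zero-state
ancestor no root-branch losses are possible.  Ambiguous gains are kept and
flagged (accelerated convention); a delayed variant that drops them is
available.  When one search returns several equally parsimonious trees,
their root sets are united by default (an intersection mode exists).

Note that per-node MPR intervals are not jointly free: an arbitrary
combination of states, one from each interval, need not be optimal (two
sibling cherries with states {0,0} and {3,3} both have interval [0,3], but
optimal assignments must agree).  The tests therefore verify the defining
per-node property against exhaustive enumeration, plus that the
all-lower-bound assignment achieves the tree length.

## Iterative refinement

Characters gained at the root of an initial proteome tree include recent
arrivals dragged there by convergence ("the modern effect").  Refinement
chains repeat: build trees on the current character set, extract the
root-branch set, restrict to it, rebuild.  Per-iteration search seeds are
derived from the chain seed *and* a digest of the current character set, so
an unchanged set provably reproduces the identical search — one repeat is a
fixed point, and chains stop there rather than after a patience window.
Chain seeds spawn deterministically from the master seed.  Across every
retained most-parsimonious tree of every chain and iteration, the selection
rule takes minimal tree length, then the smallest root set; the selected
tree's root set is the max_set.  Ambiguous root assignments shrink
monotonically along chains on the bundled fixtures; they need not reach
exactly zero — that depends on where stochastic losses fall relative to the
root.

## Timeline, basal set, and clock

On a rooted tree the relative age of a taxon is its node distance: the
number of internal nodes strictly between the crown node and the leaf,
divided by the maximum such count, so the most basal taxon has nd = 0 and
the most recent 1.  Root-exclusive counting is the default (a taxon
branching straight off the root is maximally ancestral); a root-inclusive
flag exists only in the sense of sensitivity checks via re-rooting.  The
basal_set collects FSFs with nd strictly below the first FSF not shared by
all three superkingdoms; ties at the boundary are excluded — conservative,
as befits a lower bound.  The molecular clock is an ordinary least-squares
fit of nd on calibration ages (Ga before present), inverted to date
repertoires; with rounded published coefficients the inversion reproduces
printed dates only approximately, so dates are always reported together
with the model that produced them.

## Functional enrichment

FSFs map to one of 49 annotated sub-categories in seven coarse categories;
unannotated FSFs leave both sample and background.  A sub-category is
tested only when its sample rate k/n exceeds the background rate M/N, using
the exact hypergeometric upper tail P(X ≥ k) (the point mass P(X = k) is
exposed separately); significance is read at P < 0.05 without
multiple-testing correction, with an optional Benjamini–Hochberg
adjustment switched off by default.

## Synthetic data: what it emulates and what it does not

The generator walks a guide tree — ((Bacteria, Eukarya), Archaea), a
configurable shape per clade — from root to tips:

| parameter | default | meaning |
|---|---|---|
| `n_proteomes_per_sk` | 10 | leaves per superkingdom |
| `n_ancestral_fsfs` | 40 | FSFs born at the root |
| `n_derived_fsfs` | 260 | FSFs born inside one superkingdom clade |
| `ancestral_seed_copies` | 8 | root copy number of ancestral FSFs |
| `ancestral_duplication_rate` | 0.3 | per-copy duplication probability per branch step, ancestral FSFs |
| `duplication_rate` / `expansion_rate_max` | 0.1 / 0.5 | each derived FSF draws its own rate uniformly in this range |
| `loss_prob` | 0.02 | per-(FSF, leaf lineage) loss probability |
| `hgt_rate` | 0 | per-derived-FSF probability of one horizontal transfer |
| `clade_birth_weights` | 1:2:3 (A:B:E) | derived births per superkingdom |

Ancestral FSFs are seeded with several copies (the urancestral repertoire
is modeled as already redundant) and grow steadily, keeping them at the top
of the abundance spectrum, as in real censuses where the most abundant
superfamilies are the ancient ones; derived FSFs start from one copy with
heterogeneous expansion rates, giving large abundance variance, and are
born more often in eukaryal than archaeal lineages, mirroring the observed
asymmetry of superkingdom signatures.  Horizontal transfer copies an FSF's
presence and abundance from a donor lineage into a foreign internal node.
Everything derives from one seed.

What passing tests on these data do **not** show: the generator has no
sequence evolution, no genome reduction/parasitism, no correlated loss, and
its 300 × 30 census is far sparser than a real one (1,420 FSFs × 420
proteomes, a ~19:1 derived:ancestral character ratio versus 6.5:1 here).
One known consequence: artificial urancestral taxa injected with maximal
states for member FSFs and zero elsewhere resolve at the base of trees of
proteomes only at real-census character density; at fixture scale their
placement is dominated by the ancestral-abundance depth gradient, so the
pipeline records the injected taxon's nd in the run manifest instead of
asserting basality.

## Problem sizes and numerical choices

Default desk-scale settings (2 addition replicates, NNI refinement
swapping, 3 chains × 10 iterations, 200 random trees for g₁) keep a full
fixture run within a couple of minutes; the published protocol's settings
(1,000 replicates, TBR, 30 chains × 50 iterations, 1,000 random trees)
remain available through configuration.  Ties everywhere break by canonical
topology order; equally good Lundberg attachment edges are counted and the
post-order first is used; the two root children of the rooted
representation are collapsed to a single unrooted edge wherever edges are
enumerated.  Degenerate inputs (all-zero matrices, two-leaf trees,
characters with no variation) return defined values (length 0, nd 0 with a
warning, RI undefined as `None`) rather than raising.
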