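# Methods

## The coalescent model

Gene trees are simulated under the multispecies coalescent (MSC) on a
rooted, ultrametric species tree whose branch lengths are in coalescent
units with pairwise coalescence rate 1 (two lineages in one population
coalesce after an Exp(1) waiting time; *k* lineages at rate k(k−1)/2).
This is the unit convention of summary-coalescent species-tree programs,
so simulated branch lengths are directly comparable to coalescent-unit
branch lengths reported on empirical species trees.  Units are stored as
tree metadata ("coalescent" vs "subs/site") and never inferred from the
numbers.

One reticulation is supported.  The hybrid is a tip of the base tree; at
time `t_hybrid` on its pendant edge each of its (possibly already
partially coalesced) lineages independently chooses the donor path with
probability γ.  Donor-path lineages enter a ghost population in which they
may coalesce among themselves, and join the donor edge (the edge above the
most recent common ancestor of the declared donor clade) at `t_donor`.
Per-lineage independent assignment is the standard network-MSC; γ = 0 and
γ = 1 degenerate exactly to trees (the degenerate cases skip the random
assignment entirely, so γ = 0 is bit-identical to the recipient tree's
simulation).  A single reticulation is a deliberate scope limit: the
hybrid-detection statistics implemented here (D, γ votes, quartet
classification) are all single-event diagnostics.

Closed forms used for validation: for a quartet whose internal branch has
length *t*, the concordant unrooted topology has probability
1 − (2/3)e^(−t) and each alternative (1/3)e^(−t); the simulator is checked
against this at t ∈ {0.1, 0.5, 1, 2} with binomial 3σ bounds at 30,000
loci, and independently against an msprime demography with the same split
times.

## Sequence layer

Sites evolve independently under JC69 (default) or HKY85.  The rate
matrix is built reversible with the given base frequencies, normalised to
one expected substitution per unit time, and exponentiated through its
symmetrised eigendecomposition (computed once per model); a branch of
length *b* coalescent units contributes b·μ expected substitutions/site.
The default μ = 0.01 substitutions/site per coalescent unit keeps
pairwise divergence in the few-percent range typical of conspecific
transcriptome loci (ingroup distances ~2–10%, outgroup ~15–20% under the
default scenarios).  The model requires μ > 0; the zero-divergence limit
is approached with a vanishing μ and yields all-invariant alignments.

## Scenario presets (the synthetic study system)

`ils_only` is a ten-taxon complex in three clades — A1–A3, B1–B3
(((B1,B2),B3) shape), C1–C4 — plus an outgroup OUT.  Within-clade first
coalescences sit at depth 1.0; every internal branch lasts `internal`
coalescent units (default 0.5, giving ~40% discordance per short branch —
widespread ILS); the outgroup attaches 5 units above the ingroup root.
`hybrid` uses the same backbone with the A- and B-stem lengths exposed as
`parental_branch`, and tip B1 receiving γ from the Clade-A stem
(`t_hybrid` = 0.5, `t_donor` = 1.6 by default).  Long parental branches
(the recovery experiments use 3.0) make the parental assignment of each
locus nearly unambiguous; short ones blur it, which is exactly the ILS
bias documented below.

What the generator emulates: locus-to-locus topology heterogeneity from
ILS, a single hybridization event with tunable inheritance, block
structure for jackknifing, and full-occupancy loci of transcriptome-like
divergence.  What it does not emulate: gene-tree estimation error,
alignment error, missing data, intralocus recombination, rate variation
across loci and sites, and continuous migration.  Passing tests therefore
demonstrate correctness of the statistics under the MSC(+1 reticulation)
model, not robustness to empirical noise sources.

## Concordance factors

For each internal (unrooted-sense) branch the four surrounding groups are
the two child clades on one side and the sibling clade plus the remainder
on the other.  A gene tree is decisive when every group has at least one
tip present; decisive trees are classified by which of the three
NNI-related bipartitions they display (restricted to the taxa present),
else paraphyletic.  Percentages are always out of decisive trees;
indecisive trees are excluded from every denominator.  Polytomies
displaying none of the three splits fall into gDFP.  The equal-frequency
test uses χ² = (n₁−n₂)²/(n₁+n₂) on 1 df, as the field's standard
implementation does; an exact binomial alternative is available behind a
flag.  Its type-I error at α = 0.05 is verified to be 0.05 ± 0.02 over
1,000 replicate simulated branches (200 loci each).

## ABBA-BABA

Groups (((P1,P2),P3),O) may have multiple members; each group is
collapsed to its majority state per site, sites with any missing data in
the four groups or a majority tie are skipped, and only sites with
exactly two states across the four collapsed values are considered.  The
jackknife deletes contiguous blocks (default 1000 sites; a trailing block
under half size is dropped) and uses SE² = ((B−1)/B)·Σ(D₍₋b₎ − D̄)²; a
randomized delete-m mode caps the replicate count when a fixed budget is
wanted.  At least `min_blocks` (default 10) informative blocks are
required.

The default role assignment puts the hybrid's species-tree *sister* (B2)
as P1: E[D] = 0 under the null requires P1 and P2 to be sister
populations, and a paraphyletic P1 (e.g. pooling B2 with B3, which
brackets B1) is measurably biased even without gene flow.  Pooled
multi-member parental populations remain fully supported for empirical
use where the user chooses the grouping.

## Inheritance probability

Each gene tree, rooted on the outgroup, votes for the parental population
whose taxa share the smallest clade with the hybrid to the exclusion of
the other parent; γ̂ is the vote share and the CI a seeded percentile
bootstrap over loci (default 1,000 resamples).  The estimator is
method-of-moments, not a network pseudo-likelihood: with parental
branches ≥ 3 coalescent units it recovers γ = 0.3 within [0.25, 0.35]
from 2,000 loci; with short parental branches ILS makes votes noisy and
pulls γ̂ toward 0.5.  That bias is inherent to topology-vote estimators
and is documented rather than corrected.

## Quartet tests and the network distance

Per quartet, the star test is a goodness-of-fit of the three counts to
(⅓,⅓,⅓) on 2 df and the tree test a fit to (p̂,(1−p̂)/2,(1−p̂)/2) with
p̂ = max(n_max/n, ⅓) on 1 df.  Classification at the recommended
operating point: star if p_star > β (0.95), else tree if p_tree ≥ α
(0.01), else network.  Below 30 decisive trees both tests switch to exact
multinomial tails with the same statistic ordering (at desk scale
exactness matters more than asymptotics); below 10 the quartet is flagged
low-count and defaults to star.

The distance aggregation is a declared simplification of the published
NANUQ weighting: a tree quartet contributes its split as 0/1 increments
over its six pairs, a star or network quartet contributes the uniform
expectation 2/3 everywhere.  This preserves the diagnostic contract —
when all quartets are tree-like the matrix is the quartet distance of the
displayed tree and neighbor joining recovers it; a γ = 0.5 hybrid's
distance asymmetry between its two parental clades collapses to about
half the clade-separation scale.  The weighting function is pluggable and
the matrix is exported as a NEXUS DISTANCES block for split-network
software; Neighbor-Net layout itself is out of scope.

## Orthology pruning

The outlier-tip step is an explicit median-ratio filter (drop a tip while
its pendant branch exceeds `factor` × median pendant length, default 10,
never below four tips) — a deliberately simple, auditable stand-in for
signature-based outlier detectors, switchable off.  Same-taxon masking
iterates two collapse moves to a fixed point: a tip whose sister is a
same-taxon tip, and a tip whose parent's sister is a same-taxon tip; the
retained tip is the one with the most unambiguous characters.  The
long-branch cut-off (default 0.6) is interpreted as absolute internal
branch length in substitutions/site.  Maximum inclusion repeatedly
extracts the edge-cut subtree with the most distinct taxa and no
duplicated taxon (tie-breaks: more tips, larger summed character counts,
lexicographically smallest label tuple), with `min_taxa` defaulting to
full occupancy.  The pipeline order (outliers → mask → cut → MI) is
configurable.  The greedy extraction is verified equivalent to an
exhaustive edge-cut search (networkx-based, independent code path) on
1,000 random homolog trees of ≤ 8 tips.

## Site classification

Per column, over non-missing states only: invariant = one distinct state
observed at least twice; parsimony-informative = at least two states each
observed at least twice; variable-uninformative = variable but not
informative; columns with fewer than two non-missing observations go to a
separate all-missing bucket rather than inflating the invariant count.
Ambiguity codes and gaps are both treated as missing (transcriptome
consensus sequences are haploid-like, and keeping one missing category
makes the bookkeeping auditable).  Percentages are reported to one
decimal of the total; exact agreement with other tools on gapped columns
is not claimed, since conventions differ.

## Numerical and design notes

* Coordinates are 0-based half-open internally, 1-based only in printed
  reports (e.g. RAxML-style partition files).
* All randomness flows from explicit integer seeds; the CLI fans a single
  global seed out to per-stage substreams, and pipeline reruns are
  bit-identical (checksummed manifest).
* SE = 0 in the jackknife yields Z = ±∞ (NaN when D = 0 too), flagged
  rather than raised.
* D with zero informative sites returns 0 with a no-informative flag.
* Newick output headers start with `#`; the package's own readers skip
  such comment lines.

## Problem sizes in the checks

The statistical test suite uses 30,000 loci for simulator calibration
(binomial 3σ), 200 replicates of 200 loci × 500 sites for the D null,
1,000 replicate branches of 200 loci for the χ² level, 100 replicates for
γ = 0.3 power, 2,000 loci for γ recovery, and 300 loci for the
quartet-network diagnostics; `scripts/acceptance.py` reports the same
quantities at moderately reduced replicate counts.  These sizes were
chosen so Monte-Carlo error is small against each test's tolerance.

## Known limitations

Single reticulation; no recombination within loci, migration bands or
demographic size changes; gene trees are taken as known (no estimation
error model); the γ estimator is biased toward 0.5 under strong ILS; the
quartet tests are approximations with the same accept/reject semantics as
the specialised asymptotic tests they stand in for.
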