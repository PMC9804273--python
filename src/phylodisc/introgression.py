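"""Patterson's D (ABBA-BABA) with block-jackknife significance, and a
gene-tree-frequency estimator of a hybrid's inheritance probability.

Given four taxon groups in the arrangement (((P1, P2), P3), O), biallelic
sites where P2 and P3 share the derived allele (ABBA) or P1 and P3 share it
(BABA) are expected in equal numbers under ILS alone; Patterson's

    D = (nABBA - nBABA) / (nABBA + nBABA)

quantifies the imbalance, and its standard error is estimated by deleting
contiguous alignment blocks (delete-one block jackknife) so that linkage
within loci is respected.  Z = D/SE is treated as approximately standard
normal.

The inheritance probability gamma of a putative hybrid is estimated by a
topology vote over gene trees: each tree rooted on the outgroup votes for
the parental population whose taxa the hybrid clusters with, and
gamma-hat = votes1 / (votes1 + votes2).  This is a method-of-moments
estimator, not a pseudo-likelihood network search; its bias toward 0.5 when
parental branches are short (ILS noise) is documented and tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import splits
from .core_io import MISSING, Alignment


class InsufficientDataError(ValueError):
    pass


class UndefinedGammaError(ValueError):
    pass


@dataclass
class PatternCounts:
    n_abba: int
    n_baba: int
    n_bbaa: int
    n_considered: int
    n_skipped: int


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    block_size: int
    n_blocks: int
    counts: PatternCounts
    groups: tuple
    no_informative: bool = False


@dataclass
class GammaEstimate:
    gamma_hat: float
    votes_parent1: int
    votes_parent2: int
    abstentions: int
    ci_low: float
    ci_high: float


def _collapse(M: np.ndarray, rows: list[int]):
    """Majority-collapse a group's rows; returns (state, valid) vectors.

    A column is invalid for the group when any member is missing
    (conservative policy for gappy transcriptome alignments) or when the
    majority is tied.
    """
    sub = M[rows]
    valid = ~(sub == MISSING).any(axis=0)
    if len(rows) == 1:
        return sub[0].copy(), valid
    cnt = np.stack([(sub == s).sum(axis=0) for s in range(4)], axis=0)
    top = cnt.max(axis=0)
    tie = (cnt == top).sum(axis=0) > 1
    state = cnt.argmax(axis=0).astype(np.uint8)
    return state, valid & ~tie & (top > 0)


def _site_codes(aln: Alignment, p1, p2, p3, out):
    """Per-column code: 0 skipped, 1 considered-other, 2 ABBA, 3 BABA,
    4 BBAA."""
    groups = [frozenset(p1), frozenset(p2), frozenset(p3), frozenset(out)]
    for i in range(4):
        for j in range(i + 1, 4):
            if groups[i] & groups[j]:
                raise ValueError("P1/P2/P3/outgroup groups must be disjoint")
        if not groups[i]:
            raise ValueError("all four groups must be non-empty")
        missing = groups[i] - set(aln.names)
        if missing:
            raise ValueError(f"taxa {sorted(missing)} not in the alignment")
    idx = [[aln.names.index(t) for t in sorted(g)] for g in groups]
    states, valids = zip(*[_collapse(aln.data, rows) for rows in idx])
    s1, s2, s3, so = states
    ok = valids[0] & valids[1] & valids[2] & valids[3]
    n_states = sum(((np.stack(states) == s).any(axis=0)) for s in range(4))
    biallelic = ok & (n_states == 2)
    codes = np.zeros(aln.n_sites, dtype=np.uint8)
    codes[biallelic] = 1
    abba = biallelic & (s1 == so) & (s2 != so) & (s3 != so)
    baba = biallelic & (s2 == so) & (s1 != so) & (s3 != so)
    bbaa = biallelic & (s3 == so) & (s1 != so) & (s2 != so)
    codes[abba] = 2
    codes[baba] = 3
    codes[bbaa] = 4
    return codes


def count_site_patterns(aln: Alignment, p1, p2, p3, out) -> PatternCounts:
    """Count ABBA/BABA/BBAA site patterns for groups (((P1,P2),P3),O).

    Multi-member groups are collapsed to their majority state; sites with
    any missing data in the four groups, majority ties, or other than
    exactly two states overall are skipped.
    """
    codes = _site_codes(aln, p1, p2, p3, out)
    considered = int((codes >= 1).sum())
    return PatternCounts(
        n_abba=int((codes == 2).sum()),
        n_baba=int((codes == 3).sum()),
        n_bbaa=int((codes == 4).sum()),
        n_considered=considered,
        n_skipped=aln.n_sites - considered,
    )


def d_statistic(counts: PatternCounts) -> float:
    """D = (nABBA - nBABA)/(nABBA + nBABA); 0 when no informative sites."""
    denom = counts.n_abba + counts.n_baba
    if denom == 0:
        return 0.0
    return (counts.n_abba - counts.n_baba) / denom


def _block_counts(codes: np.ndarray, block_size: int):
    """ABBA/BABA totals per contiguous block; a short trailing block is
    dropped when it is under half the block size."""
    n = len(codes)
    n_blocks = n // block_size
    rem = n - n_blocks * block_size
    if rem >= (block_size + 1) // 2:
        n_blocks += 1
    if n_blocks < 2:
        raise InsufficientDataError(
            f"alignment of {n} sites is too short for block size {block_size}")
    block_of = np.minimum(np.arange(n) // block_size, n_blocks - 1)
    used = np.arange(n) < (n_blocks * block_size if rem < (block_size + 1) // 2
                           else n)
    abba = np.bincount(block_of[used & (codes == 2)], minlength=n_blocks)
    baba = np.bincount(block_of[used & (codes == 3)], minlength=n_blocks)
    return abba.astype(float), baba.astype(float)


def block_jackknife(aln: Alignment, groups, block_size: int = 1000,
                    min_blocks: int = 10,
                    n_replicates: int | None = None,
                    seed: int = 0) -> tuple[float, float]:
    """Delete-one-block jackknife standard error and Z for D.

    ``groups`` is the tuple (p1, p2, p3, outgroup) of taxon sets.  By
    default every block is deleted once; passing ``n_replicates`` caps the
    number of deleted blocks at a random (seeded) subset, the randomized
    delete-m reading of a fixed replicate budget.
    """
    p1, p2, p3, out = groups
    codes = _site_codes(aln, p1, p2, p3, out)
    abba_b, baba_b = _block_counts(codes, block_size)
    informative = int(((abba_b + baba_b) > 0).sum())
    if informative < min_blocks:
        raise InsufficientDataError(
            f"only {informative} informative blocks (< {min_blocks})")
    A, B = abba_b.sum(), baba_b.sum()
    n_blocks = len(abba_b)
    if n_replicates is not None and n_replicates < n_blocks:
        rng = np.random.default_rng(seed)
        pick = rng.choice(n_blocks, size=n_replicates, replace=False)
        abba_b, baba_b = abba_b[pick], baba_b[pick]
    loo_num = (A - abba_b) - (B - baba_b)
    loo_den = (A - abba_b) + (B - baba_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_loo = np.where(loo_den > 0, loo_num / np.maximum(loo_den, 1), 0.0)
    B_n = len(d_loo)
    se = math.sqrt((B_n - 1) / B_n * ((d_loo - d_loo.mean()) ** 2).sum())
    d = (A - B) / (A + B) if (A + B) > 0 else 0.0
    z = d / se if se > 0 else (math.inf if d > 0 else
                               -math.inf if d < 0 else math.nan)
    return se, z


def abba_baba(aln: Alignment, p1, p2, p3, out, block_size: int = 1000,
              min_blocks: int = 10,
              n_replicates: int | None = None) -> DStatResult:
    """Full ABBA-BABA test: pattern counts, D, jackknife SE and Z."""
    counts = count_site_patterns(aln, p1, p2, p3, out)
    d = d_statistic(counts)
    no_informative = (counts.n_abba + counts.n_baba) == 0
    se, z = block_jackknife(aln, (p1, p2, p3, out), block_size=block_size,
                            min_blocks=min_blocks, n_replicates=n_replicates)
    codes = _site_codes(aln, p1, p2, p3, out)
    abba_b, _ = _block_counts(codes, block_size)
    return DStatResult(d=d, se=se, z=z, block_size=block_size,
                       n_blocks=len(abba_b), counts=counts,
                       groups=(frozenset(p1), frozenset(p2), frozenset(p3),
                               frozenset(out)),
                       no_informative=no_informative)


# ---------------------------------------------------------------------------
# Inheritance probability
# ---------------------------------------------------------------------------


def _vote(tree, index, hybrid_bit, p1_mask, p2_mask, out_bit) -> int:
    """0 abstain, 1 parent1, 2 parent2, for one gene tree."""
    present, masks = splits.clade_masks(tree, index)
    clades = splits.rooted_clades(masks, present, out_bit)
    both = p1_mask | p2_mask
    for m in clades:
        if m & hybrid_bit and m & both:
            has1 = bool(m & p1_mask)
            has2 = bool(m & p2_mask)
            if has1 and not has2:
                return 1
            if has2 and not has1:
                return 2
            return 0
    return 0


def estimate_gamma(gene_trees, hybrid: str, parent1, parent2, outgroup: str,
                   n_boot: int = 1000, seed: int = 0) -> GammaEstimate:
    """Vote-based inheritance-probability estimate with a bootstrap CI.

    Per gene tree (rooted on the outgroup) the smallest clade containing
    the hybrid and at least one parental taxon decides the vote: parent1
    when it holds no parent2 taxon, parent2 symmetrically, otherwise the
    tree abstains.  The CI is a seeded percentile bootstrap over loci.
    """
    parent1, parent2 = frozenset(parent1), frozenset(parent2)
    if hybrid in parent1 or hybrid in parent2 or (parent1 & parent2):
        raise ValueError("hybrid and the two parental sets must be disjoint")
    if outgroup in parent1 | parent2 | {hybrid}:
        raise ValueError("outgroup must be distinct from hybrid and parents")
    trees = list(gene_trees)
    labels = sorted(parent1 | parent2 | {hybrid, outgroup})
    index = splits.taxon_index(labels)
    hybrid_bit = 1 << index[hybrid]
    out_bit = 1 << index[outgroup]
    p1_mask = sum(1 << index[t] for t in parent1)
    p2_mask = sum(1 << index[t] for t in parent2)
    votes = np.empty(len(trees), dtype=np.int8)
    for i, gt in enumerate(trees):
        tlabels = gt.tip_labels() if callable(getattr(gt, "tip_labels", None)) \
            else list(gt.tip_labels)
        ext = dict(index)
        for lab in tlabels:
            if lab not in ext:
                ext[lab] = len(ext)
        votes[i] = _vote(gt, ext, hybrid_bit, p1_mask, p2_mask, out_bit)
    v1 = int((votes == 1).sum())
    v2 = int((votes == 2).sum())
    if v1 + v2 == 0:
        raise UndefinedGammaError(
            "every gene tree abstained; gamma is undefined")
    gamma_hat = v1 / (v1 + v2)
    rng = np.random.default_rng(seed)
    n = len(votes)
    boots = []
    for _ in range(n_boot):
        vb = votes[rng.integers(0, n, size=n)]
        b1 = int((vb == 1).sum())
        b2 = int((vb == 2).sum())
        if b1 + b2:
            boots.append(b1 / (b1 + b2))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots
              else (math.nan, math.nan))
    return GammaEstimate(gamma_hat=gamma_hat, votes_parent1=v1,
                         votes_parent2=v2,
                         abstentions=int((votes == 0).sum()),
                         ci_low=float(lo), ci_high=float(hi))
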