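"""Gene-tree concordance and discordance factors around species-tree branches.

Every internal branch of a species tree splits the taxa into two sides, and
the two branches adjacent on each side split those into four groups
(A1, A2 | B1, B2).  A gene tree containing at least one taxon from each
group is *decisive* for the branch and falls into exactly one category:

* concordant — it displays the species-tree split (A1+A2 | B1+B2), counted
  toward gCF;
* the first or second nearest-neighbour-interchange alternative
  (A1+B1 | A2+B2 or A1+B2 | A2+B1), counted toward gDF1 / gDF2;
* paraphyletic — none of the three resolutions is displayed, counted toward
  gDFP.

Under ILS alone the two alternative resolutions are expected in equal
frequency, which is tested per branch with a chi-squared test on the
(n_df1, n_df2) counts; a significant imbalance is a classic gene-flow
signal.  Percentages are always reported out of the decisive trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from . import splits
from .core_io import Tree


@dataclass
class Chi2Result:
    statistic: float
    p_value: float
    no_discordance: bool = False


def chi2_equal_discordance(n_df1: int, n_df2: int,
                           exact: bool = False) -> Chi2Result:
    """Test H0: discordant gene trees split evenly between the two NNI
    alternatives.

    The statistic is (n1-n2)^2/(n1+n2) on 1 degree of freedom; ``exact``
    switches to a two-sided binomial test with the same null.
    """
    if n_df1 < 0 or n_df2 < 0:
        raise ValueError("counts must be non-negative")
    n = n_df1 + n_df2
    if n == 0:
        return Chi2Result(0.0, 1.0, no_discordance=True)
    stat = (n_df1 - n_df2) ** 2 / n
    if exact:
        p = float(stats.binomtest(n_df1, n, 0.5).pvalue)
    else:
        p = float(stats.chi2.sf(stat, df=1))
    return Chi2Result(float(stat), p)


@dataclass
class BranchConcordance:
    """Counts, percentages and the equal-frequency test for one branch."""

    branch_id: str
    groups: tuple[frozenset, frozenset, frozenset, frozenset]
    n_concordant: int
    n_df1: int
    n_df2: int
    n_paraphyletic: int
    n_decisive: int
    chi2: Chi2Result

    @property
    def gCF(self) -> float:
        return 100.0 * self.n_concordant / self.n_decisive if self.n_decisive else math.nan

    @property
    def gDF1(self) -> float:
        return 100.0 * self.n_df1 / self.n_decisive if self.n_decisive else math.nan

    @property
    def gDF2(self) -> float:
        return 100.0 * self.n_df2 / self.n_decisive if self.n_decisive else math.nan

    @property
    def gDFP(self) -> float:
        return 100.0 * self.n_paraphyletic / self.n_decisive if self.n_decisive else math.nan


def _clade(nd) -> frozenset:
    return frozenset(l.taxon.label for l in nd.leaf_iter())


def internal_branches(species_tree: Tree) -> list[tuple[str, tuple]]:
    """Enumerate internal (unrooted-sense) branches with their four
    surrounding taxon groups.

    Each entry is ``(branch_id, (A1, A2, B1, B2))`` where the branch splits
    the taxa into A1+A2 versus B1+B2.  Branch ids name the sorted child-side
    clade.  When the root is a bifurcation the single unrooted branch its
    two edges form is reported once.
    """
    dtree = species_tree.dtree
    all_taxa = frozenset(species_tree.tip_labels)
    root = dtree.seed_node
    root_children = root.child_nodes()
    out = []
    seen_root_edge = False
    for v in dtree.preorder_internal_node_iter():
        if v is root:
            continue
        cv = _clade(v)
        if len(cv) < 2 or len(all_taxa - cv) < 2:
            continue
        kids = v.child_nodes()
        a1 = _clade(kids[0])
        a2 = frozenset().union(*[_clade(k) for k in kids[1:]])
        p = v.parent_node
        sibs = [c for c in p.child_nodes() if c is not v]
        if p is root and len(root_children) == 2:
            w = sibs[0]
            if w.is_leaf():
                continue  # unrooted endpoint is a tip: pendant branch
            if seen_root_edge:
                continue  # same unrooted branch as the other root child
            seen_root_edge = True
            wk = w.child_nodes()
            b1 = _clade(wk[0])
            b2 = frozenset().union(*[_clade(k) for k in wk[1:]])
        elif p is root:
            b1 = _clade(sibs[0])
            b2 = frozenset().union(*[_clade(s) for s in sibs[1:]])
        else:
            b1 = frozenset().union(*[_clade(s) for s in sibs])
            b2 = all_taxa - _clade(p)
        if not (b1 and b2):
            continue
        bid = "{" + ",".join(sorted(cv)) + "}"
        out.append((bid, (a1, a2, b1, b2)))
    return out


def branch_groups(species_tree: Tree, branch) -> tuple:
    """The four taxon groups around one internal branch.

    ``branch`` may be a branch id string (as produced by
    :func:`internal_branches`) or a set of taxa naming the child-side
    clade.  Pendant branches raise ``ValueError``.
    """
    table = internal_branches(species_tree)
    if isinstance(branch, (set, frozenset)):
        branch = "{" + ",".join(sorted(branch)) + "}"
    for bid, groups in table:
        if bid == branch:
            return groups
    raise ValueError(f"{branch!r} is not an internal branch of the species tree")


def classify_gene_tree(gene_tree, groups) -> str:
    """Classify one gene tree against a branch's four groups.

    Returns one of ``concordant``, ``df1``, ``df2``, ``paraphyletic`` or
    ``indecisive``.  Gene trees with duplicate taxa are rejected: the
    concordance analysis requires one-to-one orthologs.
    """
    a1, a2, b1, b2 = (frozenset(g) for g in groups)
    index = splits.taxon_index(sorted(a1 | a2 | b1 | b2))
    labels = gene_tree.tip_labels() if callable(getattr(gene_tree, "tip_labels", None)) \
        else list(gene_tree.tip_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("gene tree has duplicate taxa; orthologs required")
    masks = _group_masks((a1, a2, b1, b2), index)
    present, tree_masks = splits.clade_masks(
        gene_tree, _extended_index(index, labels))
    present &= (1 << len(index)) - 1
    return _classify_masks(tree_masks, present, masks)


def _extended_index(index: dict, labels: Iterable[str]) -> dict:
    """Taxa outside the four groups get high bits so they never collide."""
    ext = dict(index)
    nxt = len(index)
    for lab in labels:
        if lab not in ext:
            ext[lab] = nxt
            nxt += 1
    return ext


def _group_masks(groups, index) -> tuple[int, int, int, int]:
    out = []
    for g in groups:
        m = 0
        for t in g:
            m |= 1 << index[t]
        out.append(m)
    return tuple(out)


def _classify_masks(tree_masks: Sequence[int], present: int,
                    gmasks: tuple[int, int, int, int]) -> str:
    g1, g2, g3, g4 = gmasks
    if not (present & g1 and present & g2 and present & g3 and present & g4):
        return "indecisive"
    if splits.split_present(tree_masks, present, g1 | g2):
        return "concordant"
    if splits.split_present(tree_masks, present, g1 | g3):
        return "df1"
    if splits.split_present(tree_masks, present, g1 | g4):
        return "df2"
    return "paraphyletic"


def concordance_table(species_tree: Tree, gene_trees,
                      exact: bool = False) -> list[BranchConcordance]:
    """One :class:`BranchConcordance` record per internal species-tree
    branch, tallied over all gene trees."""
    trees = list(gene_trees)
    if not trees:
        raise ValueError("need at least one gene tree")
    branches = internal_branches(species_tree)
    species_taxa = sorted(species_tree.tip_labels)
    index = splits.taxon_index(species_taxa)
    nbits = len(index)
    branch_masks = [(bid, groups, _group_masks(groups, index))
                    for bid, groups in branches]
    tallies = {bid: {"concordant": 0, "df1": 0, "df2": 0, "paraphyletic": 0}
               for bid, _, _ in branch_masks}
    for gt in trees:
        labels = gt.tip_labels() if callable(getattr(gt, "tip_labels", None)) \
            else list(gt.tip_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("gene tree has duplicate taxa; orthologs required")
        present, masks = splits.clade_masks(gt, _extended_index(index, labels))
        present &= (1 << nbits) - 1
        for bid, _, gmasks in branch_masks:
            cat = _classify_masks(masks, present, gmasks)
            if cat != "indecisive":
                tallies[bid][cat] += 1
    out = []
    for bid, groups, _ in branch_masks:
        t = tallies[bid]
        n_dec = sum(t.values())
        out.append(BranchConcordance(
            branch_id=bid, groups=groups,
            n_concordant=t["concordant"], n_df1=t["df1"], n_df2=t["df2"],
            n_paraphyletic=t["paraphyletic"], n_decisive=n_dec,
            chi2=chi2_equal_discordance(t["df1"], t["df2"], exact=exact)))
    return out


def to_dataframe(records: Sequence[BranchConcordance]):
    import pandas as pd

    rows = []
    for r in records:
        a1, a2, b1, b2 = (";".join(sorted(g)) for g in r.groups)
        rows.append({
            "branch": r.branch_id, "A1": a1, "A2": a2, "B1": b1, "B2": b2,
            "n_concordant": r.n_concordant, "n_df1": r.n_df1,
            "n_df2": r.n_df2, "n_paraphyletic": r.n_paraphyletic,
            "n_decisive": r.n_decisive,
            "gCF": round(r.gCF, 2), "gDF1": round(r.gDF1, 2),
            "gDF2": round(r.gDF2, 2), "gDFP": round(r.gDFP, 2),
            "chi2": round(r.chi2.statistic, 4), "p": r.chi2.p_value,
        })
    return pd.DataFrame(rows)


def annotated_newick(species_tree: Tree,
                     records: Sequence[BranchConcordance]) -> str:
    """Species tree with ``gCF/gDF1/gDF2/gDFP`` internal labels (the
    pie-chart data in text form)."""
    by_clade = {r.branch_id: r for r in records}
    tree = species_tree.copy()
    for nd in tree.dtree.preorder_internal_node_iter():
        if nd is tree.dtree.seed_node:
            continue
        bid = "{" + ",".join(sorted(_clade(nd))) + "}"
        r = by_clade.get(bid)
        if r is not None and r.n_decisive:
            nd.label = (f"{r.gCF:.1f}/{r.gDF1:.1f}/"
                        f"{r.gDF2:.1f}/{r.gDFP:.1f}")
    return tree.newick()
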