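"""Tree-based orthology decomposition of homolog trees.

Multi-copy homolog trees mix orthologs and paralogs.  The decomposition
applied here follows the classic phylogenomic tree-pruning recipe:

1. remove outlier long pendant branches (an explicit median-ratio filter:
   a tip is dropped while its pendant branch exceeds ``factor`` times the
   median pendant length, never reducing the tree below four tips);
2. mask mono- and paraphyletic tips belonging to the same strain, keeping
   the tip with the most unambiguous characters in its trimmed alignment;
3. cut aberrantly long internal branches (absolute substitutions/site
   cut-off), splitting the tree into components;
4. extract one-to-one orthologs by maximum inclusion (MI): repeatedly take
   the edge-cut subtree covering the most distinct taxa without duplicating
   any, until fewer than ``min_taxa`` taxa remain.

Alignment-side helpers (orthogroup occupancy filtering and minimum-column-
occupancy trimming) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core_io import Alignment, EmptyAlignmentWarning, Tree


@dataclass
class PruningReport:
    """Audit trail for one homolog tree."""

    tree_id: str
    n_input_tips: int
    outliers_removed: list[str] = field(default_factory=list)
    tips_masked: list[str] = field(default_factory=list)
    n_components: int = 1
    orthologs_extracted: int = 0
    ortholog_sizes: list[int] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "tree": self.tree_id,
            "n_input_tips": self.n_input_tips,
            "outliers_removed": ";".join(self.outliers_removed),
            "tips_masked": ";".join(self.tips_masked),
            "n_components": self.n_components,
            "orthologs_extracted": self.orthologs_extracted,
            "ortholog_sizes": ";".join(map(str, self.ortholog_sizes)),
        }


def filter_orthogroups(table: pd.DataFrame, required_taxa) -> list:
    """Orthogroup ids whose taxon set covers ``required_taxa``, in input
    order.

    ``table`` needs columns ``orthogroup`` and ``taxon`` (the per-sequence
    rows of an orthogroup membership table).
    """
    required = set(required_taxa)
    if not required:
        raise ValueError("required_taxa must be non-empty")
    if table.empty:
        return []
    cover = table.groupby("orthogroup", sort=False)["taxon"].agg(set)
    return [og for og, taxa in cover.items() if required <= taxa]


# ---------------------------------------------------------------------------
# Tree surgery helpers
# ---------------------------------------------------------------------------


def _leaves(dtree) -> list:
    return list(dtree.leaf_node_iter())


def _label(nd) -> str:
    return nd.taxon.label


def _drop_leaf(dtree, leaf) -> None:
    parent = leaf.parent_node
    parent.remove_child(leaf)
    dtree.suppress_unifurcations()


def remove_outlier_tips(tree: Tree, factor: float = 10.0
                        ) -> tuple[Tree, list[str]]:
    """Iteratively drop tips whose pendant branch exceeds ``factor`` times
    the median pendant length; re-evaluated after each removal and never
    taken below four tips."""
    work = tree.copy()
    removed: list[str] = []
    while True:
        leaves = _leaves(work.dtree)
        if len(leaves) <= 4:
            break
        lengths = []
        for lf in leaves:
            if lf.edge.length is None:
                raise ValueError(
                    f"tip {_label(lf)!r} has no branch length; outlier "
                    "filtering needs pendant lengths")
            lengths.append(lf.edge.length)
        med = float(np.median(lengths))
        if med <= 0:
            break
        worst = max(leaves, key=lambda lf: lf.edge.length)
        if worst.edge.length <= factor * med:
            break
        removed.append(_label(worst))
        _drop_leaf(work.dtree, worst)
    return work, removed


def mask_same_taxon_tips(tree: Tree, char_counts: Mapping[str, int],
                         taxon_of: Mapping[str, str] | None = None
                         ) -> tuple[Tree, list[str]]:
    """Collapse mono- and paraphyletic same-taxon tips to the best-covered
    tip.

    Two collapse moves are iterated to a fixed point: a tip whose *sister*
    is a same-taxon tip (monophyly), and a tip whose *parent's sister* is a
    same-taxon tip (paraphyly — this is what reduces a same-taxon ladder to
    its single best tip).  The retained tip of each pair is the one with
    the larger unambiguous-character count (ties: lexicographically
    smaller label).  Tips of different taxa separated by other taxa are
    never touched.
    """
    if not tree.homolog:
        raise ValueError("masking applies to homolog trees")
    taxon_of = taxon_of or {}

    def taxon(lab: str) -> str:
        return taxon_of.get(lab, lab)

    def count(lab: str) -> int:
        if lab not in char_counts:
            raise ValueError(f"tip {lab!r} has no character count")
        return int(char_counts[lab])

    work = tree.copy()
    masked: list[str] = []

    def better(x, y):
        """Return (keep, drop): larger count wins, smaller label on ties."""
        lx, ly = _label(x), _label(y)
        cx, cy = count(lx), count(ly)
        if cx != cy:
            return (x, y) if cx > cy else (y, x)
        return (x, y) if lx <= ly else (y, x)

    changed = True
    while changed:
        changed = False
        for lf in _leaves(work.dtree):
            parent = lf.parent_node
            if parent is None:
                continue
            # monophyly: same-taxon sister tip
            for sib in parent.child_nodes():
                if sib is not lf and sib.is_leaf() and \
                        taxon(_label(sib)) == taxon(_label(lf)):
                    _, drop = better(lf, sib)
                    masked.append(_label(drop))
                    _drop_leaf(work.dtree, drop)
                    changed = True
                    break
            if changed:
                break
            # paraphyly: same-taxon tip one node up (parent's sister)
            grand = parent.parent_node
            if grand is None:
                continue
            for aunt in grand.child_nodes():
                if aunt is not parent and aunt.is_leaf() and \
                        taxon(_label(aunt)) == taxon(_label(lf)):
                    _, drop = better(lf, aunt)
                    masked.append(_label(drop))
                    _drop_leaf(work.dtree, drop)
                    changed = True
                    break
            if changed:
                break
    return work, masked


def cut_long_internal_branches(tree: Tree, cutoff: float,
                               min_tips: int = 1) -> list[Tree]:
    """Split the tree on every internal branch longer than ``cutoff``.

    Components with fewer than ``min_tips`` tips are discarded.  Branches
    without a stored length are treated as not long.
    """
    pieces: list[Tree] = []

    def rec(t: Tree):
        dtree = t.dtree
        for nd in dtree.preorder_internal_node_iter():
            if nd is dtree.seed_node:
                continue
            if not nd.is_internal():
                continue
            bl = nd.edge.length
            if bl is not None and bl > cutoff:
                sub_leaves = [l.taxon for l in nd.leaf_iter()]
                sub = dtree.extract_tree_with_taxa(taxa=sub_leaves)
                rest_leaves = [l.taxon for l in dtree.leaf_node_iter()
                               if l.taxon not in set(sub_leaves)]
                rest = dtree.extract_tree_with_taxa(taxa=rest_leaves)
                rec(Tree(sub, units=t.units, homolog=t.homolog))
                rec(Tree(rest, units=t.units, homolog=t.homolog))
                return
        pieces.append(t)

    rec(tree.copy())
    return [p for p in pieces if p.n_tips >= min_tips]


# ---------------------------------------------------------------------------
# Maximum inclusion
# ---------------------------------------------------------------------------


def _candidate_tipsets(dtree) -> list[frozenset]:
    """Tip-node sets of every single-edge-cut component (both sides of each
    edge) plus the whole tree."""
    leaves = frozenset(id(l) for l in dtree.leaf_node_iter())
    below: dict[int, frozenset] = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([id(nd)])
        else:
            s = frozenset()
            for ch in nd.child_nodes():
                s |= below[id(ch)]
            below[id(nd)] = s
    cands = {leaves}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        s = below[id(nd)]
        cands.add(s)
        cands.add(leaves - s)
    return [c for c in cands if c]


def _mi_key(tip_nodes, taxon, char_counts):
    """Minimisation key: most taxa, then most tips, then most summed
    characters, then lexicographically smallest sorted label tuple."""
    labels = sorted(_label(nd) for nd in tip_nodes)
    taxa = {taxon(l) for l in labels}
    chars = sum(int(char_counts.get(l, 0)) for l in labels)
    return (-len(taxa), -len(labels), -chars, tuple(labels))


def extract_mi_orthologs(tree: Tree, cutoff: float = 0.6,
                         min_taxa: int | None = None,
                         char_counts: Mapping[str, int] | None = None,
                         taxon_of: Mapping[str, str] | None = None
                         ) -> list[Tree]:
    """Maximum-inclusion extraction of one-to-one ortholog subtrees.

    The tree is first split on internal branches longer than ``cutoff``
    (deep paralog separation), then within each component the edge-cut
    subtree with the most distinct taxa and no duplicated taxon is
    repeatedly extracted and removed.  ``min_taxa`` defaults to the number
    of distinct taxa in the input (full occupancy).  Tie-breaks: more tips,
    larger summed character counts, lexicographically smallest tip label.
    """
    taxon_of = taxon_of or {}
    char_counts = char_counts or {}

    def taxon(lab: str) -> str:
        return taxon_of.get(lab, lab)

    if min_taxa is None:
        min_taxa = len({taxon(l) for l in tree.tip_labels})
    components = cut_long_internal_branches(tree, cutoff, min_tips=1)
    orthologs: list[Tree] = []
    for comp in components:
        work = comp.copy()
        while True:
            labels = work.tip_labels
            if len({taxon(l) for l in labels}) < min_taxa:
                break
            node_by_id = {id(nd): nd for nd in work.dtree.leaf_node_iter()}
            best, best_key = None, None
            for cand in _candidate_tipsets(work.dtree):
                tips = [node_by_id[i] for i in cand]
                taxa = [taxon(_label(nd)) for nd in tips]
                if len(set(taxa)) != len(taxa):
                    continue
                key = _mi_key(tips, taxon, char_counts)
                if best_key is None or key < best_key:
                    best, best_key = tips, key
            if best is None or len(best) < min_taxa:
                break
            chosen = [nd.taxon for nd in best]
            sub = work.dtree.extract_tree_with_taxa(taxa=chosen)
            orthologs.append(Tree(sub, units=work.units, homolog=False))
            if len(best) == len(labels):
                break
            rest = [l.taxon for l in work.dtree.leaf_node_iter()
                    if l.taxon not in set(chosen)]
            work = Tree(work.dtree.extract_tree_with_taxa(taxa=rest),
                        units=work.units, homolog=True)
    return orthologs


# ---------------------------------------------------------------------------
# Alignment trimming and the whole-tree pipeline
# ---------------------------------------------------------------------------


def trim_columns(aln: Alignment, min_occupancy: float = 0.2) -> Alignment:
    """Drop columns whose non-missing fraction is below ``min_occupancy``
    (a column at exactly the threshold is kept)."""
    if not 0 < min_occupancy <= 1:
        raise ValueError("min_occupancy must be in (0, 1]")
    occ = (aln.data != 4).mean(axis=0)
    keep = occ >= min_occupancy - 1e-12
    out = aln.subset_columns(keep)
    if out.n_sites == 0:
        warnings.warn("column-occupancy trimming removed every column",
                      EmptyAlignmentWarning)
    return out


def prune_homolog_tree(tree: Tree, char_counts: Mapping[str, int],
                       taxon_of: Mapping[str, str] | None = None,
                       outlier_factor: float | None = 10.0,
                       cutoff: float = 0.6,
                       min_taxa: int | None = None,
                       tree_id: str = "tree"
                       ) -> tuple[list[Tree], PruningReport]:
    """Outliers → masking → long-branch cutting → MI, with an audit trail.

    ``outlier_factor=None`` switches the outlier stand-in filter off.
    """
    report = PruningReport(tree_id=tree_id, n_input_tips=tree.n_tips)
    work = tree
    if outlier_factor is not None:
        work, removed = remove_outlier_tips(work, factor=outlier_factor)
        report.outliers_removed = removed
    work, masked = mask_same_taxon_tips(work, char_counts, taxon_of=taxon_of)
    report.tips_masked = masked
    report.n_components = len(
        cut_long_internal_branches(work, cutoff, min_tips=1))
    orthologs = extract_mi_orthologs(
        work, cutoff=cutoff, min_taxa=min_taxa, char_counts=char_counts,
        taxon_of=taxon_of)
    report.orthologs_extracted = len(orthologs)
    report.ortholog_sizes = [t.n_tips for t in orthologs]
    return orthologs, report


def reports_to_frame(reports: Sequence[PruningReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
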