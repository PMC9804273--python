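"""Bitmask split/clade utilities shared by the discordance statistics.

Gene trees arrive either as :class:`phylodisc.core_io.Tree` (dendropy-backed,
parsed from Newick) or as the simulator's lightweight ``SimTree``; both are
reduced here to integer bitmasks over a fixed taxon index, which is the
representation every downstream counting loop runs on.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import core_io


def taxon_index(labels: Sequence[str]) -> dict[str, int]:
    """Stable label → bit position map (input order)."""
    idx = {}
    for lab in labels:
        if lab not in idx:
            idx[lab] = len(idx)
    return idx


def clade_masks(tree, index: Mapping[str, int]) -> tuple[int, list[int]]:
    """Return ``(present_mask, masks)`` for a tree.

    ``present_mask`` has a bit set for every tip present in the tree;
    ``masks`` holds one bitmask per node (tips included), i.e. the clade
    below each node under the tree's stored rooting.  Tips not in ``index``
    raise ``KeyError``.
    """
    if hasattr(tree, "clade_masks"):  # simulator trees
        return tree.clade_masks(index)
    if isinstance(tree, core_io.Tree):
        dtree = tree.dtree
    else:
        dtree = tree
    masks = []
    node_mask: dict[int, int] = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            m = 1 << index[nd.taxon.label]
        else:
            m = 0
            for ch in nd.child_nodes():
                m |= node_mask[id(ch)]
        node_mask[id(nd)] = m
        masks.append(m)
    present = masks[-1] if masks else 0
    return present, masks


def split_present(masks: Sequence[int], present: int, side: int) -> bool:
    """Is the unrooted bipartition ``side | (present \\ side)`` displayed?

    ``side`` is taken modulo restriction to ``present`` (taxa absent from
    the gene tree are ignored).  Trivial splits (either side empty) return
    False.
    """
    s = side & present
    t = present & ~s
    if s == 0 or t == 0:
        return False
    for m in masks:
        mp = m & present
        if mp == s or mp == t:
            return True
    return False


def rooted_clades(masks: Sequence[int], present: int, outgroup_bit: int) -> list[int]:
    """Clades of the tree re-rooted on the outgroup, as bitmasks.

    Each stored clade is canonicalised to the side *not* containing the
    outgroup bit, which is exactly the clade set of the outgroup-rooted
    tree; sorted by size so callers can walk from the smallest enclosing
    clade outward.
    """
    out = set()
    for m in masks:
        mp = m & present
        if mp & outgroup_bit:
            mp = present & ~mp
        if mp:
            out.add(mp)
    return sorted(out, key=lambda m: m.bit_count())


def unrooted_split_set(tree, index: Mapping[str, int]) -> frozenset[int]:
    """Canonical non-trivial splits of a tree (topology fingerprint).

    Each split is represented by the side not containing bit 0 of the
    present taxa, so identical unrooted topologies compare equal regardless
    of rooting.
    """
    present, masks = clade_masks(tree, index)
    anchor = present & -present  # lowest set bit
    out = set()
    for m in masks:
        mp = m & present
        if mp & anchor:
            mp = present & ~mp
        if mp.bit_count() >= 2 and (present & ~mp).bit_count() >= 2:
            out.add(mp)
    return frozenset(out)
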