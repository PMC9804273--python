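"""Shared fixtures and independent oracles for the test suite.

Oracles deliberately use different code paths from the implementation:
networkx connected components for maximum-inclusion search, dendropy
bipartition encoding for split/quartet restriction, msprime for the
coalescent process, and closed-form expectations where they exist.
"""

from __future__ import annotations

import random
from itertools import combinations

import dendropy
import numpy as np
import pytest

from phylodisc import core_io, msc_sim
from phylodisc.core_io import Tree, read_newick


# ---------------------------------------------------------------------------
# Random tree / alignment generators
# ---------------------------------------------------------------------------


def random_tree_newick(rng: random.Random, n_tips: int,
                       max_bl: float = 2.0) -> str:
    """Random binary topology with random branch lengths via sequential
    joining (not via the package's simulator)."""
    nodes = [f"t{i}" for i in range(1, n_tips + 1)]
    parts = [f"{n}:{rng.uniform(0.01, max_bl):.4f}" for n in nodes]
    while len(parts) > 2:
        i = rng.randrange(len(parts))
        a = parts.pop(i)
        j = rng.randrange(len(parts))
        b = parts.pop(j)
        parts.append(f"({a},{b}):{rng.uniform(0.01, max_bl):.4f}")
    return f"({parts[0]},{parts[1]});"


def random_homolog_newick(rng: random.Random, taxa: list[str],
                          n_tips: int) -> tuple[str, dict, dict]:
    """Random homolog tree: tips are sequence ids mapped onto ``taxa``
    (with repeats), plus per-sequence character counts."""
    seq_ids = [f"s{i}" for i in range(1, n_tips + 1)]
    taxon_of = {s: rng.choice(taxa) for s in seq_ids}
    char_counts = {s: rng.randrange(100, 1000) for s in seq_ids}
    parts = [f"{s}:{rng.uniform(0.01, 0.5):.4f}" for s in seq_ids]
    while len(parts) > 2:
        a = parts.pop(rng.randrange(len(parts)))
        b = parts.pop(rng.randrange(len(parts)))
        parts.append(f"({a},{b}):{rng.uniform(0.01, 0.5):.4f}")
    nwk = f"({parts[0]},{parts[1]});"
    return nwk, taxon_of, char_counts


def graft_paralogs(gt: msc_sim.SimTree, rng: random.Random,
                   p_dup: float = 0.3) -> tuple[str, dict, dict]:
    """Turn an ortholog gene tree into a homolog tree by attaching extra
    same-taxon copies as close sisters of random tips."""
    counter = {}
    taxon_of, char_counts = {}, {}

    def seq_id(taxon: str) -> str:
        counter[taxon] = counter.get(taxon, 0) + 1
        sid = f"{taxon}x{counter[taxon]}"
        taxon_of[sid] = taxon
        char_counts[sid] = rng.randrange(100, 1000)
        return sid

    def rec(i: int, parent_time: float) -> str:
        bl = parent_time - gt.times[i]
        if not gt.children[i]:
            sid = seq_id(gt.labels[i])
            if rng.random() < p_dup:
                dup = seq_id(gt.labels[i])
                eps = min(bl / 2, 0.01)
                return (f"({sid}:{eps:.6f},{dup}:{eps:.6f})"
                        f":{bl - eps:.6f}")
            return f"{sid}:{bl:.6f}"
        inner = ",".join(rec(c, gt.times[i]) for c in gt.children[i])
        return f"({inner}):{bl:.6f}"

    inner = ",".join(rec(c, gt.times[gt.root]) for c in gt.children[gt.root])
    return f"({inner});", taxon_of, char_counts


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def mi_oracle(tree: Tree, cutoff: float, min_taxa: int,
              taxon_of: dict, char_counts: dict) -> list[frozenset]:
    """Exhaustive maximum-inclusion over networkx edge-cut components;
    mirrors the documented greedy contract with brute-force enumeration."""
    import networkx as nx

    g = nx.Graph()
    leaf_label = {}
    dtree = tree.dtree
    for nd in dtree.preorder_node_iter():
        g.add_node(id(nd))
        if nd.is_leaf():
            leaf_label[id(nd)] = nd.taxon.label
        for ch in nd.child_nodes():
            internal_child = ch.is_internal() and ch is not dtree.seed_node
            g.add_edge(id(nd), id(ch),
                       length=ch.edge.length or 0.0,
                       long=internal_child and (ch.edge.length or 0.0) > cutoff)

    def taxon(lab):
        return taxon_of.get(lab, lab)

    g.remove_edges_from([(u, v) for u, v, d in g.edges(data=True) if d["long"]])
    results = []
    for comp_nodes in list(nx.connected_components(g)):
        sub = g.subgraph(comp_nodes).copy()
        while True:
            leaves = {n for n in sub if n in leaf_label}
            if len({taxon(leaf_label[n]) for n in leaves}) < min_taxa:
                break
            cands = [frozenset(leaves)]
            for u, v in list(sub.edges()):
                s2 = sub.copy()
                s2.remove_edge(u, v)
                for cc in nx.connected_components(s2):
                    cands.append(frozenset(n for n in cc if n in leaf_label))
            best = None
            for cand in cands:
                if not cand:
                    continue
                labs = sorted(leaf_label[n] for n in cand)
                taxa = [taxon(l) for l in labs]
                if len(set(taxa)) != len(taxa):
                    continue
                key = (-len(set(taxa)), -len(labs),
                       -sum(char_counts.get(l, 0) for l in labs),
                       tuple(labs))
                if best is None or key < best[0]:
                    best = (key, cand, labs)
            if best is None or len(best[2]) < min_taxa:
                break
            results.append(frozenset(best[2]))
            sub.remove_nodes_from(best[1])
            if sub.number_of_nodes() == 0:
                break
    return results


def quartet_restriction_oracle(trees: list[Tree], taxa: list[str]) -> dict:
    """Per-quartet topology counts by literally restricting each tree with
    dendropy and reading off the induced split."""
    counts = {}
    for q in combinations(sorted(taxa), 4):
        counts[q] = [0, 0, 0]
        for t in trees:
            labels = set(t.tip_labels)
            if not set(q) <= labels:
                continue
            d = t.dtree.clone(depth=1)
            d.retain_taxa_with_labels(list(q))
            topo = _induced_quartet(d, q)
            if topo is not None:
                counts[q][topo] += 1
    return counts


def _induced_quartet(dtree, q) -> int | None:
    q = list(q)
    for nd in dtree.preorder_node_iter():
        leaves = {l.taxon.label for l in nd.leaf_iter()}
        if len(leaves) == 2 and leaves < set(q):
            pair = tuple(sorted(q.index(x) for x in leaves))
            return {(0, 1): 0, (2, 3): 0, (0, 2): 1, (1, 3): 1,
                    (0, 3): 2, (1, 2): 2}[pair]
    return None


def concordance_category_oracle(gt: Tree, groups) -> str:
    """Brute-force category via dendropy bipartition enumeration."""
    a1, a2, b1, b2 = (frozenset(g) for g in groups)
    present = set(gt.tip_labels) & (a1 | a2 | b1 | b2)
    if any(not (g & present) for g in (a1, a2, b1, b2)):
        return "indecisive"
    d = gt.dtree.clone(depth=1)
    d.is_rooted = False
    d.encode_bipartitions()
    sides = []
    all_taxa = frozenset(l.taxon.label for l in d.leaf_node_iter())
    for edge in d.preorder_edge_iter():
        if edge.head_node is None:
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        sides.append(side)
        sides.append(all_taxa - side)

    def displayed(target: frozenset) -> bool:
        t = target & present
        comp = present - t
        if not t or not comp:
            return False
        return any((s & present) == t for s in sides)

    if displayed(a1 | a2):
        return "concordant"
    if displayed(a1 | b1):
        return "df1"
    if displayed(a1 | b2):
        return "df2"
    return "paraphyletic"


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def roles():
    return msc_sim.default_roles()


@pytest.fixture(scope="session")
def ils_gene_trees():
    """Shared high-ILS simulation: 500 loci on the ten-taxon backbone."""
    net = msc_sim.make_scenario("ils_only")
    return net, msc_sim.simulate_gene_trees(net, 500, 1234)


@pytest.fixture(scope="session")
def hybrid_gene_trees():
    """Shared gamma=0.5, long-parental-branch simulation (300 loci)."""
    net = msc_sim.make_scenario("hybrid", gamma=0.5, parental_branch=3.0)
    return net, msc_sim.simulate_gene_trees(net, 300, 4321)
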