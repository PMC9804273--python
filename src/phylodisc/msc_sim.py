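"""Multispecies-coalescent simulation on a species tree with at most one
reticulation, plus a sequence layer.

The generator realises the strict-ILS null — within every species-tree edge,
``k`` lineages coalesce at rate ``C(k,2)`` in coalescent units (pairwise rate
1) — extended with a single hybridization edge: lineages sampled from the
hybrid tip independently choose the donor parental edge with inheritance
probability ``gamma`` and are carried to the donor edge through a ghost
population in which they may coalesce among themselves.  With ``gamma`` 0 or
1 the network degenerates to a tree.

Sequences evolve site-independently under JC69 or HKY85, with branch lengths
``coalescent length x mu`` expected substitutions per site.

Branch-length convention: coalescent units with per-pair coalescence rate 1
(the ASTRAL convention), so simulated species-tree scales are directly
comparable to coalescent-unit branch lengths reported on empirical species
trees.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import Alignment, Tree, read_newick

_ULTRAMETRIC_TOL = 1e-6


class UnsupportedNetworkError(ValueError):
    """More reticulations than the single supported one."""


@dataclass(frozen=True)
class Reticulation:
    """One hybridization edge.

    ``hybrid`` is a tip of the base tree; at time ``t_hybrid`` on its
    pendant edge each of its lineages independently takes the donor path
    with probability ``gamma``, entering the edge above the most recent
    common ancestor of ``donor_clade`` at time ``t_donor``.
    """

    hybrid: str
    donor_clade: frozenset
    gamma: float
    t_hybrid: float
    t_donor: float

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if self.t_donor < self.t_hybrid:
            raise ValueError("t_donor must be >= t_hybrid")
        if self.hybrid in self.donor_clade:
            raise ValueError("hybrid tip cannot be part of the donor clade")


@dataclass
class SpeciesNetwork:
    """Species tree in coalescent units plus zero or one reticulation."""

    tree: Tree
    reticulation: Reticulation | None = None
    samples_per_tip: int | Mapping[str, int] = 1

    def __post_init__(self):
        if self.tree.units not in ("coalescent", "unknown"):
            raise ValueError(
                "species network branch lengths must be in coalescent units")
        _SpeciesModel(self)  # validates ages / attachment times eagerly

    def n_samples(self, taxon: str) -> int:
        if isinstance(self.samples_per_tip, int):
            return self.samples_per_tip
        return int(self.samples_per_tip.get(taxon, 1))

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.tree.tip_labels)


class _SpeciesModel:
    """Preprocessed species network: node ages, children, hybrid/donor
    bookkeeping — everything `sample_gene_tree` needs per locus."""

    def __init__(self, net: SpeciesNetwork):
        self.net = net
        dtree = net.tree.dtree
        # dendropy deroots unflagged trees as a side effect of mrca();
        # species networks are always time-rooted here
        dtree.is_rooted = True
        self.age: dict[int, float] = {}
        self.parent_age: dict[int, float] = {}
        self.children: dict[int, list] = {}
        self.leaves: dict[int, str] = {}
        root = dtree.seed_node
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                self.age[id(nd)] = 0.0
                self.leaves[id(nd)] = nd.taxon.label
            else:
                ages = []
                for ch in nd.child_nodes():
                    if ch.edge.length is None:
                        raise ValueError(
                            f"missing branch length above {ch!r}: lengths are "
                            "required for coalescent simulation")
                    ages.append(self.age[id(ch)] + ch.edge.length)
                if max(ages) - min(ages) > _ULTRAMETRIC_TOL * max(1.0, max(ages)):
                    raise ValueError(
                        "species tree is not ultrametric in coalescent time "
                        f"(child ages {ages})")
                self.age[id(nd)] = float(np.mean(ages))
                self.children[id(nd)] = list(nd.child_nodes())
        for nd in dtree.preorder_node_iter():
            if nd is root:
                self.parent_age[id(nd)] = math.inf
            else:
                self.parent_age[id(nd)] = self.age[id(nd.parent_node)]
        self.root = root

        # tips and sample labels, in species-tree leaf order
        self.tip_labels: list[str] = []
        self.tip_slices: dict[str, tuple[int, int]] = {}
        for nd in dtree.leaf_node_iter():
            name = nd.taxon.label
            k = net.n_samples(name)
            start = len(self.tip_labels)
            if k == 1:
                self.tip_labels.append(name)
            else:
                self.tip_labels.extend(f"{name}_{i + 1}" for i in range(k))
            self.tip_slices[name] = (start, start + k)
        self.n_tips = len(self.tip_labels)

        # reticulation bookkeeping
        ret = net.reticulation
        self.hybrid_leaf_id = None
        self.donor_node_id = None
        if ret is not None:
            labels = set(net.tree.tip_labels)
            if ret.hybrid not in labels:
                raise ValueError(f"hybrid tip {ret.hybrid!r} not in tree")
            if not ret.donor_clade <= labels:
                raise ValueError("donor clade not a subset of the taxa")
            for nid, lab in self.leaves.items():
                if lab == ret.hybrid:
                    self.hybrid_leaf_id = nid
            if not 0.0 <= ret.t_hybrid <= self.parent_age[self.hybrid_leaf_id]:
                raise ValueError(
                    "t_hybrid outside the hybrid tip's pendant edge")
            mrca = dtree.mrca(taxon_labels=sorted(ret.donor_clade))
            self.donor_node_id = id(mrca)
            lo, hi = self.age[self.donor_node_id], self.parent_age[self.donor_node_id]
            if not lo <= ret.t_donor <= hi:
                raise ValueError(
                    f"t_donor={ret.t_donor} outside the donor edge span "
                    f"[{lo}, {hi}]")
            hyb_mask_check = self.leaves[self.hybrid_leaf_id]
            # donor clade must not contain the hybrid lineage's own ancestry
            # below t_donor: disallow hybrid inside the donor subtree
            donor_tips = {l.taxon.label for l in mrca.leaf_iter()}
            if hyb_mask_check in donor_tips:
                raise ValueError("hybrid tip lies inside the donor clade")

    # -- per-locus sampling -------------------------------------------------

    def sample_gene_tree(self, rng: random.Random) -> "SimTree":
        n = self.n_tips
        times = [0.0] * n
        children: list[tuple[int, ...]] = [()] * n

        def coalesce(L: list[int], t0: float, t1: float) -> float:
            t = t0
            while len(L) >= 2:
                k = len(L)
                t += rng.expovariate(k * (k - 1) / 2.0)
                if t > t1:
                    return t1
                a = L.pop(rng.randrange(len(L)))
                b = L.pop(rng.randrange(len(L)))
                times.append(t)
                children.append((a, b))
                L.append(len(times) - 1)
            return max(t0, t1 if t1 < math.inf else t0)

        ret = self.net.reticulation
        migrants: list[int] = []
        stayers: list[int] | None = None
        if ret is not None and self.hybrid_leaf_id is not None:
            s, e = self.tip_slices[ret.hybrid]
            L = list(range(s, e))
            coalesce(L, 0.0, ret.t_hybrid)
            if ret.gamma == 0.0:
                stayers = L
            elif ret.gamma == 1.0:
                migrants, stayers = L, []
            else:
                stayers = []
                for x in L:
                    (migrants if rng.random() < ret.gamma else stayers).append(x)
            coalesce(migrants, ret.t_hybrid, ret.t_donor)

        def up(nd) -> list[int]:
            nid = id(nd)
            if nid in self.leaves:
                name = self.leaves[nid]
                if ret is not None and nid == self.hybrid_leaf_id:
                    L = list(stayers)
                    t0 = ret.t_hybrid
                else:
                    s, e = self.tip_slices[name]
                    L = list(range(s, e))
                    t0 = 0.0
            else:
                L = []
                for ch in self.children[nid]:
                    L.extend(up(ch))
                t0 = self.age[nid]
            t1 = self.parent_age[nid]
            if ret is not None and nid == self.donor_node_id:
                coalesce(L, t0, ret.t_donor)
                L.extend(migrants)
                t0 = ret.t_donor
            coalesce(L, t0, t1)
            return L

        L = up(self.root)
        assert len(L) == 1
        return SimTree(tuple(self.tip_labels), times, children, root=L[0])


class SimTree:
    """Lightweight rooted gene tree produced by the simulator.

    Tips are indices ``0..n-1`` labelled by ``labels``; internal nodes are
    appended in coalescence order with their times; branch length of a node
    is its parent's time minus its own.
    """

    __slots__ = ("labels", "times", "children", "root")

    def __init__(self, labels: tuple[str, ...], times: list[float],
                 children: list[tuple[int, ...]], root: int):
        self.labels = labels
        self.times = times
        self.children = children
        self.root = root

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def tip_labels(self) -> list[str]:
        return list(self.labels)

    def newick(self, precision: int = 6) -> str:
        fmt = f"%.{precision}g"

        def rec(i: int, parent_time: float) -> str:
            bl = fmt % (parent_time - self.times[i])
            if not self.children[i]:
                return f"{self.labels[i]}:{bl}"
            inner = ",".join(rec(c, self.times[i]) for c in self.children[i])
            return f"({inner}):{bl}"

        inner = ",".join(rec(c, self.times[self.root])
                         for c in self.children[self.root])
        return f"({inner});"

    def clade_masks(self, index: Mapping[str, int]) -> tuple[int, list[int]]:
        masks = [0] * len(self.times)
        order = self._postorder()
        for i in order:
            if not self.children[i]:
                masks[i] = 1 << index[self.labels[i]]
            else:
                m = 0
                for c in self.children[i]:
                    m |= masks[c]
                masks[i] = m
        return masks[self.root], masks

    def _postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        order.reverse()
        return order

    def to_core_tree(self) -> Tree:
        return read_newick(self.newick(precision=12), units="coalescent")


@dataclass
class GeneTreeSet:
    """A set of per-locus gene trees plus the provenance of their simulation."""

    trees: list
    locus_ids: list[str]
    seed: int | None = None
    scenario: str = ""
    taxa: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.taxa and self.trees:
            t0 = self.trees[0]
            labs = t0.tip_labels() if callable(getattr(t0, "tip_labels", None)) \
                else list(t0.tip_labels)
            self.taxa = tuple(dict.fromkeys(labs))

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def write(self, path, header: str | None = None):
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            for t in self.trees:
                fh.write((t.newick() if hasattr(t, "newick") else str(t)) + "\n")


def simulate_gene_trees(net: SpeciesNetwork, n_loci: int,
                        seed: int) -> GeneTreeSet:
    """Sample ``n_loci`` independent gene trees under the (network) MSC.

    Identical ``(net, n_loci, seed)`` gives identical output.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    model = _SpeciesModel(net)
    rng = random.Random(seed)
    trees = [model.sample_gene_tree(rng) for _ in range(n_loci)]
    desc = "msc" if net.reticulation is None else \
        f"msc+reticulation(gamma={net.reticulation.gamma})"
    return GeneTreeSet(trees, [f"L{i + 1}" for i in range(n_loci)],
                       seed=seed, scenario=desc, taxa=tuple(model.tip_labels))


# ---------------------------------------------------------------------------
# Sequence layer
# ---------------------------------------------------------------------------


class SubstModel:
    """JC69 or HKY85 with scale ``mu`` (expected substitutions/site per
    coalescent unit).

    The rate matrix is normalised to one expected substitution per unit
    time, then scaled by ``mu`` times the coalescent branch length, so
    ``mu`` controls the overall divergence of the simulated loci.
    """

    def __init__(self, name: str = "JC69", kappa: float = 2.0,
                 freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                 mu: float = 0.01):
        if name not in ("JC69", "HKY85"):
            raise ValueError(f"unknown model {name!r}")
        freqs = np.asarray(freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9 or (freqs <= 0).any():
            raise ValueError("base frequencies must be positive and sum to 1")
        if mu <= 0:
            raise ValueError("mu must be > 0")
        if name == "JC69":
            kappa = 1.0
            freqs = np.full(4, 0.25)
        self.name = name
        self.kappa = float(kappa)
        self.freqs = freqs
        self.mu = float(mu)
        # reversible Q via symmetrisation; eigendecomposition cached once
        Q = np.empty((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = (kappa if (i, j) in transitions else 1.0) * freqs[j]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(freqs * np.diag(Q)).sum()
        Q /= rate
        d = np.sqrt(freqs)
        S = (Q * d[:, None]) / d[None, :]  # D^1/2 Q D^-1/2, symmetric
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._w = w
        self._left = U / d[:, None]
        self._right = (U * d[:, None]).T

    def transition_matrix(self, t_subs: float) -> np.ndarray:
        """P(t) for a branch of ``t_subs`` expected substitutions/site."""
        P = (self._left * np.exp(self._w * t_subs)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def _edge_list(gt) -> tuple[list[str], list[tuple[int, int, float]], int, int]:
    """Normalise a gene tree to (tip labels, preorder edges, n_nodes, root).

    Edges are ``(parent_index, child_index, branch_length_coalescent)``
    with tips occupying indices ``0..n_tips-1``.  Accepts ``SimTree`` or
    :class:`phylodisc.core_io.Tree`.
    """
    if isinstance(gt, SimTree):
        edges = []
        stack = [gt.root]
        while stack:
            i = stack.pop()
            for c in gt.children[i]:
                edges.append((i, c, gt.times[i] - gt.times[c]))
                stack.append(c)
        return list(gt.labels), edges, len(gt.times), gt.root
    if isinstance(gt, Tree):
        dtree = gt.dtree
        leaves = [nd for nd in dtree.leaf_node_iter()]
        labels = [nd.taxon.label for nd in leaves]
        idx = {id(nd): i for i, nd in enumerate(leaves)}
        nxt = len(leaves)
        for nd in dtree.preorder_internal_node_iter():
            idx[id(nd)] = nxt
            nxt += 1
        edges = []
        for nd in dtree.preorder_node_iter():
            for ch in nd.child_nodes():
                bl = ch.edge.length
                if bl is None:
                    raise ValueError("gene tree has a branch without length")
                edges.append((idx[id(nd)], idx[id(ch)], float(bl)))
        return labels, edges, nxt, idx[id(dtree.seed_node)]
    raise TypeError(f"cannot simulate sequences on {type(gt)!r}")


def simulate_alignment(gt, model: SubstModel, n_sites: int,
                       seed: int) -> Alignment:
    """Evolve ``n_sites`` independent sites down a gene tree.

    The root state is drawn from the model's base frequencies; each branch
    applies the continuous-time transition matrix for ``length x mu``
    expected substitutions per site.  Deterministic under a fixed seed.
    """
    labels, edges, n_nodes, root = _edge_list(gt)
    if all(bl == 0.0 for _, _, bl in edges):
        warnings.warn("all branch lengths are zero: output will be invariant")
    rng = np.random.default_rng(seed)
    states = np.empty((n_nodes, n_sites), dtype=np.uint8)
    cumf = np.cumsum(model.freqs)
    states[root] = np.searchsorted(cumf, rng.random(n_sites), side="right")
    for parent, child, bl in edges:  # preorder: parents before children
        P = model.transition_matrix(bl * model.mu)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_sites)
        ps = states[parent]
        out = np.empty(n_sites, dtype=np.uint8)
        for s in range(4):
            m = ps == s
            if m.any():
                out[m] = np.searchsorted(cum[s], u[m], side="right")
        states[child] = out
    return Alignment(labels, states[:len(labels)])


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

CLADE_A = ("A1", "A2", "A3")
CLADE_B = ("B1", "B2", "B3")
CLADE_C = ("C1", "C2", "C3", "C4")
OUTGROUP = "OUT"
HYBRID = "B1"


def _backbone_newick(h1: float, cl: float, ab: float, abc: float,
                     root: float) -> str:
    a = f"((A1:{h1},A2:{h1}):{cl - h1},A3:{cl}):{ab - cl}"
    b = f"((B1:{h1},B2:{h1}):{cl - h1},B3:{cl}):{ab - cl}"
    c = f"((C1:{h1},C2:{h1}):{cl - h1},(C3:{h1},C4:{h1}):{cl - h1}):{abc - cl}"
    return (f"((({a},{b}):{abc - ab},{c}):{root - abc},"
            f"{OUTGROUP}:{root});")


def make_scenario(preset: str, **params) -> SpeciesNetwork:
    """Build a fully parameterised :class:`SpeciesNetwork`.

    Presets
    -------
    ``ils_only``
        Ten ingroup taxa in three clades (A1-3, B1-3, C1-4) plus an
        outgroup, with short internal branches (``internal``, default 0.5
        coalescent units) producing widespread ILS and no reticulation.
    ``hybrid``
        Same backbone, with tip B1 receiving a fraction ``gamma`` of its
        lineages from the Clade-A stem edge.  ``parental_branch`` sets the
        length of the A- and B-stem edges (longer = cleaner parental
        signal); ``t_hybrid``/``t_donor`` place the reticulation in time.
    ``custom``
        ``newick=`` species tree (coalescent units) plus optional
        ``reticulation=`` and ``samples_per_tip=``.
    """
    if preset == "ils_only":
        internal = float(params.pop("internal", 0.5))
        outgroup_depth = float(params.pop("outgroup_depth", 5.0))
        if params:
            raise ValueError(f"unknown ils_only parameters {sorted(params)}")
        h1 = 1.0
        cl = h1 + internal
        ab = h1 + 2 * internal
        abc = h1 + 3 * internal
        nwk = _backbone_newick(h1, cl, ab, abc, abc + outgroup_depth)
        return SpeciesNetwork(read_newick(nwk, units="coalescent"))
    if preset == "hybrid":
        gamma = float(params.pop("gamma"))
        pb = float(params.pop("parental_branch", 1.0))
        t_hybrid = float(params.pop("t_hybrid", 0.5))
        t_donor = params.pop("t_donor", None)
        outgroup_depth = float(params.pop("outgroup_depth", 5.0))
        if params:
            raise ValueError(f"unknown hybrid parameters {sorted(params)}")
        h1, cl = 1.0, 1.5
        ab = cl + pb
        abc = ab + 0.5
        t_donor = float(t_donor) if t_donor is not None else min(cl + 0.1, ab)
        nwk = _backbone_newick(h1, cl, ab, abc, abc + outgroup_depth)
        ret = Reticulation(hybrid=HYBRID, donor_clade=frozenset(CLADE_A),
                           gamma=gamma, t_hybrid=t_hybrid, t_donor=t_donor)
        return SpeciesNetwork(read_newick(nwk, units="coalescent"),
                              reticulation=ret)
    if preset == "custom":
        nwk = params.pop("newick")
        ret = params.pop("reticulation", None)
        samples = params.pop("samples_per_tip", 1)
        if params:
            raise ValueError(f"unknown custom parameters {sorted(params)}")
        return SpeciesNetwork(read_newick(nwk, units="coalescent"),
                              reticulation=ret, samples_per_tip=samples)
    raise ValueError(f"unknown preset {preset!r}")


def quartet_scenario(t: float) -> SpeciesNetwork:
    """Four-taxon caterpillar whose AB-ancestral internal branch has length
    ``t``; the classic substrate for the 1 - (2/3)e^(-t) concordance
    calibration."""
    nwk = f"(((A:1,B:1):{t},C:{1 + t}):1,D:{2 + t});"
    return make_scenario("custom", newick=nwk)


def default_roles() -> dict:
    """Taxon-role assignment mirroring the preset backbone: the hybrid tip,
    its two candidate parental populations, and the ABBA-BABA groups
    (((P1, P2), P3), O) with P2 the hybrid.

    P1 is the hybrid's species-tree sister (B2): the D-statistic's null
    expectation E[D] = 0 requires P1 and P2 to be sister populations, so
    a paraphyletic P1 grouping would be biased even without gene flow.
    """
    return {
        "hybrid": HYBRID,
        "parent1": frozenset(CLADE_A),
        "parent2": frozenset({"B2"}),
        "p1": frozenset({"B2"}),
        "p2": frozenset({HYBRID}),
        "p3": frozenset(CLADE_A),
        "outgroup": frozenset({OUTGROUP}),
        "clade_a": frozenset(CLADE_A),
        "clade_b": frozenset(CLADE_B),
        "clade_c": frozenset(CLADE_C),
    }
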