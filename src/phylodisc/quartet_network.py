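"""Quartet topology counting, per-quartet tree/star tests and a NANUQ-style
network distance.

For every 4-subset of taxa, the three unrooted resolutions are counted over
all decisive gene trees.  Each quartet is then classified by two hypothesis
tests on the count vector: a goodness-of-fit against the star model
(uniform 1/3,1/3,1/3) and against the tree model (one dominant topology,
the two minor ones equal).  Following the recommended operating point, a
quartet is called *star* when the star p-value exceeds beta (default 0.95),
*tree* when the tree model is not rejected at alpha (default 0.01), and
*network* otherwise — the network calls are the reticulation signal.

Classified quartets are aggregated into a pairwise distance: a tree quartet
with split ij|kl adds 1 to the four cross pairs and 0 to the two within
pairs; star and network quartets add 2/3 to all six pairs (the expectation
under a uniformly random resolution).  When every quartet is tree-like this
is exactly the quartet distance of the displayed tree, so neighbor joining
recovers it; a hybrid taxon flattens its quartets and lands between its
parents.  The matrix is exported as a NEXUS DISTANCES block for external
split-network (Neighbor-Net) software; neighbor joining is provided
in-package for automated checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from . import splits
from .core_io import Tree, read_newick

_PAIRING = {3: 0, 12: 0, 5: 1, 10: 1, 6: 2, 9: 2}
# weight = bit0 + 2*bit1 + 4*bit2 + 8*bit3 over quartet membership; a clade
# holding exactly two quartet taxa has weight in this table, keyed to the
# canonical topology order 01|23, 02|13, 03|12.


@dataclass
class QuartetRecord:
    taxa: tuple[str, str, str, str]
    counts: tuple[int, int, int]  # canonical order t0t1|t2t3, t0t2|t1t3, t0t3|t1t2
    n_decisive: int
    p_tree: float | None = None
    p_star: float | None = None
    classification: str | None = None  # "tree" | "star" | "network"
    winner: int | None = None
    low_count: bool = False


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon list")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(m).any():
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM
        return SkbioDM(self.matrix, ids=self.taxa)


def quartet_topology_counts(gene_trees,
                            taxa: Sequence[str] | None = None
                            ) -> list[QuartetRecord]:
    """Count the three unrooted resolutions of every 4-subset of taxa.

    Trees missing any of the four taxa or unresolved on them do not count
    toward that quartet's decisive total.  Gene trees must be one-to-one
    (duplicate taxa raise).
    """
    trees = list(gene_trees)
    if taxa is None:
        seen: dict[str, None] = {}
        for gt in trees:
            labels = _labels(gt)
            for l in labels:
                seen.setdefault(l)
        taxa = sorted(seen)
    else:
        taxa = list(taxa)
    index = splits.taxon_index(taxa)
    n = len(taxa)
    quartets = list(combinations(range(n), 4))
    q_arr = np.array(quartets, dtype=np.int64)
    counts = np.zeros((len(quartets), 3), dtype=np.int64)
    decis = np.zeros(len(quartets), dtype=np.int64)
    for gt in trees:
        labels = _labels(gt)
        if len(set(labels)) != len(labels):
            raise ValueError("gene tree has duplicate taxa; orthologs required")
        ext = dict(index)
        for lab in labels:
            if lab not in ext:
                ext[lab] = len(ext)
        present, masks = splits.clade_masks(gt, ext)
        cl = sorted(set(masks))
        if n <= 63:
            cl_arr = np.array(cl, dtype=np.uint64)
            member = ((cl_arr[:, None] >> np.arange(n, dtype=np.uint64)) & 1
                      ).astype(bool)
        else:
            member = np.zeros((len(cl), n), dtype=bool)
            for i, m in enumerate(cl):
                for b in range(n):
                    if m >> b & 1:
                        member[i, b] = True
        pres = np.array([(present >> b) & 1 for b in range(n)], dtype=bool)
        q_ok = pres[q_arr].all(axis=1)
        sub = member[:, q_arr]                      # (c, q, 4)
        two = sub.sum(axis=2) == 2                  # (c, q)
        w = (sub[:, :, 0] * 1 + sub[:, :, 1] * 2
             + sub[:, :, 2] * 4 + sub[:, :, 3] * 8)
        topo = np.full(w.shape, -1, dtype=np.int64)
        for key, val in _PAIRING.items():
            topo[two & (w == key)] = val
        any_res = (topo >= 0).any(axis=0)
        first = np.argmax(topo >= 0, axis=0)
        resolved = q_ok & any_res
        t_sel = topo[first, np.arange(len(quartets))]
        for qi in np.nonzero(resolved)[0]:
            counts[qi, t_sel[qi]] += 1
            decis[qi] += 1
    out = []
    for qi, q in enumerate(quartets):
        out.append(QuartetRecord(
            taxa=tuple(taxa[i] for i in q),
            counts=tuple(int(c) for c in counts[qi]),
            n_decisive=int(decis[qi])))
    return out


def _labels(gt) -> list[str]:
    tl = gt.tip_labels
    return tl() if callable(tl) else list(tl)


def _chi2_stat(obs: np.ndarray, exp: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1),
                         np.where(obs > 0, np.inf, 0.0))
    return float(terms.sum())


def _exact_p(obs_counts: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial tail: P(stat(X) >= stat(obs)) under ``probs``,
    ordered by the same chi-squared statistic."""
    n = int(obs_counts.sum())
    exp = n * probs
    s_obs = _chi2_stat(obs_counts, exp)
    p = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            x = np.array([a, b, c], dtype=float)
            if _chi2_stat(x, exp) >= s_obs - 1e-12:
                p += math.exp(
                    math.lgamma(n + 1) - math.lgamma(a + 1)
                    - math.lgamma(b + 1) - math.lgamma(c + 1)
                    + sum(k * math.log(pr) if pr > 0 else
                          (0.0 if k == 0 else -math.inf)
                          for k, pr in zip((a, b, c), probs)))
    return min(p, 1.0)


def quartet_tests(rec: QuartetRecord, alpha: float = 0.01,
                  beta: float = 0.95,
                  exact_below: int = 30) -> QuartetRecord:
    """Classify one quartet as tree, star or network.

    Star test: goodness of fit to (1/3,1/3,1/3) on 2 df.  Tree test: fit to
    (p, (1-p)/2, (1-p)/2) with p = max(n_max/n, 1/3) on 1 df.  Below
    ``exact_below`` decisive trees both tests switch to exact multinomial
    tails with the same orderings; below 10 the quartet defaults to star
    with a low-count flag.
    """
    if not 0 < alpha < beta < 1:
        raise ValueError("need 0 < alpha < beta < 1")
    n = rec.n_decisive
    obs = np.array(rec.counts, dtype=float)
    if n < 10:
        return replace(rec, p_tree=None, p_star=None, classification="star",
                       winner=None, low_count=True)
    star_probs = np.full(3, 1 / 3)
    winner = int(np.argmax(obs))
    p_hat = max(obs[winner] / n, 1 / 3)
    tree_probs = np.full(3, (1 - p_hat) / 2)
    tree_probs[winner] = p_hat
    if n < exact_below:
        p_star = _exact_p(obs, star_probs)
        p_tree = _exact_p(obs, tree_probs)
    else:
        p_star = float(stats.chi2.sf(_chi2_stat(obs, n * star_probs), df=2))
        p_tree = float(stats.chi2.sf(_chi2_stat(obs, n * tree_probs), df=1))
    if p_star > beta:
        cls, win = "star", None
    elif p_tree >= alpha:
        cls, win = "tree", winner
    else:
        cls, win = "network", None
    return replace(rec, p_tree=p_tree, p_star=p_star, classification=cls,
                   winner=win)


def classify_quartets(records: Sequence[QuartetRecord], alpha: float = 0.01,
                      beta: float = 0.95) -> list[QuartetRecord]:
    return [quartet_tests(r, alpha=alpha, beta=beta) for r in records]


def nanuq_distance(records: Sequence[QuartetRecord],
                   taxa: Sequence[str] | None = None,
                   normalize: bool = False) -> DistanceMatrix:
    """Aggregate classified quartets into the network distance.

    Tree quartets contribute their split (0 within pairs, 1 across); star
    and network quartets contribute the uniform expectation 2/3 to all six
    pairs.  ``normalize`` divides each pair by the number of quartets
    containing it.
    """
    if taxa is None:
        seen: dict[str, None] = {}
        for r in records:
            for t in r.taxa:
                seen.setdefault(t)
        taxa = sorted(seen)
    else:
        taxa = list(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))
    npairs = np.zeros((n, n))
    for r in records:
        if r.classification is None:
            raise ValueError(
                f"quartet {r.taxa} is unclassified; run quartet_tests first")
        q = [idx[t] for t in r.taxa]
        pairs = list(combinations(range(4), 2))
        if r.classification == "tree":
            if r.winner == 0:
                within = {(0, 1), (2, 3)}
            elif r.winner == 1:
                within = {(0, 2), (1, 3)}
            else:
                within = {(0, 3), (1, 2)}
            for a, b in pairs:
                w = 0.0 if (a, b) in within else 1.0
                d[q[a], q[b]] += w
                d[q[b], q[a]] += w
        else:
            for a, b in pairs:
                d[q[a], q[b]] += 2 / 3
                d[q[b], q[a]] += 2 / 3
        for a, b in pairs:
            npairs[q[a], q[b]] += 1
            npairs[q[b], q[a]] += 1
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(npairs > 0, d / np.maximum(npairs, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(taxa), d)


# ---------------------------------------------------------------------------
# NEXUS export / NJ
# ---------------------------------------------------------------------------


def _nexus_label(lab: str) -> str:
    if any(c in lab for c in " ()[]{}/\\,;:=*'\"`<>"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


def export_nexus_distance(d: DistanceMatrix, path) -> None:
    """Write a NEXUS DISTANCES block (triangle=both, labelled) readable by
    standard split-network tools."""
    n = len(d.taxa)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={n};\n  TAXLABELS\n")
        for t in d.taxa:
            fh.write(f"    {_nexus_label(t)}\n")
        fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write(f"  DIMENSIONS NTAX={n};\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS=LEFT;\n  MATRIX\n")
        for i, t in enumerate(d.taxa):
            row = " ".join(f"{x:.6f}" for x in d.matrix[i])
            fh.write(f"    {_nexus_label(t)} {row}\n")
        fh.write("  ;\nEND;\n")


def read_nexus_distance(path) -> DistanceMatrix:
    """Read back a DISTANCES block written by :func:`export_nexus_distance`."""
    import re

    text = open(path).read()
    m = re.search(r"BEGIN DISTANCES;.*?MATRIX\n(.*?)\n\s*;", text,
                  re.S | re.I)
    if not m:
        raise ValueError(f"no DISTANCES matrix found in {path}")
    taxa, rows = [], []
    for line in m.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            end = line.index("'", 1)
            while end + 1 < len(line) and line[end + 1] == "'":
                end = line.index("'", end + 2)
            lab = line[1:end].replace("''", "'")
            rest = line[end + 1:]
        else:
            lab, _, rest = line.partition(" ")
        taxa.append(lab)
        rows.append([float(x) for x in rest.split()])
    return DistanceMatrix(taxa, np.array(rows))


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Neighbor joining on the network distance (diagnostic: recovers the
    species topology when every quartet is tree-like)."""
    from skbio.tree import nj

    sk = nj(d.to_skbio())
    nwk = str(sk).strip()
    return read_newick(nwk)
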