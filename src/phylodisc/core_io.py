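"""Tree and alignment handling plus alignment composition statistics.

Trees are thin wrappers around :class:`dendropy.Tree` carrying the two pieces
of metadata the pipeline cares about: the unit of the branch lengths
(``"subs/site"`` for empirical gene trees, ``"coalescent"`` for simulated
species trees — never inferred) and whether the tree is a multi-copy homolog
tree (duplicate taxa allowed) or a one-to-one ortholog tree.

Alignments are dense ``numpy`` matrices over the nucleotide alphabet.
Anything outside ``{A, C, G, T}`` — gap characters and IUPAC ambiguity codes
alike — is stored under a single *missing* code, and the number of characters
so mapped is recorded on the alignment.  Coordinates are 0-based half-open
internally; 1-based only in printed reports.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO

A, C, G, T, MISSING = 0, 1, 2, 3, 4

_CODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGT-", dtype=np.uint8)

_VALID = np.zeros(256, dtype=bool)
for _b in "ACGTacgt-":
    _VALID[ord(_b)] = True


class NewickParseError(ValueError):
    """Malformed Newick input; carries a character offset where known."""


class DuplicateTaxonError(ValueError):
    """Duplicate tip labels on a tree not flagged as a homolog tree."""


class AlignmentFormatError(ValueError):
    """Ragged or otherwise malformed alignment input."""


class EmptyAlignmentWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Tree:
    """A phylogeny with taxon-labelled tips.

    Parameters
    ----------
    dtree:
        Backing :class:`dendropy.Tree`.
    units:
        Branch-length units, ``"subs/site"``, ``"coalescent"`` or
        ``"unknown"``.  Recorded metadata, never inferred from the lengths.
    homolog:
        Whether duplicate taxa (paralogs) are permitted among the tips.
    """

    __slots__ = ("dtree", "units", "homolog")

    def __init__(self, dtree: dendropy.Tree, units: str = "unknown",
                 homolog: bool = False):
        self.dtree = dtree
        self.units = units
        self.homolog = homolog
        labels = self.tip_labels
        if any(not lab for lab in labels):
            raise ValueError("every tip must carry a non-empty label")
        if not homolog and len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise DuplicateTaxonError(
                f"duplicate tip labels {dup} on a non-homolog tree")

    # -- structure ---------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label if lf.taxon else ""
                for lf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def is_rooted(self) -> bool:
        """True when the root is a bifurcation (rooted representation)."""
        return len(self.dtree.seed_node.child_nodes()) == 2

    def copy(self) -> "Tree":
        return Tree(self.dtree.clone(depth=1), units=self.units,
                    homolog=self.homolog)

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Tree n_tips={self.n_tips} units={self.units!r}>"


def read_newick(text: str, homolog_ok: bool = False,
                units: str = "unknown") -> Tree:
    """Parse one Newick string into a :class:`Tree`.

    Support values encoded as internal-node labels are kept as labels;
    numeric bracket comments adjacent to internal nodes are promoted to
    labels when the node has none.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"newick string must end in ';' (offset {len(stripped)})")
    if stripped.count("(") != stripped.count(")"):
        raise NewickParseError(
            "unbalanced parentheses "
            f"({stripped.count('(')} open vs {stripped.count(')')} close)")
    try:
        # leaf taxa are assigned manually below so that duplicate labels
        # (paralogs in homolog trees) survive parsing
        dtree = dendropy.Tree.get(
            data=stripped, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, suppress_leaf_node_taxa=True)
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    for lf in dtree.leaf_node_iter():
        taxon = dendropy.Taxon(label=lf.label or "")
        dtree.taxon_namespace.add_taxon(taxon)
        lf.taxon = taxon
        lf.label = None
    for nd in dtree.preorder_internal_node_iter():
        if nd.label is None and nd.comments:
            m = re.search(r"(\d+(?:\.\d+)?)", " ".join(nd.comments))
            if m:
                nd.label = m.group(1)
    return Tree(dtree, units=units, homolog=homolog_ok)


def write_newick(tree: Tree) -> str:
    s = tree.dtree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True)
    return s.strip()


def read_newick_file(path, homolog_ok: bool = False,
                     units: str = "unknown") -> list[Tree]:
    """Read a multi-tree Newick file, one tree per line.

    Lines starting with ``#`` (pipeline output headers) and blank lines are
    skipped.
    """
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        trees.append(read_newick(line, homolog_ok=homolog_ok, units=units))
    return trees


def write_newick_file(trees: Iterable[Tree], path, header: str | None = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for t in trees:
            fh.write(t.newick() + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


class Alignment:
    """Taxon → sequence map over ``{A,C,G,T}`` + missing.

    ``data`` is a ``(n_taxa, n_sites)`` uint8 matrix with codes 0..3 for
    A,C,G,T and 4 for missing (gap or ambiguity).  ``partitions`` is an
    optional list of ``(locus_id, start, end)`` half-open 0-based column
    intervals; when present the intervals must tile the alignment.
    """

    __slots__ = ("names", "data", "partitions", "n_mapped_missing")

    def __init__(self, names: Sequence[str], data: np.ndarray,
                 partitions: list[tuple[str, int, int]] | None = None,
                 n_mapped_missing: int = 0):
        names = list(names)
        if len(set(names)) != len(names):
            raise ValueError("taxon names must be unique")
        data = np.asarray(data, dtype=np.uint8)
        if data.ndim != 2 or data.shape[0] != len(names):
            raise ValueError("data must be (n_taxa, n_sites)")
        if partitions is not None:
            width = sum(e - s for _, s, e in partitions)
            if width != data.shape[1]:
                raise ValueError(
                    f"partition widths sum to {width}, alignment has "
                    f"{data.shape[1]} columns")
        self.names = names
        self.data = data
        self.partitions = partitions
        self.n_mapped_missing = n_mapped_missing

    @classmethod
    def from_sequences(cls, pairs: Mapping[str, str] | Iterable[tuple[str, str]],
                       partitions=None) -> "Alignment":
        items = list(pairs.items()) if isinstance(pairs, Mapping) else list(pairs)
        if not items:
            raise ValueError("empty alignment input")
        lengths = {name: len(seq) for name, seq in items}
        if len(set(lengths.values())) > 1:
            ref = len(items[0][1])
            bad = next(n for n, l in lengths.items() if l != ref)
            raise AlignmentFormatError(
                f"ragged alignment: taxon {bad!r} has length {lengths[bad]}, "
                f"expected {ref}")
        n_mapped = 0
        rows = []
        for _, seq in items:
            raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            n_mapped += int((~_VALID[raw]).sum())
            rows.append(_CODE[raw])
        data = np.vstack(rows) if rows else np.zeros((0, 0), np.uint8)
        return cls([n for n, _ in items], data, partitions=partitions,
                   n_mapped_missing=n_mapped)

    # -- accessors ---------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, name: str) -> str:
        row = self.data[self.names.index(name)]
        return _DECODE[row].tobytes().decode("ascii")

    def subset_columns(self, keep: np.ndarray) -> "Alignment":
        """Return a new alignment with only the columns where ``keep`` is
        True; partition intervals are recomputed."""
        keep = np.asarray(keep, dtype=bool)
        parts = None
        if self.partitions is not None:
            parts, pos = [], 0
            for pid, s, e in self.partitions:
                w = int(keep[s:e].sum())
                if w:
                    parts.append((pid, pos, pos + w))
                    pos += w
            if not parts:
                parts = None
        return Alignment(self.names, self.data[:, keep], partitions=parts,
                         n_mapped_missing=self.n_mapped_missing)

    # -- output ------------------------------------------------------------

    def to_fasta(self, path, header: str | None = None):
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            for name in self.names:
                fh.write(f">{name}\n{self.sequence(name)}\n")

    def to_phylip(self, path, header: str | None = None):
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write(f"{self.n_taxa} {self.n_sites}\n")
            for name in self.names:
                fh.write(f"{name}  {self.sequence(name)}\n")

    def write_partitions_tsv(self, path, header: str | None = None):
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("locus\tstart\tend\n")
            for pid, s, e in self.partitions or []:
                fh.write(f"{pid}\t{s}\t{e}\n")

    def write_partitions_raxml(self, path):
        """RAxML-style partition file; printed coordinates are 1-based
        inclusive."""
        with open(path, "w") as fh:
            for pid, s, e in self.partitions or []:
                fh.write(f"DNA, {pid} = {s + 1}-{e}\n")


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    Case-insensitive; characters outside ``{A,C,G,T,-}`` are mapped to
    missing and counted on ``n_mapped_missing``.
    """
    import io as _io

    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    while lines and lines[0].startswith("#"):  # pipeline output headers
        lines.pop(0)
    handle = _io.StringIO("".join(lines))
    if format == "fasta":
        records = list(SeqIO.parse(handle, "fasta"))
        if not records:
            raise AlignmentFormatError(f"no sequences in {path}")
        return Alignment.from_sequences([(r.id, str(r.seq)) for r in records])
    if format in ("phylip-relaxed", "phylip"):
        msa = AlignIO.read(handle, "phylip-relaxed")
        return Alignment.from_sequences([(r.id, str(r.seq)) for r in msa])
    raise ValueError(f"unknown alignment format {format!r}")


def read_partitions_tsv(path) -> list[tuple[str, int, int]]:
    parts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("locus\t"):
            continue
        pid, s, e = line.split("\t")
        parts.append((pid, int(s), int(e)))
    return parts


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteClassCounts:
    """Per-column composition of an alignment.

    A column is *invariant* when exactly one distinct non-missing state is
    observed (at least twice), *parsimony-informative* when at least two
    states are each observed at least twice, *variable-uninformative* when
    variable but not informative, and lands in the *all-missing* bucket when
    fewer than two non-missing observations exist.  The four counts always
    sum to the total.
    """

    n_invariant: int
    n_parsimony_informative: int
    n_variable_uninformative: int
    n_all_missing: int
    n_total: int

    def __post_init__(self):
        s = (self.n_invariant + self.n_parsimony_informative
             + self.n_variable_uninformative + self.n_all_missing)
        if s != self.n_total:
            raise ValueError(f"category counts sum to {s} != {self.n_total}")

    def percentages(self) -> tuple[float, float, float]:
        """(invariant, informative, variable-uninformative) as percent of
        the total, reported to one decimal."""
        f = 100.0 / self.n_total
        return (round(self.n_invariant * f, 1),
                round(self.n_parsimony_informative * f, 1),
                round(self.n_variable_uninformative * f, 1))


def classify_sites(aln: Alignment) -> SiteClassCounts:
    if aln.n_sites == 0:
        raise ValueError("empty alignment: no columns to classify")
    M = aln.data
    cnt = np.stack([(M == s).sum(axis=0) for s in range(4)], axis=1)
    nobs = cnt.sum(axis=1)
    ndistinct = (cnt > 0).sum(axis=1)
    n_ge2 = (cnt >= 2).sum(axis=1)
    all_missing = nobs < 2
    invariant = ~all_missing & (ndistinct == 1)
    informative = ~all_missing & (ndistinct >= 2) & (n_ge2 >= 2)
    variable_un = ~all_missing & (ndistinct >= 2) & ~informative
    return SiteClassCounts(
        n_invariant=int(invariant.sum()),
        n_parsimony_informative=int(informative.sum()),
        n_variable_uninformative=int(variable_un.sum()),
        n_all_missing=int(all_missing.sum()),
        n_total=aln.n_sites,
    )


def concatenate(alignments: Sequence[Alignment],
                locus_ids: Sequence[str] | None = None) -> Alignment:
    """Concatenate loci over the union of their taxa.

    A taxon absent from a locus is filled with missing for that locus's
    block.  The partition table records each locus's half-open column
    interval in input order.
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    if locus_ids is None:
        locus_ids = [f"L{i + 1}" for i in range(len(alignments))]
    names: list[str] = []
    for aln in alignments:
        for n in aln.names:
            if n not in names:
                names.append(n)
    total = sum(a.n_sites for a in alignments)
    data = np.full((len(names), total), MISSING, dtype=np.uint8)
    parts, pos = [], 0
    n_mapped = 0
    for pid, aln in zip(locus_ids, alignments):
        idx = [names.index(n) for n in aln.names]
        data[idx, pos:pos + aln.n_sites] = aln.data
        parts.append((pid, pos, pos + aln.n_sites))
        pos += aln.n_sites
        n_mapped += aln.n_mapped_missing
    return Alignment(names, data, partitions=parts, n_mapped_missing=n_mapped)
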