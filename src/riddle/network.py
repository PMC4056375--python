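"""Weighted gene network and gene-set containers plus their file formats.

The network is an undirected, weighted graph over opaque gene identifiers,
stored as a symmetric CSR adjacency matrix.  Edge weights are evidence
strengths (dimensionless, strictly positive).  Gene sets are named member
collections; members absent from the network are retained in the set object
but excluded from every network computation, with ``network_coverage``
reporting the loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "GeneSet",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "centrality",
    "set_centrality",
    "network_coverage",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (query, pathway, or module)."""

    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def in_network(self, net: "GeneNetwork") -> frozenset[str]:
        return self.members & net.gene_set


class GeneNetwork:
    """Undirected weighted gene network backed by a symmetric sparse matrix.

    Invariants: weights > 0, no self-loops, (a, b) and (b, a) are the same
    edge.  Genes with no edges are permitted (isolated nodes).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]],
        extra_genes: Iterable[str] = (),
    ) -> None:
        best: dict[tuple[str, str], float] = {}
        genes: set[str] = set(extra_genes)
        n_self = 0
        for a, b, w in edges:
            w = float(w)
            if w <= 0:
                raise ValueError(f"edge ({a}, {b}) has non-positive weight {w}")
            genes.add(a)
            genes.add(b)
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            prev = best.get(key)
            if prev is None or w > prev:
                best[key] = w
        if n_self:
            logger.info("dropped %d self-loop(s)", n_self)

        self.genes: tuple[str, ...] = tuple(sorted(genes))
        self.gene_set: frozenset[str] = frozenset(self.genes)
        self._index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        n = len(self.genes)
        if best:
            rows, cols, vals = [], [], []
            for (a, b), w in best.items():
                i, j = self._index[a], self._index[b]
                rows += [i, j]
                cols += [j, i]
                vals += [w, w]
            self.adjacency = sp.csr_array(
                (np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
                shape=(n, n),
            )
        else:
            self.adjacency = sp.csr_array((n, n))
        self._degree = np.asarray(self.adjacency.sum(axis=1)).ravel()
        self._norm_cache: dict[str, sp.csr_array] = {}

    # -- basic queries ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} is not in the network") from None

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        """Indices of the given genes, silently skipping out-of-network ones."""
        return np.asarray(
            sorted(self._index[g] for g in genes if g in self._index), dtype=np.intp
        )

    def degree_vector(self) -> np.ndarray:
        """Weighted degree (centrality) of every gene, in ``self.genes`` order."""
        return self._degree

    def edge_iter(self) -> Iterable[tuple[str, str, float]]:
        coo = self.adjacency.tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            if i < j:
                yield self.genes[i], self.genes[j], float(w)

    def normalized_adjacency(self, scheme: str = "symmetric") -> sp.csr_array:
        """Degree-normalized adjacency, cached per scheme.

        symmetric: D^{-1/2} W D^{-1/2}; row: D^{-1} W.  Zero-degree rows and
        columns stay zero.
        """
        if scheme not in ("symmetric", "row"):
            raise ValueError(f"unknown normalization {scheme!r}")
        cached = self._norm_cache.get(scheme)
        if cached is not None:
            return cached
        d = self._degree.copy()
        with np.errstate(divide="ignore"):
            if scheme == "symmetric":
                inv = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
                mat = sp.diags_array(inv) @ self.adjacency @ sp.diags_array(inv)
            else:
                inv = np.where(d > 0, 1.0 / d, 0.0)
                mat = sp.diags_array(inv) @ self.adjacency
        mat = sp.csr_array(mat)
        self._norm_cache[scheme] = mat
        return mat


# -- file formats ---------------------------------------------------------


def read_edge_list(path: str | Path) -> GeneNetwork:
    """Read a HumanNet-style TSV edge list (gene TAB gene TAB weight).

    Comment lines starting with '#' are ignored.  Duplicate edges keep the
    maximum weight; self-loops are dropped (counted in the log); lines with a
    non-positive weight are rejected with a log message.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    n_nonpos = n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            a, b = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: weight {fields[2]!r} is not a number") from None
            if not np.isfinite(w) or w <= 0:
                n_nonpos += 1
                logger.warning("%s:%d: rejected edge with non-positive weight %s", path, lineno, fields[2])
                continue
            if a == b:
                n_self += 1
                continue
            edges.append((a, b, w))
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    if not edges:
        raise ValueError(f"{path}: no edges")
    return GeneNetwork(edges)


def write_edge_list(net: GeneNetwork, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write the network as a 3-column TSV; isolated genes are not encoded."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for a, b, w in net.edge_iter():
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a Broad-dialect GMT file: set-id TAB description TAB gene1 TAB ...

    Duplicate member genes are deduplicated; a duplicate set id is an error.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, description and >=1 gene")
            sid, desc = fields[0], fields[1]
            if sid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members = frozenset(g for g in fields[2:] if g)
            sets[sid] = GeneSet(id=sid, name=desc, members=members)
    return sets


def write_gmt(sets: Iterable[GeneSet] | Mapping[str, GeneSet], path: str | Path) -> None:
    if isinstance(sets, Mapping):
        sets = list(sets.values())
    path = Path(path)
    with path.open("w") as fh:
        for s in sets:
            fh.write(s.id + "\t" + s.name + "\t" + "\t".join(sorted(s.members)) + "\n")


# -- centrality & coverage -------------------------------------------------


def centrality(net: GeneNetwork, gene: str) -> float:
    """Weighted degree: the sum of the gene's incident edge weights."""
    return float(net.degree_vector()[net.index_of(gene)])


def set_centrality(net: GeneNetwork, s: GeneSet) -> float:
    """Average centrality over the set's in-network members."""
    idx = net.indices_of(s.members)
    if idx.size == 0:
        raise ValueError(f"gene set {s.id!r} has no member in the network")
    return float(net.degree_vector()[idx].mean())


def network_coverage(net: GeneNetwork, s: GeneSet) -> float:
    """Fraction of the set's members contained in the network."""
    return len(s.in_network(net)) / len(s.members)
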