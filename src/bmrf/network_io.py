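"""Reading and writing networks, annotations and prediction tables.

The central in-memory containers are :class:`ProteinNetwork` (an undirected
simple graph over protein identifiers, stored in CSR form for fast neighbor
iteration), :class:`AnnotationTable` (protein -> set of functional terms) and
trilean label vectors.  A label vector is a plain ``int8`` numpy array aligned
with the network's node order, with values :data:`POS` (1), :data:`NEG` (0)
and :data:`UNKNOWN` (-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Node carries the term of interest.
POS: int = 1
#: Node is annotated, but not with the term of interest.
NEG: int = 0
#: Node is unannotated (or masked); its state is to be inferred.
UNKNOWN: int = -1


class ConfigurationError(ValueError):
    """Inconsistent options (e.g. a threshold without a weight column)."""


class ParseError(ValueError):
    """Malformed input line; the message names the offending line number."""


class ProteinNetwork:
    """Undirected simple graph over protein identifiers.

    Parameters
    ----------
    nodes:
        Ordered iterable of unique node identifiers.
    edges:
        Iterable of ``(u, v)`` identifier pairs.  Self-loops and duplicate
        (unordered) pairs are rejected here; the file reader sanitises its
        input before construction.
    weights:
        Optional mapping from unordered pair (any orientation) to a real
        confidence score, e.g. a purification-enrichment (PE) score.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        weights: Mapping[tuple[str, str], float] | None = None,
    ) -> None:
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        seen: set[tuple[int, int]] = set()
        pairs: list[tuple[int, int]] = []
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            try:
                i, j = self.index[u], self.index[v]
            except KeyError as exc:
                raise ValueError(f"edge endpoint {exc} not in nodes") from exc
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)
            pairs.append(key)
        self._edge_index = np.array(sorted(seen), dtype=np.int64).reshape(-1, 2)
        self.weights: dict[tuple[str, str], float] = {}
        if weights is not None:
            for (u, v), w in weights.items():
                i, j = self.index[u], self.index[v]
                key = (min(i, j), max(i, j))
                if key not in seen:
                    raise ValueError(f"weight for non-edge ({u!r}, {v!r})")
                self.weights[self._canonical(u, v)] = float(w)
        n = len(self.nodes)
        if self._edge_index.size:
            rows = np.concatenate([self._edge_index[:, 0], self._edge_index[:, 1]])
            cols = np.concatenate([self._edge_index[:, 1], self._edge_index[:, 0]])
            data = np.ones(rows.shape[0], dtype=np.int8)
            self.adjacency = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        else:
            self.adjacency = sp.csr_matrix((n, n), dtype=np.int8)

    def _canonical(self, u: str, v: str) -> tuple[str, str]:
        i, j = self.index[u], self.index[v]
        return (u, v) if i < j else (v, u)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self._edge_index.shape[0]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(self.nodes[i], self.nodes[j]) for i, j in self._edge_index]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def neighbors(self, node: str) -> list[str]:
        i = self.index[node]
        row = self.adjacency.indices[self.adjacency.indptr[i]:self.adjacency.indptr[i + 1]]
        return [self.nodes[j] for j in row]

    def neighbor_indices(self, i: int) -> np.ndarray:
        return self.adjacency.indices[self.adjacency.indptr[i]:self.adjacency.indptr[i + 1]]

    def has_edge(self, u: str, v: str) -> bool:
        i, j = self.index[u], self.index[v]
        return bool(self.adjacency[i, j])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v in self.edges:
            w = self.weights.get(self._canonical(u, v))
            if w is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, weight=w)
        return g


@dataclass
class AnnotationTable:
    """Protein -> set-of-terms assignments.

    ``unknown_marker`` designates a term (e.g. "biological process unknown")
    whose carriers are treated as unannotated.  A protein carrying the marker
    alongside real terms keeps the real terms; the marker is ignored for it.
    """

    assignments: dict[str, set[str]] = field(default_factory=dict)
    unknown_marker: str | None = None

    def terms_of(self, protein: str) -> set[str]:
        return self.assignments.get(protein, set())

    def is_unannotated(self, protein: str) -> bool:
        terms = self.assignments.get(protein)
        if not terms:
            return True
        if self.unknown_marker is not None and terms == {self.unknown_marker}:
            return True
        return False

    def effective_terms(self, protein: str) -> set[str]:
        """Terms of *protein* with the unknown marker stripped."""
        terms = set(self.assignments.get(protein, set()))
        if self.unknown_marker is not None and self.unknown_marker in terms:
            if len(terms) > 1:
                logger.warning(
                    "protein %s carries the unknown marker alongside other "
                    "terms; marker ignored", protein,
                )
            terms.discard(self.unknown_marker)
        return terms


def read_edge_list(
    path,
    weight_column: int | None = None,
    threshold: float | None = None,
) -> ProteinNetwork:
    """Read a whitespace/tab-delimited edge list into a :class:`ProteinNetwork`.

    Lines starting with ``#`` are comments.  If *threshold* is given, edges
    with weight <= threshold are dropped (strictly-greater weights are kept,
    i.e. "PE score larger than" semantics).  Duplicate unordered pairs are
    collapsed keeping the maximum weight; self-loops are dropped and counted
    in a log message.
    """
    if threshold is not None and weight_column is None:
        raise ConfigurationError("threshold given without weight_column")
    best: dict[tuple[str, str], float | None] = {}
    n_self_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ParseError(f"line {lineno}: fewer than 2 columns")
            u, v = cols[0], cols[1]
            w: float | None = None
            if weight_column is not None:
                if weight_column >= len(cols):
                    raise ParseError(
                        f"line {lineno}: no column {weight_column} for weight"
                    )
                w = float(cols[weight_column])
            if u == v:
                n_self_loops += 1
                continue
            key = (u, v) if u <= v else (v, u)
            if key in best:
                prev = best[key]
                if w is not None and (prev is None or w > prev):
                    best[key] = w
            else:
                best[key] = w
    if n_self_loops:
        logger.info("dropped %d self-loop(s)", n_self_loops)
    if threshold is not None:
        best = {k: w for k, w in best.items() if w is not None and w > threshold}
    node_order: list[str] = []
    seen_nodes: set[str] = set()
    for u, v in best:
        for x in (u, v):
            if x not in seen_nodes:
                seen_nodes.add(x)
                node_order.append(x)
    weights = {k: w for k, w in best.items() if w is not None}
    return ProteinNetwork(node_order, best.keys(), weights or None)


def write_edge_list(path, network: ProteinNetwork, header_comment: str | None = None) -> None:
    """Write a network back out as a TSV edge list (weights if present)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# proteinA\tproteinB" + ("\tscore" if network.weights else "") + "\n")
        for u, v in network.edges:
            w = network.weights.get(network._canonical(u, v))
            if w is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:g}\n")


_GAF_ASPECT_COL = 8
_GAF_SYMBOL_COL = 2
_GAF_GOID_COL = 4


def read_annotations(
    path,
    format: str = "tsv2col",
    aspect: str | None = None,
    unknown_marker: str | None = None,
) -> AnnotationTable:
    """Read protein->term annotations.

    ``format='tsv2col'``: two tab/whitespace-separated columns (protein, term),
    ``#`` comments.  ``format='gaf'``: GAF 2.x, ``!`` comments; the DB Object
    Symbol (column 3) and GO ID (column 5) are used, optionally restricted to
    one *aspect* letter (column 9, e.g. ``"P"``).
    """
    assignments: dict[str, set[str]] = {}
    if format == "tsv2col":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split()
                if len(cols) < 2:
                    raise ParseError(f"line {lineno}: fewer than 2 columns")
                assignments.setdefault(cols[0], set()).add(cols[1])
    elif format == "gaf":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) <= _GAF_GOID_COL:
                    raise ParseError(f"line {lineno}: too few GAF columns")
                if aspect is not None:
                    if len(cols) <= _GAF_ASPECT_COL or cols[_GAF_ASPECT_COL] != aspect:
                        continue
                assignments.setdefault(cols[_GAF_SYMBOL_COL], set()).add(
                    cols[_GAF_GOID_COL]
                )
    else:
        raise ConfigurationError(f"unknown annotation format {format!r}")
    return AnnotationTable(assignments, unknown_marker=unknown_marker)


def build_label_vector(
    network: ProteinNetwork,
    annotations: AnnotationTable,
    term: str,
) -> np.ndarray:
    """Trilean label vector for one term, aligned with ``network.nodes``.

    POS if the protein carries *term*; UNKNOWN if it is unannotated (no
    assignment row, or only the unknown marker); NEG otherwise (annotated to
    at least one other term).
    """
    labels = np.empty(network.n_nodes, dtype=np.int8)
    for i, node in enumerate(network.nodes):
        terms = annotations.effective_terms(node)
        if term in terms:
            labels[i] = POS
        elif not terms:
            labels[i] = UNKNOWN
        else:
            labels[i] = NEG
    return labels


def write_predictions(
    path,
    rows: Sequence[tuple[str, str, float]],
    header_comment: str | None = None,
) -> None:
    """Write a prediction table [protein, term, posterior, rank] as TSV.

    Ranks are dense and per-term: 1 = highest posterior; ties are broken by
    lexicographic protein identifier.
    """
    for _, _, p in rows:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"posterior probability {p} outside [0, 1]")
    by_term: dict[str, list[tuple[str, float]]] = {}
    term_order: list[str] = []
    for protein, term, p in rows:
        if term not in by_term:
            by_term[term] = []
            term_order.append(term)
        by_term[term].append((protein, p))
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("protein\tterm\tposterior\trank\n")
        for term in term_order:
            ranked = sorted(by_term[term], key=lambda pr: (-pr[1], pr[0]))
            for rank, (protein, p) in enumerate(ranked, start=1):
                fh.write(f"{protein}\t{term}\t{p:.6g}\t{rank}\n")
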