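"""PPI network, drug-target, and pathway ingestion.

Loads the three data layers the predictor runs on:

* an undirected protein-protein interaction (PPI) network given as a
  two-column tab-separated edge list (HIPPIE/HPRD style), with an optional
  numeric confidence column;
* drug-target associations as a two-column TSV (drug id, protein id);
* pathway gene sets in GMT format (KEGG style).

Node ordering is fixed lexicographically at load time so that every
downstream vector and matrix is aligned identically across runs and
platforms. Edge confidence, when present, is used only for optional
filtering at ingest; the random walk itself runs on the binary adjacency.
"""

from __future__ import annotations

import gzip
import logging
from collections.abc import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "InputFormatError",
    "PPINetwork",
    "TransitionMatrix",
    "DrugTargetMap",
    "PathwayCollection",
    "load_ppi_edgelist",
    "row_normalize",
    "load_drug_targets",
    "restrict_to_network",
    "load_pathways",
]


class InputFormatError(ValueError):
    """An input file violates its expected format."""


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


class PPINetwork:
    """Undirected network over protein identifiers.

    Edges are stored once per unordered pair; nodes exist only through
    edges, so every node has degree >= 1 by construction. ``nodes`` is the
    lexicographically sorted identifier tuple and ``node_index`` maps each
    identifier to its position 0..N-1.
    """

    def __init__(self, edges: Iterable[tuple[str, str]]):
        canon = {(a, b) if a <= b else (b, a) for a, b in ((str(x), str(y)) for x, y in edges)}
        if not canon:
            raise InputFormatError("network has no edges")
        self.edges: frozenset[tuple[str, str]] = frozenset(canon)
        self.nodes: tuple[str, ...] = tuple(sorted({n for e in canon for n in e}))
        self.node_index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        self._adj: sp.csr_matrix | None = None
        self._nx: nx.Graph | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.node_index

    def __eq__(self, other) -> bool:
        return isinstance(other, PPINetwork) and self.edges == other.edges

    def __hash__(self):  # edges fully determine the network
        return hash(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency in CSR form, aligned to ``nodes``."""
        if self._adj is None:
            rows, cols = [], []
            for a, b in self.edges:
                i, j = self.node_index[a], self.node_index[b]
                rows.append(i)
                cols.append(j)
                if i != j:
                    rows.append(j)
                    cols.append(i)
            n = self.n_nodes
            data = np.ones(len(rows))
            self._adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        return self._adj

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def to_networkx(self) -> nx.Graph:
        if self._nx is None:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            g.add_edges_from(self.edges)
            self._nx = g
        return self._nx


class TransitionMatrix:
    """Row-stochastic transition weights of the walk on a :class:`PPINetwork`.

    Row i holds the probabilities of stepping from protein i to each
    neighbour: 1/degree(i) on neighbours, 0 elsewhere.
    """

    def __init__(self, nodes: tuple[str, ...], matrix: sp.csr_matrix):
        self.nodes = nodes
        self.matrix = matrix
        self._op: sp.csr_matrix | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def operator(self) -> sp.csr_matrix:
        """W^T in CSR form — the column-stochastic propagation operator."""
        if self._op is None:
            self._op = self.matrix.T.tocsr()
        return self._op


def row_normalize(network: PPINetwork) -> TransitionMatrix:
    """Degree-normalize the adjacency into the walk's transition matrix.

    Entry (i, j) is 1/degree(i) when {i, j} is an edge and 0 otherwise, so
    every row sums to 1 and the walk conserves probability mass.

    Raises
    ------
    ValueError
        If any node has degree zero (precluded by the loader defaults,
        which admit nodes only through edges).
    """
    adj = network.adjacency()
    deg = network.degrees()
    if np.any(deg == 0):
        zero = [network.nodes[i] for i in np.flatnonzero(deg == 0)]
        raise ValueError(f"cannot normalize: zero-degree nodes {zero[:5]}")
    inv = sp.diags(1.0 / deg)
    return TransitionMatrix(network.nodes, (inv @ adj).tocsr())


_HEADER_TOKENS = {
    "protein_a", "protein_b", "protein1", "protein2", "proteina", "proteinb",
    "node1", "node2", "node_a", "node_b", "gene_a", "gene_b", "gene1", "gene2",
    "source", "target", "from", "to", "id_a", "id_b", "interactor_a",
    "interactor_b", "drug", "drug_id", "protein", "protein_id", "drug_a",
    "drug_b", "confidence", "score", "weight",
}


def _is_header(fields: list[str]) -> bool:
    lowered = [f.strip().lower() for f in fields]
    if any(f in _HEADER_TOKENS for f in lowered):
        return True
    if len(fields) >= 3 and fields[2].strip():
        try:
            float(fields[2])
        except ValueError:
            return True
    return False


def load_ppi_edgelist(
    path,
    *,
    keep_self_loops: bool = False,
    min_confidence: float | None = None,
    header: bool | str = "auto",
) -> PPINetwork:
    """Load an undirected PPI network from a tab-separated edge list.

    Parameters
    ----------
    path
        TSV with at least two protein-identifier columns and an optional
        third numeric confidence column; ``.gz`` paths are decompressed.
    keep_self_loops
        Self-interactions (same identifier twice) are dropped by default:
        PPI resources typically record them as artifacts, and they distort
        degree normalization.
    min_confidence
        If given, rows whose confidence column is below this value are
        dropped. Rows without a confidence value are kept.
    header
        ``"auto"`` (default) skips the first line when it looks like a
        header; ``True``/``False`` force the decision.

    Counts of dropped records (self-loops, low-confidence rows, duplicate
    pairs) are reported through the module logger so data loss is auditable.
    """
    edges: list[tuple[str, str]] = []
    dropped_self = dropped_conf = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and (header is True or (header == "auto" and _is_header(fields))):
                continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise InputFormatError(
                    f"{path}: line {lineno}: expected at least two tab-separated identifiers"
                )
            a, b = fields[0].strip(), fields[1].strip()
            conf = None
            if len(fields) >= 3 and fields[2].strip():
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise InputFormatError(
                        f"{path}: line {lineno}: confidence column is not numeric"
                    ) from exc
            if min_confidence is not None and conf is not None and conf < min_confidence:
                dropped_conf += 1
                continue
            if a == b and not keep_self_loops:
                dropped_self += 1
                continue
            edges.append((a, b))
    if not edges:
        raise InputFormatError(f"{path}: no edges remain after filtering")
    net = PPINetwork(edges)
    dup = len(edges) - net.n_edges
    logger.info(
        "loaded %s: %d nodes, %d edges (dropped %d self-loops, %d low-confidence, %d duplicates)",
        path, net.n_nodes, net.n_edges, dropped_self, dropped_conf, dup,
    )
    return net


class DrugTargetMap(Mapping):
    """Mapping from drug identifier to its nonempty set of target proteins."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        data = {}
        for drug, prots in mapping.items():
            pset = frozenset(str(p) for p in prots)
            if pset:
                data[str(drug)] = pset
        self._data: dict[str, frozenset[str]] = dict(sorted(data.items()))

    def __getitem__(self, drug: str) -> frozenset[str]:
        return self._data[drug]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other) -> bool:
        if isinstance(other, DrugTargetMap):
            return self._data == other._data
        return NotImplemented

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self._data)

    @property
    def n_associations(self) -> int:
        return sum(len(v) for v in self._data.values())


def load_drug_targets(path) -> DrugTargetMap:
    """Load drug-target associations from a two-column TSV.

    Duplicate (drug, protein) rows are collapsed; the distinct association
    count is logged. An empty file yields an empty map with a warning.
    """
    assoc: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and _is_header(fields[:2]):
                continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise InputFormatError(
                    f"{path}: line {lineno}: expected drug and protein identifiers"
                )
            assoc.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    tmap = DrugTargetMap(assoc)
    if len(tmap) == 0:
        logger.warning("%s: no drug-target associations found", path)
    else:
        logger.info("loaded %s: %d drugs, %d associations", path, len(tmap), tmap.n_associations)
    return tmap


def restrict_to_network(
    targets: DrugTargetMap, network: PPINetwork, drop_drugs_below: int = 1
) -> DrugTargetMap:
    """Keep only targets that are network nodes; drop drugs left too small.

    Drugs retaining fewer than ``drop_drugs_below`` in-network targets are
    removed entirely (they cannot seed a walk). The operation is idempotent
    and all removals are logged.
    """
    kept: dict[str, frozenset[str]] = {}
    removed_targets = 0
    removed_drugs = []
    for drug, prots in targets.items():
        inside = frozenset(p for p in prots if p in network)
        removed_targets += len(prots) - len(inside)
        if len(inside) >= drop_drugs_below and inside:
            kept[drug] = inside
        else:
            removed_drugs.append(drug)
    if removed_targets or removed_drugs:
        logger.info(
            "restricted to network: dropped %d off-network targets, removed %d drugs: %s",
            removed_targets, len(removed_drugs), ",".join(removed_drugs[:10]),
        )
    if not kept:
        logger.warning("no drugs retain in-network targets")
    return DrugTargetMap(kept)


class PathwayCollection(Mapping):
    """Mapping from pathway identifier to its member protein set."""

    def __init__(self, sets: Mapping[str, Iterable[str]], names: Mapping[str, str] | None = None):
        data = {str(k): frozenset(str(p) for p in v) for k, v in sets.items()}
        for k, v in data.items():
            if not v:
                raise ValueError(f"pathway {k!r} has no members")
        self._data = dict(sorted(data.items()))
        self.names = dict(names or {})

    def __getitem__(self, key: str) -> frozenset[str]:
        return self._data[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def membership_index(self) -> dict[str, frozenset[str]]:
        """Invert the collection: protein -> pathway ids containing it."""
        idx: dict[str, set[str]] = {}
        for pw, members in self._data.items():
            for p in members:
                idx.setdefault(p, set()).add(pw)
        return {p: frozenset(s) for p, s in idx.items()}


def load_pathways(path) -> PathwayCollection:
    """Load gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}: line {lineno}: GMT lines need name, description and >=1 member"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(f.strip() for f in fields[2:] if f.strip())
            if not members:
                raise InputFormatError(f"{path}: line {lineno}: pathway {name!r} has no members")
            sets[name] = members
            names[name] = desc
    logger.info("loaded %s: %d pathways", path, len(sets))
    return PathwayCollection(sets, names)
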