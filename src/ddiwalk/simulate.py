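"""Synthetic benchmark generation: networks, drugs, pathways, planted pairs.

Everything the pipeline consumes can be generated here with controllable
structure and full seed reproducibility, so the predictor is testable end
to end without any external database. The generator emulates the shape of
real inputs — a sparse, heavy-tailed interactome; drugs with one to a few
targets, optionally clustered in a network neighbourhood; pathways as
connected regions of the graph — and plants positive drug pairs that
satisfy the pharmacodynamic gold-standard rule by construction:

* ``shared_target`` — the two drugs hit at least one common protein;
* ``shared_pathway`` — targets disjoint but co-member of some pathway;
* ``cross_talk`` — targets disjoint AND in different pathways, yet linked
  by short network paths. These are the pairs a shortest-path baseline
  systematically under-ranks and that signal propagation should recover.

Pathways are generated as BFS balls around random centers so that "same
pathway" correlates with network proximity, mirroring the modularity of
curated pathway collections.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .evaluation import GoldStandard
from .network import DrugTargetMap, PathwayCollection, PPINetwork, load_pathways, load_ppi_edgelist, load_drug_targets

logger = logging.getLogger(__name__)

__all__ = [
    "BundleConfig",
    "BenchmarkBundle",
    "generate_network",
    "generate_pathways",
    "assign_drugs",
    "plant_positives",
    "generate_bundle",
    "write_bundle",
    "read_bundle",
]

PLANT_MODES = ("shared_target", "shared_pathway", "cross_talk")


@dataclass(frozen=True)
class BundleConfig:
    """Generation parameters of one benchmark bundle.

    Defaults describe a desk-scale interactome: a 500-protein
    preferential-attachment graph (2 edges per arriving node, giving the
    heavy-tailed degree profile of curated PPI data), 40 drugs with 1-4
    targets drawn mostly within a 2-hop neighbourhood (clustering 0.8,
    since real targets of one drug tend to be co-complex or co-pathway),
    10 pathways as radius-2 BFS balls — few enough that every planting
    mode keeps a comfortable pool of eligible pairs at this graph size —
    and 60 planted positive pairs.
    """

    n_nodes: int = 500
    model: str = "preferential_attachment"  # or "erdos_renyi"
    density: float = 2.0  # BA: edges per new node; ER: edge probability
    n_drugs: int = 40
    targets_min: int = 1
    targets_max: int = 4
    clustering: float = 0.8
    n_pathways: int = 10
    pathway_radius: int = 2
    pathway_max_size: int = 40
    n_positive: int = 60
    mode: str = "cross_talk"
    hops: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.mode not in PLANT_MODES:
            raise ValueError(f"mode must be one of {PLANT_MODES}")
        if self.n_nodes < 2 or self.n_drugs < 2:
            raise ValueError("need at least 2 nodes and 2 drugs")
        if not 1 <= self.targets_min <= self.targets_max:
            raise ValueError("invalid target count range")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering must be in [0, 1]")


@dataclass
class BenchmarkBundle:
    network: PPINetwork
    targets: DrugTargetMap
    pathways: PathwayCollection
    gold: GoldStandard
    config: BundleConfig


def _relabel(g: nx.Graph, width: int) -> PPINetwork:
    nodes = sorted(g.nodes())
    label = {n: f"P{idx + 1:0{width}d}" for idx, n in enumerate(nodes)}
    return PPINetwork([(label[a], label[b]) for a, b in g.edges() if a != b])


def generate_network(
    n_nodes: int,
    model: str = "preferential_attachment",
    density: float = 2.0,
    seed: int = 0,
) -> PPINetwork:
    """Random graph reduced to its largest connected component.

    ``density`` is the attachment count m for the preferential-attachment
    model and the edge probability p for Erdos-Renyi. Node labels are
    zero-padded ("P001", ...) so lexicographic node order matches the
    generation order. The retained component's actual size is logged.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if model == "preferential_attachment":
        m = max(1, int(round(density)))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "erdos_renyi":
        g = nx.gnp_random_graph(n_nodes, float(density), seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    if g.number_of_edges() == 0:
        raise ValueError("generated graph has no edges; increase density")
    largest = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    g = g.subgraph(largest).copy()
    net = _relabel(g, width=len(str(n_nodes)))
    if net.n_nodes < n_nodes:
        logger.info("largest component retained: %d of %d nodes", net.n_nodes, n_nodes)
    return net


def generate_pathways(
    network: PPINetwork,
    n_pathways: int = 10,
    radius: int = 2,
    seed: int = 0,
    max_size: int = 40,
) -> PathwayCollection:
    """Pathways as BFS balls of the given radius around random centers.

    A ball centered near a hub can swallow a large share of a small graph,
    which no curated pathway does, so each ball is truncated to ``max_size``
    members keeping the closest nodes first (ties broken lexicographically).
    """
    rng = np.random.default_rng(seed)
    g = network.to_networkx()
    nodes = list(network.nodes)
    centers = rng.choice(len(nodes), size=min(n_pathways, len(nodes)), replace=False)
    width = len(str(n_pathways))
    sets = {}
    for idx, ci in enumerate(sorted(centers)):
        ball = nx.single_source_shortest_path_length(g, nodes[ci], cutoff=radius)
        ranked = sorted(ball, key=lambda p: (ball[p], p))
        sets[f"PW{idx + 1:0{width}d}"] = frozenset(ranked[:max_size])
    return PathwayCollection(sets, {k: f"ball around center {k}" for k in sets})


def assign_drugs(
    network: PPINetwork,
    n_drugs: int = 40,
    targets_per_drug: tuple[int, int] = (1, 4),
    clustering: float = 0.8,
    seed: int = 0,
) -> DrugTargetMap:
    """Draw each drug's target set, optionally localized on the network.

    Each drug gets a uniform target count in ``targets_per_drug``. Its
    first target seeds the set; each further target is drawn from the
    2-hop BFS ball around that seed with probability ``clustering`` and
    uniformly from the whole network otherwise. At clustering 1 every
    multi-target drug is fully local; at 0 targets are uniform.
    """
    lo, hi = targets_per_drug
    if not 1 <= lo <= hi <= network.n_nodes:
        raise ValueError("infeasible target count range")
    rng = np.random.default_rng(seed)
    g = network.to_networkx()
    nodes = list(network.nodes)
    width = len(str(n_drugs))
    mapping = {}
    for d in range(n_drugs):
        k = int(rng.integers(lo, hi + 1))
        anchor = nodes[int(rng.integers(len(nodes)))]
        ball = sorted(nx.single_source_shortest_path_length(g, anchor, cutoff=2))
        chosen = {anchor}
        while len(chosen) < k:
            if rng.random() < clustering and len(ball) > len(chosen & set(ball)):
                pick = ball[int(rng.integers(len(ball)))]
            else:
                pick = nodes[int(rng.integers(len(nodes)))]
            chosen.add(pick)
        mapping[f"D{d + 1:0{width}d}"] = frozenset(chosen)
    return DrugTargetMap(mapping)


def _min_cross_distance(
    ta: frozenset[str], tb: frozenset[str], ball_index: dict[str, dict[str, int]]
) -> int | None:
    """Smallest hop count between the two target sets, within the cutoff."""
    best = None
    for p in ta:
        lengths = ball_index[p]
        for q in tb:
            d = lengths.get(q)
            if d is not None and (best is None or d < best):
                best = d
    return best


def plant_positives(
    targets: DrugTargetMap,
    pathways: PathwayCollection,
    n_positive: int,
    mode: str = "cross_talk",
    seed: int = 0,
    network: PPINetwork | None = None,
    hops: int = 2,
) -> GoldStandard:
    """Sample positive pairs from those eligible under the chosen mode.

    The universe is every unordered drug pair. Eligibility:
    ``shared_target`` — nonempty target intersection; ``shared_pathway`` —
    disjoint targets, some pathway holding a target of each;
    ``cross_talk`` — disjoint targets, no shared pathway, and minimum
    cross-target distance at most ``hops`` (requires ``network``).
    Raises with the achievable count when fewer pairs are eligible.
    """
    if mode not in PLANT_MODES:
        raise ValueError(f"mode must be one of {PLANT_MODES}")
    drugs = sorted(targets)
    pw_index = pathways.membership_index()

    def drug_pathways(d: str) -> frozenset[str]:
        out: set[str] = set()
        for p in targets[d]:
            out |= pw_index.get(p, frozenset())
        return frozenset(out)

    pws = {d: drug_pathways(d) for d in drugs}
    ball_index: dict[str, dict[str, int]] = {}
    if mode == "cross_talk":
        if network is None:
            raise ValueError("cross_talk mode requires the network")
        g = network.to_networkx()
        for p in sorted(set().union(*(targets[d] for d in drugs))):
            ball_index[p] = dict(nx.single_source_shortest_path_length(g, p, cutoff=hops))

    universe = [(drugs[i], drugs[j]) for i in range(len(drugs)) for j in range(i + 1, len(drugs))]
    eligible = []
    for a, b in universe:
        shared_t = bool(targets[a] & targets[b])
        shared_pw = bool(pws[a] & pws[b])
        if mode == "shared_target":
            ok = shared_t
        elif mode == "shared_pathway":
            ok = (not shared_t) and shared_pw
        else:
            ok = (
                not shared_t
                and not shared_pw
                and _min_cross_distance(targets[a], targets[b], ball_index) is not None
            )
        if ok:
            eligible.append((a, b))
    if len(eligible) < n_positive:
        raise ValueError(
            f"only {len(eligible)} pairs eligible for mode {mode!r}, "
            f"cannot plant {n_positive}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n_positive, replace=False)
    positives = frozenset(eligible[i] for i in sorted(picked))
    return GoldStandard(positives, frozenset(universe), f"planted:{mode}")


def generate_bundle(config: BundleConfig = BundleConfig()) -> BenchmarkBundle:
    """Generate a full benchmark: network, drugs, pathways, planted gold.

    Sub-seeds for the network, target, pathway, and planting stages are
    derived deterministically from ``config.seed``, so a bundle is fully
    reproducible from its config alone.
    """
    base = int(config.seed)
    network = generate_network(config.n_nodes, config.model, config.density, seed=base)
    pathways = generate_pathways(
        network,
        config.n_pathways,
        config.pathway_radius,
        seed=base + 1,
        max_size=config.pathway_max_size,
    )
    targets = assign_drugs(
        network,
        config.n_drugs,
        (config.targets_min, config.targets_max),
        config.clustering,
        seed=base + 2,
    )
    gold = plant_positives(
        targets,
        pathways,
        config.n_positive,
        config.mode,
        seed=base + 3,
        network=network,
        hops=config.hops,
    )
    return BenchmarkBundle(network, targets, pathways, gold, config)


def write_bundle(bundle: BenchmarkBundle, out_dir) -> dict[str, Path]:
    """Write a bundle in the pipeline's standard on-disk formats.

    Emits edges.tsv (edge list), targets.tsv, pathways.gmt, gold.tsv
    (positive pairs), universe.tsv (all candidate pairs) and config.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "edges.tsv",
        "targets": out / "targets.tsv",
        "pathways": out / "pathways.gmt",
        "gold": out / "gold.tsv",
        "universe": out / "universe.tsv",
        "config": out / "config.yaml",
    }
    with open(paths["network"], "w") as fh:
        for a, b in sorted(bundle.network.edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["targets"], "w") as fh:
        for drug in bundle.targets:
            for p in sorted(bundle.targets[drug]):
                fh.write(f"{drug}\t{p}\n")
    with open(paths["pathways"], "w") as fh:
        for pw in bundle.pathways:
            members = "\t".join(sorted(bundle.pathways[pw]))
            fh.write(f"{pw}\t{bundle.pathways.names.get(pw, '')}\t{members}\n")
    with open(paths["gold"], "w") as fh:
        for a, b in sorted(bundle.gold.positives):
            fh.write(f"{a}\t{b}\n")
    with open(paths["universe"], "w") as fh:
        for a, b in sorted(bundle.gold.universe):
            fh.write(f"{a}\t{b}\n")
    with open(paths["config"], "w") as fh:
        cfg = dataclasses.asdict(bundle.config)
        cfg["provenance"] = bundle.gold.provenance
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def read_bundle(in_dir) -> BenchmarkBundle:
    """Read a bundle written by :func:`write_bundle` back into memory."""
    d = Path(in_dir)
    with open(d / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    provenance = raw.pop("provenance", "")
    config = BundleConfig(**raw)
    network = load_ppi_edgelist(d / "edges.tsv", header=False)
    targets = load_drug_targets(d / "targets.tsv")
    pathways = load_pathways(d / "pathways.gmt")
    positives = frozenset(load_pairs(d / "gold.tsv"))
    universe = frozenset(load_pairs(d / "universe.tsv"))
    gold = GoldStandard(positives, universe, provenance)
    return BenchmarkBundle(network, targets, pathways, gold, config)


def load_pairs(path) -> list[tuple[str, str]]:
    """Load unordered drug pairs from a two-column TSV."""
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: line {lineno}: expected two drug identifiers")
            a, b = fields[0].strip(), fields[1].strip()
            pairs.append((a, b) if a <= b else (b, a))
    return pairs
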