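"""Genome-ortholog bipartite network construction and community detection.

Gene sharing among viral genomes is summarized as a bipartite graph linking
genome nodes to ortholog-cluster nodes (edge weight = number of member
proteins the genome contributes). Communities are found by greedy
optimization of Barber's bipartite modularity

    Q_B = (1/m) * sum_ij (A_ij - k_i * d_j / m) * delta(c_i, c_j)

with A the genome x ortholog weight matrix, k and d the two classes' degree
vectors and m the total edge weight. The optimizer alternates Louvain-style
local-move sweeps over the genome class and the ortholog class (sequential
mode), interleaved with community-merge steps, and is deterministic for a
given seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)


@dataclass
class BipartiteGraph:
    genomes: list[str]
    orthologs: list[str]
    graph: nx.Graph = field(repr=False)

    @property
    def total_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def weight(self, genome: str, ortholog: str) -> float:
        if self.graph.has_edge(genome, ortholog):
            return self.graph[genome][ortholog]["weight"]
        return 0.0


@dataclass
class CommunityAssignment:
    membership: dict[str, int]
    barber_modularity: float
    n_genome_communities: int
    n_ortholog_communities: int
    seed: int


def _as_frame(table, columns) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        df.columns = list(columns) + list(df.columns[len(columns):])
        return df
    df = pd.read_csv(table, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"membership table missing columns {missing}")
    return df


def build_graph(
    membership, genome_map, min_cluster_size: int = 10
) -> BipartiteGraph:
    """Build the genome-ortholog graph from protein membership tables.

    ``membership`` maps protein_id -> ortholog_id (two-column TSV or frame);
    ``genome_map`` maps protein_id -> genome_id. Ortholog clusters with fewer
    than ``min_cluster_size`` member proteins are excluded before edges are
    built. A protein assigned to two genomes is a hard error.
    """
    mem = _as_frame(membership, ["protein_id", "ortholog_id"])
    gen = _as_frame(genome_map, ["protein_id", "genome_id"])
    conflicts = gen.groupby("protein_id")["genome_id"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise ValueError(f"protein(s) assigned to multiple genomes: {list(bad.index)[:5]}")
    genome_of = dict(zip(gen["protein_id"], gen["genome_id"]))
    unknown = [p for p in mem["protein_id"] if p not in genome_of]
    if unknown:
        raise ValueError(f"protein(s) without genome assignment: {unknown[:5]}")

    sizes = mem.groupby("ortholog_id")["protein_id"].count()
    keep = set(sizes[sizes >= min_cluster_size].index)
    n_excluded = len(sizes) - len(keep)
    if n_excluded:
        logger.info(
            "excluded %d ortholog clusters with < %d proteins",
            n_excluded,
            min_cluster_size,
        )
    g = nx.Graph()
    genomes: dict[str, None] = {}
    orthologs: dict[str, None] = {}
    for _, row in mem.iterrows():
        o = row["ortholog_id"]
        if o not in keep:
            continue
        gm = genome_of[row["protein_id"]]
        gnode, onode = f"genome::{gm}", f"og::{o}"
        genomes.setdefault(gnode)
        orthologs.setdefault(onode)
        if g.has_edge(gnode, onode):
            g[gnode][onode]["weight"] += 1
        else:
            g.add_edge(gnode, onode, weight=1)
    for n in genomes:
        g.nodes[n]["bipartite"] = 0
    for n in orthologs:
        g.nodes[n]["bipartite"] = 1
    return BipartiteGraph(list(genomes), list(orthologs), g)


def barber_modularity(
    graph: BipartiteGraph, membership: dict[str, int], resolution: float = 1.0
) -> float:
    """Recompute Q_B for an assignment (independent of the optimizer state)."""
    m = graph.total_weight
    if m == 0:
        raise ValueError("graph has no edges")
    k = {g: sum(d["weight"] for _, _, d in graph.graph.edges(g, data=True))
         for g in graph.genomes}
    d = {o: sum(dd["weight"] for _, _, dd in graph.graph.edges(o, data=True))
         for o in graph.orthologs}
    q = 0.0
    for g in graph.genomes:
        cg = membership[g]
        for o in graph.orthologs:
            if membership[o] != cg:
                continue
            q += graph.weight(g, o) - resolution * k[g] * d[o] / m
    return q / m


class _State:
    """Mutable community bookkeeping for the optimizer."""

    def __init__(self, graph: BipartiteGraph, resolution: float):
        self.m = graph.total_weight
        self.resolution = resolution
        self.adj: dict[str, dict[str, float]] = {}
        for n in itertools.chain(graph.genomes, graph.orthologs):
            self.adj[n] = {
                nb: d["weight"] for _, nb, d in graph.graph.edges(n, data=True)
            }
        self.k = {n: sum(w.values()) for n, w in self.adj.items()}
        self.is_genome = {n: True for n in graph.genomes}
        self.is_genome.update({n: False for n in graph.orthologs})
        self.comm: dict[str, int] = {}
        self.K: dict[int, float] = {}  # genome-degree mass per community
        self.D: dict[int, float] = {}  # ortholog-degree mass per community
        self.members: dict[int, set[str]] = {}
        for cid, n in enumerate(itertools.chain(graph.genomes, graph.orthologs)):
            self.comm[n] = cid
            self.members[cid] = {n}
            self.K[cid] = self.k[n] if self.is_genome[n] else 0.0
            self.D[cid] = 0.0 if self.is_genome[n] else self.k[n]

    def opposite_mass(self, node: str, cid: int) -> float:
        # cid may refer to a just-emptied community; treat it as empty
        return self.D.get(cid, 0.0) if self.is_genome[node] else self.K.get(cid, 0.0)

    def gain(self, node: str, cid: int, w_to: float) -> float:
        """Q contribution of node if placed in community cid (node removed)."""
        return (
            w_to - self.resolution * self.k[node] * self.opposite_mass(node, cid) / self.m
        ) / self.m

    def remove(self, node: str) -> int:
        cid = self.comm.pop(node)
        self.members[cid].discard(node)
        if self.is_genome[node]:
            self.K[cid] -= self.k[node]
        else:
            self.D[cid] -= self.k[node]
        if not self.members[cid]:
            del self.members[cid], self.K[cid], self.D[cid]
        return cid

    def insert(self, node: str, cid: int) -> None:
        self.comm[node] = cid
        self.members.setdefault(cid, set()).add(node)
        self.K.setdefault(cid, 0.0)
        self.D.setdefault(cid, 0.0)
        if self.is_genome[node]:
            self.K[cid] += self.k[node]
        else:
            self.D[cid] += self.k[node]

    def weights_to_communities(self, node: str) -> dict[int, float]:
        out: dict[int, float] = {}
        for nb, w in self.adj[node].items():
            c = self.comm.get(nb)
            if c is not None:
                out[c] = out.get(c, 0.0) + w
        return out

    def quality(self) -> float:
        inner = 0.0
        for n, nbrs in self.adj.items():
            if not self.is_genome[n]:
                continue
            cn = self.comm[n]
            for nb, w in nbrs.items():
                if self.comm[nb] == cn:
                    inner += w
        null = sum(
            self.resolution * self.K[c] * self.D[c] / self.m for c in self.members
        )
        return (inner - null) / self.m


_TOL = 1e-12


def _sweep(state: _State, order: list[str], fresh_id: list[int]) -> int:
    moves = 0
    for node in order:
        old = state.remove(node)
        w = state.weights_to_communities(node)
        w.setdefault(old, 0.0)
        best_cid, best_gain = None, -np.inf
        for cid in sorted(w):
            gainc = state.gain(node, cid, w[cid])
            if gainc > best_gain + _TOL:
                best_cid, best_gain = cid, gainc
        # isolating the node in a fresh community has gain exactly 0; take it
        # when every existing community is a strict loss
        if best_gain < -_TOL:
            best_cid = fresh_id[0]
            fresh_id[0] += 1
        state.insert(node, best_cid)
        if best_cid != old:
            moves += 1
    return moves


def _merge_pass(state: _State) -> int:
    """Merge community pairs with positive (or connected zero) Q gain."""
    merges = 0
    while True:
        cross: dict[tuple[int, int], float] = {}
        for n, nbrs in state.adj.items():
            if not state.is_genome[n]:
                continue
            cn = state.comm[n]
            for nb, w in nbrs.items():
                cb = state.comm[nb]
                if cn == cb:
                    continue
                key = (min(cn, cb), max(cn, cb))
                cross[key] = cross.get(key, 0.0) + w
        best_key, best_gain = None, -np.inf
        for (c1, c2), w in sorted(cross.items()):
            gain = (
                w
                - state.resolution
                * (state.K[c1] * state.D[c2] + state.K[c2] * state.D[c1])
                / state.m
            ) / state.m
            if gain > best_gain + _TOL:
                best_key, best_gain = (c1, c2), gain
        if best_key is None or best_gain < -_TOL:
            return merges
        if best_gain <= _TOL and cross[best_key] <= 0:
            return merges
        c1, c2 = best_key
        for node in list(state.members[c2]):
            state.remove(node)
            state.insert(node, c1)
        merges += 1


def detect_communities(
    graph: BipartiteGraph,
    seed: int,
    resolution: float = 1.0,
    restarts: int = 8,
) -> CommunityAssignment:
    """Optimize Barber modularity with alternating-class local moves.

    Sweeps run over all genome nodes, then all ortholog nodes, repeated until
    no single-node move improves Q_B; community merges are then attempted and
    the cycle repeats. Several restarts with different node orders (all
    derived from ``seed``) guard against shallow local optima; the best
    partition wins, ties going to the earliest restart.
    """
    if not graph.genomes and not graph.orthologs:
        raise ValueError("empty graph")
    if graph.total_weight == 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    best_membership, best_q = None, -np.inf
    for restart in range(restarts):
        g_order = list(graph.genomes)
        o_order = list(graph.orthologs)
        rng.shuffle(g_order)
        rng.shuffle(o_order)
        state = _State(graph, resolution)
        n_nodes = len(state.comm)
        if restart > 0:
            # random coarse initial partition; local moves from a randomized
            # start can cross barriers the all-singletons basin cannot
            n_groups = int(rng.integers(2, max(3, n_nodes // 2 + 1)))
            init = {
                node: int(rng.integers(n_groups)) for node in state.comm
            }
            for node, cid in init.items():
                state.remove(node)
                state.insert(node, cid)
        fresh_id = [n_nodes + 1]
        while True:
            moved = 0
            while True:
                sweep_moves = _sweep(state, g_order, fresh_id) + _sweep(
                    state, o_order, fresh_id
                )
                moved += sweep_moves
                if sweep_moves == 0:
                    break
            if _merge_pass(state) == 0 and moved == 0:
                break
        q = state.quality()
        if q > best_q + _TOL:
            best_q = q
            best_membership = dict(state.comm)
    # canonical community ids: 0..K-1 in order of first appearance
    relabel: dict[int, int] = {}
    membership: dict[str, int] = {}
    for node in itertools.chain(graph.genomes, graph.orthologs):
        c = best_membership[node]
        relabel.setdefault(c, len(relabel))
        membership[node] = relabel[c]
    n_gc = len({membership[n] for n in graph.genomes})
    n_oc = len({membership[n] for n in graph.orthologs})
    return CommunityAssignment(
        membership=membership,
        barber_modularity=barber_modularity(graph, membership, resolution),
        n_genome_communities=n_gc,
        n_ortholog_communities=n_oc,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dereplication (CD-HIT-style greedy clustering) and cluster summaries
# ---------------------------------------------------------------------------

_DEREP_ALIGNER = Align.PairwiseAligner()
_DEREP_ALIGNER.mode = "local"
_DEREP_ALIGNER.match_score = 2
_DEREP_ALIGNER.mismatch_score = -3
_DEREP_ALIGNER.open_gap_score = -5
_DEREP_ALIGNER.extend_gap_score = -2


def _similar(a: str, b: str, identity: float, coverage: float) -> bool:
    short = min(len(a), len(b))
    best = _DEREP_ALIGNER.align(a, b)[0]
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return False
    t_blocks, q_blocks = best.aligned
    span_a = int(t_blocks[-1][1] - t_blocks[0][0])
    span_b = int(q_blocks[-1][1] - q_blocks[0][0])
    span_short = span_a if len(a) <= len(b) else span_b
    return (
        counts.identities / columns >= identity and span_short / short >= coverage
    )


def dereplicate_genomes(
    sequences: dict[str, str], identity: float = 0.90, coverage: float = 0.90
) -> dict[str, list[str]]:
    """Greedy longest-first clustering of element sequences.

    A sequence joins the first (longest) representative it matches at
    >= ``identity`` over >= ``coverage`` of the shorter sequence; otherwise it
    founds a new cluster. Returns representative -> member ids (members
    include the representative). Forward strand only.
    """
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    clusters: dict[str, list[str]] = {}
    for sid in order:
        for rep in clusters:
            if _similar(sequences[sid], sequences[rep], identity, coverage):
                clusters[rep].append(sid)
                break
        else:
            clusters[sid] = [sid]
    return clusters


def summarize_clusters(
    assignment: CommunityAssignment,
    genome_markers: dict[str, set[str]],
    marker_classes: list[str] | None = None,
) -> pd.DataFrame:
    """Per genome community: member count and per-marker carrier fraction.

    ``genome_markers`` maps genome id (without the ``genome::`` prefix) to the
    set of marker classes its element encodes; fractions are the share of
    community members carrying each class.
    """
    if marker_classes is None:
        seen: list[str] = []
        for classes in genome_markers.values():
            for c in sorted(classes):
                if c not in seen:
                    seen.append(c)
        marker_classes = seen
    by_comm: dict[int, list[str]] = {}
    for node, cid in assignment.membership.items():
        if node.startswith("genome::"):
            by_comm.setdefault(cid, []).append(node.removeprefix("genome::"))
    rows = []
    for cid in sorted(by_comm):
        members = by_comm[cid]
        row = {"community": cid, "n_members": len(members)}
        for cls in marker_classes:
            n_with = sum(1 for g in members if cls in genome_markers.get(g, set()))
            row[f"frac_{cls}"] = n_with / len(members)
        rows.append(row)
    return pd.DataFrame(rows)


def write_communities(assignment: CommunityAssignment, path) -> None:
    rows = []
    for node, cid in sorted(assignment.membership.items()):
        klass, _, name = node.partition("::")
        rows.append({"node": name, "class": klass, "community": cid})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edge_list(graph: BipartiteGraph, path) -> None:
    rows = []
    for u, v, d in graph.graph.edges(data=True):
        g, o = (u, v) if u.startswith("genome::") else (v, u)
        rows.append(
            {
                "genome": g.removeprefix("genome::"),
                "ortholog": o.removeprefix("og::"),
                "weight": d["weight"],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
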