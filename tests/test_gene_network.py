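import itertools

import numpy as np
import pandas as pd
import pytest

from plvscan.gene_network import (
    barber_modularity,
    build_graph,
    dereplicate_genomes,
    detect_communities,
    summarize_clusters,
)
from plvscan.seq_io import revcomp

from .conftest import random_dna
from .oracles import barber_optimum


def _tables(assignments):
    """assignments: list of (genome, ortholog, n_proteins) triples."""
    mem, gen = [], []
    pid = 0
    for g, o, n in assignments:
        for _ in range(n):
            mem.append((f"p{pid}", o))
            gen.append((f"p{pid}", g))
            pid += 1
    return (
        pd.DataFrame(mem, columns=["protein_id", "ortholog_id"]),
        pd.DataFrame(gen, columns=["protein_id", "genome_id"]),
    )


def _blocks(n_blocks, genomes_per_block, orthologs_per_block, rng,
            p_in=0.8, p_out=0.02, copies=4):
    triples = []
    for gb in range(n_blocks):
        for g in range(genomes_per_block):
            for ob in range(n_blocks):
                for o in range(orthologs_per_block):
                    p = p_in if gb == ob else p_out
                    if rng.random() < p:
                        triples.append((f"g{gb}_{g}", f"o{ob}_{o}", copies))
    return triples


class TestBuildGraph:
    def test_small_clusters_excluded_boundary_inclusive(self):
        mem, gen = _tables([("gA", "o_small", 9), ("gA", "o_big", 10)])
        graph = build_graph(mem, gen, min_cluster_size=10)
        assert graph.orthologs == ["og::o_big"]

    def test_cluster_spread_over_ten_genomes(self):
        triples = [(f"g{i}", "oX", 1) for i in range(10)]
        mem, gen = _tables(triples)
        graph = build_graph(mem, gen, min_cluster_size=10)
        assert len(graph.genomes) == 10
        assert graph.graph.degree("og::oX") == 10

    def test_edge_weights_count_proteins(self):
        mem, gen = _tables([("gA", "oX", 7), ("gB", "oX", 3)])
        graph = build_graph(mem, gen, min_cluster_size=10)
        assert graph.weight("genome::gA", "og::oX") == 7
        assert graph.weight("genome::gB", "og::oX") == 3

    def test_random_table_recount(self):
        rng = np.random.default_rng(0)
        triples = [
            (f"g{rng.integers(5)}", f"o{rng.integers(6)}", int(rng.integers(1, 5)))
            for _ in range(60)
        ]
        mem, gen = _tables(triples)
        graph = build_graph(mem, gen, min_cluster_size=10)
        sizes = mem.groupby("ortholog_id").size()
        keep = set(sizes[sizes >= 10].index)
        counts = {}
        gmap = dict(zip(gen.protein_id, gen.genome_id))
        for pid, o in zip(mem.protein_id, mem.ortholog_id):
            if o in keep:
                counts[(gmap[pid], o)] = counts.get((gmap[pid], o), 0) + 1
        assert len(graph.orthologs) == len(keep)
        for (g, o), w in counts.items():
            assert graph.weight(f"genome::{g}", f"og::{o}") == w

    def test_protein_in_two_genomes_rejected(self):
        mem, gen = _tables([("gA", "oX", 10)])
        gen.loc[0, "genome_id"] = "gB"
        gen = pd.concat([gen, gen.iloc[[0]].assign(genome_id="gC")])
        with pytest.raises(ValueError, match="multiple genomes"):
            build_graph(mem, gen)


class TestDetectCommunities:
    def test_two_disjoint_bicliques(self):
        triples = [
            (f"g{b}_{i}", f"o{b}_{j}", 4)
            for b in range(2) for i in range(3) for j in range(3)
        ]
        mem, gen = _tables(triples)
        graph = build_graph(mem, gen)
        result = detect_communities(graph, seed=0)
        assert result.n_genome_communities == 2
        assert result.n_ortholog_communities == 2
        # block membership is pure
        blocks = {}
        for node, cid in result.membership.items():
            blocks.setdefault(cid, set()).add(node.split("::")[1][1])
        assert all(len(b) == 1 for b in blocks.values())
        edges = [
            (u if u.startswith("genome") else v, v if u.startswith("genome") else u,
             d["weight"])
            for u, v, d in graph.graph.edges(data=True)
        ]
        assert result.barber_modularity == pytest.approx(
            barber_optimum(edges), abs=1e-9
        )

    def test_single_edge_merges_into_one_community(self):
        mem, gen = _tables([("gX", "oX", 10)])
        graph = build_graph(mem, gen)
        result = detect_communities(graph, seed=0)
        assert result.membership["genome::gX"] == result.membership["og::oX"]
        assert result.barber_modularity == pytest.approx(0.0, abs=1e-12)

    def test_empty_graph_rejected(self):
        mem, gen = _tables([("gA", "oX", 3)])  # below cluster-size threshold
        graph = build_graph(mem, gen)
        with pytest.raises(ValueError):
            detect_communities(graph, seed=0)

    @pytest.mark.parametrize("case", range(12))
    def test_matches_exhaustive_optimum_on_small_graphs(self, case):
        rng = np.random.default_rng(500 + case)
        n_g, n_o = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        triples = []
        for g in range(n_g):
            for o in range(n_o):
                if rng.random() < 0.5:
                    triples.append((f"g{g}", f"o{o}", int(rng.integers(1, 4))))
        if not triples:
            triples = [("g0", "o0", 1)]
        mem, gen = _tables([(g, o, 10 * w) for g, o, w in triples])
        graph = build_graph(mem, gen)
        result = detect_communities(graph, seed=case)
        edges = []
        for u, v, d in graph.graph.edges(data=True):
            g, o = (u, v) if u.startswith("genome") else (v, u)
            edges.append((g, o, d["weight"]))
        assert result.barber_modularity == pytest.approx(
            barber_optimum(edges), abs=1e-9
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        mem, gen = _tables(_blocks(3, 3, 3, rng))
        graph = build_graph(mem, gen, min_cluster_size=2)
        a = detect_communities(graph, seed=5)
        b = detect_communities(graph, seed=5)
        assert a.membership == b.membership

    def test_modularity_recomputable_and_beats_baselines(self):
        rng = np.random.default_rng(2)
        mem, gen = _tables(_blocks(3, 4, 4, rng))
        graph = build_graph(mem, gen, min_cluster_size=2)
        result = detect_communities(graph, seed=0)
        recomputed = barber_modularity(graph, result.membership)
        assert recomputed == pytest.approx(result.barber_modularity, abs=1e-9)
        singletons = {n: i for i, n in enumerate(graph.genomes + graph.orthologs)}
        one = {n: 0 for n in graph.genomes + graph.orthologs}
        assert result.barber_modularity >= barber_modularity(graph, singletons)
        assert result.barber_modularity >= barber_modularity(graph, one)

    def test_planted_six_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        triples = _blocks(6, 6, 6, rng, p_in=0.8, p_out=0.02)
        mem, gen = _tables(triples)
        graph = build_graph(mem, gen, min_cluster_size=2)
        truth = {g: g.split("::")[1].split("_")[0] for g in graph.genomes}
        scores = []
        for seed in range(5):
            result = detect_communities(graph, seed=seed)
            labels = [result.membership[g] for g in graph.genomes]
            scores.append(
                adjusted_rand_score([truth[g] for g in graph.genomes], labels)
            )
        assert min(scores) >= 0.95

    def test_communities_are_connected(self):
        rng = np.random.default_rng(4)
        mem, gen = _tables(_blocks(3, 3, 3, rng))
        graph = build_graph(mem, gen, min_cluster_size=2)
        result = detect_communities(graph, seed=0)
        import networkx as nx

        for cid in set(result.membership.values()):
            nodes = [n for n, c in result.membership.items() if c == cid]
            if len(nodes) > 1:
                assert nx.is_connected(graph.graph.subgraph(nodes))


class TestDereplicate:
    def test_identical_elements_merge(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 2_000)
        clusters = dereplicate_genomes({"a": seq, "b": seq})
        assert len(clusters) == 1

    def test_divergent_elements_stay_apart(self):
        rng = np.random.default_rng(6)
        a, b = random_dna(rng, 2_000), random_dna(rng, 2_000)
        clusters = dereplicate_genomes({"a": a, "b": b})
        assert len(clusters) == 2

    def test_graded_divergence_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        base = random_dna(rng, 1_500)

        def mutate(seq, frac):
            out = list(seq)
            for p in rng.choice(len(seq), size=int(frac * len(seq)), replace=False):
                out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
            return "".join(out)

        seqs = {"ref": base}
        for i, frac in enumerate([0.02, 0.05, 0.30, 0.35]):
            seqs[f"v{i}"] = mutate(base, frac)
        seqs["other"] = random_dna(rng, 1_400)
        clusters = dereplicate_genomes(seqs)
        # oracle: same greedy rule, naive all-pairs hamming identity
        order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
        reps = []
        assign = {}
        for sid in order:
            for rep in reps:
                a, b = seqs[sid], seqs[rep]
                short = min(len(a), len(b))
                ident = sum(x == y for x, y in zip(a, b)) / short
                if ident >= 0.90:
                    assign[sid] = rep
                    break
            else:
                reps.append(sid)
                assign[sid] = sid
        assert set(clusters) == set(reps)

    def test_short_contained_sequence_joins_by_coverage(self):
        rng = np.random.default_rng(8)
        long = random_dna(rng, 3_000)
        fragment = long[500:2_000]
        clusters = dereplicate_genomes({"long": long, "frag": fragment})
        assert list(clusters) == ["long"]
        assert clusters["long"] == ["long", "frag"]


class TestSummaries:
    def test_fig3_style_fraction(self):
        membership = {f"genome::g{i}": 0 for i in range(305)}
        assignment = type("A", (), {"membership": membership})
        markers = {f"g{i}": ({"rve_INT"} if i < 260 else set()) for i in range(305)}
        table = summarize_clusters(assignment, markers)
        row = table.iloc[0]
        assert row.n_members == 305
        assert row["frac_rve_INT"] == pytest.approx(260 / 305)
        assert round(row["frac_rve_INT"], 3) == 0.852

    def test_unannotated_cluster_fractions_zero(self):
        membership = {"genome::gA": 0, "genome::gB": 0}
        assignment = type("A", (), {"membership": membership})
        table = summarize_clusters(assignment, {}, marker_classes=["YREC"])
        assert table.iloc[0]["frac_YREC"] == 0.0

    def test_random_table_recount(self):
        rng = np.random.default_rng(9)
        classes = ["rve_INT", "YREC", "pPolB"]
        membership = {f"genome::g{i}": int(rng.integers(3)) for i in range(40)}
        markers = {
            f"g{i}": {c for c in classes if rng.random() < 0.4} for i in range(40)
        }
        assignment = type("A", (), {"membership": membership})
        table = summarize_clusters(assignment, markers, marker_classes=classes)
        for _, row in table.iterrows():
            members = [
                g.split("::")[1]
                for g, c in membership.items()
                if c == row.community
            ]
            assert row.n_members == len(members)
            for cls in classes:
                frac = sum(cls in markers[g] for g in members) / len(members)
                assert row[f"frac_{cls}"] == pytest.approx(frac)
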