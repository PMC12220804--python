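"""End-to-end orchestration: simulate, detect, and network runs.

Each run archives its effective configuration, input checksums, and package
version in a manifest so results are reproducible from the output directory
alone. Every filter logs its drop count, making the candidate funnel
(raw inverted repeats -> size-filtered -> marker-confirmed) auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import element_caller, gene_network, gc_scan, synthetic_data, tir_finder
from .seq_io import FeatureRecord, read_fasta, write_features
from .tir_finder import IRScoring

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Bad or missing user input (CLI exit code 2)."""


@dataclass
class DetectConfig:
    window_bp: int = 500
    min_delta_points: float = 10.0
    scoring: IRScoring = field(default_factory=IRScoring)
    min_insert: int = 6000
    max_insert: int = 80000
    min_tir: int = 100
    max_tir: int = 8000
    flank_bp: int = 50
    min_tsd: int = 4
    max_tsd: int = 25
    max_offset: int = 3
    max_mismatch: int = 2
    e_value_max: float = 1e-3
    min_model_cov: float = 0.0
    min_query_cov: float = 0.0
    mcp_min_cov: float = 0.70
    require_marker: bool = True
    min_gc_delta: float = 0.0
    gc_flank_bp: int = 10000
    min_cluster_size: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectConfig":
        d = dict(d)
        if "scoring" in d and isinstance(d["scoring"], dict):
            d["scoring"] = IRScoring(**d["scoring"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DetectConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("detect", data))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config_dict: dict, inputs: dict[str, str]) -> None:
    manifest = {
        "version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {name: _sha256(p) for name, p in inputs.items() if Path(p).exists()},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def elements_to_frame(calls: list[element_caller.ElementCall]) -> pd.DataFrame:
    rows = []
    for e in calls:
        rows.append(
            {
                "element_id": e.element_id,
                "contig_id": e.interval.contig_id,
                "start": e.interval.start,
                "end": e.interval.end,
                "length_bp": e.interval.length,
                "classification": e.classification,
                "complete": e.complete,
                "tir5_len": e.tir.arm5_len,
                "tir3_len": e.tir.arm3_len,
                "tir_score": e.tir.score,
                "tir_mismatches": e.tir.n_mismatches,
                "tir_identity_pct": round(e.tir.arm_identity_pct, 2),
                "gc_delta_points": round(e.gc_delta_points, 2),
                "n_markers": len(e.markers),
                "marker_classes": ",".join(
                    sorted({m.marker_class for m in e.markers})
                ),
                "n_nested": len(e.nested_inserts),
                "tsd_seq": e.tsd.consensus if e.tsd else "",
                "tsd_len": e.tsd.length_bp if e.tsd else 0,
                "tsd_mismatches": e.tsd.n_mismatches if e.tsd else -1,
                "tsd_low_complexity": bool(e.tsd.low_complexity) if e.tsd else False,
            }
        )
    return pd.DataFrame(rows)


def tsds_to_frame(calls: list[element_caller.ElementCall]) -> pd.DataFrame:
    rows = []
    for e in calls:
        if e.tsd is None:
            continue
        t = e.tsd
        rows.append(
            {
                "element_id": e.element_id,
                "tsd_seq": t.consensus,
                "length_bp": t.length_bp,
                "n_mismatches": t.n_mismatches,
                "left_offset_bp": t.left_offset_bp,
                "right_offset_bp": t.right_offset_bp,
                "low_complexity": t.low_complexity,
            }
        )
    return pd.DataFrame(rows)


def elements_to_features(calls) -> list[FeatureRecord]:
    feats = []
    for e in calls:
        feats.append(
            FeatureRecord(
                e.interval,
                "element",
                {"ID": e.element_id, "classification": e.classification},
            )
        )
        feats.append(FeatureRecord(e.tir.arm5, "TIR", {"Parent": e.element_id}))
        feats.append(FeatureRecord(e.tir.arm3, "TIR", {"Parent": e.element_id}))
        for m in e.markers:
            feats.append(
                FeatureRecord(
                    m.interval,
                    "marker",
                    {"Parent": e.element_id, "class": m.marker_class},
                )
            )
        for iv in e.nested_inserts:
            feats.append(FeatureRecord(iv, "retroelement", {"Parent": e.element_id}))
    return feats


def detect_elements(
    contigs,
    markers: list[element_caller.MarkerHit],
    config: DetectConfig,
) -> tuple[list[element_caller.ElementCall], list[tir_finder.TIRPair]]:
    """Run the detection stages over an in-memory assembly."""
    calls: list[element_caller.ElementCall] = []
    candidates: list[tir_finder.TIRPair] = []
    for contig in contigs:
        pairs = tir_finder.find_inverted_repeats(contig, config.scoring)
        filtered = tir_finder.filter_candidates(
            pairs, config.min_insert, config.max_insert, config.min_tir, config.max_tir
        )
        logger.info(
            "%s: %d raw inverted repeats, %d after size filter",
            contig.id,
            len(pairs),
            len(filtered),
        )
        contig_markers = [m for m in markers if m.contig_id == contig.id]
        contig_calls, rejected = element_caller.call_elements(
            contig,
            filtered,
            contig_markers,
            require_marker=config.require_marker,
            min_gc_delta=config.min_gc_delta,
            gc_flank_bp=config.gc_flank_bp,
            tsd_flank_bp=config.flank_bp,
            return_rejected=True,
        )
        calls.extend(contig_calls)
        candidates.extend(rejected)
    return calls, candidates


def run_detect(
    assembly_path,
    marker_path,
    outdir,
    config: DetectConfig | None = None,
    genome_id: str = "assembly",
) -> element_caller.GenomeStats:
    """Full detection run: FASTA + marker TSV in, tables/GFF3/manifest out."""
    config = config or DetectConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not Path(assembly_path).exists():
        raise InputError(f"assembly not found: {assembly_path}")
    contigs = read_fasta(assembly_path)
    if marker_path is None or not Path(marker_path).exists():
        if config.require_marker:
            raise InputError(
                "marker hit table required when require_marker is set; "
                "provide --markers or pass require_marker=false"
            )
        markers = []
    else:
        markers = element_caller.load_marker_hits(
            marker_path,
            e_value_max=config.e_value_max,
            min_model_cov=config.min_model_cov,
            min_query_cov=config.min_query_cov,
            mcp_min_cov=config.mcp_min_cov,
        )
    calls, candidates = detect_elements(contigs, markers, config)

    elements_to_frame(calls).to_csv(outdir / "elements.tsv", sep="\t", index=False)
    tsds_to_frame(calls).to_csv(outdir / "tsds.tsv", sep="\t", index=False)
    write_features(elements_to_features(calls), outdir / "elements.gff3", "gff3")
    cand_rows = [
        {
            "contig_id": p.contig_id,
            "start": p.insert.start,
            "end": p.insert.end,
            "score": p.score,
            "tir_identity_pct": round(p.arm_identity_pct, 2),
        }
        for p in candidates
    ]
    pd.DataFrame(cand_rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    gc_rows = []
    for contig in contigs:
        gc_rows.extend(gc_scan.windowed_gc(contig, config.window_bp))
    gc_scan.write_gc_track(gc_rows, outdir / "gc_track.tsv")

    assembly_len = sum(c.length for c in contigs)
    stats = element_caller.genome_stats(
        calls, max(assembly_len, 1), genome_id=genome_id
    )
    pd.DataFrame([dataclasses.asdict(stats)]).to_csv(
        outdir / "genome_stats.tsv", sep="\t", index=False
    )
    inputs = {"assembly": str(assembly_path)}
    if marker_path is not None and Path(marker_path).exists():
        inputs["markers"] = str(marker_path)
    _write_manifest(outdir, config.to_dict(), inputs)
    if assembly_len == 0:
        logger.warning("empty assembly: no contigs read")
    return stats


def run_network(
    membership_path,
    genome_map_path,
    outdir,
    seed: int = 0,
    min_cluster_size: int = 10,
    resolution: float = 1.0,
    annotations: dict[str, set[str]] | None = None,
) -> gene_network.CommunityAssignment:
    """Build the bipartite graph, detect communities, summarize clusters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in (membership_path, genome_map_path):
        if not Path(p).exists():
            raise InputError(f"membership table not found: {p}")
    graph = gene_network.build_graph(
        membership_path, genome_map_path, min_cluster_size
    )
    assignment = gene_network.detect_communities(graph, seed, resolution)
    gene_network.write_communities(assignment, outdir / "communities.tsv")
    gene_network.write_edge_list(graph, outdir / "network_edges.tsv")
    if annotations is not None:
        gene_network.summarize_clusters(assignment, annotations).to_csv(
            outdir / "cluster_summary.tsv", sep="\t", index=False
        )
    _write_manifest(
        outdir,
        {"seed": seed, "min_cluster_size": min_cluster_size, "resolution": resolution},
        {"membership": str(membership_path), "genomes": str(genome_map_path)},
    )
    return assignment


def run_simulate(config: synthetic_data.SimConfig, outdir) -> synthetic_data.TruthTable:
    """Generate a synthetic fixture bundle plus expected per-genome stats."""
    outdir = Path(outdir)
    contigs, truth, marker_df = synthetic_data.simulate(config)
    synthetic_data.write_bundle(outdir, contigs, truth, marker_df, config)
    assembly_len = sum(c.length for c in contigs)
    expected = {
        "genome_id": "synthetic",
        "assembly_len_bp": assembly_len,
        "n_elements": len(truth),
        "density_per_mb": len(truth) / (assembly_len / 1e6) if assembly_len else 0.0,
        "pct_genome_in_elements": (
            100.0 * sum(t.element.length for t in truth) / assembly_len
            if assembly_len
            else 0.0
        ),
    }
    pd.DataFrame([expected]).to_csv(
        outdir / "expected_stats.tsv", sep="\t", index=False
    )
    _write_manifest(outdir, synthetic_data.config_to_yaml_dict(config), {})
    return truth
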