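"""Integrate TIR pairs, GC evidence, and hallmark-gene hits into element calls.

An element candidate is a size-filtered TIR pair. It becomes a call when it
contains at least one hallmark marker gene (major capsid protein, packaging
ATPase, maturation protease, integrase, ...) and, optionally, shows a GC
shift against its host flanks. Classification follows the capsid gene:
PLV-type MCP only -> PLV, virophage-type only -> virophage, both -> hybrid,
hallmarks without an MCP -> unassigned.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from . import gc_scan, tsd_caller
from .seq_io import Contig, Interval
from .tir_finder import TIRPair, tir_identity
from .tsd_caller import TSDCall

logger = logging.getLogger(__name__)

MARKER_CLASSES = frozenset(
    {
        "MCP_PLV",
        "MCP_virophage",
        "mCP",
        "pATPase",
        "protease",
        "rve_INT",
        "YREC",
        "pPolB",
        "other",
    }
)
MCP_CLASSES = frozenset({"MCP_PLV", "MCP_virophage"})


@dataclass(frozen=True)
class MarkerHit:
    protein_id: str
    contig_id: str
    interval: Interval
    marker_class: str
    model_id: str
    e_value: float
    model_coverage: float
    query_coverage: float

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {self.marker_class!r}")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not (0 <= self.model_coverage <= 1 and 0 <= self.query_coverage <= 1):
            raise ValueError("coverages must be in [0, 1]")


@dataclass
class ElementCall:
    element_id: str
    interval: Interval
    tir: TIRPair
    tsd: TSDCall | None
    gc_delta_points: float
    markers: list[MarkerHit]
    classification: str
    nested_inserts: list[Interval] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.tir is not None


@dataclass(frozen=True)
class GenomeStats:
    genome_id: str
    assembly_len_bp: int
    n_elements: int
    n_complete: int
    density_per_mb: float
    pct_genome_in_elements: float
    mean_element_len_bp: float
    mean_tir_identity_pct: float
    frac_tsd_conserved: float

    @property
    def density_per_mb_rounded(self) -> float:
        """Density as reported (1 decimal); full precision kept internally."""
        return round(self.density_per_mb, 1)


_REQUIRED_COLUMNS = [
    "protein_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "marker_class",
    "model_id",
    "e_value",
    "model_coverage",
    "query_coverage",
]

# HMMER3 domtblout fixed column indices (whitespace-delimited)
_DOMTBL_TARGET, _DOMTBL_TLEN, _DOMTBL_QUERY, _DOMTBL_QLEN = 0, 2, 3, 5
_DOMTBL_IEVALUE, _DOMTBL_HMM_FROM, _DOMTBL_HMM_TO = 12, 15, 16
_DOMTBL_ALI_FROM, _DOMTBL_ALI_TO = 17, 18


def load_gene_coords(path) -> dict[str, tuple[str, int, int, str]]:
    """protein_id -> (contig, start, end, strand) from a 5-column TSV."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.protein_id): (str(r.contig_id), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    }


def _parse_domtblout(path, gene_coords, class_of_model) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 19:
                raise ValueError(f"{path}: malformed domtblout row at line {lineno}")
            pid = cols[_DOMTBL_TARGET]
            if pid not in gene_coords:
                raise ValueError(
                    f"{path}: line {lineno}: no gene coordinates for {pid}"
                )
            contig, start, end, strand = gene_coords[pid]
            tlen, qlen = int(cols[_DOMTBL_TLEN]), int(cols[_DOMTBL_QLEN])
            hmm_span = int(cols[_DOMTBL_HMM_TO]) - int(cols[_DOMTBL_HMM_FROM]) + 1
            ali_span = int(cols[_DOMTBL_ALI_TO]) - int(cols[_DOMTBL_ALI_FROM]) + 1
            model = cols[_DOMTBL_QUERY]
            rows.append(
                {
                    "protein_id": pid,
                    "contig_id": contig,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "marker_class": class_of_model.get(model, "other"),
                    "model_id": model,
                    "e_value": float(cols[_DOMTBL_IEVALUE]),
                    "model_coverage": hmm_span / qlen,
                    "query_coverage": ali_span / tlen,
                }
            )
    return rows


def load_marker_hits(
    path,
    e_value_max: float = 1e-3,
    min_model_cov: float = 0.0,
    min_query_cov: float = 0.0,
    mcp_min_cov: float = 0.70,
    fmt: str = "tsv",
    gene_coords: dict | None = None,
    class_of_model: dict | None = None,
) -> list[MarkerHit]:
    """Load and filter hallmark-gene hits.

    ``fmt='tsv'`` expects the pipeline's own header layout; ``fmt='domtblout'``
    parses an HMMER3 domain table and requires ``gene_coords`` to place the
    proteins on contigs. MCP-class hits must additionally satisfy the stricter
    ``mcp_min_cov`` on both model and query coverage. Per protein and marker
    class, only the best (lowest e-value) hit is kept.
    """
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise ValueError(f"cannot read marker table {path}: {exc}") from exc
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing marker-table columns {missing}")
        rows = []
        for lineno, r in enumerate(df.to_dict("records"), start=2):
            try:
                rows.append(
                    {
                        "protein_id": str(r["protein_id"]),
                        "contig_id": str(r["contig_id"]),
                        "start": int(r["start"]),
                        "end": int(r["end"]),
                        "strand": str(r["strand"]),
                        "marker_class": str(r["marker_class"]),
                        "model_id": str(r["model_id"]),
                        "e_value": float(r["e_value"]),
                        "model_coverage": float(r["model_coverage"]),
                        "query_coverage": float(r["query_coverage"]),
                    }
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed marker row at line {lineno}: {exc}"
                ) from exc
    elif fmt == "domtblout":
        if gene_coords is None:
            raise ValueError("domtblout input requires gene_coords")
        rows = _parse_domtblout(path, gene_coords, class_of_model or {})
    else:
        raise ValueError(f"unknown marker table format {fmt!r}")

    dropped = {"e_value": 0, "coverage": 0}
    kept: dict[tuple[str, str], MarkerHit] = {}
    for r in rows:
        if r["e_value"] >= e_value_max:
            dropped["e_value"] += 1
            continue
        is_mcp = r["marker_class"] in MCP_CLASSES
        mcov = max(min_model_cov, mcp_min_cov) if is_mcp else min_model_cov
        qcov = max(min_query_cov, mcp_min_cov) if is_mcp else min_query_cov
        if r["model_coverage"] < mcov or r["query_coverage"] < qcov:
            dropped["coverage"] += 1
            continue
        hit = MarkerHit(
            protein_id=r["protein_id"],
            contig_id=r["contig_id"],
            interval=Interval(r["contig_id"], r["start"], r["end"], r["strand"]),
            marker_class=r["marker_class"],
            model_id=r["model_id"],
            e_value=r["e_value"],
            model_coverage=r["model_coverage"],
            query_coverage=r["query_coverage"],
        )
        key = (hit.protein_id, hit.marker_class)
        if key not in kept or hit.e_value < kept[key].e_value:
            kept[key] = hit
    logger.info(
        "marker hits: kept %d, dropped %d by e-value, %d by coverage",
        len(kept),
        dropped["e_value"],
        dropped["coverage"],
    )
    return list(kept.values())


def _shrink_boundary(
    contig: Contig, element: Interval, pair: TIRPair, shift_l: int, shift_r: int
) -> tuple[Interval, TIRPair]:
    """Pull an element's outer edges in by the given shifts.

    The dropped alignment columns are matches by construction (a local
    alignment never ends on a mismatch), so the pair's score drops by the
    match score per column; identity is re-measured on the shrunken arms.
    """
    if max(shift_l, shift_r) >= min(pair.arm5.length, pair.arm3.length):
        return element, pair
    new_element = Interval(contig.id, element.start + shift_l, element.end - shift_r)
    new_pair = dataclasses.replace(
        pair,
        arm5=Interval(contig.id, pair.arm5.start + shift_l, pair.arm5.end),
        arm3=Interval(contig.id, pair.arm3.start, pair.arm3.end - shift_r),
        insert=new_element,
        score=pair.score - 3 * max(shift_l, shift_r),
    )
    new_pair = dataclasses.replace(
        new_pair, arm_identity_pct=tir_identity(new_pair, contig)
    )
    return new_element, new_pair


def classify_markers(marker_classes) -> str:
    """Total, deterministic classification from the set of marker classes."""
    classes = set(marker_classes)
    has_plv = "MCP_PLV" in classes
    has_vph = "MCP_virophage" in classes
    if has_plv and has_vph:
        return "hybrid"
    if has_plv:
        return "PLV"
    if has_vph:
        return "virophage"
    return "unassigned"


def find_nested_inserts(
    contig: Contig,
    element: Interval,
    markers: list[MarkerHit],
    window_bp: int = 500,
    min_delta_points: float = 5.0,
    min_len_bp: int = 3000,
    max_len_bp: int = 12000,
) -> list[Interval]:
    """GC-divergent sub-segments of an element that carry a retroelement gene.

    Retroelement evidence is a non-hallmark ('other' class) marker hit, e.g.
    a reverse-transcriptase domain, inside the sub-segment. The delta
    threshold is lower than for whole-element calling because the baseline
    (the element's own mean GC) is diluted by the insertion itself.
    """
    sub = Contig(contig.id, contig.seq[element.start : element.end])
    from .seq_io import gc_fraction

    baseline = gc_fraction(sub.seq)
    windows = gc_scan.windowed_gc(sub, window_bp)
    segments = gc_scan.call_gc_segments(
        windows, baseline, min_delta_points, min_len_bp, max_len_bp
    )
    out = []
    for seg in segments:
        iv = Interval(
            contig.id,
            element.start + seg.interval.start,
            element.start + seg.interval.end,
        )
        if any(
            m.marker_class == "other" and iv.overlaps(m.interval) for m in markers
        ):
            out.append(iv)
    return out


def call_elements(
    contig: Contig,
    tir_pairs: list[TIRPair],
    markers: list[MarkerHit] = (),
    require_marker: bool = True,
    min_gc_delta: float = 0.0,
    gc_flank_bp: int = 10000,
    tsd_flank_bp: int = 50,
    return_rejected: bool = False,
):
    """Turn filtered TIR pairs into classified element calls.

    Each pair defines an element spanning TIR outer edge to TIR outer edge
    (TSDs lie outside). With ``require_marker`` a candidate needs at least one
    marker hit inside; TIR-only candidates are returned separately when
    ``return_rejected`` is set rather than silently dropped.
    """
    all_intervals = [p.insert for p in tir_pairs]
    calls: list[ElementCall] = []
    rejected: list[TIRPair] = []
    n_dropped_marker = n_dropped_gc = 0
    for i, pair in enumerate(tir_pairs):
        element = pair.insert
        inside = [
            m
            for m in markers
            if m.contig_id == contig.id and element.contains(m.interval)
        ]
        neighbor = [iv for j, iv in enumerate(all_intervals) if j != i]
        delta = gc_scan.element_gc_delta(
            element, contig, gc_flank_bp, neighbor_elements=neighbor
        )
        if require_marker and not inside:
            n_dropped_marker += 1
            rejected.append(pair)
            continue
        if abs(delta) < min_gc_delta:
            n_dropped_gc += 1
            rejected.append(pair)
            continue
        tsd = tsd_caller.call_tsd_near_boundary(
            contig, element, flank_bp=tsd_flank_bp
        )
        if tsd is not None and (tsd.shift_left_bp or tsd.shift_right_bp):
            # junction-aware TSD evidence corrects an over-extended boundary
            element, pair = _shrink_boundary(
                contig, element, pair, tsd.shift_left_bp, tsd.shift_right_bp
            )
        eid = f"{contig.id}_elem_{element.start}_{element.end}"
        if tsd is not None:
            tsd = dataclasses.replace(tsd, element_id=eid)
        nested = find_nested_inserts(contig, element, inside)
        calls.append(
            ElementCall(
                element_id=eid,
                interval=element,
                tir=pair,
                tsd=tsd,
                gc_delta_points=delta,
                markers=inside,
                classification=classify_markers(m.marker_class for m in inside),
                nested_inserts=nested,
            )
        )
    logger.info(
        "%s: %d candidates -> %d calls (%d lacked markers, %d below GC delta)",
        contig.id,
        len(tir_pairs),
        len(calls),
        n_dropped_marker,
        n_dropped_gc,
    )
    if return_rejected:
        return calls, rejected
    return calls


def genome_stats(
    elements: list[ElementCall], assembly_len_bp: int, genome_id: str = "assembly"
) -> GenomeStats:
    """Per-genome expansion statistics for a set of element calls."""
    if assembly_len_bp <= 0:
        raise ValueError("assembly_len_bp must be > 0")
    n = len(elements)
    total_bp = sum(e.interval.length for e in elements)
    n_complete = sum(1 for e in elements if e.complete)
    mean_len = total_bp / n if n else 0.0
    identities = [e.tir.arm_identity_pct for e in elements if e.tir is not None]
    mean_identity = sum(identities) / len(identities) if identities else math.nan
    calls = {e.element_id: e.tsd for e in elements}
    cons = tsd_caller.tsd_conservation_summary(calls, [e.element_id for e in elements])
    return GenomeStats(
        genome_id=genome_id,
        assembly_len_bp=assembly_len_bp,
        n_elements=n,
        n_complete=n_complete,
        density_per_mb=n / (assembly_len_bp / 1e6),
        pct_genome_in_elements=100.0 * total_bp / assembly_len_bp,
        mean_element_len_bp=mean_len,
        mean_tir_identity_pct=mean_identity,
        frac_tsd_conserved=(
            cons.frac_conserved if cons.frac_conserved is not None else math.nan
        ),
    )
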