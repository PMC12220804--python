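"""Synthetic host genomes with planted endogenous viral elements.

The generator emulates the genomic signatures the detection pipeline keys on:
host background of configurable GC, planted elements whose interior GC is
offset from the host, terminal inverted repeat arms at a configurable
identity, target-site duplications immediately outside the arms, synthetic
hallmark-gene hits inside each element, and nested GC-rich retroelement
insertions flanked by direct repeats. Background and interiors are drawn
i.i.d. per base, which keeps analytic expectations (window GC variance,
chance seed-match rates) available for tests. Every run is a pure function
of the config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_io import Contig, FeatureRecord, Interval, revcomp, write_features

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# hard bounds observed for real elements; configs must stay inside them
ELEMENT_BOUNDS = (6000, 80000)
TIR_BOUNDS = (100, 8000)
TSD_BOUNDS = (4, 25)
NESTED_BOUNDS = (4000, 9500)

_CASSETTE_SPAN = 4400  # interior bp reserved for the marker cassette


class PackingError(ValueError):
    """Raised when planted elements cannot fit inside the configured contigs."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    n_contigs: int = 10
    contig_len_bp: int = 2_000_000
    host_gc: float = 0.42
    n_elements: int = 100
    element_len_bp: tuple[int, int] = (6000, 40000)
    tir_len_bp: tuple[int, int] = (100, 3000)
    tir_identity: float = 0.95
    element_gc: float = 0.60
    tsd_len_bp: tuple[int, int] = (4, 6)
    tsd_mismatches: int = 0
    tsd_offset_bp: int = 0
    tsd_fraction: float = 1.0
    n_nested: int = 10
    nested_len_bp: tuple[int, int] = (4000, 9500)
    nested_gc: float = 0.70
    dr_len_bp: int = 300
    marker_cassette: tuple[str, ...] = ("MCP_PLV", "pATPase", "protease")

    def __post_init__(self) -> None:
        for name, (lo, hi), (blo, bhi) in (
            ("element_len_bp", self.element_len_bp, ELEMENT_BOUNDS),
            ("tir_len_bp", self.tir_len_bp, TIR_BOUNDS),
            ("tsd_len_bp", self.tsd_len_bp, TSD_BOUNDS),
            ("nested_len_bp", self.nested_len_bp, NESTED_BOUNDS),
        ):
            if not (blo <= lo <= hi <= bhi):
                raise ValueError(f"{name}={lo, hi} outside bounds {blo}-{bhi}")
        if not 0 <= self.tsd_offset_bp <= 3:
            raise ValueError("tsd_offset_bp must be in [0, 3]")
        if self.tsd_mismatches < 0:
            raise ValueError("tsd_mismatches must be >= 0")
        for name, frac in (
            ("host_gc", self.host_gc),
            ("element_gc", self.element_gc),
            ("nested_gc", self.nested_gc),
            ("tir_identity", self.tir_identity),
            ("tsd_fraction", self.tsd_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TruthElement:
    element_id: str
    contig_id: str
    element: Interval
    arm5: Interval
    arm3: Interval
    tir_identity: float
    tsd_seq: str | None
    tsd_left: Interval | None
    tsd_right: Interval | None
    tsd_mismatches: int
    tsd_offset_bp: int
    markers: list[tuple[str, Interval]] = field(default_factory=list)
    nested: list[Interval] = field(default_factory=list)


@dataclass
class TruthTable:
    elements: list[TruthElement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.elements:
            rows.append(
                {
                    "element_id": t.element_id,
                    "contig_id": t.contig_id,
                    "start": t.element.start,
                    "end": t.element.end,
                    "arm5_start": t.arm5.start,
                    "arm5_end": t.arm5.end,
                    "arm3_start": t.arm3.start,
                    "arm3_end": t.arm3.end,
                    "tir_identity": t.tir_identity,
                    "tsd_seq": t.tsd_seq or "",
                    "tsd_mismatches": t.tsd_mismatches,
                    "tsd_offset_bp": t.tsd_offset_bp,
                    "n_markers": len(t.markers),
                    "n_nested": len(t.nested),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_features(self) -> list[FeatureRecord]:
        feats: list[FeatureRecord] = []
        for t in self.elements:
            feats.append(
                FeatureRecord(t.element, "element", {"ID": t.element_id})
            )
            feats.append(
                FeatureRecord(t.arm5, "TIR", {"Parent": t.element_id, "arm": "5"})
            )
            feats.append(
                FeatureRecord(t.arm3, "TIR", {"Parent": t.element_id, "arm": "3"})
            )
            if t.tsd_left is not None:
                feats.append(
                    FeatureRecord(
                        t.tsd_left, "TSD", {"Parent": t.element_id, "seq": t.tsd_seq}
                    )
                )
                feats.append(
                    FeatureRecord(
                        t.tsd_right, "TSD", {"Parent": t.element_id, "seq": t.tsd_seq}
                    )
                )
            for label, iv in t.markers:
                feats.append(
                    FeatureRecord(iv, "marker", {"Parent": t.element_id, "class": label})
                )
            for iv in t.nested:
                feats.append(
                    FeatureRecord(iv, "retroelement", {"Parent": t.element_id})
                )
        return feats

    def write_gff3(self, path) -> None:
        write_features(self.to_features(), path, "gff3")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _mutate(rng: np.random.Generator, arr: np.ndarray, n_mut: int) -> np.ndarray:
    """Substitute n_mut distinct positions with a different base."""
    out = arr.copy()
    if n_mut == 0:
        return out
    pos = rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate(config: SimConfig) -> tuple[list[Contig], TruthTable, pd.DataFrame]:
    """Generate (assembly, truth table, synthetic marker-hit table)."""
    rng = np.random.default_rng(config.seed)
    # per-contig element counts, as even as possible
    base, rem = divmod(config.n_elements, config.n_contigs)
    counts = [base + (1 if i < rem else 0) for i in range(config.n_contigs)]

    # sample element geometry up front so nested capability is known
    elem_lens = rng.integers(
        config.element_len_bp[0], config.element_len_bp[1] + 1, config.n_elements
    )
    arm_caps = np.minimum(
        config.tir_len_bp[1], (elem_lens - _CASSETTE_SPAN) // 2
    )
    arm_lens = np.array(
        [
            rng.integers(config.tir_len_bp[0], max(config.tir_len_bp[0], cap) + 1)
            for cap in arm_caps
        ]
    )
    interior_lens = elem_lens - 2 * arm_lens
    nested_lens = rng.integers(
        config.nested_len_bp[0], config.nested_len_bp[1] + 1, config.n_elements
    )
    room = interior_lens - (nested_lens + 2 * config.dr_len_bp) >= _CASSETTE_SPAN + 600
    capable = np.flatnonzero(room)
    if config.n_nested > 0 and len(capable) > 0:
        chosen = rng.choice(
            capable, size=min(config.n_nested, len(capable)), replace=False
        )
        nested_flags = np.zeros(config.n_elements, dtype=bool)
        nested_flags[chosen] = True
    else:
        nested_flags = np.zeros(config.n_elements, dtype=bool)

    contigs: list[Contig] = []
    truth = TruthTable()
    marker_rows: list[dict] = []
    margin = 600  # free host bp kept on each side of an element
    elem_idx = 0
    for ci in range(config.n_contigs):
        cid = f"sim_contig_{ci:03d}"
        k = counts[ci]
        bg = _random_seq(rng, config.contig_len_bp, config.host_gc)
        lens = elem_lens[elem_idx : elem_idx + k]
        total = int(lens.sum()) + (k + 1) * margin
        if total > config.contig_len_bp:
            raise PackingError(
                f"infeasible packing on {cid}: element #{elem_idx} "
                f"(total {total} bp > contig {config.contig_len_bp} bp)"
            )
        slack = config.contig_len_bp - total
        cuts = np.sort(rng.random(k)) * slack if k else np.empty(0)
        offsets = np.concatenate([[0], np.cumsum(lens)])[:-1]
        starts = (
            margin * (np.arange(k) + 1) + offsets + cuts.astype(np.int64)
        ).astype(int)

        for local in range(k):
            gi = elem_idx + local
            eid = f"sim_elem_{gi:04d}"
            s = int(starts[local])
            E, A = int(elem_lens[gi]), int(arm_lens[gi])
            arm5 = _random_seq(rng, A, config.element_gc)
            n_mut = int(round((1 - config.tir_identity) * A))
            arm3 = _mutate(
                rng,
                np.frombuffer(
                    revcomp(_to_str(arm5)).encode("ascii"), dtype=np.uint8
                ),
                n_mut,
            )
            interior_len = int(interior_lens[gi])
            nested_ivs: list[Interval] = []
            if nested_flags[gi]:
                dr = _random_seq(rng, config.dr_len_bp, config.nested_gc)
                nested_seq = _random_seq(rng, int(nested_lens[gi]), config.nested_gc)
                block = np.concatenate([dr, nested_seq, dr])
                core_len = interior_len - len(block)
                insert_at = int(rng.integers(_CASSETTE_SPAN, core_len - 200))
                core = _random_seq(rng, core_len, config.element_gc)
                interior = np.concatenate(
                    [core[:insert_at], block, core[insert_at:]]
                )
                nested_start = s + A + insert_at
                nested_ivs.append(
                    Interval(cid, nested_start, nested_start + len(block))
                )
            else:
                interior = _random_seq(rng, interior_len, config.element_gc)
            element_arr = np.concatenate([arm5, interior, arm3])
            bg[s : s + E] = element_arr

            # target-site duplication outside the TIRs
            tsd_seq = tsd_left = tsd_right = None
            tsd_mm = 0
            offset = 0
            if rng.random() < config.tsd_fraction:
                T = int(
                    rng.integers(config.tsd_len_bp[0], config.tsd_len_bp[1] + 1)
                )
                left_copy = _random_seq(rng, T, config.host_gc)
                right_copy = _mutate(rng, left_copy, config.tsd_mismatches)
                offset = config.tsd_offset_bp
                bg[s - T : s] = left_copy
                bg[s + E + offset : s + E + offset + T] = right_copy
                # The i.i.d. junction bases can extend the planted duplication
                # by chance (a symmetric perfect repeat across both junctions).
                # Truth records the maximal duplication actually present in
                # the emitted sequence, not merely the sampled core.
                e_ext = 0
                if offset == 0:
                    while e_ext < 10:
                        e = e_ext + 1
                        front = bg[s - T - e] == bg[s + E - e]
                        back = bg[s + e - 1] == bg[s + E + T + e - 1]
                        if not (front and back):
                            break
                        e_ext = e
                lo, hi = s - T - e_ext, s + e_ext
                rlo, rhi = s + E + offset - e_ext, s + E + offset + T + e_ext
                tsd_left_arr = bg[lo:hi]
                tsd_right_arr = bg[rlo:rhi]
                tsd_seq = _to_str(tsd_left_arr)
                tsd_left = Interval(cid, lo, hi)
                tsd_right = Interval(cid, rlo, rhi)
                tsd_mm = int(np.count_nonzero(tsd_left_arr != tsd_right_arr))

            markers: list[tuple[str, Interval]] = []
            for mi, label in enumerate(config.marker_cassette):
                mstart = s + A + 200 + mi * 1000
                iv = Interval(cid, mstart, mstart + 800, "+")
                markers.append((label, iv))
                marker_rows.append(
                    {
                        "protein_id": f"{eid}_m{mi}",
                        "contig_id": cid,
                        "start": iv.start,
                        "end": iv.end,
                        "strand": "+",
                        "marker_class": label,
                        "model_id": f"{label}_model",
                        "e_value": 1e-10,
                        "model_coverage": 0.95,
                        "query_coverage": 0.95,
                    }
                )
            for ni, iv in enumerate(nested_ivs):
                rv = Interval(cid, iv.start + config.dr_len_bp + 100,
                              iv.start + config.dr_len_bp + 900, "+")
                markers_label = "other"
                marker_rows.append(
                    {
                        "protein_id": f"{eid}_rvt{ni}",
                        "contig_id": cid,
                        "start": rv.start,
                        "end": rv.end,
                        "strand": "+",
                        "marker_class": markers_label,
                        "model_id": "RVT_1",
                        "e_value": 1e-8,
                        "model_coverage": 0.9,
                        "query_coverage": 0.9,
                    }
                )

            truth.elements.append(
                TruthElement(
                    element_id=eid,
                    contig_id=cid,
                    element=Interval(cid, s, s + E),
                    arm5=Interval(cid, s, s + A),
                    arm3=Interval(cid, s + E - A, s + E),
                    tir_identity=100.0 * (1 - n_mut / A),
                    tsd_seq=tsd_seq,
                    tsd_left=tsd_left,
                    tsd_right=tsd_right,
                    tsd_mismatches=tsd_mm,
                    tsd_offset_bp=offset if tsd_seq else 0,
                    markers=markers,
                    nested=nested_ivs,
                )
            )
        contigs.append(Contig(cid, _to_str(bg)))
        elem_idx += k

    marker_df = pd.DataFrame(
        marker_rows,
        columns=[
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
        ],
    )
    return contigs, truth, marker_df


def config_to_yaml_dict(config: SimConfig) -> dict:
    d = asdict(config)
    for key in ("element_len_bp", "tir_len_bp", "tsd_len_bp", "nested_len_bp",
                "marker_cassette"):
        d[key] = list(d[key])
    return d


def config_from_dict(d: dict) -> SimConfig:
    kwargs = dict(d)
    for key in ("element_len_bp", "tir_len_bp", "tsd_len_bp", "nested_len_bp",
                "marker_cassette"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimConfig(**kwargs)


def _toy_marker_rows(eid, cid, element, labels):
    rows = []
    for mi, label in enumerate(labels):
        start = element.start + 400 + mi * 1200
        rows.append(
            {
                "protein_id": f"{eid}_m{mi}",
                "contig_id": cid,
                "start": start,
                "end": start + 800,
                "strand": "+",
                "marker_class": label,
                "model_id": f"{label}_model",
                "e_value": 1e-12,
                "model_coverage": 0.92,
                "query_coverage": 0.9,
            }
        )
    return rows


def toy_worked_examples() -> tuple[list[Contig], TruthTable, pd.DataFrame]:
    """Two fixed constructs with literature-style TSD motifs.

    Construct (a): a 10 kb element with perfect 200 bp TIRs whose left flank
    ends in TGAATAA and right flank begins with TCAATAA (a 7 bp duplication
    with one mismatched base, rve-INT style). Construct (b): an 8 kb element
    flanked by exact 5 bp GTTAT copies. Deterministic by construction.
    """
    rng = np.random.default_rng(202406)
    contigs: list[Contig] = []
    truth = TruthTable()
    marker_rows: list[dict] = []

    specs = [
        ("toy_rve", 14000, 2000, 10000, "TGAATAA", "TCAATAA", ("MCP_PLV", "pATPase", "rve_INT")),
        ("toy_yrec", 12000, 2000, 8000, "GTTAT", "GTTAT", ("MCP_PLV", "protease", "YREC")),
    ]
    for idx, (cid, clen, s, elen, left_motif, right_motif, labels) in enumerate(specs):
        bg = _random_seq(rng, clen, 0.45)
        arm = 200
        arm5 = _random_seq(rng, arm, 0.62)
        arm3 = np.frombuffer(
            revcomp(_to_str(arm5)).encode("ascii"), dtype=np.uint8
        ).copy()
        interior = _random_seq(rng, elen - 2 * arm, 0.62)
        bg[s : s + elen] = np.concatenate([arm5, interior, arm3])
        T = len(left_motif)
        bg[s - T : s] = np.frombuffer(left_motif.encode("ascii"), dtype=np.uint8)
        bg[s + elen : s + elen + T] = np.frombuffer(
            right_motif.encode("ascii"), dtype=np.uint8
        )
        eid = f"toy_elem_{idx}"
        element = Interval(cid, s, s + elen)
        marker_rows.extend(_toy_marker_rows(eid, cid, element, labels))
        truth.elements.append(
            TruthElement(
                element_id=eid,
                contig_id=cid,
                element=element,
                arm5=Interval(cid, s, s + arm),
                arm3=Interval(cid, s + elen - arm, s + elen),
                tir_identity=100.0,
                tsd_seq=left_motif,
                tsd_left=Interval(cid, s - T, s),
                tsd_right=Interval(cid, s + elen, s + elen + T),
                tsd_mismatches=sum(
                    a != b for a, b in zip(left_motif, right_motif)
                ),
                tsd_offset_bp=0,
                markers=[],
                nested=[],
            )
        )
        contigs.append(Contig(cid, _to_str(bg)))

    marker_df = pd.DataFrame(marker_rows)
    return contigs, truth, marker_df


def write_bundle(outdir, contigs, truth: TruthTable, marker_df: pd.DataFrame,
                 config: SimConfig | None = None) -> None:
    """Write a simulation bundle: FASTA, truth (GFF3 + TSV), marker TSV."""
    from .seq_io import write_fasta
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(contigs, outdir / "assembly.fasta")
    truth.write_tsv(outdir / "truth.tsv")
    truth.write_gff3(outdir / "truth.gff3")
    marker_df.to_csv(outdir / "marker_hits.tsv", sep="\t", index=False)
    if config is not None:
        with open(outdir / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(config_to_yaml_dict(config), fh, sort_keys=False)
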