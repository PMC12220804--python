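"""Sequence and feature I/O plus the coordinate vocabulary shared by all stages.

All in-memory coordinates are 0-based half-open intervals. Dialect conversion
(GFF3 is 1-based inclusive on disk, BED stays 0-based half-open) happens only
inside the writers/readers in this module.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = frozenset(
    {"gene", "TIR", "TSD", "element", "retroelement", "marker"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"contig {self.id}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval; strand '.' means strand-agnostic."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class FeatureRecord:
    """A typed genomic feature with free-form attributes."""

    interval: Interval
    kind: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if any(not k for k in self.attributes):
            raise ValueError("attribute keys must be non-empty")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC over non-N bases; nan when no A/C/G/T base is present."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def read_fasta(path) -> list[Contig]:
    """Read a multi-FASTA into Contigs.

    Sequences are uppercased; characters outside {A,C,G,T,N} are masked to N
    (count logged). Duplicate headers are a hard error; an empty file yields
    an empty list with a warning.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    n_masked = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        masked = _NON_ACGTN.sub("N", seq)
        n_masked += sum(a != b for a, b in zip(seq, masked))
        contigs.append(Contig(id=rec.id, seq=masked))
    if n_masked:
        logger.info("masked %d non-ACGTN characters to N", n_masked)
    if not contigs:
        logger.warning("no records in FASTA file %s", path)
    return contigs


def write_fasta(contigs, path, width: int = 60) -> None:
    """Write contigs as FASTA wrapped at `width` columns."""
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


_DIALECTS = ("gff3", "bed", "tsv")


def write_features(records, path, dialect: str) -> None:
    """Write FeatureRecords as GFF3 (1-based inclusive), BED6, or flat TSV."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in records:
                iv = rec.interval
                attrs = ";".join(f"{k}={v}" for k, v in rec.attributes.items())
                fh.write(
                    "\t".join(
                        [
                            iv.contig_id,
                            "plvscan",
                            rec.kind,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs or ".",
                        ]
                    )
                    + "\n"
                )
    elif dialect == "bed":
        with open(path, "w") as fh:
            for rec in records:
                iv = rec.interval
                name = rec.attributes.get("ID", rec.kind)
                fh.write(
                    "\t".join(
                        [iv.contig_id, str(iv.start), str(iv.end), str(name), "0", iv.strand]
                    )
                    + "\n"
                )
    else:
        keys: list[str] = []
        for rec in records:
            for k in rec.attributes:
                if k not in keys:
                    keys.append(k)
        rows = []
        for rec in records:
            iv = rec.interval
            row = {
                "contig_id": iv.contig_id,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "kind": rec.kind,
            }
            row.update({k: rec.attributes.get(k, "") for k in keys})
            rows.append(row)
        pd.DataFrame(
            rows, columns=["contig_id", "start", "end", "strand", "kind", *keys]
        ).to_csv(path, sep="\t", index=False)


def read_features(path, dialect: str) -> list[FeatureRecord]:
    """Read back features written by :func:`write_features`."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    records: list[FeatureRecord] = []
    if dialect == "gff3":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                seqid, _src, kind, start, end, _score, strand, _frame, attrs = cols
                attributes = {}
                if attrs != ".":
                    for item in attrs.split(";"):
                        k, _, v = item.partition("=")
                        attributes[k] = v
                records.append(
                    FeatureRecord(
                        Interval(seqid, int(start) - 1, int(end), strand),
                        kind,
                        attributes,
                    )
                )
    elif dialect == "bed":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                contig, start, end, name, _score, strand = cols[:6]
                kind = name if name in FEATURE_KINDS else "element"
                records.append(
                    FeatureRecord(
                        Interval(contig, int(start), int(end), strand),
                        kind,
                        {"ID": name} if name not in FEATURE_KINDS else {},
                    )
                )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for _, row in df.iterrows():
            attributes = {
                k: row[k]
                for k in df.columns
                if k not in ("contig_id", "start", "end", "strand", "kind")
                and pd.notna(row[k])
                and row[k] != ""
            }
            records.append(
                FeatureRecord(
                    Interval(
                        row["contig_id"], int(row["start"]), int(row["end"]), row["strand"]
                    ),
                    row["kind"],
                    attributes,
                )
            )
    return records
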