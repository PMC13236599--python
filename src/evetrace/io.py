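"""Standard-format I/O: FASTA, FASTQ, BED6, GFF3, TSV, and run configuration.

All internal coordinates are 0-based half-open; BED keeps that convention,
GFF3 is emitted 1-based inclusive.  FASTA/FASTQ parsing goes through
Biopython; sequences are uppercased on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .util import SeqRecord, TruthFeature, TruthSet


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[SeqRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(SeqRecord(rec.id, str(rec.seq).upper(), rec.description))
    return out


def write_fasta(records: Sequence[SeqRecord], path: str | Path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.seq), wrap):
                fh.write(r.seq[i : i + wrap] + "\n")


def read_fastq(path: str | Path) -> list[tuple[SeqRecord, str]]:
    """Reads with their quality strings."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((SeqRecord(rec.id, str(rec.seq).upper(), rec.description), qual))
    return out


def write_fastq(
    records: Sequence[SeqRecord], path: str | Path, qualities: Sequence[str] | None = None
) -> None:
    """Write reads; a constant quality 'I' (Q40) is used when none is given."""
    bio = []
    for i, r in enumerate(records):
        b = BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        qual = qualities[i] if qualities is not None else "I" * len(r.seq)
        if len(qual) != len(r.seq):
            raise ValueError(f"quality length mismatch for record {r.id!r}")
        b.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        bio.append(b)
    SeqIO.write(bio, str(path), "fastq")


# ---------------------------------------------------------------------------
# features


def write_bed(features: Iterable[TruthFeature], path: str | Path) -> None:
    """BED6 (0-based half-open); column 4 carries the feature type."""
    rows = sorted(features, key=lambda f: (f.genome_id, f.start))
    with open(path, "w") as fh:
        for f in rows:
            if f.start < 0:
                raise ValueError("negative coordinate")
            fh.write(f"{f.genome_id}\t{f.start}\t{f.end}\t{f.feature}\t0\t+\n")


def read_bed(path: str | Path) -> TruthSet:
    truth = TruthSet()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cols = line.split("\t")
        truth.add(cols[0], cols[3], int(cols[1]), int(cols[2]))
    return truth


def write_gff3(features: Iterable[TruthFeature], path: str | Path, source: str = "evetrace") -> None:
    """GFF3, 1-based inclusive coordinates."""
    rows = sorted(features, key=lambda f: (f.genome_id, f.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in rows:
            if f.start < 0:
                raise ValueError("negative coordinate")
            attrs = f"Name={f.feature}" + (f";Note={f.detail}" if f.detail else "")
            fh.write(
                f"{f.genome_id}\t{source}\t{f.feature}\t{f.start + 1}\t{f.end}\t.\t+\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (the defaults are the bundled demo)."""

    seed: int = 1
    host_length: int = 10_000
    host_gc: float = 0.52
    eve_length: int = 8_000
    eve_gc: float = 0.52
    attP_core: str = "CC"
    read_depth_integrated: float = 5.0
    read_depth_circle: float = 15.0
    read_depth_hairpin: float = 15.0
    read_depth_host: float = 5.0
    read_length_mean: float = 1200.0
    read_length_sd: float = 120.0
    error_rate: float = 0.0
    symptomatic: bool = True
    k: int = 15
    flank_w: int = 30
    min_len: int = 80
    max_dist: int = 50
    min_span: int = 3
    min_fb: int = 3
    min_ratio: float = 2.0
    n_progeny: int = 200
    penetrance: float = 1.0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Fingerprint of the scientific parameters (output paths excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunLog:
    """Machine-parseable line-delimited run events."""

    path: Path | None = None
    events: list[dict] = field(default_factory=list)

    def log(self, event: str, **details) -> None:
        rec = {"event": event, **details}
        self.events.append(rec)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
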