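"""Readers and writers for the standard interchange formats.

FASTA/FASTQ go through Biopython (gzip-transparent); BED, GMT, arm tables
and matrices are plain tab-separated text.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .isomir import MatureArm, PremirnaReference, normalize_rna
from .targets import GenomicInterval


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    with _open_text(path) as handle:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fastq")]


def write_fastq(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs; RNA is emitted in the DNA alphabet."""
    seq_records = []
    for name, seq in records:
        dna = str(seq).upper().replace("U", "T")
        rec = SeqRecord(Seq(dna), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(dna)
        seq_records.append(rec)
    with _open_text(path, "wt") as handle:
        SeqIO.write(seq_records, handle, "fastq")


def read_arm_table(path) -> dict[str, list[MatureArm]]:
    """TSV of (premirna_id, arm_id, start, end), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"premirna_id": str, "arm_id": str})
    required = {"premirna_id", "arm_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"arm table needs columns {sorted(required)}")
    arms: dict[str, list[MatureArm]] = {}
    for row in df.itertuples(index=False):
        arms.setdefault(row.premirna_id, []).append(
            MatureArm(row.arm_id, int(row.start), int(row.end))
        )
    return arms


def write_arm_table(path, references: Iterable[PremirnaReference]) -> None:
    rows = [
        (ref.premirna_id, arm.arm_id, arm.start, arm.end)
        for ref in references
        for arm in ref.mature_arms
    ]
    pd.DataFrame(rows, columns=["premirna_id", "arm_id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def load_premirna_references(fasta_path, arm_table_path) -> dict[str, PremirnaReference]:
    seqs = read_fasta(fasta_path)
    arms = read_arm_table(arm_table_path)
    refs = {}
    for premirna_id, seq in seqs.items():
        if premirna_id not in arms:
            raise ValueError(f"no arm annotation for {premirna_id!r}")
        refs[premirna_id] = PremirnaReference(
            premirna_id, normalize_rna(seq), tuple(arms[premirna_id])
        )
    return refs


def read_bed(path) -> list[GenomicInterval]:
    intervals = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) > 5 else "+"
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return intervals


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with _open_text(path, "wt") as handle:
        for iv in intervals:
            handle.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _description, *members = fields
            sets[name] = {m for m in members if m}
    return sets


def write_gmt(path, sets: Mapping[str, Iterable[str]], description: str = "na") -> None:
    with _open_text(path, "wt") as handle:
        for name in sorted(sets):
            members = "\t".join(sorted(set(sets[name])))
            handle.write(f"{name}\t{description}\t{members}\n")
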