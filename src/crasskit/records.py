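"""Core sequence record types and standard-format I/O (FASTA, GFF3, PAF).

Coordinates are 0-based half-open everywhere in memory; GFF3 output converts
to its native 1-based inclusive convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class GenomeRecord:
    """A contig or phage/bacterial genome."""

    id: str
    seq: str
    circular: bool = False
    source_sample: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        self.seq = self.seq.upper().replace("U", "T")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-nucleotide characters "
                f"{sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """A protein sequence, either gene-called (frame 0) or a raw six-frame
    translation (frame in +-1..3)."""

    id: str
    seq: str
    source_genome: str = ""
    frame: int = 0
    genetic_code: int = 11

    def __post_init__(self) -> None:
        # empty is allowed: a short frame translation can have no codons
        self.seq = self.seq.upper()
        bad = set(self.seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains invalid characters {sorted(bad)}")
        if self.frame not in (-3, -2, -1, 0, 1, 2, 3):
            raise ValueError(f"invalid frame {self.frame}")
        if self.genetic_code not in (4, 11, 15):
            raise ValueError(f"unsupported genetic code {self.genetic_code}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneAnnotation:
    """A called gene or marker annotation on a genome (0-based half-open)."""

    genome_id: str
    start: int
    end: int
    strand: str
    label: str = "unknown"
    length_aa: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"bad gene interval [{self.start}, {self.end}) on "
                f"{self.genome_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class AlignmentResult:
    """A local alignment between two sequences."""

    query_id: str
    target_id: str
    score: float
    evalue: float
    identity: float          # percent of aligned columns identical
    aln_len: int             # aligned columns
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, *, protein: bool = False) -> list:
    """Read a FASTA file into GenomeRecord (default) or ProteinRecord objects.

    Sequences are uppercased; U is converted to T in nucleotide mode.
    Duplicate ids raise a ValueError naming the offending id.
    """
    records = []
    seen = set()
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0]
            if rid in seen:
                raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
            seen.add(rid)
            if protein:
                records.append(ProteinRecord(id=rid, seq=seq))
            else:
                records.append(GenomeRecord(id=rid, seq=seq))
    return records


def write_fasta(records: Iterable, path, *, width: int = 80) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = rec.seq
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk)


def write_gff3(genes: Sequence[GeneAnnotation], path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"label={g.label};length_aa={g.length_aa}"
            fh.write("\t".join([
                g.genome_id, "crasskit", "CDS",
                str(g.start + 1), str(g.end), f"{g.score:g}",
                g.strand, ".", attrs]) + "\n")


def read_gff3(path) -> List[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            genes.append(GeneAnnotation(
                genome_id=f[0], start=int(f[3]) - 1, end=int(f[4]),
                strand=f[6], label=attrs.get("label", "unknown"),
                length_aa=int(attrs.get("length_aa", 0)),
                score=0.0 if f[5] == "." else float(f[5])))
    return genes


# ---------------------------------------------------------------------------
# PAF (minimal subset: positions, strand, matches / alignment block length)


def write_paf(blocks: Sequence[AlignmentResult], a_len: int, b_len: int,
              path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for blk in blocks:
            matches = round(blk.identity / 100.0 * blk.aln_len)
            fh.write("\t".join(map(str, [
                blk.query_id, a_len, blk.q_start, blk.q_end, blk.strand,
                blk.target_id, b_len, blk.t_start, blk.t_end,
                matches, blk.aln_len, 255])) + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
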