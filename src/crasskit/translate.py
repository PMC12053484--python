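"""Translation and ORF calling under genetic codes 11, 4 and 15.

crAss-like phages frequently reassign a stop codon: code 15 reads TAG as
glutamine, code 4 reads TGA as tryptophan. ORF calling therefore has to be
parameterised by the stop-codon set, and six-frame translation (used by the
profile-search detection route) must tolerate in-frame stops by masking them.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .records import GenomeRecord, GeneAnnotation, ProteinRecord, \
    reverse_complement

SUPPORTED_CODES = (11, 4, 15)

#: stop codons per genetic code, taken from the NCBI translation tables
STOP_CODONS: Dict[int, frozenset] = {
    code: frozenset(CodonTable.unambiguous_dna_by_id[code].stop_codons)
    for code in SUPPORTED_CODES
}


def translate(seq: str, code: int = 11, *, to_stop: bool = False) -> str:
    """Translate an in-frame nucleotide string; trailing 1-2 bases dropped.

    Codons containing N yield X and never count as stops.
    """
    if code not in SUPPORTED_CODES:
        raise ValueError(f"unsupported genetic code {code}")
    usable = len(seq) - len(seq) % 3
    aa = str(Seq(seq[:usable]).translate(table=code))
    if to_stop:
        pos = aa.find("*")
        if pos >= 0:
            aa = aa[:pos]
    return aa


def six_frame_translate(genome: GenomeRecord,
                        clean: bool = False) -> List[ProteinRecord]:
    """Translate all six reading frames under the standard code.

    Frames +1..+3 are offsets 0/1/2 on the forward strand, -1..-3 offsets
    0/1/2 on the reverse complement. ``clean=True`` replaces the stop symbol
    '*' with 'X' so downstream peptide extraction can split on X-runs.
    """
    if len(genome.seq) < 3:
        raise ValueError(f"genome {genome.id} shorter than one codon")
    out = []
    rc = reverse_complement(genome.seq)
    for strand, template in (("+", genome.seq), ("-", rc)):
        for offset in range(3):
            frame = (offset + 1) if strand == "+" else -(offset + 1)
            aa = translate(template[offset:], 11)
            if clean:
                aa = aa.replace("*", "X")
            out.append(ProteinRecord(
                id=f"{genome.id}|frame{frame:+d}", seq=aa,
                source_genome=genome.id, frame=frame, genetic_code=11))
    return out


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
_BASE_CODE[ord("N")] = -1


def _codon_ids(seq: str, offset: int) -> np.ndarray:
    """Encode codons starting at ``offset`` as integers 0..63 (-1 if any N)."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    usable = (len(seq) - offset) // 3
    if usable <= 0:
        return np.empty(0, dtype=np.int32)
    a = arr[offset:offset + usable * 3].reshape(-1, 3).astype(np.int32)
    ids = a[:, 0] * 16 + a[:, 1] * 4 + a[:, 2]
    ids[(a < 0).any(axis=1)] = -1
    return ids


def _codon_id(codon: str) -> int:
    return ("ACGT".index(codon[0]) * 16 + "ACGT".index(codon[1]) * 4
            + "ACGT".index(codon[2]))


_ATG = _codon_id("ATG")


def find_orfs(genome: GenomeRecord, code: int = 11,
              min_len_aa: int = 60) -> List[GeneAnnotation]:
    """Call all maximal ATG-to-stop ORFs on both strands.

    Within each frame an ORF runs from the first ATG after the previous stop
    through its stop codon (the reported interval includes the stop codon;
    ``length_aa`` does not count it). Overlaps across frames/strands are kept:
    phage genes overlap, and gene-counting operations use all calls.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    if code not in SUPPORTED_CODES:
        raise ValueError(f"unsupported genetic code {code}")
    stop_ids = np.array(sorted(_codon_id(c) for c in STOP_CODONS[code]),
                        dtype=np.int32)
    n = len(genome.seq)
    rc = reverse_complement(genome.seq)
    orfs: List[GeneAnnotation] = []
    for strand, template in (("+", genome.seq), ("-", rc)):
        for offset in range(3):
            ids = _codon_ids(template, offset)
            if ids.size == 0:
                continue
            is_stop = np.isin(ids, stop_ids)
            stop_pos = np.flatnonzero(is_stop)
            is_atg = ids == _ATG
            prev = -1
            for sp in stop_pos:
                atgs = np.flatnonzero(is_atg[prev + 1:sp])
                if atgs.size:
                    start_codon = prev + 1 + int(atgs[0])
                    length_aa = int(sp) - start_codon
                    if length_aa >= min_len_aa:
                        s = offset + start_codon * 3
                        e = offset + (int(sp) + 1) * 3
                        if strand == "-":
                            s, e = n - e, n - s
                        orfs.append(GeneAnnotation(
                            genome_id=genome.id, start=s, end=e,
                            strand=strand, label="unknown",
                            length_aa=length_aa))
                prev = int(sp)
    orfs.sort(key=lambda g: (g.start, g.end, g.strand))
    return orfs


def orf_protein(genome: GenomeRecord, orf: GeneAnnotation,
                code: int = 11) -> ProteinRecord:
    """Translate a called ORF (stop codon trimmed) to a ProteinRecord."""
    sub = genome.seq[orf.start:orf.end]
    if orf.strand == "-":
        sub = reverse_complement(sub)
    aa = translate(sub, code)
    if aa.endswith("*"):
        aa = aa[:-1]
    return ProteinRecord(
        id=f"{genome.id}|{orf.start}-{orf.end}{orf.strand}",
        seq=aa.replace("*", "X"), source_genome=genome.id, frame=0,
        genetic_code=code)


def coding_density(genome: GenomeRecord, orfs: List[GeneAnnotation]) -> float:
    """Fraction of genome bases covered by the union of ORF spans."""
    if not orfs:
        return 0.0
    mask = np.zeros(len(genome.seq), dtype=bool)
    for g in orfs:
        mask[g.start:g.end] = True
    return float(mask.mean())
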