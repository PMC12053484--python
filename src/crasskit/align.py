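"""Alignment primitives: local protein alignment with E-values, and k-mer
anchored nucleotide block alignment (the substrate for ANI/AF clustering).
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import AlignmentResult, GenomeRecord, ProteinRecord, \
    reverse_complement

# Ungapped Karlin-Altschul constants for BLOSUM62; the 1e-5 decision
# threshold downstream is orders of magnitude away from hits of interest,
# so the exact statistic is not load-bearing.
KA_LAMBDA = 0.267
KA_K = 0.041

_PROT_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="local", open_gap_score=-11.0,
                               extend_gap_score=-1.0)
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return al


_SHARED_ALIGNER = _aligner()


def karlin_altschul_evalue(score: float, qlen: int, tlen: int) -> float:
    """E = K * m * n * exp(-lambda * S), clipped into [0, inf)."""
    return KA_K * qlen * tlen * math.exp(-KA_LAMBDA * score)


def align_protein_local(query: ProteinRecord,
                        target: ProteinRecord) -> AlignmentResult:
    """Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1).

    Deterministic: the aligner's first optimal traceback is reported.
    """
    for rec in (query, target):
        bad = set(rec.seq) - _PROT_ALPHABET
        if bad:
            raise ValueError(
                f"protein {rec.id!r} contains unalignable characters "
                f"{sorted(bad)}")
    aln = _SHARED_ALIGNER.align(query.seq, target.seq)[0]
    counts = aln.counts()
    aln_len = counts.aligned + counts.gaps
    identity = (100.0 * counts.identities / aln_len) if aln_len else 0.0
    q_blocks, t_blocks = aln.aligned
    return AlignmentResult(
        query_id=query.id, target_id=target.id, score=float(aln.score),
        evalue=karlin_altschul_evalue(aln.score, len(query.seq),
                                      len(target.seq)),
        identity=identity, aln_len=int(aln_len),
        q_start=int(q_blocks[0][0]), q_end=int(q_blocks[-1][1]),
        t_start=int(t_blocks[0][0]), t_end=int(t_blocks[-1][1]))


# ---------------------------------------------------------------------------
# Nucleotide block alignment: shared-k-mer anchoring, per-diagonal chaining.

_NT_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_hashes(enc: np.ndarray, k: int) -> np.ndarray:
    """Rolling polynomial encoding of all k-mers; -1 where any N."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = enc >= 0
    h = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        h = h * 4 + enc[j:j + n]
        ok &= valid[j:j + n]
    h[~ok] = -1
    return h


def _anchor_blocks(enc_a: np.ndarray, enc_b: np.ndarray, k: int,
                   max_gap: int) -> List[Tuple[int, int, int]]:
    """Chain same-diagonal anchors into (a_start, b_start, length) blocks."""
    ha = _kmer_hashes(enc_a, k)
    hb = _kmer_hashes(enc_b, k)
    if ha.size == 0 or hb.size == 0:
        return []
    # unique k-mers in a -> position map
    order = np.argsort(ha, kind="stable")
    sh = ha[order]
    uniq_mask = np.ones(len(sh), dtype=bool)
    uniq_mask[1:] &= sh[1:] != sh[:-1]
    uniq_mask[:-1] &= sh[:-1] != sh[1:]
    kept = order[uniq_mask & (sh >= 0)]
    pos_of = dict(zip(ha[kept].tolist(), kept.tolist()))
    hits_b = []
    hits_a = []
    for j, h in enumerate(hb.tolist()):
        if h >= 0:
            i = pos_of.get(h)
            if i is not None:
                hits_a.append(i)
                hits_b.append(j)
    if not hits_a:
        return []
    ia = np.array(hits_a)
    ib = np.array(hits_b)
    diag = ia - ib
    # group anchors per diagonal, merge runs with gaps <= max_gap
    order = np.lexsort((ia, diag))
    ia, ib, diag = ia[order], ib[order], diag[order]
    blocks = []
    start_a = prev_a = int(ia[0])
    start_b = int(ib[0])
    prev_d = int(diag[0])
    for x in range(1, len(ia)):
        a, b, d = int(ia[x]), int(ib[x]), int(diag[x])
        if d == prev_d and 0 < a - prev_a <= max_gap:
            prev_a = a
        else:
            blocks.append((start_a, start_b, prev_a - start_a + k))
            start_a = prev_a = a
            start_b = b
            prev_d = d
    blocks.append((start_a, start_b, prev_a - start_a + k))
    return blocks


def align_nt_banded(a: GenomeRecord, b: GenomeRecord, *, k: int = 15,
                    max_gap: int = 300,
                    min_block: int = 100) -> List[AlignmentResult]:
    """Gapless k-mer anchored local nucleotide alignments on both strands.

    Anchors sharing a diagonal are chained into blocks (substitution-rich
    regions between anchors are spanned up to ``max_gap``); indels break the
    diagonal and start a new block. Identity is counted column-by-column over
    each block span.
    """
    enc_a = _encode(a.seq)
    out: List[AlignmentResult] = []
    for strand, bseq in (("+", b.seq), ("-", reverse_complement(b.seq))):
        enc_b = _encode(bseq)
        for (sa, sb, length) in _anchor_blocks(enc_a, enc_b, k, max_gap):
            if length < min_block and length < min(len(a.seq), len(b.seq)):
                continue
            seg_a = enc_a[sa:sa + length]
            seg_b = enc_b[sb:sb + length]
            matches = int(((seg_a == seg_b) & (seg_a >= 0)).sum())
            t_start, t_end = sb, sb + length
            if strand == "-":
                t_start, t_end = len(b.seq) - t_end, len(b.seq) - t_start
            out.append(AlignmentResult(
                query_id=a.id, target_id=b.id, score=float(matches),
                evalue=0.0, identity=100.0 * matches / length,
                aln_len=length, q_start=sa, q_end=sa + length,
                t_start=t_start, t_end=t_end, strand=strand))
    out.sort(key=lambda r: (r.q_start, r.t_start, r.strand))
    return out
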