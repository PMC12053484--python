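"""Viral-contig retention and dual-route crAss-like phage identification.

Retention uses the four published predictor criteria (VirSorter2 /
DeepVirFinder / VIBRANT score combinations). crAss identification then runs
two routes: (1) the p-crAssphage signature proteins (UGP_018 polymerase,
UGP_092 terminase) aligned to code-11 gene calls, gated at E < 1e-5,
>= 350 aligned residues and genome length > 70 kb; and (2) profile search
for the three conserved structural proteins (TerL, portal, MCP) over all
six reading frames, which also catches genomes using alternative genetic
codes. The final call combines the routes (union by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .config import DEFAULT_CONFIG, ThresholdConfig
from .pssm import Profile, pssm_search
from .records import GenomeRecord, ProteinRecord
from .align import align_protein_local
from .translate import find_orfs, orf_protein, six_frame_translate


@dataclass
class ViralScoreRecord:
    """Per-contig virus-predictor scores; missing values fail the criteria
    that need them."""

    contig_id: str
    vs2_score: Optional[float] = None
    dvf_score: Optional[float] = None
    dvf_p: Optional[float] = None
    vibrant_positive: bool = False


@dataclass
class CrassCall:
    contig_id: str
    route1_hit: str = "none"          # polymerase | terminase | none
    route2_hits: Dict[str, int] = field(default_factory=dict)  # marker->frame
    route1_pass: bool = False
    route2_pass: bool = False
    is_crass: bool = False


def retain_viral_contig(rec: ViralScoreRecord,
                        cfg: ThresholdConfig = DEFAULT_CONFIG) -> bool:
    """The four-criterion retention rule, with the published boundary
    conventions: >= for criteria 1-2 scores, strict > for criterion 3
    scores, strict < for both p-value gates."""
    vs2, dvf, p = rec.vs2_score, rec.dvf_score, rec.dvf_p
    if vs2 is not None and vs2 >= cfg.vs2_hi:
        return True
    if dvf is not None and p is not None \
            and dvf >= cfg.dvf_hi and p < cfg.dvf_p_hi:
        return True
    if vs2 is not None and dvf is not None and p is not None \
            and vs2 > cfg.vs2_lo and dvf > cfg.dvf_lo and p < cfg.dvf_p_lo:
        return True
    if rec.vibrant_positive:
        return True
    return False


@dataclass
class Route1Result:
    passed: bool
    hit: str = "none"                 # polymerase | terminase | none
    best_evalue: float = float("inf")
    best_aln_len: int = 0


def signature_route(genome: GenomeRecord,
                    signatures: Dict[str, ProteinRecord],
                    cfg: ThresholdConfig = DEFAULT_CONFIG,
                    min_len_aa: int = 100) -> Route1Result:
    """Signature-protein route: align UGP_018/UGP_092 to code-11 gene calls.

    A hit needs E < sig_evalue and >= sig_minlen aligned residues; the route
    passes only for genomes longer than the crAss genome floor. Gene calling
    uses the standard code only - the structural route covers recoded
    genomes.
    """
    if not signatures:
        raise ValueError("no signature proteins provided")
    sig_kind = {"UGP_018": "polymerase", "UGP_092": "terminase"}
    orfs = [o for o in find_orfs(genome, 11, min_len_aa)
            if o.length_aa >= cfg.sig_minlen]
    best = Route1Result(passed=False)
    for orf in orfs:
        prot = orf_protein(genome, orf, 11)
        for sig_id, sig in signatures.items():
            aln = align_protein_local(sig, prot)
            if aln.evalue < cfg.sig_evalue and aln.aln_len >= cfg.sig_minlen:
                if aln.evalue < best.best_evalue:
                    best = Route1Result(
                        passed=True, hit=sig_kind.get(sig_id, sig_id),
                        best_evalue=aln.evalue, best_aln_len=aln.aln_len)
    if genome.length <= cfg.crass_min_genome:
        best.passed = False
    return best


@dataclass
class Route2Result:
    passed: bool
    hits: Dict[str, int] = field(default_factory=dict)   # marker -> frame


def split_on_x(seq: str, min_len: int = 50) -> List[tuple]:
    """Split a cleaned six-frame translation on X runs into (offset, peptide)
    pieces of at least ``min_len`` residues."""
    out = []
    start = None
    for i, c in enumerate(seq + "X"):
        if c != "X" and start is None:
            start = i
        elif c == "X" and start is not None:
            if i - start >= min_len:
                out.append((start, seq[start:i]))
            start = None
    return out


def structural_route(genome: GenomeRecord,
                     profiles: Dict[str, Profile],
                     min_peptide: int = 50) -> Route2Result:
    """Structural-protein route: six-frame translate (stops masked to X),
    split into clean peptides, profile-search each against TerL / portal /
    MCP. Passes if any profile is hit in any frame."""
    hits: Dict[str, int] = {}
    for frame_rec in six_frame_translate(genome, clean=True):
        for offset, peptide in split_on_x(frame_rec.seq, min_peptide):
            pep = ProteinRecord(
                id=f"{frame_rec.id}|{offset}", seq=peptide,
                source_genome=genome.id, frame=frame_rec.frame)
            for name, prof in profiles.items():
                if name in hits:
                    continue
                if pssm_search(pep, prof) is not None:
                    hits[name] = frame_rec.frame
    return Route2Result(passed=bool(hits), hits=hits)


def call_crass(genome: GenomeRecord, route1: Route1Result,
               route2: Route2Result, mode: str = "union") -> CrassCall:
    """Combine the two routes into the final call (union by default)."""
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown combination mode {mode!r}")
    is_crass = (route1.passed or route2.passed) if mode == "union" \
        else (route1.passed and route2.passed)
    return CrassCall(contig_id=genome.id, route1_hit=route1.hit,
                     route2_hits=dict(route2.hits),
                     route1_pass=route1.passed, route2_pass=route2.passed,
                     is_crass=is_crass)


def detect_crass(contigs: Sequence[GenomeRecord],
                 scores: Dict[str, ViralScoreRecord],
                 signatures: Dict[str, ProteinRecord],
                 profiles: Dict[str, Profile],
                 cfg: ThresholdConfig = DEFAULT_CONFIG,
                 mode: str = "union") -> List[CrassCall]:
    """Full detection stage: retention rule, then both crAss routes on the
    retained contigs. Non-retained contigs get an all-false call."""
    calls = []
    for genome in contigs:
        rec = scores.get(genome.id, ViralScoreRecord(contig_id=genome.id))
        if not retain_viral_contig(rec, cfg):
            calls.append(CrassCall(contig_id=genome.id))
            continue
        r1 = signature_route(genome, signatures, cfg)
        r2 = structural_route(genome, profiles)
        calls.append(call_crass(genome, r1, r2, mode))
    return calls
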