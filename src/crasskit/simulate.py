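"""Synthetic gut-virome communities with planted ground truth.

The generator emulates the study conditions every downstream stage needs:
crAss-like phage genomes >= 70 kb carrying the five landmark genes in the
canonical order IHF_54 ... MCP ... portal ... TerL ... primase (plus a
polymerase signature gene), optional TAG/TGA stop-codon recoding with a
suppressor-tRNA cassette, bacterial genomes with CRISPR arrays whose spacers
derive from the phages, and multi-sample read sets with known relative
abundances under a two-group (fat/lean) design. Every planted fact is
recorded in a TruthBundle so recovery can be scored exactly.

All randomness derives from a single integer seed; the same spec + seed
reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .config import DEFAULT_CONFIG
from .markers import (MARKER_NAMES, TRNA_ANTICODON_OFFSET, marker_consensus,
                      signature_proteins, trna_template)
from .pssm import AA
from .records import GenomeRecord, GeneAnnotation, reverse_complement, \
    write_fasta
from .translate import STOP_CODONS

FAMILIES = ("alpha", "beta", "delta", "zeta")
REFERENCE_FAMILIES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")

# filler-gene counts per inter-marker block, by family: (ihf54->mcp,
# mcp->portal, portal->terl, terl->primase). Assembly-block counts differ
# between the alpha/delta and beta/zeta groups; the replication block
# (TerL->primase) is largest in zeta.
BLOCK_PLAN = {
    "alpha": (22, 6, 3, 10),
    "delta": (20, 7, 3, 11),
    "beta": (8, 16, 3, 10),
    "zeta": (9, 15, 3, 25),
    # reference-only families (used for human-reference genomes in tests)
    "gamma": (21, 6, 3, 10),
    "epsilon": (19, 7, 3, 0),
}

_SYNONYMS: Dict[str, List[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            if _codon in ("TAA", "TAG", "TGA"):
                continue
            from Bio.Seq import Seq as _Seq
            _SYNONYMS.setdefault(str(_Seq(_codon).translate()), []).append(_codon)


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community; defaults are the study-scale
    fixture (20 phages >= 70 kb, 30 bacteria, 16 samples in an 8v8
    fat/lean design)."""

    n_phages: int = 20
    genome_len_range: Tuple[int, int] = (70_000, 110_000)
    family_mix: Dict[str, float] = field(default_factory=lambda: {
        "alpha": 0.30, "beta": 0.35, "delta": 0.20, "zeta": 0.15})
    code_mix: Dict[int, float] = field(default_factory=lambda: {
        11: 0.50, 15: 0.35, 4: 0.15})
    n_bacteria: int = 30
    spacers_per_array: Tuple[int, int] = (3, 6)
    n_samples: int = 16
    reads_per_sample: int = 30_000
    read_len: int = 150
    subst_error: float = 0.005
    group_design: Dict[str, str] = field(default_factory=dict)
    effect_votus: List[Tuple[str, float]] = field(default_factory=lambda: [
        ("phage_01", 2.0), ("phage_02", -2.0)])
    seed: int = 0
    # structural knobs
    n_mutants: int = 2              # extra 2%-divergent copies of phage_01..
    mutant_divergence: float = 0.02
    n_decoys: int = 3               # non-crAss contigs in the contig pool
    family_marker_divergence: float = 0.20
    genome_marker_divergence: float = 0.05
    recoded_gene_fraction: float = 0.5
    recode_codon_prob: float = 0.5
    zeta_len_factor: float = 1.5
    bacteria_len: int = 40_000
    phage_spacer_fraction: float = 0.5   # fraction of spacers phage-derived
    decoy_spacer_mismatches: int = 2     # planted non-link decoy distance
    sample_jitter_sigma: float = 0.3
    refs_per_family: int = 8
    ref_divergence: float = 0.10     # reference leaves span more diversity
                                     # than pig leaves so family MRCAs cover

    def __post_init__(self) -> None:
        for mix in (self.family_mix, self.code_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("mixture proportions must sum to 1")
        if not self.group_design:
            half = self.n_samples // 2
            self.group_design = {
                f"s{i + 1:02d}": ("fat" if i < half else "lean")
                for i in range(self.n_samples)}
        if len(self.group_design) != self.n_samples:
            raise ValueError("group_design must cover n_samples samples")

    @property
    def samples(self) -> List[str]:
        return list(self.group_design)


@dataclass
class PhageTruth:
    genome_id: str
    family: str
    code: int
    length: int
    votu_rep: str                     # representative id of its vOTU
    markers: List[GeneAnnotation]
    genes: List[GeneAnnotation]       # every planted gene, sorted by start
    trna_positions: List[Tuple[int, str]]   # (0-based start, anticodon)
    block_fillers: Tuple[int, int, int, int]


@dataclass
class SpacerTruth:
    bacterium_id: str
    array_index: int
    spacer_seq: str
    phage_id: str                     # "" for random / decoy spacers
    mismatches: int                   # planted Hamming distance; -1 random
    phage_pos: int = -1
    phage_strand: str = "+"


@dataclass
class ArrayTruth:
    bacterium_id: str
    start: int
    repeat_seq: str
    n_repeats: int
    spacers: List[SpacerTruth]


@dataclass
class TruthBundle:
    spec: CommunitySpec
    phages: List[GenomeRecord]
    phage_truth: Dict[str, PhageTruth]
    bacteria: List[GenomeRecord]
    taxonomy: Dict[str, str]
    arrays: List[ArrayTruth]
    reference_terl: List[Tuple[str, str, str]]   # (id, family, aa seq)
    abundance: Optional["np.ndarray"] = None     # phage x sample rel. abund.
    read_counts: Optional["np.ndarray"] = None
    covered_fraction: Optional["np.ndarray"] = None  # vOTU-rep x sample, %
    votu_reps: List[str] = field(default_factory=list)

    def links(self) -> List[SpacerTruth]:
        """Planted spacer->phage links obeying the one-mismatch cap."""
        return [s for a in self.arrays for s in a.spacers
                if s.phage_id and 0 <= s.mismatches <= 1]


# ---------------------------------------------------------------------------
# helpers


def _rng(spec_seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=spec_seed, spawn_key=(stage, index)))


def _random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_protein(rng, n: int) -> str:
    return "M" + "".join(np.array(list(AA))[rng.integers(0, 20, n - 1)])


def _mutate_protein(rng, seq: str, divergence: float) -> str:
    arr = np.array([AA.index(c) for c in seq])
    mut = rng.random(len(arr)) < divergence
    arr[mut] = (arr[mut] + rng.integers(1, 20, int(mut.sum()))) % 20
    out = "".join(AA[i] for i in arr)
    return "M" + out[1:]


def _mutate_dna(rng, seq: str, divergence: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
    idx = np.searchsorted(np.sort(codes), arr)  # ACGT are sorted bytes
    mut = rng.random(len(arr)) < divergence
    shift = rng.integers(1, 4, int(mut.sum()))
    idx[mut] = (idx[mut] + shift) % 4
    return "".join("ACGT"[i] for i in idx)


def _reverse_translate(rng, aa: str, code: int, recode: bool,
                       recode_prob: float) -> str:
    """Encode a protein; under code 15 (4) a ``recode_prob`` fraction of
    Q (W) residues use the reassigned stop codon TAG (TGA)."""
    codons = []
    for c in aa:
        if recode and code == 15 and c == "Q" and rng.random() < recode_prob:
            codons.append("TAG")
        elif recode and code == 4 and c == "W" and rng.random() < recode_prob:
            codons.append("TGA")
        else:
            options = _SYNONYMS[c]
            codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def _stop_codon(rng, code: int) -> str:
    stops = sorted(STOP_CODONS[code])
    return stops[rng.integers(0, len(stops))]


# ---------------------------------------------------------------------------
# phages


def family_marker_variants(spec: CommunitySpec) -> Dict[str, Dict[str, str]]:
    """Per-family marker protein variants (consensus mutated at the
    family_marker_divergence rate; deterministic given the spec seed)."""
    out: Dict[str, Dict[str, str]] = {}
    cons = marker_consensus()
    for fi, fam in enumerate(REFERENCE_FAMILIES):
        rng = _rng(spec.seed, 1, fi)
        out[fam] = {m: _mutate_protein(rng, cons[m],
                                       spec.family_marker_divergence)
                    for m in MARKER_NAMES}
        rng2 = _rng(spec.seed, 2, fi)
        out[fam]["UGP_018"] = _mutate_protein(
            rng2, signature_proteins()["UGP_018"].seq,
            spec.family_marker_divergence)
    return out


def _assign_from_mix(rng, n: int, mix: Dict) -> List:
    keys = list(mix)
    counts = [int(np.floor(mix[k] * n)) for k in keys]
    # largest remainder
    rem = [(mix[k] * n - c, k) for k, c in zip(keys, counts)]
    rem.sort(key=lambda t: (-t[0], str(t[1])))
    for i in range(n - sum(counts)):
        counts[keys.index(rem[i % len(rem)][1])] += 1
    pool = [k for k, c in zip(keys, counts) for _ in range(c)]
    return list(np.array(pool, dtype=object)[rng.permutation(n)])


def simulate_phage(spec: CommunitySpec, index: int, family: str,
                   code: int) -> Tuple[GenomeRecord, PhageTruth]:
    """Build one planted phage genome with its full truth record."""
    rng = _rng(spec.seed, 3, index)
    lo, hi = spec.genome_len_range
    if lo < DEFAULT_CONFIG.crass_min_genome:
        raise ValueError("genome_len_range minimum below the crAss genome "
                         f"floor ({DEFAULT_CONFIG.crass_min_genome})")
    target = int(rng.integers(lo, hi + 1))
    if family == "zeta":
        target = int(target * spec.zeta_len_factor)
    variants = family_marker_variants(spec)[family]

    blocks = BLOCK_PLAN[family]
    # gene plan: (label, aa_seq or None for random filler)
    plan: List[Tuple[str, Optional[str]]] = []
    for _ in range(4):
        plan.append(("filler", None))
    order = ["IHF_54", "MCP", "portal", "TerL", "primase"]
    for mi, marker in enumerate(order):
        aa = _mutate_protein(rng, variants[marker],
                             spec.genome_marker_divergence)
        plan.append((marker, aa))
        if mi < 4:
            for _ in range(blocks[mi]):
                plan.append(("filler", None))
    plan.append(("UGP_018", _mutate_protein(rng, variants["UGP_018"],
                                            spec.genome_marker_divergence)))

    genome_id = f"phage_{index + 1:02d}"
    parts: List[str] = [_random_dna(rng, int(rng.integers(80, 200)))]
    pos = len(parts[0])
    genes: List[GeneAnnotation] = []
    markers: List[GeneAnnotation] = []
    trnas: List[Tuple[int, str]] = []

    def emit_gene(label: str, aa: Optional[str]) -> None:
        nonlocal pos
        if aa is None:
            aa = _random_protein(rng, int(rng.integers(250, 500)))
            recode = (code in (4, 15)
                      and rng.random() < spec.recoded_gene_fraction)
        else:
            recode = False   # landmark/signature genes stay standard-readable
        nt = _reverse_translate(rng, aa, code, recode,
                                spec.recode_codon_prob) + _stop_codon(rng, code)
        ann = GeneAnnotation(genome_id=genome_id, start=pos,
                             end=pos + len(nt), strand="+", label=label,
                             length_aa=len(aa))
        genes.append(ann)
        if label in MARKER_NAMES:
            markers.append(ann)
        parts.append(nt)
        pos += len(nt)
        gap = _random_dna(rng, int(rng.integers(10, 60)))
        parts.append(gap)
        pos += len(gap)

    for label, aa in plan:
        emit_gene(label, aa)
    if pos >= target:
        raise ValueError(
            f"markers and blocks do not fit in requested length {target}")
    # suppressor-tRNA cassette for recoded genomes
    if code in (4, 15):
        anticodon = "CTA" if code == 15 else "TCA"
        template = trna_template()
        cassette = (template[:TRNA_ANTICODON_OFFSET] + anticodon
                    + template[TRNA_ANTICODON_OFFSET + 3:])
        cassette = "".join(
            c if (rng.random() > 0.02 or c == "N") else "ACGT"[rng.integers(0, 4)]
            for c in cassette)
        trnas.append((pos, anticodon))
        parts.append(cassette)
        pos += len(cassette)
        gap = _random_dna(rng, 30)
        parts.append(gap)
        pos += len(gap)
    # tail fillers up to the target length
    while pos < target - 1700:
        emit_gene("filler", None)
    if target > pos:
        parts.append(_random_dna(rng, target - pos))
    seq = "".join(parts)
    genome = GenomeRecord(id=genome_id, seq=seq)
    truth = PhageTruth(
        genome_id=genome_id, family=family, code=code, length=len(seq),
        votu_rep=genome_id, markers=markers, genes=genes,
        trna_positions=trnas, block_fillers=blocks)
    return genome, truth


def simulate_phages(spec: CommunitySpec) \
        -> Tuple[List[GenomeRecord], Dict[str, PhageTruth]]:
    rng = _rng(spec.seed, 4)
    families = _assign_from_mix(rng, spec.n_phages, spec.family_mix)
    codes = _assign_from_mix(rng, spec.n_phages, spec.code_mix)
    phages, truth = [], {}
    for i in range(spec.n_phages):
        g, t = simulate_phage(spec, i, families[i], int(codes[i]))
        phages.append(g)
        truth[g.id] = t
    # mutant co-vOTU members (same length, planted substitutions; nonsense
    # mutations in planted genes are reverted - purifying selection)
    for m in range(spec.n_mutants):
        parent = phages[m % spec.n_phages]
        mrng = _rng(spec.seed, 5, m)
        mid = f"{parent.id}_m{m + 1}"
        mseq = _mutate_dna(mrng, parent.seq, spec.mutant_divergence)
        stops = STOP_CODONS[truth[parent.id].code]
        chars = list(mseq)
        for ann in truth[parent.id].genes:
            for cs in range(ann.start, ann.end - 3, 3):
                if "".join(chars[cs:cs + 3]) in stops:
                    chars[cs:cs + 3] = parent.seq[cs:cs + 3]
        mseq = "".join(chars)
        phages.append(GenomeRecord(id=mid, seq=mseq))
        pt = truth[parent.id]
        truth[mid] = PhageTruth(
            genome_id=mid, family=pt.family, code=pt.code, length=len(mseq),
            votu_rep=parent.id, markers=pt.markers, genes=pt.genes,
            trna_positions=pt.trna_positions, block_fillers=pt.block_fillers)
    return phages, truth


def simulate_decoys(spec: CommunitySpec) -> List[GenomeRecord]:
    """Marker-free non-crAss contigs for the detection stage."""
    rng = _rng(spec.seed, 6)
    return [GenomeRecord(id=f"decoy_{i + 1:02d}",
                         seq=_random_dna(rng, int(rng.integers(20_000, 40_000))))
            for i in range(spec.n_decoys)]


def viral_score_table(spec: CommunitySpec, phages: Sequence[GenomeRecord],
                      decoys: Sequence[GenomeRecord]) -> "pd.DataFrame":
    """Simulated virus-predictor scores: phages retained confidently, the
    last decoy failing every retention criterion."""
    import pandas as pd
    rng = _rng(spec.seed, 7)
    rows = []
    for g in phages:
        rows.append((g.id, float(0.91 + 0.08 * rng.random()),
                     float(0.91 + 0.08 * rng.random()),
                     float(0.001 * rng.random()), True))
    for i, g in enumerate(decoys):
        if i == len(decoys) - 1 and len(decoys) > 1:
            rows.append((g.id, 0.40, 0.40, 0.60, False))
        else:
            rows.append((g.id, float(0.91 + 0.08 * rng.random()),
                         float(rng.random() * 0.5), 0.5, False))
    return pd.DataFrame(rows, columns=[
        "contig_id", "vs2_score", "dvf_score", "dvf_p", "vibrant_positive"])


# ---------------------------------------------------------------------------
# bacteria + CRISPR arrays

_GENERA = [
    ("Prevotella", "d__Bacteria;p__Bacteroidota;c__Bacteroidia;"
     "o__Bacteroidales;f__Bacteroidaceae;g__Prevotella;s__Prevotella sp"),
    ("Parabacteroides", "d__Bacteria;p__Bacteroidota;c__Bacteroidia;"
     "o__Bacteroidales;f__Tannerellaceae;g__Parabacteroides;"
     "s__Parabacteroides sp"),
    ("UBA4372", "d__Bacteria;p__Bacteroidota;c__Bacteroidia;"
     "o__Bacteroidales;f__Bacteroidaceae;g__UBA4372;s__UBA4372 sp"),
    ("Bacteroides", "d__Bacteria;p__Bacteroidota;c__Bacteroidia;"
     "o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__Bacteroides sp"),
    ("Faecalibacterium", "d__Bacteria;p__Firmicutes_A;c__Clostridia;"
     "o__Oscillospirales;f__Ruminococcaceae;g__Faecalibacterium;"
     "s__Faecalibacterium sp"),
]
_GENUS_WEIGHTS = np.array([0.40, 0.20, 0.15, 0.15, 0.10])


def simulate_bacteria(spec: CommunitySpec, phages: Sequence[GenomeRecord]) \
        -> Tuple[List[GenomeRecord], Dict[str, str], List[ArrayTruth]]:
    """Bacterial genomes carrying CRISPR arrays; a configured fraction of
    spacers are exact or 1-mismatch copies of phage subsequences, and each
    array also carries one 2-mismatch decoy spacer."""
    if not phages:
        raise ValueError("phages must be non-empty")
    rng = _rng(spec.seed, 8)
    bacteria: List[GenomeRecord] = []
    taxonomy: Dict[str, str] = {}
    arrays: List[ArrayTruth] = []
    genus_idx = _assign_from_mix(
        rng, spec.n_bacteria,
        {i: w for i, w in enumerate(_GENUS_WEIGHTS / _GENUS_WEIGHTS.sum())})
    for b in range(spec.n_bacteria):
        brng = _rng(spec.seed, 9, b)
        bid = f"bact_{b + 1:02d}"
        genus, lineage = _GENERA[int(genus_idx[b])]
        taxonomy[bid] = lineage
        backbone = _random_dna(brng, spec.bacteria_len)
        n_arrays = int(brng.integers(1, 3))
        pieces = []
        cursor = 0
        if n_arrays == 1:
            offsets = [int(brng.integers(2_000, spec.bacteria_len - 2_000))]
        else:
            half = spec.bacteria_len // 2
            offsets = [int(brng.integers(2_000, half - 1_000)),
                       int(brng.integers(half + 1_000,
                                         spec.bacteria_len - 2_000))]
        inserted = 0
        for ai, off in enumerate(offsets):
            repeat = _random_dna(brng, int(brng.integers(28, 33)))
            n_spacers = int(brng.integers(spec.spacers_per_array[0],
                                          spec.spacers_per_array[1] + 1))
            spacer_truths: List[SpacerTruth] = []
            seg = []
            array_start = off + inserted
            for si in range(n_spacers + 1):
                seg.append(repeat)
                if si == n_spacers:
                    break
                slen = int(brng.integers(30, 36))
                if si == 0 and spec.decoy_spacer_mismatches >= 2:
                    # decoy: phage-derived but beyond the mismatch cap
                    sp, truthrec = _phage_spacer(
                        brng, phages, slen, bid, ai,
                        mismatches=spec.decoy_spacer_mismatches)
                elif brng.random() < spec.phage_spacer_fraction:
                    mism = int(brng.integers(0, 2))   # exact or 1-mismatch
                    sp, truthrec = _phage_spacer(brng, phages, slen, bid, ai,
                                                 mismatches=mism)
                else:
                    sp = _random_dna(brng, slen)
                    truthrec = SpacerTruth(bid, ai, sp, "", -1)
                spacer_truths.append(truthrec)
                seg.append(sp)
            cassette = "".join(seg)
            pieces.append(backbone[cursor:off])
            pieces.append(cassette)
            cursor = off
            inserted += len(cassette)
            arrays.append(ArrayTruth(bid, array_start, repeat,
                                     n_spacers + 1, spacer_truths))
        pieces.append(backbone[cursor:])
        bacteria.append(GenomeRecord(id=bid, seq="".join(pieces)))
    return bacteria, taxonomy, arrays


def _phage_spacer(rng, phages: Sequence[GenomeRecord], slen: int, bid: str,
                  ai: int, mismatches: int) -> Tuple[str, SpacerTruth]:
    phage = phages[int(rng.integers(0, len(phages)))]
    if slen > len(phage.seq):
        raise ValueError("spacer length exceeds phage length")
    pos = int(rng.integers(0, len(phage.seq) - slen + 1))
    proto = phage.seq[pos:pos + slen]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        proto = reverse_complement(proto)
    sp = list(proto)
    # mismatches stay clear of spacer edges so array-boundary jitter in the
    # detector cannot change a spacer's planted Hamming distance
    sites = 2 + rng.choice(slen - 4, size=mismatches, replace=False)
    for s in sites:
        choices = [c for c in "ACGT" if c != sp[s]]
        sp[s] = choices[int(rng.integers(0, 3))]
    spacer = "".join(sp)
    return spacer, SpacerTruth(bid, ai, spacer, phage.id, mismatches,
                               phage_pos=pos, phage_strand=strand)


# ---------------------------------------------------------------------------
# reads / abundances


def planted_abundances(spec: CommunitySpec,
                       phages: Sequence[GenomeRecord]) -> np.ndarray:
    """Per-sample relative abundances (phage x sample), with the planted
    fat/lean log2 fold-changes applied to the effect vOTUs."""
    rng = _rng(spec.seed, 10)
    n = len(phages)
    base = rng.lognormal(0.0, 1.0, n)
    effects = dict(spec.effect_votus)
    # effect vOTUs are planted at comfortably detectable abundance in both
    # groups, so the fold-change (not the detection gate) carries the signal
    floor = float(np.median(base)) * 1.5
    for pi, g in enumerate(phages):
        if g.id in effects:
            base[pi] = max(base[pi], floor)
    mat = np.empty((n, spec.n_samples))
    for si, sample in enumerate(spec.samples):
        jitter = rng.lognormal(0.0, spec.sample_jitter_sigma, n)
        col = base * jitter
        if spec.group_design[sample] == "fat":
            for pi, g in enumerate(phages):
                if g.id in effects:
                    col[pi] *= 2.0 ** effects[g.id]
        mat[:, si] = col / col.sum()
    return mat


def simulate_reads(spec: CommunitySpec, phages: Sequence[GenomeRecord],
                   truth: Dict[str, PhageTruth]) \
        -> Tuple[Dict[str, List[Tuple[str, str]]], np.ndarray, np.ndarray,
                 np.ndarray, List[str]]:
    """Per-sample substitution-error reads plus the planted abundance,
    per-vOTU read-count and covered-fraction truth tables."""
    if spec.reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    abund = planted_abundances(spec, phages)
    lengths = np.array([len(g.seq) for g in phages], dtype=float)
    reps = sorted({truth[g.id].votu_rep for g in phages})
    rep_index = {r: i for i, r in enumerate(reps)}
    rep_len = {r: len(next(g for g in phages if g.id == r).seq) for r in reps}
    reads: Dict[str, List[Tuple[str, str]]] = {}
    read_counts = np.zeros((len(reps), spec.n_samples))
    covered = np.zeros((len(reps), spec.n_samples))
    for si, sample in enumerate(spec.samples):
        rng = _rng(spec.seed, 11, si)
        weights = abund[:, si] * lengths
        weights = weights / weights.sum()
        counts = rng.multinomial(spec.reads_per_sample, weights)
        sample_reads: List[Tuple[str, str]] = []
        cover_masks = {r: np.zeros(rep_len[r], dtype=bool) for r in reps}
        rn = 0
        for pi, g in enumerate(phages):
            c = int(counts[pi])
            if c == 0:
                continue
            rep = truth[g.id].votu_rep
            read_counts[rep_index[rep], si] += c
            span = len(g.seq) - spec.read_len
            starts = rng.integers(0, span + 1, c)
            for st in starts:
                st = int(st)
                frag = g.seq[st:st + spec.read_len]
                nerr = rng.binomial(spec.read_len, spec.subst_error)
                if nerr:
                    fl = list(frag)
                    for p in rng.choice(spec.read_len, nerr, replace=False):
                        alt = [x for x in "ACGT" if x != fl[p]]
                        fl[p] = alt[int(rng.integers(0, 3))]
                    frag = "".join(fl)
                rn += 1
                sample_reads.append((f"{sample}_r{rn:06d}", frag))
                mask = cover_masks[rep]
                mask[st:min(st + spec.read_len, len(mask))] = True
        for r in reps:
            covered[rep_index[r], si] = 100.0 * cover_masks[r].mean()
        reads[sample] = sample_reads
    return reads, abund, read_counts, covered, reps


# ---------------------------------------------------------------------------
# reference TerL proteins (stand-ins for labeled human vOTUs)


def reference_terl(spec: CommunitySpec,
                   per_family: Optional[int] = None) \
        -> List[Tuple[str, str, str]]:
    if per_family is None:
        per_family = spec.refs_per_family
    variants = family_marker_variants(spec)
    out = []
    for fi, fam in enumerate(REFERENCE_FAMILIES):
        rng = _rng(spec.seed, 12, fi)
        for i in range(per_family):
            aa = _mutate_protein(rng, variants[fam]["TerL"],
                                 spec.ref_divergence)
            out.append((f"href_{fam}_{i + 1}", fam, aa))
    return out


# ---------------------------------------------------------------------------
# bundle + fixture directory


def simulate_community(spec: CommunitySpec) -> TruthBundle:
    phages, ptruth = simulate_phages(spec)
    bacteria, taxonomy, arrays = simulate_bacteria(spec, phages)
    refs = reference_terl(spec)
    bundle = TruthBundle(spec=spec, phages=phages, phage_truth=ptruth,
                         bacteria=bacteria, taxonomy=taxonomy, arrays=arrays,
                         reference_terl=refs)
    return bundle


def write_fixture(bundle: TruthBundle, outdir: str, *,
                  with_reads: bool = True) -> None:
    """Write the community as a fixture directory of standard text formats."""
    import pandas as pd
    spec = bundle.spec
    os.makedirs(outdir, exist_ok=True)
    decoys = simulate_decoys(spec)
    write_fasta(bundle.phages + decoys, os.path.join(outdir, "contigs.fasta"))
    write_fasta(bundle.phages, os.path.join(outdir, "phages.fasta"))
    write_fasta(bundle.bacteria, os.path.join(outdir, "bacteria.fasta"))
    viral_score_table(spec, bundle.phages, decoys).to_csv(
        os.path.join(outdir, "viral_scores.tsv"), sep="\t", index=False)
    pd.DataFrame([(k, v) for k, v in bundle.taxonomy.items()],
                 columns=["genome_id", "lineage"]).to_csv(
        os.path.join(outdir, "taxonomy.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "ref_terl.fasta"), "w") as fh:
        for rid, fam, aa in bundle.reference_terl:
            fh.write(f">{rid}|{fam}\n{aa}\n")
    pd.DataFrame(
        [(t.genome_id, t.family, t.code, t.length, t.votu_rep)
         for t in bundle.phage_truth.values()],
        columns=["genome_id", "family", "code", "length", "votu_rep"]).to_csv(
        os.path.join(outdir, "truth_phages.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(g.genome_id, m.label, m.start, m.end, m.strand)
         for g in bundle.phage_truth.values() if g.votu_rep == g.genome_id
         for m in g.markers],
        columns=["genome_id", "marker", "start", "end", "strand"]).to_csv(
        os.path.join(outdir, "truth_markers.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(t.genome_id, t.block_fillers[0], t.block_fillers[1],
          t.block_fillers[3])
         for t in bundle.phage_truth.values() if t.votu_rep == t.genome_id],
        columns=["genome_id", "ihf54_mcp", "mcp_portal",
                 "terl_primase"]).to_csv(
        os.path.join(outdir, "truth_blocks.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(s.bacterium_id, s.array_index, s.spacer_seq, s.phage_id,
          s.mismatches) for a in bundle.arrays for s in a.spacers],
        columns=["bacterium_id", "array_index", "spacer", "phage_id",
                 "mismatches"]).to_csv(
        os.path.join(outdir, "truth_spacers.tsv"), sep="\t", index=False)
    pd.DataFrame([(s, g) for s, g in spec.group_design.items()],
                 columns=["sample", "group"]).to_csv(
        os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "spec.yaml"), "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=True)
    if with_reads:
        reads, abund, counts, covered, reps = simulate_reads(
            spec, bundle.phages, bundle.phage_truth)
        bundle.abundance = abund
        bundle.read_counts = counts
        bundle.covered_fraction = covered
        bundle.votu_reps = reps
        rdir = os.path.join(outdir, "reads")
        os.makedirs(rdir, exist_ok=True)
        for sample, rs in reads.items():
            with open(os.path.join(rdir, f"{sample}.fasta"), "w") as fh:
                for rid, seq in rs:
                    fh.write(f">{rid}\n{seq}\n")
        pd.DataFrame(abund, index=[g.id for g in bundle.phages],
                     columns=spec.samples).rename_axis("genome_id").to_csv(
            os.path.join(outdir, "truth_abundance.tsv"), sep="\t")
        pd.DataFrame(covered, index=reps,
                     columns=spec.samples).rename_axis("votu_rep").to_csv(
            os.path.join(outdir, "truth_covered_fraction.tsv"), sep="\t")


def _spec_to_dict(spec: CommunitySpec) -> dict:
    d = asdict(spec)
    d["genome_len_range"] = list(spec.genome_len_range)
    d["spacers_per_array"] = list(spec.spacers_per_array)
    d["effect_votus"] = [[v, float(f)] for v, f in spec.effect_votus]
    return d


def spec_from_yaml(path: str) -> CommunitySpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["genome_len_range"] = tuple(d["genome_len_range"])
    d["spacers_per_array"] = tuple(d["spacers_per_array"])
    d["effect_votus"] = [(v, float(f)) for v, f in d.get("effect_votus", [])]
    d["code_mix"] = {int(k): v for k, v in d["code_mix"].items()}
    return CommunitySpec(**d)
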