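"""CRISPR-spacer host prediction.

Arrays are detected CRT/MinCED-style: >= 3 near-identical repeats (23-47 bp,
<= 1 mismatch between copies) separated by 17-50 bp spacers. Spacers are
matched to phage genomes by exhaustive Hamming scan on both strands with at
most one mismatch over the full spacer - the published criterion is exactly
a Hamming condition, so the scan is exact.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ThresholdConfig
from .records import GenomeRecord, reverse_complement

REPEAT_MIN, REPEAT_MAX = 23, 47
SPACER_MIN, SPACER_MAX = 17, 50
MIN_REPEATS = 3
_SEED_K = 13


@dataclass
class CrisprArray:
    genome_id: str
    repeat_seq: str
    repeat_positions: List[int]
    spacers: List[Tuple[str, int, int]]    # (seq, start, end)

    def validate(self) -> None:
        if len(self.repeat_positions) < MIN_REPEATS:
            raise ValueError("array with fewer than 3 repeats")
        if len(self.spacers) != len(self.repeat_positions) - 1:
            raise ValueError("spacer count must be repeat count - 1")
        rl = len(self.repeat_seq)
        if not REPEAT_MIN <= rl <= REPEAT_MAX:
            raise ValueError(f"repeat length {rl} outside bounds")
        for (seq, s, e) in self.spacers:
            if not SPACER_MIN <= e - s <= SPACER_MAX:
                raise ValueError("spacer length outside bounds")


@dataclass
class SpacerHit:
    spacer: str
    phage_id: str
    position: int
    strand: str
    mismatches: int


@dataclass
class HostAssignment:
    votu_id: str
    bacterial_genome_id: str
    taxonomy: str
    n_matching_spacers: int
    mismatches_per_hit: List[int]


def find_crispr_arrays(genome: GenomeRecord) -> List[CrisprArray]:
    """Detect CRISPR arrays by seeding on recurring k-mers with array-like
    spacing, then extending the repeat across all copies."""
    if len(genome.seq) < 200:
        raise ValueError("sequence too short for CRISPR detection")
    seq = genome.seq
    positions: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - _SEED_K + 1):
        positions[seq[i:i + _SEED_K]].append(i)
    min_period = REPEAT_MIN + SPACER_MIN
    max_period = REPEAT_MAX + SPACER_MAX
    candidates: List[CrisprArray] = []
    seen_spans = []
    for kmer, pos in positions.items():
        if len(pos) < MIN_REPEATS:
            continue
        # maximal runs with array-like spacing
        run = [pos[0]]
        runs = []
        for p in pos[1:]:
            if min_period <= p - run[-1] <= max_period:
                run.append(p)
            else:
                if len(run) >= MIN_REPEATS:
                    runs.append(run)
                run = [p]
        if len(run) >= MIN_REPEATS:
            runs.append(run)
        for run in runs:
            arr = _extend_array(seq, run)
            if arr is None:
                continue
            span = (arr.repeat_positions[0],
                    arr.repeat_positions[-1] + len(arr.repeat_seq))
            if any(not (span[1] <= s or span[0] >= e)
                   for s, e in seen_spans):
                # overlapping candidate: keep the one with more repeats
                for idx, other in enumerate(candidates):
                    ospan = (other.repeat_positions[0],
                             other.repeat_positions[-1]
                             + len(other.repeat_seq))
                    if not (span[1] <= ospan[0] or span[0] >= ospan[1]):
                        if len(arr.repeat_positions) > \
                                len(other.repeat_positions):
                            candidates[idx] = arr
                            seen_spans[idx] = span
                        break
                continue
            candidates.append(arr)
            seen_spans.append(span)
    candidates.sort(key=lambda a: a.repeat_positions[0])
    for arr in candidates:
        arr.validate()
    return candidates


def _extend_array(seq: str, run: List[int]) -> Optional[CrisprArray]:
    """Extend seed positions to the maximal repeat consistent across all
    copies (<= 1 internal mismatch per copy vs the first), then carve out
    spacers. Boundary columns with any mismatch are trimmed so a tolerated
    mismatch can only be internal."""
    first = run[0]
    mism = [0] * len(run)
    agree: Dict[int, bool] = {}     # column offset (relative to seed) -> all agree
    left = 0
    while left < first and all(p - left - 1 >= 0 for p in run) \
            and left + _SEED_K < REPEAT_MAX:
        c0 = seq[first - left - 1]
        trial = [seq[p - left - 1] for p in run]
        new_m = [m + (t != c0) for m, t in zip(mism, trial)]
        if max(new_m) > 1:
            break
        mism = new_m
        left += 1
        agree[-left] = all(t == c0 for t in trial)
    right = _SEED_K
    while all(p + right < len(seq) for p in run) \
            and left + right < REPEAT_MAX:
        c0 = seq[first + right]
        trial = [seq[p + right] for p in run]
        new_m = [m + (t != c0) for m, t in zip(mism, trial)]
        if max(new_m) > 1:
            break
        mism = new_m
        agree[right] = all(t == c0 for t in trial)
        right += 1
    # trim boundary columns containing a tolerated mismatch
    while left > 0 and not agree.get(-left, True):
        left -= 1
    while right > _SEED_K and not agree.get(right - 1, True):
        right -= 1
    rep_len = left + right
    if rep_len < REPEAT_MIN:
        return None
    starts = [p - left for p in run]
    # spacer sanity
    spacers = []
    for s1, s2 in zip(starts, starts[1:]):
        sp_start, sp_end = s1 + rep_len, s2
        if not SPACER_MIN <= sp_end - sp_start <= SPACER_MAX:
            return None
        spacers.append((seq[sp_start:sp_end], sp_start, sp_end))
    return CrisprArray(genome_id="", repeat_seq=seq[starts[0]:
                                                    starts[0] + rep_len],
                       repeat_positions=starts, spacers=spacers)


def find_all_arrays(bacteria: Sequence[GenomeRecord]) -> List[CrisprArray]:
    out = []
    for g in bacteria:
        for arr in find_crispr_arrays(g):
            arr.genome_id = g.id
            out.append(arr)
    return out


# ---------------------------------------------------------------------------
# spacer matching


_NT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NT[ord(_b)] = _i


def match_spacer(spacer: str, phage: GenomeRecord,
                 cfg: ThresholdConfig = DEFAULT_CONFIG) -> List[SpacerHit]:
    """All placements on either strand with Hamming distance within the
    mismatch cap over the full spacer (no indels)."""
    if not SPACER_MIN <= len(spacer) <= SPACER_MAX:
        raise ValueError(f"spacer length {len(spacer)} outside bounds")
    if "N" in spacer:
        raise ValueError("spacer contains N")
    m = len(spacer)
    encoded = {
        "+": _NT[np.frombuffer(phage.seq.encode(), dtype=np.uint8)],
        "-": _NT[np.frombuffer(reverse_complement(phage.seq).encode(),
                               dtype=np.uint8)]}
    return _scan_encoded(spacer, phage.id, encoded,
                         cfg.spacer_max_mismatch)


def _scan_encoded(spacer: str, phage_id: str,
                  encoded: Dict[str, np.ndarray],
                  max_mismatch: int) -> List[SpacerHit]:
    m = len(spacer)
    sp = _NT[np.frombuffer(spacer.encode(), dtype=np.uint8)]
    hits: List[SpacerHit] = []
    n = len(encoded["+"])
    for strand in ("+", "-"):
        arr = encoded[strand]
        if len(arr) < m:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(arr, m)
        mism = (wins != sp).sum(axis=1)
        for pos in np.flatnonzero(mism <= max_mismatch):
            pos = int(pos)
            start = pos if strand == "+" else n - pos - m
            hits.append(SpacerHit(spacer=spacer, phage_id=phage_id,
                                  position=start, strand=strand,
                                  mismatches=int(mism[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# host assignment


def genus_of(lineage: str) -> str:
    for part in lineage.split(";"):
        part = part.strip()
        if part.startswith("g__"):
            return part[3:]
    return "unknown"


def assign_hosts(arrays: Sequence[CrisprArray],
                 phages: Sequence[GenomeRecord],
                 votu_of: Dict[str, str],
                 taxonomy: Dict[str, str],
                 cfg: ThresholdConfig = DEFAULT_CONFIG) \
        -> Tuple[List[HostAssignment], pd.DataFrame]:
    """Aggregate spacer hits to (vOTU x bacterial genome) assignments and a
    per-vOTU genus-breadth summary."""
    encodings = {
        p.id: {"+": _NT[np.frombuffer(p.seq.encode(), dtype=np.uint8)],
               "-": _NT[np.frombuffer(
                   reverse_complement(p.seq).encode(), dtype=np.uint8)]}
        for p in phages}
    agg: Dict[Tuple[str, str], List[int]] = defaultdict(list)
    for arr in arrays:
        for spacer, _, _ in arr.spacers:
            for phage in phages:
                for hit in _scan_encoded(spacer, phage.id,
                                         encodings[phage.id],
                                         cfg.spacer_max_mismatch):
                    votu = votu_of.get(phage.id, phage.id)
                    agg[(votu, arr.genome_id)].append(hit.mismatches)
    assignments = []
    for (votu, bact), mms in sorted(agg.items()):
        lineage = taxonomy.get(bact)
        if lineage is None:
            import warnings
            warnings.warn(f"bacterial genome {bact} missing taxonomy")
            lineage = "unknown"
        assignments.append(HostAssignment(
            votu_id=votu, bacterial_genome_id=bact, taxonomy=lineage,
            n_matching_spacers=len(mms), mismatches_per_hit=sorted(mms)))
    genera: Dict[str, set] = defaultdict(set)
    for a in assignments:
        genera[a.votu_id].add(genus_of(a.taxonomy))
    summary = pd.DataFrame(
        [(v, len(gs), ";".join(sorted(gs)), len(gs) >= 2)
         for v, gs in sorted(genera.items())],
        columns=["votu_id", "n_genera", "genera", "multi_genus"])
    return assignments, summary
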