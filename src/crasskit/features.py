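"""Genome-level characterization: genetic-code inference, suppressor-tRNA
detection, marker annotation, gene-block statistics, anti-CRISPR filtering
and CAZyme prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, ThresholdConfig
from .markers import TRNA_ANTICODON_OFFSET, marker_profiles, trna_template
from .pssm import Profile, pssm_search
from .records import GenomeRecord, GeneAnnotation, reverse_complement
from .translate import SUPPORTED_CODES, coding_density, find_orfs, orf_protein


@dataclass
class CodeCall:
    genome_id: str
    code: int
    densities: Dict[int, float]


#: margin by which an alternative code's coding density must beat the
#: standard code before it is called (guards against spurious switches)
CODE_MARGIN = 0.05


def infer_genetic_code(genome: GenomeRecord, *, min_len_aa: int = 60,
                       margin: float = CODE_MARGIN,
                       codes: Sequence[int] = SUPPORTED_CODES) -> CodeCall:
    """Pick the genetic code that maximizes coding density.

    Stop-codon reassignment (TAG->Q under code 15, TGA->W under code 4)
    fragments genes when called under the wrong code, so the true code shows
    a clearly higher density of called ORFs. The standard code wins unless
    an alternative exceeds it by ``margin``.
    """
    if len(genome.seq) < 3000:
        raise ValueError("genome too short for code inference (< 3 kb)")
    densities = {}
    for code in codes:
        orfs = find_orfs(genome, code, min_len_aa)
        densities[code] = coding_density(genome, orfs)
    best_alt = max((c for c in codes if c != 11),
                   key=lambda c: (densities[c], -c), default=None)
    if best_alt is not None and \
            densities[best_alt] > densities.get(11, 0.0) + margin:
        chosen = best_alt
    else:
        chosen = 11 if 11 in densities else max(
            codes, key=lambda c: densities[c])
    return CodeCall(genome_id=genome.id, code=chosen, densities=densities)


# ---------------------------------------------------------------------------
# suppressor tRNA


@dataclass
class SuppressorTrna:
    genome_id: str
    position: int               # 0-based start of the cassette match
    strand: str
    anticodon: str              # CTA or TCA
    suppresses: str             # TAG or TGA


_SUPPRESSOR_ANTICODONS = {"CTA": "TAG", "TCA": "TGA"}


def detect_suppressor_trna(genome: GenomeRecord,
                           template: Optional[str] = None,
                           min_identity: float = 0.9) -> List[SuppressorTrna]:
    """Scan both strands for >= 90%-identity matches to the tRNA template
    (anticodon positions excluded from scoring); report matches whose
    anticodon is CTA (suppresses TAG) or TCA (suppresses TGA)."""
    if template is None:
        template = trna_template()
    tlen = len(template)
    tmpl = np.frombuffer(template.encode(), dtype=np.uint8)
    scored = tmpl != ord("N")
    n_scored = int(scored.sum())
    out: List[SuppressorTrna] = []
    for strand, seq in (("+", genome.seq),
                        ("-", reverse_complement(genome.seq))):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < tlen:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(arr, tlen)
        matches = ((wins == tmpl) & scored).sum(axis=1)
        for pos in np.flatnonzero(matches >= min_identity * n_scored):
            pos = int(pos)
            anticodon = seq[pos + TRNA_ANTICODON_OFFSET:
                            pos + TRNA_ANTICODON_OFFSET + 3]
            if anticodon in _SUPPRESSOR_ANTICODONS:
                start = pos if strand == "+" \
                    else len(seq) - pos - tlen
                out.append(SuppressorTrna(
                    genome_id=genome.id, position=start, strand=strand,
                    anticodon=anticodon,
                    suppresses=_SUPPRESSOR_ANTICODONS[anticodon]))
    out.sort(key=lambda t: t.position)
    return out


# ---------------------------------------------------------------------------
# marker annotation


def resolve_overlaps(orfs: Sequence[GeneAnnotation],
                     genome_length: int,
                     max_overlap_frac: float = 0.75,
                     max_opposite_frac: float = 0.5) -> List[GeneAnnotation]:
    """Greedy, strand-aware gene-set selection.

    Marker-labeled ORFs are kept first (a real marker gene must not be
    displaced by a chance stop-free frame), then longer ORFs win. An ORF is
    dropped once more than ``max_overlap_frac`` of it overlaps kept genes,
    or more than ``max_opposite_frac`` overlaps kept genes on the opposite
    strand: a same-strand call that runs through a chance stop-free stretch
    into its neighbor is a legitimate extended gene, whereas a deep
    opposite-strand overlap is almost always a spurious mirror frame. The
    rule is symmetric under reverse complementation."""
    kept: List[GeneAnnotation] = []
    masks = {"+": np.zeros(genome_length, dtype=bool),
             "-": np.zeros(genome_length, dtype=bool)}
    ordered = sorted(orfs, key=lambda o: (o.label == "unknown",
                                          -(o.end - o.start), o.start))
    for orf in ordered:
        L = orf.end - orf.start
        ov_same = int(masks[orf.strand][orf.start:orf.end].sum())
        other = "-" if orf.strand == "+" else "+"
        ov_opp = int(masks[other][orf.start:orf.end].sum())
        if ov_same + ov_opp <= max_overlap_frac * L \
                and ov_opp <= max_opposite_frac * L:
            kept.append(orf)
            masks[orf.strand][orf.start:orf.end] = True
    kept.sort(key=lambda o: (o.start, o.end))
    return kept


def annotate_markers(genome: GenomeRecord,
                     profiles: Optional[Dict[str, Profile]] = None,
                     code: Optional[int] = None,
                     min_len_aa: int = 100) -> List[GeneAnnotation]:
    """Call genes under the genome's (inferred) code, label each with the
    best-hitting marker profile (else "unknown"), and resolve overlapping
    reading frames label-aware."""
    if profiles is None:
        profiles = marker_profiles()
    if code is None:
        code = infer_genetic_code(genome).code
    annotated = []
    for orf in find_orfs(genome, code, min_len_aa):
        prot = orf_protein(genome, orf, code)
        best_name, best_score = "unknown", -np.inf
        for name, prof in profiles.items():
            hit = pssm_search(prot, prof)
            if hit is not None and hit.score > best_score:
                best_name, best_score = name, hit.score
        annotated.append(GeneAnnotation(
            genome_id=orf.genome_id, start=orf.start, end=orf.end,
            strand=orf.strand, label=best_name, length_aa=orf.length_aa,
            score=0.0 if best_name == "unknown" else best_score))
    return resolve_overlaps(annotated, genome.length)


# ---------------------------------------------------------------------------
# gene blocks


BLOCK_PAIRS = (("IHF_54", "MCP"), ("MCP", "portal"), ("TerL", "primase"))


@dataclass
class BlockCounts:
    genome_id: str
    ihf54_mcp: Optional[int]
    mcp_portal: Optional[int]
    terl_primase: Optional[int]


def _marker_span(genes: Sequence[GeneAnnotation], marker: str) \
        -> Optional[Tuple[int, int]]:
    copies = [g for g in genes if g.label == marker]
    if not copies:
        return None
    if len(copies) > 1:
        warnings.warn(f"marker {marker} present {len(copies)}x; using the "
                      "highest-scoring copy")
        copies.sort(key=lambda g: (-g.score, g.start))
    return copies[0].start, copies[0].end


def count_genes_between(genes: Sequence[GeneAnnotation], a: str, b: str,
                        circular: bool = False,
                        genome_length: Optional[int] = None) -> Optional[int]:
    """Number of genes strictly between markers ``a`` and ``b`` (midpoint
    rule); on circular genomes the shorter arc is used. None when either
    marker is missing."""
    span_a = _marker_span(genes, a)
    span_b = _marker_span(genes, b)
    if span_a is None or span_b is None:
        return None
    mid = lambda s: (s[0] + s[1]) / 2.0
    ma, mb = mid(span_a), mid(span_b)
    others = [g for g in genes
              if (g.start, g.end) != span_a and (g.start, g.end) != span_b]
    mids = np.array([mid((g.start, g.end)) for g in others])
    lo, hi = min(ma, mb), max(ma, mb)
    inside = int(((mids > lo) & (mids < hi)).sum())
    if not circular:
        return inside
    if genome_length is None:
        raise ValueError("circular counting needs genome_length")
    arc_inner = hi - lo
    arc_outer = genome_length - arc_inner
    if arc_inner <= arc_outer:
        return inside
    return len(others) - inside


def block_counts(genes: Sequence[GeneAnnotation], genome_id: str,
                 circular: bool = False,
                 genome_length: Optional[int] = None) -> BlockCounts:
    vals = [count_genes_between(genes, a, b, circular, genome_length)
            for a, b in BLOCK_PAIRS]
    return BlockCounts(genome_id, *vals)


# ---------------------------------------------------------------------------
# rank-sum test


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) \
        -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by full enumeration of labelings when n + m <= 10 (correct under
    ties); otherwise the normal approximation with tie and continuity
    correction. Returns (W = rank sum of x, two-sided p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:x.size].sum())
    if np.all(pooled == pooled[0]):
        return w_obs, 1.0
    n, m = x.size, y.size
    if n + m <= 10:
        idx = range(n + m)
        ws = np.array([ranks[list(c)].sum()
                       for c in combinations(idx, n)])
        mean_w = ws.mean()
        dev = abs(w_obs - mean_w)
        p = float((np.abs(ws - mean_w) >= dev - 1e-12).mean())
        return w_obs, min(p, 1.0)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return w_obs, float(res.pvalue)


def pairwise_block_tests(blocks: pd.DataFrame,
                         family_col: str = "family") -> pd.DataFrame:
    """All pairwise family comparisons of each gene-block count."""
    rows = []
    fams = sorted(blocks[family_col].dropna().unique())
    for col in ("ihf54_mcp", "mcp_portal", "terl_primase"):
        for fa, fb in combinations(fams, 2):
            xa = blocks.loc[blocks[family_col] == fa, col].dropna()
            xb = blocks.loc[blocks[family_col] == fb, col].dropna()
            if len(xa) == 0 or len(xb) == 0:
                continue
            w, p = wilcoxon_rank_sum(xa, xb)
            rows.append((col, fa, fb, len(xa), len(xb),
                         float(xa.median()), float(xb.median()), w, p))
    return pd.DataFrame(rows, columns=[
        "block", "family_a", "family_b", "n_a", "n_b",
        "median_a", "median_b", "W", "pvalue"])


# ---------------------------------------------------------------------------
# anti-CRISPR filtering and CAZyme prevalence


@dataclass
class AcrCandidate:
    protein_id: str
    length_aa: int
    pred_a: bool
    pred_b: bool


def filter_acr(cands: Sequence[AcrCandidate],
               cfg: ThresholdConfig = DEFAULT_CONFIG) -> List[AcrCandidate]:
    """Keep candidates called by both predictors and at most 200 aa long."""
    return [c for c in cands
            if c.pred_a and c.pred_b and c.length_aa <= cfg.acr_maxlen]


def cazyme_cluster_prevalence(annots: pd.DataFrame,
                              genome_families: Dict[str, str],
                              cazyme_types: Optional[Sequence[str]] = None) \
        -> pd.DataFrame:
    """Percent of genomes per family carrying >= 1 gene of each CAZyme type.

    ``annots`` needs columns genome_id and cazyme_type (one row per gene).
    Types absent from a family report 0; families with no annotated genome
    still appear.
    """
    if cazyme_types is None:
        cazyme_types = sorted(annots["cazyme_type"].dropna().unique())
    fams = sorted(set(genome_families.values()))
    genomes_by_fam = {f: [g for g, gf in genome_families.items() if gf == f]
                      for f in fams}
    table = pd.DataFrame(0.0, index=fams, columns=list(cazyme_types))
    for f in fams:
        members = genomes_by_fam[f]
        if not members:
            continue
        sub = annots[annots["genome_id"].isin(members)]
        for t in cazyme_types:
            carriers = sub.loc[sub["cazyme_type"] == t, "genome_id"].nunique()
            table.loc[f, t] = 100.0 * carriers / len(members)
    table.index.name = "family"
    return table
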