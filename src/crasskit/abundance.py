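"""Coverage-gated RPKM quantification, prevalence rules and fat/lean
association testing.

Quantification follows the virome-profiling convention: reads map gaplessly
to vOTU representatives, alignments under 90% identity or under 95% of the
read length are discarded, RPKM is reads x 10^9 / (genome length x total
reads), and a vOTU's abundance is zeroed in samples where less than 75% of
its representative genome is covered. Detection for prevalence uses the
strict complement (> 75% covered).

Association is a MaAsLin-style per-feature linear model: total-sum scaling,
log2 transform with a half-minimum pseudocount, per-vOTU regression on the
group label, Benjamini-Hochberg correction, and the signed significance
score -log10(qval) * sign(coeff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, ThresholdConfig
from .records import GenomeRecord

_NT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT[ord(_b)] = _i

SEED_K = 31
_INDEX_STRIDE = 4


def _encode(seq: str) -> np.ndarray:
    return _NT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _rolling_hashes(enc: np.ndarray, k: int) -> np.ndarray:
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        seg = enc[j:j + n]
        h = h * 4 + seg
        bad |= seg == 255
    h[bad] = -1
    return h


@dataclass
class ReferenceIndex:
    """Seed index over vOTU representative genomes (stride-sampled
    k-mers)."""

    rep_ids: List[str]
    encoded: Dict[str, np.ndarray]
    lengths: Dict[str, int]
    seeds: Dict[int, int]       # hash -> (rep_index << 34) | position


def build_index(reps: Sequence[GenomeRecord]) -> ReferenceIndex:
    rep_ids = [g.id for g in reps]
    encoded = {g.id: _encode(g.seq) for g in reps}
    seeds: Dict[int, int] = {}
    for ri, g in enumerate(reps):
        h = _rolling_hashes(encoded[g.id], SEED_K)
        for pos in range(0, len(h), _INDEX_STRIDE):
            hv = int(h[pos])
            if hv >= 0 and hv not in seeds:
                seeds[hv] = (ri << 34) | pos
    return ReferenceIndex(rep_ids=rep_ids, encoded=encoded,
                          lengths={g.id: len(g.seq) for g in reps},
                          seeds=seeds)


def map_reads(reads: Sequence[Tuple[str, str]], index: ReferenceIndex,
              cfg: ThresholdConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Gapless seed-and-extend mapping of reads to representatives.

    Every read is placed at most once: all candidate placements from seed
    hits are scored and the best identity wins (ties to the first
    representative in canonical order). Placements failing the identity or
    aligned-percent gate are dropped.

    Returns a DataFrame with columns read_id, votu_rep_id, identity,
    aligned_percent, start, end.
    """
    rows = []
    mask = (1 << 34) - 1
    for read_id, seq in reads:
        if len(seq) < SEED_K:
            continue
        enc = _encode(seq)
        hashes = _rolling_hashes(enc, SEED_K)
        candidates = {}
        for o in range(len(hashes)):
            hv = int(hashes[o])
            if hv < 0:
                continue
            packed = index.seeds.get(hv)
            if packed is None:
                continue
            ri, pos = packed >> 34, packed & mask
            start = pos - o
            key = (ri, start)
            if key in candidates:
                continue
            rep_id = index.rep_ids[ri]
            renc = index.encoded[rep_id]
            g_start = max(0, start)
            g_end = min(len(renc), start + len(seq))
            r_start = g_start - start
            r_end = r_start + (g_end - g_start)
            overlap = g_end - g_start
            if overlap <= 0:
                continue
            mism = int((renc[g_start:g_end] != enc[r_start:r_end]).sum())
            identity = 100.0 * (overlap - mism) / overlap
            aligned_percent = 100.0 * overlap / len(seq)
            candidates[key] = (identity, aligned_percent, ri, g_start, g_end)
            if mism == 0 and overlap == len(seq):
                break     # perfect placement; nothing can beat it
        if not candidates:
            continue
        best = max(candidates.values(),
                   key=lambda c: (c[0], -c[2]))
        identity, aligned_percent, ri, g_start, g_end = best
        if identity < cfg.read_min_identity \
                or aligned_percent < cfg.read_min_aligned:
            continue
        rows.append((read_id, index.rep_ids[ri], identity,
                     aligned_percent, g_start, g_end))
    return pd.DataFrame(rows, columns=[
        "read_id", "votu_rep_id", "identity", "aligned_percent",
        "start", "end"])


# ---------------------------------------------------------------------------
# quantification


@dataclass
class AbundanceMatrix:
    rpkm: pd.DataFrame               # vOTU x sample
    covered_fraction: pd.DataFrame   # same shape, percent
    detected: pd.DataFrame           # boolean, covered_fraction > threshold
    read_counts: pd.DataFrame


def quantify(alignments_by_sample: Dict[str, pd.DataFrame],
             reps: Sequence[GenomeRecord],
             total_reads_per_sample: Dict[str, int],
             cfg: ThresholdConfig = DEFAULT_CONFIG) -> AbundanceMatrix:
    """RPKM with the 75% coverage gate.

    rpkm(v, s) = count x 10^9 / (genome length x total reads); abundance is
    zeroed where covered fraction < 75%, and detection requires covered
    fraction > 75% (the published rules use < and > respectively, leaving
    exactly-75% zero-but-not-detected).
    """
    samples = list(alignments_by_sample)
    rep_ids = [g.id for g in reps]
    lengths = {g.id: len(g.seq) for g in reps}
    rpkm = pd.DataFrame(0.0, index=rep_ids, columns=samples)
    covered = pd.DataFrame(0.0, index=rep_ids, columns=samples)
    counts = pd.DataFrame(0, index=rep_ids, columns=samples)
    for s, aln in alignments_by_sample.items():
        total = total_reads_per_sample[s]
        if total <= 0:
            raise ValueError(f"sample {s}: total reads must be positive")
        for rep in rep_ids:
            sub = aln[aln["votu_rep_id"] == rep]
            n = len(sub)
            counts.loc[rep, s] = n
            if n == 0:
                continue
            mask = np.zeros(lengths[rep], dtype=bool)
            for st, en in zip(sub["start"].to_numpy(),
                              sub["end"].to_numpy()):
                mask[st:en] = True
            covered.loc[rep, s] = 100.0 * mask.mean()
            rpkm.loc[rep, s] = n * 1e9 / (lengths[rep] * total)
    gated = rpkm.where(covered >= cfg.min_covered_fraction, 0.0)
    detected = covered > cfg.min_covered_fraction
    return AbundanceMatrix(rpkm=gated, covered_fraction=covered,
                           detected=detected, read_counts=counts)


# ---------------------------------------------------------------------------
# prevalence


def prevalence(detected: pd.DataFrame,
               sample_to_population: Optional[Dict[str, str]] = None,
               votu_families: Optional[Dict[str, str]] = None) \
        -> Tuple[pd.Series, Optional[pd.DataFrame], Optional[pd.DataFrame]]:
    """Per-vOTU sample prevalence (%), per-population detection, and
    per-sample family-cluster presence.

    A vOTU is detected in a population if any of its samples detects it; a
    cluster is present in a sample if any member vOTU is detected there.
    """
    prev = 100.0 * detected.mean(axis=1)
    prev.name = "prevalence_percent"
    pop_det = None
    if sample_to_population is not None:
        missing = set(detected.columns) - set(sample_to_population)
        if missing:
            raise ValueError(f"samples without population: {sorted(missing)}")
        pops = sorted(set(sample_to_population.values()))
        pop_det = pd.DataFrame(False, index=detected.index, columns=pops)
        for p in pops:
            cols = [s for s in detected.columns
                    if sample_to_population[s] == p]
            pop_det[p] = detected[cols].any(axis=1)
    cluster_presence = None
    if votu_families is not None:
        fams = sorted(set(votu_families.values()))
        cluster_presence = pd.DataFrame(False, index=fams,
                                        columns=detected.columns)
        for f in fams:
            members = [v for v in detected.index
                       if votu_families.get(v) == f]
            if members:
                cluster_presence.loc[f] = detected.loc[members].any(axis=0)
    return prev, pop_det, cluster_presence


# ---------------------------------------------------------------------------
# association


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class AssociationResult:
    votu_id: str
    coeff: float
    pval: float
    qval: float
    signed_score: float
    significant: bool


def associate_groups(abund: AbundanceMatrix, groups: Dict[str, str],
                     cfg: ThresholdConfig = DEFAULT_CONFIG,
                     case_label: str = "fat",
                     min_prevalence: float = 0.5) -> List[AssociationResult]:
    """Per-vOTU linear model of transformed abundance on group membership.

    Abundances are total-sum scaled per sample, transformed with
    y = log2(x + half the smallest nonzero value), and each tested vOTU is
    regressed on the binary group indicator (``case_label`` coded 1).
    P-values are BH-adjusted across tested vOTUs; the signed score is
    -log10(qval) * sign(coeff).

    Only vOTUs observed (nonzero) in at least ``min_prevalence`` of the
    samples are tested: with the coverage gate zeroing sparse features, the
    linear model's p-values are calibrated only for features seen in most
    samples (set 0 to test everything nonzero anywhere).
    """
    mat = abund.rpkm
    samples = list(mat.columns)
    labels = np.array([1.0 if groups[s] == case_label else 0.0
                       for s in samples])
    if labels.sum() < 3 or (len(samples) - labels.sum()) < 3:
        raise ValueError("need at least 3 samples per group")
    tss = mat.div(mat.sum(axis=0).replace(0.0, np.nan), axis=1).fillna(0.0)
    nonzero_frac = (tss > 0).mean(axis=1)
    tested = tss.loc[(nonzero_frac > 0)
                     & (nonzero_frac >= min_prevalence)]
    nz = tested.to_numpy()
    pseudo = nz[nz > 0].min() / 2.0
    y = np.log2(tested.to_numpy() + pseudo)
    coeffs, pvals = [], []
    for row in y:
        if np.allclose(row, row[0]) or np.allclose(labels, labels[0]):
            coeffs.append(0.0)
            pvals.append(1.0)
            continue
        res = stats.linregress(labels, row)
        coeffs.append(float(res.slope))
        pvals.append(float(res.pvalue) if np.isfinite(res.pvalue) else 1.0)
    qvals = bh_adjust(pvals)
    out = []
    for vid, c, p, q in zip(tested.index, coeffs, pvals, qvals):
        score = -np.log10(max(q, 1e-300)) * np.sign(c)
        out.append(AssociationResult(
            votu_id=vid, coeff=c, pval=p, qval=float(q),
            signed_score=float(score), significant=bool(q < cfg.assoc_q)))
    return out


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.votu_id, r.coeff, r.pval, r.qval, r.signed_score, r.significant)
         for r in results],
        columns=["votu_id", "coeff", "pval", "qval", "signed_score",
                 "significant"])
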