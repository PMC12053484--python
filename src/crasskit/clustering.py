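"""vOTU dereplication: greedy centroid clustering at 95% ANI over >= 85%
aligned fraction of the shorter genome, longest genome as representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import align_nt_banded
from .config import DEFAULT_CONFIG, ThresholdConfig
from .records import GenomeRecord


@dataclass
class VOTU:
    rep_id: str
    member_ids: List[str]
    family: str = "unclassified"

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def _merge_spans(spans: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def pairwise_ani(a: GenomeRecord, b: GenomeRecord) -> Tuple[float, float]:
    """(ANI %, aligned fraction %) from chained gapless alignment blocks.

    ANI is the column-weighted identity over all blocks; the aligned
    fraction is the merged aligned span on the shorter genome divided by
    its length. (0, 0) when nothing aligns.
    """
    blocks = align_nt_banded(a, b)
    if not blocks:
        return 0.0, 0.0
    total_cols = sum(blk.aln_len for blk in blocks)
    ident_cols = sum(blk.identity / 100.0 * blk.aln_len for blk in blocks)
    ani = 100.0 * ident_cols / total_cols
    if len(a.seq) <= len(b.seq):
        spans = [(blk.q_start, blk.q_end) for blk in blocks]
        short_len = len(a.seq)
    else:
        spans = [(blk.t_start, blk.t_end) for blk in blocks]
        short_len = len(b.seq)
    covered = sum(e - s for s, e in _merge_spans(spans))
    af = 100.0 * covered / short_len
    return ani, af


def greedy_cluster(genomes: Sequence[GenomeRecord],
                   cfg: ThresholdConfig = DEFAULT_CONFIG,
                   comparisons: Optional[list] = None) -> List[VOTU]:
    """Greedy centroid clustering in length order.

    Genomes are scanned longest-first (ties by id); each joins the first
    centroid with ANI >= ani_thresh and aligned fraction >= af_thresh,
    else founds a new vOTU. The scan order makes the partition invariant
    to input order. Pass a list as ``comparisons`` to record every
    (query, centroid, ani, af) evaluated.
    """
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    order = sorted(genomes, key=lambda g: (-len(g.seq), g.id))
    votus: List[VOTU] = []
    centroids: List[GenomeRecord] = []
    for g in order:
        placed = False
        for votu, cen in zip(votus, centroids):
            ani, af = pairwise_ani(g, cen)
            if comparisons is not None:
                comparisons.append((g.id, cen.id, ani, af))
            if ani >= cfg.ani_thresh and af >= cfg.af_thresh:
                votu.member_ids.append(g.id)
                placed = True
                break
        if not placed:
            votus.append(VOTU(rep_id=g.id, member_ids=[g.id]))
            centroids.append(g)
    return votus


def clusters_table(votus: Sequence[VOTU]) -> "pd.DataFrame":
    import pandas as pd
    return pd.DataFrame(
        [(v.rep_id, ",".join(v.member_ids), v.n_members, v.family)
         for v in votus],
        columns=["rep_id", "members", "n_members", "family"])
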