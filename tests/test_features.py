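"""Genetic-code inference, suppressor tRNAs, gene blocks, rank-sum test,
Acr filtering and CAZyme prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from itertools import combinations
from scipy import stats

from crasskit.features import (AcrCandidate, block_counts,
                               cazyme_cluster_prevalence,
                               count_genes_between, detect_suppressor_trna,
                               filter_acr, infer_genetic_code,
                               wilcoxon_rank_sum)
from crasskit.records import GenomeRecord, GeneAnnotation, \
    reverse_complement
from crasskit.simulate import CommunitySpec, simulate_phage


@pytest.fixture(scope="module")
def planted_genomes():
    spec = CommunitySpec(seed=21, genome_len_range=(70_000, 75_000))
    out = {}
    for code, fam in ((11, "alpha"), (15, "delta"), (4, "zeta")):
        out[code] = simulate_phage(spec, code, fam, code)
    return out


@pytest.mark.parametrize("code", [11, 15, 4])
def test_code_inference_recovers_planted_code(planted_genomes, code):
    genome, truth = planted_genomes[code]
    call = infer_genetic_code(genome)
    assert call.code == code


def test_code_inference_rejects_short_genome():
    with pytest.raises(ValueError):
        infer_genetic_code(GenomeRecord(id="g", seq="ACGT" * 100))


def test_suppressor_trna_planted(planted_genomes):
    genome, truth = planted_genomes[15]
    found = detect_suppressor_trna(genome)
    assert [(t.position, t.anticodon) for t in found] == \
        truth.trna_positions
    assert all(t.suppresses == "TAG" for t in found)


def test_suppressor_trna_minus_strand(planted_genomes):
    genome, truth = planted_genomes[4]
    flipped = GenomeRecord(id="flip", seq=reverse_complement(genome.seq))
    found = detect_suppressor_trna(flipped)
    assert len(found) == len(truth.trna_positions) >= 1
    assert all(t.strand == "-" and t.suppresses == "TGA" for t in found)


def test_suppressor_trna_absent_on_standard_code(planted_genomes):
    genome, _ = planted_genomes[11]
    assert detect_suppressor_trna(genome) == []


# ---------------------------------------------------------------------------
# gene blocks


def _gene(gid, start, end, label="unknown", strand="+", score=0.0):
    return GeneAnnotation(genome_id=gid, start=start, end=end, strand=strand,
                          label=label, length_aa=(end - start) // 3,
                          score=score)


def toy_genes(k_between=3):
    genes = [_gene("g", 0, 300, "IHF_54")]
    pos = 400
    for _ in range(k_between):
        genes.append(_gene("g", pos, pos + 300))
        pos += 400
    genes.append(_gene("g", pos, pos + 300, "MCP"))
    return genes, pos + 300


def test_count_genes_between_construction():
    genes, _ = toy_genes(24)
    assert count_genes_between(genes, "IHF_54", "MCP") == 24


def test_count_adjacent_markers_zero():
    genes, _ = toy_genes(0)
    assert count_genes_between(genes, "IHF_54", "MCP") == 0


def test_count_missing_marker_undefined():
    genes, _ = toy_genes(2)
    assert count_genes_between(genes, "TerL", "primase") is None
    bc = block_counts(genes, "g")
    assert bc.terl_primase is None
    assert bc.ihf54_mcp == 2


def test_count_invariant_under_reverse_complement():
    genes, total = toy_genes(5)
    L = total + 100
    flipped = [_gene("g", L - g.end, L - g.start, g.label,
                     "-" if g.strand == "+" else "+")
               for g in genes]
    assert count_genes_between(sorted(flipped, key=lambda g: g.start),
                               "IHF_54", "MCP") == \
        count_genes_between(genes, "IHF_54", "MCP")


def test_count_circular_uses_shorter_arc():
    # markers near the ends: the short arc crosses the origin
    genes = [_gene("g", 0, 90, "MCP"),
             _gene("g", 150, 240),
             _gene("g", 300, 390),
             _gene("g", 500, 590),
             _gene("g", 800, 890, "IHF_54"),
             _gene("g", 910, 980)]
    linear = count_genes_between(genes, "IHF_54", "MCP", circular=False)
    circ = count_genes_between(genes, "IHF_54", "MCP", circular=True,
                               genome_length=1000)
    assert linear == 3
    assert circ == 1      # the wrap-around arc holds only the 910-980 gene


def test_duplicate_marker_uses_best_scoring_copy():
    genes = [_gene("g", 0, 300, "IHF_54", score=900.0),
             _gene("g", 400, 700),
             _gene("g", 800, 1100, "IHF_54", score=5.0),
             _gene("g", 1200, 1500, "MCP", score=400.0)]
    with pytest.warns(UserWarning):
        n = count_genes_between(genes, "IHF_54", "MCP")
    assert n == 2      # low-scoring duplicate counts as an ordinary gene


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def enumeration_pvalue(x, y):
    """Independent oracle: direct enumeration over all labelings."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    ws = [sum(ranks[i] for i in c)
          for c in combinations(range(len(pooled)), n)]
    mean = sum(ws) / len(ws)
    dev = abs(obs - mean)
    return sum(abs(w - mean) >= dev - 1e-12 for w in ws) / len(ws)


def test_wilcoxon_small_sample_example():
    w, p = wilcoxon_rank_sum([1, 2], [3, 4])
    assert p == pytest.approx(2 / 6)


def test_wilcoxon_identical_multisets_p_one():
    _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p == 1.0
    _, p2 = wilcoxon_rank_sum([5, 5], [5, 5, 5])
    assert p2 == 1.0


@given(st.lists(st.integers(0, 5), min_size=1, max_size=4),
       st.lists(st.integers(0, 5), min_size=1, max_size=4))
def test_wilcoxon_exact_matches_enumeration_oracle(x, y):
    _, p = wilcoxon_rank_sum(x, y)
    assert p == pytest.approx(enumeration_pvalue(x, y))


def test_wilcoxon_exact_matches_scipy_untied(rng):
    """Independent cross-check on tie-free data."""
    for _ in range(20):
        x = rng.permutation(100)[:4].tolist()
        y = rng.permutation(100)[90:95].tolist()
        x = [v + 0.5 for v in x]     # guarantee no tie with y
        _, p = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
        assert p == pytest.approx(ref)


def test_wilcoxon_approx_close_to_exact(rng):
    for _ in range(5):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.3, 1, 20)
        _, p_approx = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
        assert abs(p_approx - ref) < 0.02


# ---------------------------------------------------------------------------
# Acr filtering


@pytest.mark.parametrize("pred_a,pred_b,length,kept", [
    (True, True, 150, True),
    (True, False, 150, False),
    (False, True, 150, False),
    (False, False, 150, False),
    (True, True, 200, True),       # boundary: exactly 200 aa stays
    (True, True, 201, False),      # > 200 aa removed
    (True, True, 250, False),
    (False, False, 250, False),
])
def test_filter_acr_rule(pred_a, pred_b, length, kept):
    c = AcrCandidate("p1", length, pred_a, pred_b)
    assert (filter_acr([c]) == [c]) == kept


def test_filter_acr_subset_and_idempotent(rng):
    cands = [AcrCandidate(f"p{i}", int(rng.integers(50, 300)),
                          bool(rng.integers(0, 2)), bool(rng.integers(0, 2)))
             for i in range(50)]
    kept = filter_acr(cands)
    assert set(c.protein_id for c in kept) <= \
        set(c.protein_id for c in cands)
    assert filter_acr(kept) == kept


# ---------------------------------------------------------------------------
# CAZyme prevalence


def test_cazyme_prevalence_toy_table():
    fams = {f"g{i}": ("alpha" if i < 10 else "beta") for i in range(15)}
    annots = pd.DataFrame({
        "genome_id": ["g0", "g1", "g1", "g12"],
        "cazyme_type": ["GH73", "GH73", "GH73", "GH108"],
    })
    tab = cazyme_cluster_prevalence(annots, fams,
                                    cazyme_types=["GH73", "GH108", "GT2"])
    assert tab.loc["alpha", "GH73"] == pytest.approx(20.0)
    assert tab.loc["beta", "GH108"] == pytest.approx(20.0)
    assert tab.loc["alpha", "GH108"] == 0.0
    assert (tab["GT2"] == 0.0).all()     # absent type keeps an all-zero row
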