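"""Planted-truth community generator: determinism and internal
consistency of the truth bundle."""

import os

import numpy as np
import pytest

from crasskit.records import read_fasta
from crasskit.simulate import (CommunitySpec, planted_abundances,
                               simulate_bacteria, simulate_community,
                               simulate_phage, simulate_phages,
                               simulate_reads, spec_from_yaml,
                               write_fixture)
from crasskit.translate import STOP_CODONS, translate


def small_spec(**kw):
    base = dict(seed=7, n_phages=4, n_mutants=1, n_bacteria=5,
                n_samples=6, reads_per_sample=300,
                group_design={f"s{i}": ("fat" if i < 3 else "lean")
                              for i in range(6)},
                effect_votus=[("phage_01", 2.0)])
    base.update(kw)
    return CommunitySpec(**base)


def test_same_seed_identical_fixture_bytes(tmp_path):
    for sub in ("a", "b"):
        spec = small_spec()
        bundle = simulate_community(spec)
        write_fixture(bundle, str(tmp_path / sub), with_reads=True)
    for name in ("phages.fasta", "bacteria.fasta", "truth_phages.tsv",
                 "truth_spacers.tsv", "viral_scores.tsv",
                 os.path.join("reads", "s0.fasta")):
        a = (tmp_path / "a" / name).read_bytes()
        b = (tmp_path / "b" / name).read_bytes()
        assert a == b, name


def test_different_seed_changes_sequences():
    p1, _ = simulate_phages(small_spec(seed=1))
    p2, _ = simulate_phages(small_spec(seed=2))
    assert p1[0].seq != p2[0].seq


def test_code11_only_community_has_no_suppressor_trna():
    spec = small_spec(code_mix={11: 1.0})
    phages, truth = simulate_phages(spec)
    assert all(truth[g.id].trna_positions == [] for g in phages)


def test_marker_genes_in_canonical_order():
    phages, truth = simulate_phages(small_spec())
    for g in phages:
        markers = [m.label for m in truth[g.id].markers]
        assert markers == ["IHF_54", "MCP", "portal", "TerL", "primase"]
        starts = [m.start for m in truth[g.id].markers]
        assert starts == sorted(starts)


def test_truth_genes_translate_cleanly_under_true_code():
    phages, truth = simulate_phages(small_spec())
    for g in phages[:2]:
        t = truth[g.id]
        for ann in t.genes:
            aa = translate(g.seq[ann.start:ann.end], t.code)
            assert aa.endswith("*")
            assert "*" not in aa[:-1]


def test_mutants_preserve_code_and_length():
    phages, truth = simulate_phages(small_spec(n_mutants=2))
    mutants = [g for g in phages if "_m" in g.id]
    assert mutants
    for m in mutants:
        parent_id = truth[m.id].votu_rep
        parent = next(g for g in phages if g.id == parent_id)
        assert len(m.seq) == len(parent.seq)
        # no nonsense substitutions inside planted genes
        stops = STOP_CODONS[truth[m.id].code]
        for ann in truth[m.id].genes:
            for cs in range(ann.start, ann.end - 3, 3):
                assert m.seq[cs:cs + 3] not in stops


def test_arrays_have_spacer_count_repeats_minus_one():
    spec = small_spec()
    phages, _ = simulate_phages(spec)
    _, _, arrays = simulate_bacteria(spec, phages)
    for a in arrays:
        assert a.n_repeats >= 3
        assert len(a.spacers) == a.n_repeats - 1


def test_planted_spacers_within_mismatch_budget():
    spec = small_spec()
    phages, _ = simulate_phages(spec)
    by_id = {g.id: g for g in phages}
    _, _, arrays = simulate_bacteria(spec, phages)
    from crasskit.records import reverse_complement
    n_links = 0
    for a in arrays:
        for s in a.spacers:
            if not s.phage_id or s.mismatches < 0:
                continue
            phage = by_id[s.phage_id]
            sub = phage.seq[s.phage_pos:s.phage_pos + len(s.spacer_seq)]
            if s.phage_strand == "-":
                sub = reverse_complement(sub)
            d = sum(x != y for x, y in zip(sub, s.spacer_seq))
            assert d == s.mismatches
            n_links += 0 <= s.mismatches <= 1
    assert n_links > 0


def test_read_ratio_tracks_planted_abundance():
    spec = small_spec(n_phages=2, n_mutants=0, reads_per_sample=4000,
                      subst_error=0.0, effect_votus=[])
    phages, truth = simulate_phages(spec)
    reads, abund, counts, covered, reps = simulate_reads(
        spec, phages, truth)
    lengths = np.array([len(g.seq) for g in phages], float)
    for si in range(spec.n_samples):
        expected = abund[:, si] * lengths
        expected = expected / expected.sum()
        got = counts[:, si] / counts[:, si].sum()
        # multinomial sampling: within a few percent at n=4000
        assert np.abs(got - expected).max() < 0.05


def test_zero_error_reads_match_genome_exactly():
    spec = small_spec(n_phages=1, n_mutants=0, subst_error=0.0,
                      reads_per_sample=50, effect_votus=[])
    phages, truth = simulate_phages(spec)
    reads, *_ = simulate_reads(spec, phages, truth)
    genome = phages[0].seq
    for _, seq in reads[spec.samples[0]]:
        assert seq in genome


def test_fat_lean_effect_applied():
    spec = small_spec(sample_jitter_sigma=0.0)
    phages, _ = simulate_phages(spec)
    abund = planted_abundances(spec, phages)
    fat = [i for i, s in enumerate(spec.samples)
           if spec.group_design[s] == "fat"]
    lean = [i for i, s in enumerate(spec.samples)
            if spec.group_design[s] == "lean"]
    idx = [g.id for g in phages].index("phage_01")
    ratio = abund[idx, fat].mean() / abund[idx, lean].mean()
    # log2FC 2 -> 4x before renormalization; the relative-abundance ratio
    # shrinks compositionally when the effect vOTU holds a large share
    assert ratio > 1.8


def test_spec_yaml_roundtrip(tmp_path):
    spec = small_spec()
    bundle = simulate_community(spec)
    write_fixture(bundle, str(tmp_path), with_reads=False)
    back = spec_from_yaml(str(tmp_path / "spec.yaml"))
    assert back == spec


def test_bad_mixtures_rejected():
    with pytest.raises(ValueError):
        CommunitySpec(family_mix={"alpha": 0.5, "beta": 0.4})


def test_markers_must_fit():
    with pytest.raises(ValueError):
        simulate_phage(CommunitySpec(seed=0,
                                     genome_len_range=(10_000, 12_000)),
                       0, "alpha", 11)
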