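"""Read mapping gates, RPKM closed form, coverage-gate boundaries,
prevalence rules, BH adjustment and group association."""

import numpy as np
import pandas as pd
import pytest

from crasskit.abundance import (AbundanceMatrix, associate_groups,
                                bh_adjust, build_index, map_reads,
                                prevalence, quantify)
from crasskit.records import GenomeRecord


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def ref_index():
    rng = np.random.default_rng(42)
    reps = [GenomeRecord(id="repA", seq=random_dna(rng, 20000)),
            GenomeRecord(id="repB", seq=random_dna(rng, 15000))]
    return reps, build_index(reps)


def test_error_free_read_maps_perfectly(ref_index):
    reps, index = ref_index
    read = reps[0].seq[5000:5150]
    df = map_reads([("r1", read)], index)
    assert len(df) == 1
    row = df.iloc[0]
    assert row["votu_rep_id"] == "repA"
    assert row["identity"] == 100.0
    assert (row["start"], row["end"]) == (5000, 5150)


def test_read_below_identity_gate_dropped(ref_index):
    reps, index = ref_index
    rng = np.random.default_rng(1)
    read = list(reps[0].seq[3000:3150])
    for i in rng.choice(150, 17, replace=False):     # ~11% substitutions
        read[i] = "ACGT"[("ACGT".index(read[i]) + 1) % 4]
    df = map_reads([("r1", "".join(read))], index)
    assert len(df) == 0


def test_overhanging_read_dropped(ref_index):
    reps, index = ref_index
    read = reps[0].seq[-75:] + random_dna(np.random.default_rng(2), 75)
    df = map_reads([("r1", read)], index)
    assert len(df) == 0          # aligned_percent 50 < 95


def test_moderate_errors_still_map(ref_index):
    reps, index = ref_index
    rng = np.random.default_rng(3)
    read = list(reps[1].seq[1000:1150])
    for i in rng.choice(150, 5, replace=False):
        read[i] = "ACGT"[("ACGT".index(read[i]) + 2) % 4]
    df = map_reads([("r1", "".join(read))], index)
    assert len(df) == 1
    assert df.iloc[0]["votu_rep_id"] == "repB"
    assert df.iloc[0]["identity"] == pytest.approx(100 * 145 / 150)


# ---------------------------------------------------------------------------
# quantification


def _aln(rows):
    return pd.DataFrame(rows, columns=[
        "read_id", "votu_rep_id", "identity", "aligned_percent",
        "start", "end"])


def test_rpkm_closed_form(rng):
    rep = GenomeRecord(id="v", seq=random_dna(rng, 100_000))
    # 1,000 reads tiling the genome, 10^6 total reads -> RPKM 10
    rows = [(f"r{i}", "v", 100.0, 100.0, (i * 100) % 99_900,
             (i * 100) % 99_900 + 150) for i in range(1000)]
    mat = quantify({"s1": _aln(rows)}, [rep], {"s1": 1_000_000})
    assert mat.rpkm.loc["v", "s1"] == pytest.approx(10.0)
    assert mat.detected.loc["v", "s1"]


def test_coverage_gate_boundaries(rng):
    rep = GenomeRecord(id="v", seq=random_dna(rng, 1000))
    # exactly 75.0% covered: abundance kept (only < 75 zeroes), NOT detected
    rows = [("r1", "v", 100.0, 100.0, 0, 750)]
    mat = quantify({"s": _aln(rows)}, [rep], {"s": 1000})
    assert mat.covered_fraction.loc["v", "s"] == pytest.approx(75.0)
    assert mat.rpkm.loc["v", "s"] > 0
    assert not mat.detected.loc["v", "s"]
    # 74.9% covered: zeroed and not detected
    rows = [("r1", "v", 100.0, 100.0, 0, 749)]
    mat = quantify({"s": _aln(rows)}, [rep], {"s": 1000})
    assert mat.rpkm.loc["v", "s"] == 0.0
    assert not mat.detected.loc["v", "s"]
    # 75.1%: detected with positive abundance
    rows = [("r1", "v", 100.0, 100.0, 0, 751)]
    mat = quantify({"s": _aln(rows)}, [rep], {"s": 1000})
    assert mat.rpkm.loc["v", "s"] > 0
    assert mat.detected.loc["v", "s"]


def test_zero_alignments_zero_matrix(rng):
    rep = GenomeRecord(id="v", seq=random_dna(rng, 1000))
    mat = quantify({"s": _aln([])}, [rep], {"s": 10})
    assert (mat.rpkm.to_numpy() == 0).all()
    assert not mat.detected.to_numpy().any()


# ---------------------------------------------------------------------------
# prevalence rules


def test_prevalence_rules():
    det = pd.DataFrame(
        [[True] * 4 + [False] * 9,
         [False] * 12 + [True]],
        index=["v1", "v2"], columns=[f"s{i}" for i in range(13)])
    prev, pop_det, cluster_pres = prevalence(
        det,
        sample_to_population={f"s{i}": ("P1" if i < 6 else "P2")
                              for i in range(13)},
        votu_families={"v1": "alpha", "v2": "beta"})
    assert prev["v1"] == pytest.approx(100 * 4 / 13, abs=0.01)
    assert bool(pop_det.loc["v2", "P2"]) and not bool(pop_det.loc["v2", "P1"])
    assert bool(cluster_pres.loc["alpha", "s0"])
    assert not bool(cluster_pres.loc["alpha", "s12"])
    assert bool(cluster_pres.loc["beta", "s12"])


def test_prevalence_requires_population_cover():
    det = pd.DataFrame([[True]], index=["v"], columns=["s1"])
    with pytest.raises(ValueError):
        prevalence(det, sample_to_population={})


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_computed_example():
    q = bh_adjust([0.01, 0.02, 0.03, 0.5])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])


def test_bh_all_ones():
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    p = rng.random(40)
    q = bh_adjust(p)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, q_ref)


def test_bh_monotone_in_sorted_order(rng):
    p = rng.random(25)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# association


def _matrix_from_rpkm(rpkm):
    covered = rpkm * 0 + 100.0
    return AbundanceMatrix(rpkm=rpkm, covered_fraction=covered,
                           detected=covered > 75, read_counts=rpkm * 0)


def test_association_recovers_planted_effect(rng):
    samples = [f"s{i}" for i in range(16)]
    groups = {s: ("fat" if i < 8 else "lean")
              for i, s in enumerate(samples)}
    base = rng.lognormal(2, 0.2, (20, 16))
    base[0, :8] *= 4.0        # planted log2FC = 2 in fat samples
    rpkm = pd.DataFrame(base, index=[f"v{i}" for i in range(20)],
                        columns=samples)
    results = associate_groups(_matrix_from_rpkm(rpkm), groups)
    hit = next(r for r in results if r.votu_id == "v0")
    assert hit.coeff > 0
    assert hit.qval < 0.05
    assert hit.significant
    assert hit.signed_score == pytest.approx(-np.log10(hit.qval))


def test_association_signed_score_formula():
    # q = 0.001 with a negative coefficient gives signed score -3
    assert -np.log10(0.001) * np.sign(-1.2) == pytest.approx(-3.0)


def test_association_needs_three_per_group(rng):
    rpkm = pd.DataFrame(rng.random((5, 4)),
                        index=[f"v{i}" for i in range(5)],
                        columns=["a", "b", "c", "d"])
    groups = {"a": "fat", "b": "fat", "c": "lean", "d": "lean"}
    with pytest.raises(ValueError):
        associate_groups(_matrix_from_rpkm(rpkm), groups)


def test_association_null_simulation_controls_false_discoveries(rng):
    """200 null features over 20 seeds: BH at q < 0.05 yields almost no
    false discoveries."""
    samples = [f"s{i}" for i in range(16)]
    groups = {s: ("fat" if i < 8 else "lean")
              for i, s in enumerate(samples)}
    total_discoveries = 0
    for _ in range(20):
        rpkm = pd.DataFrame(rng.lognormal(0, 1, (200, 16)),
                            index=[f"v{i}" for i in range(200)],
                            columns=samples)
        results = associate_groups(_matrix_from_rpkm(rpkm), groups)
        total_discoveries += sum(r.significant for r in results)
    assert total_discoveries <= 3


def test_association_excludes_all_zero_and_handles_constant(rng):
    samples = [f"s{i}" for i in range(12)]
    groups = {s: ("fat" if i < 6 else "lean")
              for i, s in enumerate(samples)}
    data = rng.lognormal(0, 0.3, (4, 12))
    data[1] = 0.0                      # absent everywhere: excluded
    rpkm = pd.DataFrame(data, index=["v0", "v1", "v2", "v3"],
                        columns=samples)
    results = associate_groups(_matrix_from_rpkm(rpkm), groups)
    assert {r.votu_id for r in results} == {"v0", "v2", "v3"}
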