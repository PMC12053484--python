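"""Stage drivers: each function reads/writes the fixture-directory file
formats and returns the in-memory results, so the CLI stays a thin shell.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import abundance as ab
from . import clustering, detection, features, hosts, phylo
from .config import DEFAULT_CONFIG, ThresholdConfig
from .markers import marker_profiles, signature_proteins, structural_profiles
from .records import GenomeRecord, ProteinRecord, read_fasta, write_fasta, \
    write_gff3
from .translate import orf_protein


def stage_detect(fixture: str, outdir: str,
                 cfg: ThresholdConfig = DEFAULT_CONFIG,
                 mode: str = "union") -> pd.DataFrame:
    contigs = read_fasta(os.path.join(fixture, "contigs.fasta"))
    scores_df = pd.read_csv(os.path.join(fixture, "viral_scores.tsv"),
                            sep="\t")
    scores = {}
    for _, r in scores_df.iterrows():
        scores[r["contig_id"]] = detection.ViralScoreRecord(
            contig_id=r["contig_id"],
            vs2_score=None if pd.isna(r["vs2_score"]) else float(r["vs2_score"]),
            dvf_score=None if pd.isna(r["dvf_score"]) else float(r["dvf_score"]),
            dvf_p=None if pd.isna(r["dvf_p"]) else float(r["dvf_p"]),
            vibrant_positive=bool(r["vibrant_positive"]))
    calls = detection.detect_crass(contigs, scores, signature_proteins(),
                                   structural_profiles(), cfg, mode)
    df = pd.DataFrame(
        [(c.contig_id, c.route1_pass, c.route1_hit, c.route2_pass,
          ";".join(f"{k}:{v}" for k, v in sorted(c.route2_hits.items())),
          c.is_crass) for c in calls],
        columns=["contig_id", "route1_pass", "route1_hit", "route2_pass",
                 "route2_hits", "is_crass"])
    os.makedirs(outdir, exist_ok=True)
    df.to_csv(os.path.join(outdir, "crass_calls.tsv"), sep="\t", index=False)
    keep = {c.contig_id for c in calls if c.is_crass}
    write_fasta([g for g in contigs if g.id in keep],
                os.path.join(outdir, "crass_genomes.fasta"))
    return df


def stage_cluster(outdir: str,
                  cfg: ThresholdConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    genomes = read_fasta(os.path.join(outdir, "crass_genomes.fasta"))
    comparisons: list = []
    votus = clustering.greedy_cluster(genomes, cfg, comparisons=comparisons)
    df = clustering.clusters_table(votus)
    df.to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t", index=False)
    pd.DataFrame(comparisons,
                 columns=["query_id", "centroid_id", "ani", "af"]).to_csv(
        os.path.join(outdir, "ani.tsv"), sep="\t", index=False)
    reps = {v.rep_id for v in votus}
    write_fasta([g for g in genomes if g.id in reps],
                os.path.join(outdir, "votu_reps.fasta"))
    return df


def stage_features(outdir: str) -> Dict[str, pd.DataFrame]:
    genomes = read_fasta(os.path.join(outdir, "crass_genomes.fasta"))
    reps = read_fasta(os.path.join(outdir, "votu_reps.fasta"))
    profiles = marker_profiles()
    code_rows = []
    trna_rows = []
    codes: Dict[str, int] = {}
    for g in genomes:
        call = features.infer_genetic_code(g)
        codes[g.id] = call.code
        code_rows.append((g.id, call.code,
                          *(round(call.densities[c], 4) for c in (11, 4, 15))))
        for t in features.detect_suppressor_trna(g):
            trna_rows.append((g.id, t.position, t.strand, t.anticodon,
                              t.suppresses))
    code_df = pd.DataFrame(code_rows, columns=[
        "genome_id", "code", "density_11", "density_4", "density_15"])
    trna_df = pd.DataFrame(trna_rows, columns=[
        "genome_id", "position", "strand", "anticodon", "suppresses"])
    all_genes = []
    block_rows = []
    for g in reps:
        genes = features.annotate_markers(g, profiles, code=codes[g.id])
        all_genes.extend(genes)
        bc = features.block_counts(genes, g.id)
        n_genes = len(genes)
        n_labeled = sum(1 for x in genes if x.label != "unknown")
        block_rows.append((g.id, bc.ihf54_mcp, bc.mcp_portal,
                           bc.terl_primase, n_genes, n_labeled))
    block_df = pd.DataFrame(block_rows, columns=[
        "genome_id", "ihf54_mcp", "mcp_portal", "terl_primase",
        "n_genes", "n_labeled"])
    code_df.to_csv(os.path.join(outdir, "code_calls.tsv"), sep="\t",
                   index=False)
    trna_df.to_csv(os.path.join(outdir, "trnas.tsv"), sep="\t", index=False)
    block_df.to_csv(os.path.join(outdir, "block_counts.tsv"), sep="\t",
                    index=False)
    write_gff3(all_genes, os.path.join(outdir, "annotations.gff3"))
    return {"codes": code_df, "trnas": trna_df, "blocks": block_df}


def stage_classify(fixture: str, outdir: str) -> pd.DataFrame:
    """TerL tree over vOTU representatives plus labeled references, then
    MRCA family propagation."""
    reps = read_fasta(os.path.join(outdir, "votu_reps.fasta"))
    codes = pd.read_csv(os.path.join(outdir, "code_calls.tsv"), sep="\t") \
        .set_index("genome_id")["code"].to_dict()
    gff = os.path.join(outdir, "annotations.gff3")
    from .records import read_gff3
    genes = read_gff3(gff)
    terl: List[ProteinRecord] = []
    for g in reps:
        own = [x for x in genes if x.genome_id == g.id and x.label == "TerL"]
        if not own:
            continue
        prot = orf_protein(g, own[0], codes.get(g.id, 11))
        prot.id = g.id
        terl.append(prot)
    reference: Dict[str, str] = {}
    for rec in read_fasta(os.path.join(fixture, "ref_terl.fasta"),
                          protein=True):
        rid, fam = rec.id.rsplit("|", 1)
        rec.id = f"{rid}|{fam}"
        reference[rec.id] = fam
        terl.append(rec)
    tree, assignments = phylo.classify_terl(terl, reference)
    tree.write(path=os.path.join(outdir, "terl_tree.nwk"), schema="newick")
    df = pd.DataFrame(
        [(a.leaf_id, a.family) for a in assignments
         if a.leaf_id not in reference],
        columns=["votu_rep", "family"])
    df.to_csv(os.path.join(outdir, "taxonomy_assignments.tsv"), sep="\t",
              index=False)
    # fold family labels back into the cluster table
    clusters = pd.read_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
    fam_map = df.set_index("votu_rep")["family"].to_dict()
    clusters["family"] = clusters["rep_id"].map(fam_map).fillna("unclassified")
    clusters.to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t",
                    index=False)
    return df


def stage_block_tests(outdir: str) -> pd.DataFrame:
    blocks = pd.read_csv(os.path.join(outdir, "block_counts.tsv"), sep="\t")
    clusters = pd.read_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
    fam = clusters.set_index("rep_id")["family"].to_dict()
    blocks["family"] = blocks["genome_id"].map(fam)
    tests = features.pairwise_block_tests(blocks)
    tests.to_csv(os.path.join(outdir, "block_tests.tsv"), sep="\t",
                 index=False)
    return tests


def stage_hosts(fixture: str, outdir: str,
                cfg: ThresholdConfig = DEFAULT_CONFIG) \
        -> Tuple[pd.DataFrame, pd.DataFrame]:
    bacteria = read_fasta(os.path.join(fixture, "bacteria.fasta"))
    phages = read_fasta(os.path.join(outdir, "crass_genomes.fasta"))
    clusters = pd.read_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
    votu_of = {}
    for _, r in clusters.iterrows():
        for m in r["members"].split(","):
            votu_of[m] = r["rep_id"]
    taxonomy = pd.read_csv(os.path.join(fixture, "taxonomy.tsv"), sep="\t") \
        .set_index("genome_id")["lineage"].to_dict()
    arrays = hosts.find_all_arrays(bacteria)
    arr_df = pd.DataFrame(
        [(a.genome_id, a.repeat_positions[0], a.repeat_seq,
          len(a.repeat_positions),
          ";".join(s for s, _, _ in a.spacers)) for a in arrays],
        columns=["genome_id", "start", "repeat", "n_repeats", "spacers"])
    arr_df.to_csv(os.path.join(outdir, "crispr_arrays.tsv"), sep="\t",
                  index=False)
    assignments, summary = hosts.assign_hosts(arrays, phages, votu_of,
                                              taxonomy, cfg)
    asg_df = pd.DataFrame(
        [(a.votu_id, a.bacterial_genome_id, a.taxonomy,
          a.n_matching_spacers,
          ",".join(map(str, a.mismatches_per_hit))) for a in assignments],
        columns=["votu_id", "bacterial_genome_id", "taxonomy",
                 "n_matching_spacers", "mismatches"])
    asg_df.to_csv(os.path.join(outdir, "host_assignments.tsv"), sep="\t",
                  index=False)
    summary.to_csv(os.path.join(outdir, "host_genus_summary.tsv"), sep="\t",
                   index=False)
    return asg_df, summary


def stage_quantify(fixture: str, outdir: str,
                   cfg: ThresholdConfig = DEFAULT_CONFIG) \
        -> ab.AbundanceMatrix:
    reps = read_fasta(os.path.join(outdir, "votu_reps.fasta"))
    reps.sort(key=lambda g: g.id)
    index = ab.build_index(reps)
    read_dir = os.path.join(fixture, "reads")
    samples = sorted(f[:-6] for f in os.listdir(read_dir)
                     if f.endswith(".fasta"))
    alignments = {}
    totals = {}
    for s in samples:
        reads = [(r.id, r.seq) for r in
                 read_fasta(os.path.join(read_dir, f"{s}.fasta"))]
        totals[s] = len(reads)
        alignments[s] = ab.map_reads(reads, index, cfg)
    mat = ab.quantify(alignments, reps, totals, cfg)
    mat.rpkm.rename_axis("votu_rep").to_csv(
        os.path.join(outdir, "rpkm.tsv"), sep="\t")
    mat.covered_fraction.rename_axis("votu_rep").to_csv(
        os.path.join(outdir, "covered_fraction.tsv"), sep="\t")
    mat.detected.rename_axis("votu_rep").to_csv(
        os.path.join(outdir, "detected.tsv"), sep="\t")
    mat.read_counts.rename_axis("votu_rep").to_csv(
        os.path.join(outdir, "read_counts.tsv"), sep="\t")
    pd.DataFrame(sorted(totals.items()),
                 columns=["sample", "total_reads"]).to_csv(
        os.path.join(outdir, "total_reads.tsv"), sep="\t", index=False)
    pd.DataFrame([(g.id, len(g.seq)) for g in reps],
                 columns=["votu_rep", "length"]).to_csv(
        os.path.join(outdir, "rep_lengths.tsv"), sep="\t", index=False)
    clusters = pd.read_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
    fam = clusters.set_index("rep_id")["family"].to_dict()
    prev, _, cluster_pres = ab.prevalence(
        mat.detected, votu_families=fam)
    prev.rename_axis("votu_rep").to_csv(
        os.path.join(outdir, "prevalence.tsv"), sep="\t")
    if cluster_pres is not None:
        cluster_pres.rename_axis("family").to_csv(
            os.path.join(outdir, "cluster_presence.tsv"), sep="\t")
    return mat


def stage_associate(fixture: str, outdir: str,
                    cfg: ThresholdConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    rpkm = pd.read_csv(os.path.join(outdir, "rpkm.tsv"), sep="\t",
                       index_col=0)
    covered = pd.read_csv(os.path.join(outdir, "covered_fraction.tsv"),
                          sep="\t", index_col=0)
    counts = rpkm * 0
    mat = ab.AbundanceMatrix(rpkm=rpkm, covered_fraction=covered,
                             detected=covered > cfg.min_covered_fraction,
                             read_counts=counts)
    groups = pd.read_csv(os.path.join(fixture, "metadata.tsv"), sep="\t") \
        .set_index("sample")["group"].to_dict()
    results = ab.associate_groups(mat, groups, cfg)
    df = ab.association_table(results)
    df.to_csv(os.path.join(outdir, "associations.tsv"), sep="\t",
              index=False)
    return df


# ---------------------------------------------------------------------------
# run-all + truth comparison report


def run_all(fixture: str, outdir: str,
            cfg: ThresholdConfig = DEFAULT_CONFIG) -> Dict[str, object]:
    os.makedirs(outdir, exist_ok=True)
    out: Dict[str, object] = {}
    out["detect"] = stage_detect(fixture, outdir, cfg)
    out["cluster"] = stage_cluster(outdir, cfg)
    out["features"] = stage_features(outdir)
    out["classify"] = stage_classify(fixture, outdir)
    out["block_tests"] = stage_block_tests(outdir)
    out["hosts"] = stage_hosts(fixture, outdir, cfg)
    out["quantify"] = stage_quantify(fixture, outdir, cfg)
    out["associate"] = stage_associate(fixture, outdir, cfg)
    out["summary"] = write_summary(fixture, outdir)
    return out


def _truth_path(fixture: str, name: str) -> Optional[str]:
    p = os.path.join(fixture, name)
    return p if os.path.exists(p) else None


def write_summary(fixture: str, outdir: str) -> pd.DataFrame:
    """Compare pipeline outputs against the planted truth tables (when the
    fixture carries them) and write summary.tsv + report.md."""
    rows: List[Tuple[str, int, int]] = []   # (check, matched, total)
    truth_p = _truth_path(fixture, "truth_phages.tsv")
    clusters = pd.read_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
    if truth_p:
        truth = pd.read_csv(truth_p, sep="\t").set_index("genome_id")
        # detection: every planted phage called crAss, no decoy called
        calls = pd.read_csv(os.path.join(outdir, "crass_calls.tsv"),
                            sep="\t").set_index("contig_id")
        n_ok = sum(int(calls.loc[g, "is_crass"]) for g in truth.index
                   if g in calls.index)
        n_decoy_ok = sum(int(not r["is_crass"])
                         for cid, r in calls.iterrows()
                         if cid not in truth.index)
        rows.append(("crass_detection", n_ok, len(truth)))
        rows.append(("decoy_rejection", n_decoy_ok,
                     len(calls) - len(truth)))
        # clustering membership
        votu_of = {}
        for _, r in clusters.iterrows():
            for m in r["members"].split(","):
                votu_of[m] = r["rep_id"]
        n_cl = sum(int(votu_of.get(g) == truth.loc[g, "votu_rep"])
                   for g in truth.index)
        rows.append(("votu_membership", n_cl, len(truth)))
        # family labels (per vOTU representative)
        fam_map = clusters.set_index("rep_id")["family"].to_dict()
        reps = [g for g in truth.index if truth.loc[g, "votu_rep"] == g]
        n_fam = sum(int(fam_map.get(g) == truth.loc[g, "family"])
                    for g in reps)
        rows.append(("family_labels", n_fam, len(reps)))
        # genetic codes
        codes = pd.read_csv(os.path.join(outdir, "code_calls.tsv"),
                            sep="\t").set_index("genome_id")["code"]
        n_code = sum(int(codes.get(g) == truth.loc[g, "code"])
                     for g in truth.index if g in codes.index)
        rows.append(("genetic_codes", n_code, len(truth)))
    # gene blocks vs planted filler counts
    truth_m = _truth_path(fixture, "truth_blocks.tsv")
    if truth_m:
        tb = pd.read_csv(truth_m, sep="\t").set_index("genome_id")
        blocks = pd.read_csv(os.path.join(outdir, "block_counts.tsv"),
                             sep="\t").set_index("genome_id")
        n_blk, tot = 0, 0
        for g in tb.index:
            if g not in blocks.index:
                continue
            for col in ("ihf54_mcp", "mcp_portal", "terl_primase"):
                tot += 1
                n_blk += int(blocks.loc[g, col] == tb.loc[g, col])
        rows.append(("gene_blocks", n_blk, tot))
    # hosts
    truth_s = _truth_path(fixture, "truth_spacers.tsv")
    if truth_s and truth_p:
        ts = pd.read_csv(truth_s, sep="\t")
        truth = pd.read_csv(truth_p, sep="\t").set_index("genome_id")
        links = ts[(ts["phage_id"] != "") & ts["phage_id"].notna()
                   & (ts["mismatches"].between(0, 1))]
        expected = {(truth.loc[p, "votu_rep"], b)
                    for p, b in zip(links["phage_id"],
                                    links["bacterium_id"])}
        asg = pd.read_csv(os.path.join(outdir, "host_assignments.tsv"),
                          sep="\t")
        got = set(zip(asg["votu_id"], asg["bacterial_genome_id"]))
        n_found = len(expected & got)
        rows.append(("host_links_recovered", n_found, len(expected)))
        rows.append(("host_links_spurious", len(got - expected), 0))
    # detections
    truth_c = _truth_path(fixture, "truth_covered_fraction.tsv")
    if truth_c:
        tc = pd.read_csv(truth_c, sep="\t", index_col=0)
        det = pd.read_csv(os.path.join(outdir, "detected.tsv"), sep="\t",
                          index_col=0)
        shared = sorted(set(tc.index) & set(det.index))
        t_det = tc.loc[shared, det.columns] > 75.0
        n_det = int((t_det.to_numpy() == det.loc[shared].to_numpy()).sum())
        rows.append(("sample_detections", n_det, t_det.size))
    summary = pd.DataFrame(rows, columns=["check", "matched", "total"])
    summary.to_csv(os.path.join(outdir, "summary.tsv"), sep="\t",
                   index=False)
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("# Pipeline summary\n\n")
        fh.write(f"vOTUs: {len(clusters)}\n\n")
        fh.write("| check | matched | total |\n|---|---|---|\n")
        for _, r in summary.iterrows():
            fh.write(f"| {r['check']} | {r['matched']} | {r['total']} |\n")
    return summary
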