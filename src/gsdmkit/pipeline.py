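"""Pipeline stages: simulate, curate, build-hmm, scan, tree, motifs, report.

Each stage reads and writes only declared files (the pipeline is
restartable at any stage), logs to stderr plus a run-local file, writes
a ``<stage>_manifest.json`` with reconciling record counts
(input = surviving + removed) and the resolved configuration, and is
idempotent given identical inputs.
"""

from __future__ import annotations

import json
import logging
import os
import sys
from importlib.metadata import version as _pkg_version

import pandas as pd

from . import align, curation, hmm, motifs, phylo, seqio, synthetic
from .config import PipelineConfig

logger = logging.getLogger("gsdmkit")


def _version() -> str:
    try:
        return _pkg_version("gsdmkit")
    except Exception:  # pragma: no cover
        return "unknown"


def setup_logging(out_dir: str, level: str = "INFO") -> None:
    os.makedirs(out_dir, exist_ok=True)
    handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(os.path.join(out_dir, "run.log")),
    ]
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def _write_manifest(out_dir: str, stage: str, config: PipelineConfig, counts: dict) -> dict:
    bad = [k for k, v in counts.items() if v < 0]
    if bad:
        raise ValueError(f"negative counts in manifest: {bad}")
    manifest = {
        "stage": stage,
        "tool_version": _version(),
        "config": config.to_dict(),
        "counts": counts,
    }
    path = os.path.join(out_dir, f"{stage}_manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("%s: wrote %s", stage, path)
    return manifest


def cmd_simulate(config: PipelineConfig, out_dir: str) -> dict:
    """Generate the synthetic dataset bundle plus a boundaries file."""
    os.makedirs(out_dir, exist_ok=True)
    sim = synthetic.SimulationConfig(
        seed=config.seed, include_contigs=config.simulate_contigs
    )
    records, truth = synthetic.generate_dataset(sim, out_dir)
    # boundary annotation on the first family record: the linker is the
    # region strictly between beta11_end and alpha5_start
    ref_id = sorted(truth.family_ids)[0]
    start, end = truth.linker_intervals[ref_id]
    ref = motifs.ReferenceBoundaries(
        reference_id=ref_id,
        beta11_end=start - 1,
        alpha5_start=end + 1,
        nterm_range=(1, start - 1),
    )
    motifs.write_boundaries_yaml(ref, os.path.join(out_dir, "boundaries.yaml"))
    n_family = len(truth.family_ids)
    return _write_manifest(
        out_dir,
        "simulate",
        config,
        {
            "input": 0,
            "surviving": len(records),
            "removed": 0,
            "family": n_family,
            "decoys": len(records) - n_family,
            "planted_sites": len(truth.planted_sites),
        },
    )


def cmd_curate(fasta: str, metadata: str | None, config: PipelineConfig, out_dir: str) -> dict:
    """Cluster redundancy away, align representatives, trim partial rows."""
    os.makedirs(out_dir, exist_ok=True)
    records = seqio.read_fasta(fasta)
    if metadata:
        records = seqio.apply_metadata(records, seqio.read_metadata_tsv(metadata))
    clusters = curation.greedy_cluster(records, config.identity_threshold)
    curation.write_clusters_tsv(clusters, os.path.join(out_dir, "clusters.tsv"))
    reps = {c.representative_id for c in clusters}
    rep_records = [r for r in records if r.id in reps]
    msa = align.progressive_align(
        rep_records, gap_open=config.gap_open, gap_extend=config.gap_extend
    )
    trimmed = curation.trim_partial(msa)
    align.write_alignment(trimmed, os.path.join(out_dir, "alignment.fasta"))
    seqio.write_metadata_tsv(rep_records, os.path.join(out_dir, "curated_metadata.tsv"))
    return _write_manifest(
        out_dir,
        "curate",
        config,
        {
            "input": len(records),
            "surviving": len(trimmed),
            "removed": len(records) - len(trimmed),
            "removed_redundant": len(records) - len(reps),
            "removed_partial": len(rep_records) - len(trimmed),
        },
    )


def cmd_build_hmm(alignment: str, config: PipelineConfig, out_dir: str) -> dict:
    """Build the family profile HMM and its consensus sequence."""
    os.makedirs(out_dir, exist_ok=True)
    msa = align.read_alignment(alignment)
    profile = hmm.build_profile(
        msa, gap_threshold=config.hmm_gap_threshold, pseudocount=config.hmm_pseudocount
    )
    profile.to_json(os.path.join(out_dir, "profile.json"))
    with open(os.path.join(out_dir, "consensus.txt"), "w") as fh:
        fh.write(hmm.consensus(profile) + "\n")
    return _write_manifest(
        out_dir,
        "build_hmm",
        config,
        {"input": len(msa), "surviving": len(msa), "removed": 0,
         "n_match": profile.n_match},
    )


def cmd_scan(
    profile_path: str,
    fasta: str,
    config: PipelineConfig,
    out_dir: str,
    contigs: bool = False,
) -> dict:
    """Scan proteins (or six-frame-translated contigs) with the profile."""
    os.makedirs(out_dir, exist_ok=True)
    profile = hmm.ProfileHmm.from_json(profile_path)
    if contigs:
        from Bio import SeqIO

        hits = []
        n_input = 0
        for entry in SeqIO.parse(fasta, "fasta"):
            n_input += 1
            hits.extend(
                hmm.six_frame_scan(
                    entry.id, str(entry.seq), profile,
                    min_orf_aa=config.min_orf_aa,
                    bits_threshold=config.bits_threshold,
                )
            )
        hits.sort(key=lambda h: (-h.bit_score, h.sequence_id))
    else:
        records = seqio.read_fasta(fasta)
        n_input = len(records)
        hits = hmm.scan_proteins(profile, records, bits_threshold=config.bits_threshold)
    hmm.write_hits_tsv(hits, os.path.join(out_dir, "hits.tsv"))
    return _write_manifest(
        out_dir,
        "scan",
        config,
        {"input": n_input, "surviving": len(hits), "removed": n_input - len(hits)}
        if not contigs
        else {"input": n_input, "surviving": n_input, "removed": 0, "hits": len(hits)},
    )


def cmd_tree(
    alignment: str, config: PipelineConfig, out_dir: str, metadata: str | None = None
) -> dict:
    """Distances, neighbor joining, midpoint rooting and clade monophyly."""
    os.makedirs(out_dir, exist_ok=True)
    msa = align.read_alignment(alignment)
    dm = phylo.poisson_distance(msa)
    dm.to_tsv(os.path.join(out_dir, "distances.tsv"))
    tree = phylo.neighbor_joining(dm)
    rooted = phylo.midpoint_root(tree)
    with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
        fh.write(phylo.write_newick(rooted) + "\n")
    monophyly: dict[str, bool] = {}
    if metadata:
        table = seqio.read_metadata_tsv(metadata)
        leaf_set = phylo.leaf_labels(rooted)
        for clade, group in table.groupby("clade"):
            labels = set(group["id"]) & leaf_set
            if labels and clade and clade != "decoy":
                monophyly[str(clade)] = phylo.is_monophyletic(rooted, labels)
    with open(os.path.join(out_dir, "monophyly.json"), "w") as fh:
        json.dump(monophyly, fh, indent=2, sort_keys=True)
    return _write_manifest(
        out_dir,
        "tree",
        config,
        {"input": len(msa), "surviving": len(msa), "removed": 0,
         "monophyletic_clades": sum(monophyly.values())},
    )


def cmd_motifs(
    alignment: str,
    fasta: str,
    boundaries: str,
    config: PipelineConfig,
    out_dir: str,
    metadata: str | None = None,
) -> dict:
    """Linker projection, tetrapeptide extraction, logos, clade summaries."""
    os.makedirs(out_dir, exist_ok=True)
    msa = align.read_alignment(alignment)
    records = seqio.read_fasta(fasta)
    if metadata:
        records = seqio.apply_metadata(records, seqio.read_metadata_tsv(metadata))
    by_id = {r.id: r for r in records}
    ref = motifs.read_boundaries_yaml(boundaries)
    linkers = motifs.project_boundaries(msa, ref)
    all_sites = []
    sites_by_record: dict[str, list] = {}
    n_null = 0
    for rid, linker in linkers.items():
        if linker is None or rid not in by_id:
            n_null += 1
            continue
        sites = [
            motifs.classify_site(s)
            for s in motifs.find_tetrapeptide_sites(by_id[rid], linker)
        ]
        for site in sites:
            site.yvad_like = motifs.is_yvad_like(site, config.yvad_threshold)
        sites_by_record[rid] = sites
        all_sites.extend(sites)
    clades = {r.id: r.clade for r in records}
    motifs.write_sites_tsv(all_sites, os.path.join(out_dir, "sites.tsv"), clades)
    scanned = [by_id[rid] for rid in sites_by_record]
    summaries = motifs.clade_summary(scanned, sites_by_record)
    motifs.write_clade_summaries_tsv(summaries, os.path.join(out_dir, "clade_summaries.tsv"))
    logos = {}
    for summary in summaries:
        clade_sites = [
            s for s in all_sites
            if clades.get(s.sequence_id) == summary.clade
            and s.site_class == motifs.CASPASE1_LIKE
        ]
        if clade_sites:
            logos[summary.clade] = motifs.build_logo(
                clade_sites, small_sample_correction=config.logo_small_sample_correction
            )
    with open(os.path.join(out_dir, "logos.json"), "w") as fh:
        json.dump(
            {
                clade: {
                    "position_labels": logo.position_labels,
                    "frequency_matrix": logo.frequency_matrix.tolist(),
                    "information_content": logo.information_content.tolist(),
                    "n_sequences": logo.n_sequences,
                }
                for clade, logo in sorted(logos.items())
            },
            fh,
            indent=2,
        )
    return _write_manifest(
        out_dir,
        "motifs",
        config,
        {
            "input": len(linkers),
            "surviving": len(linkers) - n_null,
            "removed": n_null,
            "sites": len(all_sites),
        },
    )


def cmd_report(run_dir: str, config: PipelineConfig) -> dict:
    """Aggregate stage manifests into one reconciled run report."""
    stages = ["simulate", "curate", "build_hmm", "scan", "tree", "motifs"]
    report: dict = {"tool_version": _version(), "stages": {}}
    for stage in stages:
        path = os.path.join(run_dir, f"{stage}_manifest.json")
        if not os.path.exists(path):
            continue
        with open(path) as fh:
            manifest = json.load(fh)
        counts = manifest["counts"]
        if counts["input"] and counts["input"] != counts["surviving"] + counts["removed"]:
            raise ValueError(f"counts do not reconcile in stage {stage}")
        report["stages"][stage] = counts
    for extra in ("clade_summaries.tsv", "monophyly.json"):
        path = os.path.join(run_dir, extra)
        if os.path.exists(path):
            if extra.endswith(".json"):
                with open(path) as fh:
                    report[extra.split(".")[0]] = json.load(fh)
            else:
                report["clade_summaries"] = (
                    pd.read_csv(path, sep="\t").to_dict(orient="records")
                )
    with open(os.path.join(run_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    lines = [f"gsdmkit run report (version {report['tool_version']})"]
    for stage, counts in report["stages"].items():
        lines.append(
            f"  {stage}: input={counts['input']} surviving={counts['surviving']} "
            f"removed={counts['removed']}"
        )
    for summary in report.get("clade_summaries", []):
        lines.append(
            f"  clade {summary['clade']}: {summary['n_sequences']} sequences, "
            f"{summary['n_with_caspase1_like']} with caspase-1-like sites, "
            f"YVAD-like fraction {summary['fraction_yvad_like']:.2f}"
        )
    for clade, mono in report.get("monophyly", {}).items():
        lines.append(f"  monophyly[{clade}] = {mono}")
    with open(os.path.join(run_dir, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("report: %d stages aggregated", len(report["stages"]))
    return report


def run_all(config: PipelineConfig, out_dir: str) -> dict:
    """simulate -> curate -> build-hmm -> scan -> tree -> motifs -> report."""
    setup_logging(out_dir)
    cmd_simulate(config, out_dir)
    fasta = os.path.join(out_dir, "proteins.fasta")
    seed_fasta = os.path.join(out_dir, "seed_family.fasta")
    metadata = os.path.join(out_dir, "metadata.tsv")
    cmd_curate(seed_fasta, metadata, config, out_dir)
    alignment = os.path.join(out_dir, "alignment.fasta")
    cmd_build_hmm(alignment, config, out_dir)
    cmd_scan(os.path.join(out_dir, "profile.json"), fasta, config, out_dir)
    cmd_tree(alignment, config, out_dir, metadata=metadata)
    cmd_motifs(
        alignment, fasta, os.path.join(out_dir, "boundaries.yaml"),
        config, out_dir, metadata=metadata,
    )
    return cmd_report(out_dir, config)
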