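"""End-to-end pipeline orchestration with a single YAML-able config,
deterministic outputs and a machine-readable run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from . import io as chio
from .annotate import (
    classify_anchor_basal_genes,
    classify_anchor_basal_peaks,
    categorize_loops,
    snps_in_loops,
)
from .contacts import (
    aggregate_chromosome_analysis,
    bin_contacts,
    call_compartments,
    gene_density_track,
    ice_balance,
    segment_domains,
)
from .coexpr import distance_matched_null, expression_breadth, group_rank_test
from .cre import annotate_cres, build_expression_categories
from .hubs import compare_conditions, detect_hubs, enrich_hubs
from .intervals import ACTIVE_MARKS
from .network import build_network, network_summary, write_edge_list
from .sim import SimConfig, generate_dataset, write_dataset

__all__ = ["RunConfig", "run_pipeline", "report"]

_STAGE_KEYS = {
    "seed",
    "outdir",
    "simulate",
    "annotate",
    "architecture",
    "cres",
    "hubs",
    "network",
    "coexpr",
    "log_level",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults match the module defaults).

    Unknown keys are rejected so typos fail before any stage runs; the
    resolved config is serialized into the output directory.
    """

    seed: int = 0
    outdir: str = "chiahub_run"
    simulate: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=lambda: {"fdr_max": 0.05, "min_overlap_bp": 1})
    architecture: dict = field(
        default_factory=lambda: {
            "resolution": 100_000,
            "tol": 1e-4,
            "grid": 50,
            "domain_bin": 10_000,
            "gap_tolerance_bins": 1,
        }
    )
    cres: dict = field(default_factory=lambda: {"near_bp": 500, "overlap_frac": 0.5})
    hubs: dict = field(default_factory=lambda: {"min_degree": 5, "alpha": 0.05, "rounds": 20})
    network: dict = field(default_factory=lambda: {"hops": 1, "n_seeds": 20})
    coexpr: dict = field(
        default_factory=lambda: {"n_sim": 200, "mode": "A", "bin_width": 0.25}
    )
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        unknown = set(data) - _STAGE_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in data.items():
            if isinstance(getattr(cfg, key), dict):
                block = dict(getattr(cfg, key))
                extra = set(value) - set(block) if key != "simulate" else set()
                if extra:
                    raise ValueError(f"unknown keys in {key!r} block: {sorted(extra)}")
                block.update(value)
                setattr(cfg, key, block)
            else:
                setattr(cfg, key, value)
        if cfg.network["hops"] not in (1, 2):
            raise ValueError("network.hops must be 1 or 2")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: Optional[str] = None) -> dict:
    """Execute all stages in dependency order on a simulated dataset.

    Stages: simulate -> annotate-loops -> architecture -> annotate-cres ->
    hubs/diff-hubs -> network -> coexpr -> report. Every stage writes its
    outputs under the run directory; the returned manifest lists per-stage
    outputs with SHA-256 checksums, so identical config + seed reproduces
    identical hashes.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": {}, "seed": config.seed}
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True, default=str)
    )

    def record(stage: str, files: list[Path], extra: Optional[dict] = None) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in sorted(files)},
            **(extra or {}),
        }

    # -- simulate ---------------------------------------------------------
    sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
    ds = generate_dataset(sim_cfg)
    files = write_dataset(ds, out / "data")
    record("simulate", list(files))

    # -- annotate loops ---------------------------------------------------
    stage_files = []
    all_peaks = [p for m in ACTIVE_MARKS for p in ds.peaks.get(m, [])]
    all_loops = [lp for m in ACTIVE_MARKS for lp in ds.loops.get(m, [])]
    peak_status = classify_anchor_basal_peaks(
        all_peaks, all_loops, min_overlap_bp=config.annotate["min_overlap_bp"]
    )
    gene_status = classify_anchor_basal_genes(
        ds.genes, all_peaks, peak_status, chrom_sizes=ds.chrom_sizes
    )
    status_path = out / "anchor_status.tsv"
    pd.DataFrame(
        [
            {"subject_id": st.subject_id, "kind": kind, "status": st.status}
            for kind, statuses in (("peak", peak_status), ("gene", gene_status))
            for st in statuses
        ]
    ).to_csv(status_path, sep="\t", index=False)
    stage_files.append(status_path)
    cats = categorize_loops(
        [lp for m, ls in sorted(ds.loops.items()) if m != "ATAC" for lp in ls],
        ds.genes,
        chrom_sizes=ds.chrom_sizes,
    )
    cat_path = out / "loop_categories.tsv"
    pd.DataFrame([dataclasses.asdict(c) for c in cats]).to_csv(
        cat_path, sep="\t", index=False
    )
    stage_files.append(cat_path)
    snps = [
        s for s in chio.read_snps(out / "data" / "snps.bed", chrom_sizes=ds.chrom_sizes)
    ]
    snp_path = out / "snp_loop_overlap.tsv"
    fractions = snps_in_loops(snps, ds.loops)
    pd.DataFrame([fractions]).to_csv(snp_path, sep="\t", index=False)
    stage_files.append(snp_path)
    record("annotate", stage_files)

    # -- architecture -----------------------------------------------------
    stage_files = []
    arch = config.architecture
    all_mark_loops = [lp for m, ls in ds.loops.items() if m != "ATAC" for lp in ls]
    matrices = bin_contacts(all_mark_loops, ds.chrom_sizes, arch["resolution"])
    comp_rows = []
    for chrom, cm in sorted(matrices.items()):
        balanced, bias, _ = ice_balance(cm, tol=arch["tol"])
        track = gene_density_track(ds.genes, chrom, cm.n_bins, arch["resolution"])
        try:
            call = call_compartments(balanced, track)
            for b in range(cm.n_bins):
                comp_rows.append(
                    {
                        "chrom": chrom,
                        "bin": b,
                        "eigenvector": call.eigenvector[b],
                        "label": call.labels[b],
                    }
                )
        except ValueError:
            pass
        mat_path = out / f"matrix_{chrom}.tsv"
        balanced.to_tsv(mat_path)
        stage_files.extend([mat_path, Path(str(mat_path) + ".json")])
    comp_path = out / "compartments.tsv"
    pd.DataFrame(comp_rows).to_csv(comp_path, sep="\t", index=False)
    stage_files.append(comp_path)
    aca = aggregate_chromosome_analysis(matrices.values(), grid=arch["grid"])
    import numpy as np

    aca_path = out / "aca.tsv"
    np.savetxt(aca_path, aca, delimiter="\t", fmt="%.6g")
    stage_files.append(aca_path)
    segments, summary = segment_domains(
        ds.loops,
        ds.chrom_sizes,
        bin_size=arch["domain_bin"],
        gap_tolerance_bins=arch["gap_tolerance_bins"],
    )
    seg_path = out / "domains.bed"
    with open(seg_path, "w") as fh:
        for seg in segments:
            iv = seg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.label}\n")
    sum_path = out / "domain_coverage.tsv"
    summary.to_csv(sum_path, sep="\t", index=False)
    stage_files.extend([seg_path, sum_path])
    record("architecture", stage_files)

    # -- CREs -------------------------------------------------------------
    stage_files = []
    mark_peaks = [p for m, ps in sorted(ds.peaks.items()) if m != "ATAC" for p in ps]
    mark_loops_flat = [lp for m, ls in sorted(ds.loops.items()) if m != "ATAC" for lp in ls]
    mark_status = classify_anchor_basal_peaks(mark_peaks, mark_loops_flat)
    # gene status over all marks (a gene linked only to H3K27me3 basal peaks
    # must read as basal here, not as unclassified)
    gene_status_all = classify_anchor_basal_genes(
        ds.genes, mark_peaks, mark_status, chrom_sizes=ds.chrom_sizes
    )
    gene_status_map = {st.subject_id: st.status for st in gene_status_all}
    annotations = annotate_cres(
        ds.peaks.get("ATAC", []),
        ds.genes,
        mark_peaks,
        mark_status,
        gene_status_map,
        all_loops,
        expression=ds.expression,
        near_bp=config.cres["near_bp"],
        overlap_frac=config.cres["overlap_frac"],
        chrom_sizes=ds.chrom_sizes,
    )
    cre_path = out / "cre_annotations.tsv"
    pd.DataFrame(
        [
            {
                "cre_id": a.cre_id,
                "chrom": a.interval.chrom,
                "start": a.interval.start,
                "end": a.interval.end,
                "genomic_class": a.genomic_class,
                "state": a.state,
                "interaction_status": a.interaction_status,
                "nearest_gene": a.nearest_gene,
                "connecting_genes": ",".join(a.connecting_genes),
            }
            for a in annotations
        ]
    ).to_csv(cre_path, sep="\t", index=False)
    groups = build_expression_categories(annotations, ds.genes)
    grp_path = out / "cre_gene_groups.tsv"
    pd.DataFrame(
        [{"group": k, "gene_id": g} for k, v in sorted(groups.items()) for g in v]
    ).to_csv(grp_path, sep="\t", index=False)
    stage_files.extend([cre_path, grp_path])
    record("cres", stage_files)

    # -- hubs and differential hubs --------------------------------------
    stage_files = []
    hubs1 = detect_hubs(
        ds.condition_pair.loops_cond1,
        ds.genes,
        ds.expression,
        min_degree=config.hubs["min_degree"],
    )
    hubs2 = detect_hubs(
        ds.condition_pair.loops_cond2,
        ds.genes,
        ds.expression,
        min_degree=config.hubs["min_degree"],
    )
    hub_path = out / "hubs.tsv"
    pd.DataFrame(
        [
            {
                "hub_id": h.hub_id,
                "node": str(h.node_anchor),
                "node_gene": h.node_gene,
                "degree": h.degree,
                "connecting_genes": ",".join(sorted(h.connecting_genes)),
            }
            for h in hubs1
        ]
    ).to_csv(hub_path, sep="\t", index=False)
    universe = sorted(
        {g for h in hubs1 for g in h.connecting_genes}
        | {h.node_gene for h in hubs1 if h.node_gene}
    )
    tf_targets = set(ds.truth.tf_targets.gene_id) if len(ds.truth.tf_targets) else set()
    enr = enrich_hubs(hubs1, tf_targets, universe, alpha=config.hubs["alpha"])
    enr_path = out / "hub_enrichment.tsv"
    pd.DataFrame(
        [
            {
                "hub_id": r.hub_id,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "enriched": r.enriched,
            }
            for r in enr
        ]
    ).to_csv(enr_path, sep="\t", index=False)
    deltas = compare_conditions(hubs1, hubs2)
    delta_path = out / "hub_deltas.tsv"
    pd.DataFrame(
        [
            {
                "node_gene": d.node_gene,
                "n_c": d.n_c,
                "n_m": d.n_m,
                "n_s": d.n_s,
                "category": d.category,
            }
            for d in deltas
        ]
    ).to_csv(delta_path, sep="\t", index=False)
    part_path = out / "hub_gene_partition.tsv"
    pd.DataFrame(
        [
            {"node_gene": d.node_gene, "gene_id": g, "partition": part}
            for d in deltas
            if d.category in ("EDH", "PDH")
            for part, gene_set in (("aggregated", d.aggregated), ("separated", d.separated))
            for g in sorted(gene_set)
        ]
    ).to_csv(part_path, sep="\t", index=False)
    stage_files.extend([hub_path, enr_path, delta_path, part_path])
    record("hubs", stage_files)

    # -- network ----------------------------------------------------------
    stage_files = []
    seeds = [h.node_gene for h in hubs1 if h.node_gene][: config.network["n_seeds"]]
    if seeds:
        loops_by_mark = {
            m: ds.loops.get(m, []) for m in list(ACTIVE_MARKS) + ["H3K27me3"]
        }
        graph = build_network(
            seeds, loops_by_mark, ds.genes, ds.expression, hops=config.network["hops"]
        )
        edge_path = out / "network_edges.tsv"
        write_edge_list(graph, edge_path)
        summary = network_summary(graph)
        net_path = out / "network_summary.json"
        net_path.write_text(json.dumps(
            {k: v for k, v in summary.items() if k != "nodes"}, indent=2, sort_keys=True
        ))
        stage_files.extend([edge_path, net_path])
    record("network", stage_files)

    # -- co-expression ----------------------------------------------------
    stage_files = []
    pairs = list(ds.truth.pairs[["gene_a", "gene_b"]].itertuples(index=False, name=None))
    coex_path = out / "coexpression.json"
    if pairs:
        result = distance_matched_null(
            pairs,
            [g.gene_id for g in ds.genes],
            ds.genes,
            ds.expression,
            n_sim=config.coexpr["n_sim"],
            mode=config.coexpr["mode"],
            seed=config.seed,
            bin_width=config.coexpr["bin_width"],
        )
        coex_path.write_text(
            json.dumps(
                {
                    "observed_mean_pcc": result.observed_mean_pcc,
                    "null_mean": float(result.null_means.mean()),
                    "p_value": result.p_value,
                    "n_pairs": result.n_pairs,
                    "mode": result.null_mode,
                    "seed": result.seed,
                },
                indent=2,
                sort_keys=True,
            )
        )
        stage_files.append(coex_path)
    breadth = expression_breadth(ds.expression, sim_cfg.detection_threshold)
    breadth_path = out / "breadth.tsv"
    breadth.rename("n_tissues_detected").to_csv(breadth_path, sep="\t")
    stage_files.append(breadth_path)
    record("coexpr", stage_files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def report(run_dir) -> str:
    """Render a Markdown summary of a completed run directory."""
    run_dir = Path(run_dir)
    lines = ["# chiahub run report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"Seed: {manifest.get('seed')}")
        lines.append("")

    def section(title: str, path: str, renderer) -> None:
        lines.append(f"## {title}")
        file = run_dir / path
        if not file.exists():
            lines.append("_absent_")
        else:
            lines.extend(renderer(file))
        lines.append("")

    def table_counts(col):
        def render(file):
            df = pd.read_csv(file, sep="\t")
            counts = df[col].value_counts()
            return [f"- {k}: {v}" for k, v in counts.items()]

        return render

    section("Loop categories", "loop_categories.tsv", table_counts("category"))
    section("Domain coverage", "domain_coverage.tsv", lambda f: [
        f"- {r.label}: {r.bp / 1e6:.1f} Mb ({r.percent:.1f}%)"
        for r in pd.read_csv(f, sep="\t").itertuples()
    ])
    section("CRE states", "cre_annotations.tsv", table_counts("state"))

    def hub_render(file):
        df = pd.read_csv(file, sep="\t")
        if df.empty:
            return ["no hubs at the configured min_degree"]
        counts = df["category"].value_counts()
        return [f"- {k}: {v}" for k, v in counts.items()]

    section("Differential hubs", "hub_deltas.tsv", hub_render)
    section("Co-expression", "coexpression.json", lambda f: [
        f"- {k}: {v}" for k, v in sorted(json.loads(f.read_text()).items())
    ])
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
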