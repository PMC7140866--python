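"""End-to-end pipeline: simulate/qc -> count -> select -> re-count -> vaf -> report.

Each stage is a pure function of its declared inputs and writes one or more
plain-text outputs under the run directory; with ``resume=True`` existing
stage outputs are reused, so deleting an intermediate file and re-running
regenerates identical content. A machine-readable manifest (config
snapshot, input checksums, per-stage row counts, seed) is written at the
end. The manifest deliberately carries no wall-clock timestamps so that
identical runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from scvaf import __version__
from scvaf.counting import SNVLocus, count_alleles, load_snvs_from_vcf, pool_counts
from scvaf.errors import ConfigError
from scvaf.io import read_annotation, read_counts, read_mtx_dir, sha256_file, write_counts
from scvaf.qc import qc_cells
from scvaf.selection import HetFilterConfig, select_het_snvs
from scvaf.simulate import SimConfig, simulate_dataset
from scvaf.vaf import (
    ClassificationConfig,
    aggregate_gene,
    compare_intronic,
    estimate_vaf,
    summarize_snv,
    vaf_histogram,
)

log = logging.getLogger("scvaf")


def _sub(config: dict, key: str) -> dict:
    value = config.get(key, {}) or {}
    if not isinstance(value, dict):
        raise ConfigError(f"config section {key!r} must be a mapping")
    return dict(value)


def write_vcf_subset(snvs: list[SNVLocus], path: Path) -> None:
    """Re-emit retained SNVs as a minimal VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">',
    ]
    contigs = sorted({s.chrom for s in snvs})
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for snv in sorted(snvs, key=lambda s: (s.chrom, s.pos)):
        info = ";".join(
            f"{k.upper()}={getattr(snv, k):g}"
            for k in ("mq", "qd", "fs")
            if getattr(snv, k) is not None
        )
        qual = f"{snv.qual:g}" if snv.qual is not None else "."
        lines.append(
            f"{snv.chrom}\t{snv.pos}\t{snv.id}\t{snv.ref}\t{snv.alt}"
            f"\t{qual}\tPASS\t{info or '.'}"
        )
    path.write_text("".join(line + "\n" for line in lines))


def render_summary_tables(
    estimates_by_minr: dict[int, pd.DataFrame], stage_counts: dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-count table and percent mono-/bi-allelic table (one row per minR).

    Percentages are on the 0-100 scale, rounded to one decimal; the
    predominant and bi-allelic columns of each row sum to 100.
    """
    table1 = pd.DataFrame(
        [{"stage": k, "count": v} for k, v in stage_counts.items()],
        columns=["stage", "count"],
    )
    rows = []
    for minr in sorted(estimates_by_minr):
        est = estimates_by_minr[minr]
        n = len(est)
        if n == 0:
            continue
        strict = int(((est["n_ref"] == 0) | (est["n_var"] == 0)).sum())
        bi = int(((est["vaf"] > 0.2) & (est["vaf"] < 0.8)).sum())
        rows.append(
            {
                "minR": minr,
                "n_estimates": n,
                "pct_strict_mono": round(100.0 * strict / n, 1),
                "pct_predom_mono": round(100.0 * (n - bi) / n, 1),
                "pct_biallelic": round(100.0 * bi / n, 1),
            }
        )
    table2 = pd.DataFrame(
        rows,
        columns=["minR", "n_estimates", "pct_strict_mono", "pct_predom_mono", "pct_biallelic"],
    )
    return table1, table2


def run_pipeline(
    config: dict,
    out_dir: str | Path,
    seed: Optional[int] = None,
    resume: bool = False,
) -> Path:
    """Execute the full workflow described by a config mapping.

    Config sections: ``simulate`` (optional; replaces ``inputs``),
    ``inputs`` (alignment, vcf, annotation, matrix), ``qc``, ``count``,
    ``select``, ``vaf``. ``seed`` overrides the config-level seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(config.get("seed", 0))
    stage_counts: dict[str, int] = {}

    # --- stage 0: inputs (simulated or provided) ----------------------------
    qc_cfg = _sub(config, "qc")
    if "simulate" in config:
        sim_spec = dict(_sub(config, "simulate"))
        sim_spec["seed"] = seed
        sim_config = SimConfig.from_dict(sim_spec)
        truth = simulate_dataset(sim_config, out / "sim")
        inputs = {str(k): str(v) for k, v in truth.paths.items()}
        qc_cfg.setdefault("min_genes", truth.qc_min_genes)
        qc_cfg.setdefault("max_pct_mito", truth.qc_max_pct_mito)
        log.info("simulate: %d cells, %d SNVs", len(truth.cells), len(truth.snvs))
    else:
        inputs = _sub(config, "inputs")
        missing = {"alignment", "vcf", "annotation", "matrix"} - set(inputs)
        if missing:
            raise ConfigError(f"inputs section missing keys: {sorted(missing)}")
        for name, path in inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"input {name!r} does not exist: {path}")

    annotation = read_annotation(inputs["annotation"])

    # --- stage 1: cell QC ---------------------------------------------------
    cells_path = out / "cells.tsv"
    if resume and cells_path.exists():
        cells = pd.read_csv(cells_path, sep="\t")
    else:
        matrix, features, barcodes = read_mtx_dir(inputs["matrix"])
        mito_genes = set(qc_cfg["mito_genes"]) if qc_cfg.get("mito_genes") else None
        cells = qc_cells(
            matrix,
            features,
            barcodes,
            mito_genes=mito_genes,
            mito_prefix=qc_cfg.get("mito_prefix", "MT-"),
            min_genes=int(qc_cfg.get("min_genes", 3000)),
            max_pct_mito=float(qc_cfg.get("max_pct_mito", 6.0)),
        )
        cells.to_csv(cells_path, sep="\t", index=False)
    whitelist = set(cells.loc[cells["pass_qc"], "barcode"])
    (out / "whitelist.txt").write_text("".join(f"{b}\n" for b in sorted(whitelist)))
    stage_counts["cells_total"] = len(cells)
    stage_counts["cells_pass_qc"] = len(whitelist)
    log.info("qc: %d/%d cells pass", len(whitelist), len(cells))

    # --- stage 2: counting over all candidate SNVs --------------------------
    count_cfg = _sub(config, "count")
    count_kwargs = dict(
        min_base_qual=int(count_cfg.get("min_base_qual", 20)),
        min_map_qual=int(count_cfg.get("min_map_qual", 30)),
        honor_wasp_tag=bool(count_cfg.get("honor_wasp_tag", True)),
    )
    snvs = load_snvs_from_vcf(inputs["vcf"], annotation)
    stage_counts["candidate_snvs"] = len(snvs)
    counts_all_path = out / "counts_all.tsv"
    if resume and counts_all_path.exists():
        counts_all = read_counts(counts_all_path)
    else:
        counts_all = count_alleles(
            inputs["alignment"], snvs, barcode_whitelist=whitelist, **count_kwargs
        )
        write_counts(counts_all, counts_all_path)
    log.info("count: %d (cell, SNV) pairs", len(counts_all))

    # --- stage 3: heterozygous SNV selection --------------------------------
    select_cfg = _sub(config, "select")
    het_cfg = HetFilterConfig(
        **{
            k: (frozenset(v) if k == "excluded_categories" else v)
            for k, v in select_cfg.items()
        }
    )
    retained, audit = select_het_snvs(snvs, pool_counts(counts_all), het_cfg)
    audit.to_csv(out / "select_audit.tsv", sep="\t", index=False)
    write_vcf_subset(retained, out / "selected.vcf")
    stage_counts["selected_snvs"] = len(retained)
    log.info("select: %d/%d SNVs retained", len(retained), len(snvs))

    # --- stage 4: counting restricted to selected SNVs and passing cells ----
    counts_path = out / "counts_selected.tsv"
    if resume and counts_path.exists():
        counts = read_counts(counts_path)
    else:
        counts = count_alleles(
            inputs["alignment"], retained, barcode_whitelist=whitelist, **count_kwargs
        )
        write_counts(counts, counts_path)
    stage_counts["count_rows"] = len(counts)

    # --- stage 5: VAF estimation, summaries, classification -----------------
    vaf_cfg_dict = _sub(config, "vaf")
    minr_grid = tuple(vaf_cfg_dict.pop("minr_grid", (3, 5, 10)))
    cls_cfg = ClassificationConfig(minr_grid=minr_grid, **vaf_cfg_dict)
    cls_cfg.validate()
    vaf_dir = out / "vaf"
    vaf_dir.mkdir(exist_ok=True)
    estimates_by_minr: dict[int, pd.DataFrame] = {}
    summaries_list = []
    chi2_reports = []
    for minr in minr_grid:
        est = estimate_vaf(counts, minr)
        est.to_csv(vaf_dir / f"estimates_minR{minr}.tsv", sep="\t", index=False)
        estimates_by_minr[minr] = est
        summary = summarize_snv(est, cls_cfg)
        summaries_list.append(summary)
        vaf_histogram(est).to_csv(
            vaf_dir / f"histogram_minR{minr}.tsv", sep="\t", index=False
        )
        stage_counts[f"estimates_minR{minr}"] = len(est)
        stage_counts[f"snvs_min{cls_cfg.min_cells_stats}cells_minR{minr}"] = int(
            (summary["n_cells"] >= cls_cfg.min_cells_stats).sum()
        )
        chi2_reports.append(compare_intronic(summary, annotation, minr))
    summaries = (
        pd.concat(summaries_list, ignore_index=True)
        if summaries_list
        else pd.DataFrame()
    )
    summaries.to_csv(vaf_dir / "summaries.tsv", sep="\t", index=False)
    genes = aggregate_gene(summaries, annotation) if len(summaries) else pd.DataFrame()
    genes.to_csv(vaf_dir / "genes.tsv", sep="\t", index=False)
    (vaf_dir / "chi2.json").write_text(json.dumps(chi2_reports, indent=2) + "\n")

    # --- stage 6: report ----------------------------------------------------
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    table1, table2 = render_summary_tables(estimates_by_minr, stage_counts)
    table1.to_csv(report_dir / "table1.tsv", sep="\t", index=False)
    table2.to_csv(report_dir / "table2.tsv", sep="\t", index=False)

    manifest = {
        "tool": "scvaf",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            name: sha256_file(path) if Path(path).is_file() else "dir"
            for name, path in inputs.items()
        },
        "stages": stage_counts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return out
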