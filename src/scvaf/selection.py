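"""Heterozygous SNV selection from pooled counts, quality gates and annotation.

An SNV is retained iff it has at least ``min_reads_per_allele`` pooled reads
supporting *both* alleles, passes QUAL/MQ/QD strictly-greater gates, has a
strand-bias score of exactly zero (within tolerance), and is not annotated
as repetitive or intergenic. Rejected SNVs carry the first failing rule in a
fixed evaluation order: counts, qual, mq, qd, fs, annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from scvaf.counting import SNVLocus


@dataclass
class HetFilterConfig:
    min_reads_per_allele: int = 50
    min_qual: float = 100.0
    min_mq: float = 60.0
    min_qd: float = 2.0
    max_fs: float = 0.0  # equality gate: fs must not exceed this (tolerance below)
    fs_tol: float = 1e-9
    excluded_categories: frozenset = field(
        default_factory=lambda: frozenset({"repetitive", "intergenic"})
    )
    # when True, skip the pooled-count heterozygosity rule (e.g. external
    # genotype VCF already restricts to het sites)
    trust_external_genotypes: bool = False

    def validate(self) -> None:
        for name in ("min_reads_per_allele", "min_qual", "min_mq", "min_qd", "max_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _first_failure(
    snv: SNVLocus, pooled: tuple[int, int], cfg: HetFilterConfig
) -> Optional[str]:
    """First failing rule name, or None if the SNV passes every gate."""
    if not cfg.trust_external_genotypes:
        n_ref, n_var = pooled
        if n_ref < cfg.min_reads_per_allele or n_var < cfg.min_reads_per_allele:
            return "counts"
    for rule, value in (("qual", snv.qual), ("mq", snv.mq), ("qd", snv.qd)):
        if value is None:
            return "missing_field"
        threshold = getattr(cfg, f"min_{rule}")
        if not value > threshold:
            return rule
    if snv.fs is None:
        return "missing_field"
    if snv.fs > cfg.max_fs + cfg.fs_tol:
        return "fs"
    if snv.category in cfg.excluded_categories:
        return "annotation"
    return None


def select_het_snvs(
    snvs: Sequence[SNVLocus],
    pooled: pd.DataFrame,
    cfg: Optional[HetFilterConfig] = None,
) -> tuple[list[SNVLocus], pd.DataFrame]:
    """Apply the heterozygosity and quality gates.

    Parameters
    ----------
    snvs : candidate loci, in the order they should be evaluated
    pooled : per-SNV pooled counts with columns snv_id, N_ref, N_var
        (SNVs absent from the table have zero pooled reads)
    cfg : thresholds; defaults mirror the published gates

    Returns
    -------
    (retained, audit) where retained preserves input order and audit has one
    row per input SNV with columns snv_id, retained, reason.
    """
    cfg = cfg or HetFilterConfig()
    cfg.validate()
    pooled_map = {
        row.snv_id: (int(row.N_ref), int(row.N_var)) for row in pooled.itertuples()
    }
    retained: list[SNVLocus] = []
    audit_rows = []
    for snv in snvs:
        reason = _first_failure(snv, pooled_map.get(snv.key, (0, 0)), cfg)
        if reason is None:
            retained.append(snv)
        audit_rows.append(
            {"snv_id": snv.key, "retained": reason is None, "reason": reason or ""}
        )
    return retained, pd.DataFrame(audit_rows, columns=["snv_id", "retained", "reason"])
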