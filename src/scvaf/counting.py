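"""Per-cell, per-SNV allele counting from tagged alignments.

Reads are gathered per locus, filtered on tags and qualities, grouped per
cell and UMI-deduplicated (highest mapping quality wins, deterministic
tie-break); each surviving molecule contributes one unit to ``n_ref``,
``n_var`` or ``n_other`` according to its base at the variant position.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd
import pysam

from scvaf.errors import DataError
from scvaf.io import COUNTS_COLUMNS

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SNVLocus:
    """One bi-allelic candidate SNV with its quality and annotation fields."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    id: str = "."
    qual: Optional[float] = None
    mq: Optional[float] = None
    qd: Optional[float] = None
    fs: Optional[float] = None
    gene: str = ""
    category: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"SNV position must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise DataError(f"non-ACGT alleles at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise DataError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return self.id if self.id not in (".", "", None) else f"{self.chrom}:{self.pos}"


class ReadAtLocus(NamedTuple):
    """The slice of one aligned read that is relevant at one locus."""

    umi: str
    mapq: int
    pos: int  # 0-based alignment start, dedup tie-break
    qname: str
    base: str
    base_qual: int


def load_snvs_from_vcf(
    vcf_path, annotation: Optional[pd.DataFrame] = None
) -> list[SNVLocus]:
    """Read bi-allelic SNVs from a VCF, optionally joining gene/category.

    Multi-allelic records and non-SNV alleles are skipped (the study design
    is confined to bi-allelic substitutions). INFO keys MQ/QD/FS and the
    QUAL column are carried through; absent fields become None.
    """
    annot_map = {}
    if annotation is not None:
        for row in annotation.itertuples():
            annot_map[(str(row.chrom), int(row.pos))] = (row.gene, row.category)
    snvs = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            if ref not in VALID_BASES or alt not in VALID_BASES:
                continue
            gene, category = annot_map.get((rec.chrom, rec.pos), ("", "other"))

            def _info(key):
                try:
                    val = rec.info.get(key)
                except (KeyError, ValueError):  # key absent from the header
                    return None
                return float(val) if val is not None else None

            snvs.append(
                SNVLocus(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    id=rec.id or ".",
                    qual=float(rec.qual) if rec.qual is not None else None,
                    mq=_info("MQ"),
                    qd=_info("QD"),
                    fs=_info("FS"),
                    gene=gene,
                    category=str(category),
                )
            )
    snvs.sort(key=lambda s: (s.chrom, s.pos))
    return snvs


def dedup_umis(reads: Iterable[ReadAtLocus]) -> list[ReadAtLocus]:
    """Collapse PCR duplicates: one molecule per exact UMI string.

    Within a UMI group the read with the highest mapping quality is kept;
    ties are broken deterministically by (alignment position, query name).
    """
    best: dict[str, ReadAtLocus] = {}
    for read in reads:
        rank = (-read.mapq, read.pos, read.qname)
        incumbent = best.get(read.umi)
        if incumbent is None or rank < (-incumbent.mapq, incumbent.pos, incumbent.qname):
            best[read.umi] = read
    return sorted(best.values(), key=lambda r: (r.pos, r.qname))


def _base_at(read: pysam.AlignedSegment, p0: int) -> Optional[tuple[str, int]]:
    """Base and base quality of `read` at reference position p0 (0-based).

    Returns None for deletions, reference skips or clipped-over positions.
    """
    cigar = read.cigartuples
    if cigar is not None and len(cigar) == 1 and cigar[0][0] == 0:
        qpos = p0 - read.reference_start
    else:
        qpos = None
        for q, r in read.get_aligned_pairs(matches_only=True):
            if r == p0:
                qpos = q
                break
        if qpos is None:
            return None
    seq = read.query_sequence
    if seq is None or qpos >= len(seq):
        return None
    quals = read.query_qualities
    return seq[qpos], (quals[qpos] if quals is not None else 0)


def count_alleles(
    alignment,
    snvs: Sequence[SNVLocus],
    barcode_whitelist: Optional[set] = None,
    min_base_qual: int = 20,
    min_map_qual: int = 30,
    honor_wasp_tag: bool = True,
) -> pd.DataFrame:
    """Deduplicated ref/var/other molecule counts per (cell, SNV).

    Reads lacking CB or UB tags, mapped below ``min_map_qual``, with a base
    quality below ``min_base_qual`` at the locus, or (when
    ``honor_wasp_tag``) carrying a vW tag != 1 are discarded. Cells outside
    the whitelist (when given) are dropped; (cell, SNV) pairs with zero
    surviving molecules are omitted from the output.
    """
    loci_by_chrom: dict[str, tuple[list[int], list[SNVLocus]]] = {}
    for snv in sorted(snvs, key=lambda s: (s.chrom, s.pos)):
        positions, loci = loci_by_chrom.setdefault(snv.chrom, ([], []))
        positions.append(snv.pos - 1)
        loci.append(snv)

    gathered: dict[tuple[str, str], list[ReadAtLocus]] = {}
    with pysam.AlignmentFile(str(alignment), check_sq=False) as aln:
        header_contigs = set(aln.references or ())
        missing = set(loci_by_chrom) - header_contigs
        if missing:
            raise DataError(
                f"SNV contigs absent from alignment header: {sorted(missing)}"
            )
        for read in aln:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_map_qual:
                continue
            if honor_wasp_tag and read.has_tag("vW") and read.get_tag("vW") != 1:
                continue
            if not (read.has_tag("CB") and read.has_tag("UB")):
                continue
            cb, umi = read.get_tag("CB"), read.get_tag("UB")
            if not isinstance(cb, str) or not isinstance(umi, str):
                raise DataError(f"malformed CB/UB tag on read {read.query_name}")
            if barcode_whitelist is not None and cb not in barcode_whitelist:
                continue
            entry = loci_by_chrom.get(read.reference_name)
            if entry is None:
                continue
            positions, loci = entry
            start, end = read.reference_start, read.reference_end
            lo = bisect.bisect_left(positions, start)
            hi = bisect.bisect_left(positions, end)
            for i in range(lo, hi):
                locus = loci[i]
                hit = _base_at(read, positions[i])
                if hit is None:
                    continue
                base, base_qual = hit
                if base_qual < min_base_qual:
                    continue
                gathered.setdefault((locus.key, cb), []).append(
                    ReadAtLocus(
                        umi=umi,
                        mapq=read.mapping_quality,
                        pos=start,
                        qname=read.query_name,
                        base=base,
                        base_qual=base_qual,
                    )
                )

    locus_by_key = {snv.key: snv for snv in snvs}
    rows = []
    for (snv_key, cb), reads in gathered.items():
        locus = locus_by_key[snv_key]
        n_ref = n_var = n_other = 0
        for molecule in dedup_umis(reads):
            if molecule.base == locus.ref:
                n_ref += 1
            elif molecule.base == locus.alt:
                n_var += 1
            else:
                n_other += 1  # includes N calls
        rows.append((cb, snv_key, n_ref, n_var, n_other))
    counts = pd.DataFrame(rows, columns=COUNTS_COLUMNS)
    return counts.sort_values(["snv_id", "cell_barcode"], ignore_index=True)


def pool_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Pool per-cell counts into per-SNV totals (exact column sums)."""
    if counts.empty:
        return pd.DataFrame(columns=["snv_id", "N_ref", "N_var"])
    pooled = (
        counts.groupby("snv_id", as_index=False)[["n_ref", "n_var"]]
        .sum()
        .rename(columns={"n_ref": "N_ref", "n_var": "N_var"})
    )
    return pooled.sort_values("snv_id", ignore_index=True)
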