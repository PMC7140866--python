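"""Seeded synthetic data generator for the VAF pipeline.

Emits a toy reference, a tagged single-end SAM alignment, a candidate VCF,
an SNV annotation table and a gene-by-cell count matrix, together with the
full ground truth (per-locus allelic class, per-(cell, SNV) unique-molecule
counts, engineered QC failures).

Layout conventions
------------------
One contig per gene. Each SNV owns a block of ``2 * read_length`` bases and
sits ``read_length`` bases into its block, so a read covering an SNV never
leaves the block and never covers a second SNV. Reads are emitted un-clipped
with an exact-match CIGAR; cell barcode and UMI travel in the ``CB:Z`` and
``UB:Z`` tags. PCR duplicates are extra records sharing (CB, UB) and
position. Records failing the allele-aware remapping filter are emulated by
emitting extra reads tagged ``vW:i:2``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scvaf.errors import ConfigError, DataError
from scvaf.io import write_mtx_dir

BASES = np.array(["A", "C", "G", "T"])
CLASSES = ("symmetric", "skewed", "rme", "strict_mono")
MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1")
NON_INTRON_CATEGORIES = ("utr3", "coding", "utr5", "near-splice")
NON_INTRON_WEIGHTS = (0.5, 0.3, 0.1, 0.1)

# engineered VCF values per quality gate: (passing, failing)
_QUAL_VALUES = (200.0, 50.0)
_MQ_VALUES = (70.0, 30.0)
_QD_VALUES = (10.0, 1.0)
_FS_VALUES = (0.0, 3.5)


@dataclass
class DepthModel:
    """Per-(cell, SNV) unique-molecule depth distribution."""

    kind: str = "fixed"  # fixed | poisson | nb
    n: int = 5
    lam: float = 10.0
    mean: float = 10.0
    dispersion: float = 2.0

    @classmethod
    def from_dict(cls, spec: dict | "DepthModel") -> "DepthModel":
        if isinstance(spec, DepthModel):
            return spec
        return cls(**spec)

    def draw(self, rng: np.random.Generator, size: int, scale: float = 1.0) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, int(round(self.n * scale)), dtype=int)
        if self.kind == "poisson":
            return rng.poisson(self.lam * scale, size=size)
        if self.kind == "nb":
            mean = self.mean * scale
            # NB(mean m, dispersion r): p = r / (r + m)
            r = self.dispersion
            return rng.negative_binomial(r, r / (r + mean), size=size)
        raise ConfigError(f"unknown depth model kind {self.kind!r}")


@dataclass
class SimConfig:
    seed: int = 0
    n_cells: int = 50
    n_genes: int = 10
    snvs_per_gene: int = 2
    barcode_length: int = 14
    umi_length: int = 10
    read_length: int = 150
    depth_model: DepthModel = field(default_factory=DepthModel)
    class_fractions: dict = field(default_factory=lambda: {"symmetric": 1.0})
    skew_p: float = 0.9
    overdispersion: float = math.inf  # beta-binomial concentration; inf = binomial
    pcr_duplication_rate: float = 0.0  # mean extra copies per unique molecule
    fraction_intronic_snvs: float = 0.0
    intron_depth_scale: float = 1.0
    n_bad_cells_low_genes: int = 0
    n_bad_cells_high_mito: int = 0
    base_error_rate: float = 0.0  # substitution probability at the SNV base
    wasp_fail_rate: float = 0.0  # extra vW:i:2 records per molecule
    frac_fail_qual: float = 0.0
    frac_fail_mq: float = 0.0
    frac_fail_qd: float = 0.0
    frac_fail_fs: float = 0.0

    def __post_init__(self) -> None:
        self.depth_model = DepthModel.from_dict(self.depth_model)

    @classmethod
    def from_dict(cls, spec: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(spec) - known
        if unknown:
            raise ConfigError(f"unknown simulate config keys: {sorted(unknown)}")
        return cls(**spec)

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0 or self.snvs_per_gene <= 0:
            raise ConfigError("n_cells, n_genes and snvs_per_gene must be positive")
        for name in ("barcode_length", "umi_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ConfigError(f"unknown allelic classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_fractions sum to {total}, expected 1")
        if not 0.0 <= self.fraction_intronic_snvs <= 1.0:
            raise ConfigError("fraction_intronic_snvs must be in [0, 1]")
        if not 0.0 < self.skew_p < 1.0:
            raise ConfigError("skew_p must be in (0, 1)")
        if self.intron_depth_scale <= 0:
            raise ConfigError("intron_depth_scale must be positive")
        if self.n_bad_cells_low_genes + self.n_bad_cells_high_mito > self.n_cells:
            raise ConfigError("more engineered bad cells than cells")
        for name in ("pcr_duplication_rate", "wasp_fail_rate", "base_error_rate",
                     "frac_fail_qual", "frac_fail_mq", "frac_fail_qd", "frac_fail_fs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset.

    snvs    one row per SNV: id, locus, alleles, gene, category, class, p
    counts  one row per (cell, SNV) with depth > 0: true unique ref/alt molecules
    cells   one row per cell: engineered QC outcome and the observable QC stats
    """

    snvs: pd.DataFrame
    counts: pd.DataFrame
    cells: pd.DataFrame
    qc_min_genes: int
    qc_max_pct_mito: float
    paths: dict = field(default_factory=dict)


def _random_kmers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Draw n distinct random DNA k-mers."""
    if n > 4 ** length:
        raise ConfigError(f"cannot draw {n} distinct {length}-mers")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = ["".join(row) for row in BASES[rng.integers(0, 4, size=(n, length))]]
        for kmer in block:
            if kmer not in seen:
                seen.add(kmer)
                out.append(kmer)
                if len(out) == n:
                    break
    return out


def _write_fasta(path: Path, contigs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in contigs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _write_vcf(path: Path, snvs: pd.DataFrame, contigs: dict[str, str]) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">',
    ]
    lines += [f"##contig=<ID={name},length={len(seq)}>" for name, seq in contigs.items()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for row in snvs.itertuples():
        info = f"MQ={row.mq:.2f};QD={row.qd:.2f};FS={row.fs:.3f}"
        lines.append(
            f"{row.chrom}\t{row.pos}\t{row.snv_id}\t{row.ref}\t{row.alt}"
            f"\t{row.qual:.2f}\tPASS\t{info}"
        )
    path.write_text("".join(line + "\n" for line in lines))


def _pick_failing(rng: np.random.Generator, n_snvs: int, frac: float) -> np.ndarray:
    mask = np.zeros(n_snvs, dtype=bool)
    k = int(round(frac * n_snvs))
    if k:
        mask[rng.choice(n_snvs, size=k, replace=False)] = True
    return mask


def _draw_alt_counts(
    rng: np.random.Generator, depths: np.ndarray, cls: str, p: float, cfg: SimConfig
) -> np.ndarray:
    """True alt-molecule counts for all cells of one locus."""
    n = len(depths)
    if cls == "rme":
        # fair coin per cell: the whole cell expresses one allele
        p_cell = rng.integers(0, 2, size=n).astype(float)
        return rng.binomial(depths, p_cell)
    if cls == "symmetric" and np.isfinite(cfg.overdispersion):
        c = cfg.overdispersion
        p_cell = rng.beta(c / 2.0, c / 2.0, size=n)
        return rng.binomial(depths, p_cell)
    return rng.binomial(depths, p)


def simulate_dataset(config: SimConfig, output_dir: str | Path) -> SimTruth:
    """Generate the four pipeline inputs plus ground-truth tables.

    Writes under ``output_dir``: ``reference.fa``, ``alignment.sam``,
    ``variants.vcf``, ``annotation.tsv``, ``matrix/`` (MTX + sidecars) and
    ``truth_snvs.tsv`` / ``truth_counts.tsv`` / ``truth_cells.tsv``.
    Identical configs (including seed) produce byte-identical outputs.
    """
    config.validate()
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DataError(f"output directory not writable: {out}") from exc

    rng = np.random.default_rng(config.seed)
    read_len = config.read_length
    block = 2 * read_len

    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    barcodes = _random_kmers(rng, config.n_cells, config.barcode_length)

    # --- reference and SNV table -------------------------------------------
    contigs: dict[str, str] = {}
    snv_rows = []
    for gene in genes:
        length = config.snvs_per_gene * block
        seq = rng.integers(0, 4, size=length)
        for j in range(config.snvs_per_gene):
            p0 = j * block + read_len  # 0-based
            ref_base = BASES[seq[p0]]
            alt_base = BASES[(seq[p0] + rng.integers(1, 4)) % 4]
            snv_rows.append(
                {
                    "snv_id": f"s{len(snv_rows) + 1:05d}",
                    "chrom": gene,
                    "pos": p0 + 1,
                    "ref": ref_base,
                    "alt": alt_base,
                    "gene": gene,
                }
            )
        contigs[gene] = "".join(BASES[seq])
    snvs = pd.DataFrame(snv_rows)
    n_snvs = len(snvs)

    # --- annotation categories ---------------------------------------------
    categories = rng.choice(
        NON_INTRON_CATEGORIES, size=n_snvs, p=NON_INTRON_WEIGHTS
    ).astype(object)
    n_intronic = int(round(config.fraction_intronic_snvs * n_snvs))
    if n_intronic:
        categories[rng.choice(n_snvs, size=n_intronic, replace=False)] = "intron"
    snvs["category"] = categories

    # --- allelic class and locus-level allele fraction ----------------------
    class_names = [c for c in CLASSES if config.class_fractions.get(c, 0) > 0]
    class_probs = [config.class_fractions[c] for c in class_names]
    snvs["allelic_class"] = rng.choice(class_names, size=n_snvs, p=class_probs)
    p_locus = np.full(n_snvs, 0.5)
    p_locus[snvs["allelic_class"] == "skewed"] = config.skew_p
    strict = (snvs["allelic_class"] == "strict_mono").to_numpy()
    p_locus[strict] = rng.integers(0, 2, size=int(strict.sum())).astype(float)
    snvs["true_p"] = p_locus

    # --- engineered variant-quality failures --------------------------------
    for col, frac, (good, bad) in (
        ("qual", config.frac_fail_qual, _QUAL_VALUES),
        ("mq", config.frac_fail_mq, _MQ_VALUES),
        ("qd", config.frac_fail_qd, _QD_VALUES),
        ("fs", config.frac_fail_fs, _FS_VALUES),
    ):
        fail = _pick_failing(rng, n_snvs, frac)
        snvs[col] = np.where(fail, bad, good)

    # --- per-(cell, SNV) truth counts ---------------------------------------
    truth_rows = []
    for idx, snv in enumerate(snvs.itertuples()):
        scale = config.intron_depth_scale if snv.category == "intron" else 1.0
        depths = config.depth_model.draw(rng, config.n_cells, scale=scale)
        alts = _draw_alt_counts(
            rng, depths, snv.allelic_class, snv.true_p, config
        )
        for c in range(config.n_cells):
            if depths[c] > 0:
                truth_rows.append(
                    (barcodes[c], snv.snv_id, int(depths[c] - alts[c]), int(alts[c]))
                )
    truth_counts = pd.DataFrame(
        truth_rows, columns=["cell_barcode", "snv_id", "n_ref", "n_var"]
    )

    # --- SAM records --------------------------------------------------------
    snv_by_id = snvs.set_index("snv_id")
    records_by_chrom: dict[str, list[tuple]] = {g: [] for g in genes}
    mol_idx = 0
    qual_str = "I" * read_len
    for row in truth_counts.itertuples():
        snv = snv_by_id.loc[row.snv_id]
        chrom = snv["chrom"]
        p0 = int(snv["pos"]) - 1
        ref_seq = contigs[chrom]
        umis = _random_kmers(rng, row.n_ref + row.n_var, config.umi_length)
        for m in range(row.n_ref + row.n_var):
            is_alt = m >= row.n_ref
            base = snv["alt"] if is_alt else snv["ref"]
            if config.base_error_rate > 0 and rng.random() < config.base_error_rate:
                base = str(rng.choice([b for b in BASES if b != base]))
            offset = int(rng.integers(0, read_len))
            start = p0 - offset
            seq = ref_seq[start:p0] + base + ref_seq[p0 + 1 : start + read_len]
            n_copies = 1
            if config.pcr_duplication_rate > 0:
                n_copies += int(rng.poisson(config.pcr_duplication_rate))
            mol_idx += 1
            for copy in range(n_copies):
                mapq = 255 if copy == 0 else int(rng.integers(30, 255))
                records_by_chrom[chrom].append(
                    (
                        start + 1,
                        f"m{mol_idx:08d}.{copy}",
                        mapq,
                        seq,
                        row.cell_barcode,
                        umis[m],
                        None,
                    )
                )
            if config.wasp_fail_rate > 0 and rng.random() < config.wasp_fail_rate:
                # ambiguous-mapping read: new molecule-like record, filtered by vW
                bad_umi = _random_kmers(rng, 1, config.umi_length)[0]
                records_by_chrom[chrom].append(
                    (
                        start + 1,
                        f"w{mol_idx:08d}",
                        int(rng.integers(30, 256)),
                        seq,
                        row.cell_barcode,
                        bad_umi,
                        2,
                    )
                )

    sam_path = out / "alignment.sam"
    with open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:coordinate\n")
        for gene in genes:
            sam.write(f"@SQ\tSN:{gene}\tLN:{len(contigs[gene])}\n")
        for gene in genes:
            for pos, qname, mapq, seq, cb, umi, vw in sorted(records_by_chrom[gene]):
                tags = f"CB:Z:{cb}\tUB:Z:{umi}"
                if vw is not None:
                    tags += f"\tvW:i:{vw}"
                sam.write(
                    f"{qname}\t0\t{gene}\t{pos}\t{mapq}\t{read_len}M\t*\t0\t0"
                    f"\t{seq}\t{qual_str}\t{tags}\n"
                )

    # --- gene-by-cell count matrix with engineered QC failures --------------
    features = genes + list(MITO_GENES)
    n_bad_low = config.n_bad_cells_low_genes
    n_bad_mito = config.n_bad_cells_high_mito
    cell_rows = []
    matrix = np.zeros((len(features), config.n_cells), dtype=int)
    n_low_detect = max(1, config.n_genes // 4)
    for c, barcode in enumerate(barcodes):
        if c < n_bad_low:
            reason = "low_genes"
            detected = rng.choice(config.n_genes, size=n_low_detect, replace=False)
            mito_frac = 0.02
        elif c < n_bad_low + n_bad_mito:
            reason = "high_mito"
            detected = np.arange(config.n_genes)
            mito_frac = 0.25
        else:
            reason = ""
            detected = np.arange(config.n_genes)
            mito_frac = 0.02
        matrix[detected, c] = rng.poisson(5, size=len(detected)) + 1
        total_reg = int(matrix[: config.n_genes, c].sum())
        # deterministic mito load so good cells can never drift over threshold
        mito_total = max(1, int(round(mito_frac * total_reg)))
        per_gene = np.full(len(MITO_GENES), mito_total // len(MITO_GENES))
        per_gene[: mito_total % len(MITO_GENES)] += 1
        matrix[config.n_genes :, c] = per_gene
        cell_rows.append(
            {
                "cell_barcode": barcode,
                "qc_fail": reason != "",
                "reason": reason,
                "n_genes_detected": int((matrix[:, c] > 0).sum()),
                "pct_mito": 100.0 * matrix[config.n_genes :, c].sum() / matrix[:, c].sum(),
            }
        )
    truth_cells = pd.DataFrame(cell_rows)
    write_mtx_dir(out / "matrix", matrix, features, barcodes)

    # --- remaining text outputs ---------------------------------------------
    _write_fasta(out / "reference.fa", contigs)
    _write_vcf(out / "variants.vcf", snvs, contigs)
    annotation = snvs[["snv_id", "chrom", "pos", "ref", "alt", "gene", "category"]]
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    snvs.to_csv(out / "truth_snvs.tsv", sep="\t", index=False)
    truth_counts.to_csv(out / "truth_counts.tsv", sep="\t", index=False)
    truth_cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)

    return SimTruth(
        snvs=snvs,
        counts=truth_counts,
        cells=truth_cells,
        qc_min_genes=config.n_genes,
        qc_max_pct_mito=6.0,
        paths={
            "reference": out / "reference.fa",
            "alignment": sam_path,
            "vcf": out / "variants.vcf",
            "annotation": out / "annotation.tsv",
            "matrix": out / "matrix",
        },
    )
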