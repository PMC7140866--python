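"""Readers and writers for the plain-text interchange formats.

Count matrices travel as MatrixMarket triplets plus ``barcodes.tsv`` /
``features.tsv`` sidecars (CellRanger-style layout); tabular data as TSV.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from scvaf.errors import DataError

COUNTS_COLUMNS = ["cell_barcode", "snv_id", "n_ref", "n_var", "n_other"]


def write_mtx_dir(
    out_dir: str | Path,
    matrix: scipy.sparse.spmatrix,
    features: list[str],
    barcodes: list[str],
) -> None:
    """Write a genes-by-cells integer matrix in MatrixMarket triplet form."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.coo_matrix(matrix).astype(int)
    if mat.shape != (len(features), len(barcodes)):
        raise DataError(
            f"matrix shape {mat.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), mat, field="integer")
    (out_dir / "features.tsv").write_text("".join(f"{g}\n" for g in features))
    (out_dir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))


def read_mtx_dir(mtx_dir: str | Path):
    """Read a matrix directory; returns (csr genes-by-cells, features, barcodes)."""
    mtx_dir = Path(mtx_dir)
    mtx_path = mtx_dir / "matrix.mtx"
    if not mtx_path.exists():
        raise DataError(f"no matrix.mtx under {mtx_dir}")
    matrix = scipy.io.mmread(str(mtx_path)).tocsr()
    features = (mtx_dir / "features.tsv").read_text().splitlines()
    barcodes = (mtx_dir / "barcodes.tsv").read_text().splitlines()
    if matrix.shape != (len(features), len(barcodes)):
        raise DataError(
            f"matrix shape {matrix.shape} inconsistent with sidecar files "
            f"({len(features)} features, {len(barcodes)} barcodes)"
        )
    return matrix, features, barcodes


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the SNV annotation table (snv_id, chrom, pos, ref, alt, gene, category)."""
    annot = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snv_id", "gene", "category"}
    missing = required - set(annot.columns)
    if missing:
        raise DataError(f"annotation table missing columns: {sorted(missing)}")
    return annot


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", dtype={"cell_barcode": str, "snv_id": str})
    missing = set(COUNTS_COLUMNS) - set(counts.columns)
    if missing:
        raise DataError(f"counts table missing columns: {sorted(missing)}")
    return counts


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
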