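"""Cell quality control on the raw gene-by-cell count matrix.

A cell passes iff it has at least ``min_genes`` detected genes (count > 0)
and a mitochondrial fraction of total raw counts not exceeding
``max_pct_mito`` percent. Raw counts are used throughout; no normalization.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from scvaf.errors import DataError

DEFAULT_MITO_PREFIX = "MT-"


def qc_cells(
    matrix,
    features: Sequence[str],
    barcodes: Sequence[str],
    mito_genes: Optional[set] = None,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    min_genes: int = 3000,
    max_pct_mito: float = 6.0,
) -> pd.DataFrame:
    """Per-cell QC table with columns barcode, n_genes_detected, pct_mito, pass_qc.

    ``matrix`` is genes-by-cells (dense or sparse). Mitochondrial genes are
    either the explicit ``mito_genes`` set or all features starting with
    ``mito_prefix``. A cell with zero total counts gets pct_mito = 0 and
    fails on the gene-count rule.
    """
    matrix = scipy.sparse.csr_matrix(matrix)
    if matrix.shape != (len(features), len(barcodes)):
        raise DataError(
            f"matrix shape {matrix.shape} inconsistent with "
            f"{len(features)} features / {len(barcodes)} barcodes"
        )
    if len(barcodes) == 0:
        raise DataError("empty matrix: no cells")
    if mito_genes is not None:
        unknown = set(mito_genes) - set(features)
        if unknown:
            raise DataError(f"mito genes absent from matrix: {sorted(unknown)}")
        mito_mask = np.array([g in mito_genes for g in features])
    else:
        mito_mask = np.array([g.startswith(mito_prefix) for g in features])

    n_detected = np.asarray((matrix > 0).sum(axis=0)).ravel()
    totals = np.asarray(matrix.sum(axis=0)).ravel().astype(float)
    mito_totals = np.asarray(matrix[mito_mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, 100.0 * mito_totals / np.maximum(totals, 1e-300), 0.0)

    return pd.DataFrame(
        {
            "barcode": list(barcodes),
            "n_genes_detected": n_detected.astype(int),
            "pct_mito": pct_mito,
            "pass_qc": (n_detected >= min_genes) & (pct_mito <= max_pct_mito),
        }
    )
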