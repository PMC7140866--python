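import numpy as np
import pandas as pd
import pytest

from scvaf.counting import ReadAtLocus
from scvaf.simulate import DepthModel, SimConfig, simulate_dataset

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def make_read(umi, mapq=60, pos=0, qname="r1", base="A", base_qual=40):
    return ReadAtLocus(
        umi=umi, mapq=mapq, pos=pos, qname=qname, base=base, base_qual=base_qual
    )


def write_sam(path, records, header=SAM_HEADER):
    """records: (qname, pos1, mapq, seq, cb, umi[, extra_tags]) with 1-based pos."""
    lines = [header]
    for rec in records:
        qname, pos1, mapq, seq, cb, umi, *rest = rec
        tags = f"CB:Z:{cb}\tUB:Z:{umi}"
        if rest and rest[0]:
            tags += "\t" + rest[0]
        lines.append(
            f"{qname}\t0\tchr1\t{pos1}\t{mapq}\t{len(seq)}M\t*\t0\t0"
            f"\t{seq}\t{'I' * len(seq)}\t{tags}\n"
        )
    path.write_text("".join(lines))
    return path


def make_counts(rows):
    """rows: (cell_barcode, snv_id, n_ref, n_var[, n_other])."""
    out = []
    for row in rows:
        cb, sid, n_ref, n_var = row[:4]
        n_other = row[4] if len(row) > 4 else 0
        out.append(
            {
                "cell_barcode": cb,
                "snv_id": sid,
                "n_ref": n_ref,
                "n_var": n_var,
                "n_other": n_other,
            }
        )
    return pd.DataFrame(out)


def binomial_counts(rng, n_cells, depth, p, snv_id="s1"):
    """Counts table for one locus: fixed depth, Binomial(depth, p) alt draws."""
    alts = rng.binomial(depth, p, size=n_cells)
    return make_counts(
        [(f"c{i:05d}", snv_id, int(depth - a), int(a)) for i, a in enumerate(alts)]
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Mixed-class simulation reused across modules (truth + file outputs)."""
    cfg = SimConfig(
        seed=11,
        n_cells=60,
        n_genes=8,
        snvs_per_gene=2,
        depth_model=DepthModel("poisson", lam=8.0),
        class_fractions={"symmetric": 0.7, "rme": 0.2, "skewed": 0.1},
        pcr_duplication_rate=1.5,
        fraction_intronic_snvs=0.25,
        intron_depth_scale=0.5,
        n_bad_cells_low_genes=3,
        n_bad_cells_high_mito=2,
    )
    out = tmp_path_factory.mktemp("small_sim")
    return cfg, simulate_dataset(cfg, out)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
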