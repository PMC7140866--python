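"""Per-cell VAF estimation, per-SNV summaries and allelic-pattern calls.

The expressed variant allele fraction of one cell at one locus is
``vaf = n_var / (n_var + n_ref)``; ambiguous calls (``n_other``) never enter
the denominator. A cell/locus pair qualifies only when its informative depth
``n_ref + n_var`` reaches the threshold in force (minR).

Per-cell classes partition exactly: a cell is strictly monoallelic when one
allele count is zero (vaf is exactly 0 or 1, decided on the integer counts,
not on floats), predominantly monoallelic when vaf <= lower or vaf >= upper
(inclusive of strict), and bi-allelic on the open interval in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

from scvaf.errors import ConfigError, DataError

PATTERNS = ("biallelic", "skewed", "RME", "insufficient_cells")

SUMMARY_COLUMNS = [
    "snv_id",
    "minR",
    "n_cells",
    "mean_vaf",
    "median_vaf",
    "n_strict_mono",
    "n_low",
    "n_high",
    "n_biallelic",
    "frac_strict_mono",
    "frac_predom_mono",
    "frac_biallelic",
    "pattern",
]


@dataclass
class ClassificationConfig:
    lower: float = 0.2
    upper: float = 0.8
    min_cells_stats: int = 10
    min_cells_pattern: int = 50
    rme_max_biallelic_frac: float = 0.05
    skew_min_one_allele_frac: float = 0.10
    skew_max_biallelic_frac: float = 0.80
    minr_grid: tuple = (3, 5, 10)

    def validate(self) -> None:
        if not 0.0 < self.lower < self.upper < 1.0:
            raise ConfigError("need 0 < lower < upper < 1")
        for name in (
            "rme_max_biallelic_frac",
            "skew_min_one_allele_frac",
            "skew_max_biallelic_frac",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.min_cells_stats < 1 or self.min_cells_pattern < 1:
            raise ConfigError("cell minima must be >= 1")
        if any(r < 1 for r in self.minr_grid):
            raise ConfigError("minR values must be >= 1")


def estimate_vaf(counts: pd.DataFrame, minr: int) -> pd.DataFrame:
    """Per-cell VAF estimates at loci meeting the informative-depth threshold.

    Rows with ``n_ref + n_var < minr`` are omitted entirely; ``n_other``
    contributes to neither depth nor VAF.
    """
    if minr < 1:
        raise ConfigError(f"minR must be >= 1, got {minr}")
    est = counts[["cell_barcode", "snv_id", "n_ref", "n_var"]].copy()
    est["depth_informative"] = est["n_ref"] + est["n_var"]
    est = est[est["depth_informative"] >= minr].reset_index(drop=True)
    est["vaf"] = est["n_var"] / est["depth_informative"]
    est["minR"] = minr
    return est


def _cell_classes(est: pd.DataFrame, lower: float, upper: float):
    """Boolean masks (strict, low, high, biallelic); strict uses exact counts."""
    strict = (est["n_ref"] == 0) | (est["n_var"] == 0)
    low = est["vaf"] <= lower
    high = est["vaf"] >= upper
    biallelic = ~(low | high)
    return strict, low, high, biallelic


def classify_pattern(
    n_cells: int,
    frac_biallelic: float,
    frac_low: float,
    frac_high: float,
    cfg: Optional[ClassificationConfig] = None,
) -> str:
    """Allelic-pattern label for one SNV from its cell-class fractions.

    RME when fewer than ``rme_max_biallelic_frac`` of cells are bi-allelic;
    otherwise skewed when one allele is expressed by fewer than
    ``skew_min_one_allele_frac`` of cells and bi-allelic cells stay below
    ``skew_max_biallelic_frac``; otherwise bi-allelic. SNVs measured in
    fewer than ``min_cells_pattern`` cells are not classified.
    """
    cfg = cfg or ClassificationConfig()
    if n_cells < cfg.min_cells_pattern:
        return "insufficient_cells"
    if frac_biallelic < cfg.rme_max_biallelic_frac:
        return "RME"
    if (
        min(frac_low, frac_high) < cfg.skew_min_one_allele_frac
        and frac_biallelic < cfg.skew_max_biallelic_frac
    ):
        return "skewed"
    return "biallelic"


def summarize_snv(
    estimates: pd.DataFrame, cfg: Optional[ClassificationConfig] = None
) -> pd.DataFrame:
    """Cross-cell summary and pattern per SNV, one minR per call.

    SNVs observed in fewer than ``min_cells_stats`` cells are emitted with
    pattern ``insufficient_cells`` and NaN statistics. The median uses the
    midpoint-of-two rule for even cell counts.
    """
    cfg = cfg or ClassificationConfig()
    cfg.validate()
    if estimates.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    minrs = estimates["minR"].unique()
    if len(minrs) != 1:
        raise DataError(f"summarize_snv expects a single minR, got {sorted(minrs)}")
    minr = int(minrs[0])

    strict, low, high, biallelic = _cell_classes(estimates, cfg.lower, cfg.upper)
    work = estimates.assign(
        _strict=strict.astype(int),
        _low=low.astype(int),
        _high=high.astype(int),
        _bi=biallelic.astype(int),
    )
    grouped = work.groupby("snv_id", sort=True)
    agg = grouped.agg(
        n_cells=("vaf", "size"),
        mean_vaf=("vaf", "mean"),
        median_vaf=("vaf", "median"),
        n_strict_mono=("_strict", "sum"),
        n_low=("_low", "sum"),
        n_high=("_high", "sum"),
        n_biallelic=("_bi", "sum"),
    ).reset_index()

    n = agg["n_cells"].to_numpy(dtype=float)
    agg["frac_strict_mono"] = agg["n_strict_mono"] / n
    agg["frac_predom_mono"] = (agg["n_low"] + agg["n_high"]) / n
    agg["frac_biallelic"] = agg["n_biallelic"] / n
    agg["minR"] = minr

    thin = agg["n_cells"] < cfg.min_cells_stats
    stat_cols = [
        "mean_vaf",
        "median_vaf",
        "frac_strict_mono",
        "frac_predom_mono",
        "frac_biallelic",
    ]
    agg.loc[thin, stat_cols] = np.nan

    patterns = [
        "insufficient_cells"
        if row.n_cells < cfg.min_cells_stats
        else classify_pattern(
            int(row.n_cells),
            row.frac_biallelic,
            row.n_low / row.n_cells,
            row.n_high / row.n_cells,
            cfg,
        )
        for row in agg.itertuples()
    ]
    agg["pattern"] = patterns
    return agg[SUMMARY_COLUMNS]


def aggregate_gene(
    summaries: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Gene-level aggregation of SNV summaries, split intronic/non-intronic.

    Per (gene, minR): member SNV lists, per-group mean bi-allelic fraction,
    a concordance score (max pairwise absolute difference of the bi-allelic
    fraction over members with defined statistics) and a majority-vote gene
    pattern over classified members (tie -> "discordant").
    """
    meta = annotation.set_index("snv_id")[["gene", "category"]]
    joined = summaries.join(meta, on="snv_id")
    if joined["gene"].isna().any():
        missing = joined.loc[joined["gene"].isna(), "snv_id"].tolist()
        raise DataError(f"SNVs missing from annotation: {missing[:5]}")

    rows = []
    for (gene, minr), grp in joined.groupby(["gene", "minR"], sort=True):
        intronic = grp[grp["category"] == "intron"]
        nonintronic = grp[grp["category"] != "intron"]
        def spread(frame):
            # max pairwise |difference| of defined bi-allelic fractions
            vals = frame["frac_biallelic"].dropna().to_numpy()
            return float(vals.max() - vals.min()) if len(vals) > 1 else 0.0

        concordance = spread(grp)
        votes = grp.loc[grp["pattern"] != "insufficient_cells", "pattern"]
        if votes.empty:
            pattern = "insufficient_cells"
        else:
            counts = votes.value_counts()
            top = counts[counts == counts.iloc[0]]
            pattern = top.index[0] if len(top) == 1 else "discordant"
        rows.append(
            {
                "gene": gene,
                "minR": int(minr),
                "n_snvs": len(grp),
                "snv_ids": ";".join(sorted(grp["snv_id"])),
                "n_intronic": len(intronic),
                "n_nonintronic": len(nonintronic),
                "mean_frac_biallelic_intronic": intronic["frac_biallelic"].mean(),
                "mean_frac_biallelic_nonintronic": nonintronic["frac_biallelic"].mean(),
                "concordance_score": concordance,
                "concordance_intronic": spread(intronic),
                "concordance_nonintronic": spread(nonintronic),
                "pattern": pattern,
            }
        )
    return pd.DataFrame(rows)


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {table.shape}")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("chi-square undefined: zero marginal")
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def compare_intronic(
    summaries: pd.DataFrame, annotation: pd.DataFrame, minr: int
) -> dict:
    """Chi-square comparison of bi-allelic cell-measurement proportions
    between intronic and non-intronic SNVs at one minR.

    Cell measurements are pooled within each SNV group into a 2x2 table
    (bi-allelic vs not) x (intronic vs not). Returns the statistic without
    continuity correction, its p-value and the per-group proportions; when
    either group is empty the result is flagged not applicable.
    """
    meta = annotation.set_index("snv_id")["category"]
    sub = summaries[(summaries["minR"] == minr) & summaries["frac_biallelic"].notna()]
    sub = sub.assign(_intron=sub["snv_id"].map(meta).eq("intron"))

    def group_counts(frame):
        n_bi = int(frame["n_biallelic"].sum())
        n_total = int(frame["n_cells"].sum())
        return n_bi, n_total - n_bi

    intr = sub[sub["_intron"]]
    nonintr = sub[~sub["_intron"]]
    if intr.empty or nonintr.empty:
        return {"applicable": False, "minR": minr}
    table = np.array([group_counts(intr), group_counts(nonintr)], dtype=float)
    stat, p = chi2_2x2(table)
    return {
        "applicable": True,
        "minR": minr,
        "chi2": stat,
        "p_value": p,
        "intronic_biallelic_prop": table[0, 0] / table[0].sum(),
        "nonintronic_biallelic_prop": table[1, 0] / table[1].sum(),
        "table": table.astype(int).tolist(),
    }


def vaf_histogram(estimates: pd.DataFrame, bin_width: float = 0.1) -> pd.DataFrame:
    """Histogram of VAF estimates with dedicated bins for exactly 0 and 1.

    With the default width the bins are {0}, (0,0.1], ..., (0.9,1), {1};
    strict-monoallelic membership is decided on the integer allele counts.
    Bin counts always sum to the number of estimates.
    """
    if not 0.0 < bin_width <= 0.5:
        raise ConfigError("bin_width must be in (0, 0.5]")
    n_interior = int(round(1.0 / bin_width))
    if abs(n_interior * bin_width - 1.0) > 1e-9:
        raise ConfigError("bin_width must divide 1 evenly")

    strict_zero = (estimates["n_var"] == 0).to_numpy()
    strict_one = (estimates["n_ref"] == 0).to_numpy()
    vaf = estimates["vaf"].to_numpy(dtype=float)
    interior = ~(strict_zero | strict_one)
    idx = np.ceil(vaf[interior] / bin_width - 1e-12).astype(int) - 1
    idx = np.clip(idx, 0, n_interior - 1)
    interior_counts = np.bincount(idx, minlength=n_interior)

    rows = [{"bin": "0", "lo": 0.0, "hi": 0.0, "count": int(strict_zero.sum())}]
    for k in range(n_interior):
        lo, hi = k * bin_width, (k + 1) * bin_width
        closing = "]" if k < n_interior - 1 else ")"
        rows.append(
            {
                "bin": f"({lo:g},{hi:g}{closing}",
                "lo": lo,
                "hi": hi,
                "count": int(interior_counts[k]),
            }
        )
    rows.append({"bin": "1", "lo": 1.0, "hi": 1.0, "count": int(strict_one.sum())})
    return pd.DataFrame(rows)
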