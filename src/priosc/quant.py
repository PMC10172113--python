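"""Single-cell reporter-ion quantification: QC, normalization, aggregation.

Implements the isobaric single-cell processing chain: per-cell quality control
on the coefficient of variation (CV) of peptides mapping to the same protein,
missing-data filters, column/row normalization, log2 transform and median
protein aggregation.  Negative-control samples (droplets that received
reagents but no cell) are tracked separately and are expected to fail the CV
filter, since their reporter signal is uncorrelated noise.  No imputation is
performed anywhere; missing values propagate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "QuantMatrix",
    "CellQCReport",
    "qc_cells",
    "normalize_and_aggregate",
    "missingness_filter",
    "completeness",
    "intensity_distribution",
]


@dataclass
class QuantMatrix:
    """Features x cells relative-abundance matrix with metadata.

    ``data``: DataFrame, rows = features (precursors or proteins), columns =
    cells; NaN marks missing.  ``cell_meta``: DataFrame indexed by cell id with
    at least ``condition`` and boolean ``control`` columns (``run_id``
    optional).  ``tier``: optional Series mapping features to priority tiers.
    """

    data: pd.DataFrame
    cell_meta: pd.DataFrame
    tier: pd.Series | None = None
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("feature ids must be unique")
        missing_cells = [c for c in self.data.columns if c not in self.cell_meta.index]
        if missing_cells:
            raise ValueError(f"cells missing from metadata: {missing_cells[:5]}")
        if "control" not in self.cell_meta.columns:
            raise ValueError("cell_meta must carry a boolean 'control' column")
        if (np.asarray(self.data, dtype=float) < 0).any():
            raise ValueError("abundances must be non-negative before log transform")

    def controls(self) -> list[str]:
        return [c for c in self.data.columns if bool(self.cell_meta.loc[c, "control"])]

    def single_cells(self) -> list[str]:
        return [c for c in self.data.columns if not bool(self.cell_meta.loc[c, "control"])]

    def subset_cells(self, cells) -> "QuantMatrix":
        return QuantMatrix(
            self.data[list(cells)],
            self.cell_meta.loc[list(cells)],
            self.tier,
            dict(self.channel_meta),
        )


@dataclass
class CellQCReport:
    """Per-cell protein-level CV summary and pass/fail flags."""

    table: pd.DataFrame  # index cell; columns: aggregate_cv, n_proteins, control, passed, reason
    cv_threshold: float = 0.4
    aggregator: str = "mean"


def _per_cell_protein_cvs(
    values: pd.Series, protein_of: pd.Series
) -> pd.Series:
    """CV (sd/mean) per protein over its observed peptides in one cell."""
    df = pd.DataFrame({"v": values, "protein": protein_of})
    df = df.dropna(subset=["v"])
    grouped = df.groupby("protein")["v"]
    counts = grouped.count()
    eligible = counts[counts >= 2].index
    if len(eligible) == 0:
        return pd.Series(dtype=float)
    means = grouped.mean()[eligible]
    sds = grouped.std(ddof=1)[eligible]
    return sds / means


def qc_cells(
    matrix: QuantMatrix,
    protein_map: pd.Series,
    cv_threshold: float = 0.4,
    aggregator: str = "mean",
) -> tuple[CellQCReport, QuantMatrix]:
    """Filter cells on aggregate protein-level quantification variability.

    For each cell, the CV (sd scaled by mean) is computed over the relative
    abundances of observed peptides for every protein with >= 2 observed
    peptides; the cell's aggregate is the mean (default) or median of those
    protein CVs.  Cells with aggregate CV above ``cv_threshold`` are removed,
    as are cells where no protein has two observed peptides.  Control samples
    are reported alongside but never enter the filtered matrix.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    agg: Callable = np.mean if aggregator == "mean" else np.median
    protein_of = protein_map.reindex(matrix.data.index)

    rows = []
    keep: list[str] = []
    for cell in matrix.data.columns:
        cvs = _per_cell_protein_cvs(matrix.data[cell], protein_of)
        is_control = bool(matrix.cell_meta.loc[cell, "control"])
        if len(cvs) == 0:
            rows.append(
                {"cell": cell, "aggregate_cv": np.nan, "n_proteins": 0,
                 "control": is_control, "passed": False, "reason": "no multi-peptide protein"}
            )
            continue
        a = float(agg(cvs.to_numpy()))
        passed = a <= cv_threshold
        reason = "" if passed else f"aggregate CV {a:.3f} > {cv_threshold}"
        rows.append(
            {"cell": cell, "aggregate_cv": a, "n_proteins": int(len(cvs)),
             "control": is_control, "passed": passed, "reason": reason}
        )
        if passed and not is_control:
            keep.append(cell)
    report = CellQCReport(pd.DataFrame(rows).set_index("cell"), cv_threshold, aggregator)
    return report, matrix.subset_cells(keep)


def normalize_and_aggregate(
    matrix: QuantMatrix,
    protein_map: pd.Series,
    reference_channel: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Normalize the precursor matrix and aggregate to log2 protein abundances.

    Steps, in order: (1) optional division of each precursor row by its
    reference-channel intensity; (2) each cell column divided by its median
    over observed entries; (3) each precursor row divided by its mean over
    observed entries; (4) log2; (5) per protein and cell, the median over
    observed peptide values.  Missing values propagate untouched.  Columns with
    no observed entries are dropped and reported.

    Returns (protein x cell log2 matrix, intermediates).
    """
    x = matrix.data.astype(float).copy()
    intermediates: dict[str, pd.DataFrame] = {}

    if reference_channel is not None:
        x = x.div(reference_channel.reindex(x.index), axis=0)
        intermediates["reference_scaled"] = x.copy()

    all_missing = x.columns[x.notna().sum(axis=0) == 0].tolist()
    if all_missing:
        x = x.drop(columns=all_missing)
    intermediates["dropped_cells"] = pd.DataFrame({"cell": all_missing})

    x = x.div(x.median(axis=0, skipna=True), axis=1)
    intermediates["column_normalized"] = x.copy()
    x = x.div(x.mean(axis=1, skipna=True), axis=0)
    intermediates["row_normalized"] = x.copy()
    x = np.log2(x)
    intermediates["log2_precursors"] = x.copy()

    prot = x.groupby(protein_map.reindex(x.index)).median()
    prot.index.name = "protein"
    return prot, intermediates


def missingness_filter(
    matrix: QuantMatrix, max_missing_fraction: float = 0.99
) -> QuantMatrix:
    """Drop cells, then features, with missing fraction >= the threshold.

    The threshold side is strict: a feature or cell is retained iff its missing
    fraction is strictly below ``max_missing_fraction``.
    """
    x = matrix.data
    cell_missing = x.isna().mean(axis=0)
    keep_cells = cell_missing.index[cell_missing < max_missing_fraction]
    x = x[keep_cells]
    feat_missing = x.isna().mean(axis=1)
    keep_feats = feat_missing.index[feat_missing < max_missing_fraction]
    out = matrix.subset_cells(keep_cells)
    out.data = out.data.loc[keep_feats]
    if out.tier is not None:
        out.tier = out.tier.reindex(keep_feats)
    return out


def completeness(
    matrix: QuantMatrix, tier_annotation: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Percent data completeness per cell and tier, plus per-feature rates.

    Returns (cells x tiers DataFrame of 100 * observed/total tier features,
    per-feature Series of 100 * cells observed / total cells).
    """
    tiers = tier_annotation if tier_annotation is not None else matrix.tier
    if tiers is None:
        tiers = pd.Series("all", index=matrix.data.index)
    tiers = tiers.reindex(matrix.data.index)
    observed = matrix.data.notna()
    per_tier = {}
    for tier, feats in observed.groupby(tiers).groups.items():
        sub = observed.loc[feats]
        per_tier[tier] = 100.0 * sub.sum(axis=0) / len(feats)
    cell_by_tier = pd.DataFrame(per_tier)
    feature_rates = 100.0 * observed.sum(axis=1) / observed.shape[1]
    return cell_by_tier, feature_rates


def intensity_distribution(
    psms: pd.DataFrame,
    n_bins: int = 30,
    platform_col: str = "platform",
    run_col: str = "run_id",
    intensity_col: str = "precursor_intensity",
) -> pd.DataFrame:
    """Binned identification counts contrasting acquisition platforms.

    Per run, the log10 intensity range is split into ``n_bins`` equal-width
    bins and identifications are counted per bin; the per-bin median and s.d.
    of those counts are then taken across the runs of each platform.  With a
    single run per platform the s.d. is 0 and ``single_run`` is flagged.
    """
    rows = []
    for platform, group in psms.groupby(platform_col):
        counts = []
        for _run, run_df in group.groupby(run_col):
            logint = np.log10(run_df[intensity_col].to_numpy(dtype=float))
            lo, hi = logint.min(), logint.max()
            edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.linspace(lo - 0.5, lo + 0.5, n_bins + 1)
            c, _ = np.histogram(logint, bins=edges)
            counts.append(c)
        arr = np.vstack(counts)
        med = np.median(arr, axis=0)
        sd = arr.std(axis=0, ddof=0) if len(counts) > 1 else np.zeros(n_bins)
        for b in range(n_bins):
            rows.append(
                {"platform": platform, "bin": b, "median_count": med[b],
                 "sd_count": sd[b], "n_runs": len(counts), "single_run": len(counts) == 1}
            )
    return pd.DataFrame(rows)
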