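"""Bespoke statistics for prioritized single-cell proteomics analyses.

Four procedures:

* **Intensity-binned null differential abundance.**  Replicate injections of
  the same sample define a null distribution of log2 precursor fold changes;
  because quantification noise shrinks with intensity, the null is stratified
  into equal-count bins over average precursor intensity (15 by default).
  Condition fold changes are z-scored through their intensity bin, and each
  protein's precursor z-scores are t-tested against a seeded draw of 10,000
  standard-normal values, with Benjamini-Hochberg correction across proteins.

* **Protein-set enrichment (PSEA) on PC loadings.**  Each eligible protein
  set's loading weights are compared to the background weights with a
  two-tailed Wilcoxon rank-sum test; per-set median loadings are reported as
  z-scores standardized across the tested sets.

* **Marker-panel permutation test.**  For a target peptide, the observed
  statistic is the difference of its median Pearson correlation with two
  marker panels; the null permutes the protein-column labels of the cells x
  proteins matrix.  Zero empirical p-values receive a q-value floor of 1e-5.

* **Spike-in accuracy regression.**  Reporter intensities normalized to the
  median 1x sample are regressed through the origin on relative spike level
  (both log2); a single-predictor through-origin least-squares fit, which
  coincides with the one-component through-origin projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NullFoldChangeModel",
    "fit_null_model",
    "differential_proteins",
    "psea",
    "marker_permutation_test",
    "select_markers",
    "SpikeInDesign",
    "spikein_regression",
    "bh_qvalues",
    "Q_FLOOR",
]

Q_FLOOR = 1e-5


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class NullFoldChangeModel:
    """Intensity-binned null distribution of log2 replicate fold changes."""

    upper_edges: np.ndarray  # ascending bin upper bounds on average intensity
    bin_mean: np.ndarray
    bin_sd: np.ndarray
    bin_count: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_mean)

    def bin_of(self, avg_intensity) -> np.ndarray:
        idx = np.searchsorted(self.upper_edges[:-1], np.asarray(avg_intensity, dtype=float), side="left")
        return np.clip(idx, 0, self.n_bins - 1)

    def zscore(self, log2fc, avg_intensity) -> np.ndarray:
        b = self.bin_of(avg_intensity)
        return (np.asarray(log2fc, dtype=float) - self.bin_mean[b]) / self.bin_sd[b]


def fit_null_model(
    replicate_a: pd.Series,
    replicate_b: pd.Series,
    n_bins: int = 15,
) -> NullFoldChangeModel:
    """Fit the intensity-binned null fold-change model from a replicate pair.

    ``replicate_a`` / ``replicate_b`` are precursor intensity vectors indexed
    by precursor id; only shared precursors are used.  log2(a/b) values are
    split into ``n_bins`` equal-count bins over the pair's average intensity,
    storing each bin's mean and s.d.  Identical replicates produce zero-s.d.
    bins and are rejected as degenerate.
    """
    shared = replicate_a.index.intersection(replicate_b.index)
    if len(shared) < n_bins:
        raise ValueError(f"need >= {n_bins} paired precursors, got {len(shared)}")
    a = replicate_a[shared].to_numpy(dtype=float)
    b = replicate_b[shared].to_numpy(dtype=float)
    log2fc = np.log2(a / b)
    avg = (a + b) / 2.0

    order = np.argsort(avg, kind="stable")
    groups = np.array_split(order, n_bins)
    means = np.array([log2fc[g].mean() for g in groups])
    sds = np.array([log2fc[g].std(ddof=1) for g in groups])
    counts = np.array([len(g) for g in groups])
    uppers = np.array([avg[g].max() for g in groups])
    if np.any(sds == 0):
        raise ValueError(
            "null model has zero-s.d. intensity bins (identical replicates?); "
            "add measurement noise or more paired precursors"
        )
    return NullFoldChangeModel(upper_edges=uppers, bin_mean=means, bin_sd=sds, bin_count=counts)


def differential_proteins(
    cond1: pd.Series,
    cond2: pd.Series,
    null: NullFoldChangeModel,
    protein_map: pd.Series,
    null_sample_n: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Protein-level differential abundance against the replicate-noise null.

    Per shared precursor: log2(cond1/cond2) z-scored through its intensity
    bin.  Per protein: a two-sample Welch t-test of the protein's precursor
    z-scores against one seeded draw of ``null_sample_n`` standard-normal
    values (pooled-variance test when a single precursor leaves the group
    variance undefined, flagged in ``single_precursor``).  BH correction
    across proteins.
    """
    shared = cond1.index.intersection(cond2.index)
    if len(shared) == 0:
        raise ValueError("conditions share no precursors")
    a = cond1[shared].to_numpy(dtype=float)
    b = cond2[shared].to_numpy(dtype=float)
    log2fc = np.log2(a / b)
    z = null.zscore(log2fc, (a + b) / 2.0)
    prot = protein_map.reindex(shared)

    rng = np.random.default_rng(seed)
    null_draw = rng.standard_normal(null_sample_n)

    rows = []
    zs = pd.Series(z, index=shared)
    fcs = pd.Series(log2fc, index=shared)
    for protein, idx in zs.groupby(prot).groups.items():
        zvals = zs[idx].to_numpy()
        single = len(zvals) == 1
        res = sps.ttest_ind(zvals, null_draw, equal_var=single)
        rows.append(
            {
                "protein": protein,
                "n_precursors": len(zvals),
                "log2fc": float(np.median(fcs[idx])),
                "mean_z": float(zvals.mean()),
                "p": float(res.pvalue),
                "single_precursor": single,
            }
        )
    out = pd.DataFrame(rows).set_index("protein")
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def psea(
    loadings: pd.Series,
    sets: dict[str, set[str] | list[str]],
    min_n: int = 5,
    min_fraction: float = 0.10,
    max_size: int = 200,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Protein-set enrichment on principal-component loading weights.

    A set is tested iff >= ``min_n`` of its members have loadings, those
    members are >= ``min_fraction`` of the set, and the set has fewer than
    ``max_size`` entries.  Member weights are compared to all non-member
    weights with a two-tailed Wilcoxon rank-sum test.  ``z_median`` is the
    per-set median loading standardized across all tested sets.  ``significant``
    flags q <= ``fdr``.
    """
    if not np.isfinite(loadings.to_numpy(dtype=float)).all():
        raise ValueError("loadings must be finite")
    ids = set(loadings.index)
    rows = []
    for name, members in sets.items():
        members = set(members)
        present = members & ids
        if len(members) >= max_size:
            continue
        if len(present) < min_n or len(present) / len(members) < min_fraction:
            continue
        inside = loadings[sorted(present)].to_numpy()
        outside = loadings[sorted(ids - present)].to_numpy()
        if len(outside) == 0:
            continue
        res = sps.mannwhitneyu(inside, outside, alternative="two-sided", method="auto")
        rows.append(
            {
                "set": name,
                "n_present": len(present),
                "set_size": len(members),
                "median_loading": float(np.median(inside)),
                "p": float(res.pvalue),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["n_present", "set_size", "median_loading", "z_median", "p", "q", "significant"]
        )
    out = pd.DataFrame(rows).set_index("set")
    med = out["median_loading"].to_numpy()
    sd = med.std(ddof=1) if len(med) > 1 else 0.0
    out["z_median"] = (med - med.mean()) / sd if sd > 0 else 0.0
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["significant"] = out["q"] <= fdr
    return out[["n_present", "set_size", "median_loading", "z_median", "p", "q", "significant"]]


def marker_permutation_test(
    matrix: pd.DataFrame,
    targets: list[str],
    panel_a: list[str],
    panel_b: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
    min_panel: int = 2,
) -> pd.DataFrame:
    """Permutation test of target association with two marker panels.

    ``matrix`` is cells x proteins (targets and panel members as columns).
    Observed statistic per target: median Pearson r with panel A minus median
    Pearson r with panel B.  The null permutes the protein-column labels
    ``n_perm`` times; p is the fraction of |null| >= |observed|.  BH across
    targets; a zero p-value receives the q floor of 1e-5.
    """
    pa, pb = set(panel_a), set(panel_b)
    if pa & pb:
        raise ValueError("panels must be disjoint")
    if set(targets) & (pa | pb):
        raise ValueError("targets must not belong to either panel")
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 cells for correlation analysis")

    cols = list(matrix.columns)
    corr = matrix.corr(method="pearson").to_numpy()
    pos = {c: i for i, c in enumerate(cols)}

    a_q = [c for c in panel_a if c in pos and matrix[c].notna().sum() >= 3]
    b_q = [c for c in panel_b if c in pos and matrix[c].notna().sum() >= 3]

    rows = []
    rng = np.random.default_rng(seed)
    skipped = []
    testable = []
    for t in targets:
        if t not in pos:
            skipped.append((t, "target not in matrix"))
        elif len(a_q) < min_panel or len(b_q) < min_panel:
            skipped.append((t, "panel with <2 quantified members"))
        else:
            testable.append(t)

    if testable:
        ia = np.array([pos[c] for c in a_q])
        ib = np.array([pos[c] for c in b_q])
        it = np.array([pos[t] for t in testable])
        observed = np.array(
            [np.median(corr[i, ia]) - np.median(corr[i, ib]) for i in it]
        )
        n = len(cols)
        exceed = np.zeros(len(testable))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            null_stat = np.median(corr[np.ix_(perm[it], perm[ia])], axis=1) - np.median(
                corr[np.ix_(perm[it], perm[ib])], axis=1
            )
            exceed += np.abs(null_stat) >= np.abs(observed)
        pvals = exceed / n_perm
        qvals = bh_qvalues(pvals)
        qvals = np.where(pvals == 0, np.maximum(qvals, Q_FLOOR), qvals)
        for t, obs, p, q in zip(testable, observed, pvals, qvals):
            rows.append({"target": t, "statistic": float(obs), "p": float(p), "q": float(q), "reason": ""})
    for t, reason in skipped:
        rows.append({"target": t, "statistic": np.nan, "p": np.nan, "q": np.nan, "reason": reason})
    return pd.DataFrame(rows).set_index("target")


def select_markers(
    result: pd.DataFrame, q_max: float = 0.01, min_abs_log2fc: float = 1.0
) -> pd.Index:
    """Marker-panel gate over differential results: q and effect-size caps.

    A protein enters a marker panel only when both statistically significant
    (q <= ``q_max``) and of sufficient magnitude (|log2 fold change| >=
    ``min_abs_log2fc``).
    """
    keep = (result["q"] <= q_max) & (result["log2fc"].abs() >= min_abs_log2fc)
    return result.index[keep]


@dataclass
class SpikeInDesign:
    """Spike level (1x..16x) per experiment and channel.

    ``levels``: DataFrame with columns (experiment, channel, level); the 1x
    channels anchor normalization, so each experiment must contain at least
    one.
    """

    levels: pd.DataFrame
    expected_levels: tuple = (1, 2, 4, 8, 16)

    def __post_init__(self) -> None:
        if (self.levels["level"] <= 0).any():
            raise ValueError("spike levels must be positive")

    @property
    def fold_range(self) -> float:
        lv = self.levels["level"]
        return float(lv.max() / lv.min())

    @property
    def n_levels(self) -> int:
        return int(self.levels["level"].nunique())


def spikein_regression(
    psms: pd.DataFrame,
    design: SpikeInDesign,
) -> dict:
    """Accuracy regression of normalized reporter intensity on spike level.

    ``psms`` is long-format: columns (experiment, sequence, charge, channel,
    intensity), restricted to spike-in sequences.  Per experiment and
    precursor, intensities are divided by the median intensity of that
    precursor's 1x channels; charge states are collapsed per sequence by the
    median; log2(normalized intensity) is regressed on log2(relative level)
    through the origin.

    Returns dict with slope, r_squared (uncentered, as appropriate through the
    origin), per-level summaries, n_points and excluded experiments.
    """
    lv = design.levels.set_index(["experiment", "channel"])["level"]
    df = psms.copy()
    df["level"] = [
        lv.get((e, c), np.nan) for e, c in zip(df["experiment"], df["channel"])
    ]
    df = df.dropna(subset=["level", "intensity"])

    excluded = []
    norm_parts = []
    for (exp, seq, charge), grp in df.groupby(["experiment", "sequence", "charge"]):
        anchors = grp.loc[grp["level"] == 1, "intensity"]
        if len(anchors) == 0:
            excluded.append((exp, seq, charge, "no 1x anchor"))
            continue
        g = grp.copy()
        g["norm"] = g["intensity"] / anchors.median()
        norm_parts.append(g)
    if not norm_parts:
        raise ValueError("no precursor had 1x anchor samples")
    normed = pd.concat(norm_parts)

    # Collapse charge states: median normalized intensity per sequence/channel.
    collapsed = (
        normed.groupby(["experiment", "sequence", "channel", "level"])["norm"]
        .median()
        .reset_index()
    )
    y = np.log2(collapsed["norm"].to_numpy(dtype=float))
    x = np.log2(collapsed["level"].to_numpy(dtype=float))
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y) / sxx) if sxx > 0 else 0.0
    resid = y - slope * x
    ss_tot = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum(resid * resid)) / ss_tot if ss_tot > 0 else 1.0

    per_level = (
        collapsed.groupby("level")["norm"]
        .agg(median="median", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return {
        "slope": slope,
        "r_squared": r2,
        "per_level": per_level,
        "n_points": int(len(collapsed)),
        "excluded": excluded,
    }
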