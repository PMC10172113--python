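"""Tiered inclusion-list construction from PSM (evidence-style) tables.

The workflow mirrors how directed single-cell acquisitions are planned from
prior shotgun/DIA searches: PSMs are filtered on spectral purity (PIF), on the
ratio of single-cell to carrier reporter signal, and at a decoy-based FDR
computed as the largest posterior-error-probability (PEP) cutoff at which the
decoy fraction stays at or below the target.  Charge states of the same
modified sequence are condensed to the most confident one, and the surviving
precursors are partitioned into disjoint priority tiers by declarative rule
sets.  High-priority precursors may receive intensity-dependent MS2 fill
times: 1000/750/500 ms for the bottom/middle/top intensity tertile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .acquisition import InclusionEntry, RT_ONLY_TIER

__all__ = [
    "REQUIRED_PSM_COLUMNS",
    "read_psm_table",
    "write_psm_table",
    "compute_fdr_threshold",
    "filter_psms",
    "dedupe_charge_states",
    "TierSpec",
    "InclusionList",
    "build_tiers",
    "assign_fill_times",
    "tertile_bins",
]

REQUIRED_PSM_COLUMNS = [
    "sequence",
    "modified_sequence",
    "charge",
    "mz",
    "rt",
    "pep",
    "pif",
    "precursor_intensity",
    "leading_protein",
    "decoy",
    "contaminant",
    "run_id",
]

REPORTER_PREFIX = "reporter_"


def read_psm_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a PSM table from TSV, optionally renaming arbitrary headers.

    ``column_map`` maps file headers to the canonical column names in
    :data:`REQUIRED_PSM_COLUMNS`; reporter-ion columns use the
    ``reporter_<channel>`` convention.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing required columns: {missing}")
    df["decoy"] = df["decoy"].astype(bool)
    df["contaminant"] = df["contaminant"].astype(bool)
    return df


def write_psm_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def reporter_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(REPORTER_PREFIX)]


def compute_fdr_threshold(
    peps: np.ndarray | pd.Series,
    decoy_flags: np.ndarray | pd.Series,
    target_fdr: float = 0.01,
) -> tuple[float, np.ndarray]:
    """Largest PEP cutoff with decoy fraction <= ``target_fdr``.

    The decoy fraction at a cutoff is (decoys at pep <= cutoff) / (entries at
    pep <= cutoff).  Returns (cutoff, retained boolean index); the retained set
    excludes the decoys themselves.  If no candidate cutoff achieves the
    target, the retained set is empty and the cutoff is NaN.
    """
    peps = np.asarray(peps, dtype=float)
    decoy = np.asarray(decoy_flags, dtype=bool)
    if peps.shape != decoy.shape:
        raise ValueError("peps and decoy_flags must have equal length")
    if not (0 < target_fdr < 1):
        raise ValueError("target_fdr must be in (0, 1)")
    if len(peps) == 0:
        return float("nan"), np.zeros(0, dtype=bool)
    order = np.argsort(peps, kind="stable")
    sorted_pep = peps[order]
    cum_decoy = np.cumsum(decoy[order])
    n_at = np.arange(1, len(peps) + 1)
    # Evaluate each distinct PEP value at its last occurrence (all ties included).
    last_of_value = np.r_[sorted_pep[1:] != sorted_pep[:-1], True]
    frac = cum_decoy / n_at
    ok = last_of_value & (frac <= target_fdr)
    if not ok.any():
        return float("nan"), np.zeros(len(peps), dtype=bool)
    cutoff = float(sorted_pep[np.nonzero(ok)[0][-1]])
    retained = (peps <= cutoff) & ~decoy
    return cutoff, retained


def filter_psms(
    table: pd.DataFrame,
    pif_min: float = 0.5,
    carrier_ratio_max: float = 0.10,
    fdr: float = 0.01,
    carrier_channel: str | None = None,
    single_cell_channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Quality filters applied when assembling inclusion-list candidates.

    Drops PSMs with PIF below ``pif_min``; drops PSMs whose mean single-cell
    reporter intensity exceeds ``carrier_ratio_max`` of the carrier-channel
    intensity; applies the decoy-PEP FDR threshold; removes decoys and
    contaminants.
    """
    df = table
    df = df[df["pif"] >= pif_min]
    if carrier_ratio_max is not None:
        if carrier_channel is None:
            raise ValueError("carrier_channel must be named to apply the carrier-ratio filter")
        ccol = REPORTER_PREFIX + carrier_channel
        if ccol not in df.columns:
            raise ValueError(f"carrier channel column {ccol!r} not present in table")
        if single_cell_channels is None:
            sc_cols = [c for c in reporter_columns(df) if c != ccol]
        else:
            sc_cols = [REPORTER_PREFIX + ch for ch in single_cell_channels]
        ratio = df[sc_cols].mean(axis=1) / df[ccol]
        df = df[ratio <= carrier_ratio_max]
    _, retained = compute_fdr_threshold(df["pep"].to_numpy(), df["decoy"].to_numpy(), fdr)
    df = df[retained]
    return df[~df["contaminant"]].copy()


def dedupe_charge_states(table: pd.DataFrame) -> pd.DataFrame:
    """One row per modified sequence: minimum PEP, ties to higher intensity."""
    df = table.sort_values(
        ["modified_sequence", "pep", "precursor_intensity"],
        ascending=[True, True, False],
        kind="stable",
    )
    return df.drop_duplicates("modified_sequence", keep="first").reset_index(drop=True)


@dataclass
class TierSpec:
    """Declarative description of one priority tier.

    ``rules`` is an ordered mapping evaluated in insertion order on the pool of
    not-yet-assigned precursors.  Supported rules: ``pep_max``, ``pif_min``,
    ``top_k_per_protein`` (by PEP ascending), ``run_fraction_max`` /
    ``run_fraction_min`` (fraction of runs in which the peptide was
    identified), ``sample_k`` (seeded sampling without replacement),
    ``size_cap`` (truncate by PEP ascending).
    """

    name: str
    priority: int
    rules: dict = field(default_factory=dict)
    fill_policy: str = "fixed"  # "fixed" | "tertile"


@dataclass
class InclusionList:
    """Tiered inclusion entries with provenance header."""

    entries: pd.DataFrame  # id, mz, charge, apex_rt_min, priority, ms2_enabled, max_fill_ms, tier
    header: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    COLUMNS = ["id", "mz", "charge", "apex_rt_min", "priority", "ms2_enabled", "max_fill_ms", "tier"]

    def to_entries(self) -> list[InclusionEntry]:
        return [
            InclusionEntry(
                id=row.id,
                mz=row.mz,
                apex_rt_predicted=row.apex_rt_min,
                priority=int(row.priority),
                ms2_enabled=bool(row.ms2_enabled),
                max_fill_ms=float(row.max_fill_ms),
            )
            for row in self.entries.itertuples()
        ]

    def to_tsv(self, path) -> None:
        df = self.entries.copy()
        df["ms2_enabled"] = df["ms2_enabled"].astype(int)
        with open(path, "w") as fh:
            for k, v in self.header.items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "InclusionList":
        header: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                header[k.strip()] = v
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        df["ms2_enabled"] = df["ms2_enabled"].astype(bool)
        return cls(entries=df, header=header)

    def tier_sizes(self) -> pd.Series:
        return self.entries.groupby("tier").size()


def _precursor_id(df: pd.DataFrame) -> pd.Series:
    return df["modified_sequence"].astype(str) + "/" + df["charge"].astype(str)


def identified_run_fraction(raw_table: pd.DataFrame) -> pd.Series:
    """Fraction of runs in which each modified sequence was identified.

    Counts runs with >= 1 PSM for the sequence over all distinct runs in the
    table (the table should already be FDR-filtered).
    """
    n_runs = raw_table["run_id"].nunique()
    per_seq = raw_table.groupby("modified_sequence")["run_id"].nunique()
    return per_seq / n_runs


def build_tiers(
    table: pd.DataFrame,
    specs: list[TierSpec],
    seed: int = 0,
    run_fraction: pd.Series | None = None,
    calibration_from_remainder: bool = True,
) -> InclusionList:
    """Partition filtered, deduplicated precursors into disjoint priority tiers.

    Specs are evaluated highest-priority-first; each draws only from precursors
    not yet assigned.  Precursors left over after all specs become
    RT-calibration-only entries (MS2 disabled) when
    ``calibration_from_remainder`` is set.  Sampling rules use a single
    integer seed recorded in the list header.
    """
    if len({s.priority for s in specs}) != len(specs):
        raise ValueError("tier priorities must be unique")
    df = table.reset_index(drop=True).copy()
    df["entry_id"] = _precursor_id(df)
    if run_fraction is not None:
        df["run_fraction_"] = df["modified_sequence"].map(run_fraction)
    rng = np.random.default_rng(seed)

    assigned: dict[str, tuple[str, int, bool, float]] = {}
    warn_records: list[str] = []
    available = df

    for spec in specs:
        pool = available[~available["entry_id"].isin(assigned)].copy()
        for rule, value in spec.rules.items():
            if rule == "pep_max":
                pool = pool[pool["pep"] <= value]
            elif rule == "pif_min":
                pool = pool[pool["pif"] >= value]
            elif rule == "top_k_per_protein":
                pool = (
                    pool.sort_values(["leading_protein", "pep"], kind="stable")
                    .groupby("leading_protein", group_keys=False)
                    .head(int(value))
                )
            elif rule == "run_fraction_max":
                pool = pool[pool["run_fraction_"] <= value]
            elif rule == "run_fraction_min":
                pool = pool[pool["run_fraction_"] >= value]
            elif rule == "sample_k":
                k = int(value)
                if k < len(pool):
                    idx = rng.choice(len(pool), size=k, replace=False)
                    pool = pool.iloc[np.sort(idx)]
                else:
                    warn_records.append(
                        f"tier {spec.name!r}: sample_k={k} exceeds pool size {len(pool)}; kept all"
                    )
            elif rule == "size_cap":
                k = int(value)
                if len(pool) < k:
                    warn_records.append(
                        f"tier {spec.name!r}: size_cap={k} unreachable, emitting {len(pool)} entries"
                    )
                pool = pool.sort_values(["pep", "entry_id"], kind="stable").head(k)
            else:
                raise ValueError(f"unknown tier rule {rule!r}")
        for row in pool.itertuples():
            assigned[row.entry_id] = (spec.name, spec.priority, True, 500.0)

    entries = []
    for row in df.itertuples():
        if row.entry_id in assigned:
            tier, pri, enabled, fill = assigned[row.entry_id]
        elif calibration_from_remainder:
            tier, pri, enabled, fill = RT_ONLY_TIER, 0, False, 500.0
        else:
            continue
        entries.append(
            {
                "id": row.entry_id,
                "mz": row.mz,
                "charge": row.charge,
                "apex_rt_min": row.rt,
                "priority": pri,
                "ms2_enabled": enabled,
                "max_fill_ms": fill,
                "tier": tier,
            }
        )
    edf = pd.DataFrame(entries, columns=InclusionList.COLUMNS)
    # Order: priority desc, RT-only last.
    edf = edf.sort_values(["ms2_enabled", "priority"], ascending=[False, False], kind="stable").reset_index(drop=True)
    ilist = InclusionList(entries=edf, header={"seed": seed}, warnings=warn_records)
    for w in warn_records:
        warnings.warn(w, stacklevel=2)
    return ilist


def tertile_bins(values: np.ndarray | pd.Series) -> tuple[float, float]:
    """Tertile boundary values of an intensity pool.

    Boundaries are the largest values of the bottom and middle rank-thirds;
    membership uses ``x <= boundary`` so boundary ties fall into the
    lower-intensity bin.  On distinct values the three bins differ in size by
    at most one.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) < 3:
        raise ValueError("tertile policy requires at least 3 intensity values")
    parts = np.array_split(v, 3)
    return float(parts[0][-1]), float(parts[1][-1])


def assign_fill_times(
    ilist: InclusionList,
    intensities: pd.Series,
    policy: str = "tertile",
    pool_intensities: np.ndarray | pd.Series | None = None,
    high_priority: int | None = None,
    fill_ms: tuple[float, float, float] = (1000.0, 750.0, 500.0),
    default_fill_ms: float = 500.0,
) -> InclusionList:
    """Set per-entry MS2 fill times; intensity-aware for the top tier.

    Under the ``tertile`` policy, tertile boundaries are computed across the
    full candidate intensity pool (``pool_intensities``; defaults to
    ``intensities``).  High-priority entries in the bottom/middle/top tertile
    receive 1000/750/500 ms; all other entries receive the fixed default
    (500 ms).  Entries without an intensity fall back to the default with a
    warning.
    """
    df = ilist.entries.copy()
    warns = list(ilist.warnings)
    if policy == "fixed":
        df["max_fill_ms"] = default_fill_ms
        return InclusionList(df, dict(ilist.header), warns)
    if policy != "tertile":
        raise ValueError(f"unknown fill policy {policy!r}")
    pool = intensities if pool_intensities is None else pool_intensities
    b1, b2 = tertile_bins(pool)
    if high_priority is None:
        high_priority = int(df.loc[df["ms2_enabled"], "priority"].max())
    fills = np.full(len(df), default_fill_ms)
    for i, row in enumerate(df.itertuples()):
        if not row.ms2_enabled or row.priority != high_priority:
            continue
        inten = intensities.get(row.id)
        if inten is None or (isinstance(inten, float) and np.isnan(inten)):
            warns.append(f"entry {row.id!r}: missing intensity, default fill applied")
            continue
        if inten <= b1:
            fills[i] = fill_ms[0]
        elif inten <= b2:
            fills[i] = fill_ms[1]
        else:
            fills[i] = fill_ms[2]
    df["max_fill_ms"] = fills
    for w in warns[len(ilist.warnings):]:
        warnings.warn(w, stacklevel=2)
    return InclusionList(df, dict(ilist.header), warns)
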