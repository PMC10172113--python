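"""Synthetic data generation for every input the toolkit consumes.

All generators are deterministic functions of a single integer seed: the seed
spawns a hierarchy of independent substreams, so any downstream result can be
reproduced from one number.  Each generator also returns a ground-truth table
joining the simulated observations to the quantities that produced them.

The generators emulate the statistical structure of prioritized single-cell
LC-MS experiments: log-normally distributed precursor intensities, Gaussian
elution profiles with per-run retention-time drift, decoy PSMs with inflated
posterior error probabilities, carrier/reference reporter channels scaled
roughly 200x and 5x above single cells, protein-module covariation across
cells, and negative-control samples carrying uncorrelated noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import SimPeptide, InclusionEntry

__all__ = [
    "FixtureSpec",
    "make_lcms_population",
    "make_psm_table",
    "make_singlecell_matrix",
    "make_replicate_pair",
    "make_spikein_dataset",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    # LC-MS population
    n_peptides: int = 1000
    gradient_min: float = 60.0
    intensity_log_mean: float = np.log(1e5)
    intensity_log_sd: float = 1.5
    elution_sigma_range: tuple[float, float] = (0.08, 0.25)  # minutes
    drift_model: str = "constant"  # "constant" | "linear"
    drift_magnitude: float = 0.5  # min (constant) or min per min (linear)
    drift_jitter_sd: float = 0.0
    mz_range: tuple[float, float] = (450.0, 1600.0)
    # PSM table
    n_psms: int = 2000
    decoy_fraction: float = 0.1
    contaminant_fraction: float = 0.02
    n_runs: int = 6
    n_proteins: int = 200
    carrier_scale: float = 200.0
    reference_scale: float = 5.0
    n_single_cells_per_run: int = 12
    # single-cell matrix
    n_cells_per_condition: int = 100
    n_controls: int = 20
    module_size: int = 10
    n_modules: int = 8
    within_module_corr: float = 0.6
    peptides_per_protein: int = 4
    condition_effects: dict = field(default_factory=dict)  # protein -> log2 effect
    cell_noise_sd: float = 0.10  # log-scale residual noise in real cells
    control_noise_sd: float = 0.80  # log-scale noise in negative controls
    missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_peptides", "n_psms", "n_cells_per_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 <= self.within_module_corr <= 1.0:
            raise ValueError("within_module_corr must lie in [-1, 1]")

    def rngs(self, n: int, salt: int = 0) -> list[np.random.Generator]:
        children = np.random.SeedSequence(entropy=self.seed, spawn_key=(salt,)).spawn(n)
        return [np.random.default_rng(c) for c in children]


def make_lcms_population(
    spec: FixtureSpec,
) -> tuple[list[SimPeptide], list[InclusionEntry], pd.DataFrame]:
    """Ground-truth eluting peptide population plus matching inclusion candidates.

    Apex times are uniform over the gradient, intensities log-normal, elution
    sigmas uniform in the configured range.  The drift model is either a
    constant per-run offset or linear in apex time, with optional Gaussian
    jitter.  Inclusion candidates predict the undrifted apex.
    """
    (rng,) = spec.rngs(1, salt=1)
    n = spec.n_peptides
    apex = rng.uniform(0.05 * spec.gradient_min, 0.95 * spec.gradient_min, n)
    sigma = rng.uniform(*spec.elution_sigma_range, n)
    inten = rng.lognormal(spec.intensity_log_mean, spec.intensity_log_sd, n)
    mz = rng.uniform(*spec.mz_range, n)
    charge = rng.integers(2, 4, n)
    if spec.drift_model == "constant":
        drift = np.full(n, spec.drift_magnitude)
    elif spec.drift_model == "linear":
        drift = spec.drift_magnitude * apex
    else:
        raise ValueError(f"unknown drift model {spec.drift_model!r}")
    if spec.drift_jitter_sd > 0:
        drift = drift + rng.normal(0, spec.drift_jitter_sd, n)

    peptides = []
    entries = []
    for i in range(n):
        pid = f"pep{i:05d}"
        peptides.append(
            SimPeptide(pid, float(mz[i]), int(charge[i]), float(apex[i]), float(sigma[i]),
                       float(inten[i]), float(drift[i]))
        )
        entries.append(InclusionEntry(pid, float(mz[i]), float(apex[i])))
    truth = pd.DataFrame(
        {
            "id": [p.id for p in peptides],
            "mz": mz,
            "charge": charge,
            "apex_rt": apex,
            "peak_sigma": sigma,
            "max_intensity": inten,
            "rt_drift": drift,
        }
    ).set_index("id")
    return peptides, entries, truth


def make_psm_table(spec: FixtureSpec) -> pd.DataFrame:
    """Evidence-style PSM table with decoys, PEP/PIF and reporter channels.

    Decoy PEPs are drawn stochastically larger than target PEPs so the 1%
    decoy-fraction threshold is informative.  Reporter channels comprise one
    carrier (~``carrier_scale`` over a mean cell), one reference
    (~``reference_scale``) and the single-cell channels.
    """
    (rng,) = spec.rngs(1, salt=2)
    n = spec.n_psms
    # Exact decoy count by construction (shuffled), not a Bernoulli draw.
    n_decoy = int(round(n * spec.decoy_fraction))
    decoy = np.zeros(n, dtype=bool)
    decoy[rng.permutation(n)[:n_decoy]] = True
    contaminant = (~decoy) & (rng.random(n) < spec.contaminant_fraction)
    # Targets: PEP concentrated near 0; decoys: PEP pushed toward 1.
    pep = np.where(decoy, rng.beta(4.0, 1.5, n), rng.beta(0.35, 6.0, n))
    pif = np.clip(rng.beta(6.0, 1.5, n), 0.0, 1.0)
    inten = rng.lognormal(spec.intensity_log_mean, spec.intensity_log_sd, n)
    rt = rng.uniform(0.05 * spec.gradient_min, 0.95 * spec.gradient_min, n)
    mz = rng.uniform(*spec.mz_range, n)
    charge = rng.integers(2, 4, n)
    protein = np.array([f"P{rng.integers(0, spec.n_proteins):04d}" for _ in range(n)])
    run = np.array([f"run{rng.integers(0, spec.n_runs)}" for _ in range(n)])
    seq_pool = n // 2  # force some charge-state duplicates
    seq_idx = rng.integers(0, seq_pool, n)
    seqs = np.array([f"PEPTIDESEQ{j:05d}" for j in seq_idx])

    df = pd.DataFrame(
        {
            "sequence": seqs,
            "modified_sequence": seqs,
            "charge": charge,
            "mz": mz,
            "rt": rt,
            "pep": pep,
            "pif": pif,
            "precursor_intensity": inten,
            "leading_protein": protein,
            "decoy": decoy,
            "contaminant": contaminant,
            "run_id": run,
        }
    )
    base = inten / 50.0
    df["reporter_carrier"] = base * spec.carrier_scale * rng.lognormal(0, 0.1, n)
    df["reporter_reference"] = base * spec.reference_scale * rng.lognormal(0, 0.1, n)
    for c in range(spec.n_single_cells_per_run):
        df[f"reporter_sc{c:02d}"] = base * rng.lognormal(0, 0.25, n)
    return df


def make_singlecell_matrix(spec: FixtureSpec):
    """Cells x peptides reporter matrix with planted structure, plus truth.

    Proteins are grouped into modules whose underlying cell scores covary at
    ``within_module_corr``; each protein contributes ``peptides_per_protein``
    peptides whose abundances track the protein with log-normal measurement
    noise (sd ``cell_noise_sd`` on the natural-log scale).  Condition effects
    are additive log2 shifts for selected proteins.  Negative-control columns
    carry independent noise at ``control_noise_sd``.  Missingness is applied
    uniformly at random.

    Returns (QuantMatrix, protein_map Series, truth dict).
    """
    from .quant import QuantMatrix

    (rng,) = spec.rngs(1, salt=3)
    n_prot = spec.n_modules * spec.module_size
    proteins = [f"P{i:04d}" for i in range(n_prot)]
    module_of = {p: i // spec.module_size for i, p in enumerate(proteins)}
    n_cells = 2 * spec.n_cells_per_condition
    conditions = ["A"] * spec.n_cells_per_condition + ["B"] * spec.n_cells_per_condition

    # Protein log2 levels: module factor shared within a module.
    r = np.sqrt(spec.within_module_corr) if spec.within_module_corr > 0 else 0.0
    module_scores = rng.normal(0, 1, (n_cells, spec.n_modules))
    prot_log2 = np.empty((n_cells, n_prot))
    for j, p in enumerate(proteins):
        shared = module_scores[:, module_of[p]]
        own = rng.normal(0, 1, n_cells)
        prot_log2[:, j] = r * shared + np.sqrt(max(0.0, 1 - r**2)) * own
    for j, p in enumerate(proteins):
        eff = spec.condition_effects.get(p, 0.0)
        if eff:
            prot_log2[np.array(conditions) == "B", j] += eff

    peptides = []
    protein_of_peptide = []
    cols = {}
    cell_ids = [f"cell{i:03d}" for i in range(n_cells)]
    for j, p in enumerate(proteins):
        for k in range(spec.peptides_per_protein):
            pid = f"{p}_pep{k}"
            peptides.append(pid)
            protein_of_peptide.append(p)
            noise = rng.normal(0, spec.cell_noise_sd, n_cells)
            cols[pid] = np.exp(prot_log2[:, j] * np.log(2) + noise)
    data = pd.DataFrame(cols, index=cell_ids).T  # peptides x cells

    control_ids = [f"ctrl{i:03d}" for i in range(spec.n_controls)]
    ctrl = np.exp(rng.normal(0, spec.control_noise_sd, (len(peptides), spec.n_controls)))
    ctrl_df = pd.DataFrame(ctrl, index=peptides, columns=control_ids)
    data = pd.concat([data, ctrl_df], axis=1)

    if spec.missing_fraction > 0:
        mask = rng.random(data.shape) < spec.missing_fraction
        data = data.mask(mask)

    cell_meta = pd.DataFrame(
        {
            "condition": conditions + ["control"] * spec.n_controls,
            "control": [False] * n_cells + [True] * spec.n_controls,
            "run_id": ["run0"] * (n_cells + spec.n_controls),
        },
        index=cell_ids + control_ids,
    )
    protein_map = pd.Series(protein_of_peptide, index=peptides, name="protein")
    truth = {
        "module_of": module_of,
        "protein_log2": pd.DataFrame(prot_log2, index=cell_ids, columns=proteins),
        "condition_effects": dict(spec.condition_effects),
    }
    return QuantMatrix(data, cell_meta), protein_map, truth


def make_replicate_pair(
    spec: FixtureSpec,
    n_precursors: int = 1500,
    noise_sd_log2: float = 0.3,
    intensity_dependent: bool = True,
    salt: int = 4,
) -> tuple[pd.Series, pd.Series]:
    """Paired replicate-injection intensities for null fold-change modelling.

    Multiplicative log-normal noise; when ``intensity_dependent`` the log2
    noise s.d. shrinks from ~2x ``noise_sd_log2`` at the lowest intensities to
    ~0.5x at the highest, mimicking more precise quantification of abundant
    precursors.
    """
    (rng,) = spec.rngs(1, salt=salt)
    base = rng.lognormal(spec.intensity_log_mean, spec.intensity_log_sd, n_precursors)
    if intensity_dependent:
        rank = np.argsort(np.argsort(base)) / (n_precursors - 1)
        sd = noise_sd_log2 * (2.0 - 1.5 * rank)
    else:
        sd = np.full(n_precursors, noise_sd_log2)
    ids = pd.Index([f"prec{i:05d}" for i in range(n_precursors)])
    a = base * np.exp2(rng.normal(0, sd))
    b = base * np.exp2(rng.normal(0, sd))
    return pd.Series(a, index=ids), pd.Series(b, index=ids)


def make_spikein_dataset(
    spec: FixtureSpec,
    n_experiments: int = 8,
    sequences: tuple[str, ...] = ("AAAAK", "BBBBK", "CCCCK", "DDDDK"),
    levels: tuple[int, ...] = (1, 1, 2, 2, 4, 4, 8, 8, 16, 16),
    noise_sd_log: float = 0.0,
    salt: int = 5,
):
    """Long-format spike-in reporter table plus its design.

    Channel c of each experiment carries spike level ``levels[c]``; intensities
    are proportional to level with optional multiplicative log-normal noise.
    Returns (psms DataFrame, SpikeInDesign).
    """
    from .stats import SpikeInDesign

    (rng,) = spec.rngs(1, salt=salt)
    rows = []
    design_rows = []
    for e in range(n_experiments):
        exp = f"exp{e}"
        for c, level in enumerate(levels):
            ch = f"ch{c:02d}"
            design_rows.append({"experiment": exp, "channel": ch, "level": level})
            for seq in sequences:
                for charge in (2, 3):
                    base = rng.lognormal(np.log(1000.0), 0.0) if noise_sd_log == 0 else 1000.0
                    noise = np.exp(rng.normal(0, noise_sd_log)) if noise_sd_log > 0 else 1.0
                    rows.append(
                        {
                            "experiment": exp,
                            "sequence": seq,
                            "charge": charge,
                            "channel": ch,
                            "intensity": base * level * noise,
                        }
                    )
    return pd.DataFrame(rows), SpikeInDesign(pd.DataFrame(design_rows))
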