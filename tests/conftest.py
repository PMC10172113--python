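import numpy as np
import pandas as pd
import pytest

from priosc.acquisition import AcquisitionConfig, InclusionEntry, SimPeptide
from priosc.fixtures import FixtureSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture
def basic_config():
    return AcquisitionConfig(
        cycle_time_s=3.0,
        survey_cost_s=0.5,
        ms2_overhead_s=0.05,
        default_fill_ms=300.0,
        rt_tolerance_min=1.0,
        noise_floor=1.0,
        topn_n=5,
        dyn_exclusion_s=30.0,
        id_threshold_ions=1.0,
        gradient_min=10.0,
    )


def make_entry(eid="e0", mz=500.0, apex=5.0, priority=0, ms2=True, fill=500.0):
    return InclusionEntry(eid, mz, apex, priority, ms2, fill)


def make_peptide(pid="e0", mz=500.0, apex=5.0, sigma=0.2, intensity=1e4, drift=0.0):
    return SimPeptide(pid, mz, 2, apex, sigma, intensity, drift)


@pytest.fixture
def small_psm_table(rng):
    """Hand-sized PSM table with controllable PEP/PIF/decoy layout."""
    n = 40
    return pd.DataFrame(
        {
            "sequence": [f"SEQ{i // 2}" for i in range(n)],
            "modified_sequence": [f"SEQ{i // 2}" for i in range(n)],
            "charge": [2 + i % 2 for i in range(n)],
            "mz": rng.uniform(450, 1600, n),
            "rt": rng.uniform(5, 55, n),
            "pep": rng.uniform(0, 0.2, n),
            "pif": rng.uniform(0.3, 1.0, n),
            "precursor_intensity": rng.lognormal(11, 1, n),
            "leading_protein": [f"P{i % 5}" for i in range(n)],
            "decoy": [False] * n,
            "contaminant": [False] * n,
            "run_id": [f"run{i % 4}" for i in range(n)],
            "reporter_carrier": rng.lognormal(13, 0.2, n),
            "reporter_sc00": rng.lognormal(7, 0.3, n),
            "reporter_sc01": rng.lognormal(7, 0.3, n),
        }
    )


def bh_stepup_oracle(p):
    """Hand-coded Benjamini-Hochberg step-up adjustment (reference)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def exact_ranksum_p(inside, outside):
    """Two-tailed rank-sum p by exhaustive enumeration (no ties)."""
    import itertools
    from scipy import stats as sps
    pooled = np.concatenate([inside, outside])
    n = len(inside)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    total = extreme = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(comb)].sum()
        total += 1
        extreme += abs(s - mu) >= abs(obs - mu) - 1e-12
    return extreme / total
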