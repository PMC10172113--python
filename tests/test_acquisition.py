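"""Duty-cycle simulator: detection, alignment, selection, full-run behaviour."""

import math

import numpy as np
import pytest

from priosc.acquisition import (
    AcquisitionConfig,
    InclusionEntry,
    SimPeptide,
    align_rt,
    detect_survey,
    percent_gain,
    run_metrics,
    select_cycle,
    simulate_run,
)

from conftest import make_entry, make_peptide


class TestDetectSurvey:
    def test_outside_rt_tolerance_not_detected(self, basic_config):
        pep = make_peptide(apex=5.0, sigma=1.0, intensity=1e6)
        entry = make_entry(apex=5.0)
        t = 5.0 + 3 * basic_config.rt_tolerance_min
        detected, _ = detect_survey({"e0": pep}, [entry], t, 0.0, basic_config)
        assert detected == []

    def test_below_noise_floor_not_detected(self, basic_config):
        pep = make_peptide(apex=5.0, sigma=0.1, intensity=10.0)
        entry = make_entry(apex=5.0)
        # at 0.9 min from apex the Gaussian is ~e^-40 of max, far below floor 1
        detected, _ = detect_survey({"e0": pep}, [entry], 5.9, 0.0, basic_config)
        assert detected == []

    def test_gaussian_threshold_crossing_window(self, basic_config):
        """With floor set to the intensity at apex +/- 0.4 min, detection holds
        exactly for |t - apex| <= 0.4 (closed-form Gaussian crossing)."""
        sigma, apex, imax = 0.2, 5.0, 1e4
        floor = imax * math.exp(-(0.4**2) / (2 * sigma**2))
        cfg = AcquisitionConfig(
            rt_tolerance_min=1.0, noise_floor=floor, gradient_min=10.0
        )
        pep = make_peptide(apex=apex, sigma=sigma, intensity=imax)
        entry = make_entry(apex=apex)
        for dt in np.arange(-0.875, 0.88, 0.05):  # grid avoids the exact boundary
            detected, _ = detect_survey({"e0": pep}, [entry], apex + dt, 0.0, cfg)
            assert bool(detected) == (abs(dt) <= 0.4), f"dt={dt}"

    def test_detected_intensity_is_gaussian_value(self, basic_config):
        pep = make_peptide(apex=5.0, sigma=0.2, intensity=1e4)
        entry = make_entry(apex=5.0)
        detected, _ = detect_survey({"e0": pep}, [entry], 5.1, 0.0, basic_config)
        expected = 1e4 * math.exp(-(0.1**2) / (2 * 0.2**2))
        assert detected[0][1] == pytest.approx(expected)

    def test_unknown_mapping_reported_undetectable(self, basic_config):
        entry = make_entry("ghost", apex=5.0)
        detected, unknown = detect_survey({}, [entry], 5.0, 0.0, basic_config)
        assert detected == [] and unknown == ["ghost"]


class TestAlignRt:
    def test_no_observations_gives_zero(self, basic_config):
        assert align_rt([], basic_config) == 0.0

    def test_constant_shift_recovered(self, basic_config):
        obs = [(p, p + 2.0) for p in [5.0, 10.0, 20.0, 33.0]]
        assert align_rt(obs, basic_config) == pytest.approx(2.0)

    def test_linear_drift_tracked_within_tolerance(self):
        """Under drift of 0.05 min/min with window 10, the running offset stays
        within the RT tolerance of the true drift at the window midpoint."""
        cfg = AcquisitionConfig(rt_tolerance_min=1.0, calib_window=10, gradient_min=60)
        slope = 0.05
        preds = np.linspace(1, 59, 120)
        obs = [(p, p + slope * p) for p in preds]
        for end in range(10, len(obs)):
            window = obs[: end + 1]
            offset = align_rt(window, cfg)
            mid_pred = np.median([p for p, _ in window[-cfg.calib_window:]])
            assert abs(offset - slope * mid_pred) <= cfg.rt_tolerance_min


def _greedy_oracle(detected, budget, config, mode):
    """Independent sort-and-pack reference for select_cycle."""
    picked = []
    if mode == "prioritized":
        order = sorted(detected, key=lambda d: (-d[2], -d[1], d[0].mz))
        for entry, _i, _p in order:
            cost = entry.max_fill_ms / 1000 + config.ms2_overhead_s
            if cost <= budget:
                picked.append(entry.id)
                budget -= cost
    else:
        order = sorted(detected, key=lambda d: (-d[1], d[0].mz))[: config.topn_n]
        cost = config.default_fill_ms / 1000 + config.ms2_overhead_s
        for entry, _i, _p in order:
            if cost <= budget:
                picked.append(entry.id)
                budget -= cost
    return picked


class TestSelectCycle:
    def test_strict_priority_order_with_two_slots(self, basic_config):
        detected = [
            (make_entry("A", mz=700), 10.0, 2),
            (make_entry("B", mz=600), 100.0, 1),
            (make_entry("C", mz=500), 1000.0, 0),
        ]
        budget = 2 * (500 / 1000 + basic_config.ms2_overhead_s)
        sel = select_cycle(detected, budget, basic_config, "prioritized")
        assert [e.id for e, _ in sel] == ["A", "B"]

    @pytest.mark.parametrize("mode", ["prioritized", "topn"])
    def test_unconstrained_budget_selects_all(self, basic_config, mode):
        detected = [(make_entry(f"e{i}", mz=500 + i), 10.0 * (i + 1), i % 3) for i in range(5)]
        sel = select_cycle(detected, 1e9, basic_config, mode)
        assert {e.id for e, _ in sel} == {f"e{i}" for i in range(5)}

    def test_negative_budget_empty(self, basic_config):
        detected = [(make_entry("A"), 10.0, 1)]
        assert select_cycle(detected, -1.0, basic_config, "prioritized") == []

    @pytest.mark.parametrize("mode", ["prioritized", "topn"])
    def test_matches_greedy_oracle_on_random_instances(self, rng, basic_config, mode):
        for _ in range(50):
            n = rng.integers(1, 25)
            detected = [
                (
                    make_entry(f"e{i}", mz=float(rng.uniform(400, 1600)),
                               fill=float(rng.choice([300, 500, 750, 1000]))),
                    float(rng.lognormal(8, 1)),
                    int(rng.integers(0, 4)),
                )
                for i in range(n)
            ]
            budget = float(rng.uniform(0, 5))
            sel = select_cycle(detected, budget, basic_config, mode)
            assert [e.id for e, _ in sel] == _greedy_oracle(detected, budget, basic_config, mode)

    def test_raising_priority_never_drops_entry(self, rng, basic_config):
        """Monotonicity: with uniform fill times, promoting a selected entry
        keeps it selected."""
        for _ in range(25):
            n = int(rng.integers(2, 15))
            detected = [
                (make_entry(f"e{i}", mz=float(rng.uniform(400, 1600))),
                 float(rng.lognormal(8, 1)), int(rng.integers(0, 3)))
                for i in range(n)
            ]
            budget = float(rng.uniform(0.5, 3))
            base = {e.id for e, _ in select_cycle(detected, budget, basic_config, "prioritized")}
            for j in range(n):
                bumped = [
                    (e, i, p + 2 if e.id == f"e{j}" else p) for e, i, p in detected
                ]
                new = {e.id for e, _ in select_cycle(bumped, budget, basic_config, "prioritized")}
                if f"e{j}" in base:
                    assert f"e{j}" in new

    def test_priority_exactness_topk_under_uniform_fill(self, rng, basic_config):
        """With uniform fill times, selection equals the top-k of the
        (priority, intensity, mz) ordering, k = floor(budget / cost)."""
        cost = 500 / 1000 + basic_config.ms2_overhead_s
        for _ in range(20):
            n = int(rng.integers(1, 20))
            detected = [
                (make_entry(f"e{i}", mz=float(rng.uniform(400, 1600))),
                 float(rng.lognormal(8, 1)), int(rng.integers(0, 3)))
                for i in range(n)
            ]
            k = int(rng.integers(0, n + 1))
            budget = k * cost + 1e-9
            sel = [e.id for e, _ in select_cycle(detected, budget, basic_config, "prioritized")]
            expected = [
                d[0].id for d in sorted(detected, key=lambda d: (-d[2], -d[1], d[0].mz))
            ][:k]
            assert sel == expected


class TestSimulateRun:
    def test_empty_inclusion_only_surveys(self, basic_config):
        log = simulate_run({}, [], basic_config, "prioritized", seed=0)
        assert len(log.events) > 0
        assert all(e.event_kind == "survey" for e in log.events)

    def test_zero_gradient_empty_log(self):
        cfg = AcquisitionConfig(gradient_min=0.0)
        log = simulate_run({}, [], cfg, "prioritized", seed=0)
        assert log.events == []

    def test_priority_decrements_after_in_tolerance_fragmentation(self, basic_config):
        """An entry fragmented at priority 3 competes at priority 2 next time."""
        pep = make_peptide(apex=2.0, sigma=2.0, intensity=1e5)
        entry = make_entry(apex=2.0, priority=3)
        cfg = AcquisitionConfig(
            cycle_time_s=3.0, survey_cost_s=0.5, rt_tolerance_min=2.0,
            dyn_exclusion_s=3.0, gradient_min=5.0, noise_floor=1.0,
        )
        log = simulate_run({"e0": pep}, [entry], cfg, "prioritized", seed=0)
        pri_seq = [e.priority_at_selection for e in log.events if e.event_kind == "ms2"]
        assert len(pri_seq) >= 2
        assert pri_seq[0] == 3 and pri_seq[1] == 2

    def test_priority_floors_at_zero(self):
        pep = make_peptide(apex=2.0, sigma=2.0, intensity=1e5)
        entry = make_entry(apex=2.0, priority=1)
        cfg = AcquisitionConfig(
            cycle_time_s=3.0, survey_cost_s=0.5, rt_tolerance_min=2.0,
            dyn_exclusion_s=0.0, gradient_min=6.0,
        )
        log = simulate_run({"e0": pep}, [entry], cfg, "prioritized", seed=0)
        pri_seq = [e.priority_at_selection for e in log.events if e.event_kind == "ms2"]
        assert pri_seq[0] == 1 and set(pri_seq[1:]) == {0}

    def test_same_seed_byte_identical_log(self, tmp_path, basic_config):
        spec_peps = [make_peptide(f"e{i}", apex=1 + i, intensity=1e4) for i in range(10)]
        entries = [make_entry(f"e{i}", apex=1 + i, priority=i % 3) for i in range(10)]
        cfg = AcquisitionConfig(gradient_min=12.0, rt_jitter_sd_min=0.1, intensity_jitter_cv=0.2)
        paths = []
        for run in range(2):
            log = simulate_run(spec_peps, entries, cfg, "prioritized", seed=42)
            p = tmp_path / f"log{run}.jsonl"
            log.to_jsonl(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_budget_conserved_every_cycle(self, basic_config):
        spec_peps = [make_peptide(f"e{i}", apex=0.5 + 0.1 * i, sigma=1.0, intensity=1e5) for i in range(40)]
        entries = [make_entry(f"e{i}", apex=0.5 + 0.1 * i, priority=i % 3) for i in range(40)]
        cfg = AcquisitionConfig(cycle_time_s=2.0, survey_cost_s=0.5, dyn_exclusion_s=0.0, gradient_min=8.0)
        log = simulate_run(spec_peps, entries, cfg, "prioritized", seed=0)
        df = log.to_dataframe()
        ms2 = df[df.event_kind == "ms2"]
        for _cycle, grp in ms2.groupby("cycle_index"):
            spent = cfg.survey_cost_s + (grp.fill_ms / 1000 + cfg.ms2_overhead_s).sum()
            assert spent <= cfg.cycle_time_s + 1e-9

    def test_equivalence_limit_unconstrained_budget(self):
        """With budget fitting every detected entry, prioritized and topn modes
        fragment identical entry sets."""
        spec_peps = [make_peptide(f"e{i}", apex=1 + 0.4 * i, intensity=1e4 * (i + 1)) for i in range(12)]
        entries = [make_entry(f"e{i}", apex=1 + 0.4 * i, priority=i % 3) for i in range(12)]
        cfg = AcquisitionConfig(
            cycle_time_s=60.0, survey_cost_s=0.5, topn_n=1000, dyn_exclusion_s=0.0,
            gradient_min=8.0,
        )
        sets = {}
        for mode in ("prioritized", "topn"):
            log = simulate_run(spec_peps, entries, cfg, mode, seed=0)
            sets[mode] = {e.precursor_id for e in log.events if e.event_kind == "ms2"}
        assert sets["prioritized"] == sets["topn"]


class TestRunMetrics:
    def test_saturated_run_all_sent(self):
        spec_peps = [make_peptide(f"e{i}", apex=2 + i, sigma=0.5, intensity=1e5) for i in range(4)]
        entries = [make_entry(f"e{i}", apex=2 + i, priority=i % 2) for i in range(4)]
        cfg = AcquisitionConfig(cycle_time_s=10.0, survey_cost_s=0.5, gradient_min=8.0)
        log = simulate_run(spec_peps, entries, cfg, "prioritized", seed=0)
        m = run_metrics(log, entries)
        assert (m["send_pct"] == 100.0).all()

    def test_unreachable_entry_in_denominator(self):
        spec_peps = [make_peptide("near", apex=2.0, intensity=1e5)]
        entries = [make_entry("near", apex=2.0, priority=1),
                   make_entry("far", apex=200.0, priority=1)]
        # "far" never elutes within the gradient: counted, contributes 0
        cfg = AcquisitionConfig(gradient_min=6.0)
        log = simulate_run({"near": spec_peps[0], "far": make_peptide("far", apex=200.0)}, entries, cfg, "prioritized", seed=0)
        m = run_metrics(log, entries)
        assert m.loc["1", "n"] == 2
        assert m.loc["1", "send_pct"] == 50.0

    def test_rt_only_tier_reported_separately(self):
        pep = make_peptide("cal", apex=2.0, intensity=1e5)
        entries = [make_entry("cal", apex=2.0, ms2=False)]
        cfg = AcquisitionConfig(gradient_min=5.0)
        log = simulate_run({"cal": pep}, entries, cfg, "prioritized", seed=0)
        m = run_metrics(log, entries)
        assert "rt_only" in m.index
        assert m.loc["rt_only", "send_pct"] == 0.0
        assert m.loc["rt_only", "detection_pct"] == 100.0


class TestPercentGain:
    @pytest.mark.parametrize(
        "baseline,improved,expected",
        [(18, 59, 228), (49, 72, 47), (40, 40, 0), (63, 63, 0)],
    )
    def test_values(self, baseline, improved, expected):
        assert percent_gain(baseline, improved) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_gain(0, 10)


class TestValidation:
    def test_bad_peptide_rejected(self):
        with pytest.raises(ValueError):
            SimPeptide("x", -1.0, 2, 5.0, 0.2, 1e4)
        with pytest.raises(ValueError):
            SimPeptide("x", 500.0, 2, 5.0, 0.0, 1e4)

    def test_bad_entry_rejected(self):
        with pytest.raises(ValueError):
            InclusionEntry("x", 500.0, 5.0, priority=-1)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionConfig(cycle_time_s=0.4, survey_cost_s=0.5)
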