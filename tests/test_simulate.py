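import math

import numpy as np
import pytest

from cpgsilence import (
    MethylationCallTable,
    MethylationSimConfig,
    SimulationConfig,
    read_flow_csv,
    read_methylation_calls,
    simulate_flow_timecourse,
    simulate_methylation_calls,
    write_flow_csv,
    write_methylation_calls,
)

DILUTION_PER_DAY = 24.0 / 22.0 * math.log(2.0)  # ln-units per day post-silencing


def _committed_fraction(sample, config):
    """Fraction of events below the analytic midpoint between the active
    peak and the least-diluted silenced peak; separates the populations
    when every silenced cell has diluted >= ~2 days."""
    min_drop = (config.measure_time - config.dox_end) * DILUTION_PER_DAY
    cut = math.exp(config.active_log_mean - min_drop / 2.0)
    return float(np.mean(sample.events < cut))


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(beta=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(dox_start=5, dox_end=4, measure_time=6)
    with pytest.raises(ValueError):
        SimulationConfig(background_silenced_fraction=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_cells=0)


def test_no_hazard_no_background_gives_pure_active_population():
    config = SimulationConfig(
        n_cells=20_000, beta=0.0, dox_end=4, measure_time=6,
        background_silenced_fraction=0.0, seed=1,
    )
    sample = simulate_flow_timecourse(config)
    log_f = np.log(sample.events)
    # every event within the active peak; nothing from diluted distributions
    assert np.all(np.abs(log_f - config.active_log_mean) < 6 * config.active_log_sd)


def test_silencing_time_matches_exponential_cdf():
    """Closed-form oracle: P(t_s <= T) = 1 - exp(-beta*T) for dox over [0, T]."""
    beta, T, n = 0.274, 19.0, 100_000
    config = SimulationConfig(
        n_cells=n, beta=beta, dox_start=0.0, dox_end=T, measure_time=T + 2,
        background_silenced_fraction=0.0, seed=2,
    )
    sample = simulate_flow_timecourse(config)
    expected = 1.0 - math.exp(-beta * T)
    tol = 3.0 * math.sqrt(expected * (1 - expected) / n)
    assert _committed_fraction(sample, config) == pytest.approx(expected, abs=tol + 2e-4)


def test_flow_determinism():
    config = SimulationConfig(n_cells=5000, beta=0.2, dox_end=4, measure_time=6, seed=7)
    a = simulate_flow_timecourse(config, "P", "dox_plus")
    b = simulate_flow_timecourse(config, "P", "dox_plus")
    np.testing.assert_array_equal(a.events, b.events)
    c = simulate_flow_timecourse(config, "P", "dox_plus", replicate=1)
    assert not np.array_equal(a.events, c.events)


def test_committed_fraction_stable_after_release():
    """Same dox window measured at different times after release: the
    silenced-committed cells are the same cells (irreversibility)."""
    counts = []
    for measure in (8.0, 10.0, 12.0):
        config = SimulationConfig(
            n_cells=20_000, beta=0.3, dox_start=0.0, dox_end=4.0,
            measure_time=measure, background_silenced_fraction=0.0, seed=3,
        )
        sample = simulate_flow_timecourse(config, "P")
        counts.append(round(_committed_fraction(sample, config) * config.n_cells))
    assert counts[0] == counts[1] == counts[2]


def test_silenced_peak_dilutes_by_ln2_per_division():
    """Median silenced log-fluorescence drops by (days elapsed)·(24/22)·ln2."""
    medians = []
    for measure in (4.0, 6.0):
        config = SimulationConfig(
            n_cells=50_000, beta=0.5, dox_start=0.0, dox_end=2.0,
            measure_time=measure, background_silenced_fraction=0.0, seed=4,
        )
        sample = simulate_flow_timecourse(config, "P")
        min_drop = (measure - config.dox_end) * DILUTION_PER_DAY
        cut = math.exp(config.active_log_mean - min_drop / 2.0)
        medians.append(float(np.median(np.log(sample.events[sample.events < cut]))))
    assert medians[0] - medians[1] == pytest.approx(2.0 * DILUTION_PER_DAY, abs=0.05)


def test_expected_active_fraction_scaling():
    """Empirical deviation from exp(-beta*T) shrinks roughly as 1/sqrt(n)."""
    beta, T = 0.15, 6.0
    expected = math.exp(-beta * T)
    devs = {}
    for n in (1000, 100_000):
        errs = []
        for seed in range(8):
            config = SimulationConfig(
                n_cells=n, beta=beta, dox_start=0.0, dox_end=T, measure_time=T + 2,
                background_silenced_fraction=0.0, seed=100 + seed,
            )
            sample = simulate_flow_timecourse(config, f"n{n}")
            errs.append(abs((1 - _committed_fraction(sample, config)) - expected))
        devs[n] = np.mean(errs)
    assert devs[100_000] < devs[1000] / 3.0


def test_background_cells_in_no_dox_control():
    config = SimulationConfig(
        n_cells=50_000, beta=0.0, dox_end=0, measure_time=0,
        background_silenced_fraction=0.1, seed=5,
    )
    sample = simulate_flow_timecourse(config, "P", "dox_minus")
    cut = math.exp(
        (config.active_log_mean + config.autofluorescence_log_mean) / 2.0
    )
    frac_low = float(np.mean(sample.events < cut))
    assert frac_low == pytest.approx(0.1, abs=3 * math.sqrt(0.1 * 0.9 / 50_000))


def test_flow_csv_roundtrip(tmp_path):
    config = SimulationConfig(n_cells=200, beta=0.2, dox_end=4, measure_time=6, seed=6)
    sample = simulate_flow_timecourse(config, "P", "dox_plus")
    path = tmp_path / "flow.csv"
    write_flow_csv(sample, path)
    back = read_flow_csv(path)
    assert back.promoter_name == "P"
    assert back.condition == "dox_plus"
    assert back.measure_time == 6.0
    np.testing.assert_allclose(back.events, sample.events)


# --- methylation calls -----------------------------------------------------


def test_zero_hazard_gives_no_methylation(small_promoter):
    config = MethylationSimConfig(promoter=small_promoter, per_site_hazard=0.0, seed=1)
    table = simulate_methylation_calls(config)
    assert (table.calls["n_meth"] == 0).all()
    assert (table.calls["n_unmeth"] == config.n_reads).all()


def test_high_hazard_saturates(small_promoter):
    config = MethylationSimConfig(
        promoter=small_promoter, per_site_hazard=5.0,
        sample_plan=(("still_on", 30.0),), n_reads=400, seed=2,
    )
    table = simulate_methylation_calls(config)
    frac = table.calls["n_meth"] / 400
    assert (frac > 0.99).all()


def test_methylation_fraction_matches_closed_form(small_promoter):
    """p = 1 - exp(-h*day): h=0.05/d, day=10 -> 0.3935 within 3 binomial SDs."""
    n_reads = 10_000
    config = MethylationSimConfig(
        promoter=small_promoter, per_site_hazard=0.05,
        sample_plan=(("still_on", 10.0),), n_reads=n_reads, seed=3,
    )
    table = simulate_methylation_calls(config)
    expected = 1.0 - math.exp(-0.5)
    tol = 3.0 * math.sqrt(expected * (1 - expected) / n_reads)
    for _, row in table.calls.iterrows():
        assert row["n_meth"] / n_reads == pytest.approx(expected, abs=tol)


def test_capacity_caps_expected_total(small_promoter):
    """In saturation mode the sum of per-CpG probabilities is capped."""
    config = MethylationSimConfig(
        promoter=small_promoter, per_site_hazard=1.0, capacity=2.0,
        sample_plan=(("still_on", 20.0),), n_reads=20_000, seed=4,
    )
    table = simulate_methylation_calls(config)
    total = (table.calls["n_meth"] / 20_000).sum()
    assert total == pytest.approx(2.0, rel=0.05)


def test_master_cpg_must_be_a_promoter_cpg(small_promoter):
    with pytest.raises(ValueError, match="not a CpG"):
        MethylationSimConfig(promoter=small_promoter, master_cpg=(2, 0.5))


def test_master_cpg_only_boosts_recently_silenced(small_promoter):
    pos = small_promoter.cpg_positions[0]
    config = MethylationSimConfig(
        promoter=small_promoter, per_site_hazard=0.01, master_cpg=(pos, 1.0),
        sample_plan=(("still_on", 10.0), ("recently_silenced", 10.0)),
        n_reads=5000, seed=5,
    )
    table = simulate_methylation_calls(config)
    merged = table.calls.merge(table.samples, on="sample_id")
    at_master = merged[merged["position"] == pos].set_index("group")
    frac_on = at_master.loc["still_on", "n_meth"] / 5000
    frac_rs = at_master.loc["recently_silenced", "n_meth"] / 5000
    assert frac_rs > 0.9999 - 0.01  # 1 - exp(-1.01*10)
    assert frac_on < 0.2  # 1 - exp(-0.1) ~ 0.095


def test_methylation_call_roundtrip(tmp_path, small_promoter):
    config = MethylationSimConfig(promoter=small_promoter, seed=6)
    table = simulate_methylation_calls(config)
    write_methylation_calls(table, tmp_path)
    back = read_methylation_calls(tmp_path)
    assert isinstance(back, MethylationCallTable)
    assert back.promoter_name == table.promoter_name
    a = table.calls.sort_values(["sample_id", "position"], ignore_index=True)
    b = back.calls.sort_values(["sample_id", "position"], ignore_index=True)
    assert a.equals(b)
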