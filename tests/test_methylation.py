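import math

import numpy as np
import pandas as pd
import pytest

from cpgsilence import (
    MethylationCallTable,
    MethylationSimConfig,
    PromoterSequence,
    accumulation_metrics,
    differential_cpg_test,
    random_promoter,
    select_master_cpgs,
    simulate_methylation_calls,
)


def _table(promoter_name, samples, calls):
    return MethylationCallTable(
        promoter_name=promoter_name,
        samples=pd.DataFrame(samples),
        calls=pd.DataFrame(calls),
    )


def _sample(sid, group="still_on", day=5):
    return {"sample_id": sid, "group": group, "day": day}


def test_accumulation_all_methylated():
    promoter = random_promoter("p", 500, 8.0, seed=1)  # 20 CpGs, length 500
    assert promoter.n_cpg == 20
    calls = [
        {"sample_id": "s1", "position": p, "n_meth": 10, "n_unmeth": 0}
        for p in promoter.cpg_positions
    ]
    acc = accumulation_metrics(_table("p", [_sample("s1")], calls), promoter)
    row = acc.iloc[0]
    assert row["freq"] == 1.0
    assert row["total"] == 20.0
    assert row["per_bp"] == pytest.approx(0.04)


def test_accumulation_coverage_weighted_frequency(small_promoter):
    p1, p2 = small_promoter.cpg_positions[:2]
    calls = [
        {"sample_id": "s1", "position": p1, "n_meth": 3, "n_unmeth": 1},
        {"sample_id": "s1", "position": p2, "n_meth": 1, "n_unmeth": 3},
    ]
    acc = accumulation_metrics(_table("toy", [_sample("s1")], calls), small_promoter)
    assert acc["freq"].iloc[0] == pytest.approx(0.5)  # 4 of 8 reads
    assert acc["total"].iloc[0] == pytest.approx(0.5 * small_promoter.n_cpg)


def test_accumulation_zero_coverage_flagged_not_dropped(small_promoter):
    calls = [
        {"sample_id": "s1", "position": p, "n_meth": 0, "n_unmeth": 0}
        for p in small_promoter.cpg_positions
    ]
    acc = accumulation_metrics(_table("toy", [_sample("s1")], calls), small_promoter)
    assert len(acc) == 1
    assert acc["flagged"].iloc[0]
    assert math.isnan(acc["freq"].iloc[0])


def test_accumulation_rejects_foreign_positions(small_promoter):
    calls = [{"sample_id": "s1", "position": 2, "n_meth": 1, "n_unmeth": 1}]
    with pytest.raises(ValueError, match="not CpGs"):
        accumulation_metrics(_table("toy", [_sample("s1")], calls), small_promoter)


def test_accumulation_follows_hazard_closed_form(small_promoter):
    """freq tracks 1 - exp(-h*day) at each sampled day."""
    h, n_reads = 0.05, 10_000
    config = MethylationSimConfig(
        promoter=small_promoter, per_site_hazard=h, n_reads=n_reads,
        sample_plan=tuple(("still_on", d) for d in (2, 4, 6, 8)), seed=2,
    )
    acc = accumulation_metrics(simulate_methylation_calls(config), small_promoter)
    for _, row in acc.iterrows():
        expected = 1 - math.exp(-h * row["day"])
        tol = 3 * math.sqrt(expected * (1 - expected) / (n_reads * small_promoter.n_cpg))
        assert row["freq"] == pytest.approx(expected, abs=tol)


def test_accumulation_freq_invariant_to_count_scaling(small_promoter):
    calls = [
        {"sample_id": "s1", "position": p, "n_meth": 2 + i, "n_unmeth": 5}
        for i, p in enumerate(small_promoter.cpg_positions)
    ]
    base = accumulation_metrics(_table("toy", [_sample("s1")], calls), small_promoter)
    scaled_calls = [
        {**c, "n_meth": c["n_meth"] * 7, "n_unmeth": c["n_unmeth"] * 7} for c in calls
    ]
    scaled = accumulation_metrics(
        _table("toy", [_sample("s1")], scaled_calls), small_promoter
    )
    assert scaled["freq"].iloc[0] == pytest.approx(base["freq"].iloc[0])


def test_saturation_decouples_total_from_cpg_count():
    """With a binding capacity cap, total methylation per promoter is flat
    across promoters while per-CpG frequency falls with CpG count."""
    low = random_promoter("low", 500, 8.0, seed=3)  # 20 CpGs
    high = random_promoter("high", 1500, 8.0, seed=3)  # 60 CpGs
    totals, freqs = {}, {}
    for prom in (low, high):
        config = MethylationSimConfig(
            promoter=prom, per_site_hazard=0.1, capacity=8.0, n_reads=4000,
            sample_plan=(("still_on", 10.0),), seed=4,
        )
        acc = accumulation_metrics(simulate_methylation_calls(config), prom)
        totals[prom.name] = acc["total"].iloc[0]
        freqs[prom.name] = acc["freq"].iloc[0]
    assert totals["high"] == pytest.approx(totals["low"], rel=0.05)
    assert freqs["low"] / freqs["high"] >= 2.0


# --- differential screen ---------------------------------------------------


def _two_group_table(values_on, values_rs, n_reads=1000, position=3):
    samples, calls = [], []
    for i, v in enumerate(values_on):
        sid = f"on{i}"
        samples.append(_sample(sid, "still_on"))
        calls.append(
            {"sample_id": sid, "position": position,
             "n_meth": round(v * n_reads), "n_unmeth": n_reads - round(v * n_reads)}
        )
    for i, v in enumerate(values_rs):
        sid = f"rs{i}"
        samples.append(_sample(sid, "recently_silenced"))
        calls.append(
            {"sample_id": sid, "position": position,
             "n_meth": round(v * n_reads), "n_unmeth": n_reads - round(v * n_reads)}
        )
    return _table("p", samples, calls)


def test_identical_groups_give_null_result():
    table = _two_group_table([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
    res = differential_cpg_test(table)
    assert res["t_statistic"].iloc[0] == 0.0
    assert res["p_value"].iloc[0] == 1.0


def test_pooled_variance_t_closed_form():
    """Hand-computed pooled-variance t: (0.1,0.2,0.3) vs (0.4,0.5,0.6)
    gives t = -3.674, df = 4, p ~ 0.0213."""
    table = _two_group_table([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
    res = differential_cpg_test(table)
    assert res["t_statistic"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
    assert res["p_value"].iloc[0] == pytest.approx(0.0213, abs=1e-3)


def test_zero_coverage_sample_excluded_per_cpg():
    table = _two_group_table([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
    table.calls.loc[0, ["n_meth", "n_unmeth"]] = 0
    res = differential_cpg_test(table)
    assert res["n_still_on"].iloc[0] == 2
    assert res["testable"].iloc[0]


def test_group_below_min_size_is_untestable():
    table = _two_group_table([0.1, 0.2], [0.4, 0.5])
    table.calls.loc[0, ["n_meth", "n_unmeth"]] = 0
    res = differential_cpg_test(table)
    assert not res["testable"].iloc[0]
    assert math.isnan(res["p_value"].iloc[0])


def test_planted_master_cpg_ranks_first():
    promoter = random_promoter("pEF1s", 500, 18.0, seed=5)
    pos = promoter.cpg_positions[len(promoter.cpg_positions) // 2]
    config = MethylationSimConfig(
        promoter=promoter, per_site_hazard=0.02, master_cpg=(pos, 0.2), seed=6
    )
    res = differential_cpg_test(simulate_methylation_calls(config))
    assert int(res["position"].iloc[0]) == pos
    assert res["p_value"].iloc[0] < 0.05
    assert select_master_cpgs(res)[0] == pos
    # master is hypermethylated in the recently-silenced group
    top = res.iloc[0]
    assert top["mean_recently_silenced"] > top["mean_still_on"]


def test_select_master_cpgs_alpha_bounds():
    table = _two_group_table([0.3, 0.31, 0.3], [0.32, 0.3, 0.31])
    res = differential_cpg_test(table)
    assert select_master_cpgs(res, alpha=res["p_value"].min()) == []
    assert len(select_master_cpgs(res, alpha=1.0)) == len(res)


def test_q_values_are_bh_adjusted_and_ranked():
    promoter = random_promoter("p", 400, 12.0, seed=7)
    config = MethylationSimConfig(promoter=promoter, per_site_hazard=0.02, seed=8)
    res = differential_cpg_test(simulate_methylation_calls(config))
    assert (res["q_value"] >= res["p_value"] - 1e-12).all()
    assert list(res["rank"]) == sorted(res["rank"])
    assert res["p_value"].is_monotonic_increasing
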