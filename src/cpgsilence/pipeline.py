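"""End-to-end orchestration of the simulate → gate → normalize → fit pipeline.

A run takes a promoter library (explicit sequences or synthetic ones at
requested CpG densities), assigns each promoter a silencing rate β —
either explicitly or through a density→β law β = intercept + slope·c —
and then, per promoter and timepoint, simulates dox+ samples and dox−
controls, fits the log-normal gate on each control, forms all pairwise
background-corrected silenced fractions (the bootstrap error-bar
procedure), fits β by the exponential-decay regression, and summarizes
the library with the Pearson correlation between fitted β and CpG
density.  Optionally the methylation channel is simulated and analysed
(accumulation metrics, differential CpG screen, master-CpG selection).

The dox protocol default is induce for t days then release for 2 days
and measure, so the committed silenced fraction is stable at
measurement.  Identical config + seed gives an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .gating import LogNormalGate
from .kinetics import (
    SilencingTimecourse,
    bootstrap_normalization,
    empirical_rates,
    fit_switching_rate,
)
from .methylation import accumulation_metrics, differential_cpg_test, select_master_cpgs
from .seq import PromoterSequence, random_promoter, read_fasta
from .simulate import (
    MethylationSimConfig,
    SimulationConfig,
    simulate_flow_timecourse,
    simulate_methylation_calls,
    write_flow_csv,
    write_methylation_calls,
)

__all__ = ["PromoterSpec", "RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)

#: default density→β law: β = slope·c, spanning ≈0.03–0.27 d⁻¹ over c = 4–36%
DEFAULT_BETA_PER_PCT = 0.0076


@dataclasses.dataclass(frozen=True)
class PromoterSpec:
    """One library member: an explicit sequence or a synthetic density."""

    name: str
    sequence: str | None = None
    density_pct: float | None = None
    length: int = 500
    beta: float | None = None

    def __post_init__(self):
        if self.sequence is None and self.density_pct is None:
            raise ValueError(f"{self.name}: give either a sequence or a density_pct")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run."""

    library: tuple[PromoterSpec, ...]
    timepoints: tuple[float, ...] = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19)
    release_days: float = 2.0
    n_cells: int = 10_000
    replicate_samples: int = 3
    replicate_controls: int = 3
    gating_mode: str = "lognormal_2sigma"
    beta_slope_per_pct: float = DEFAULT_BETA_PER_PCT
    beta_intercept: float = 0.0
    exclude_t0: bool = False
    background_silenced_fraction: float = 0.02
    active_log_mean: float = 9.2
    active_log_sd: float = 0.20
    division_time: float = 22.0
    run_methylation: bool = False
    methylation_base_hazard: float = 0.02
    methylation_capacity: float | None = None
    methylation_n_reads: int = 500
    master_cpg_extra_hazard: float | None = None
    write_events: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.library:
            raise ValueError("library must be non-empty")
        if not self.timepoints:
            raise ValueError("timepoints must be non-empty")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be ascending")
        if self.replicate_samples < 1 or self.replicate_controls < 1:
            raise ValueError("replicates must be >= 1")


def _resolve_promoter(spec: PromoterSpec, seed: int) -> PromoterSequence:
    if spec.sequence is not None:
        return PromoterSequence(spec.name, spec.sequence)
    return random_promoter(spec.name, spec.length, spec.density_pct, seed=seed)


def _resolve_beta(spec: PromoterSpec, density: float, config: RunConfig) -> float:
    if spec.beta is not None:
        return spec.beta
    return config.beta_intercept + config.beta_slope_per_pct * density


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run the full analysis; write intermediates and a JSON report.

    Outputs under ``out_dir``: per-promoter flow CSVs (if
    ``write_events``), ``gating.tsv``, ``timecourses.tsv``, ``fits.tsv``,
    ``rates.tsv``, methylation TSVs (if enabled) and ``report.json``.
    Returns the report as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gating_rows, tc_rows, fit_rows, rate_rows = [], [], [], []
    promoter_reports = []

    for spec in config.library:
        promoter = _resolve_promoter(spec, seed=config.seed)
        beta_true = _resolve_beta(spec, promoter.density_c, config)
        logger.info(
            "promoter %s: density %.2f%%, beta %.4f/d",
            promoter.name,
            promoter.density_c,
            beta_true,
        )
        t_points, s_norm_points, s_plus_means, s_minus_means, sd_points = (
            [],
            [],
            [],
            [],
            [],
        )
        for t in config.timepoints:
            measure = t + config.release_days
            sim_kwargs = dict(
                n_cells=config.n_cells,
                beta=beta_true,
                dox_start=0.0,
                dox_end=float(t),
                measure_time=float(measure),
                division_time=config.division_time,
                active_log_mean=config.active_log_mean,
                active_log_sd=config.active_log_sd,
                background_silenced_fraction=config.background_silenced_fraction,
                seed=config.seed,
            )
            sim = SimulationConfig(**sim_kwargs)
            controls = [
                simulate_flow_timecourse(sim, promoter.name, "dox_minus", replicate=j)
                for j in range(config.replicate_controls)
            ]
            samples = [
                simulate_flow_timecourse(sim, promoter.name, "dox_plus", replicate=i)
                for i in range(config.replicate_samples)
            ]
            gates = [LogNormalGate(mode=config.gating_mode).fit(c.events) for c in controls]
            s_minus = [
                g.silenced_fraction(c.events) for g, c in zip(gates, controls)
            ]
            pairs_plus, pairs_minus = [], []
            for smp in samples:
                for g, sm in zip(gates, s_minus):
                    pairs_plus.append(g.silenced_fraction(smp.events))
                    pairs_minus.append(sm)
            points, mean_norm, sd_norm = bootstrap_normalization_pairs(
                pairs_plus, pairs_minus
            )
            t_points.append(float(t))
            s_norm_points.append(mean_norm)
            sd_points.append(sd_norm)
            s_plus_means.append(float(np.mean(pairs_plus)))
            s_minus_means.append(float(np.mean(s_minus)))
            for j, g in enumerate(gates):
                gating_rows.append(
                    {
                        "promoter": promoter.name,
                        "t_dox_days": t,
                        "control_rep": j,
                        "mu": g.mu_,
                        "sigma": g.sigma_,
                        "threshold": g.threshold_,
                        "raw_fraction": g.raw_silenced_fraction_,
                    }
                )
            if config.write_events:
                flow_dir = out_dir / "flow"
                flow_dir.mkdir(exist_ok=True)
                for group in (controls, samples):
                    for k, fs in enumerate(group):
                        write_flow_csv(
                            fs,
                            flow_dir
                            / f"{promoter.name}_t{t:g}_{fs.condition}_rep{k}.csv",
                        )

        df = pd.DataFrame(
            {
                "t": t_points,
                "s_plus": s_plus_means,
                "s_minus": s_minus_means,
                "s_norm": s_norm_points,
            }
        )
        df["active"] = 1.0 - df["s_norm"]
        tc = SilencingTimecourse(promoter.name, df)
        for row in df.assign(promoter=promoter.name, sd=sd_points).to_dict("records"):
            tc_rows.append(row)
        fit = fit_switching_rate(
            tc, exclude_times=(0.0,) if config.exclude_t0 else ()
        )
        fit_rows.append(
            {
                "promoter": promoter.name,
                "density_pct": promoter.density_c,
                "beta_true": beta_true,
                "beta": fit.beta,
                "beta_se": fit.beta_se,
                "r2": fit.r_squared,
                "n_points": fit.n_points_used,
            }
        )
        for row in empirical_rates(tc).to_dict("records"):
            rate_rows.append({"promoter": promoter.name, **row})
        promoter_reports.append(
            {
                "name": promoter.name,
                "density_pct": round(promoter.density_c, 6),
                "n_cpg": promoter.n_cpg,
                "beta_true": round(beta_true, 8),
                "beta_fit": round(fit.beta, 8),
                "beta_se": round(fit.beta_se, 8),
                "r_squared": round(fit.r_squared, 8),
            }
        )

    pd.DataFrame(gating_rows).to_csv(out_dir / "gating.tsv", sep="\t", index=False)
    pd.DataFrame(tc_rows).to_csv(out_dir / "timecourses.tsv", sep="\t", index=False)
    fits_df = pd.DataFrame(fit_rows)
    fits_df.to_csv(out_dir / "fits.tsv", sep="\t", index=False)
    pd.DataFrame(rate_rows).to_csv(out_dir / "rates.tsv", sep="\t", index=False)

    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "n_promoters": len(config.library),
        "promoters": promoter_reports,
    }
    if len(fits_df) >= 2 and fits_df["density_pct"].nunique() > 1:
        r, p = stats.pearsonr(fits_df["density_pct"], fits_df["beta"])
        report["density_beta_pearson_r"] = round(float(r), 8)
        report["density_beta_pearson_p"] = float(p)

    if config.run_methylation:
        meth_report = []
        for spec in config.library:
            promoter = _resolve_promoter(spec, seed=config.seed)
            mconfig = MethylationSimConfig(
                promoter=promoter,
                per_site_hazard=config.methylation_base_hazard,
                capacity=config.methylation_capacity,
                master_cpg=(
                    (promoter.cpg_positions[len(promoter.cpg_positions) // 2],
                     config.master_cpg_extra_hazard)
                    if config.master_cpg_extra_hazard is not None
                    and promoter.n_cpg > 0
                    else None
                ),
                n_reads=config.methylation_n_reads,
                seed=config.seed,
            )
            table = simulate_methylation_calls(mconfig)
            meth_dir = out_dir / "methylation" / promoter.name
            write_methylation_calls(table, meth_dir)
            acc = accumulation_metrics(table, promoter)
            acc.to_csv(meth_dir / "accumulation.tsv", sep="\t", index=False)
            diff = differential_cpg_test(table)
            diff.to_csv(meth_dir / "differential.tsv", sep="\t", index=False)
            masters = select_master_cpgs(diff)
            entry = {
                "name": promoter.name,
                "master_cpgs": masters,
            }
            if mconfig.master_cpg is not None:
                entry["planted_master"] = int(mconfig.master_cpg[0])
            meth_report.append(entry)
        report["methylation"] = meth_report

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def bootstrap_normalization_pairs(
    pairs_plus: Sequence[float], pairs_minus: Sequence[float]
) -> tuple[np.ndarray, float, float]:
    """Bootstrap over already-formed (sample, control) pairs."""
    from .kinetics import normalize_fraction

    points = np.array(
        [normalize_fraction(p, m) for p, m in zip(pairs_plus, pairs_minus)]
    )
    sd = float(points.std(ddof=1)) if points.size > 1 else 0.0
    return points, float(points.mean()), sd


def load_run_config(data: dict[str, Any], base_dir: str | Path = ".") -> RunConfig:
    """Build a RunConfig from a parsed YAML/JSON mapping.

    Library entries may give ``sequence``, ``fasta`` (path, all records
    loaded), or ``density_pct`` (+ optional ``length``); each may carry
    an explicit ``beta``.
    """
    base_dir = Path(base_dir)
    specs: list[PromoterSpec] = []
    for entry in data.get("library", []):
        if "fasta" in entry:
            for prom in read_fasta(base_dir / entry["fasta"]):
                specs.append(
                    PromoterSpec(
                        name=prom.name,
                        sequence=prom.sequence,
                        beta=entry.get("beta"),
                    )
                )
        else:
            specs.append(
                PromoterSpec(
                    name=entry["name"],
                    sequence=entry.get("sequence"),
                    density_pct=entry.get("density_pct"),
                    length=int(entry.get("length", 500)),
                    beta=entry.get("beta"),
                )
            )
    kwargs = {k: v for k, v in data.items() if k != "library"}
    if "timepoints" in kwargs:
        kwargs["timepoints"] = tuple(float(t) for t in kwargs["timepoints"])
    return RunConfig(library=tuple(specs), **kwargs)
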