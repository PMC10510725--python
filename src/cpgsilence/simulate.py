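"""Synthetic experiment generator.

Emulates the two measurement channels of a dox-timed DNMT-recruitment
reporter experiment:

* **Flow cytometry** — a clonal population in which each cell silences
  its reporter irreversibly at a stochastic time while the recruiter is
  present (exponential hazard β per day, active only inside the dox
  window).  Active cells emit log-normal fluorescence; silenced cells
  stop producing the stable H2B-fused fluorophore and dilute it two-fold
  per cell division (~22 h), so their log-mean drifts down by ln 2 per
  division until it reaches the autofluorescence floor.  A configurable
  background fraction of pre-silenced cells is present in both the dox+
  and dox− arms; the dox− arm additionally has β = 0.

* **Methylation calls** — per-CpG methylated/unmethylated read counts
  from sorted "still ON" / "recently silenced" subpopulations.  Each CpG
  accumulates methylation with a per-day hazard h_i, so the per-read
  methylation probability at day d is 1 − exp(−h_i·d).  An optional
  capacity cap rescales probabilities so the expected number of
  methylated CpGs per promoter saturates (emulating a methylation
  machinery that writes a roughly fixed number of marks regardless of
  CpG density).  An optional "master" CpG gets extra hazard only in the
  recently-silenced group, planting a known differential signal.

Randomness is keyed per sample by (seed, promoter, condition, replicate,
dox window, time): regenerating one sample never perturbs another, and
the silencing fates of a given dox window are shared across measurement
times, so the committed-silenced set is literally identical before and
after release (irreversibility by construction), while different
induction durations are independent aliquots of the culture.

Neither channel is mechanistically coupled to the other: the study this
emulates found silencing rate and bulk methylation accumulation to be
empirically decoupled.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seq import PromoterSequence

__all__ = [
    "SimulationConfig",
    "FlowSample",
    "simulate_flow_timecourse",
    "MethylationSimConfig",
    "MethylationCallTable",
    "simulate_methylation_calls",
    "write_flow_csv",
    "read_flow_csv",
    "write_methylation_calls",
    "read_methylation_calls",
]

LN2 = math.log(2.0)

#: still-ON samples pooled across induction days (10 samples)
DEFAULT_STILL_ON_DAYS = (3, 6, 9, 12, 15, 18, 21, 24, 27, 30)
#: recently-silenced samples pooled across induction days (6 samples)
DEFAULT_RECENTLY_SILENCED_DAYS = (5, 10, 15, 20, 25, 30)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Flow-cytometry simulation parameters.

    Parameters
    ----------
    n_cells : int
        Events per sample.
    beta : float
        Per-day silencing hazard while dox is present.
    dox_start, dox_end, measure_time : float
        Days.  Silencing can only occur in [dox_start, dox_end]; the
        histogram is taken at measure_time.
    division_time : float
        Hours per cell division (default 22), sets the dilution speed of
        the silenced peak: ln 2 per division.
    active_log_mean, active_log_sd : float
        Natural-log fluorescence of the active population.  The default
        sd 0.20 puts the μ−2σ gate at exp(−2σ−σ²/2) ≈ 66% of the mean,
        inside the 54–71% range typical of single-peaked controls.
    autofluorescence_log_mean, autofluorescence_log_sd : float
        Floor distribution for fully diluted cells; default 200-fold
        below the active mean.
    silenced_log_sd : float or None
        Log-sd of the still-diluting silenced peak; None → active_log_sd.
    background_silenced_fraction : float
        Pre-silenced cells present in every arm (no-dox controls show
        exactly this, plus gate false positives).
    seed : int
        Base seed; per-sample streams are derived from it.
    """

    n_cells: int = 10_000
    beta: float = 0.1
    dox_start: float = 0.0
    dox_end: float = 4.0
    measure_time: float = 6.0
    division_time: float = 22.0
    active_log_mean: float = 9.2
    active_log_sd: float = 0.20
    autofluorescence_log_mean: float = 9.2 - math.log(200.0)
    autofluorescence_log_sd: float = 0.35
    silenced_log_sd: float | None = None
    background_silenced_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (self.dox_start <= self.dox_end <= self.measure_time):
            raise ValueError("require dox_start <= dox_end <= measure_time")
        if self.division_time <= 0:
            raise ValueError("division_time must be > 0")
        if not (0 <= self.background_silenced_fraction < 1):
            raise ValueError("background_silenced_fraction must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class FlowSample:
    """Per-cell fluorescence events for one (promoter, condition, time)."""

    promoter_name: str
    condition: str  # "dox_plus" | "dox_minus"
    measure_time: float
    events: np.ndarray
    config: SimulationConfig | None = None

    def __post_init__(self):
        ev = np.asarray(self.events, dtype=float)
        if ev.ndim != 1:
            raise ValueError("events must be 1-D")
        if np.any(ev <= 0):
            raise ValueError("all fluorescence events must be > 0")
        object.__setattr__(self, "events", ev)


def _sample_streams(
    seed: int,
    promoter_name: str,
    condition: str,
    replicate: int,
    dox_start: float,
    dox_end: float,
    measure_time: float,
) -> tuple[np.random.Generator, np.random.Generator]:
    """Two generators per sample: silencing-fate and emission streams.

    The fate stream is keyed by the dox window but not the measurement
    time: measuring the same induction at several times after release
    reuses the same committed-silenced cells (irreversibility by
    construction), while different induction durations model independent
    aliquots of a large culture, as in a destructive flow measurement.
    """
    name_key = zlib.crc32(promoter_name.encode()) & 0x7FFFFFFF
    cond_key = {"dox_plus": 1, "dox_minus": 2}[condition]
    window = [int(round(dox_start * 1000)), int(round(dox_end * 1000))]
    fate = np.random.default_rng(
        np.random.SeedSequence([seed, name_key, cond_key, replicate, *window])
    )
    emission = np.random.default_rng(
        np.random.SeedSequence(
            [
                seed,
                name_key,
                cond_key,
                replicate,
                *window,
                int(round(measure_time * 1000)) + 1,
            ]
        )
    )
    return fate, emission


def simulate_flow_timecourse(
    config: SimulationConfig,
    promoter_name: str = "promoter",
    condition: str = "dox_plus",
    replicate: int = 0,
) -> FlowSample:
    """Simulate one flow-cytometry sample under all-or-none silencing.

    Each cell draws a silencing time ``t_s = dox_start + Exp(1/β)``;
    cells with ``t_s`` beyond ``min(dox_end, measure_time)`` never
    silence (hazard acts only while dox is present; silencing is
    irreversible afterwards).  In the ``dox_minus`` arm β is forced to 0.
    Background-silenced cells emit from the fully diluted
    (autofluorescence) distribution in both arms.

    Fluorescence: active cells ~ exp(N(μ_a, σ_a)); a cell silenced at
    ``t_s`` has log-mean μ_a − (measure_time − t_s)·(24/division_time)·ln 2,
    floored at the autofluorescence log-mean.

    Fixed (config.seed, promoter_name, condition, replicate) fixes the
    silencing fates for every measure_time; output is bit-identical for
    identical inputs.
    """
    if condition not in ("dox_plus", "dox_minus"):
        raise ValueError(f"unknown condition {condition!r}")
    n = config.n_cells
    fate, emission = _sample_streams(
        config.seed,
        promoter_name,
        condition,
        replicate,
        config.dox_start,
        config.dox_end,
        config.measure_time,
    )

    is_background = fate.random(n) < config.background_silenced_fraction
    beta = config.beta if condition == "dox_plus" else 0.0
    if beta > 0:
        t_s = config.dox_start + fate.exponential(1.0 / beta, size=n)
    else:
        t_s = np.full(n, np.inf)
    window_end = min(config.dox_end, config.measure_time)
    silenced = (~is_background) & (t_s <= window_end)
    active = (~is_background) & (~silenced)

    log_f = np.empty(n)
    log_f[active] = emission.normal(
        config.active_log_mean, config.active_log_sd, size=int(active.sum())
    )

    divisions_per_day = 24.0 / config.division_time
    sil_sd = (
        config.silenced_log_sd
        if config.silenced_log_sd is not None
        else config.active_log_sd
    )
    mu_sil = config.active_log_mean - (
        (config.measure_time - t_s[silenced]) * divisions_per_day * LN2
    )
    floored = mu_sil <= config.autofluorescence_log_mean
    mu_sil = np.maximum(mu_sil, config.autofluorescence_log_mean)
    sd_sil = np.where(floored, config.autofluorescence_log_sd, sil_sd)
    log_f[silenced] = emission.standard_normal(int(silenced.sum())) * sd_sil + mu_sil

    log_f[is_background] = emission.normal(
        config.autofluorescence_log_mean,
        config.autofluorescence_log_sd,
        size=int(is_background.sum()),
    )

    return FlowSample(
        promoter_name=promoter_name,
        condition=condition,
        measure_time=config.measure_time,
        events=np.exp(log_f),
        config=config,
    )


# ---------------------------------------------------------------------------
# methylation calls


@dataclasses.dataclass(frozen=True)
class MethylationSimConfig:
    """Per-CpG methylation-call simulation parameters.

    ``per_site_hazard`` is a scalar or one value per CpG of ``promoter``
    (per day).  ``capacity``, if set, caps the expected number of
    methylated CpGs per promoter: when Σᵢ pᵢ would exceed it, the pᵢ are
    rescaled multiplicatively (saturation mode).  ``master_cpg`` plants a
    (position, extra_hazard) differential signal applied only in
    recently-silenced samples.  ``sample_plan`` lists (group, day) pairs;
    the default mirrors a pooled design of 10 still-ON and 6
    recently-silenced samples across induction days.
    """

    promoter: PromoterSequence
    per_site_hazard: float | Sequence[float] = 0.02
    capacity: float | None = None
    master_cpg: tuple[int, float] | None = None
    n_reads: int = 500
    sample_plan: tuple[tuple[str, float], ...] = tuple(
        [("still_on", d) for d in DEFAULT_STILL_ON_DAYS]
        + [("recently_silenced", d) for d in DEFAULT_RECENTLY_SILENCED_DAYS]
    )
    seed: int = 0

    def __post_init__(self):
        h = np.atleast_1d(np.asarray(self.per_site_hazard, dtype=float))
        n_cpg = self.promoter.n_cpg
        if h.size == 1:
            h = np.full(n_cpg, float(h[0]))
        if h.size != n_cpg:
            raise ValueError(
                f"per_site_hazard has {h.size} entries for {n_cpg} CpGs"
            )
        if np.any(h < 0):
            raise ValueError("per-site hazards must be >= 0")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.master_cpg is not None:
            pos, extra = self.master_cpg
            if pos not in self.promoter.cpg_positions:
                raise ValueError(
                    f"master CpG position {pos} is not a CpG of {self.promoter.name}"
                )
            if extra < 0:
                raise ValueError("master CpG extra hazard must be >= 0")
        for group, day in self.sample_plan:
            if group not in ("still_on", "recently_silenced"):
                raise ValueError(f"unknown group {group!r}")
            if day < 0:
                raise ValueError("days must be >= 0")
        object.__setattr__(self, "hazards", h)

    hazards: np.ndarray = dataclasses.field(init=False, repr=False)


@dataclasses.dataclass
class MethylationCallTable:
    """Per-CpG methylated/unmethylated counts per sample.

    ``samples``: DataFrame with columns (sample_id, group, day).
    ``calls``: DataFrame with columns (sample_id, position, n_meth,
    n_unmeth); every CpG position appears for every sample (zero
    coverage allowed).
    """

    promoter_name: str
    samples: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self):
        need_s = {"sample_id", "group", "day"}
        need_c = {"sample_id", "position", "n_meth", "n_unmeth"}
        if not need_s.issubset(self.samples.columns):
            raise ValueError(f"samples must have columns {sorted(need_s)}")
        if not need_c.issubset(self.calls.columns):
            raise ValueError(f"calls must have columns {sorted(need_c)}")
        if (self.calls[["n_meth", "n_unmeth"]] < 0).any().any():
            raise ValueError("counts must be >= 0")

    @property
    def positions(self) -> list[int]:
        return sorted(self.calls["position"].unique())


def simulate_methylation_calls(config: MethylationSimConfig) -> MethylationCallTable:
    """Simulate per-CpG methylation counts for every sample in the plan.

    Per-read methylation probability at CpG i on day d is
    ``p_i = 1 − exp(−h_i·d)`` (with the master CpG's extra hazard added in
    recently-silenced samples), optionally rescaled so Σ p_i ≤ capacity;
    counts are Binomial(n_reads, p_i).
    """
    promoter = config.promoter
    positions = np.asarray(promoter.cpg_positions)
    rows = []
    sample_rows = []
    for idx, (group, day) in enumerate(config.sample_plan):
        sample_id = f"{promoter.name}_{group}_d{day:g}_{idx}"
        sample_rows.append({"sample_id": sample_id, "group": group, "day": day})
        hazards = config.hazards.copy()
        if config.master_cpg is not None and group == "recently_silenced":
            pos, extra = config.master_cpg
            hazards[list(positions).index(pos)] += extra
        p = 1.0 - np.exp(-hazards * day)
        if config.capacity is not None and p.sum() > config.capacity:
            p = p * (config.capacity / p.sum())
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [config.seed, zlib.crc32(promoter.name.encode()) & 0x7FFFFFFF, 3, idx]
            )
        )
        n_meth = rng.binomial(config.n_reads, p)
        for pos_i, m in zip(positions, n_meth):
            rows.append(
                {
                    "sample_id": sample_id,
                    "position": int(pos_i),
                    "n_meth": int(m),
                    "n_unmeth": int(config.n_reads - m),
                }
            )
    return MethylationCallTable(
        promoter_name=promoter.name,
        samples=pd.DataFrame(sample_rows),
        calls=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# plain-text I/O

_FLOW_COLUMNS = ["promoter", "condition", "measure_time_days", "fluorescence"]


def write_flow_csv(sample: FlowSample, path: str | Path) -> None:
    """One row per event: promoter, condition, measure_time_days, fluorescence."""
    df = pd.DataFrame(
        {
            "promoter": sample.promoter_name,
            "condition": sample.condition,
            "measure_time_days": sample.measure_time,
            "fluorescence": sample.events,
        }
    )
    df.to_csv(path, index=False)


def read_flow_csv(path: str | Path) -> FlowSample:
    df = pd.read_csv(path)
    missing = set(_FLOW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flow CSV missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"flow CSV {path} has no events")
    return FlowSample(
        promoter_name=str(df["promoter"].iloc[0]),
        condition=str(df["condition"].iloc[0]),
        measure_time=float(df["measure_time_days"].iloc[0]),
        events=df["fluorescence"].to_numpy(),
    )


def write_methylation_calls(
    table: MethylationCallTable, out_dir: str | Path
) -> tuple[Path, list[Path]]:
    """Write a sample sheet TSV and one cytosine-report-style TSV per sample.

    Report columns: sequence_name, position_1based, strand,
    count_methylated, count_unmethylated, context (always "CG", forward
    strand by the package's counting convention).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = out_dir / "samples.tsv"
    table.samples.to_csv(sheet, sep="\t", index=False)
    paths = []
    for sample_id, sub in table.calls.groupby("sample_id", sort=False):
        report = pd.DataFrame(
            {
                "sequence_name": table.promoter_name,
                "position_1based": sub["position"],
                "strand": "+",
                "count_methylated": sub["n_meth"],
                "count_unmethylated": sub["n_unmeth"],
                "context": "CG",
            }
        )
        p = out_dir / f"{sample_id}.CpG_report.tsv"
        report.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return sheet, paths


def read_methylation_calls(out_dir: str | Path) -> MethylationCallTable:
    """Read the sample sheet + per-sample cytosine reports written above."""
    out_dir = Path(out_dir)
    samples = pd.read_csv(out_dir / "samples.tsv", sep="\t")
    rows = []
    promoter_name = None
    for sample_id in samples["sample_id"]:
        report = pd.read_csv(out_dir / f"{sample_id}.CpG_report.tsv", sep="\t")
        promoter_name = str(report["sequence_name"].iloc[0])
        for _, r in report.iterrows():
            rows.append(
                {
                    "sample_id": sample_id,
                    "position": int(r["position_1based"]),
                    "n_meth": int(r["count_methylated"]),
                    "n_unmeth": int(r["count_unmethylated"]),
                }
            )
    return MethylationCallTable(
        promoter_name=promoter_name or "promoter",
        samples=samples,
        calls=pd.DataFrame(rows),
    )
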