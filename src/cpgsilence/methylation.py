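"""Methylation accumulation metrics and the per-CpG differential screen.

Three bulk accumulation metrics are computed per sample from per-CpG
methylated/unmethylated counts:

* ``freq`` — methylation frequency, Σ n_meth / Σ (n_meth + n_unmeth)
  across CpGs (coverage-weighted; methyl-CpG over total CpG reads);
* ``total`` — expected number of methylated CpGs per promoter,
  freq × N_CpG;
* ``per_bp`` — total normalized by promoter length.

The differential screen contrasts FACS-sorted "still ON" and "recently
silenced" populations, pooling samples across days.  The unit of
analysis is each sample's per-CpG methylation percentage; groups are
compared per CpG with a two-sided pooled-variance Student t-test.
Benjamini–Hochberg q-values are reported alongside, but selection of
candidate "master" CpGs — single sites whose methylation status
disproportionately tracks silencing — follows the raw p < alpha rule.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .seq import PromoterSequence
from .simulate import MethylationCallTable

__all__ = [
    "accumulation_metrics",
    "differential_cpg_test",
    "select_master_cpgs",
]

logger = logging.getLogger(__name__)

GROUPS = ("still_on", "recently_silenced")


def accumulation_metrics(
    table: MethylationCallTable, promoter: PromoterSequence
) -> pd.DataFrame:
    """Per-sample methylation accumulation metrics.

    Returns a DataFrame with columns (sample_id, group, day, coverage,
    freq, total, per_bp, flagged).  A sample with zero total coverage
    gets NaN metrics and ``flagged=True`` rather than being dropped.

    Raises
    ------
    ValueError
        If the call table contains positions that are not CpGs of
        ``promoter``.
    """
    positions = set(table.positions)
    extra = positions - set(promoter.cpg_positions)
    if extra:
        raise ValueError(
            f"call table has positions {sorted(extra)} that are not CpGs of "
            f"{promoter.name}"
        )
    n_cpg = promoter.n_cpg
    rows = []
    meta = table.samples.set_index("sample_id")
    for sample_id, sub in table.calls.groupby("sample_id", sort=False):
        n_meth = int(sub["n_meth"].sum())
        cov = int((sub["n_meth"] + sub["n_unmeth"]).sum())
        if cov == 0:
            logger.warning("sample %s has zero coverage; metrics undefined", sample_id)
            freq = total = per_bp = float("nan")
            flagged = True
        else:
            freq = n_meth / cov
            total = freq * n_cpg
            per_bp = total / promoter.length
            flagged = False
        rows.append(
            {
                "sample_id": sample_id,
                "group": meta.loc[sample_id, "group"],
                "day": meta.loc[sample_id, "day"],
                "coverage": cov,
                "freq": freq,
                "total": total,
                "per_bp": per_bp,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) t-test.

    Degenerate case of identical constant groups returns (0, 1): no
    evidence of a difference rather than an undefined statistic.
    """
    with warnings.catch_warnings():
        # identical groups trip scipy's catastrophic-cancellation warning;
        # that case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), float(
            np.finfo(float).tiny
        )
    return t, p


def differential_cpg_test(
    table: MethylationCallTable, min_group: int = 2
) -> pd.DataFrame:
    """Per-CpG pooled-days t-test of still-ON vs recently-silenced percentages.

    For each CpG, each sample contributes its methylation percentage
    n_meth/(n_meth + n_unmeth); samples with zero coverage at that CpG
    are excluded for that CpG (with a warning).  CpGs whose group size
    falls below ``min_group`` are reported as untestable (NaN statistics,
    ``testable=False``).  Columns: position, mean_still_on,
    mean_recently_silenced, n_still_on, n_recently_silenced,
    t_statistic, p_value, q_value (Benjamini–Hochberg over testable
    CpGs), rank (ascending raw p; untestable CpGs last), testable.
    """
    groups = table.samples.set_index("sample_id")["group"]
    unknown = set(groups.unique()) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels {sorted(unknown)}")
    calls = table.calls.copy()
    calls["coverage"] = calls["n_meth"] + calls["n_unmeth"]
    calls["group"] = calls["sample_id"].map(groups)

    rows = []
    for position, sub in calls.groupby("position", sort=True):
        zero = sub["coverage"] == 0
        if zero.any():
            logger.warning(
                "CpG%d: excluding %d zero-coverage sample(s)", position, int(zero.sum())
            )
            sub = sub[~zero]
        pct = sub["n_meth"] / sub["coverage"]
        a = pct[sub["group"] == "still_on"].to_numpy(dtype=float)
        b = pct[sub["group"] == "recently_silenced"].to_numpy(dtype=float)
        row = {
            "position": int(position),
            "mean_still_on": float(a.mean()) if a.size else float("nan"),
            "mean_recently_silenced": float(b.mean()) if b.size else float("nan"),
            "n_still_on": int(a.size),
            "n_recently_silenced": int(b.size),
        }
        if a.size < min_group or b.size < min_group:
            row.update(t_statistic=float("nan"), p_value=float("nan"), testable=False)
        else:
            t, p = _pooled_t(a, b)
            row.update(t_statistic=t, p_value=p, testable=True)
        rows.append(row)
    result = pd.DataFrame(rows)

    result["q_value"] = float("nan")
    testable = result["testable"].to_numpy()
    if testable.any():
        result.loc[testable, "q_value"] = stats.false_discovery_control(
            result.loc[testable, "p_value"].to_numpy()
        )
    order = result["p_value"].rank(method="first", na_option="bottom")
    result["rank"] = order.astype(int)
    return result.sort_values("rank", ignore_index=True)


def select_master_cpgs(result: pd.DataFrame, alpha: float = 0.05) -> list[int]:
    """CpG positions with raw p < alpha, ordered by rank.

    Raw p is the selection rule (q-values are reported for reference
    only); with the conventional alpha = 0.05 this mirrors screening for
    sites with significantly different methylation between expression
    groups.
    """
    hits = result[result["testable"] & (result["p_value"] < alpha)]
    return hits.sort_values("rank")["position"].astype(int).tolist()
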