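"""Per-participant feature vectors for disease-status classification.

For each task (prosaccade, correct antisaccade) and each of five
saccade-level metrics — second-order fit MSE, damping ratio, latency,
amplitude, peak velocity — six distribution summaries are computed:
median, lower quartile, upper quartile, interquartile range, skewness
(adjusted Fisher-Pearson) and excess kurtosis.  Together with the
antisaccade directional error rate this yields a fixed 61-element named
vector per participant.

Erroneous prosaccades made during the antisaccade task contribute only to
the error rate, never to the distribution summaries.  Insufficient data
produces missing values (NaN), never fabricated zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import AS_CORRECT, AS_ERROR, PS_CORRECT

__all__ = [
    "FEATURE_NAMES",
    "STAT_NAMES",
    "METRICS",
    "summarize_distribution",
    "build_feature_vector",
    "build_feature_table",
]

STAT_NAMES = ("median", "q1", "q3", "iqr", "skewness", "kurtosis")
METRICS = ("fit_mse", "damping_ratio", "latency", "amplitude", "peak_velocity")
_TASK_PREFIX = {"ps": PS_CORRECT, "as": AS_CORRECT}

FEATURE_NAMES = tuple(
    f"{task}_{metric}_{stat}"
    for task in ("ps", "as")
    for metric in METRICS
    for stat in STAT_NAMES
) + ("as_error_rate",)

# Saccade-table column feeding each feature metric.
_METRIC_COLUMNS = {
    "fit_mse": "fit_mse",
    "damping_ratio": "sigma",
    "latency": "latency_ms",
    "amplitude": "amplitude_deg",
    "peak_velocity": "peak_velocity_deg_s",
}


def summarize_distribution(values):
    """Six summary statistics of a sample.

    Quartiles use linear interpolation between order statistics.  Skewness
    is the adjusted Fisher-Pearson coefficient and kurtosis is excess
    kurtosis, both bias-corrected; they require at least 3 (skewness) / 4
    (kurtosis) observations with at least 3 distinct values, else NaN.
    Empty input gives an all-NaN result.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    out = dict.fromkeys(STAT_NAMES, np.nan)
    if v.size == 0:
        return out
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    out.update(median=med, q1=q1, q3=q3, iqr=q3 - q1)
    distinct = np.unique(v).size
    if v.size >= 3 and distinct >= 3 and np.std(v) > 0:
        out["skewness"] = float(sps.skew(v, bias=False))
        if v.size >= 4:
            out["kurtosis"] = float(sps.kurtosis(v, fisher=True, bias=False))
    return out


def build_feature_vector(saccades: pd.DataFrame):
    """Reduce one participant's QC'd, response-typed saccade table to the
    61 named features.

    Expects columns ``response_type``, ``latency_ms``, ``amplitude_deg``,
    ``peak_velocity_deg_s`` and, for fit-derived metrics, ``sigma``,
    ``fit_mse`` and a boolean ``fit_kept`` marking fits that survived the
    damping-ratio precision filter.  Prosaccade features come from correct
    prosaccades, antisaccade features from correct antisaccades only; the
    error rate is AS errors over all directional AS responses.
    """
    feats = {}
    for prefix, rtype in _TASK_PREFIX.items():
        sub = saccades[saccades["response_type"] == rtype]
        for metric in METRICS:
            col = _METRIC_COLUMNS[metric]
            if col in sub.columns:
                vals = sub[col]
                if metric in ("fit_mse", "damping_ratio") and "fit_kept" in sub.columns:
                    vals = vals[sub["fit_kept"].fillna(False).astype(bool)]
            else:
                vals = pd.Series(dtype=float)
            stats = summarize_distribution(vals)
            for stat in STAT_NAMES:
                feats[f"{prefix}_{metric}_{stat}"] = stats[stat]
    n_err = int((saccades["response_type"] == AS_ERROR).sum())
    n_cor = int((saccades["response_type"] == AS_CORRECT).sum())
    denom = n_err + n_cor
    feats["as_error_rate"] = n_err / denom if denom else np.nan
    return feats


def build_feature_table(saccade_table: pd.DataFrame) -> pd.DataFrame:
    """Participant x 61 feature table from a pooled saccade-level table.

    ``saccade_table`` must carry ``participant_id`` and ``group`` columns
    in addition to the per-saccade columns of :func:`build_feature_vector`.
    """
    rows = []
    for (pid, group), sub in saccade_table.groupby(
        ["participant_id", "group"], sort=True
    ):
        row = {"participant_id": pid, "group": group}
        row.update(build_feature_vector(sub))
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "group", *FEATURE_NAMES])
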