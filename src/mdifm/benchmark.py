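"""Force-field benchmarking against a reference potential.

Given per-force-field tables of ω₀, σ and τ_c (with 95% half-widths), this
module computes percent differences relative to a designated reference
(conventionally the many-body MB-pol potential), propagates uncertainties
to first order, flags significance by whether the propagated interval
excludes zero, and emits the (reference, force field) correlation pairs
used for y = x scatter plots.

Sign convention: percent difference = 100·(value − reference)/reference,
so positive values mean the reference predicted the lower number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "METRICS",
    "percent_difference",
    "propagate_difference_uncertainty",
    "metric_table",
    "build_benchmark",
]

METRICS = ("omega0", "sigma", "tau_c")
METRIC_TABLE_COLUMNS = ["force_field", "mode", "metric", "value", "err"]


def percent_difference(value: float, reference: float) -> float:
    """100·(value − reference)/reference; positive ⇒ reference is lower."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (value - reference) / reference


def propagate_difference_uncertainty(
    value: float, err_value: float, reference: float, err_reference: float
) -> float:
    """First-order 95% half-width of the percent difference.

    Treats the two measurements as independent:
    100·sqrt((e₁/r)² + (v·e₂/r²)²).
    """
    if err_value < 0 or err_reference < 0:
        raise ValueError("uncertainties must be non-negative")
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * float(
        np.sqrt((err_value / reference) ** 2 + (value * err_reference / reference**2) ** 2)
    )


def metric_table(rows: list[dict]) -> pd.DataFrame:
    """Validate and assemble a metric table from row dicts.

    Each row needs force_field, mode, metric ∈ {omega0, sigma, tau_c},
    value and err (95% half-width).
    """
    df = pd.DataFrame(rows)
    missing = set(METRIC_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    bad = df[~df["metric"].isin(METRICS)]
    if len(bad):
        raise ValueError(f"unknown metric names: {sorted(bad['metric'].unique())}")
    dup = df.duplicated(["force_field", "mode", "metric"])
    if dup.any():
        raise ValueError("duplicate (force_field, mode, metric) rows")
    if not np.isfinite(df["value"]).all():
        raise ValueError("metric values must be finite")
    return df[METRIC_TABLE_COLUMNS].reset_index(drop=True)


def build_benchmark(
    table: pd.DataFrame, reference: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent-difference table and correlation pairs against a reference.

    Returns ``(differences, pairs)``. ``differences`` has one row per
    (non-reference force field, mode, metric) with the percent difference,
    its propagated 95% half-width and a significance flag (interval
    excludes zero). ``pairs`` holds (reference value, force-field value)
    per cell for correlation plots. Missing cells raise with the full gap
    list.
    """
    table = metric_table(table.to_dict("records"))
    ffs = list(dict.fromkeys(table["force_field"]))
    if reference not in ffs:
        raise ValueError(f"reference {reference!r} not present in the table")
    modes = sorted(table["mode"].unique())
    metrics = [m for m in METRICS if m in set(table["metric"])]

    indexed = table.set_index(["force_field", "mode", "metric"])
    gaps = [
        (ff, mode, metric)
        for ff in ffs
        for mode in modes
        for metric in metrics
        if (ff, mode, metric) not in indexed.index
    ]
    if gaps:
        raise ValueError(f"metric table has missing cells: {gaps}")

    diff_rows, pair_rows = [], []
    for ff in ffs:
        if ff == reference:
            continue
        for mode in modes:
            for metric in metrics:
                v, e1 = indexed.loc[(ff, mode, metric)]
                r, e2 = indexed.loc[(reference, mode, metric)]
                pct = percent_difference(v, r)
                hw = propagate_difference_uncertainty(v, e1, r, e2)
                diff_rows.append({
                    "force_field": ff, "mode": mode, "metric": metric,
                    "percent": pct, "percent_err": hw,
                    "significant": bool(abs(pct) > hw),
                })
                pair_rows.append({
                    "force_field": ff, "mode": mode, "metric": metric,
                    "reference_value": r, "value": v,
                })
    return pd.DataFrame(diff_rows), pd.DataFrame(pair_rows)
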