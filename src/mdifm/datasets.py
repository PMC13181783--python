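"""Bundled reference data.

``water_ff_table`` carries published MD-IFM vibrational observables for
five classical water force fields and the MB-pol reference: ω₀ and σ in
cm⁻¹ and τ_c in ps for the HOD bend, OD stretch and OH stretch, each with
its 95% half-width. These are inputs for the benchmark module (percent
differences, correlation pairs), not values this package recomputes.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["water_ff_table", "REFERENCE_FORCE_FIELD"]

REFERENCE_FORCE_FIELD = "MB-pol"

# force_field: {mode: (omega0, err, sigma, err, tau_c, err)}
_TABLE = {
    "TIP3P": {
        "bend": (1350.2, 0.5, 26.0, 0.3, 0.23, 0.02),
        "OD": (2520.0, 2.0, 70.0, 5.0, 0.39, 0.01),
        "OH": (3468.0, 2.0, 95.0, 7.0, 0.43, 0.03),
    },
    "SPC/E": {
        "bend": (1339.8, 0.5, 27.4, 0.5, 0.86, 0.07),
        "OD": (2473.0, 2.0, 82.0, 6.0, 0.80, 0.04),
        "OH": (3406.0, 2.0, 115.0, 7.0, 0.65, 0.03),
    },
    "TIP4P/Ew": {
        "bend": (1348.5, 0.5, 25.5, 0.6, 0.40, 0.03),
        "OD": (2498.0, 2.0, 75.0, 5.0, 0.80, 0.05),
        "OH": (3418.0, 2.0, 109.0, 6.0, 0.83, 0.05),
    },
    "OPC": {
        "bend": (1341.2, 0.5, 24.0, 1.0, 0.44, 0.07),
        "OD": (2551.0, 1.0, 63.0, 2.0, 0.64, 0.02),
        "OH": (3507.0, 2.0, 85.0, 4.0, 0.85, 0.04),
    },
    "TIP5P": {
        "bend": (1346.1, 0.5, 25.8, 0.6, 0.95, 0.05),
        "OD": (2488.0, 2.0, 82.0, 8.0, 0.69, 0.02),
        "OH": (3426.0, 2.0, 110.0, 10.0, 1.09, 0.03),
    },
    "MB-pol": {
        "bend": (1340.9, 0.6, 28.9, 0.7, 0.51, 0.04),
        "OD": (2470.0, 2.0, 82.0, 5.0, 1.21, 0.06),
        "OH": (3403.0, 2.0, 115.0, 8.0, 1.34, 0.08),
    },
}


def water_ff_table() -> pd.DataFrame:
    """Published benchmark observables in the metric-table schema.

    Columns: force_field, mode, metric ∈ {omega0, sigma, tau_c}, value,
    err (95% half-width). Suitable as direct input to
    :func:`mdifm.benchmark.build_benchmark`.
    """
    rows = []
    for ff, modes in _TABLE.items():
        for mode, (om, om_e, sg, sg_e, tc, tc_e) in modes.items():
            rows += [
                {"force_field": ff, "mode": mode, "metric": "omega0", "value": om, "err": om_e},
                {"force_field": ff, "mode": mode, "metric": "sigma", "value": sg, "err": sg_e},
                {"force_field": ff, "mode": mode, "metric": "tau_c", "value": tc, "err": tc_e},
            ]
    return pd.DataFrame(rows)
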