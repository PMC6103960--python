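"""Published benchmark measurements for regression-testing the metrics suite.

A dual-layer spectral CT phantom evaluation reported per-insert relative
electron densities for an 18-material set (12 tissue surrogates plus 6
sensitometry plastics) estimated at a standard 20 mGy dose by both the
cross-sectional (Lehmann) inversion and the phantom-calibrated (Saito)
conversion, alongside the manufacturer nominal values.  Those printed
per-insert numbers are reproduced here as the package's reference input:
feeding them through :mod:`rhoct.metrics` must regenerate the published
summary statistics (RMSE, NRMSE, correlation, regression) to the printed
rounding, which pins the statistical definitions used in this package to
the field's.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["benchmark_estimates", "BENCHMARK_DOSE_MGY"]

#: Dose (CTDIvol, mGy) at which the benchmark estimates were measured.
BENCHMARK_DOSE_MGY = 20.0

# label, phantom, nominal rho_rel, Lehmann estimate, Saito estimate
_ROWS = [
    ("SB3 cortical bone", "gammex467", 1.696, 1.675, 1.702),
    ("CB2 50% CaCO3", "gammex467", 1.471, 1.463, 1.472),
    ("CB2 30% CaCO3", "gammex467", 1.280, 1.282, 1.276),
    ("B200 bone mineral", "gammex467", 1.109, 1.116, 1.107),
    ("IB inner bone", "gammex467", 1.107, 1.114, 1.106),
    ("LV1 liver", "gammex467", 1.062, 1.081, 1.061),
    ("BRN-SR2 brain", "gammex467", 1.047, 1.064, 1.041),
    ("CT water", "gammex467", 0.990, 1.026, 1.009),
    ("BR-12 breast", "gammex467", 0.961, 0.977, 0.959),
    ("AP6 adipose", "gammex467", 0.928, 0.941, 0.923),
    ("LN-450 lung", "gammex467", 0.466, 0.470, 0.471),
    ("LN-300 lung", "gammex467", 0.264, 0.246, 0.255),
    ("Teflon", "catphan504", 1.868, 1.895, 1.850),
    ("Delrin", "catphan504", 1.363, 1.373, 1.341),
    ("Acrylic", "catphan504", 1.147, 1.161, 1.135),
    ("Polystyrene", "catphan504", 0.998, 1.014, 0.992),
    ("LDPE", "catphan504", 0.945, 0.959, 0.939),
    ("PMP", "catphan504", 0.853, 0.866, 0.850),
]


def benchmark_estimates(method: str = "lehmann", phantom: str | None = None) -> pd.DataFrame:
    """Benchmark (label, rho_est, rho_nom) pairs for one estimation method.

    Parameters
    ----------
    method : {'lehmann', 'saito'}
    phantom : {'gammex467', 'catphan504'} or None
        Restrict to one phantom; None returns all 18 rows.
    """
    col = {"lehmann": 3, "saito": 4}
    if method not in col:
        raise ValueError(f"method must be 'lehmann' or 'saito', got {method!r}")
    rows = [r for r in _ROWS if phantom is None or r[1] == phantom]
    if not rows:
        raise ValueError(f"unknown phantom {phantom!r}")
    return pd.DataFrame(
        {
            "label": [r[0] for r in rows],
            "phantom": [r[1] for r in rows],
            "rho_nom": [r[2] for r in rows],
            "rho_est": [r[col[method]] for r in rows],
        }
    )
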