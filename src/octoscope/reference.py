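"""Bundled reference feature vectors.

Nine-feature descriptors measured from clinically acquired OCT B-scans,
five cases per class. They serve as arithmetic cross-checks for the
feature-table summaries and as per-class statistics from which
statistically matched synthetic training sets can be drawn when no imagery
is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

# (f1, f2, f3, f4, f5, f6, f7, f8, f9) per case
_CASES = {
    "healthy": [
        (36.51, 11.38, 25.13, 124.27, 1165.2, 1.20, -0.36, 1.56, 24.070),
        (39.69, 27.02, 12.67, 140.28, 1328.8, 0.87, -0.80, 1.67, 29.060),
        (34.13, 19.58, 14.55, 0.0, 0.0, 0.80, -0.57, 1.37, 26.008),
        (50.54, 32.55, 17.99, 126.71, 1124.1, 4.00, -2.56, 6.56, 68.206),
        (38.36, 18.26, 20.10, 174.34, 983.24, 0.93, -0.36, 1.29, 32.036),
    ],
    "CSCR": [
        (64.29, 38.10, 26.19, 11827.0, 10417.0, 1.40, -0.26, 1.66, 32.010),
        (82.02, 42.33, 39.69, 20981.0, 8570.6, 1.72, -0.79, 2.51, 31.050),
        (68.79, 34.66, 34.13, 22936.0, 12061.0, 0.76, -0.65, 1.41, 27.038),
        (63.50, 43.39, 20.11, 8724.1, 12940.0, 3.96, -3.12, 7.08, 78.519),
        (71.70, 35.98, 35.72, 26443.0, 13051.0, 0.89, -0.65, 1.54, 42.213),
    ],
    "RE": [
        (72.23, 36.25, 35.98, 7023.8, 56835.0, 1.32, -0.56, 1.88, 42.030),
        (48.42, 25.66, 22.76, 18400.0, 32093.0, 1.75, -0.49, 2.24, 31.430),
        (49.48, 21.96, 27.52, 14619.0, 23180.0, 0.72, -0.75, 1.47, 37.148),
        (62.18, 33.07, 29.11, 27120.0, 27419.0, 4.93, -2.42, 7.35, 58.159),
        (65.62, 39.43, 26.19, 3201.17, 25871.0, 0.69, -0.15, 0.84, 39.535),
    ],
    "ARMD": [
        (32.83, 16.25, 16.58, 1523.0, 1147.1, 10.93, -1.20, 12.13, 118.47),
        (38.22, 25.36, 12.86, 2040.9, 1452.7, 13.08, -1.64, 14.72, 207.68),
        (39.18, 16.66, 22.52, 1534.1, 1365.2, 16.48, -5.60, 22.08, 439.89),
        (47.58, 30.37, 17.21, 1670.2, 1678.3, 11.37, -2.35, 13.72, 140.38),
        (35.72, 12.22, 23.50, 2019.5, 417.26, 11.93, -0.88, 12.81, 106.29),
    ],
}


def reference_feature_table() -> pd.DataFrame:
    """The 20 reference cases as a tidy feature table (f1..f9 + label)."""
    rows = []
    for label, cases in _CASES.items():
        for case in cases:
            rows.append(dict(zip(FEATURE_NAMES, case), label=label))
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label"])


def sample_reference_like(n_per_class: int, seed: int) -> pd.DataFrame:
    """Synthetic feature table drawn per class from the reference statistics.

    Each class is modeled as an independent Gaussian per feature with the
    reference per-class mean and sample SD. Useful for exercising the
    classifier cascade without imagery.
    """
    rng = np.random.default_rng(seed)
    table = reference_feature_table()
    rows = []
    for label, grp in table.groupby("label", sort=False):
        mu = grp[list(FEATURE_NAMES)].mean().to_numpy()
        sd = grp[list(FEATURE_NAMES)].std(ddof=1).to_numpy()
        draws = rng.normal(mu, sd, size=(n_per_class, len(FEATURE_NAMES)))
        for d in draws:
            rows.append(dict(zip(FEATURE_NAMES, d), label=label))
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label"])
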