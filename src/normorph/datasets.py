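"""Small bundled example datasets.

``ms_followup_demographics`` is the demographic and clinical summary of a
published five-patient relapsing-remitting multiple-sclerosis follow-up
cohort (55 scans total, natalizumab-treated, all female, single 3T
scanner).  It is used in examples and as a worked arithmetic reference:
follow-up spans derive from the first/last scan ages, and per-patient mean
scan intervals are the reported values.
"""

from __future__ import annotations

import pandas as pd


def ms_followup_demographics() -> pd.DataFrame:
    """Per-patient demographics of the example MS follow-up cohort.

    Columns: sex, age at first and last scan (years), number of scans,
    reported mean inter-scan interval (years), EDSS at first/last scan
    (NaN where not assessed) and the reported annual EDSS change rate.
    """
    rows = [
        # patient, sex, age_first, age_last, n_scans, mean_interval, edss_first, edss_last, edss_rate
        ("pat1", "F", 16.32, 22.19, 10, 0.65, 1.5, 1.0, -0.087),
        ("pat2", "F", 29.93, 35.24, 13, 0.48, None, None, None),
        ("pat3", "F", 31.72, 36.78, 11, 0.56, 2.0, 4.0, 0.435),
        ("pat4", "F", 21.43, 25.09, 10, 0.52, 1.5, 1.0, -0.169),
        ("pat5", "F", 41.41, 46.67, 11, 0.53, 2.0, 2.0, 0.067),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "sex", "age_first", "age_last", "n_scans",
            "mean_interval", "edss_first", "edss_last", "edss_annual_rate",
        ],
    ).astype({"age_first": float, "age_last": float, "mean_interval": float})
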