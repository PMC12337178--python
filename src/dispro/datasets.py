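"""Small built-in example datasets (synthetic reconstructions).

:func:`published_profile_cohort` rebuilds, record by record, a cohort whose
marginal counts equal those of a published post-marketing safety profile of
a myelofibrosis drug (1,940 primary-suspect reports: 356 with known sex,
634 serious, 470 with computable time-to-onset, and so on).  The individual
records are synthetic — only the printed marginal counts are encoded — so
the dataset serves as a worked example and as a fixture for exercising the
descriptive-summary denominator rules end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_TOTAL = 1940


def _onset_days_470() -> np.ndarray:
    """470 onset values with median 27, quartiles 2 and 115.75 (linear
    interpolation), and bin counts 244 / 87 / 123 / 16 over
    [0,30] / (30,90] / (90,365] / (365, inf)."""
    seg = [
        np.linspace(0, 2, 118),     # idx 0..117, ends at 2
        np.linspace(2, 27, 118),    # idx 118..235, ends at 27
        np.linspace(27, 30, 8),     # idx 236..243
        np.linspace(31, 90, 87),    # idx 244..330
        np.linspace(91, 115, 21),   # idx 331..351, ends at 115
        np.array([116.0]),          # idx 352
        np.linspace(117, 365, 101), # idx 353..453
        np.linspace(366, 500, 16),  # idx 454..469
    ]
    days = np.rint(np.concatenate(seg)).astype(int)
    days[234] = days[235] = 27
    days[117] = days[118] = 2
    assert np.all(np.diff(days) >= 0)
    return days


def _ages_338() -> np.ndarray:
    """338 known ages: 92 in 18..65, 246 above, median 72, quartiles 65/77."""
    seg = [
        np.linspace(18, 64, 84),    # idx 0..83
        np.full(8, 65.0),           # idx 84..91  -> Q1 = 65
        np.linspace(66, 72, 77),    # idx 92..168 -> median 72
        np.linspace(72, 77, 85),    # idx 169..253 -> Q3 = 77
        np.linspace(78, 99, 84),    # idx 254..337
    ]
    ages = np.rint(np.concatenate(seg)).astype(int)
    ages[168] = ages[169] = 72
    ages[252] = ages[253] = 77
    assert np.all(np.diff(ages) >= 0) and len(ages) == 338
    return ages


def published_profile_cohort() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return ``(demo, outc, ps_mentions)`` frames for the worked example.

    Marginals encoded: sex known for 356 (156 F / 200 M); age known for 338
    (92 aged 18-65, 246 over 65; median 72, IQR 65-77); countries 1922 US /
    4 PL / 14 other; reporters known for 1925 (293 professional / 1632
    consumer); receipt years 375 / 1073 / 492 over 2022-2024; 634 serious
    reports carrying 220 death, 2 life-threatening, 335 hospitalisation and
    185 other-serious codes (codes overlap); 470 reports with a computable
    time-to-onset whose median is 27 days (IQR 2-115.75).
    """
    n = N_TOTAL
    ids = np.array([str(3_000_000 + i) for i in range(n)])

    sex = np.array([""] * n, dtype=object)
    sex[:156] = "F"
    sex[156:356] = "M"

    age_years = np.full(n, np.nan)
    age_years[:338] = _ages_338()

    country = np.array(["US"] * n, dtype=object)
    country[:4] = "PL"
    country[4:18] = "GB"

    occp = np.array([""] * n, dtype=object)
    occp[:293] = "MD"
    occp[293:1925] = "CN"

    fda_dt = np.array([""] * n, dtype=object)
    fda_dt[:375] = "20220601"
    fda_dt[375:1448] = "20230601"
    fda_dt[1448:] = "20240301"
    report_year = pd.to_numeric(pd.Series(fda_dt).str.slice(0, 4)).astype("Int64")

    # 470 evaluable onsets: therapy start 2022-01-01, event = start + days
    onset = _onset_days_470()
    start = np.array([""] * n, dtype=object)
    event = np.array([""] * n, dtype=object)
    base = np.datetime64("2022-01-01")
    start[:470] = "20220101"
    ev = base + onset
    event[:470] = np.char.replace(np.datetime_as_string(ev, unit="D"), "-", "")

    demo = pd.DataFrame({
        "primaryid": ids, "caseid": ids, "sex": sex, "age_years": age_years,
        "occr_country": country, "occp_cod": occp, "fda_dt": fda_dt,
        "report_year": report_year, "event_dt": event,
    })

    # 634 serious reports (ids 0..633); overlapping codes: death 0..219,
    # LT 220..221, hospitalisation 222..556, other 557..633 and 0..107
    rows = []
    for i in range(220):
        rows.append((ids[i], "DE"))
    for i in range(220, 222):
        rows.append((ids[i], "LT"))
    for i in range(222, 557):
        rows.append((ids[i], "HO"))
    for i in range(557, 634):
        rows.append((ids[i], "OT"))
    for i in range(108):
        rows.append((ids[i], "OT"))
    outc = pd.DataFrame(rows, columns=["primaryid", "outc_cod"])

    ps_mentions = pd.DataFrame({
        "primaryid": ids, "drug_seq": "1", "role_cod": "1",
        "drugname": "pacritinib", "start_dt": start,
    })
    return demo, outc, ps_mentions
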