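"""Two-day moving-window transition surveillance.

Each window pairs a day with its predecessor and combines three p-values:
the one-sample uniformity tests of both days and the two-sample test
between them.  A *transition* between adherence and non-adherence is
flagged when the two days differ significantly (2S p < α) and exactly one
of them deviates significantly from uniformity (1S p < α): the day-level
evidence switched while the distribution itself changed.  Windows where
both days are significantly non-uniform yet differ from each other are
reported separately as ``shape_change`` (the timing pattern moved without
either day looking uniform); windows with any missing p-value are
``unevaluable`` and never flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ks import ALPHA_DEFAULT


def detect_transitions(
    ks1: pd.DataFrame, ks2: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Evaluate the transition rule over all consecutive-day windows.

    Parameters
    ----------
    ks1 : per-ward-day table with columns ward, day_index, p_value
        (from :func:`glucotime.ks.panel_ks1`; NaN = not computable).
    ks2 : per-window table with columns ward, day_index (the current day of
        the pair), p_value (from :func:`glucotime.ks.panel_ks2`).
    alpha : shared significance level.

    Returns one row per window: ward, day_prev, day_curr, p1_prev, p1_curr,
    p2, category ∈ {transition, shape_change, none, unevaluable}, flagged,
    and direction ∈ {to_adherence, to_nonadherence, none}.
    """
    p1 = ks1.set_index(["ward", "day_index"])["p_value"]
    if p1.index.has_duplicates:
        raise ValueError("ks1 has duplicate (ward, day) rows; inputs misaligned")
    rows = []
    for _, win in ks2.iterrows():
        ward, day = win["ward"], int(win["day_index"])
        key_prev, key_curr = (ward, day - 1), (ward, day)
        if key_prev not in p1.index or key_curr not in p1.index:
            raise ValueError(f"ks1 is missing day {day - 1} or {day} for ward {ward}")
        p1_prev, p1_curr, p2 = p1[key_prev], p1[key_curr], win["p_value"]
        if any(not np.isfinite(v) for v in (p1_prev, p1_curr, p2)):
            category, flagged, direction = "unevaluable", False, "none"
        else:
            sig_prev, sig_curr, sig2 = p1_prev < alpha, p1_curr < alpha, p2 < alpha
            if sig2 and (sig_prev != sig_curr):
                category, flagged = "transition", True
                direction = "to_adherence" if sig_curr else "to_nonadherence"
            elif sig2 and sig_prev and sig_curr:
                category, flagged, direction = "shape_change", False, "none"
            else:
                category, flagged, direction = "none", False, "none"
        rows.append(
            dict(ward=ward, day_prev=day - 1, day_curr=day,
                 p1_prev=p1_prev, p1_curr=p1_curr, p2=p2,
                 category=category, flagged=flagged, direction=direction)
        )
    return pd.DataFrame(rows)
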