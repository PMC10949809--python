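"""Study outcomes: four-year progression and per-subject MMSE slope.

The continuous outcome is the ordinary-least-squares slope of MMSE on time,
fitted separately for each subject from all follow-up points within four
years of baseline (closed interval).  The binary outcome is whether an AD
dementia diagnosis occurs within that window.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, UndefinedOutcomeError
from .synthetic import SubjectRecord

WINDOW_YEARS = 4.0


def mmse_slope(followups: Sequence[tuple[float, float]]) -> float:
    """OLS slope (points/year) of MMSE on time, points with time <= 4 only.

    Raises
    ------
    UndefinedOutcomeError
        fewer than two usable points.
    DegenerateDesignError
        all usable times identical (vertical design).
    """
    pts = [(t, y) for (t, y) in followups if 0.0 <= t <= WINDOW_YEARS]
    if len(pts) < 2:
        raise UndefinedOutcomeError(
            f"need >= 2 follow-up points within [0, {WINDOW_YEARS}] years, "
            f"got {len(pts)}")
    t = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    st = t - t.mean()
    denom = float(st @ st)
    if denom == 0.0:
        raise DegenerateDesignError("all follow-up times identical")
    return float(st @ (y - y.mean()) / denom)


def progression_label(
        diagnosis_timeline: Iterable[tuple[float, str]]) -> bool:
    """True iff an 'AD dementia' diagnosis occurs at time <= 4 years."""
    timeline = list(diagnosis_timeline)
    if not timeline:
        raise UndefinedOutcomeError("empty diagnosis timeline")
    return any(t <= WINDOW_YEARS and _is_ad(dx) for t, dx in timeline)


def _is_ad(diagnosis: str) -> bool:
    return diagnosis.strip().lower().replace("_", " ") in {
        "ad", "ad dementia", "alzheimer dementia"}


def derive_outcomes(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Outcomes table for a synthetic cohort.

    ``progressed_4y`` comes from the generator's group label (the generator
    does not simulate diagnosis timelines); ``mmse_slope_4y`` is fitted from
    the observed follow-ups.
    """
    rows = [{
        "subject_id": s.subject_id,
        "progressed_4y": s.progressed_4y,
        "mmse_slope_4y": mmse_slope(s.followups),
    } for s in cohort]
    return pd.DataFrame(rows, columns=[
        "subject_id", "progressed_4y", "mmse_slope_4y"])
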