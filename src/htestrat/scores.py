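"""Clinical hemorrhagic-transformation risk scores: DRAGON, SEDAN and HTI.

All three are additive on-admission point scores for patients considered for
(or treated with) intravenous thrombolysis.  Each point increment corresponds
to a higher probability of hemorrhagic transformation (HT) or poor outcome.

Component bands, as published:

DRAGON (range 0-10, functional outcome after IVT)
    HMCA sign / ASPECTS < 10: both = 2, either = 1, none = 0
    pre-stroke mRS > 1: 1
    age: >= 80 -> 2, 65-79 -> 1, < 65 -> 0
    glucose > 8 mmol/L: 1
    onset-to-treatment > 90 min: 1
    NIHSS: > 15 -> 3, 10-15 -> 2, 5-9 -> 1, 0-4 -> 0

SEDAN (range 0-6, symptomatic HT after IVT)
    glucose: 8.1-12.0 mmol/L -> 1, > 12.0 -> 2
    ASPECTS < 10: 1
    HMCA sign: 1
    age > 75: 1
    NIHSS >= 10: 1

HTI (range 0-8, any HT in MCA stroke)
    ASPECTS: 10-7 -> 0, 6-5 -> 1, 4-3 -> 2, 2-0 -> 3
    NIHSS: 0-11 -> 0, 12-17 -> 1, 18-23 -> 2, > 23 -> 3
    HMCA sign: 1
    atrial fibrillation on ECG: 1

HT risk is graded from HTI alone: low (HTI = 0), moderate (HTI = 1),
high (HTI >= 2).

Conventions (documented, not in the published component tables): ages are
floored to integer years before banding; the SEDAN glucose band "8.1-12.0"
is read literally as (8.0, 12.0] on the measured value with no rounding;
DRAGON onset-to-treatment scores 1 only for strictly more than 90 minutes.
"""

from __future__ import annotations

import math

__all__ = [
    "compute_dragon",
    "compute_sedan",
    "compute_hti",
    "grade_ht_risk",
    "HTI_ASPECTS_BANDS",
    "HTI_NIHSS_BANDS",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _check_common(aspects: int, nihss: int) -> None:
    _check(0 <= aspects <= 10, f"aspects must be in [0, 10], got {aspects}")
    _check(0 <= nihss <= 42, f"nihss must be in [0, 42], got {nihss}")


def compute_dragon(
    hmca: int,
    aspects: int,
    prestroke_mrs: int,
    age: float,
    glucose: float,
    onset_to_treatment: float,
    nihss: int,
) -> int:
    """DRAGON score, range 0-10."""
    _check_common(aspects, nihss)
    _check(hmca in (0, 1), "hmca must be 0/1")
    _check(0 <= prestroke_mrs <= 6, "prestroke_mrs must be in [0, 6]")
    _check(0 < age < 130, "age out of physiologic range")
    _check(0 < glucose < 60, "glucose out of physiologic range")
    _check(onset_to_treatment >= 0, "onset_to_treatment must be nonnegative")

    d = int(hmca) + int(aspects < 10)          # both = 2, either = 1, none = 0
    r = int(prestroke_mrs > 1)
    age_y = math.floor(age)
    a = 2 if age_y >= 80 else (1 if age_y >= 65 else 0)
    g = int(glucose > 8.0)
    o = int(onset_to_treatment > 90)
    if nihss > 15:
        n = 3
    elif nihss >= 10:
        n = 2
    elif nihss >= 5:
        n = 1
    else:
        n = 0
    return d + r + a + g + o + n


def compute_sedan(
    glucose: float, aspects: int, hmca: int, age: float, nihss: int
) -> int:
    """SEDAN score, range 0-6."""
    _check_common(aspects, nihss)
    _check(hmca in (0, 1), "hmca must be 0/1")
    _check(0 < age < 130, "age out of physiologic range")
    _check(0 < glucose < 60, "glucose out of physiologic range")

    if glucose > 12.0:
        s = 2
    elif glucose > 8.0:                         # band "8.1-12.0" read as (8.0, 12.0]
        s = 1
    else:
        s = 0
    e = int(aspects < 10)
    d = int(hmca)
    a = int(math.floor(age) > 75)
    n = int(nihss >= 10)
    return s + e + d + a + n


#: HTI component bands: (inclusive low, inclusive high) -> points.
HTI_ASPECTS_BANDS = {(7, 10): 0, (5, 6): 1, (3, 4): 2, (0, 2): 3}
HTI_NIHSS_BANDS = {(0, 11): 0, (12, 17): 1, (18, 23): 2, (24, 42): 3}


def _band(value: int, bands: dict[tuple[int, int], int]) -> int:
    for (lo, hi), pts in bands.items():
        if lo <= value <= hi:
            return pts
    raise ValueError(f"value {value} outside banded range")


def compute_hti(aspects: int, nihss: int, hmca: int, af_ecg: int) -> int:
    """Hemorrhagic Transformation Index (HTI), range 0-8."""
    _check_common(aspects, nihss)
    _check(hmca in (0, 1), "hmca must be 0/1")
    _check(af_ecg in (0, 1), "af_ecg must be 0/1")
    return (_band(aspects, HTI_ASPECTS_BANDS) + _band(nihss, HTI_NIHSS_BANDS)
            + int(hmca) + int(af_ecg))


def grade_ht_risk(hti: int) -> str:
    """Grade HT risk from HTI: 0 -> 'low', 1 -> 'moderate', >= 2 -> 'high'."""
    if not 0 <= hti <= 8:
        raise ValueError(f"hti must be in [0, 8], got {hti}")
    return "low" if hti == 0 else ("moderate" if hti == 1 else "high")
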