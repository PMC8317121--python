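"""Fast/medium/slow tercile classification and the fsmf agreement statistic.

Each position of a normalized occupancy profile is labelled *fast*, *medium*
or *slow* according to whether it falls in the bottom, middle or top third
of occupancy values within that profile.  The fsmf value of two profiles in
shared coordinates is the fraction of positions carrying the same label in
both.  Because the classification is rank-based, fsmf is invariant under any
strictly increasing transform applied to a profile, and two independent
profiles agree at a rate approaching 1/3 as their length grows
(3 classes x (1/3)^2 each).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

FAST, MEDIUM, SLOW = 0, 1, 2
LABEL_NAMES = {FAST: "fast", MEDIUM: "medium", SLOW: "slow"}


def _values(profile) -> np.ndarray:
    # Accept raw vectors or ProcessedProfile-like objects with .values
    vals = getattr(profile, "values", profile)
    return np.asarray(vals, dtype=float)


def classify_speeds(profile: Sequence[float]) -> np.ndarray:
    """Label each position fast (0), medium (1) or slow (2) by occupancy rank.

    Positions are ranked by value ascending with ties broken stably by
    position index; the position of rank r out of L receives label
    ``floor(3 r / L)``, so class sizes differ by at most one and any
    remainder positions go to the lower-occupancy classes first.
    """
    values = _values(profile)
    n = len(values)
    if n < 3:
        raise ValueError(f"profile of length {n} cannot be split into terciles")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=np.int8)
    labels[order] = (3 * np.arange(n)) // n
    return labels


def fsmf(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Fraction of positions with the same fast/medium/slow label in both profiles.

    The two profiles must already be in shared coordinates (same length).
    Returns a value in [0, 1]; identical profiles give 1.0.
    """
    a = _values(profile_a)
    b = _values(profile_b)
    if len(a) != len(b):
        raise ValueError(f"profile lengths differ: {len(a)} vs {len(b)}")
    return float(np.mean(classify_speeds(a) == classify_speeds(b)))
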