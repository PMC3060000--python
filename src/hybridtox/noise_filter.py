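"""Monotonicity-enforcing noise filter for qHTS concentration-response curves.

Cell-viability qHTS readouts are noisy: responses jitter around baseline at
low concentrations and single points can spike or dip far from the curve.
For a cytotoxic compound the idealized response (percent loss of viability)
is non-decreasing with concentration, so departures from monotonicity beyond
assay variability are treated as noise and repaired rather than fitted.

Two parameters control the filter:

THR (baseline threshold, percent)
    The largest deviation of a response from baseline (no cell death) that is
    still treated as baseline.  Responses with ``|r| < THR`` are zeroed.
MXDV (maximum curve deviation, percent)
    The largest drop between the running maximum of the curve and a later
    response that is still considered "unchanged".  Larger drops are flagged
    as monotonicity violations.

Violating points are replaced from their neighbors: each maximal run of
flagged points is linearly interpolated between the nearest non-flagged
responses on either side, and a flagged run at the high-concentration end is
replaced by the last non-flagged response (constant extension).  The filter
is deliberately a point-replacement scheme, not a Hill/4PL regression: it
never invents a parametric shape, only restores monotonicity-within-MXDV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .qhts_io import ConcentrationResponseProfile

__all__ = [
    "FilterLog",
    "FilterParams",
    "apply_baseline_threshold",
    "enforce_monotonicity",
    "filter_profile",
    "filter_profiles",
    "monotonicity_violations",
]


@dataclass(frozen=True)
class FilterParams:
    """Noise-filter settings, both in percent-response units."""

    thr: float = 15.0
    mxdv: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.thr <= 100.0):
            raise ValueError(f"thr must be in [0, 100], got {self.thr}")
        if not (0.0 <= self.mxdv <= 100.0):
            raise ValueError(f"mxdv must be in [0, 100], got {self.mxdv}")


@dataclass(frozen=True)
class FilterLog:
    """Indices modified by each stage, for per-curve reporting."""

    zeroed: tuple[int, ...]    # baseline-thresholded (or negative-clipped) points
    replaced: tuple[int, ...]  # monotonicity-violating points that were repaired


def _threshold(responses: np.ndarray, thr: float) -> np.ndarray:
    out = responses.copy()
    out[np.abs(out) < thr] = 0.0
    np.clip(out, 0.0, None, out=out)  # surviving viability *increases* are clipped
    return out


def apply_baseline_threshold(
    profile: ConcentrationResponseProfile, thr: float
) -> ConcentrationResponseProfile:
    """Zero every response within ``thr`` of baseline; clip survivors at 0.

    ``thr = 0`` is the no-threshold setting: nothing is zeroed, but negative
    responses (apparent viability increase) are still clipped to 0 so that all
    downstream descriptors live on the 0-100 toxicity scale.
    """
    if not (0.0 <= thr <= 100.0):
        raise ValueError(f"thr must be in [0, 100], got {thr}")
    r = np.asarray(profile.responses, dtype=float)
    return profile.with_responses(_threshold(r, thr))


def monotonicity_violations(responses: Sequence[float], mxdv: float) -> list[int]:
    """Indices that fall more than ``mxdv`` below the running maximum.

    The running maximum is taken over preceding *non-flagged* points, so a
    multi-point dip is flagged as a unit instead of re-anchoring the baseline
    partway down.  The first point can never be flagged.
    """
    r = np.asarray(responses, dtype=float)
    flagged: list[int] = []
    run_max = -np.inf
    for i, value in enumerate(r):
        if value < run_max - mxdv:
            flagged.append(i)
        else:
            run_max = max(run_max, value)
    return flagged


def _repair(responses: np.ndarray, mxdv: float) -> tuple[np.ndarray, list[int]]:
    flagged = monotonicity_violations(responses, mxdv)
    if not flagged:
        return responses.copy(), []
    out = responses.copy()
    flag_set = set(flagged)
    n = len(out)
    i = 0
    while i < n:
        if i not in flag_set:
            i += 1
            continue
        start = i
        while i < n and i in flag_set:
            i += 1
        end = i - 1            # maximal flagged run [start, end]
        left = start - 1       # exists: the first point is never flagged
        right = end + 1
        if right >= n:
            out[start : end + 1] = out[left]  # constant extension at the top end
        else:
            span = right - left
            for j in range(start, end + 1):
                t = (j - left) / span
                out[j] = out[left] + t * (out[right] - out[left])
    return out, flagged


def enforce_monotonicity(
    profile: ConcentrationResponseProfile, mxdv: float
) -> ConcentrationResponseProfile:
    """Repair monotonicity violations by neighbor interpolation.

    On return, ``r[i+1] >= r[i] - mxdv`` holds at every adjacent pair, and no
    repaired value exceeds the original curve maximum.
    """
    if not (0.0 <= mxdv <= 100.0):
        raise ValueError(f"mxdv must be in [0, 100], got {mxdv}")
    r = np.asarray(profile.responses, dtype=float)
    repaired, _ = _repair(r, mxdv)
    return profile.with_responses(repaired)


def filter_profile(
    profile: ConcentrationResponseProfile,
    params: FilterParams,
    return_log: bool = False,
):
    """Full noise filter: baseline threshold (THR) first, then monotonicity (MXDV).

    Thresholding runs first so that baseline jitter cannot seed a false
    running maximum for the monotonicity pass.  The operation is idempotent.
    """
    r = np.asarray(profile.responses, dtype=float)
    thresholded = _threshold(r, params.thr)
    repaired, replaced = _repair(thresholded, params.mxdv)
    out = profile.with_responses(repaired)
    if return_log:
        zeroed = tuple(int(i) for i in np.nonzero(thresholded != r)[0])
        return out, FilterLog(zeroed=zeroed, replaced=tuple(replaced))
    return out


def filter_profiles(
    profiles: Sequence[ConcentrationResponseProfile], params: FilterParams
) -> list[ConcentrationResponseProfile]:
    return [filter_profile(p, params) for p in profiles]
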