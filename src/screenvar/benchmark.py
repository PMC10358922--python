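"""Missed-screens counterfactual against a centile benchmark.

Quantifies how many additional screens would have occurred if every area
below a chosen centile of the smoothed participation distribution (default:
the 80th centile, i.e. the top 20% of ranked areas) had screened at that
centile's level, and the national participation rate that would imply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .standardization import ScreeningCounts

__all__ = ["BenchmarkResult", "centile_threshold", "missed_screens"]


@dataclass
class BenchmarkResult:
    """Counterfactual summary of screens missed below the benchmark."""

    centile: float
    threshold_sspr: float
    extra_per_area: np.ndarray
    total_extra: int
    baseline_rate: float
    counterfactual_rate: float
    mode: str = "expected"
    screened_total: int = 0

    @property
    def extra_pct_of_screened(self) -> float:
        """Extra screens as a percentage of those actually conducted."""
        if not self.screened_total:
            return float("nan")
        return 100.0 * self.total_extra / self.screened_total


def centile_threshold(sspr: np.ndarray, centile: float = 80.0) -> float:
    """Value at the stated centile of the unweighted area distribution,
    nearest-rank definition: the ceil(centile/100 * n)-th smallest value."""
    sspr = np.asarray(sspr, dtype=float)
    if sspr.size == 0:
        raise ValueError("empty sSPR vector")
    if not 0.0 < centile < 100.0:
        raise ValueError("centile must lie strictly between 0 and 100")
    rank = math.ceil(centile / 100.0 * sspr.size)
    return float(np.sort(sspr)[rank - 1])


def missed_screens(
    sspr: np.ndarray,
    expected: pd.DataFrame | np.ndarray,
    threshold: float,
    counts: ScreeningCounts | None = None,
    centile: float = 80.0,
    mode: str = "expected",
) -> BenchmarkResult:
    """Extra screens if all areas below ``threshold`` reached it.

    In the default ``"expected"`` mode each area below the benchmark
    contributes max(0, threshold - sspr_i) * E_i extra screens -- the gap
    on the same SPR scale the areas were ranked on.  The ``"invitees"``
    sensitivity mode scales the gap by observed invitees times the national
    rate instead.  The counterfactual national rate adds the total extra to
    observed screens over observed invitees (requires ``counts``).
    """
    sspr = np.asarray(sspr, dtype=float)
    if isinstance(expected, pd.DataFrame):
        E = expected["expected"].to_numpy(float)
    else:
        E = np.asarray(expected, dtype=float)
    if sspr.shape != E.shape:
        raise ValueError("sSPR and expected counts are not aligned")
    if (E < 0).any():
        raise ValueError("expected counts must be non-negative")

    gap = np.maximum(0.0, threshold - sspr)
    if mode == "expected":
        extra = gap * E
    elif mode == "invitees":
        if counts is None:
            raise ValueError("invitee mode requires observed counts")
        inv = counts.area["invitees"].to_numpy(float)
        scr = counts.area["screened"].to_numpy(float)
        nat_rate = scr.sum() / inv.sum()
        extra = gap * inv * nat_rate
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total_extra = int(round(extra.sum()))

    baseline = counterfactual = float("nan")
    screened_total = 0
    if counts is not None:
        inv = counts.area["invitees"].sum()
        scr = counts.area["screened"].sum()
        screened_total = int(scr)
        baseline = 100.0 * scr / inv
        counterfactual = 100.0 * (scr + total_extra) / inv
    return BenchmarkResult(
        centile=centile, threshold_sspr=float(threshold),
        extra_per_area=extra, total_extra=total_extra,
        baseline_rate=baseline, counterfactual_rate=counterfactual, mode=mode,
        screened_total=screened_total,
    )
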