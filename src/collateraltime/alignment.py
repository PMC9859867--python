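"""Temporal alignment of multiphase CTA acquisitions to the CTP time axis.

The three mCTA volumes have known inter-acquisition delays but an unknown
start time relative to the CTP injection. The alignment places them on the
CTP time axis by minimizing the summed absolute difference between the
three mCTA AV enhancement ratios and the CTP AV-ratio curve evaluated at
the three candidate times — an exhaustive grid search (default 0.1 s step)
with linear interpolation of the CTP curve, which is exact at grid
resolution. Ties break to the earliest offset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import TimeIntensityCurves
from .errors import AlignmentInfeasibleError, ConfigurationError, DegenerateAlignmentWarning
from .phases import NormalizedAVCurve, Phase, classify_phase


@dataclass
class AlignmentResult:
    """Optimal temporal placement of the three mCTA volumes on the CTP axis."""

    offset_s: float                       # time of the first (baseline) mCTA volume
    aligned_times_s: tuple[float, float, float]
    residual: float                       # summed |AV-ratio difference| at the optimum
    per_volume_ratio_diff: tuple[float, float, float]
    phases: tuple[Phase, Phase, Phase] | None = None
    manual: bool = False                  # True when the offset was overridden


def align_mcta(mcta_ratios,
               delays_s,
               ctp_curve: TimeIntensityCurves,
               grid_step_s: float = 0.1,
               phase_curve: NormalizedAVCurve | None = None,
               offset_override: float | None = None,
               use_normalized: bool = False) -> AlignmentResult:
    """Align three mCTA acquisitions to the CTP AV-ratio curve.

    Parameters
    ----------
    mcta_ratios
        The three mCTA AV enhancement ratios (baseline, delay 1, delay 2).
    delays_s
        The two known inter-acquisition gaps.
    ctp_curve
        The subject's CTP time-intensity curves (raw AV ratio is used unless
        ``use_normalized``).
    grid_step_s
        Offset search resolution in seconds.
    phase_curve
        When given, the acquisition phase of each aligned volume is looked up.
    offset_override
        Manual fallback: skip the search and evaluate at this offset.
    """
    mcta_ratios = np.asarray(mcta_ratios, dtype=float)
    if mcta_ratios.shape != (3,) or not np.isfinite(mcta_ratios).all():
        raise ConfigurationError("exactly three finite mCTA AV ratios are required")
    delays_s = tuple(float(d) for d in delays_s)
    if len(delays_s) != 2 or any(d < 0 for d in delays_s):
        raise ConfigurationError("delays_s must be two non-negative gaps")
    if grid_step_s <= 0:
        raise ConfigurationError("grid_step_s must be positive")
    cum = np.array([0.0, delays_s[0], delays_s[0] + delays_s[1]])

    r = np.asarray(ctp_curve.av_ratio, dtype=float)
    t = np.asarray(ctp_curve.times_s, dtype=float)
    valid = np.isfinite(r)
    if valid.sum() < 2:
        raise AlignmentInfeasibleError("CTP AV-ratio curve has fewer than 2 valid samples")
    tv, rv = t[valid], r[valid]
    if use_normalized:
        if phase_curve is None:
            raise ConfigurationError("use_normalized requires phase_curve")
        tv, rv = phase_curve.times_s, phase_curve.normalized

    if offset_override is not None:
        best = float(offset_override)
        manual = True
    else:
        lo, hi = tv[0], tv[-1] - cum[-1]
        if hi < lo:
            raise AlignmentInfeasibleError(
                "CTP valid range is shorter than the mCTA acquisition span")
        offsets = lo + np.arange(int(np.floor((hi - lo) / grid_step_s)) + 1) * grid_step_s
        sample_t = offsets[:, None] + cum[None, :]
        pred = np.interp(sample_t, tv, rv)
        objective = np.abs(pred - mcta_ratios[None, :]).sum(axis=1)
        if rv.max() - rv.min() < 1e-9:
            warnings.warn("CTP AV-ratio curve is flat; alignment offset is arbitrary",
                          DegenerateAlignmentWarning, stacklevel=2)
        best = float(offsets[int(np.argmin(objective))])   # first minimum = earliest
        manual = False

    times = tuple(float(best + c) for c in cum)
    diffs = tuple(float(abs(np.interp(ti, tv, rv) - ri))
                  for ti, ri in zip(times, mcta_ratios))
    phases = None
    if phase_curve is not None:
        phases = tuple(classify_phase(phase_curve, ti) for ti in times)
    return AlignmentResult(
        offset_s=best,
        aligned_times_s=times,
        residual=float(sum(diffs)),
        per_volume_ratio_diff=diffs,
        phases=phases,
        manual=manual,
    )


MCTA_POSITIONS = ["mcta_baseline", "mcta_delay1", "mcta_delay2"]


def summarize_phase_distribution(alignments) -> pd.DataFrame:
    """Contingency table of acquisition phases per mCTA position.

    Rows are the three mCTA positions, columns the six phase labels; each
    row sums to the number of aligned subjects.
    """
    alignments = list(alignments)
    if not alignments:
        raise ConfigurationError("at least one alignment is required")
    counts = pd.DataFrame(0, index=MCTA_POSITIONS,
                          columns=[p.value for p in Phase], dtype=int)
    for al in alignments:
        if al.phases is None:
            raise ConfigurationError("alignment lacks phase labels")
        for pos, ph in zip(MCTA_POSITIONS, al.phases):
            counts.loc[pos, ph.value] += 1
    return counts
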