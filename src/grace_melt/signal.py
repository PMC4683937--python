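"""Melt-curve signal processing.

Two read-outs are computed from a raw multiplex melt curve:

* **Derivative peaks** — the −dF/dT trace has one peak per amplicon at its Tm,
  with height proportional to the amount of product (for a logistic transition
  of amplitude A and width w the analytic peak height is A/(4w)).

* **Two-window normalization** — the mechanism HRM software uses for
  genotype-scanning, repurposed here for copy quantification: fit a line to
  the fluorescence in a flat *pre* window and a flat *post* window, rescale so
  the pre line is 100% and the post line is 0%, and read the height of the
  inter-melt plateau. With pre below the reference melt and post between the
  two target melts, the plateau between the reference and HBA1 melts sits at
  A_HBA1/(A_ref + A_HBA1) (stage 1). With pre in the reference→HBA1 gap and
  post above the HBA2 melt, the plateau between the HBA1 and HBA2 melts sits
  at A_HBA2/(A_HBA1 + A_HBA2) (stage 2).

Window placement is automatic (flattest point of each eligible plateau on the
run's control curve) with manual override, since an analyst normally drags
these bars by eye.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .curves import MeltCurve
from .errors import (
    NormalizationError,
    ParameterError,
    PlacementError,
    ReferencePeakError,
)
from .panel import AmpliconPanel

__all__ = [
    "DerivativeTrace",
    "Peak",
    "PeakSet",
    "NormalizationWindows",
    "PlateauMeasurement",
    "NormalizedCurve",
    "smooth",
    "negative_derivative",
    "locate_plateaus",
    "place_windows",
    "detect_peaks",
    "normalize_between",
    "plateau_height",
]

Stage = Literal["reference_vs_target1", "target1_vs_target2"]
STAGES: tuple[Stage, Stage] = ("reference_vs_target1", "target1_vs_target2")

#: Default width (°C) of an automatically placed normalization window. Wide
#: windows (6–7 grid points) stabilise the line fits that are extrapolated
#: across the melt region, as an analyst's hand-set bars would.
DEFAULT_WINDOW_WIDTH_C = 1.2

#: A peak below this fraction of the control's peak for the same gene is
#: treated as absent (zero copies). One copy sits near 50%, so 10% cleanly
#: separates true absence from the lowest real copy state.
DEFAULT_ABSENCE_FRACTION = 0.10

#: Automatic placement fails if the flattest eligible window still has a mean
#: |−dF/dT| above this fraction of the tallest derivative peak.
PLACEMENT_FLATNESS_FRACTION = 0.15

DEFAULT_SMOOTH_WINDOW = 7
DEFAULT_SMOOTH_ORDER = 2


# ---------------------------------------------------------------------------
# basic traces


@dataclass(frozen=True)
class DerivativeTrace:
    """−dF/dT on the curve's own grid."""

    sample_id: str
    temperatures_c: np.ndarray
    values: np.ndarray

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.temperatures_c >= lo) & (self.temperatures_c <= hi)


def smooth(
    curve: MeltCurve,
    window_points: int = DEFAULT_SMOOTH_WINDOW,
    poly_order: int = DEFAULT_SMOOTH_ORDER,
) -> MeltCurve:
    """Savitzky–Golay smoothing on the curve's grid.

    ``window_points`` must be odd, larger than ``poly_order`` and no longer
    than the curve; endpoints are handled by polynomial-fit truncation.
    """
    n = curve.temperatures_c.size
    if window_points % 2 == 0 or window_points <= poly_order or window_points > n:
        raise ParameterError(
            f"invalid smoothing parameters: window_points={window_points} "
            f"(odd, > poly_order={poly_order}, <= {n} required)"
        )
    f = savgol_filter(curve.fluorescence, window_points, poly_order, mode="interp")
    return MeltCurve(curve.sample_id, curve.temperatures_c, np.clip(f, 0.0, None))


def negative_derivative(curve: MeltCurve) -> DerivativeTrace:
    """Central-difference −dF/dT (one-sided at the two ends)."""
    d = -np.gradient(curve.fluorescence, curve.temperatures_c)
    return DerivativeTrace(curve.sample_id, curve.temperatures_c, d)


# ---------------------------------------------------------------------------
# plateau location / normalization windows


@dataclass(frozen=True)
class NormalizationWindows:
    """A pre-melt and a post-melt normalization window (each (lo, hi) in °C)."""

    pre_window: tuple[float, float]
    post_window: tuple[float, float]

    def __post_init__(self) -> None:
        (a, b), (c, d) = self.pre_window, self.post_window
        if not (a < b and c < d):
            raise ValueError("each window must satisfy t_start < t_end")
        if not b < c:
            raise ValueError("pre_window must lie entirely below post_window")


@dataclass(frozen=True)
class PlateauMeasurement:
    sample_id: str
    stage: Stage
    plateau_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must be in [0, 1]")


@dataclass(frozen=True)
class NormalizedCurve:
    """Fluorescence rescaled so pre-window ≈ 100 and post-window ≈ 0 (%)."""

    sample_id: str
    temperatures_c: np.ndarray
    values: np.ndarray
    windows: NormalizationWindows


def _sliding_flattest(
    deriv: DerivativeTrace, lo: float, hi: float, width_c: float
) -> tuple[float, float] | None:
    """Flattest ``width_c``-wide window inside [lo, hi], or None if it cannot fit.

    Flatness is the mean |−dF/dT| over the window's grid points.
    """
    t = deriv.temperatures_c
    step = float(t[1] - t[0])
    npts = max(2, int(round(width_c / step)) + 1)
    idx = np.where((t >= lo) & (t <= hi))[0]
    if idx.size < npts:
        return None
    best, best_score = None, np.inf
    vals = np.abs(deriv.values)
    for start in range(idx[0], idx[-1] - npts + 2):
        score = float(vals[start : start + npts].mean())
        if score < best_score:
            best_score = score
            best = (float(t[start]), float(t[start + npts - 1]))
    return best


def locate_plateaus(
    deriv: DerivativeTrace,
    panel: AmpliconPanel,
    width_c: float = DEFAULT_WINDOW_WIDTH_C,
    flatness_fraction: float = PLACEMENT_FLATNESS_FRACTION,
) -> tuple[tuple[float, float], ...]:
    """Locate the flattest window in each of the n_amplicons+1 plateau regions.

    Regions are: below the first melt, each inter-Tm gap, and above the last
    melt. Raises :class:`PlacementError` if any region has no window flatter
    than ``flatness_fraction`` of the tallest derivative peak.
    """
    t = deriv.temperatures_c
    tms = [a.tm_c for a in panel.amplicons]
    bounds = [float(t[0])] + tms + [float(t[-1])]
    peak_scale = float(np.max(np.abs(deriv.values)))
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        win = _sliding_flattest(deriv, lo, hi, width_c)
        if win is None:
            raise PlacementError(
                f"region [{lo:.1f}, {hi:.1f}] °C too narrow for a "
                f"{width_c} °C normalization window; set windows manually"
            )
        mask = deriv.window_mask(*win)
        if float(np.abs(deriv.values[mask]).mean()) > flatness_fraction * peak_scale:
            raise PlacementError(
                f"no flat plateau in [{lo:.1f}, {hi:.1f}] °C "
                f"(melt transitions overlap?); set windows manually"
            )
        out.append(win)
    return tuple(out)


def place_windows(
    run,
    panel: AmpliconPanel,
    stage: Stage,
    width_c: float = DEFAULT_WINDOW_WIDTH_C,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_order: int = DEFAULT_SMOOTH_ORDER,
) -> NormalizationWindows:
    """Automatic window placement from the run's control curve.

    Stage ``reference_vs_target1``: pre below the reference melt, post in the
    gap between the two target melts. Stage ``target1_vs_target2``: pre in the
    reference→target1 gap, post above the target2 melt. The plateau *between*
    the stage's two melts is then read by :func:`plateau_height`.
    """
    deriv = negative_derivative(smooth(run.control, smooth_window, smooth_order))
    plateaus = locate_plateaus(deriv, panel, width_c)
    if stage == "reference_vs_target1":
        pre, post = plateaus[0], plateaus[2]
    elif stage == "target1_vs_target2":
        pre, post = plateaus[1], plateaus[3]
    else:
        raise ParameterError(f"unknown stage {stage!r}")
    return NormalizationWindows(pre, post)


# ---------------------------------------------------------------------------
# peaks


@dataclass(frozen=True)
class Peak:
    temperature_c: float
    height: float


@dataclass(frozen=True)
class PeakSet:
    """Per-amplicon baseline-corrected derivative peak heights for one sample."""

    sample_id: str
    peaks: Mapping[str, Peak]
    absent: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", dict(self.peaks))
        object.__setattr__(self, "absent", frozenset(self.absent))

    def height(self, gene: str) -> float:
        return self.peaks[gene].height


def detect_peaks(
    deriv: DerivativeTrace,
    panel: AmpliconPanel,
    plateaus: Sequence[tuple[float, float]] | None = None,
    control_peaks: PeakSet | None = None,
    absence_fraction: float = DEFAULT_ABSENCE_FRACTION,
) -> PeakSet:
    """Measure each amplicon's derivative peak within its assignment window.

    The local baseline for amplicon *i* is the mean −dF/dT over the two
    plateau windows flanking its Tm (this removes the contribution of the
    fluorescence baseline slope); the height is the windowed maximum minus
    that baseline, floored at zero.

    Absence calling: with ``control_peaks`` given (a sample measured against
    the run control), a gene whose height falls below ``absence_fraction``
    of the control's height for the same gene is flagged absent and reported
    with height 0. Without ``control_peaks`` (i.e. measuring the control
    itself) a peak is absent if it does not rise above a noise floor estimated
    from the plateau windows. An absent *reference* peak is a hard error: the
    sample has no quantification anchor.
    """
    if plateaus is None:
        plateaus = locate_plateaus(deriv, panel)
    if len(plateaus) != len(panel.amplicons) + 1:
        raise ParameterError(
            f"need {len(panel.amplicons) + 1} plateau windows, got {len(plateaus)}"
        )

    t = deriv.temperatures_c
    plateau_vals = [deriv.values[deriv.window_mask(*w)] for w in plateaus]
    # Robust noise floor from plateau scatter (≈0 on noiseless data).
    resid = np.concatenate([v - np.median(v) for v in plateau_vals])
    noise_floor = 5.0 * 1.4826 * float(np.median(np.abs(resid)))

    raw: dict[str, tuple[float, float]] = {}
    for i, amp in enumerate(panel.amplicons):
        lo, hi = amp.tm_c - amp.assignment_window_c, amp.tm_c + amp.assignment_window_c
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise ParameterError(
                f"{amp.gene_name}: assignment window [{lo}, {hi}] °C is outside the grid"
            )
        baseline = float(
            np.mean([np.mean(plateau_vals[i]), np.mean(plateau_vals[i + 1])])
        )
        j = int(np.argmax(deriv.values[mask]))
        height = max(0.0, float(deriv.values[mask][j]) - baseline)
        raw[amp.gene_name] = (float(t[mask][j]), height)

    tallest = max(h for _, h in raw.values())
    peaks: dict[str, Peak] = {}
    absent: set[str] = set()
    for amp in panel.amplicons:
        temp, height = raw[amp.gene_name]
        if control_peaks is not None:
            ref_height = control_peaks.height(amp.gene_name)
            is_absent = height < absence_fraction * ref_height
        else:
            # No external anchor (measuring the control itself): a real peak
            # must clear the plateau noise floor and be within ~20x of the
            # curve's tallest melt peak.
            is_absent = (
                height <= noise_floor or height <= 0.0 or height < 0.05 * tallest
            )
        if is_absent:
            if amp.gene_name == panel.reference_gene:
                raise ReferencePeakError(
                    f"{deriv.sample_id}: reference gene {amp.gene_name} has no "
                    "melt peak; sample cannot be quantified"
                )
            absent.add(amp.gene_name)
            peaks[amp.gene_name] = Peak(temp, 0.0)
        else:
            peaks[amp.gene_name] = Peak(temp, height)
    return PeakSet(deriv.sample_id, peaks, frozenset(absent))


# ---------------------------------------------------------------------------
# two-window normalization


def _window_mask(curve: MeltCurve, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (curve.temperatures_c >= lo) & (curve.temperatures_c <= hi)
    if mask.sum() < 2:
        raise NormalizationError(
            f"window [{lo}, {hi}] °C spans fewer than 2 grid points"
        )
    return mask


def _pooled_slope(curve: MeltCurve, windows: Sequence[tuple[float, float]]) -> float:
    """Least-squares slope shared across windows (separate intercepts)."""
    num = den = 0.0
    for w in windows:
        m = _window_mask(curve, w)
        t, f = curve.temperatures_c[m], curve.fluorescence[m]
        tc = t - t.mean()
        num += float((tc * f).sum())
        den += float((tc * tc).sum())
    return num / den


def normalize_between(
    curve: MeltCurve,
    windows: NormalizationWindows,
    slope_windows: Sequence[tuple[float, float]] = (),
) -> NormalizedCurve:
    """Two-window normalization: n(T) = 100·(F − L_post)/(L_pre − L_post).

    A line is fit to the fluorescence over each window and extrapolated
    across the grid; any linear fluorescence baseline is thereby absorbed.
    In every plateau region the only true slope is that common baseline, so
    the pre and post lines share one pooled slope estimate (optionally
    strengthened by further flat ``slope_windows``) with per-window
    intercepts — an independently fitted slope from a handful of noisy points
    would be amplified by the extrapolation. Raises
    :class:`NormalizationError` when the two lines coincide over the
    inter-window span (no melt signal to normalize).
    """
    all_windows = [windows.pre_window, windows.post_window, *slope_windows]
    slope = _pooled_slope(curve, all_windows)
    t = curve.temperatures_c

    def line(window: tuple[float, float]) -> np.ndarray:
        m = _window_mask(curve, window)
        intercept = float((curve.fluorescence[m] - slope * t[m]).mean())
        return intercept + slope * t

    l_pre = line(windows.pre_window)
    l_post = line(windows.post_window)
    denom = l_pre - l_post
    t = curve.temperatures_c
    mid_mask = (t >= windows.pre_window[1]) & (t <= windows.post_window[0])
    if not mid_mask.any():
        mid_mask = np.ones_like(t, dtype=bool)
    span = float(np.median(denom[mid_mask]))
    if span <= max(1e-12, 1e-9 * float(np.max(np.abs(curve.fluorescence), initial=1.0))):
        raise NormalizationError(
            f"{curve.sample_id}: degenerate normalization "
            "(pre- and post-window levels coincide)"
        )
    values = 100.0 * (curve.fluorescence - l_post) / denom
    return NormalizedCurve(curve.sample_id, t, values, windows)


def plateau_height(
    norm_curve: NormalizedCurve,
    windows: NormalizationWindows,
    panel: AmpliconPanel,
    stage: Stage,
) -> PlateauMeasurement:
    """Mean normalized level over the central 50% of the stage's inter-Tm gap.

    Stage ``reference_vs_target1`` reads between the reference and first
    target melts (estimating A_t1/(A_ref + A_t1)); ``target1_vs_target2``
    reads between the two target melts (estimating A_t2/(A_t1 + A_t2)). The
    central half of the gap is used to avoid shoulder contamination from the
    flanking transitions.
    """
    g1, g2 = panel.target_genes[0], panel.target_genes[1]
    if stage == "reference_vs_target1":
        lo_tm, hi_tm = panel.tm_gap(panel.reference_gene, g1)
    elif stage == "target1_vs_target2":
        lo_tm, hi_tm = panel.tm_gap(g1, g2)
    else:
        raise ParameterError(f"unknown stage {stage!r}")
    gap = hi_tm - lo_tm
    lo, hi = lo_tm + 0.25 * gap, hi_tm - 0.25 * gap
    t = norm_curve.temperatures_c
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ParameterError(
            f"plateau read region [{lo:.2f}, {hi:.2f}] °C is outside the grid"
        )
    frac = float(np.mean(norm_curve.values[mask])) / 100.0
    return PlateauMeasurement(
        norm_curve.sample_id, stage, float(np.clip(frac, 0.0, 1.0))
    )
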