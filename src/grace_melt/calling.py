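"""Copy-number calling and genotype-class interpretation.

Two independent callers convert melt-curve measurements into (HBA1, HBA2)
copy pairs, both normalized against the run's wild-type control:

* **Peak-ratio method** — from the −dF/dT peaks, the normalized ratio

      ratio = (R_control / T_control) / (R_unknown / T_unknown)

  (R = reference peak height, T = target peak height) equals
  copies_unknown / copies_control for that target under the proportional-
  amplification model, so copies = ratio × 2 rounded to the nearest allowed
  state.

* **Window-ratio method** — from the two-stage normalized plateaus. A stage
  plateau p estimates A_num/(A_den + A_num), so its odds p/(1−p) is the
  amplitude ratio A_num/A_den. Stage 1 odds give HBA1:CLCN7; with CLCN7 fixed
  at two copies this resolves HBA1. Stage 2 odds give HBA2:HBA1; the already-
  resolved HBA1 count then anchors HBA2. Resolution is strictly sequential
  (reference → HBA1 → HBA2); no joint estimation.

A deletion of a target is detected by *absence* of its signal (peak below 10%
of control, or plateau below 5%), not by the ratio formula, which is
undefined at zero target signal.

Calls are never silently dropped: borderline ratios carry an ``ambiguous``
flag and reference-gene anomalies an ``improbable_reference`` flag, routing
the sample to confirmatory testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .curves import MeltRun
from .errors import GraceMeltError, NormalizationError, RunQCError
from .panel import AmpliconPanel
from .signal import (
    DEFAULT_ABSENCE_FRACTION,
    DEFAULT_SMOOTH_ORDER,
    DEFAULT_SMOOTH_WINDOW,
    NormalizationWindows,
    PeakSet,
    detect_peaks,
    locate_plateaus,
    negative_derivative,
    normalize_between,
    place_windows,
    plateau_height,
    smooth,
)

__all__ = [
    "CopyNumberCall",
    "GenotypeInterpretation",
    "normalized_peak_ratio",
    "ratio_to_copies",
    "call_by_peaks",
    "call_by_windows",
    "interpret",
    "calls_to_frame",
    "write_calls_csv",
]

Method = Literal["peak_ratio", "window_ratio"]

#: Half-width (in copies) of the acceptance band around each integer copy
#: state; a candidate farther than this from every allowed state is flagged.
DEFAULT_COPY_TOLERANCE = 0.35

#: A stage plateau at or below this fraction is read as "no second melt":
#: the stage's numerator gene is absent (zero copies).
DEFAULT_PLATEAU_ABSENCE = 0.05

#: Stage-1 ratios above this value imply >4 HBA1 copies — in practice a
#: reference-gene anomaly rather than a real α-globin state.
IMPROBABLE_STAGE1_RATIO = 2.0

FLAG_AMBIGUOUS = "ambiguous"
FLAG_IMPROBABLE_REFERENCE = "improbable_reference"
FLAG_ABSENT_TARGET = "absent_target"


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    method: Method
    hba1_copies: int
    hba2_copies: int
    stage1_ratio: float
    stage2_ratio: float
    flags: frozenset[str] = frozenset()
    interpretation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))
        if self.hba1_copies < 0 or self.hba2_copies < 0:
            raise ValueError("copy numbers must be nonnegative integers")

    @property
    def copy_pair(self) -> tuple[int, int]:
        return (self.hba1_copies, self.hba2_copies)

    @property
    def is_flagged(self) -> bool:
        return bool(
            self.flags & {FLAG_AMBIGUOUS, FLAG_IMPROBABLE_REFERENCE}
        )


@dataclass(frozen=True)
class GenotypeInterpretation:
    copy_pair: tuple[int, int]
    label: str
    caveats: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# primitive operations


def normalized_peak_ratio(
    control: PeakSet, unknown: PeakSet, gene: str, reference_gene: str = "CLCN7"
) -> float:
    """(R_control/T_control) / (R_unknown/T_unknown) for one target gene.

    Equals copies_unknown/copies_control under proportional amplification.
    Returns 0.0 when the unknown's target signal is absent (deletion case);
    raises if either reference peak is missing.
    """
    r_c, t_c = control.height(reference_gene), control.height(gene)
    r_u, t_u = unknown.height(reference_gene), unknown.height(gene)
    if r_c <= 0 or r_u <= 0:
        raise GraceMeltError(
            f"{unknown.sample_id}: reference peak height is zero; "
            "peak detection should have failed upstream"
        )
    if t_c <= 0:
        raise GraceMeltError(
            f"control sample lacks a {gene} peak; invalid wild-type control"
        )
    if gene in unknown.absent or t_u <= 0:
        return 0.0
    return (r_c / t_c) / (r_u / t_u)


def ratio_to_copies(
    ratio: float,
    control_copies: int,
    tolerance: float = DEFAULT_COPY_TOLERANCE,
    allowed_states: Sequence[int] = (0, 1, 2, 3),
) -> tuple[int, bool]:
    """Snap ``ratio × control_copies`` to the nearest allowed copy state.

    Returns ``(copies, ambiguous)``; ambiguous when the candidate is more
    than ``tolerance`` copies from every allowed state (the call still
    carries the nearest state).
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if control_copies < 1:
        raise ValueError("control_copies must be >= 1")
    candidate = ratio * control_copies
    nearest = min(allowed_states, key=lambda s: (abs(candidate - s), s))
    return nearest, abs(candidate - nearest) > tolerance


def interpret(copy_pair: tuple[int, int]) -> GenotypeInterpretation:
    """Map an (HBA1, HBA2) copy pair to its α-thalassaemia genotype class."""
    base_caveats = (
        "the hybrid -a3.7 fusion gene types as an HBA1 copy "
        "(3'-anchored primers)",
        "the -(a)20.5 deletion spares the HBA1 3' target and types as an "
        "HBA2-only deletion",
        "point mutations do not change copy number and are not excluded",
    )
    labels = {
        (2, 2): "normal α-globin copy number (point mutations not excluded)",
        (2, 1): (
            "single-gene deletion pattern (α+ heterozygote, e.g. -α3.7/αα or "
            "-α4.2/αα; also matches the -(α)20.5 pattern)"
        ),
        (2, 0): "two-gene deletion in trans pattern (-α/-α)",
        (1, 1): "α0 deletion heterozygote pattern (αα/--)",
        (1, 0): "three-gene deletion / Hb H pattern (-α/--)",
        (2, 3): "α-gene duplication pattern (αα/ααα)",
        (0, 0): "four-gene deletion pattern (--/--)",
    }
    label = labels.get(
        tuple(copy_pair), "atypical copy pair — confirm with alternative primers/MLPA"
    )
    return GenotypeInterpretation(tuple(copy_pair), label, base_caveats)


# ---------------------------------------------------------------------------
# per-run callers


def _finalize(
    sample_id: str,
    method: Method,
    panel: AmpliconPanel,
    c1: int,
    c2: int,
    r1: float,
    r2: float,
    flags: set[str],
) -> CopyNumberCall:
    g1 = panel.target_genes[0]
    if c1 not in panel.allowed_copy_states[g1] or r1 > IMPROBABLE_STAGE1_RATIO:
        flags.add(FLAG_IMPROBABLE_REFERENCE)
    return CopyNumberCall(
        sample_id=sample_id,
        method=method,
        hba1_copies=c1,
        hba2_copies=c2,
        stage1_ratio=r1,
        stage2_ratio=r2,
        flags=frozenset(flags),
        interpretation=interpret((c1, c2)).label,
    )


def _check_control(call: CopyNumberCall, control_id: str) -> None:
    if call.copy_pair != (2, 2) or call.is_flagged:
        raise RunQCError(
            f"wild-type control {control_id!r} calls as "
            f"{call.copy_pair} with flags {sorted(call.flags)}; run fails QC"
        )


def call_by_peaks(
    run: MeltRun,
    panel: AmpliconPanel | None = None,
    tolerance: float = DEFAULT_COPY_TOLERANCE,
    absence_fraction: float = DEFAULT_ABSENCE_FRACTION,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_order: int = DEFAULT_SMOOTH_ORDER,
) -> list[CopyNumberCall]:
    """Call every non-control sample by the derivative peak-ratio method.

    Curves are smoothed, differentiated, and peak heights measured against a
    local plateau baseline; each target's normalized peak ratio versus the
    wild-type control is snapped to the nearest copy state. The control's own
    implied call must be (2,2) or the whole run fails QC.
    """
    from .panel import default_panel

    panel = panel or default_panel()
    g1, g2 = panel.target_genes

    def measure(sample_id, plateaus, control_peaks=None):
        deriv = negative_derivative(
            smooth(run.curves[sample_id], smooth_window, smooth_order)
        )
        return detect_peaks(
            deriv, panel, plateaus, control_peaks, absence_fraction
        )

    control_deriv = negative_derivative(
        smooth(run.control, smooth_window, smooth_order)
    )
    plateaus = locate_plateaus(control_deriv, panel)
    control_peaks = detect_peaks(control_deriv, panel, plateaus)

    calls = []
    for sid in run.noncontrol_ids():
        ps = measure(sid, plateaus, control_peaks)
        flags: set[str] = set()
        r1 = normalized_peak_ratio(control_peaks, ps, g1, panel.reference_gene)
        r2 = normalized_peak_ratio(control_peaks, ps, g2, panel.reference_gene)
        if g1 in ps.absent:
            c1, amb1 = 0, False
            flags.add(FLAG_ABSENT_TARGET)
        else:
            c1, amb1 = ratio_to_copies(
                r1, panel.reference_copies, tolerance, panel.allowed_copy_states[g1]
            )
        if g2 in ps.absent:
            c2, amb2 = 0, False
            flags.add(FLAG_ABSENT_TARGET)
        else:
            c2, amb2 = ratio_to_copies(
                r2, panel.reference_copies, tolerance, panel.allowed_copy_states[g2]
            )
        if amb1 or amb2:
            flags.add(FLAG_AMBIGUOUS)
        calls.append(_finalize(sid, "peak_ratio", panel, c1, c2, r1, r2, flags))

    # Control QC: the control measured against itself must imply (2,2).
    qc_flags: set[str] = set()
    qc1, a1 = ratio_to_copies(1.0, panel.reference_copies, tolerance)
    qc2, a2 = ratio_to_copies(1.0, panel.reference_copies, tolerance)
    if a1 or a2 or control_peaks.absent & {g1, g2}:
        qc_flags.add(FLAG_AMBIGUOUS)
    _check_control(
        _finalize(run.control_sample_id, "peak_ratio", panel, qc1, qc2, 1.0, 1.0, qc_flags),
        run.control_sample_id,
    )
    return calls


def _odds(p: float) -> float:
    if p >= 1.0:
        raise NormalizationError("plateau fraction of 1: degenerate odds")
    return p / (1.0 - p)


def call_by_windows(
    run: MeltRun,
    panel: AmpliconPanel | None = None,
    tolerance: float = DEFAULT_COPY_TOLERANCE,
    plateau_absence: float = DEFAULT_PLATEAU_ABSENCE,
    windows1: NormalizationWindows | None = None,
    windows2: NormalizationWindows | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_order: int = DEFAULT_SMOOTH_ORDER,
) -> list[CopyNumberCall]:
    """Call every non-control sample by the two-stage window-ratio method.

    Stage 1: r1 = odds(plateau_unknown)/odds(plateau_control) = HBA1_u/HBA1_c;
    HBA1 copies = nearest state to 2·r1. Stage 2: r2 = odds ratio of the
    stage-2 plateaus = (HBA2_u/HBA1_u)/(HBA2_c/HBA1_c); with control (2,2),
    HBA2 copies = nearest state to r2 × (called HBA1). A plateau at or below
    ``plateau_absence`` short-circuits to zero copies. Windows are placed
    automatically from the control unless supplied.
    """
    from .panel import default_panel

    panel = panel or default_panel()
    g1, g2 = panel.target_genes
    if windows1 is None:
        windows1 = place_windows(run, panel, "reference_vs_target1")
    if windows2 is None:
        windows2 = place_windows(run, panel, "target1_vs_target2")

    # All four plateau windows see the same fluorescence baseline; pooling
    # the slope across them stabilises the extrapolated normalization lines.
    slope_pool = (
        windows1.pre_window,
        windows1.post_window,
        windows2.pre_window,
        windows2.post_window,
    )

    def plateaus_for(sample_id: str) -> tuple[float, float]:
        curve = smooth(run.curves[sample_id], smooth_window, smooth_order)
        p1 = plateau_height(
            normalize_between(curve, windows1, slope_pool),
            windows1, panel, "reference_vs_target1",
        ).plateau_fraction
        try:
            p2 = plateau_height(
                normalize_between(curve, windows2, slope_pool),
                windows2, panel, "target1_vs_target2",
            ).plateau_fraction
        except NormalizationError:
            # No melt signal at all between the stage-2 windows: both targets
            # absent (the stage-1 plateau then reads ~0 as well).
            p2 = 0.0
        return p1, p2

    p1_c, p2_c = plateaus_for(run.control_sample_id)
    if not plateau_absence < p1_c < 1.0 - 1e-9 or not plateau_absence < p2_c < 1.0 - 1e-9:
        raise RunQCError(
            f"control plateaus ({p1_c:.3f}, {p2_c:.3f}) are degenerate; "
            "wild-type control is not usable"
        )
    odds1_c, odds2_c = _odds(p1_c), _odds(p2_c)

    calls = []
    for sid in run.noncontrol_ids():
        p1_u, p2_u = plateaus_for(sid)
        flags: set[str] = set()
        if p1_u <= plateau_absence:
            c1, amb1, r1 = 0, False, 0.0
            flags.add(FLAG_ABSENT_TARGET)
        else:
            r1 = _odds(min(p1_u, 1.0 - 1e-9)) / odds1_c
            c1, amb1 = ratio_to_copies(
                r1, panel.reference_copies, tolerance, panel.allowed_copy_states[g1]
            )
        if p2_u <= plateau_absence:
            c2, amb2, r2 = 0, False, 0.0
            flags.add(FLAG_ABSENT_TARGET)
        else:
            r2 = _odds(min(p2_u, 1.0 - 1e-9)) / odds2_c
            if p2_u >= 1.0 - 1e-9 or c1 == 0:
                # Stage 2 cannot be anchored without an HBA1 copy count.
                c2, amb2 = ratio_to_copies(
                    r2 * panel.reference_copies / 2.0, 2, tolerance,
                    panel.allowed_copy_states[g2],
                )
                flags.add(FLAG_AMBIGUOUS)
            else:
                c2, amb2 = ratio_to_copies(
                    r2, c1, tolerance, panel.allowed_copy_states[g2]
                )
        if amb1 or amb2:
            flags.add(FLAG_AMBIGUOUS)
        calls.append(_finalize(sid, "window_ratio", panel, c1, c2, r1, r2, flags))

    _check_control(
        _finalize(
            run.control_sample_id, "window_ratio", panel, 2, 2, 1.0, 1.0, set()
        ),
        run.control_sample_id,
    )
    return calls


# ---------------------------------------------------------------------------
# tabular output


def calls_to_frame(calls: Iterable[CopyNumberCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "method": c.method,
            "hba1_copies": c.hba1_copies,
            "hba2_copies": c.hba2_copies,
            "stage1_ratio": c.stage1_ratio,
            "stage2_ratio": c.stage2_ratio,
            "flags": ";".join(sorted(c.flags)),
            "interpretation": c.interpretation,
        }
        for c in calls
    ]
    return pd.DataFrame.from_records(
        rows,
        columns=[
            "sample_id",
            "method",
            "hba1_copies",
            "hba2_copies",
            "stage1_ratio",
            "stage2_ratio",
            "flags",
            "interpretation",
        ],
    )


def write_calls_csv(calls: Iterable[CopyNumberCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, index=False)
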