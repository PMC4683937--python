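"""Melt-curve containers and the melt CSV dialect.

A :class:`MeltCurve` is one sample's raw fluorescence trace over a uniform
temperature grid; a :class:`MeltRun` bundles the curves of one instrument run
together with the identity of the wild-type control sample against which all
copy-number ratios are normalized.

CSV dialect
-----------
UTF-8, comma-separated. First line is the header
``temperature_c,<sample_id_1>,<sample_id_2>,...``; the second line is
``#control=<sample_id>`` naming the wild-type control; every following line is
one temperature point. ``read_melt_csv`` inverts ``write_melt_csv`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import MeltCsvError

__all__ = ["MeltCurve", "MeltRun", "read_melt_csv", "write_melt_csv"]

#: Tolerance on grid-step uniformity (°C).
GRID_STEP_TOL = 1e-6

MIN_POINTS = 20


@dataclass(frozen=True)
class MeltCurve:
    """One sample's fluorescence-vs-temperature trace.

    ``temperatures_c`` must be strictly increasing with a constant step (to
    within 1e-6 °C) and hold at least 20 points; ``fluorescence`` is
    nonnegative and the same length.
    """

    sample_id: str
    temperatures_c: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_c, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures_c", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or f.ndim != 1 or t.size != f.size:
            raise ValueError(
                f"{self.sample_id}: temperature and fluorescence arrays must be "
                f"1-D and equal length (got {t.shape} vs {f.shape})"
            )
        if t.size < MIN_POINTS:
            raise ValueError(
                f"{self.sample_id}: need >= {MIN_POINTS} points, got {t.size}"
            )
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError(f"{self.sample_id}: temperature grid must be strictly increasing")
        if np.ptp(steps) > GRID_STEP_TOL:
            raise ValueError(
                f"{self.sample_id}: temperature step not constant "
                f"(spread {np.ptp(steps):.2e} °C > {GRID_STEP_TOL} °C)"
            )
        if np.any(f < 0):
            raise ValueError(f"{self.sample_id}: fluorescence must be nonnegative")

    @property
    def step_c(self) -> float:
        return float(self.temperatures_c[1] - self.temperatures_c[0])

    def scaled(self, factor: float) -> "MeltCurve":
        """Return a copy with fluorescence multiplied by ``factor`` (> 0)."""
        if not factor > 0:
            raise ValueError("scale factor must be > 0")
        return MeltCurve(self.sample_id, self.temperatures_c, self.fluorescence * factor)


@dataclass(frozen=True)
class MeltRun:
    """All melt curves of one run plus the designated wild-type control."""

    run_id: str
    curves: Mapping[str, MeltCurve]
    control_sample_id: str

    def __post_init__(self) -> None:
        curves = dict(self.curves)
        object.__setattr__(self, "curves", curves)
        if not curves:
            raise ValueError(f"run {self.run_id!r}: no curves")
        if self.control_sample_id not in curves:
            raise ValueError(
                f"run {self.run_id!r}: control sample "
                f"{self.control_sample_id!r} not among curves"
            )
        grids = [c.temperatures_c for c in curves.values()]
        first = grids[0]
        for sid, c in curves.items():
            if c.temperatures_c.shape != first.shape or np.any(
                c.temperatures_c != first
            ):
                raise ValueError(
                    f"run {self.run_id!r}: sample {sid!r} is on a different "
                    "temperature grid (all curves must share one grid exactly)"
                )

    @property
    def temperatures_c(self) -> np.ndarray:
        return next(iter(self.curves.values())).temperatures_c

    @property
    def control(self) -> MeltCurve:
        return self.curves[self.control_sample_id]

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.curves)

    def noncontrol_ids(self) -> tuple[str, ...]:
        return tuple(s for s in self.curves if s != self.control_sample_id)


def write_melt_csv(run: MeltRun, path: str | Path) -> None:
    """Write ``run`` in the melt CSV dialect (exact-round-trip floats)."""
    path = Path(path)
    sample_ids = list(run.curves)
    if not sample_ids:
        raise MeltCsvError("refusing to write a run with no samples")
    t = run.temperatures_c
    cols = [run.curves[s].fluorescence for s in sample_ids]
    lines = ["temperature_c," + ",".join(sample_ids)]
    lines.append(f"#control={run.control_sample_id}")
    for i in range(t.size):
        # repr() of float64 is shortest-round-trip: read() inverts exactly.
        lines.append(",".join([repr(float(t[i]))] + [repr(float(c[i])) for c in cols]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_melt_csv(path: str | Path, run_id: str | None = None) -> MeltRun:
    """Parse a melt CSV file into a :class:`MeltRun`."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise MeltCsvError(f"{path}: cannot read: {exc}") from exc

    header: list[str] | None = None
    control: str | None = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#control="):
                control = line.split("=", 1)[1].strip()
            continue
        if header is None:
            header = [h.strip() for h in line.split(",")]
            if header[0] != "temperature_c" or len(header) < 2:
                raise MeltCsvError(
                    f"{path}:{lineno}: header must be "
                    "'temperature_c,<sample_id>,...'"
                )
            continue
        fields = line.split(",")
        if len(fields) != len(header):
            raise MeltCsvError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise MeltCsvError(f"{path}:{lineno}: non-numeric value: {exc}") from exc

    if header is None or not rows:
        raise MeltCsvError(f"{path}: no data rows")
    if control is None:
        raise MeltCsvError(f"{path}: missing '#control=<sample_id>' header line")

    data = np.asarray(rows, dtype=float)
    t = data[:, 0]
    if np.any(np.diff(t) <= 0):
        raise MeltCsvError(f"{path}: temperature column must be strictly increasing")
    curves = {}
    for j, sid in enumerate(header[1:], start=1):
        try:
            curves[sid] = MeltCurve(sid, t, data[:, j])
        except ValueError as exc:
            raise MeltCsvError(f"{path}: column {sid!r}: {exc}") from exc
    if control not in curves:
        raise MeltCsvError(f"{path}: control sample {control!r} has no column")
    return MeltRun(run_id or path.stem, curves, control)
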