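"""Synthetic multiplex melt-curve generator.

The assay terminates PCR during the exponential phase, so the amount of each
product — and therefore the amplitude of its melt step — stays proportional to
the input copy number of its gene. The simulator encodes exactly that model:
each amplicon contributes a decreasing logistic transition centred on its Tm,

    F(T) = b0 + b1·(T − T_min) + Σ_i A_i / (1 + exp((T − Tm_i)/w_i)) + ε(T),

with amplitude ``A_i = scale · per_copy_amplitude_i · copies_i`` and i.i.d.
Gaussian noise ε ~ N(0, noise_sd²); fluorescence is clipped at zero. A
zero-copy gene contributes no signal. The logistic has a closed-form
derivative peak of height ``A/(4w)`` at its Tm, which serves as an analytic
oracle for the signal-processing layer.

Saturation/plateau PCR kinetics are deliberately not modelled: linear
proportionality is the assay's operating regime. Per-sample pipetting and
amplification variation is emulated by a log-normal global ``scale`` factor,
which forces any downstream analysis to normalize against the run's wild-type
control, as the assay itself does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .curves import MeltCurve, MeltRun
from .errors import PanelConfigError
from .panel import AmpliconPanel, default_panel

__all__ = [
    "SimSampleSpec",
    "CohortRow",
    "SimCohortSpec",
    "default_grid",
    "simulate_curve",
    "simulate_cohort",
    "load_cohort_spec",
    "validation_cohort",
]

#: Acquisition defaults: 77→87 °C at 0.2 °C resolution (51 points), matching a
#: Rotor-Gene-style HRM ramp.
GRID_START_C = 77.0
GRID_STOP_C = 87.0
GRID_POINTS = 51

DEFAULT_NOISE_SD = 0.02
DEFAULT_SCALE_SIGMA = 0.15
DEFAULT_BASELINE_INTERCEPT = 2.0
DEFAULT_BASELINE_SLOPE = -0.05

CONTROL_SAMPLE_ID = "WT_CONTROL"


def default_grid() -> np.ndarray:
    return np.linspace(GRID_START_C, GRID_STOP_C, GRID_POINTS)


@dataclass(frozen=True)
class SimSampleSpec:
    """Ground truth and nuisance parameters for one simulated sample."""

    sample_id: str
    copy_numbers: Mapping[str, int]
    scale: float = 1.0
    baseline_intercept: float = DEFAULT_BASELINE_INTERCEPT
    baseline_slope: float = DEFAULT_BASELINE_SLOPE
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "copy_numbers", dict(self.copy_numbers))
        for gene, n in self.copy_numbers.items():
            if int(n) != n or n < 0:
                raise ValueError(f"{self.sample_id}: {gene} copies must be a nonnegative integer")
        if not self.scale > 0:
            raise ValueError(f"{self.sample_id}: scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"{self.sample_id}: noise_sd must be >= 0")
        if self.baseline_slope > 0:
            raise ValueError(f"{self.sample_id}: baseline_slope must be <= 0")


def simulate_curve(
    spec: SimSampleSpec,
    panel: AmpliconPanel | None = None,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> MeltCurve:
    """Render one melt curve from a sample spec.

    Copy numbers default to ``panel.reference_copies`` for the reference gene
    and must be given explicitly for every target gene. With ``noise_sd > 0``
    an ``rng`` is required; the same spec and rng state always reproduce the
    same curve.
    """
    panel = panel or default_panel()
    t = default_grid() if grid is None else np.asarray(grid, dtype=float)
    f = spec.baseline_intercept + spec.baseline_slope * (t - t[0])
    for amp in panel.amplicons:
        if amp.gene_name == panel.reference_gene:
            copies = spec.copy_numbers.get(amp.gene_name, panel.reference_copies)
        else:
            if amp.gene_name not in spec.copy_numbers:
                raise ValueError(
                    f"{spec.sample_id}: no copy number given for {amp.gene_name}"
                )
            copies = spec.copy_numbers[amp.gene_name]
        amplitude = spec.scale * amp.per_copy_amplitude * copies
        if amplitude > 0:
            f = f + amplitude / (1.0 + np.exp((t - amp.tm_c) / amp.transition_width_c))
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an explicit rng")
        f = f + rng.normal(0.0, spec.noise_sd, size=t.size)
    return MeltCurve(spec.sample_id, t, np.clip(f, 0.0, None))


@dataclass(frozen=True)
class CohortRow:
    """One genotype class of the simulated cohort.

    ``n_pregenotyped`` / ``n_unknown`` split ``count`` into the samples whose
    genotype was known before the run and those typed blind (they only matter
    for bookkeeping of the validation counts; the curves are identical).
    """

    genotype: str
    hba1_copies: int
    hba2_copies: int
    count: int
    n_pregenotyped: int | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"{self.genotype}: count must be >= 0")
        if self.n_pregenotyped is not None and not 0 <= self.n_pregenotyped <= self.count:
            raise ValueError(f"{self.genotype}: n_pregenotyped outside [0, count]")
        if self.hba1_copies < 0 or self.hba2_copies < 0:
            raise ValueError(f"{self.genotype}: copies must be nonnegative")

    @property
    def n_unknown(self) -> int:
        return self.count - (self.n_pregenotyped or 0)

    @property
    def copy_pair(self) -> tuple[int, int]:
        return (self.hba1_copies, self.hba2_copies)


@dataclass(frozen=True)
class SimCohortSpec:
    """A whole simulated run: genotype composition plus noise model."""

    rows: tuple[CohortRow, ...]
    seed: int = 0
    noise_sd: float = DEFAULT_NOISE_SD
    scale_sigma: float = DEFAULT_SCALE_SIGMA
    baseline_intercept: float = DEFAULT_BASELINE_INTERCEPT
    baseline_slope: float = DEFAULT_BASELINE_SLOPE
    control_sample_id: str = CONTROL_SAMPLE_ID

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        if sum(r.count for r in self.rows) < 1:
            raise ValueError("cohort must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return sum(r.count for r in self.rows)


def simulate_cohort(
    spec: SimCohortSpec,
    panel: AmpliconPanel | None = None,
    grid: np.ndarray | None = None,
) -> tuple[MeltRun, pd.DataFrame]:
    """Simulate a full run and its truth table.

    Returns a :class:`MeltRun` holding one wild-type control (copies 2,2)
    plus one curve per cohort sample, and a truth ``DataFrame`` with columns
    ``sample_id, genotype, hba1_copies, hba2_copies, subset`` (the control is
    a run fixture, not a cohort member, and is not listed in the truth table).
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(spec.seed)

    def draw_scale() -> float:
        return float(np.exp(rng.normal(0.0, spec.scale_sigma)))

    def make(sample_id: str, c1: int, c2: int) -> MeltCurve:
        g1, g2 = panel.target_genes
        s = SimSampleSpec(
            sample_id=sample_id,
            copy_numbers={g1: c1, g2: c2},
            scale=draw_scale(),
            baseline_intercept=spec.baseline_intercept,
            baseline_slope=spec.baseline_slope,
            noise_sd=spec.noise_sd,
        )
        return simulate_curve(s, panel, grid, rng)

    curves = {spec.control_sample_id: make(spec.control_sample_id, 2, 2)}
    records = []
    idx = 0
    for row in spec.rows:
        for k in range(row.count):
            idx += 1
            sid = f"S{idx:03d}"
            curves[sid] = make(sid, row.hba1_copies, row.hba2_copies)
            subset = (
                "pregenotyped"
                if row.n_pregenotyped is not None and k < row.n_pregenotyped
                else "unknown"
            )
            records.append(
                {
                    "sample_id": sid,
                    "genotype": row.genotype,
                    "hba1_copies": row.hba1_copies,
                    "hba2_copies": row.hba2_copies,
                    "subset": subset,
                }
            )
    truth = pd.DataFrame.from_records(records)
    return MeltRun(f"sim_seed{spec.seed}", curves, spec.control_sample_id), truth


def load_cohort_spec(path: str | Path, **overrides) -> SimCohortSpec:
    """Load a cohort spec from YAML.

    Top-level keys: ``rows`` (list of mappings with ``genotype``,
    ``hba1_copies``, ``hba2_copies``, ``count``, optional ``n_pregenotyped``)
    plus any :class:`SimCohortSpec` field. Keyword ``overrides`` win over the
    file (used by the CLI to inject ``--seed``).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping) or "rows" not in raw:
        raise PanelConfigError(f"{path}: cohort spec must be a mapping with a 'rows' list")
    rows = []
    for i, r in enumerate(raw["rows"]):
        ctx = f"{path}: rows[{i}]"
        if not isinstance(r, Mapping):
            raise PanelConfigError(f"{ctx}: must be a mapping")
        try:
            rows.append(
                CohortRow(
                    genotype=str(r.get("genotype", f"row{i + 1}")),
                    hba1_copies=int(r["hba1_copies"]),
                    hba2_copies=int(r["hba2_copies"]),
                    count=int(r["count"]),
                    n_pregenotyped=(
                        int(r["n_pregenotyped"]) if "n_pregenotyped" in r else None
                    ),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise PanelConfigError(f"{ctx}: {exc!r}") from exc
    kwargs = {
        k: raw[k]
        for k in (
            "seed",
            "noise_sd",
            "scale_sigma",
            "baseline_intercept",
            "baseline_slope",
            "control_sample_id",
        )
        if k in raw
    }
    kwargs.update(overrides)
    return SimCohortSpec(rows=tuple(rows), **kwargs)


def validation_cohort(seed: int = 0, **overrides) -> SimCohortSpec:
    """The bundled 167-sample validation cohort.

    Composition mirrors the assay's published validation set: 17 genotype
    classes spanning single- and double-gene deletions, α0 heterozygotes,
    Hb H patterns, a triplication, and point-mutation carriers that type as
    copy-normal. 105 samples are marked pre-genotyped and 62 unknown.
    """
    from importlib.resources import as_file, files

    with as_file(files("grace_melt.data") / "validation_cohort.yaml") as p:
        return load_cohort_spec(p, seed=seed, **overrides)
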