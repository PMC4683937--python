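"""Assay panel definitions.

A *panel* describes the multiplex melt assay: one low-Tm reference amplicon
(CLCN7, assumed two copies in every sample) and an ordered set of target
amplicons (HBA1, HBA2) whose product amounts — and hence melt-step amplitudes —
are proportional to gene copy number. Amplicon melting temperatures are spaced
~3 °C apart so each product contributes a separable melt transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import PanelConfigError

__all__ = ["AmpliconDef", "AmpliconPanel", "load_panel", "default_panel"]

#: Default half-width (°C) of the temperature window used to assign a
#: derivative peak to an amplicon. Tms are ~3 °C apart, so ±1.2 °C windows
#: never overlap.
DEFAULT_ASSIGNMENT_WINDOW_C = 1.2

#: Default logistic transition width (°C) used by the simulator. Chosen so a
#: short-amplicon melt completes within ~1 °C, leaving flat inter-melt plateaus
#: for the normalization windows (see docs/methods.md).
DEFAULT_TRANSITION_WIDTH_C = 0.2


@dataclass(frozen=True)
class AmpliconDef:
    """One amplicon in the panel.

    Parameters
    ----------
    gene_name
        Gene symbol the amplicon targets (e.g. ``"CLCN7"``).
    tm_c
        Product melting temperature in °C.
    transition_width_c
        Logistic width of the melt transition in °C (simulator parameter).
    per_copy_amplitude
        Dimensionless fluorescence drop contributed per gene copy.
    assignment_window_c
        Half-width in °C of the peak-to-amplicon assignment window.
    """

    gene_name: str
    tm_c: float
    transition_width_c: float = DEFAULT_TRANSITION_WIDTH_C
    per_copy_amplitude: float = 1.0
    assignment_window_c: float = DEFAULT_ASSIGNMENT_WINDOW_C

    def __post_init__(self) -> None:
        if not self.gene_name:
            raise PanelConfigError("amplicon gene_name must be non-empty")
        if not self.transition_width_c > 0:
            raise PanelConfigError(
                f"{self.gene_name}: transition_width_c must be > 0, "
                f"got {self.transition_width_c}"
            )
        if not self.per_copy_amplitude > 0:
            raise PanelConfigError(
                f"{self.gene_name}: per_copy_amplitude must be > 0, "
                f"got {self.per_copy_amplitude}"
            )
        if not self.assignment_window_c > 0:
            raise PanelConfigError(
                f"{self.gene_name}: assignment_window_c must be > 0, "
                f"got {self.assignment_window_c}"
            )


@dataclass(frozen=True)
class AmpliconPanel:
    """The full assay definition.

    ``amplicons`` are kept sorted by ascending Tm; the reference amplicon must
    be the lowest-Tm one (as in the assay, where CLCN7 melts first), and its
    copy number (``reference_copies``, normally 2) anchors all ratio math.
    """

    amplicons: tuple[AmpliconDef, ...]
    reference_gene: str = "CLCN7"
    reference_copies: int = 2
    target_genes: tuple[str, ...] = ("HBA1", "HBA2")
    allowed_copy_states: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        amps = tuple(sorted(self.amplicons, key=lambda a: a.tm_c))
        object.__setattr__(self, "amplicons", amps)
        names = [a.gene_name for a in amps]
        if len(set(names)) != len(names):
            raise PanelConfigError(f"duplicate amplicon gene names: {names}")
        if self.reference_gene not in names:
            raise PanelConfigError(
                f"reference_gene {self.reference_gene!r} has no amplicon"
            )
        if names[0] != self.reference_gene:
            raise PanelConfigError(
                "reference amplicon must have the lowest Tm "
                f"(got order {names}, reference {self.reference_gene!r})"
            )
        for gene in self.target_genes:
            if gene not in names:
                raise PanelConfigError(f"target gene {gene!r} has no amplicon")
        if self.reference_copies < 1:
            raise PanelConfigError(
                f"reference_copies must be >= 1, got {self.reference_copies}"
            )
        # Peak-assignment windows of distinct amplicons must not overlap.
        for a, b in zip(amps, amps[1:]):
            gap = b.tm_c - a.tm_c
            if gap < a.assignment_window_c + b.assignment_window_c:
                raise PanelConfigError(
                    "assignment windows overlap: "
                    f"{a.gene_name} (Tm {a.tm_c} ± {a.assignment_window_c}) and "
                    f"{b.gene_name} (Tm {b.tm_c} ± {b.assignment_window_c})"
                )
        states = dict(self.allowed_copy_states)
        for gene in self.target_genes:
            states.setdefault(gene, (0, 1, 2, 3))
        object.__setattr__(
            self,
            "allowed_copy_states",
            {g: tuple(sorted(int(s) for s in v)) for g, v in states.items()},
        )

    # -- convenience lookups -------------------------------------------------

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(a.gene_name for a in self.amplicons)

    def amplicon(self, gene: str) -> AmpliconDef:
        for a in self.amplicons:
            if a.gene_name == gene:
                return a
        raise KeyError(gene)

    @property
    def reference(self) -> AmpliconDef:
        return self.amplicon(self.reference_gene)

    def tm_gap(self, lower_gene: str, upper_gene: str) -> tuple[float, float]:
        """Return the (Tm_lower, Tm_upper) pair bounding an inter-melt gap."""
        lo, hi = self.amplicon(lower_gene).tm_c, self.amplicon(upper_gene).tm_c
        if not lo < hi:
            raise ValueError(f"{lower_gene} does not melt below {upper_gene}")
        return lo, hi


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise PanelConfigError(f"{context}: missing required field {key!r}")
    return mapping[key]


def load_panel(path: str | Path) -> AmpliconPanel:
    """Load a panel from a YAML configuration file.

    The file has top-level keys ``reference``, ``reference_copies``,
    ``targets``, optionally ``allowed_copy_states``, and ``amplicons`` — a list
    of mappings with ``name``, ``tm_c``, and optional ``width_c``,
    ``per_copy_amplitude``, ``window_c``.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise PanelConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise PanelConfigError(f"{path}: top level must be a mapping")

    amp_specs = _require(raw, "amplicons", str(path))
    if not isinstance(amp_specs, Sequence) or isinstance(amp_specs, (str, bytes)):
        raise PanelConfigError(f"{path}: 'amplicons' must be a list")
    amplicons = []
    for i, spec in enumerate(amp_specs):
        ctx = f"{path}: amplicons[{i}]"
        if not isinstance(spec, Mapping):
            raise PanelConfigError(f"{ctx}: must be a mapping")
        try:
            amplicons.append(
                AmpliconDef(
                    gene_name=str(_require(spec, "name", ctx)),
                    tm_c=float(_require(spec, "tm_c", ctx)),
                    transition_width_c=float(
                        spec.get("width_c", DEFAULT_TRANSITION_WIDTH_C)
                    ),
                    per_copy_amplitude=float(spec.get("per_copy_amplitude", 1.0)),
                    assignment_window_c=float(
                        spec.get("window_c", DEFAULT_ASSIGNMENT_WINDOW_C)
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise PanelConfigError(f"{ctx}: {exc}") from exc

    states = raw.get("allowed_copy_states", {})
    if not isinstance(states, Mapping):
        raise PanelConfigError(f"{path}: 'allowed_copy_states' must be a mapping")

    try:
        return AmpliconPanel(
            amplicons=tuple(amplicons),
            reference_gene=str(_require(raw, "reference", str(path))),
            reference_copies=int(raw.get("reference_copies", 2)),
            target_genes=tuple(_require(raw, "targets", str(path))),
            allowed_copy_states={g: tuple(v) for g, v in states.items()},
        )
    except (TypeError, ValueError) as exc:
        raise PanelConfigError(f"{path}: {exc}") from exc


def default_panel() -> AmpliconPanel:
    """The bundled CLCN7/HBA1/HBA2 panel (product Tms 79.4/82.2/85.2 °C)."""
    from importlib.resources import as_file, files

    with as_file(files("grace_melt.data") / "default_panel.yaml") as p:
        return load_panel(p)
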