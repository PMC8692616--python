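"""Replicate-level measurement curves and their long-format CSV serialization.

A :class:`Spectrum` holds one measured (or simulated) curve of a single
modality — a solid-state NMR spectrum, a time-domain NMR magnetization decay,
an ATR FT-IR spectrum, or a DTG (derivative thermogravimetry) curve — together
with its provenance: which sample pool and replicate it belongs to, and the
ordered list of processing steps (``lineage``) it has been through.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Recognized modalities and their natural axis units.
AXIS_UNITS = {
    "h1_wideline": "ppm",
    "h1_mas": "ppm",
    "c13_cpmas": "ppm",
    "tdnmr": "s",
    "ftir": "cm-1",
    "dtg": "degC",
}

#: Replicate index used to mark a replicate-averaged aggregate curve.
AGGREGATE_REPLICATE = -1


@dataclass(frozen=True)
class Spectrum:
    """One replicate measurement curve.

    Parameters
    ----------
    modality:
        One of ``h1_wideline``, ``h1_mas``, ``c13_cpmas``, ``tdnmr``,
        ``ftir``, ``dtg``.
    axis, intensity:
        Equal-length 1-D arrays; the axis must be strictly monotone.
    sample_id, replicate:
        Provenance of the curve. ``replicate == -1`` marks an aggregate.
    sample_weight:
        Sample mass in mg (DTG only; used for weight normalization).
    lineage:
        Append-only tuple of processing-step tokens.
    derivative_order:
        0 for a raw profile, 2 after Savitzky-Golay second differentiation.
    """

    modality: str
    axis: np.ndarray
    intensity: np.ndarray
    sample_id: str
    replicate: int = 0
    axis_unit: str = ""
    sample_weight: float | None = None
    lineage: tuple[str, ...] = ()
    derivative_order: int = 0

    def __post_init__(self) -> None:
        if self.modality not in AXIS_UNITS:
            raise ValueError(f"unknown modality {self.modality!r}")
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if axis.ndim != 1 or intensity.ndim != 1:
            raise ValueError("axis and intensity must be 1-D")
        if axis.shape != intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        if axis.size >= 2:
            steps = np.diff(axis)
            if not (np.all(steps > 0) or np.all(steps < 0)):
                raise ValueError("axis must be strictly monotone")
        if self.derivative_order not in (0, 2):
            raise ValueError("derivative_order must be 0 or 2")
        if not self.axis_unit:
            object.__setattr__(self, "axis_unit", AXIS_UNITS[self.modality])

    # -- convenience -------------------------------------------------------

    @property
    def n_points(self) -> int:
        return int(self.axis.size)

    def evolve(self, step: str, **changes) -> "Spectrum":
        """Return a copy with ``step`` appended to the lineage."""
        changes.setdefault("lineage", self.lineage + (step,))
        return replace(self, **changes)

    def ascending(self) -> "Spectrum":
        """Return a copy with the axis sorted ascending (no lineage entry)."""
        if self.axis.size < 2 or self.axis[1] > self.axis[0]:
            return self
        return replace(self, axis=self.axis[::-1].copy(),
                       intensity=self.intensity[::-1].copy())


# -- long-format CSV round-trip -------------------------------------------

_LONG_COLUMNS = ["sample_id", "replicate", "modality", "axis_value",
                 "intensity", "axis_unit", "sample_weight_mg"]


def spectra_to_frame(spectra: Iterable[Spectrum]) -> pd.DataFrame:
    """Flatten spectra into the long-format table (one row per point)."""
    chunks = []
    for sp in spectra:
        chunks.append(pd.DataFrame({
            "sample_id": sp.sample_id,
            "replicate": sp.replicate,
            "modality": sp.modality,
            "axis_value": sp.axis,
            "intensity": sp.intensity,
            "axis_unit": sp.axis_unit,
            "sample_weight_mg": np.nan if sp.sample_weight is None
            else sp.sample_weight,
        }))
    if not chunks:
        return pd.DataFrame(columns=_LONG_COLUMNS)
    return pd.concat(chunks, ignore_index=True)[_LONG_COLUMNS]


def frame_to_spectra(frame: pd.DataFrame) -> list[Spectrum]:
    """Rebuild :class:`Spectrum` objects from a long-format table.

    Rows are grouped by (sample_id, modality, replicate); the within-group
    row order defines the axis order, so the round trip is lossless.
    """
    spectra = []
    for (sid, modality, rep), grp in frame.groupby(
            ["sample_id", "modality", "replicate"], sort=True):
        weight = grp["sample_weight_mg"].iloc[0]
        spectra.append(Spectrum(
            modality=modality,
            axis=grp["axis_value"].to_numpy(dtype=float),
            intensity=grp["intensity"].to_numpy(dtype=float),
            sample_id=str(sid),
            replicate=int(rep),
            axis_unit=str(grp["axis_unit"].iloc[0]),
            sample_weight=None if pd.isna(weight) else float(weight),
        ))
    return spectra


def write_spectra_csv(spectra: Sequence[Spectrum], path) -> None:
    spectra_to_frame(spectra).to_csv(path, index=False)


def read_spectra_csv(path) -> list[Spectrum]:
    return frame_to_spectra(pd.read_csv(path))
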