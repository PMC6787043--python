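"""Spectrum data model, instrument profiles, and plain-text spectrum I/O.

A :class:`RamanSpectrum` is one acquisition: a strictly increasing Raman-shift
axis (cm^-1), non-negative intensities (counts per second while raw, unit-area
normalized units at the end of preprocessing), and acquisition metadata.
Spectra move through a monotone sequence of processing stages::

    raw -> despiked -> baseline_corrected -> normalized

The two :class:`InstrumentProfile` constants describe the portable systems the
pipeline targets: a 1064 nm unit (InGaAs detector, 428 effective channels over
247-2500 cm^-1) and a 785 nm unit (CCD, 1804 channels over 175-3201 cm^-1).
The 1064 nm detector cannot reach the high-wavenumber C-H stretch region
(2800-3200 cm^-1); only the 785 nm profile covers it, which is why the two
profiles carry different area-normalization regions.

File format: two numeric columns (shift, intensity), comma- or
whitespace-delimited, with optional ``#``-prefixed ``key: value`` header lines
carrying metadata.  Round-trips are lossless to 15 significant digits.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .errors import (
    AxisOrderError,
    CoverageError,
    EmptyInputError,
    ShapeError,
    SpectrumParseError,
    StageError,
)

STAGES = ("raw", "despiked", "baseline_corrected", "normalized")
LABELS = ("healthy", "tumor", "mixed", "unknown")
MODES = ("microscope", "probe")


@dataclass(frozen=True)
class InstrumentProfile:
    """Operating characteristics of one spectrometer.

    ``resolution`` is the vendor-quoted inter-pixel resolution at 1600 cm^-1;
    the working axis is the uniform grid ``np.linspace(shift_min, shift_max,
    n_channels)``.  ``normalization_region`` is the (lo, hi) interval over
    which preprocessed spectra are scaled to unit area.
    """

    excitation_nm: int
    shift_min: float
    shift_max: float
    n_channels: int
    resolution: float
    normalization_region: tuple[float, float]

    def axis(self) -> np.ndarray:
        return np.linspace(self.shift_min, self.shift_max, self.n_channels)


#: i-Raman-class 1064 nm system: 512-pixel InGaAs detector, 428 effective
#: channels, fingerprint region only.
PROFILE_1064 = InstrumentProfile(
    excitation_nm=1064,
    shift_min=247.0,
    shift_max=2500.0,
    n_channels=428,
    resolution=5.07,
    normalization_region=(400.0, 1800.0),
)

#: i-Raman-class 785 nm system: 2048-pixel CCD, 1804 effective channels,
#: fingerprint plus high-wavenumber regions.
PROFILE_785 = InstrumentProfile(
    excitation_nm=785,
    shift_min=175.0,
    shift_max=3201.0,
    n_channels=1804,
    resolution=1.78,
    normalization_region=(400.0, 3200.0),
)

PROFILES: dict[int, InstrumentProfile] = {1064: PROFILE_1064, 785: PROFILE_785}


@dataclass
class RamanSpectrum:
    """One Raman acquisition with its processing provenance."""

    shift: np.ndarray
    intensity: np.ndarray
    excitation_nm: int = 785
    mode: str = "microscope"
    integration_s: float = 30.0
    label: str = "unknown"
    site_id: str = ""
    position: tuple[float, float] | None = None
    stage: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift.ndim != 1 or self.intensity.ndim != 1:
            raise ShapeError("shift and intensity must be 1-D vectors")
        if self.shift.size != self.intensity.size:
            raise ShapeError(
                f"shift ({self.shift.size}) and intensity ({self.intensity.size}) "
                "differ in length"
            )
        if self.shift.size < 2:
            raise EmptyInputError("a spectrum needs at least 2 channels")
        if not np.all(np.diff(self.shift) > 0):
            raise AxisOrderError("Raman-shift axis must be strictly increasing")
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if self.label not in LABELS:
            from .errors import LabelError

            raise LabelError(f"unknown tissue label {self.label!r}")

    # -- stage bookkeeping -------------------------------------------------

    def advance_stage(self, new_stage: str) -> None:
        """Move to ``new_stage``; transitions must respect the stage order."""
        if new_stage not in STAGES:
            raise StageError(f"unknown stage {new_stage!r}")
        if STAGES.index(new_stage) <= STAGES.index(self.stage):
            raise StageError(
                f"cannot move from stage {self.stage!r} to {new_stage!r}: "
                "stages are monotone"
            )
        self.stage = new_stage

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, spectrum is at "
                f"{self.stage!r}"
            )

    def replace(self, **changes: Any) -> "RamanSpectrum":
        """Copy with field changes (metadata dict is shallow-copied)."""
        out = dataclasses.replace(self, **changes)
        if "meta" not in changes:
            out.meta = dict(self.meta)
        return out

    @property
    def profile(self) -> InstrumentProfile:
        return PROFILES[self.excitation_nm]


# -- text I/O ---------------------------------------------------------------

_META_FIELDS = ("excitation_nm", "mode", "integration_s", "label", "site_id", "stage")


def _format_header(s: RamanSpectrum) -> list[str]:
    lines = [f"# {k}: {getattr(s, k)}" for k in _META_FIELDS]
    if s.position is not None:
        lines.append(f"# x_mm: {s.position[0]!r}")
        lines.append(f"# y_mm: {s.position[1]!r}")
    for k, v in s.meta.items():
        lines.append(f"# {k}: {v}")
    return lines


def write_spectrum(s: RamanSpectrum, path: str | Path) -> None:
    """Write a spectrum as ``#``-headed two-column CSV, 15 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        for line in _format_header(s):
            fh.write(line + "\n")
        for x, y in zip(s.shift, s.intensity):
            fh.write(f"{x:.15g},{y:.15g}\n")


def _coerce_meta(meta: dict[str, Any]) -> dict[str, Any]:
    out = dict(meta)
    if "excitation_nm" in out:
        out["excitation_nm"] = int(float(out["excitation_nm"]))
    if "integration_s" in out:
        out["integration_s"] = float(out["integration_s"])
    return out


def read_spectrum(path: str | Path, **overrides: Any) -> RamanSpectrum:
    """Read a two-column text/CSV spectrum file.

    ``#``-prefixed ``key: value`` header lines populate metadata; keyword
    overrides win over the header.  Malformed numeric rows raise
    :class:`SpectrumParseError` with the offending line number rather than
    being skipped.
    """
    path = Path(path)
    header: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"expected 2 numeric columns, got {len(parts)}", line=lineno
                )
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"non-numeric cell: {exc}", line=lineno)
    if not xs:
        raise EmptyInputError(f"{path}: no data rows")

    known = {k: header[k] for k in _META_FIELDS if k in header}
    position = None
    if "x_mm" in header and "y_mm" in header:
        position = (float(header["x_mm"]), float(header["y_mm"]))
    extra = {
        k: v
        for k, v in header.items()
        if k not in _META_FIELDS and k not in ("x_mm", "y_mm")
    }
    fields: dict[str, Any] = {**_coerce_meta(known), "position": position, "meta": extra}
    fields.update(overrides)
    return RamanSpectrum(shift=np.array(xs), intensity=np.array(ys), **fields)


def spectrum_to_string(s: RamanSpectrum) -> str:
    buf = io.StringIO()
    for line in _format_header(s):
        buf.write(line + "\n")
    for x, y in zip(s.shift, s.intensity):
        buf.write(f"{x:.15g},{y:.15g}\n")
    return buf.getvalue()


# -- resampling -------------------------------------------------------------

def resample_to_profile(
    s: RamanSpectrum, profile: InstrumentProfile, min_coverage: float = 0.9
) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto an instrument's uniform axis.

    The spectrum must cover at least ``min_coverage`` of the profile's range.
    Channels outside the spectrum's support are zero-filled and their count is
    recorded in ``meta['resample_zero_filled']``.  Spectra already on the
    profile axis are returned unchanged (idempotence).
    """
    axis = profile.axis()
    if s.shift.size == axis.size and np.array_equal(s.shift, axis):
        return s.replace()
    lo, hi = max(s.shift[0], axis[0]), min(s.shift[-1], axis[-1])
    covered = max(0.0, hi - lo) / (axis[-1] - axis[0])
    if covered < min_coverage:
        raise CoverageError(
            f"spectrum covers {covered:.0%} of the {profile.excitation_nm} nm "
            f"axis; at least {min_coverage:.0%} required"
        )
    out = np.interp(axis, s.shift, s.intensity, left=0.0, right=0.0)
    outside = (axis < s.shift[0]) | (axis > s.shift[-1])
    new = s.replace(shift=axis, intensity=out)
    new.meta["resample_zero_filled"] = int(outside.sum())
    return new


# -- cohort manifest --------------------------------------------------------

MANIFEST_COLUMNS = ["path", "excitation_nm", "mode", "label", "site_id", "x", "y"]


def write_manifest(rows: Iterable[dict[str, Any]], path: str | Path) -> None:
    df = pd.DataFrame(list(rows))
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_cohort(manifest_path: str | Path) -> list[RamanSpectrum]:
    """Load every spectrum listed in a manifest CSV (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if df.empty:
        raise EmptyInputError(f"{manifest_path}: empty manifest")
    spectra = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        overrides: dict[str, Any] = {}
        for key in ("excitation_nm", "mode", "label", "site_id"):
            if key in row and not pd.isna(row[key]):
                overrides[key] = row[key]
        if "excitation_nm" in overrides:
            overrides["excitation_nm"] = int(overrides["excitation_nm"])
        if "x" in row and not pd.isna(row["x"]):
            overrides["position"] = (float(row["x"]), float(row["y"]))
        spectra.append(read_spectrum(p, **overrides))
    return spectra
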