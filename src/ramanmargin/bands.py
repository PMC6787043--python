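"""Class envelopes, discriminative band selection, dye exclusion, and
band-feature extraction.

The discriminative-band selector implements the confidence-interval overlap
criterion used to shrink a full spectrum (428 or 1804 channels) to a handful
of informative wavenumber windows: wherever the 95% t-interval around the
healthy class mean separates from the interval around the tumor class mean,
the channelwise separation gap is positive; contiguous runs of positive gap
wide enough to be more than a noise blip become candidate bands, scored by
their integrated gap area.

Two reference band sets ship with the package: 12 windows for the 1064 nm
system and 17 for the 785 nm system, named ``B_<center>``.  Surgical marking
ink adds its own Raman bands (693, 1260, 1348, 1398, 1541, 1597 cm^-1);
:func:`exclude_dye_bands` drops any reference window whose interval touches
an ink line so classification never reads contaminated channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AxisMismatchError,
    BandCoverageError,
    EmptyInputError,
    InsufficientSampleError,
)
from .spectra import PROFILES, InstrumentProfile, RamanSpectrum
from .synthetic import DYE_CENTERS


@dataclass(frozen=True)
class BandWindow:
    """A named wavenumber interval whose mean intensity is one feature."""

    center: float
    half_width: float
    name: str
    contaminated: bool = False
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width

    def intersects(self, lo: float, hi: float) -> bool:
        """Closed-interval intersection (shared endpoint counts)."""
        return self.lo <= hi and lo <= self.hi


@dataclass
class BandSet:
    """Ordered collection of band windows tied to an instrument profile."""

    windows: list[BandWindow]
    profile: InstrumentProfile

    def __post_init__(self) -> None:
        names = [w.name for w in self.windows]
        if len(names) != len(set(names)):
            raise ValueError("band names must be unique within a BandSet")

    @property
    def active(self) -> list[BandWindow]:
        return [w for w in self.windows if not w.contaminated]

    @property
    def names(self) -> list[str]:
        return [w.name for w in self.active]

    def __len__(self) -> int:
        return len(self.windows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "excitation_nm": self.profile.excitation_nm,
            "windows": [
                {
                    "name": w.name,
                    "center": w.center,
                    "half_width": w.half_width,
                    "contaminated": w.contaminated,
                    "assignment": w.assignment,
                }
                for w in self.windows
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BandSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        windows = [BandWindow(**w) for w in payload["windows"]]
        return cls(windows=windows, profile=PROFILES[payload["excitation_nm"]])


_ASSIGNMENTS = {
    742: "Ring breathing of DNA/RNA bases; tryptophan",
    870: "C-C stretch, collagen backbone / proline",
    941: "Proline, nu(C-C) collagen backbone; polysaccharides",
    1002: "Phenylalanine ring breathing",
    1006: "Phenylalanine ring breathing",
    1062: "Chain C-C stretch in lipids; O-P-O in DNA/RNA",
    1063: "Chain C-C stretch in lipids; O-P-O in DNA/RNA",
    1081: "Nucleic acids; C-C/C-O in phospholipids",
    1082: "Nucleic acids; C-C/C-O in phospholipids",
    1302: "CH2 twist of lipids/fatty acids/collagen",
    1303: "CH2 twist of lipids/fatty acids/collagen",
    1331: "DNA, phospholipids",
    1439: "CH2 bend, normal breast tissue",
    1442: "CH2 bend, normal breast tissue",
    1448: "CH2 bend, malignant breast tissue",
    1453: "CH2 bend, malignant breast tissue",
    1627: "Amide I",
    1640: "Amide I",
    1653: "C=C of lipids in healthy tissue",
    1657: "C=C of lipids in healthy tissue",
    1663: "Nucleic acid modes; amide I",
    1682: "Amide I disorder, collagen",
    1683: "Amide I disorder, collagen",
    1746: "nu(C=O) of phospholipids",
    2850: "CH2 symmetric stretch of lipids",
    2893: "CH2 asymmetric stretch, lipids+proteins",
    2933: "CH3 asymmetric stretch of proteins",
}

_REFERENCE_CENTERS = {
    1064: (941, 1006, 1063, 1081, 1303, 1442, 1453, 1627, 1653, 1663, 1683, 1746),
    785: (742, 870, 941, 1002, 1062, 1082, 1302, 1331, 1439, 1448, 1640, 1657,
          1682, 1746, 2850, 2893, 2933),
}

# Window half-widths for the shipped sets.  1064 nm: 2x the coarse
# instrument resolution.  785 nm: 8 cm^-1, wide enough to cover the band
# assignment ranges (e.g. 1325-1333 for the DNA band) at the fine CCD
# resolution and to register overlap with adjacent surgical-ink lines.
_REFERENCE_HALF_WIDTH = {1064: 2 * PROFILES[1064].resolution, 785: 8.0}


def reference_bands(excitation_nm: int) -> BandSet:
    """The shipped reference band set: 12 windows (1064 nm) or 17 (785 nm)."""
    profile = PROFILES[excitation_nm]
    hw = _REFERENCE_HALF_WIDTH[excitation_nm]
    windows = [
        BandWindow(
            center=float(c),
            half_width=hw,
            name=f"B_{c}",
            assignment=_ASSIGNMENTS.get(c, ""),
        )
        for c in _REFERENCE_CENTERS[excitation_nm]
    ]
    return BandSet(windows=windows, profile=profile)


# -- class envelopes --------------------------------------------------------

@dataclass
class ClassEnvelope:
    """Channelwise mean and t-based confidence band of one tissue class."""

    shift: np.ndarray
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int
    level: float = 0.95


def _common_axis(spectra: list[RamanSpectrum]) -> np.ndarray:
    axis = spectra[0].shift
    for s in spectra[1:]:
        if s.shift.size != axis.size or not np.array_equal(s.shift, axis):
            raise AxisMismatchError("spectra are not on a common axis")
    return axis


def class_envelope(
    spectra: list[RamanSpectrum], level: float = 0.95
) -> ClassEnvelope:
    """Channelwise mean +- t_{n-1,1-alpha/2} * sd / sqrt(n)."""
    if len(spectra) < 2:
        raise InsufficientSampleError(
            f"class envelope needs >= 2 spectra, got {len(spectra)}"
        )
    for s in spectra:
        s.require_stage("normalized")
    axis = _common_axis(spectra)
    mat = np.vstack([s.intensity for s in spectra])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    half = stats.t.ppf(0.5 + level / 2.0, df=n - 1) * sd / np.sqrt(n)
    return ClassEnvelope(
        shift=axis,
        mean=mean,
        ci_lower=mean - half,
        ci_upper=mean + half,
        n=n,
        level=level,
    )


def difference_spectrum(tumor: ClassEnvelope, healthy: ClassEnvelope) -> np.ndarray:
    """Tumor mean minus healthy mean; positive where tumor flux is greater."""
    if tumor.shift.size != healthy.shift.size or not np.array_equal(
        tumor.shift, healthy.shift
    ):
        raise AxisMismatchError("envelopes are not on a common axis")
    return tumor.mean - healthy.mean


# -- CI-based band selection ------------------------------------------------

def separation_gap(healthy: ClassEnvelope, tumor: ClassEnvelope) -> np.ndarray:
    """Channelwise distance between the two confidence envelopes (0 where
    they overlap)."""
    if not np.array_equal(healthy.shift, tumor.shift):
        raise AxisMismatchError("envelopes are not on a common axis")
    gap = np.maximum(
        healthy.ci_lower - tumor.ci_upper, tumor.ci_lower - healthy.ci_upper
    )
    return np.maximum(gap, 0.0)


def select_discriminative_bands(
    healthy: ClassEnvelope,
    tumor: ClassEnvelope,
    min_width: float | None = None,
    merge_gap: float | None = None,
    top_k: int | None = None,
    profile: InstrumentProfile | None = None,
) -> BandSet:
    """Turn runs of non-overlapping confidence intervals into a BandSet.

    Contiguous runs of positive separation gap wider than ``min_width``
    (default 2x the channel spacing, i.e. at least three channels) become
    candidate regions; runs closer than ``merge_gap`` (default 2x channel
    spacing) merge.  Regions are scored by integrated gap area and reported
    as windows centered on the gap-area centroid, sorted by descending score
    (ties: lower wavenumber first).  No candidate regions is a valid outcome
    and yields an empty BandSet.
    """
    x = healthy.shift
    gap = separation_gap(healthy, tumor)
    dx = float(np.median(np.diff(x)))
    if min_width is None:
        min_width = 2.0 * dx
    if merge_gap is None:
        merge_gap = 2.0 * dx

    # contiguous runs of gap > 0
    pos = gap > 0
    runs: list[tuple[int, int]] = []  # [start, end] inclusive
    i = 0
    while i < pos.size:
        if pos[i]:
            j = i
            while j + 1 < pos.size and pos[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    # merge runs separated by less than merge_gap
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and x[start] - x[merged[-1][1]] < merge_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    wide = [(a, b) for a, b in merged if x[b] - x[a] > min_width]

    scored = []
    for a, b in wide:
        seg_x, seg_g = x[a : b + 1], gap[a : b + 1]
        area = float(np.trapezoid(seg_g, seg_x))
        centroid = float(np.trapezoid(seg_g * seg_x, seg_x) / area) if area > 0 else float(
            seg_x.mean()
        )
        scored.append((area, centroid, (x[b] - x[a]) / 2.0))
    scored.sort(key=lambda t: (-t[0], t[1]))
    if top_k is not None:
        scored = scored[:top_k]

    if profile is None:
        for p in PROFILES.values():
            if x.size == p.n_channels and np.allclose(x, p.axis()):
                profile = p
                break
        else:
            profile = InstrumentProfile(
                excitation_nm=0,
                shift_min=float(x[0]),
                shift_max=float(x[-1]),
                n_channels=int(x.size),
                resolution=dx,
                normalization_region=(float(x[0]), float(x[-1])),
            )
    windows = []
    used_names: set[str] = set()
    for area, centroid, hw in scored:
        name = f"B_{int(round(centroid))}"
        while name in used_names:
            name += "'"
        used_names.add(name)
        windows.append(
            BandWindow(center=centroid, half_width=max(hw, dx), name=name)
        )
    return BandSet(windows=windows, profile=profile)


# -- dye exclusion ----------------------------------------------------------

def exclude_dye_bands(
    bands: BandSet,
    dye_centers: tuple[float, ...] = DYE_CENTERS,
    tolerance: float = 10.0,
) -> BandSet:
    """Flag (and thereby drop from the active set) windows touching ink lines.

    A window is contaminated when its closed interval intersects any
    ``dye_center +- tolerance`` interval.  Idempotent; dropped names are
    recorded so runs can report what was excluded.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    new_windows = []
    dropped = []
    for w in bands.windows:
        hit = any(w.intersects(c - tolerance, c + tolerance) for c in dye_centers)
        if hit and not w.contaminated:
            w = replace(w, contaminated=True)
        if w.contaminated:
            dropped.append(w.name)
        new_windows.append(w)
    out = BandSet(windows=new_windows, profile=bands.profile)
    out.dropped = dropped  # type: ignore[attr-defined]
    return out


# -- feature extraction -----------------------------------------------------

@dataclass
class FeatureTable:
    """Spectra x bands matrix of windowed mean intensities, plus labels."""

    values: pd.DataFrame  # rows: spectra (index = site ids), cols: band names
    labels: pd.Series  # aligned with values.index

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def band_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        df = self.values.copy()
        df["label"] = self.labels.values
        df.to_csv(path, index_label="site_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="site_id")
        labels = df.pop("label")
        return cls(values=df, labels=labels)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(values=self.values.iloc[mask], labels=self.labels.iloc[mask])


def extract_band_features(
    spectra: list[RamanSpectrum], bands: BandSet
) -> FeatureTable:
    """Windowed mean intensity per active band, one row per spectrum."""
    if len(spectra) == 0:
        raise EmptyInputError("no spectra to extract features from")
    active = bands.active
    if not active:
        raise EmptyInputError("band set has no active (uncontaminated) windows")
    for s in spectra:
        s.require_stage("normalized")
    axis = _common_axis(spectra)

    masks = []
    for w in active:
        m = (axis >= w.lo) & (axis <= w.hi)
        if not m.any():
            raise BandCoverageError(
                f"band {w.name} ({w.lo:.1f}-{w.hi:.1f} cm^-1) has no channels "
                "on the spectrum axis"
            )
        masks.append(m)

    rows = []
    ids = []
    for i, s in enumerate(spectra):
        rows.append([float(s.intensity[m].mean()) for m in masks])
        ids.append(s.site_id or f"s{i + 1}")
    # site ids may repeat across cohorts; disambiguate for the index
    seen: dict[str, int] = {}
    uniq = []
    for sid in ids:
        seen[sid] = seen.get(sid, 0) + 1
        uniq.append(sid if seen[sid] == 1 else f"{sid}_{seen[sid]}")
    values = pd.DataFrame(rows, columns=[w.name for w in active], index=uniq)
    labels = pd.Series([s.label for s in spectra], index=uniq, name="label")
    return FeatureTable(values=values, labels=labels)
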