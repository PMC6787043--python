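"""Margin-transit analysis: ordered classification and boundary detection.

A transit is a sequence of measurement sites spaced ~1 mm apart crossing the
visible boundary between healthy and tumor tissue.  Each site's normalized
spectrum is classified independently with a trained PCA-LDA model; the
posterior-probability sequence is then thresholded and a boundary is
reported wherever consecutive thresholded labels differ.  Mixed-histology
sites are never a trained class — they surface only through intermediate
posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandSet, extract_band_features
from .classify import LDAModel, PCAModel, predict_lda, project
from .errors import InsufficientSampleError, ProfileMismatchError
from .spectra import RamanSpectrum


@dataclass
class TransitResult:
    """Per-site classification of one margin transit, in site order."""

    site_ids: list[str]
    positions_mm: list[float]
    true_labels: list[str]  # ground truth where known, else "unknown"
    predicted: list[str]
    posterior_tumor: np.ndarray
    boundaries: list[int]  # boundary after site index i (0-based)

    def to_frame(self) -> pd.DataFrame:
        boundary_after = [i in self.boundaries for i in range(len(self.site_ids))]
        return pd.DataFrame(
            {
                "site_id": self.site_ids,
                "position_mm": self.positions_mm,
                "true_label": self.true_labels,
                "predicted": self.predicted,
                "posterior_tumor": self.posterior_tumor,
                "boundary_after": boundary_after,
            }
        )


def classify_transit(
    transit: list[RamanSpectrum],
    bands: BandSet,
    pca: PCAModel,
    lda: LDAModel,
    k: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Classify each site of an ordered transit; order is preserved.

    The spectra must be normalized and on the same instrument profile the
    band set (and hence the models) were built for.
    """
    if not transit:
        raise InsufficientSampleError("empty transit")
    for s in transit:
        if s.excitation_nm != bands.profile.excitation_nm:
            raise ProfileMismatchError(
                f"transit spectrum at {s.excitation_nm} nm does not match the "
                f"band set profile ({bands.profile.excitation_nm} nm)"
            )
    features = extract_band_features(transit, bands)
    if features.band_names != pca.feature_names:
        raise ProfileMismatchError(
            "band set does not match the bands the PCA model was trained on"
        )
    k = k if k is not None else lda.dim
    scores = project(pca, features, k=k)
    return predict_lda(lda, scores)


def detect_transitions(
    posterior_sequence: np.ndarray, threshold: float = 0.5
) -> list[int]:
    """Boundary indices of a posterior(tumor) sequence.

    Index ``i`` means a healthy/tumor transition in the gap after site ``i``
    (0-based): the thresholded labels of sites ``i`` and ``i+1`` differ.
    """
    p = np.asarray(posterior_sequence, dtype=float)
    if p.size < 2:
        raise InsufficientSampleError(
            f"transition detection needs >= 2 sites, got {p.size}"
        )
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    calls = p >= threshold
    return [int(i) for i in np.flatnonzero(calls[:-1] != calls[1:])]


def analyze_transit(
    transit: list[RamanSpectrum],
    bands: BandSet,
    pca: PCAModel,
    lda: LDAModel,
    threshold: float = 0.5,
    k: int | None = None,
) -> TransitResult:
    """Classify an ordered transit and locate its margin crossings."""
    predicted, post = classify_transit(transit, bands, pca, lda, k=k)
    return TransitResult(
        site_ids=[s.site_id or f"s{i + 1}" for i, s in enumerate(transit)],
        positions_mm=[
            s.position[0] if s.position is not None else float(i)
            for i, s in enumerate(transit)
        ],
        true_labels=[s.label for s in transit],
        predicted=predicted,
        posterior_tumor=post,
        boundaries=detect_transitions(post, threshold=threshold),
    )
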