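#!/usr/bin/env python
"""Margin-transit analysis: ordered classification across the boundary.

Trains PCA-LDA on the 785 nm microscope cohort, then classifies the ten-site
transit generated in step 01 (healthy at sites 1-2, a mixed signature at
site 3, healthy again at 4-5, tumor from site 6 on).  Reports the per-site
posterior(tumor) sequence and where the margin crossing is detected.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from ramanmargin.bands import extract_band_features, reference_bands  # noqa: E402
from ramanmargin.classify import fit_lda, fit_pca, project  # noqa: E402
from ramanmargin.spectra import load_cohort  # noqa: E402
from ramanmargin.transit import analyze_transit  # noqa: E402


def main() -> None:
    processed = ROOT / "scratch" / "analysis" / "processed"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    train = load_cohort(processed / "mic785" / "manifest.csv")
    bands = reference_bands(785)
    ft = extract_band_features(train, bands)
    pca = fit_pca(ft)
    lda = fit_lda(project(pca, ft, 3), ft.labels)

    transit = load_cohort(processed / "transit1" / "manifest.csv")
    transit.sort(key=lambda s: s.position[0])
    result = analyze_transit(transit, bands, pca, lda)
    frame = result.to_frame()
    frame.to_csv(results / "05_transit1.csv", index=False)

    print(frame.to_string(index=False,
                          formatters={"posterior_tumor": "{:.3f}".format}))
    crossings = [f"after site {b + 1}" for b in result.boundaries]
    print(f"margin crossings detected: {', '.join(crossings) or 'none'}")
    print(f"table -> {results / '05_transit1.csv'}")


if __name__ == "__main__":
    main()
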