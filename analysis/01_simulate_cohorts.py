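#!/usr/bin/env python
"""Generate the study's synthetic cohorts and margin transit.

Three acquisition configurations are emulated: the 1064 nm microscope cohort
(28 healthy / 29 tumor sites), the 785 nm microscope cohort (10 healthy /
40 tumor), and the 785 nm handheld-probe cohort (28 / 29, with surgical ink
present on some sites).  A ten-site margin transit with the
healthy-mixed-healthy-tumor pattern of the first published transect is
generated alongside.

Raw spectra (bulky) go to scratch/analysis/raw; a small summary table with
the realized fluorescence levels at 400 cm^-1 goes to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from ramanmargin.spectra import write_manifest, write_spectrum  # noqa: E402
from ramanmargin.synthetic import (  # noqa: E402
    TRANSIT_1,
    default_config,
    simulate_cohort,
    simulate_transit,
)

COHORTS = {
    "mic1064": dict(excitation=1064, n_healthy=28, n_tumor=29, seed=0,
                    dye_probability=0.0, mode="microscope"),
    "mic785": dict(excitation=785, n_healthy=10, n_tumor=40, seed=1,
                   dye_probability=0.0, mode="microscope"),
    "probe785": dict(excitation=785, n_healthy=28, n_tumor=29, seed=2,
                     dye_probability=0.3, mode="probe"),
}


def main() -> None:
    out_raw = ROOT / "scratch" / "analysis" / "raw"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    for name, spec in COHORTS.items():
        cfg = default_config(
            spec["excitation"], seed=spec["seed"],
            dye_probability=spec["dye_probability"],
        )
        cohort = simulate_cohort(spec["n_healthy"], spec["n_tumor"], 0, cfg)
        d = out_raw / name
        d.mkdir(parents=True, exist_ok=True)
        manifest = []
        for s in cohort:
            s.mode = spec["mode"]
            write_spectrum(s, d / f"{s.site_id}.csv")
            manifest.append({
                "path": f"{s.site_id}.csv", "excitation_nm": s.excitation_nm,
                "mode": s.mode, "label": s.label, "site_id": s.site_id,
                "x": "", "y": "",
            })
        write_manifest(manifest, d / "manifest.csv")
        # realized background level at the start of the fingerprint region
        i400 = int(np.argmin(np.abs(cohort[0].shift - 400.0)))
        level = float(np.median([s.intensity[i400] for s in cohort]))
        rows.append({
            "cohort": name, "excitation_nm": spec["excitation"],
            "n_healthy": spec["n_healthy"], "n_tumor": spec["n_tumor"],
            "dye_probability": spec["dye_probability"],
            "median_intensity_at_400cm": round(level, 1),
        })
        print(f"{name}: {len(cohort)} spectra, "
              f"median level at 400 cm^-1 = {level:.1f} cps")

    transit_dir = out_raw / "transit1"
    transit_dir.mkdir(parents=True, exist_ok=True)
    cfg = default_config(785, seed=3)
    transit = simulate_transit(TRANSIT_1, cfg)
    manifest = []
    for s in transit:
        write_spectrum(s, transit_dir / f"{s.site_id}.csv")
        manifest.append({
            "path": f"{s.site_id}.csv", "excitation_nm": 785,
            "mode": "microscope", "label": s.label, "site_id": s.site_id,
            "x": s.position[0], "y": s.position[1],
        })
    write_manifest(manifest, transit_dir / "manifest.csv")
    print(f"transit1: {len(transit)} sites, truth = {TRANSIT_1}")

    pd.DataFrame(rows).to_csv(results / "01_cohort_summary.csv", index=False)
    print(f"summary -> {results / '01_cohort_summary.csv'}")


if __name__ == "__main__":
    main()
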