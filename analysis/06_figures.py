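#!/usr/bin/env python
"""Diagnostic figures (written to scratch/figures, not versioned).

Panels: raw vs corrected/normalized class means with 95% envelopes and the
difference spectrum for each microscope cohort, and the transit posterior
profile.  Purely illustrative; every number shown is produced by the same
library calls the tables use.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from ramanmargin.bands import class_envelope, difference_spectrum  # noqa: E402
from ramanmargin.spectra import load_cohort  # noqa: E402


def main() -> None:
    processed = ROOT / "scratch" / "analysis" / "processed"
    raw = ROOT / "scratch" / "analysis" / "raw"
    figs = ROOT / "scratch" / "figures"
    figs.mkdir(parents=True, exist_ok=True)

    for name in ("mic1064", "mic785"):
        cohort = load_cohort(processed / name / "manifest.csv")
        raw_cohort = load_cohort(raw / name / "manifest.csv")
        env = {
            label: class_envelope([s for s in cohort if s.label == label])
            for label in ("healthy", "tumor")
        }
        diff = difference_spectrum(env["tumor"], env["healthy"])

        fig, axes = plt.subplots(2, 1, figsize=(9, 7), sharex=True)
        for label, color in (("healthy", "tab:green"), ("tumor", "tab:red")):
            mean_raw = sum(
                s.intensity for s in raw_cohort if s.label == label
            ) / sum(1 for s in raw_cohort if s.label == label)
            axes[0].plot(raw_cohort[0].shift, mean_raw, color=color,
                         label=f"{label} (raw mean)")
            e = env[label]
            axes[1].plot(e.shift, e.mean, color=color, label=label)
            axes[1].fill_between(e.shift, e.ci_lower, e.ci_upper,
                                 color=color, alpha=0.25, lw=0)
        axes[1].plot(env["healthy"].shift, diff, color="gray", lw=0.8,
                     label="tumor - healthy")
        axes[0].set_ylabel("counts / s")
        axes[1].set_ylabel("normalized intensity")
        axes[1].set_xlabel("Raman shift (cm$^{-1}$)")
        for ax in axes:
            ax.legend(fontsize=8)
        fig.suptitle(f"{name}: raw vs corrected class means")
        fig.tight_layout()
        fig.savefig(figs / f"{name}_envelopes.png", dpi=120)
        plt.close(fig)
        print(f"wrote {figs / f'{name}_envelopes.png'}")


if __name__ == "__main__":
    main()
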