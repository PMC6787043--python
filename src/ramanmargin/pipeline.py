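"""End-to-end orchestration: simulate -> preprocess -> bands -> classify
-> transit, with every intermediate artifact written to a run directory.

Two runs with the same configuration (and hence the same seed) produce
byte-identical ``report.json`` files: nothing time- or host-dependent enters
the report, and all randomness flows from the configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import bands as bands_mod
from . import classify as classify_mod
from .config import RunConfig
from .preprocess import PreprocessConfig, preprocess_cohort
from .spectra import write_manifest, write_spectrum
from .synthetic import GeneratorConfig, PROFILES, simulate_cohort, simulate_transit
from .transit import analyze_transit

log = logging.getLogger("ramanmargin")


def _generator_config(cfg: RunConfig) -> GeneratorConfig:
    sim = cfg.simulate
    return GeneratorConfig(
        profile=PROFILES[cfg.excitation_nm],
        noise_sd=sim.noise_sd,
        amp_cv=sim.amp_cv,
        pool_cv=sim.pool_cv,
        cosmic_ray_rate=sim.cosmic_ray_rate,
        dye_probability=sim.dye_probability,
        dye_amplitude=sim.dye_amplitude,
        mixed_fraction=sim.mixed_fraction,
        seed=cfg.seed,
    )


def _preprocess_config(cfg: RunConfig) -> PreprocessConfig:
    p = cfg.preprocess
    return PreprocessConfig(
        despike_window=p.despike_window,
        z_threshold=p.z_threshold,
        rel_threshold=p.rel_threshold,
        window_width=p.window_width,
        step=p.step,
        quantile=p.quantile,
        max_iter=p.max_iter,
        tol=p.tol,
        region=p.region,
    )


def run_pipeline(cfg: RunConfig, write_spectra: bool = True) -> Path:
    """Execute a full configured run; returns the run directory.

    Stages: simulate a cohort (and optional transit), preprocess, build or
    select the band set (with optional dye exclusion), leave-one-out
    PCA-LDA evaluation, and transit analysis.  Writes spectra + manifest,
    band set JSON, feature CSV, report JSON, run manifest, and a
    human-readable summary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- simulate
    gen = _generator_config(cfg)
    cohort = simulate_cohort(
        cfg.simulate.n_healthy, cfg.simulate.n_tumor, cfg.simulate.n_mixed, gen
    )
    log.info("stage=simulate n=%d profile=%dnm", len(cohort), cfg.excitation_nm)
    transit_spectra = None
    if cfg.simulate.transit:
        transit_spectra = simulate_transit(cfg.simulate.transit, gen)
        log.info("stage=simulate-transit sites=%d", len(transit_spectra))

    if write_spectra:
        raw_dir = out / "spectra"
        raw_dir.mkdir(exist_ok=True)
        rows = []
        for i, s in enumerate(cohort):
            name = f"{s.site_id or i}.csv"
            write_spectrum(s, raw_dir / name)
            rows.append(
                {
                    "path": f"spectra/{name}",
                    "excitation_nm": s.excitation_nm,
                    "mode": s.mode,
                    "label": s.label,
                    "site_id": s.site_id,
                    "x": s.position[0] if s.position else "",
                    "y": s.position[1] if s.position else "",
                }
            )
        write_manifest(rows, out / "manifest.csv")

    # -- preprocess
    pp = _preprocess_config(cfg)
    processed = preprocess_cohort(cohort, pp)
    n_spikes = sum(s.meta["preprocess"]["despiked_channels"] for s in processed)
    log.info("stage=preprocess n=%d despiked_channels=%d", len(processed), n_spikes)

    # -- band set
    healthy = [s for s in processed if s.label == "healthy"]
    tumor = [s for s in processed if s.label == "tumor"]
    if cfg.bands.source == "reference":
        band_set = bands_mod.reference_bands(cfg.excitation_nm)
    else:
        env_h = bands_mod.class_envelope(healthy, level=cfg.bands.level)
        env_t = bands_mod.class_envelope(tumor, level=cfg.bands.level)
        band_set = bands_mod.select_discriminative_bands(
            env_h,
            env_t,
            min_width=cfg.bands.min_width,
            merge_gap=cfg.bands.merge_gap,
            top_k=cfg.bands.top_k,
        )
    dropped: list[str] = []
    if cfg.bands.apply_dye_exclusion:
        band_set = bands_mod.exclude_dye_bands(
            band_set,
            dye_centers=tuple(cfg.bands.dye_centers),
            tolerance=cfg.bands.dye_tolerance,
        )
        dropped = getattr(band_set, "dropped", [])
        if dropped:
            log.warning("stage=bands dropped contaminated windows: %s", dropped)
    band_set.to_json(out / "bands.json")
    log.info("stage=bands active=%d of %d", len(band_set.active), len(band_set))

    # -- features + LOO evaluation
    features = bands_mod.extract_band_features(processed, band_set)
    features.to_csv(out / "features.csv")
    report = classify_mod.loo_cross_validate(
        features,
        k=cfg.classify.k,
        refit_pca_per_fold=cfg.classify.refit_pca_per_fold,
        scale=cfg.classify.scale,
    )
    log.info(
        "stage=evaluate n=%d sens=%d spec=%d acc=%d",
        report.n,
        report.sensitivity,
        report.specificity,
        report.accuracy,
    )

    # final models on the full table, for transit use and audit
    pca = classify_mod.fit_pca(features, scale=cfg.classify.scale)
    train_mask = np.asarray(features.labels.isin(classify_mod.CLASS_ORDER))
    train = features.subset(train_mask)
    pca_train = classify_mod.fit_pca(train, scale=cfg.classify.scale)
    lda = classify_mod.fit_lda(
        classify_mod.project(pca_train, train, k=cfg.classify.k), train.labels
    )

    # -- transit
    transit_payload = None
    if transit_spectra is not None:
        processed_transit = preprocess_cohort(transit_spectra, pp)
        result = analyze_transit(
            processed_transit,
            band_set,
            pca_train,
            lda,
            threshold=cfg.transit.threshold,
            k=cfg.classify.k,
        )
        result.to_frame().to_csv(out / "transit.csv", index=False)
        transit_payload = {
            "boundaries_after_site": result.boundaries,
            "predicted": result.predicted,
            "posterior_tumor": [round(float(p), 12) for p in result.posterior_tumor],
        }
        log.info("stage=transit sites=%d boundaries=%s",
                 len(result.site_ids), result.boundaries)

    payload = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "excitation_nm": cfg.excitation_nm,
        "normalization_region": list(
            cfg.preprocess.region or PROFILES[cfg.excitation_nm].normalization_region
        ),
        "bands": {
            "active": band_set.names,
            "dropped_contaminated": dropped,
        },
        "pca": {
            "eigenvalues": [float(v) for v in pca.eigenvalues],
            "percent": [round(float(v), 6) for v in pca.percent],
            "cum_percent": [round(float(v), 6) for v in pca.cum_percent],
            "loadings": np.round(pca.loadings, 12).tolist(),
            "feature_names": pca.feature_names,
        },
        "lda": {
            "class_means": np.round(lda.class_means, 12).tolist(),
            "pooled_cov": np.round(lda.pooled_cov, 18).tolist(),
            "priors": [float(p) for p in lda.priors],
            "ridge": lda.ridge,
        },
        "loo_report": report.to_dict(),
        "transit": transit_payload,
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    run_manifest = {
        "config": cfg.model_dump(mode="json"),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": _versions(),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True)
    )
    (out / "summary.txt").write_text(_summary_text(cfg, report, band_set, dropped))
    return out


def _versions() -> dict:
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "ramanmargin": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def _summary_text(cfg, report, band_set, dropped) -> str:
    lines = [
        f"ramanmargin run (seed {cfg.seed}, {cfg.excitation_nm} nm)",
        f"config hash: {cfg.config_hash()}",
        "",
        f"cohort: {cfg.simulate.n_healthy} healthy / {cfg.simulate.n_tumor} tumor"
        f" / {cfg.simulate.n_mixed} mixed",
        f"bands: {len(band_set.active)} active of {len(band_set)}"
        + (f" (dropped: {', '.join(dropped)})" if dropped else ""),
        "",
        "leave-one-out PCA-LDA:",
        f"  confusion  hh={report.hh} ht={report.ht} th={report.th} tt={report.tt}",
        f"  sensitivity {report.sensitivity}%  specificity {report.specificity}%"
        f"  accuracy {report.accuracy}%",
        "",
    ]
    return "\n".join(lines)
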