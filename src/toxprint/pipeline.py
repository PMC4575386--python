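"""End-to-end orchestration: simulate -> preprocess -> detect -> align ->
differential -> fingerprint, with every stage output written to disk and a
manifest recording the full configuration and seed for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as align_mod
from . import differential as diff_mod
from . import fingerprint as fp_mod
from . import peaks as peaks_mod
from . import preprocess as prep_mod
from . import synth
from .io import RawSpectrum, write_spectrum

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "preprocess_and_detect"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the processing defaults."""

    seed: int = 0
    replicates: int = 6
    smooth_width: int = 50
    baseline_width: int = 100
    snr_min: float = 3.0
    abs_min_mv: float = 200.0
    noise_window: int = 501
    n_calibration_refs: int = 10
    calibration_tol_da: float = 2.0
    calibration_tol_ppm: float = 500.0
    match_tol_da: float = 2.0
    match_tol_ppm: float = 500.0
    alphas: tuple = (0.05, 0.01)
    grubbs_alpha: float = 0.05
    log_ratio_pca: bool = True
    design: str = "default"  # 'default' (all concentrations) or 'marker'
    outdir: str = "toxprint_run"

    def __post_init__(self) -> None:
        for name in (
            "smooth_width", "baseline_width", "snr_min", "abs_min_mv",
            "noise_window", "match_tol_da", "replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "alphas" in data:
            data["alphas"] = tuple(data["alphas"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alphas"] = list(self.alphas)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def preprocess_and_detect(spectrum: RawSpectrum, config: RunConfig) -> peaks_mod.PeakList:
    """Smooth, remove baseline, and pick peaks on one spectrum."""
    smoothed = prep_mod.smooth(spectrum, config.smooth_width)
    baseline = prep_mod.estimate_baseline(smoothed, config.baseline_width)
    cleaned, _ = prep_mod.subtract_baseline(smoothed, baseline)
    return peaks_mod.detect_peaks(
        cleaned,
        snr_min=config.snr_min,
        abs_min_mv=config.abs_min_mv,
        noise_window=config.noise_window,
    )


@dataclass
class PipelineResult:
    consensus: align_mod.ConsensusPeakTable
    summary: align_mod.ConditionSummary
    marker_table: diff_mod.MarkerTable
    change_matrix: pd.DataFrame
    pca: fp_mod.PCAResult | None
    manifest: dict
    peaklists: list = field(default_factory=list)


def run_pipeline(
    config: RunConfig,
    model: synth.SpectrumModel | None = None,
    design: synth.ExperimentDesign | None = None,
    outdir: str | Path | None = None,
    write_spectra: bool = False,
) -> PipelineResult:
    """Run the whole analysis on a simulated experiment and write artifacts.

    Stage order: simulate -> smooth -> baseline -> detect -> internal
    recalibration -> cross-sample matching -> condition summaries ->
    marker table -> relative changes -> PCA. Reruns with the same config
    reproduce every output bit-for-bit.
    """
    if model is None:
        model = synth.make_default_truth(config.seed)
    if design is None:
        maker = synth.marker_design if config.design == "marker" else synth.default_design
        design = maker(replicates=config.replicates, seed=config.seed)
    out = Path(outdir) if outdir is not None else Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    experiment = synth.simulate_experiment(model, design)
    if write_spectra:
        specdir = out / "spectra"
        specdir.mkdir(exist_ok=True)
        for spectrum in experiment.spectra:
            write_spectrum(spectrum, specdir / f"{spectrum.sample_id}.txt")

    peaklists = []
    for spectrum in experiment.spectra:
        try:
            peaklists.append(preprocess_and_detect(spectrum, config))
        except Exception as exc:  # abort with stage + sample context
            raise RuntimeError(
                f"stage 'preprocess/detect' failed on sample {spectrum.sample_id!r}: {exc}"
            ) from exc

    warnings_log: list[str] = []
    try:
        refs = prep_mod.select_calibration_peaks(
            peaklists,
            n_refs=config.n_calibration_refs,
            tol_da=config.match_tol_da,
            tol_ppm=config.match_tol_ppm,
        )
        calibrated = []
        for pl in peaklists:
            try:
                cal, _model = prep_mod.calibrate(
                    pl, refs, config.calibration_tol_da, config.calibration_tol_ppm
                )
                calibrated.append(cal)
            except ValueError:
                warnings_log.append(f"calibration skipped for {pl.sample_id}")
                calibrated.append(pl)
        peaklists = calibrated
    except ValueError as exc:
        warnings_log.append(f"calibration stage skipped: {exc}")

    if all(len(pl) == 0 for pl in peaklists):
        warnings_log.append("no peaks detected in any spectrum")
    consensus = align_mod.match_peaks(
        peaklists, tol_da=config.match_tol_da, tol_ppm=config.match_tol_ppm
    )
    summary = align_mod.summarize_conditions(consensus, design)
    marker_table = diff_mod.build_marker_table(
        consensus, design, alphas=config.alphas, grubbs_alpha=config.grubbs_alpha
    )
    try:
        change_matrix = fp_mod.build_change_matrix(summary)
    except ValueError as exc:
        warnings_log.append(f"change matrix skipped: {exc}")
        change_matrix = pd.DataFrame()
    pca_result = None
    if change_matrix.shape[0] >= 2 and change_matrix.shape[1] >= 2:
        try:
            pca_result = fp_mod.fingerprint_pca(change_matrix, log_ratio=config.log_ratio_pca)
        except ValueError as exc:
            warnings_log.append(f"pca skipped: {exc}")

    # ---- write artifacts -------------------------------------------------
    consensus.abundance.to_csv(out / "consensus_table.csv")
    pd.DataFrame(
        {"label": consensus.labels, "consensus_mass": consensus.consensus_masses}
    ).to_csv(out / "consensus_masses.csv", index=False)
    summary.table.to_csv(out / "condition_summary.csv", index=False)
    marker_table.table.to_csv(out / "marker_table.csv", index=False)
    (out / "marker_table.txt").write_text(marker_table.render() + "\n")
    change_matrix.to_csv(out / "change_matrix.csv")
    if pca_result is not None:
        pca_result.loadings.to_csv(out / "pca_loadings.csv")
        pd.DataFrame(
            pca_result.scores,
            index=pca_result.row_names,
            columns=pca_result.loadings.columns,
        ).to_csv(out / "pca_scores.csv")
        pd.Series(
            pca_result.explained_variance_fraction,
            index=pca_result.loadings.columns,
            name="explained_variance_fraction",
        ).to_csv(out / "pca_variance.csv")

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_spectra": len(experiment.spectra),
        "n_consensus_peaks": len(consensus.labels),
        "conditions": [c.key for c in design.conditions],
        "warnings": warnings_log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return PipelineResult(
        consensus=consensus,
        summary=summary,
        marker_table=marker_table,
        change_matrix=change_matrix,
        pca=pca_result,
        manifest=manifest,
        peaklists=peaklists,
    )
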