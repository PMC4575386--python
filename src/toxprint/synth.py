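"""Ground-truthed synthetic intact-cell MALDI-TOF experiments.

The forward model emulates linear positive-mode whole-cell spectra in the
m/z 2,000-20,000 window: Gaussian protein/peptide peaks whose width grows
linearly with mass (linear-TOF resolution), a decaying-exponential chemical
baseline, additive detector noise on a uniform grid, a small per-spectrum
affine mass-calibration drift in the sqrt(m/z) domain (TOF flight time is
proportional to sqrt(m/z)), and per-replicate lognormal abundance
variability between independent biological experiments.

The default truth panel places 15 peaks at the published marker masses
(labels A-O, 4562-15292 Da) with per-toxin fold-change profiles whose signs
follow the published arrow pattern for copper sulfate, acridine and BNF, so
downstream recovery of the fingerprint can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTROL, Condition, RawSpectrum

__all__ = [
    "TruthPeak",
    "SpectrumModel",
    "ExperimentDesign",
    "ViabilityTruth",
    "make_default_truth",
    "default_design",
    "marker_design",
    "simulate_spectrum",
    "simulate_experiment",
    "simulate_abundances",
    "simulate_viability",
    "SimulatedExperiment",
]

MASS_LO = 2000.0
MASS_HI = 20000.0

#: concentration series actually used for the intact-cell exposures
CONCENTRATIONS = {
    "copper_sulfate": ([2.0, 4.0, 6.0, 9.0, 12.0], "mg/L"),
    "acridine": ([50.0, 100.0, 150.0], "uM"),
    "bnf": ([10.0, 30.0, 50.0], "uM"),
}

#: concentration feeding the marker table, per toxin
COMPARISON_CONCENTRATION = {"copper_sulfate": 9.0, "acridine": 150.0, "bnf": 50.0}


@dataclass(frozen=True)
class TruthPeak:
    """One true underlying peak with its per-toxin concentration response."""

    true_mass: float           # Da
    base_abundance: float      # mV, apex height in the control condition
    width: float               # Da, Gaussian sigma at this mass
    effect_profile: dict = field(default_factory=dict)  # toxin -> {conc: fold}

    def __post_init__(self) -> None:
        if not (MASS_LO <= self.true_mass <= MASS_HI):
            raise ValueError(f"true_mass {self.true_mass} outside [{MASS_LO}, {MASS_HI}]")
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")
        for toxin, profile in self.effect_profile.items():
            for conc, fold in profile.items():
                if fold <= 0:
                    raise ValueError(
                        f"fold-change must be positive ({toxin} @ {conc}: {fold})"
                    )

    def fold_change(self, condition: Condition) -> float:
        if condition.is_control:
            return 1.0
        try:
            profile = self.effect_profile[condition.toxin]
        except KeyError:
            raise KeyError(f"unknown toxin {condition.toxin!r} in effect profile") from None
        try:
            return profile[condition.concentration]
        except KeyError:
            raise KeyError(
                f"no effect defined for {condition.toxin!r} at "
                f"{condition.concentration:g} {condition.units}"
            ) from None


@dataclass
class SpectrumModel:
    """Forward model for one acquisition campaign."""

    peaks: list[TruthPeak]
    baseline_amplitude: float = 800.0   # mV at the low-mass edge
    baseline_decay: float = 1500.0      # Da, e-folding scale of chemical noise
    baseline_offset: float = 20.0       # mV, flat residual background
    noise_sd: float = 10.0              # mV additive detector noise (600-shot average)
    abundance_cv: float = 0.18          # lognormal CV of replicate abundances
    drift_slope_sd: float = 5e-5        # sd of (b-1) in sqrt-domain drift a+b*sqrt(m)
    drift_offset_sd: float = 0.005      # sd of a, in sqrt(Da)
    grid_step: float = 0.125            # Da; one channel = one grid sample

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((MASS_HI - MASS_LO) / self.grid_step)) + 1
        return MASS_LO + self.grid_step * np.arange(n)

    def baseline(self, mz: np.ndarray) -> np.ndarray:
        return self.baseline_amplitude * np.exp(
            -(np.asarray(mz, dtype=float) - MASS_LO) / self.baseline_decay
        ) + self.baseline_offset


@dataclass
class ExperimentDesign:
    """Which conditions are measured and with how many replicates."""

    conditions: list[Condition]
    replicates: int = 6
    seed: int = 0
    comparison: dict = field(default_factory=lambda: dict(COMPARISON_CONCENTRATION))

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        n_control = sum(c.is_control for c in self.conditions)
        if n_control != 1:
            raise ValueError(
                f"design must contain exactly one control condition, got {n_control}"
            )

    @property
    def control(self) -> Condition:
        return next(c for c in self.conditions if c.is_control)

    @property
    def treatments(self) -> list[Condition]:
        return [c for c in self.conditions if not c.is_control]


@dataclass
class ViabilityTruth:
    """True 4PL dose-response curve underlying a simulated viability plate."""

    ec50: float
    hill: float = 2.0
    top: float = 100.0
    bottom: float = 0.0
    noise_sd: float = 5.0  # percent-viability units

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")

    def response(self, dose: np.ndarray) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (dose / self.ec50) ** self.hill)


# ---------------------------------------------------------------------------
# Default truth panel
# ---------------------------------------------------------------------------

# label, mass, per-toxin annotation: +2 = strong increase (**), +1 = increase (*),
# -1 = decrease (*), -2 = strong decrease (**), 0 = unaffected
_DEFAULT_PANEL = [
    ("A", 4562, {"copper_sulfate": 0, "acridine": -2, "bnf": +1}),
    ("B", 4576, {"copper_sulfate": 0, "acridine": 0, "bnf": +1}),
    ("C", 4633, {"copper_sulfate": +2, "acridine": -2, "bnf": +1}),
    ("D", 4647, {"copper_sulfate": 0, "acridine": -1, "bnf": +1}),
    ("E", 4885, {"copper_sulfate": 0, "acridine": 0, "bnf": -2}),
    ("F", 4902, {"copper_sulfate": 0, "acridine": +2, "bnf": -2}),
    ("G", 5655, {"copper_sulfate": +1, "acridine": 0, "bnf": 0}),
    ("H", 6275, {"copper_sulfate": 0, "acridine": 0, "bnf": +1}),
    ("I", 6731, {"copper_sulfate": +2, "acridine": 0, "bnf": 0}),
    ("J", 10540, {"copper_sulfate": +1, "acridine": 0, "bnf": 0}),
    ("K", 11295, {"copper_sulfate": +2, "acridine": +1, "bnf": -1}),
    ("L", 13448, {"copper_sulfate": +2, "acridine": +1, "bnf": -1}),
    ("M", 13627, {"copper_sulfate": 0, "acridine": +1, "bnf": 0}),
    ("N", 13705, {"copper_sulfate": +1, "acridine": 0, "bnf": 0}),
    ("O", 15292, {"copper_sulfate": +1, "acridine": 0, "bnf": 0}),
]

#: fold-change at the comparison concentration for each annotation level
_FOLD_BY_LEVEL = {0: 1.0, +1: 2.0, +2: 3.0, -1: 0.5, -2: 1.0 / 3.0}

#: Gaussian sigma grows linearly with mass: FWHM ~ m/1000 (linear-TOF resolution)
_SIGMA_SLOPE = 1.0 / 2355.0


def _graded_profile(level: int, concentrations: list[float], c_ref: float) -> dict:
    """Log-fold response scales linearly with concentration up to the reference."""
    target = np.log(_FOLD_BY_LEVEL[level])
    return {c: float(np.exp(target * c / c_ref)) for c in concentrations}


def make_default_truth(seed: int = 0) -> SpectrumModel:
    """Default 15-peak truth panel at the published marker masses.

    Fold-change signs at the comparison concentrations follow the published
    arrow pattern for the three toxins; magnitudes grade monotonically with
    concentration. Base abundances are drawn once from the given seed in the
    volt-scale range that leaves post-preprocessing apexes comfortably above
    the 200 mV detection floor.
    """
    rng = np.random.default_rng(seed)
    bases = rng.uniform(3000.0, 9000.0, size=len(_DEFAULT_PANEL))
    peaks = []
    for (label, mass, levels), base in zip(_DEFAULT_PANEL, bases):
        profile = {}
        for toxin, level in levels.items():
            concs, _units = CONCENTRATIONS[toxin]
            profile[toxin] = _graded_profile(level, concs, COMPARISON_CONCENTRATION[toxin])
        peaks.append(
            TruthPeak(
                true_mass=float(mass),
                base_abundance=float(base),
                width=float(mass) * _SIGMA_SLOPE + 1.0,
                effect_profile=profile,
            )
        )
    return SpectrumModel(peaks=peaks)


def default_design(replicates: int = 6, seed: int = 0) -> ExperimentDesign:
    """Full exposure design: every concentration of every toxin plus control."""
    conditions = [CONTROL]
    for toxin, (concs, units) in CONCENTRATIONS.items():
        conditions += [Condition(toxin, c, units) for c in concs]
    return ExperimentDesign(conditions=conditions, replicates=replicates, seed=seed)


def marker_design(replicates: int = 6, seed: int = 0) -> ExperimentDesign:
    """Reduced design with only the marker-table comparison concentrations."""
    conditions = [CONTROL] + [
        Condition(toxin, COMPARISON_CONCENTRATION[toxin], CONCENTRATIONS[toxin][1])
        for toxin in CONCENTRATIONS
    ]
    return ExperimentDesign(conditions=conditions, replicates=replicates, seed=seed)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _draw_drift(model: SpectrumModel, rng: np.random.Generator) -> tuple[float, float]:
    """Per-spectrum affine drift (a, b) acting on sqrt(m/z); near-identity."""
    b = 1.0 + np.clip(rng.normal(0.0, model.drift_slope_sd), -1e-3, 1e-3)
    a = rng.normal(0.0, model.drift_offset_sd)
    return float(a), float(b)


def _apply_drift(mass: np.ndarray, a: float, b: float) -> np.ndarray:
    return (a + b * np.sqrt(np.asarray(mass, dtype=float))) ** 2


def _replicate_heights(
    model: SpectrumModel, condition: Condition, rng: np.random.Generator
) -> np.ndarray:
    folds = np.array([p.fold_change(condition) for p in model.peaks])
    bases = np.array([p.base_abundance for p in model.peaks])
    if model.abundance_cv > 0:
        sigma = np.sqrt(np.log1p(model.abundance_cv**2))
        wobble = rng.lognormal(-0.5 * sigma**2, sigma, size=len(model.peaks))
    else:
        wobble = np.ones(len(model.peaks))
    return bases * folds * wobble


def simulate_spectrum(
    model: SpectrumModel,
    condition: Condition,
    replicate_index: int = 0,
    seed: int | None = 0,
    drift: tuple[float, float] | None = None,
    return_truth: bool = False,
):
    """Render one spectrum: peaks + baseline + detector noise, with mass drift.

    The emitted truth (drifted apex positions and heights) is returned when
    ``return_truth`` so detection recall/precision can be scored downstream.
    """
    # validate the condition against the model before any drawing
    for peak in model.peaks:
        peak.fold_change(condition)

    rng = np.random.default_rng(seed)
    if drift is None:
        drift = _draw_drift(model, rng)
    a, b = drift
    grid = model.grid
    heights = _replicate_heights(model, condition, rng)
    true_masses = np.array([p.true_mass for p in model.peaks])
    widths = np.array([p.width for p in model.peaks])
    drifted = _apply_drift(true_masses, a, b)

    intensity = model.baseline(grid).copy()
    for mass, width, height in zip(drifted, widths, heights):
        lo = np.searchsorted(grid, mass - 6 * width)
        hi = np.searchsorted(grid, mass + 6 * width)
        window = grid[lo:hi]
        intensity[lo:hi] += height * np.exp(-0.5 * ((window - mass) / width) ** 2)
    if model.noise_sd > 0:
        intensity += rng.normal(0.0, model.noise_sd, size=grid.size)

    spectrum = RawSpectrum(
        mz=grid,
        intensity=intensity,
        sample_id=f"{condition.key}_r{replicate_index}",
        condition=condition,
        replicate_index=replicate_index,
        metadata={"seed": seed, "drift_a": a, "drift_b": b},
    )
    if not return_truth:
        return spectrum
    truth = pd.DataFrame(
        {
            "true_mass": true_masses,
            "drifted_mass": drifted,
            "width": widths,
            "height": heights,
            "fold": [p.fold_change(condition) for p in model.peaks],
        }
    )
    return spectrum, truth


@dataclass
class SimulatedExperiment:
    """All spectra of one simulated campaign plus the generating truth."""

    spectra: list[RawSpectrum]
    truth: pd.DataFrame          # one row per (sample, peak): masses, heights, folds
    design: ExperimentDesign
    model: SpectrumModel


def simulate_experiment(
    model: SpectrumModel, design: ExperimentDesign
) -> SimulatedExperiment:
    """One spectrum per condition x replicate, with independent drift and noise."""
    root = np.random.default_rng(design.seed)
    spectra: list[RawSpectrum] = []
    truth_rows = []
    for condition in design.conditions:
        for rep in range(design.replicates):
            sub_seed = int(root.integers(0, 2**31 - 1))
            spectrum, truth = simulate_spectrum(
                model, condition, replicate_index=rep, seed=sub_seed, return_truth=True
            )
            spectra.append(spectrum)
            truth = truth.assign(
                sample_id=spectrum.sample_id,
                condition=condition.key,
                replicate=rep,
            )
            truth_rows.append(truth)
    return SimulatedExperiment(
        spectra=spectra,
        truth=pd.concat(truth_rows, ignore_index=True),
        design=design,
        model=model,
    )


def simulate_abundances(model: SpectrumModel, design: ExperimentDesign) -> pd.DataFrame:
    """Replicate-level true peak abundances without rendering full profiles.

    Returns a tidy frame (sample_id, condition, replicate, true_mass,
    abundance). Uses the same lognormal replicate-variability model as
    :func:`simulate_spectrum`; useful for fast statistical calibration where
    the spectral rendering and detection stages are not under test.
    """
    root = np.random.default_rng(design.seed)
    rows = []
    masses = [p.true_mass for p in model.peaks]
    for condition in design.conditions:
        for rep in range(design.replicates):
            rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
            heights = _replicate_heights(model, condition, rng)
            for mass, h in zip(masses, heights):
                rows.append(
                    {
                        "sample_id": f"{condition.key}_r{rep}",
                        "condition": condition.key,
                        "replicate": rep,
                        "true_mass": mass,
                        "abundance": h,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Viability plates
# ---------------------------------------------------------------------------

def simulate_viability(
    truth: ViabilityTruth,
    doses,
    replicates: int = 4,
    seed: int | None = 0,
    blank_level: float = 500.0,
    control_level: float = 30000.0,
) -> pd.DataFrame:
    """Simulate a viability plate readout (raw signal units).

    Treated wells follow the 4PL curve; untreated control wells sit at the
    'top' response; blank wells carry only background signal. Raw signals are
    a linear map of percent viability between blank and control levels, with
    Gaussian noise of ``truth.noise_sd`` percent-viability units.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size < 2 or np.unique(doses).size < 2:
        raise ValueError("need at least two distinct doses")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    span = control_level - blank_level
    rows = []

    def raw(percent: float) -> float:
        return blank_level + span * percent / 100.0

    for rep in range(replicates):
        for dose in doses:
            resp = float(truth.response(dose))
            if truth.noise_sd > 0:
                resp += rng.normal(0.0, truth.noise_sd)
            rows.append({"dose": dose, "signal": raw(resp), "well_type": "treated", "replicate": rep})
        ctl = truth.top + (rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0)
        rows.append({"dose": 0.0, "signal": raw(ctl), "well_type": "control", "replicate": rep})
        blk = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
        rows.append({"dose": 0.0, "signal": raw(blk), "well_type": "blank", "replicate": rep})
    return pd.DataFrame(rows)
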