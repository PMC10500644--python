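"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here: random
protein sequences with controlled composition, relaxation decays
(saturation recovery, plain and J-modulated Hahn echoes) with Gaussian
noise, Gaussian-mixture chemical-shift ensembles (unimodal or bimodal,
emulating per-frame predictions from an MD trajectory), and sum-of-peaks
1D spectra.  Generative parameters ride along as ground-truth metadata so
downstream estimators can be validated by round trip.

Each generator draws from its own seeded ``numpy`` generator — no global
random state — so identical specs give bit-identical output on any
platform.  Noise is additive Gaussian throughout; that is a modeling
assumption, not a measured property of any spectrometer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensembleshift import ShiftEnsemble, Spectrum1D
from .errors import InvalidSpecError
from .relaxfit import RelaxationCurve, echo_decay_model, saturation_recovery_model
from .seqdesign import AMINO_ACIDS

DECAY_MODELS = ("saturation_recovery", "exponential_echo", "j_modulated_echo")

_SQRT8LN2 = float(np.sqrt(8.0 * np.log(2.0)))  # FWHM / sd for a Gaussian


@dataclass
class SequenceSpec:
    """Random residue string: length, optional composition, seed."""

    length: int
    alphabet: str = AMINO_ACIDS
    seed: int = 0
    composition: dict[str, float] | None = None

    def validate(self) -> None:
        if self.length < 2:
            raise InvalidSpecError("sequence length must be >= 2")
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise InvalidSpecError("alphabet must be non-empty without duplicates")
        if self.composition is not None:
            if set(self.composition) - set(self.alphabet):
                raise InvalidSpecError("composition letters outside alphabet")
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidSpecError(f"composition sums to {total}, expected 1")
            if any(p < 0 for p in self.composition.values()):
                raise InvalidSpecError("composition probabilities must be >= 0")


def make_sequence(spec: SequenceSpec) -> str:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    letters = list(spec.alphabet)
    if spec.composition is None:
        probs = None
    else:
        probs = np.array([spec.composition.get(a, 0.0) for a in letters])
        probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=spec.length, p=probs))


@dataclass
class DecaySpec:
    """One relaxation decay: model, true time constant, sampling, noise.

    ``true_T`` and ``delays`` share ``time_unit``; ``J_hz`` applies only
    to the J-modulated echo (total echo time convention, zero crossing at
    1/(2J) seconds).  ``noise_sigma`` is a fraction of the amplitude.
    A saturation-recovery "infinite" delay is whatever longest delay the
    caller requests; nothing is appended silently.
    """

    model: str
    true_T: float
    delays: list[float] | np.ndarray = field(default_factory=list)
    J_hz: float | None = None
    amplitude: float = 1.0
    noise_sigma: float = 0.0
    time_unit: str = "s"
    seed: int = 0

    def validate(self) -> None:
        if self.model not in DECAY_MODELS:
            raise InvalidSpecError(
                f"unknown decay model {self.model!r}; choose from {DECAY_MODELS}"
            )
        if self.true_T <= 0:
            raise InvalidSpecError("true_T must be positive")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        d = np.asarray(self.delays, dtype=float)
        if d.size < 3:
            raise InvalidSpecError("need at least 3 delays")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise InvalidSpecError("delays must be non-negative, strictly increasing")
        if self.model == "j_modulated_echo" and (self.J_hz is None or self.J_hz <= 0):
            raise InvalidSpecError("j_modulated_echo requires a positive J_hz")


def make_decay(spec: DecaySpec) -> RelaxationCurve:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.delays, dtype=float)
    if spec.model == "saturation_recovery":
        clean = saturation_recovery_model(t, spec.amplitude, spec.true_T)
        kind = "saturation_recovery"
    else:
        J = spec.J_hz if spec.model == "j_modulated_echo" else None
        clean = echo_decay_model(t, spec.amplitude, spec.true_T, J, spec.time_unit)
        kind = "hahn_echo"
    noisy = clean + rng.normal(0.0, spec.noise_sigma * spec.amplitude, size=t.shape)
    return RelaxationCurve(
        delays=t,
        intensities=noisy,
        kind=kind,
        time_unit=spec.time_unit,
        ground_truth={
            "model": spec.model,
            "true_T": spec.true_T,
            "J_hz": spec.J_hz,
            "amplitude": spec.amplitude,
            "noise_sigma": spec.noise_sigma,
            "seed": spec.seed,
        },
    )


@dataclass
class EnsembleSpec:
    """Gaussian-mixture shift ensemble: [(weight, mean ppm, sd ppm)], n_frames."""

    components: list[tuple[float, float, float]]
    n_frames: int
    seed: int = 0
    site: str = "site"

    def validate(self) -> None:
        if not self.components:
            raise InvalidSpecError("need at least one mixture component")
        weights = [w for w, _, _ in self.components]
        if any(w < 0 for w in weights):
            raise InvalidSpecError("weights must be >= 0")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise InvalidSpecError(f"weights sum to {sum(weights)}, expected 1")
        if any(sd <= 0 for _, _, sd in self.components):
            raise InvalidSpecError("component sd must be positive")
        if self.n_frames < 1:
            raise InvalidSpecError("n_frames must be >= 1")


def make_ensemble(spec: EnsembleSpec) -> ShiftEnsemble:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for w, _, _ in spec.components])
    labels = rng.choice(len(spec.components), size=spec.n_frames, p=weights)
    means = np.array([m for _, m, _ in spec.components])
    sds = np.array([s for _, _, s in spec.components])
    shifts = rng.normal(means[labels], sds[labels])
    return ShiftEnsemble(
        shifts={spec.site: shifts},
        provenance=f"synthetic mixture seed={spec.seed}",
        component_labels={spec.site: labels},
    )


@dataclass
class SpectrumSpec:
    """Sum-of-peaks 1D spectrum: [(center, FWHM, area, shape)], axis, noise."""

    peaks: list[tuple[float, float, float, str]]
    ppm_axis: tuple[float, float, int]
    noise_sigma: float = 0.0
    seed: int = 0
    site: str = ""
    reference_peak: tuple[str, float] | None = None

    def validate(self) -> None:
        lo, hi, n = self.ppm_axis
        if not lo < hi or n < 2:
            raise InvalidSpecError("ppm axis needs min < max and >= 2 points")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        for center, fwhm, area, shape in self.peaks:
            if fwhm <= 0:
                raise InvalidSpecError("peak FWHM must be positive")
            if shape not in ("gaussian", "lorentzian"):
                raise InvalidSpecError(f"unknown peak shape {shape!r}")


def peak_profile(
    ppm: np.ndarray, center: float, fwhm: float, area: float, shape: str
) -> np.ndarray:
    """Unit-area Gaussian or Lorentzian scaled to ``area``."""
    if shape == "gaussian":
        sd = fwhm / _SQRT8LN2
        return area / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((ppm - center) / sd) ** 2)
    hwhm = fwhm / 2.0
    return (area / np.pi) * hwhm / ((ppm - center) ** 2 + hwhm**2)


def make_spectrum(spec: SpectrumSpec) -> Spectrum1D:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi, n = spec.ppm_axis
    ppm = np.linspace(lo, hi, n)
    y = np.zeros_like(ppm)
    for center, fwhm, area, shape in spec.peaks:
        y += peak_profile(ppm, center, fwhm, area, shape)
    y += rng.normal(0.0, spec.noise_sigma, size=ppm.shape)
    return Spectrum1D(
        ppm=ppm,
        intensity=y,
        site=spec.site,
        reference_peak=spec.reference_peak,
        ground_truth={"peaks": list(spec.peaks), "noise_sigma": spec.noise_sigma,
                      "seed": spec.seed},
    )


def lorentzian_spectrum_from_t2(
    T2_s: float,
    nucleus_frequency_mhz: float,
    center_ppm: float,
    ppm_axis: tuple[float, float, int],
    area: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Spectrum1D:
    """A purely homogeneous line: Lorentzian whose FWHM is 1/(pi*T2).

    Useful as the self-consistency fixture for broadening diagnostics —
    by construction its observed/homogeneous width ratio is 1.
    """
    fwhm_ppm = 1.0 / (np.pi * T2_s) / nucleus_frequency_mhz
    return make_spectrum(
        SpectrumSpec(
            peaks=[(center_ppm, fwhm_ppm, area, "lorentzian")],
            ppm_axis=ppm_axis,
            noise_sigma=noise_sigma,
            seed=seed,
        )
    )
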