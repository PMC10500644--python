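"""DNP figures of merit: enhancement, polarization, sensitivity.

Microwave-driven polarization transfer multiplies the NMR signal by the
enhancement epsilon = I_on / I_off, but the biradical that enables it also
costs signal: MAS-induced depolarization and paramagnetic bleaching reduce
the microwave-off polarization P below the radical-free reference, and
paramagnetic relaxation enhancement shortens T1(1H), which in turn allows
faster recycling.  Signal-to-noise per square-root unit time therefore
combines all three:

    S = epsilon * P / sqrt(T1)      [s^-0.5]

The optimal recycle delay for signal-to-noise per time with exponential
recovery is ~1.26 * T1; the conventional setting 1.3 * T1 is used.

A reference screen of these quantities measured on KR2 (a hepta-helical
microbial rhodopsin in DDM micelles, a practical stand-in for a GPCR) at
0-20 mM AMUPol and AsymPol-POK ships as :data:`KR2_DDM_SCREEN`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .errors import DataError


@dataclass
class IntensityMeasurement:
    """One integrated intensity with its acquisition bookkeeping."""

    intensity: float
    microwave: str = "off"  # "on" | "off"
    n_scans: int = 1
    recycle_delay_s: float | None = None

    def __post_init__(self) -> None:
        if self.microwave not in ("on", "off"):
            raise DataError("microwave must be 'on' or 'off'")
        if self.n_scans < 1:
            raise DataError("n_scans must be >= 1")
        if not math.isfinite(self.intensity):
            raise DataError("intensity must be finite")


@dataclass
class DnpSampleRecord:
    """DNP parameters of one sample preparation.

    ``polarization`` is stored as a fraction; percent input is normalized
    on construction (53 -> 0.53).  ``t2_ms`` maps site name ("CO",
    "amide-N") to the Hahn-echo T2 in ms.  ``sensitivity`` is derived,
    never required on input.
    """

    label: str
    radical: str | None = None
    concentration_mM: float = 0.0
    enhancement: float = 1.0
    polarization: float = 1.0
    T1_on_s: float | None = None
    T1_off_s: float | None = None
    t2_ms: dict[str, float] = field(default_factory=dict)
    sensitivity: float | None = None
    matrix: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.polarization = as_fraction(self.polarization)
        if self.enhancement < 0:
            raise DataError("enhancement must be >= 0")
        if self.polarization <= 0:
            raise DataError("polarization must be positive")
        for name, t1 in (("T1_on_s", self.T1_on_s), ("T1_off_s", self.T1_off_s)):
            if t1 is not None and t1 <= 0:
                raise DataError(f"{name} must be positive")
        if self.matrix is not None:
            total = sum(self.matrix.values())
            if abs(total - 1.0) > 1e-6:
                raise DataError(f"matrix fractions sum to {total}, expected 1")

    @property
    def T1_s(self) -> float:
        """T1 used in the sensitivity: microwave-on where available.

        The radical-free reference has no microwave-on measurement, so
        its microwave-off T1 stands in.
        """
        t1 = self.T1_on_s if self.T1_on_s is not None else self.T1_off_s
        if t1 is None:
            raise DataError(f"sample {self.label!r} has no T1")
        return t1


def as_fraction(p: float) -> float:
    """Normalize a polarization given as percent or fraction to a fraction.

    Values above 1.5 are interpreted as percent (the physical ceiling for
    a fraction is ~1.2, reachable through slight over-polarization).
    """
    return p / 100.0 if p > 1.5 else p


def enhancement(on: IntensityMeasurement, off: IntensityMeasurement) -> float:
    """Microwave on/off enhancement epsilon = I_on / I_off.

    Both spectra must share scan count and recycle delay; a recycle delay
    of >= 5*T1 makes the comparison quantitative.  Mismatches warn but do
    not abort.
    """
    if off.intensity == 0:
        raise DataError("microwave-off intensity is zero")
    if on.microwave != "on" or off.microwave != "off":
        warnings.warn("measurement roles do not match their microwave flags")
    if on.n_scans != off.n_scans:
        warnings.warn("enhancement compared across different scan counts")
    if (
        on.recycle_delay_s is not None
        and off.recycle_delay_s is not None
        and on.recycle_delay_s != off.recycle_delay_s
    ):
        warnings.warn("enhancement compared across different recycle delays")
    return on.intensity / off.intensity


def polarization(
    off_sample: IntensityMeasurement,
    off_reference: IntensityMeasurement,
    loss_correction: float = 0.0,
) -> float:
    """Residual polarization of a radical-doped sample vs radical-free.

    Both intensities are microwave-off at full recovery (>= 5*T1) on equal
    analyte amounts.  ``loss_correction`` compensates a known fractional
    sample loss: P = (I_sample / I_ref) / (1 - loss).  Depolarization is
    1 - P.
    """
    if off_reference.intensity == 0:
        raise DataError("reference intensity is zero")
    if not (0.0 <= loss_correction < 0.5):
        raise DataError("loss_correction must be in [0, 0.5)")
    return (off_sample.intensity / off_reference.intensity) / (1.0 - loss_correction)


def sensitivity(epsilon: float, P: float, T1_s: float) -> float:
    """Signal-to-noise per square-root time, S = epsilon * P / sqrt(T1).

    ``P`` may be percent or fraction.  Units: s^-0.5.
    """
    P = as_fraction(P)
    if epsilon <= 0 or P <= 0 or T1_s <= 0:
        raise DataError("enhancement, polarization and T1 must all be positive")
    return epsilon * P / math.sqrt(T1_s)


def derive_sensitivity(record: DnpSampleRecord) -> DnpSampleRecord:
    """Return a copy of ``record`` with the sensitivity field computed."""
    s = sensitivity(record.enhancement, record.polarization, record.T1_s)
    return replace(record, sensitivity=s)


def optimal_recycle_delay(T1_s: float, factor: float = 1.3) -> float:
    """Recycle delay maximizing signal-to-noise per time: factor * T1."""
    if T1_s <= 0 or factor <= 0:
        raise DataError("T1 and factor must be positive")
    return factor * T1_s


def noise_normalized_intensity(
    measurements: list[IntensityMeasurement],
    reference_index: int = 0,
    reference_value: float = 1.0,
) -> list[float]:
    """Scale equal-duration spectra to common noise, then to a reference.

    Noise grows as sqrt(n_scans), so each intensity is divided by
    sqrt(n_scans); the whole series is then rescaled so that entry
    ``reference_index`` equals ``reference_value``.  This puts spectra
    recorded with different recycle delays (hence scan counts) on a
    common sensitivity scale.
    """
    if not measurements:
        raise DataError("no measurements")
    scaled = [m.intensity / math.sqrt(m.n_scans) for m in measurements]
    ref = scaled[reference_index]
    if ref == 0:
        raise DataError("reference intensity is zero after noise scaling")
    return [v * reference_value / ref for v in scaled]


def rank_conditions(
    records: list[DnpSampleRecord],
    criterion: str = "sensitivity",
    t2_site: str = "CO",
) -> list[DnpSampleRecord]:
    """Order sample conditions by a figure of merit, best first.

    ``criterion="sensitivity"`` ranks by S directly.
    ``criterion="T2_weighted"`` ranks by S * sqrt(T2_site / T2_reference),
    where the reference is the radical-free record — a heuristic score
    that makes the sensitivity-vs-coherence-lifetime compromise explicit
    (longer T2 means narrower homogeneous lines and better
    multidimensional transfer).  Ties preserve input order.
    """
    if criterion not in ("sensitivity", "T2_weighted"):
        raise DataError(f"unknown criterion {criterion!r}")
    records = [r if r.sensitivity is not None else derive_sensitivity(r) for r in records]
    if criterion == "sensitivity":
        key = [r.sensitivity for r in records]
    else:
        missing = [r.label for r in records if t2_site not in r.t2_ms]
        if missing:
            raise DataError(f"records missing T2[{t2_site}]: {missing}")
        ref = next((r for r in records if r.radical is None), None)
        if ref is None:
            raise DataError("T2_weighted ranking needs a radical-free reference record")
        t2_ref = ref.t2_ms[t2_site]
        key = [r.sensitivity * math.sqrt(r.t2_ms[t2_site] / t2_ref) for r in records]
    order = sorted(range(len(records)), key=lambda i: -key[i])
    return [records[i] for i in order]


def _rec(label, radical, conc, t1on, t1off, t2n, t2co, eps, pol) -> DnpSampleRecord:
    return DnpSampleRecord(
        label=label,
        radical=radical,
        concentration_mM=conc,
        enhancement=eps,
        polarization=pol,
        T1_on_s=t1on,
        T1_off_s=t1off,
        t2_ms={"amide-N": t2n, "CO": t2co},
    )


#: Measured radical screen on KR2 in DDM micelles (100 K, 8 kHz MAS,
#: 9.4 T): T1(1H) with/without microwave, amide-15N and carbonyl-13C
#: Hahn-echo T2, on/off enhancement, and residual polarization vs the
#: radical-free sample.  The 10 mM AsymPol-POK polarization includes a
#: 10% sample-loss correction.  Sensitivity is derived, not stored.
KR2_DDM_SCREEN: list[DnpSampleRecord] = [
    _rec("no polarizing agent", None, 0.0, None, 13.5, 59.0, 23.0, 1, 100),
    _rec("5 mM AMUPol", "AMUPol", 5.0, 7.0, 6.5, 36.4, 15.4, 92, 63),
    _rec("10 mM AMUPol", "AMUPol", 10.0, 4.8, 4.0, 30.5, 13.0, 110, 53),
    _rec("20 mM AMUPol", "AMUPol", 20.0, 2.4, 2.0, 20.5, 7.6, 127, 38),
    _rec("5 mM AsymPol-POK", "AsymPol-POK", 5.0, 2.0, 2.3, 47.0, 20.2, 63, 88),
    _rec("10 mM AsymPol-POK", "AsymPol-POK", 10.0, 1.0, 1.0, 39.1, 15.4, 74, 83),
    _rec("20 mM AsymPol-POK", "AsymPol-POK", 20.0, 0.6, 0.7, 34.1, 12.1, 77, 75),
]

#: Scan counts accumulated in a fixed 10-minute experiment at a recycle
#: delay of 1.3*T1, for the screen samples in order.  An estimator for
#: budgeting only: the exact spectrometer rounding/phase-cycling rule
#: that produced these is not modeled.
KR2_SCREEN_SCANS_10MIN: list[int] = [30, 62, 100, 190, 236, 490, 728]


def estimate_scans(T1_s: float, total_time_s: float, factor: float = 1.3) -> int:
    """Scans accumulated in ``total_time_s`` at recycle delay factor*T1."""
    return int(total_time_s / optimal_recycle_delay(T1_s, factor))
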