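"""Conformational-ensemble chemical-shift distributions vs NMR line shapes.

In a frozen sample every conformer contributes its own chemical shift, so
the line shape of a single site maps the conformational ensemble.  This
module turns per-frame predicted shifts from an MD trajectory into
histograms, classifies helical vs non-helical propensity through
empirical Calpha/CO ppm windows (methionine windows derived from joint
BMRB/PDB statistics, >=20% propensity), detects bimodality with a
Gaussian-mixture criterion, measures line widths, and compares predicted
distributions with experimental 1D line shapes.

Backbone Calpha shifts move downfield in helices and upfield in sheets;
CO behaves similarly, which is what makes window-based classification of
a single resolved site informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .errors import DataError

__all__ = [
    "ShiftEnsemble",
    "Spectrum1D",
    "PropensityWindows",
    "Histogram",
    "BimodalityResult",
    "shift_histogram",
    "propensity_fractions",
    "detect_bimodality",
    "linewidth_measures",
    "broadening_ratio",
    "compare_distribution_to_lineshape",
    "overlap_coefficient",
    "rereference",
]


@dataclass
class ShiftEnsemble:
    """Per-frame predicted chemical shifts, one vector per atom site."""

    shifts: dict[str, np.ndarray]
    provenance: str = ""
    component_labels: dict[str, np.ndarray] | None = None  # generative truth

    def __post_init__(self) -> None:
        if not self.shifts:
            raise DataError("ensemble has no sites")
        sizes = set()
        for site, vals in self.shifts.items():
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1 or arr.size < 1:
                raise DataError(f"site {site!r} must hold a non-empty 1-D shift vector")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"site {site!r} contains non-finite shifts")
            self.shifts[site] = arr
            sizes.add(arr.size)
        if len(sizes) != 1:
            raise DataError("all sites must have the same frame count")

    @property
    def n_frames(self) -> int:
        return next(iter(self.shifts.values())).size

    @property
    def sites(self) -> list[str]:
        return list(self.shifts)


@dataclass
class Spectrum1D:
    """A 1D spectrum: ppm axis (stored ascending) plus intensities.

    NMR display convention (ppm decreasing left to right) is a rendering
    concern; axes here are always ascending.  ``reference_peak`` is an
    optional (name, known ppm) anchor for re-referencing.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    site: str = ""
    reference_peak: tuple[str, float] | None = None
    original_ppm: np.ndarray | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise DataError("ppm and intensity must be 1-D and equal length")
        if self.ppm.size < 2:
            raise DataError("spectrum needs at least 2 points")
        d = np.diff(self.ppm)
        if np.any(d == 0):
            raise DataError("ppm axis has duplicate points")
        if np.all(d < 0):  # accept descending input, store ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise DataError("ppm axis must be strictly monotone")

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.ppm)))


# Methionine secondary-structure propensity windows (ppm), >= 20%
# propensity thresholds; non-helical covers random coil and beta sheet.
# The Calpha windows overlap on [56, 57.5] ppm, so helical and
# non-helical fractions are reported independently and may sum past 1.
_DEFAULT_WINDOWS = {
    "CA": {"helical": (56.0, 60.0), "non_helical": (53.0, 57.5)},
    "CO": {"helical": (176.5, 179.0), "non_helical": (173.0, 177.0)},
}


@dataclass
class PropensityWindows:
    windows: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            atom: dict(d) for atom, d in _DEFAULT_WINDOWS.items()
        }
    )

    def interval(self, atom: str, kind: str) -> tuple[float, float]:
        try:
            lo, hi = self.windows[atom][kind]
        except KeyError:
            raise DataError(f"no {kind!r} window for atom {atom!r}") from None
        if not lo < hi:
            raise DataError(f"empty window for {atom}/{kind}")
        return lo, hi


@dataclass
class Histogram:
    """Histogram with bin edges snapped to a bin-width grid."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def density(self) -> np.ndarray:
        """Counts normalized so the piecewise-constant density has area 1."""
        total = self.counts.sum() * self.bin_width
        if total == 0:
            raise DataError("empty histogram has no density")
        return self.counts / total

    def mean(self) -> float:
        return float(np.average(self.centers, weights=self.counts))

    def percentile_width(self, lo_q: float = 0.10, hi_q: float = 0.90) -> float:
        """Width between area quantiles of the piecewise-constant density."""
        cum = np.concatenate([[0.0], np.cumsum(self.counts)]) / self.counts.sum()
        return float(
            np.interp(hi_q, cum, self.edges) - np.interp(lo_q, cum, self.edges)
        )


def shift_histogram(
    ensemble: ShiftEnsemble, site: str, bin_width: float = 0.2
) -> Histogram:
    """Histogram one site's per-frame shifts on a grid snapped to bin_width.

    Edges start/end on integer multiples of ``bin_width``, so two
    ensembles of the same site bin identically regardless of their exact
    ranges.
    """
    if bin_width <= 0:
        raise DataError("bin_width must be positive")
    if site not in ensemble.shifts:
        raise DataError(f"unknown site {site!r}; have {ensemble.sites}")
    x = ensemble.shifts[site]
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:  # degenerate (constant) ensemble: one bin containing it
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return Histogram(edges=edges, counts=counts.astype(float))


def _window_area_histogram(hist: Histogram, lo: float, hi: float) -> float:
    """Area of the piecewise-constant density inside [lo, hi] (partial bins pro-rated)."""
    dens = hist.density
    left = np.maximum(hist.edges[:-1], lo)
    right = np.minimum(hist.edges[1:], hi)
    overlap = np.clip(right - left, 0.0, None)
    return float(np.sum(dens * overlap))


def _integrate_spectrum(ppm: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of y over [lo, hi] with interpolated endpoints."""
    lo = max(lo, ppm[0])
    hi = min(hi, ppm[-1])
    if hi <= lo:
        return 0.0
    xs = np.concatenate([[lo], ppm[(ppm > lo) & (ppm < hi)], [hi]])
    return float(np.trapezoid(np.interp(xs, ppm, y), xs))


def propensity_fractions(
    distribution: "Histogram | Spectrum1D",
    atom: str,
    windows: PropensityWindows | None = None,
) -> tuple[float, float]:
    """Fractions of distribution area in the helical / non-helical windows.

    Negative spectral intensities (noise) are clipped at zero for the
    area computation.  The two fractions are independent — overlapping
    windows mean they can sum to more than 1.
    """
    windows = windows or PropensityWindows()
    hel = windows.interval(atom, "helical")
    non = windows.interval(atom, "non_helical")
    if isinstance(distribution, Histogram):
        total = 1.0  # density integrates to 1 by construction
        if distribution.counts.sum() == 0:
            raise DataError("histogram has zero total area")
        f_hel = _window_area_histogram(distribution, *hel)
        f_non = _window_area_histogram(distribution, *non)
    else:
        y = np.clip(distribution.intensity, 0.0, None)
        total = _integrate_spectrum(distribution.ppm, y, distribution.ppm[0], distribution.ppm[-1])
        if total <= 0:
            raise DataError("spectrum has zero total area")
        f_hel = _integrate_spectrum(distribution.ppm, y, *hel) / total
        f_non = _integrate_spectrum(distribution.ppm, y, *non) / total
    return f_hel, f_non


@dataclass
class BimodalityResult:
    n_modes: int
    means: list[float]
    sds: list[float]
    weights: list[float]
    bic_1: float
    bic_2: float
    separation_ok: bool


def detect_bimodality(
    shifts: np.ndarray,
    min_points: int = 50,
    separation_factor: float = 2.0,
    random_state: int = 0,
) -> BimodalityResult:
    """Decide 1 vs 2 modes in a shift distribution via Gaussian mixtures.

    Fits 1- and 2-component mixtures and reports two modes only when the
    2-component model wins on BIC *and* the component means are separated
    by at least ``separation_factor`` times the larger component standard
    deviation.  The double guard keeps the call conservative, mirroring
    the cautious visual judgment it replaces.
    """
    x = np.asarray(shifts, dtype=float)
    if x.ndim != 1 or x.size < min_points:
        raise DataError(f"need at least {min_points} shift values")
    if not np.all(np.isfinite(x)):
        raise DataError("shifts contain non-finite values")
    if np.ptp(x) == 0:  # constant vector: trivially unimodal
        return BimodalityResult(1, [float(x[0])], [0.0], [1.0],
                                float("nan"), float("nan"), False)
    X = x.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=random_state).fit(X)
    gm2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(X)
    bic1, bic2 = gm1.bic(X), gm2.bic(X)
    mu = gm2.means_.ravel()
    sd = np.sqrt(gm2.covariances_.ravel())
    sep_ok = abs(mu[0] - mu[1]) >= separation_factor * sd.max()
    if bic2 < bic1 and sep_ok:
        order = np.argsort(mu)
        return BimodalityResult(
            2,
            [float(m) for m in mu[order]],
            [float(s) for s in sd[order]],
            [float(w) for w in gm2.weights_[order]],
            float(bic1), float(bic2), True,
        )
    return BimodalityResult(
        1,
        [float(gm1.means_.ravel()[0])],
        [float(np.sqrt(gm1.covariances_.ravel()[0]))],
        [1.0],
        float(bic1), float(bic2), bool(sep_ok),
    )


def _fwhm(ppm: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation around the peak."""
    i_max = int(np.argmax(y))
    ymax = y[i_max]
    if ymax <= 0 or np.ptp(y) == 0:
        raise DataError("flat or non-positive signal: FWHM undefined")
    half = ymax / 2.0
    # walk left
    left = ppm[0]
    for i in range(i_max, 0, -1):
        if y[i - 1] < half <= y[i]:
            left = np.interp(half, [y[i - 1], y[i]], [ppm[i - 1], ppm[i]])
            break
    # walk right
    right = ppm[-1]
    for i in range(i_max, len(y) - 1):
        if y[i + 1] < half <= y[i]:
            right = np.interp(half, [y[i + 1], y[i]], [ppm[i + 1], ppm[i]])
            break
    return float(right - left)


def linewidth_measures(
    spectrum: Spectrum1D, window: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """(FWHM, 10-90 inter-percentile width, centroid), all in ppm.

    ``window`` restricts the analysis to one signal region; the FWHM is
    found by interpolating the half-maximum crossings of the tallest
    peak, the inter-percentile width from the cumulative (clipped) area,
    and the centroid is the intensity-weighted mean position.
    """
    ppm, y = spectrum.ppm, spectrum.intensity
    if window is not None:
        lo, hi = min(window), max(window)
        mask = (ppm >= lo) & (ppm <= hi)
        if mask.sum() < 3:
            raise DataError("analysis window contains fewer than 3 points")
        ppm, y = ppm[mask], y[mask]
    yc = np.clip(y, 0.0, None)
    if np.ptp(yc) == 0:
        raise DataError("flat spectrum in the analysis window")
    fwhm = _fwhm(ppm, yc)
    areas = 0.5 * (yc[1:] + yc[:-1]) * np.diff(ppm)
    cum = np.concatenate([[0.0], np.cumsum(areas)])
    cum /= cum[-1]
    ipw = float(np.interp(0.90, cum, ppm) - np.interp(0.10, cum, ppm))
    centroid = float(np.sum(ppm * yc) / np.sum(yc))
    return fwhm, ipw, centroid


def broadening_ratio(
    spectrum: Spectrum1D,
    T2_s: float,
    nucleus_frequency_mhz: float,
    window: tuple[float, float] | None = None,
    threshold: float = 10.0,
) -> tuple[float, bool]:
    """Observed FWHM over the homogeneous FWHM implied by the echo T2.

    The observed width (ppm) converts to Hz via the nucleus Larmor
    frequency in MHz (ppm * MHz = Hz); the homogeneous width is
    1/(pi*T2).  A ratio far above 1 (default threshold 10) marks the line
    as inhomogeneously broadened — a static distribution of environments
    (a frozen conformational ensemble) rather than relaxation: the echo
    refocuses the former but not the latter.
    """
    from .relaxfit import homogeneous_linewidth

    if nucleus_frequency_mhz <= 0:
        raise DataError("nucleus frequency must be positive (no default magnet)")
    fwhm_ppm, _, _ = linewidth_measures(spectrum, window)
    observed_hz = fwhm_ppm * nucleus_frequency_mhz
    ratio = observed_hz / homogeneous_linewidth(T2_s)
    return float(ratio), bool(ratio >= threshold)


def _resample_density(
    grid: np.ndarray, source: "Histogram | Spectrum1D"
) -> np.ndarray:
    if isinstance(source, Histogram):
        dens = source.density
        idx = np.searchsorted(source.edges, grid, side="right") - 1
        out = np.zeros_like(grid)
        inside = (idx >= 0) & (idx < dens.size) & (grid <= source.edges[-1])
        out[inside] = dens[idx[inside]]
        return out
    y = np.clip(source.intensity, 0.0, None)
    return np.interp(grid, source.ppm, y, left=0.0, right=0.0)


def overlap_coefficient(p: np.ndarray, q: np.ndarray, dx: float) -> float:
    """Overlap of two densities on a shared uniform grid: sum(min(p,q))*dx.

    Symmetric; 1 iff the (normalized) densities are identical on the grid,
    0 iff their supports are disjoint.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise DataError("densities must share one grid")
    if p.sum() == 0 or q.sum() == 0:
        raise DataError("empty density")
    p = p / (p.sum() * dx)
    q = q / (q.sum() * dx)
    return float(np.minimum(p, q).sum() * dx)


def compare_distribution_to_lineshape(
    histogram: Histogram, spectrum: Spectrum1D
) -> tuple[float, float]:
    """(overlap coefficient, width ratio) between a predicted shift
    distribution and an experimental line shape.

    Both are area-normalized on a common ppm grid; the overlap is
    sum(min(p, q)) * dppm in [0, 1] (1 iff identical on the grid), and the
    width ratio is spectrum / histogram 10-90 inter-percentile width.  A
    ratio above 1 means the measured line is broader than the predicted
    ensemble — motions slower than the trajectory length are frozen into
    the line but absent from the prediction.
    """
    lo = min(histogram.edges[0], spectrum.ppm[0])
    hi = max(histogram.edges[-1], spectrum.ppm[-1])
    step = min(histogram.bin_width, spectrum.step) / 4.0
    n = max(int(np.ceil((hi - lo) / step)), 2)
    grid = np.linspace(lo, hi, n + 1)
    dx = grid[1] - grid[0]
    p = _resample_density(grid, histogram)
    q = _resample_density(grid, spectrum)
    if p.sum() == 0 or q.sum() == 0:
        raise DataError("empty distribution on the comparison grid")
    overlap = overlap_coefficient(p, q, dx)
    if overlap == 0.0:
        warnings.warn("distributions have disjoint ppm supports")
    _, spec_w, _ = linewidth_measures(spectrum)
    hist_w = histogram.percentile_width()
    width_ratio = spec_w / hist_w if hist_w > 0 else float("inf")
    return min(overlap, 1.0), float(width_ratio)


def rereference(spectrum: Spectrum1D) -> Spectrum1D:
    """Shift the ppm axis so the local maximum nearest the declared
    reference peak lands exactly on its known ppm.

    Typical anchors: natural-abundance glycerol at 64.78 ppm or a
    detergent sugar carbon at 105.2 ppm (both vs DSS).  The original axis
    is preserved on the returned spectrum.
    """
    if spectrum.reference_peak is None:
        raise DataError("spectrum declares no reference peak")
    _, ref_ppm = spectrum.reference_peak
    y = spectrum.intensity
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    peak_idx = np.where(interior)[0] + 1
    if peak_idx.size == 0:
        raise DataError("no local maxima found for re-referencing")
    nearest = peak_idx[np.argmin(np.abs(spectrum.ppm[peak_idx] - ref_ppm))]
    shift = ref_ppm - spectrum.ppm[nearest]
    return Spectrum1D(
        ppm=spectrum.ppm + shift,
        intensity=spectrum.intensity.copy(),
        site=spectrum.site,
        reference_peak=spectrum.reference_peak,
        original_ppm=spectrum.ppm.copy(),
        ground_truth=spectrum.ground_truth,
    )
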