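"""Spectral preprocessing: the two chains feeding the analyses.

Two canonical chains are provided.  The multivariate-analysis (MVA)
chain prepares spectra for PCA-LDA:

    QC -> baseline(degree 5) -> despike -> substrate subtraction
       -> peak alignment (1001 cm^-1) -> unit-vector normalization

The machine-learning (ML) chain prepares spectra for the classifiers:

    QC -> resample (900-point grid) -> substrate subtraction
       -> baseline(degree 6) -> despike -> normalization

Baseline removal uses plain least-squares polynomials; cosmic-ray
despiking is the Whitaker-Hayes modified-z-score detector on first
differences (threshold 3.5, 11-point replacement neighborhood by
default); substrate subtraction fits a non-negative scalar so that
drop-to-drop variation in substrate exposure is absorbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter

from .io import CohortDataset, RamanSpectrum, ValidationError

logger = logging.getLogger(__name__)

#: Consistency constant relating MAD to the standard deviation of a
#: normal distribution; used by the modified z-score of the despiker.
MAD_SCALE = 0.6745

NORMALIZATION_METHODS = ("unit_vector", "l2", "snv", "max", "minmax")


@dataclass
class PreprocessParams:
    """Tunable knobs of both preprocessing chains (defaults in cm^-1,
    points, or a.u. as noted)."""

    grid_n: int = 900
    grid_min: float = 400.0
    grid_max: float = 1600.0
    baseline_degree: int = 5            # 5 for the MVA chain, 6 for ML
    despike_threshold: float = 3.5      # modified-z cutoff
    despike_window: int = 11            # replacement neighborhood, points
    normalization: str = "unit_vector"
    align_target: float = 1001.0        # phenylalanine ring-breathing band
    align_search_halfwidth: float = 10.0
    smooth_window: int = 11
    smooth_polyorder: int = 2
    # QC thresholds (cohort-relative; see flag_artifact_spectra)
    sat_fraction: float = 0.05
    sat_epsilon: float = 0.005
    signal_floor_fraction: float = 0.10
    corr_floor: float = 0.5
    min_spectra_per_subject: int = 20

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        bad = []
        if not self.grid_min < self.grid_max:
            bad.append("grid_min must be < grid_max")
        if self.grid_n < 2:
            bad.append("grid_n must be >= 2")
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            bad.append("despike_window must be odd and >= 3")
        if self.smooth_window % 2 == 0:
            bad.append("smooth_window must be odd")
        if not self.smooth_polyorder < self.smooth_window:
            bad.append("smooth_polyorder must be < smooth_window")
        if self.normalization not in NORMALIZATION_METHODS:
            bad.append(f"normalization must be one of {NORMALIZATION_METHODS}")
        if self.baseline_degree < 0:
            bad.append("baseline_degree must be >= 0")
        return bad


@dataclass
class QcFlags:
    saturated: bool = False
    no_signal: bool = False
    reason: str = ""

    @property
    def passed(self) -> bool:
        return not (self.saturated or self.no_signal)


def standard_grid(params: PreprocessParams) -> np.ndarray:
    return np.linspace(params.grid_min, params.grid_max, params.grid_n)


def resample_to_grid(spectrum: RamanSpectrum,
                     params: PreprocessParams) -> RamanSpectrum:
    """Linear interpolation onto the uniform inclusive grid.

    The source axis must span the grid; extrapolation is refused.
    """
    grid = standard_grid(params)
    lo, hi = spectrum.shift_axis[0], spectrum.shift_axis[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValidationError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond source axis "
            f"[{lo}, {hi}]; extrapolation is not performed")
    values = np.interp(grid, spectrum.shift_axis, spectrum.intensities)
    return spectrum.with_axis(grid, values)


def fit_polynomial_baseline(spectrum: RamanSpectrum, degree: int) -> np.ndarray:
    """Least-squares polynomial of ``degree`` evaluated on the axis."""
    n = len(spectrum)
    if degree < 0:
        raise ValidationError("degree must be >= 0")
    if degree + 1 >= n:
        raise ValidationError(f"degree {degree} needs > {degree + 1} points, "
                              f"spectrum has {n}")
    # Polynomial.fit maps the axis to [-1, 1] internally, which keeps
    # degree-5/6 fits on a 400-1600 cm^-1 axis well conditioned.
    poly = Polynomial.fit(spectrum.shift_axis, spectrum.intensities, degree)
    return poly(spectrum.shift_axis)


def subtract_baseline(spectrum: RamanSpectrum, degree: int) -> RamanSpectrum:
    return spectrum.with_intensities(
        spectrum.intensities - fit_polynomial_baseline(spectrum, degree))


def despike_modified_zscores(intensities: np.ndarray) -> np.ndarray:
    """Modified z-scores of the first differences.

    Entry ``i`` (for i >= 1) scores the difference I[i] - I[i-1];
    entry 0 is zero by convention (no preceding point).
    """
    delta = np.diff(intensities)
    med = np.median(delta)
    mad = np.median(np.abs(delta - med))
    z = np.zeros_like(intensities)
    if mad == 0:
        # Flat or quantized signal: a zero scale estimate would flag
        # everything, so declare no spikes.
        return z
    z[1:] = MAD_SCALE * (delta - med) / mad
    return z


def despike_whitaker_hayes(spectrum: RamanSpectrum,
                           threshold: float = 3.5,
                           window: int = 11) -> RamanSpectrum:
    """Remove cosmic-ray spikes via the modified z-score of differences.

    A point is a spike when the modified z-score of its first
    difference exceeds ``threshold`` in magnitude.  Spikes are replaced
    by the mean of the non-spike points inside a centered window of
    ``window`` points; if the window contains only spikes it is widened
    symmetrically until a clean neighbor exists.
    """
    if window < 3 or window % 2 == 0:
        raise ValidationError("window must be odd and >= 3")
    z = despike_modified_zscores(spectrum.intensities)
    spikes = np.abs(z) > threshold
    if not spikes.any():
        return spectrum
    values = spectrum.intensities.copy()
    clean = ~spikes
    n = len(values)
    half = window // 2
    for i in np.flatnonzero(spikes):
        w = half
        while True:
            lo, hi = max(0, i - w), min(n, i + w + 1)
            neighbors = np.flatnonzero(clean[lo:hi]) + lo
            if neighbors.size:
                values[i] = spectrum.intensities[neighbors].mean()
                break
            if lo == 0 and hi == n:   # pathological: everything flagged
                values[i] = np.median(spectrum.intensities)
                break
            w += half
    return spectrum.with_intensities(values)


def subtract_substrate(spectrum: RamanSpectrum,
                       substrate: RamanSpectrum) -> RamanSpectrum:
    """Subtract a fitted non-negative multiple of the substrate spectrum.

    The scalar minimizes ||spectrum - c*substrate|| subject to c >= 0;
    a zero substrate yields c = 0 and leaves the input unchanged.
    """
    if len(substrate) != len(spectrum) or not np.allclose(
            substrate.shift_axis, spectrum.shift_axis):
        raise ValidationError("substrate must be resampled to the spectrum grid")
    denom = float(substrate.intensities @ substrate.intensities)
    if denom == 0:
        return spectrum
    c = max(0.0, float(spectrum.intensities @ substrate.intensities) / denom)
    logger.debug("substrate coefficient c=%.4f for %s/%s",
                 c, spectrum.subject_id, spectrum.acquisition_id)
    return spectrum.with_intensities(spectrum.intensities - c * substrate.intensities)


def normalize_intensity(spectrum: RamanSpectrum,
                        method: str = "unit_vector") -> RamanSpectrum:
    """Normalize per spectrum: unit_vector/l2, snv, max or minmax."""
    method = method.lower()
    y = spectrum.intensities
    if method in ("unit_vector", "l2"):
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValidationError("cannot L2-normalize an all-zero spectrum")
        out = y / norm
    elif method == "snv":
        sd = y.std(ddof=1)
        if sd == 0:
            raise ValidationError("SNV undefined for a constant spectrum")
        out = (y - y.mean()) / sd
    elif method == "max":
        m = y.max()
        if m == 0:
            raise ValidationError("max-normalization undefined when max is 0")
        out = y / m
    elif method == "minmax":
        lo, hi = y.min(), y.max()
        if hi == lo:
            raise ValidationError("min-max undefined for a constant spectrum")
        out = (y - lo) / (hi - lo)
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return spectrum.with_intensities(out)


def flag_artifact_spectra(dataset: CohortDataset,
                          params: PreprocessParams | None = None
                          ) -> dict[str, QcFlags]:
    """Flag saturated / no-signal acquisitions on raw spectra.

    Saturation: at least ``sat_fraction`` of the points sit within
    ``sat_epsilon`` (relative) of the spectrum maximum AND that maximum
    reaches the 99th percentile of cohort maxima (a clipped detector).
    No signal: total baseline-subtracted intensity below
    ``signal_floor_fraction`` of the cohort median, OR correlation with
    the cohort median spectrum below ``corr_floor``.

    Returns flags keyed by acquisition_id.  Subjects whose retained
    spectra fall below ``min_spectra_per_subject`` trigger a warning;
    a subject losing all spectra raises.
    """
    params = params or PreprocessParams()
    if not dataset.spectra:
        raise ValidationError("dataset has no spectra")
    matrix = dataset.intensity_matrix()
    maxima = matrix.max(axis=1)
    sat_level = np.percentile(maxima, 99)
    # robust "signal" measure: total intensity above a linear baseline
    degree = min(1, matrix.shape[1] - 2)
    totals = np.empty(len(dataset.spectra))
    for i, spec in enumerate(dataset.spectra):
        base = fit_polynomial_baseline(spec, degree)
        totals[i] = np.abs(spec.intensities - base).sum()
    floor = params.signal_floor_fraction * np.median(totals)
    median_spectrum = np.median(matrix, axis=0)
    med_sd = median_spectrum.std()

    flags: dict[str, QcFlags] = {}
    for i, spec in enumerate(dataset.spectra):
        f = QcFlags()
        m = maxima[i]
        if m >= sat_level and m > 0:
            near_max = np.mean(spec.intensities >= m * (1 - params.sat_epsilon))
            if near_max >= params.sat_fraction:
                f.saturated = True
                f.reason = (f"{near_max:.0%} of points within "
                            f"{params.sat_epsilon:.1%} of max")
        if totals[i] < floor:
            f.no_signal = True
            f.reason = (f.reason + "; " if f.reason else "") + \
                f"total signal {totals[i]:.3g} below floor {floor:.3g}"
        elif med_sd > 0 and spec.intensities.std() > 0:
            r = np.corrcoef(spec.intensities, median_spectrum)[0, 1]
            if r < params.corr_floor:
                f.no_signal = True
                f.reason = (f.reason + "; " if f.reason else "") + \
                    f"correlation with cohort median {r:.2f} < {params.corr_floor}"
        elif med_sd > 0:
            f.no_signal = True
            f.reason = (f.reason + "; " if f.reason else "") + "constant spectrum"
        flags[spec.acquisition_id] = f

    retained: dict[str, int] = {sid: 0 for sid in dataset.subjects}
    for spec in dataset.spectra:
        if flags[spec.acquisition_id].passed:
            retained[spec.subject_id] += 1
    for sid, n0 in dataset.counts().items():
        if n0 and retained[sid] == 0:
            raise ValidationError(f"QC removed every spectrum of subject {sid}")
        if n0 and retained[sid] < params.min_spectra_per_subject:
            logger.warning("subject %s retains only %d spectra after QC",
                           sid, retained[sid])
    return flags


def apply_qc(dataset: CohortDataset,
             params: PreprocessParams | None = None) -> CohortDataset:
    """Drop flagged spectra, keeping subjects."""
    flags = flag_artifact_spectra(dataset, params)
    kept = [s for s in dataset.spectra if flags[s.acquisition_id].passed]
    return dataset.replace_spectra(kept)


def align_to_reference_peak(spectrum: RamanSpectrum,
                            params: PreprocessParams) -> RamanSpectrum:
    """Shift the axis so the local maximum near ``align_target`` lands
    on it, then re-interpolate onto the original grid.

    If the search window contains no interior maximum (monotone
    segment) the spectrum is returned unchanged with a warning.  Edge
    values exposed by the shift are filled by edge replication.
    """
    axis, y = spectrum.shift_axis, spectrum.intensities
    win = (axis >= params.align_target - params.align_search_halfwidth) & \
          (axis <= params.align_target + params.align_search_halfwidth)
    idx = np.flatnonzero(win)
    if idx.size < 3:
        logger.warning("alignment window too narrow; spectrum unchanged")
        return spectrum
    seg = y[idx]
    k = int(np.argmax(seg))
    if k == 0 or k == seg.size - 1:
        logger.warning("no interior maximum in alignment window for %s/%s; "
                       "spectrum unchanged", spectrum.subject_id,
                       spectrum.acquisition_id)
        return spectrum
    located = axis[idx[k]]
    shift = params.align_target - located
    if shift == 0:
        return spectrum
    shifted_axis = axis + shift
    values = np.interp(axis, shifted_axis, y)  # edge-replicated by np.interp
    return spectrum.with_intensities(values)


def savitzky_golay_smooth(spectrum: RamanSpectrum,
                          window: int = 11,
                          polyorder: int = 2) -> RamanSpectrum:
    """Savitzky-Golay smoothing (representation only, never inside the
    classification chains)."""
    if window % 2 == 0:
        raise ValidationError("smoothing window must be odd")
    if polyorder >= window:
        raise ValidationError("polyorder must be < window")
    return spectrum.with_intensities(
        savgol_filter(spectrum.intensities, window, polyorder))


def run_mva_chain(dataset: CohortDataset,
                  params: PreprocessParams | None = None,
                  substrate: RamanSpectrum | None = None,
                  qc: bool = True) -> CohortDataset:
    """QC -> baseline(5) -> despike -> substrate -> align -> unit vector."""
    params = params or PreprocessParams()
    if qc:
        dataset = apply_qc(dataset, params)
    out = []
    for spec in dataset.spectra:
        s = subtract_baseline(spec, params.baseline_degree)
        s = despike_whitaker_hayes(s, params.despike_threshold,
                                   params.despike_window)
        if substrate is not None:
            sub = substrate
            if not np.array_equal(sub.shift_axis, s.shift_axis):
                sub = RamanSpectrum(s.shift_axis,
                                    np.interp(s.shift_axis, sub.shift_axis,
                                              sub.intensities))
            s = subtract_substrate(s, sub)
        s = align_to_reference_peak(s, params)
        s = normalize_intensity(s, "unit_vector")
        out.append(s)
    return dataset.replace_spectra(out)


def run_ml_chain(dataset: CohortDataset,
                 params: PreprocessParams | None = None,
                 substrate: RamanSpectrum | None = None,
                 qc: bool = True) -> CohortDataset:
    """QC -> resample(900) -> substrate -> baseline(6) -> despike -> normalize."""
    params = params or PreprocessParams(baseline_degree=6)
    if qc:
        dataset = apply_qc(dataset, params)
    grid = standard_grid(params)
    sub_on_grid = None
    if substrate is not None:
        sub_on_grid = RamanSpectrum(grid, np.interp(grid, substrate.shift_axis,
                                                    substrate.intensities))
    out = []
    for spec in dataset.spectra:
        s = resample_to_grid(spec, params)
        if sub_on_grid is not None:
            s = subtract_substrate(s, sub_on_grid)
        s = subtract_baseline(s, params.baseline_degree)
        s = despike_whitaker_hayes(s, params.despike_threshold,
                                   params.despike_window)
        s = normalize_intensity(s, params.normalization)
        out.append(s)
    return dataset.replace_spectra(out)
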