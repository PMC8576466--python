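"""Synthetic saliva-Raman cohort generator.

Emulates the statistical structure of a three-group (CTRL / PD / AD)
salivary Raman study so every downstream stage is testable without
patient data:

* spectra on the acquisition-like grid 400-1600 cm^-1 at 0.8 cm^-1/step,
  built as a sum of Lorentzian bands at the 20 canonical salivary peak
  positions (phenylalanine ring breathing at 1001 cm^-1 dominant),
* multiplicative group effects at the peaks where the group difference
  spectra diverge, per-subject amplitude effects (larger inter-subject
  spread in CTRL), smooth fluorescence background, an aluminum-substrate
  term, additive Gaussian noise and Poisson-count cosmic-ray spikes,
* cohort sizes 33/23/10 with 20-30 spectra per subject, ages and sex
  ratios per group, and PD clinical scores (UPDRS III, H&Y, LEDD) tied
  to a latent severity that also modulates protein-related bands.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CohortDataset, RamanSpectrum, SubjectRecord, assemble_cohort

ACQUISITION_STEP = 0.8  # cm^-1 per point

#: (center cm^-1, default relative amplitude, attribution) for the 20
#: canonical salivary bands; amplitudes shaped so the mean spectrum is
#: qualitatively saliva-like with 1001 cm^-1 dominant.
_PEAK_TABLE = [
    (517, 0.35, "Phosphatidylinositol"),
    (532, 0.30, "Ester of cholesterol"),
    (578, 0.25, "Tryptophan, cytosine, guanine"),
    (619, 0.25, "Phenylalanine twisting"),
    (715, 0.30, "Phospholipids"),
    (750, 0.55, "O-O stretching in protein"),
    (870, 0.40, "C-N stretching in protein, tyrosine ring breathing"),
    (920, 0.35, "Glucose/glycogen"),
    (978, 0.30, "C-C stretching of phosphorylated proteins"),
    (1001, 1.00, "Aromatic ring breathing"),
    (1047, 0.45, "C-C in plane bending"),
    (1077, 0.40, "C-C bond of lipids"),
    (1102, 0.35, "Secondary bands of Amide I"),
    (1125, 0.35, "Tyrosine, phenylalanine, CH3 rocking in protein"),
    (1203, 0.30, "Tyrosine"),
    (1244, 0.40, "Nucleic acids/secondary bands of Amide III"),
    (1268, 0.30, "C-H bond of phospholipids"),
    (1346, 0.45, "Amide III"),
    (1415, 0.30, "C-H deformation"),
    (1444, 0.55, "C-H stretching of glycoproteins"),
]


@dataclass(frozen=True)
class PeakDefinition:
    center: float          # cm^-1
    width: float           # FWHM, cm^-1
    base_amplitude: float  # a.u.
    attribution: str

    def __post_init__(self):
        if not 400 <= self.center <= 1600:
            raise ValueError(f"peak center {self.center} outside [400, 1600]")
        if self.width <= 0 or self.base_amplitude < 0:
            raise ValueError("width must be > 0 and amplitude >= 0")


def build_peak_library(width: float = 8.0) -> list[PeakDefinition]:
    """The 20 canonical salivary bands with default widths (8 cm^-1 FWHM,
    consistent with the +/-8 cm^-1 attribution tolerance)."""
    return [PeakDefinition(c, width, a, attr) for c, a, attr in _PEAK_TABLE]


@dataclass
class GroupEffectMap:
    """Multiplicative amplitude factors per group, keyed by peak center.

    CTRL is the reference group (all factors 1).  Default PD and AD
    factors perturb the bands at which the group difference spectra
    diverge; their magnitudes are order-of-magnitude placeholders (the
    true effect sizes are not published numerically) and are meant to
    be overridden per experiment.
    """

    factors: dict[str, dict[float, float]] = field(default_factory=lambda: {
        "CTRL": {},
        "PD": {715: 1.25, 1001: 1.30, 1047: 1.20, 1102: 1.15,
               1244: 1.20, 1346: 1.25, 1415: 0.85, 1444: 0.80},
        "AD": {750: 1.35, 870: 1.30, 920: 1.30, 1047: 0.80,
               1415: 0.85, 1444: 0.75},
    })

    def __post_init__(self):
        for g, fmap in self.factors.items():
            for c, f in fmap.items():
                if f <= 0:
                    raise ValueError(f"{g} factor at {c} must be > 0")
        if any(f != 1 for f in self.factors.get("CTRL", {}).values()):
            raise ValueError("CTRL is the reference group; factors must be 1")

    def factor(self, group: str, center: float) -> float:
        return self.factors.get(group, {}).get(center, 1.0)

    def affected_centers(self, group_a: str, group_b: str) -> list[float]:
        """Peak centers whose factors differ between two groups."""
        centers = set(self.factors.get(group_a, {})) | set(
            self.factors.get(group_b, {}))
        return sorted(c for c in centers
                      if self.factor(group_a, c) != self.factor(group_b, c))

    @classmethod
    def null(cls) -> "GroupEffectMap":
        """No group effects at all (for type-I-error experiments)."""
        return cls(factors={"CTRL": {}, "PD": {}, "AD": {}})


@dataclass
class SyntheticConfig:
    """Study-condition knobs of the generator (defaults = the emulated
    study's conditions where published, realistic placeholders where not)."""

    n_ctrl: int = 33
    n_pd: int = 23
    n_ad: int = 10
    spectra_per_subject: tuple[int, int] = (20, 30)
    #: lognormal sigma of per-subject amplitude effects (global and
    #: per-peak); CTRL configured larger than the pathological groups.
    subject_amp_sd: dict[str, float] = field(default_factory=lambda: {
        "CTRL": 0.10, "PD": 0.05, "AD": 0.05})
    spectrum_amp_sd: float = 0.03     # per-acquisition global amplitude jitter
    noise_sd: float = 0.01            # additive Gaussian noise, a.u.
    spike_rate: float = 0.3           # expected cosmic-ray spikes per spectrum
    baseline_coeffs_sd: float = 0.3   # scale of the fluorescence background
    substrate_amp: float = 0.15       # scale of the aluminum substrate term
    group_effects: GroupEffectMap = field(default_factory=GroupEffectMap)
    severity_peaks: tuple[float, ...] = (1001, 1346, 1444)
    severity_beta: float = 0.15       # amplitude modulation per unit severity
    clinical_link: float = 0.7        # corr(latent severity, clinical latents)
    peak_width: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ctrl, self.n_pd, self.n_ad) < 1:
            raise ValueError("group counts must be >= 1")
        if not -1 <= self.clinical_link <= 1:
            raise ValueError("clinical_link must be in [-1, 1]")
        for name in ("spectrum_amp_sd", "noise_sd", "spike_rate",
                     "baseline_coeffs_sd", "substrate_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.subject_amp_sd.values()):
            raise ValueError("subject_amp_sd values must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(round((1600 - 400) / ACQUISITION_STEP)) + 1
        return np.linspace(400.0, 1600.0, n)


@dataclass
class SubjectParams:
    """Latent per-subject state shared by all of a subject's spectra."""

    subject_id: str
    group: str
    global_amp: float
    peak_effects: dict[float, float]   # per-peak lognormal jitter
    severity: float                    # latent disease severity (PD), else 0


def lorentzian(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian line shape."""
    half = fwhm / 2.0
    return half ** 2 / ((axis - center) ** 2 + half ** 2)


def substrate_spectrum(grid: np.ndarray) -> RamanSpectrum:
    """Smooth broad profile standing in for the aluminum-foil background."""
    y = np.exp(-((grid - 950.0) / 400.0) ** 2) + 0.2 * (grid - 400.0) / 1200.0
    return RamanSpectrum(grid, y, subject_id="", acquisition_id="substrate")


def _fluorescence(grid: np.ndarray, scale: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Random smooth cubic with a positive leading trend."""
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    c = rng.uniform([0.2, 0.1, -0.5, 0.2], [0.6, 0.8, 0.5, 1.0])
    return scale * (c[0] + c[1] * t + c[2] * t ** 2 + c[3] * t ** 3)


def simulate_spectrum(subject: SubjectParams, config: SyntheticConfig,
                      rng: np.random.Generator,
                      acquisition_id: str = "a0") -> RamanSpectrum:
    """One acquisition: peak sum x subject/group/severity effects, plus
    fluorescence, substrate, noise and cosmic-ray spikes."""
    grid = config.grid()
    library = build_peak_library(config.peak_width)
    spec_amp = rng.lognormal(0.0, config.spectrum_amp_sd) \
        if config.spectrum_amp_sd > 0 else 1.0
    y = np.zeros_like(grid)
    for peak in library:
        a = (peak.base_amplitude
             * config.group_effects.factor(subject.group, peak.center)
             * subject.peak_effects.get(peak.center, 1.0))
        if peak.center in config.severity_peaks:
            a *= max(0.1, 1.0 + config.severity_beta * subject.severity)
        y += a * lorentzian(grid, peak.center, peak.width)
    y *= subject.global_amp * spec_amp
    if config.baseline_coeffs_sd > 0:
        y += _fluorescence(grid, config.baseline_coeffs_sd, rng)
    if config.substrate_amp > 0:
        y += rng.uniform(0.5, 1.5) * config.substrate_amp * \
            substrate_spectrum(grid).intensities
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=grid.size)
    if config.spike_rate > 0:
        for _ in range(rng.poisson(config.spike_rate)):
            pos = rng.integers(0, grid.size)
            y[pos] += rng.uniform(20, 100) * max(config.noise_sd, 1e-3)
    return RamanSpectrum(grid, y, subject_id=subject.subject_id,
                         acquisition_id=acquisition_id)


def simulate_clinical_scores(group: str, severity: float,
                             rng: np.random.Generator,
                             clinical_link: float = 0.7
                             ) -> tuple[float | None, float | None, float | None]:
    """PD clinical scores tied to latent severity; absent otherwise.

    Each score mixes the shared severity with independent noise so that
    corr(severity, score latent) = ``clinical_link``:
    UPDRS III ~ 31.7 + 14.5 * latent (truncated >= 0), H&Y ~ 2.19 +
    0.7 * latent (clipped to [1, 5]), LEDD ~ 466 + 220 * latent
    (truncated >= 0).
    """
    if group != "PD":
        return None, None, None
    rho = clinical_link
    mix = np.sqrt(max(0.0, 1.0 - rho ** 2))

    def latent() -> float:
        return rho * severity + mix * rng.normal()

    updrs3 = max(0.0, 31.7 + 14.5 * latent())
    hy = float(np.clip(2.19 + 0.7 * latent(), 1.0, 5.0))
    ledd = max(0.0, 466.0 + 220.0 * latent())
    return updrs3, hy, ledd


def clean_group_spectrum(group: str, config: SyntheticConfig) -> RamanSpectrum:
    """Noiseless expected spectrum of a group (no background, substrate,
    noise, spikes, subject effects or severity): the analytic peak sum
    under the configured group factors.  Useful for deciding which
    configured effects rise above a detection rule's floor."""
    clean = SyntheticConfig(
        noise_sd=0.0, spike_rate=0.0, baseline_coeffs_sd=0.0,
        substrate_amp=0.0, spectrum_amp_sd=0.0, severity_beta=0.0,
        group_effects=config.group_effects, peak_width=config.peak_width)
    subject = SubjectParams(subject_id="expected", group=group,
                            global_amp=1.0, peak_effects={}, severity=0.0)
    return simulate_spectrum(subject, clean, np.random.default_rng(0))


_AGE_DIST = {"CTRL": (63.5, 8.0), "PD": (69.9, 8.8), "AD": (78.6, 7.9)}
_MALE_FRACTION = {"CTRL": 0.666, "PD": 0.74, "AD": 0.80}


def _draw_subject(sid: str, group: str, config: SyntheticConfig,
                  rng: np.random.Generator
                  ) -> tuple[SubjectRecord, SubjectParams]:
    mean, sd = _AGE_DIST[group]
    age = float(np.clip(rng.normal(mean, sd), 30, 100))
    sex = "M" if rng.random() < _MALE_FRACTION[group] else "F"
    severity = float(rng.normal()) if group == "PD" else 0.0
    updrs3, hy, ledd = simulate_clinical_scores(
        group, severity, rng, config.clinical_link)
    record = SubjectRecord(subject_id=sid, group=group, age=age, sex=sex,
                           updrs3=updrs3, hy=hy, ledd=ledd)
    amp_sd = config.subject_amp_sd.get(group, 0.0)
    params = SubjectParams(
        subject_id=sid, group=group,
        global_amp=rng.lognormal(0.0, amp_sd) if amp_sd > 0 else 1.0,
        peak_effects={c: rng.lognormal(0.0, amp_sd) if amp_sd > 0 else 1.0
                      for c, _, _ in _PEAK_TABLE},
        severity=severity)
    return record, params


def simulate_cohort(config: SyntheticConfig | None = None) -> CohortDataset:
    """Generate a full cohort; deterministic given ``config.seed``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    plan = ([("CTRL", f"C{i:03d}") for i in range(config.n_ctrl)]
            + [("PD", f"P{i:03d}") for i in range(config.n_pd)]
            + [("AD", f"A{i:03d}") for i in range(config.n_ad)])
    subjects: dict[str, SubjectRecord] = {}
    spectra: list[RamanSpectrum] = []
    lo, hi = config.spectra_per_subject
    for group, sid in plan:
        record, params = _draw_subject(sid, group, config, rng)
        subjects[sid] = record
        n_spec = int(rng.integers(lo, hi + 1))
        for j in range(n_spec):
            spectra.append(simulate_spectrum(params, config, rng,
                                             acquisition_id=f"{sid}_s{j:03d}"))
    return assemble_cohort(spectra, subjects)
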