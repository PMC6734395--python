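"""Synthetic MEGA-PRESS acquisitions with known ground truth.

Spectral-editing MRS alternates editing-pulse ON and OFF transients; the
ON-minus-OFF difference spectrum isolates coupled resonances (GABA+, Glx)
that are otherwise hidden under larger peaks.  This module simulates such
acquisitions directly in the spectral domain: peaks are rendered on a ppm
axis per transient, frequency drift is a per-transient shift of the peak
centres, and phase drift is a zero-order rotation of the analytic
(Hilbert-transformed) spectrum.  Full time-domain pulse-sequence physics is
deliberately out of scope — every downstream stage consumes spectra.

Also houses the multi-subject cohort generator (two active viewing
conditions plus rest, counterbalanced order) and a Bernoulli simulator for
the Vernier fixation task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.stats import norm

__all__ = [
    "PeakSpec",
    "AcquisitionConfig",
    "SubjectTruth",
    "CohortConfig",
    "SpectralAcquisition",
    "ppm_axis",
    "render_peak",
    "simulate_acquisition",
    "default_peaks",
    "water_peak",
    "simulate_cohort",
    "simulate_vernier",
    "GAUSS_AREA_FACTOR",
]

# area of a unit-height Gaussian of unit FWHM: sqrt(pi / (4 ln 2))
GAUSS_AREA_FACTOR = float(np.sqrt(np.pi / (4.0 * np.log(2.0))))
# area of a unit-height Lorentzian of unit FWHM: pi / 2
LORENTZ_AREA_FACTOR = float(np.pi / 2.0)


@dataclass(frozen=True)
class PeakSpec:
    """One simulated resonance.

    ``edit_class`` controls MEGA-PRESS editing behaviour:

    - ``edited``   — present in ON transients only, so it appears with its
      full amplitude in the ON−OFF difference (GABA+, Glx analogues);
    - ``unedited`` — identical in ON and OFF, cancels in the difference
      (tCr, choline, water analogues);
    - ``inverted`` — sign-flipped in ON, so it appears with amplitude −2a
      in the difference (NAA-like behaviour).
    """

    name: str
    center: float  # ppm
    amplitude: float  # peak height, arbitrary signal units
    fwhm: float  # ppm
    shape: str = "gaussian"  # gaussian | lorentzian | mixed
    g_fraction: float = 1.0  # Gaussian fraction for shape == "mixed"
    edit_class: str = "unedited"  # edited | unedited | inverted

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"peak {self.name!r}: amplitude must be >= 0")
        if self.fwhm <= 0:
            raise ValueError(f"peak {self.name!r}: fwhm must be > 0")
        if self.shape not in ("gaussian", "lorentzian", "mixed"):
            raise ValueError(f"peak {self.name!r}: unknown shape {self.shape!r}")
        if not 0.0 <= self.g_fraction <= 1.0:
            raise ValueError(f"peak {self.name!r}: g_fraction must be in [0, 1]")
        if self.edit_class not in ("edited", "unedited", "inverted"):
            raise ValueError(
                f"peak {self.name!r}: unknown edit_class {self.edit_class!r}"
            )

    @property
    def area(self) -> float:
        """Analytic area under the peak model."""
        g = {"gaussian": 1.0, "lorentzian": 0.0, "mixed": self.g_fraction}[self.shape]
        per_unit = g * GAUSS_AREA_FACTOR + (1.0 - g) * LORENTZ_AREA_FACTOR
        return self.amplitude * self.fwhm * per_unit


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and noise model.

    Defaults follow a conventional 3T proton acquisition: 256 interleaved
    ON/OFF transients of 2,048 points, 2,000 Hz spectral width at
    123.25 MHz, axis centred on water at 4.7 ppm.
    """

    n_transients: int = 256
    n_points: int = 2048
    spectral_width: float = 2000.0  # Hz
    transmitter_freq: float = 123.25  # MHz; 1 ppm == transmitter_freq Hz
    reference_ppm: float = 4.7
    noise_sd: float = 0.02  # per-point additive white noise, signal units
    freq_drift_sd: float = 0.0  # Hz per transient
    phase_drift_sd: float = 0.0  # degrees per transient
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transients < 2 or self.n_transients % 2:
            raise ValueError("n_transients must be even and >= 2 (ON/OFF interleaving)")
        if self.n_points < 8:
            raise ValueError("n_points too small")
        if self.spectral_width <= 0 or self.transmitter_freq <= 0:
            raise ValueError("spectral_width and transmitter_freq must be > 0")
        if self.noise_sd < 0 or self.freq_drift_sd < 0 or self.phase_drift_sd < 0:
            raise ValueError("noise and drift SDs must be >= 0")

    @property
    def ppm_range(self) -> float:
        return self.spectral_width / self.transmitter_freq


@dataclass
class SpectralAcquisition:
    """Interleaved ON/OFF transients with axis metadata.

    ``transients`` holds real spectra, one row per transient; the ppm axis
    is ascending.  ``truth`` carries the simulator's drift draws and peak
    list when the acquisition is synthetic.
    """

    transients: np.ndarray  # (n_transients, n_points), real
    edit_labels: np.ndarray  # (n_transients,), "ON"/"OFF"
    config: AcquisitionConfig
    truth: dict = field(default_factory=dict)

    @property
    def axis(self) -> np.ndarray:
        return ppm_axis(self.config)

    @property
    def n_pairs(self) -> int:
        return self.transients.shape[0] // 2

    def __post_init__(self) -> None:
        n_on = int(np.sum(self.edit_labels == "ON"))
        n_off = int(np.sum(self.edit_labels == "OFF"))
        if n_on == 0 or n_off == 0:
            raise ValueError("acquisition must contain both ON and OFF transients")


def ppm_axis(config: AcquisitionConfig) -> np.ndarray:
    """Ascending chemical-shift axis (ppm) for an acquisition geometry."""
    half = 0.5 * config.ppm_range
    return np.linspace(
        config.reference_ppm - half, config.reference_ppm + half, config.n_points
    )


def render_peak(peak: PeakSpec, axis: np.ndarray) -> np.ndarray:
    """Evaluate a peak model on a ppm axis.

    Gaussian and Lorentzian shapes are FWHM-parameterised; ``mixed`` is the
    convex combination g·gaussian + (1−g)·lorentzian with shared centre and
    FWHM (a pseudo-Voigt).
    """
    axis = np.asarray(axis, dtype=float)
    d = np.diff(axis)
    if axis.ndim != 1 or axis.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be 1-D and strictly monotonic")
    lo, hi = min(axis[0], axis[-1]), max(axis[0], axis[-1])
    if not lo <= peak.center <= hi:
        raise ValueError(
            f"peak {peak.name!r} center {peak.center} ppm lies outside the "
            f"axis range [{lo:.3f}, {hi:.3f}] ppm"
        )
    delta = axis - peak.center
    gauss = np.exp(-4.0 * np.log(2.0) * (delta / peak.fwhm) ** 2)
    lorentz = 1.0 / (1.0 + (2.0 * delta / peak.fwhm) ** 2)
    g = {"gaussian": 1.0, "lorentzian": 0.0, "mixed": peak.g_fraction}[peak.shape]
    return peak.amplitude * (g * gauss + (1.0 - g) * lorentz)


def _edit_sign(peak: PeakSpec, label: str) -> float:
    if peak.edit_class == "edited":
        return 1.0 if label == "ON" else 0.0
    if peak.edit_class == "inverted":
        return -1.0 if label == "ON" else 1.0
    return 1.0


def simulate_acquisition(
    config: AcquisitionConfig,
    peaks: list[PeakSpec],
    rng: np.random.Generator | None = None,
) -> SpectralAcquisition:
    """Simulate interleaved ON/OFF transients for a peak set.

    Per transient: peak centres are shifted by a frequency-drift draw
    (N(0, freq_drift_sd) Hz), a zero-order phase draw (N(0, phase_drift_sd)
    degrees) rotates the analytic spectrum, and white noise of SD
    ``noise_sd`` is added to the real part.  The same (config, peaks, seed)
    triple reproduces the output bit-for-bit.
    """
    if not peaks:
        raise ValueError("at least one peak required")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    axis = ppm_axis(config)
    n = config.n_transients
    labels = np.array(["ON", "OFF"] * (n // 2))

    shifts_hz = (
        rng.normal(0.0, config.freq_drift_sd, size=n)
        if config.freq_drift_sd > 0
        else np.zeros(n)
    )
    phases_deg = (
        rng.normal(0.0, config.phase_drift_sd, size=n)
        if config.phase_drift_sd > 0
        else np.zeros(n)
    )

    drifting = config.freq_drift_sd > 0 or config.phase_drift_sd > 0
    transients = np.empty((n, config.n_points))
    if not drifting:
        # render each label's clean spectrum once
        clean = {}
        for lab in ("ON", "OFF"):
            s = np.zeros(config.n_points)
            for p in peaks:
                sign = _edit_sign(p, lab)
                if sign:
                    s += sign * render_peak(p, axis)
            clean[lab] = s
        for i, lab in enumerate(labels):
            transients[i] = clean[lab]
    else:
        for i, lab in enumerate(labels):
            dppm = shifts_hz[i] / config.transmitter_freq
            s = np.zeros(config.n_points)
            for p in peaks:
                sign = _edit_sign(p, lab)
                if sign:
                    shifted = replace(p, center=p.center + dppm)
                    s += sign * render_peak(shifted, axis)
            if phases_deg[i]:
                analytic = hilbert(s)
                s = np.real(analytic * np.exp(1j * np.deg2rad(phases_deg[i])))
            transients[i] = s

    if config.noise_sd > 0:
        transients += rng.normal(0.0, config.noise_sd, size=transients.shape)

    truth = {
        "peaks": list(peaks),
        "shifts_hz": shifts_hz,
        "phases_deg": phases_deg,
    }
    return SpectralAcquisition(transients, labels, config, truth)


# ---------------------------------------------------------------------------
# default peak sets


def _doublet(
    name: str,
    center: float,
    total_area: float,
    separation: float,
    fwhm: float,
    edit_class: str = "edited",
) -> list[PeakSpec]:
    """Two equal Gaussians splitting ``total_area`` around ``center``.

    GABA+ (~3 ppm) and Glx (~3.8 ppm) appear in edited difference spectra as
    pseudo-doublets; a double Gaussian is the fitting model downstream, so
    the simulated lineshape matches it by construction.
    """
    half_area = total_area / 2.0
    amp = half_area / (fwhm * GAUSS_AREA_FACTOR)
    return [
        PeakSpec(f"{name}_a", center - separation / 2, amp, fwhm, "gaussian", 1.0, edit_class),
        PeakSpec(f"{name}_b", center + separation / 2, amp, fwhm, "gaussian", 1.0, edit_class),
    ]


#: default doublet geometry (ppm): centre, sub-peak separation, sub-peak FWHM
GABA_CENTER, GABA_SEP, GABA_FWHM = 3.00, 0.11, 0.08
GLX_CENTER, GLX_SEP, GLX_FWHM = 3.75, 0.10, 0.06
TCR_CENTER, TCR_FWHM = 3.03, 0.06
CHO_CENTER, CHO_FWHM = 3.20, 0.05
TCR_AMPLITUDE = 1.0


def tcr_area() -> float:
    """Analytic area of the default simulated tCr peak."""
    g = 0.7
    per_unit = g * GAUSS_AREA_FACTOR + (1 - g) * LORENTZ_AREA_FACTOR
    return TCR_AMPLITUDE * TCR_FWHM * per_unit


def default_peaks(
    gaba_tcr: float = 0.12,
    glx_tcr: float = 0.15,
    include_inverted_naa: bool = True,
) -> list[PeakSpec]:
    """Standard simulated metabolite set with target area ratios.

    ``gaba_tcr`` / ``glx_tcr`` are the true difference-spectrum metabolite
    areas expressed as a fraction of the tCr area on the non-edited (OFF)
    spectrum — the quantity the quantification stage estimates.  Co-edited
    macromolecules are folded into the GABA+ amplitude, as in GABA+
    quantification generally.
    """
    if gaba_tcr <= 0 or glx_tcr <= 0:
        raise ValueError("true ratios must be > 0")
    area_cr = tcr_area()
    peaks = [
        PeakSpec("tCr", TCR_CENTER, TCR_AMPLITUDE, TCR_FWHM, "mixed", 0.7, "unedited"),
        PeakSpec("Cho", CHO_CENTER, 0.8, CHO_FWHM, "gaussian", 1.0, "unedited"),
    ]
    peaks += _doublet("GABA+", GABA_CENTER, gaba_tcr * area_cr, GABA_SEP, GABA_FWHM)
    peaks += _doublet("Glx", GLX_CENTER, glx_tcr * area_cr, GLX_SEP, GLX_FWHM)
    if include_inverted_naa:
        peaks.append(PeakSpec("NAA", 2.01, 1.2, 0.05, "mixed", 0.7, "inverted"))
    return peaks


def water_peak(amplitude: float = 50.0) -> PeakSpec:
    """Residual-free unsuppressed water resonance at 4.7 ppm."""
    return PeakSpec("water", 4.7, amplitude, 0.12, "mixed", 0.5, "unedited")


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class SubjectTruth:
    subject_id: str
    order: str  # single_first | mixed_first
    gaba_tcr: dict  # condition -> true ratio
    glx_tcr: dict

    def __post_init__(self) -> None:
        if self.order not in ("single_first", "mixed_first"):
            raise ValueError(f"unknown order {self.order!r}")
        for d in (self.gaba_tcr, self.glx_tcr):
            if any(v <= 0 for v in d.values()):
                raise ValueError("true ratios must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    The design mirrors a 20-subject within-subject experiment: an initial
    rest acquisition, two active acquisitions (single- and mixed-polarity
    viewing) in counterbalanced order, and a second, half-length rest.
    Condition effects are fractional shifts applied between the single and
    mixed conditions (mixed = single + delta, with delta expressed as a
    fraction of the subject's baseline ratio).  Defaults encode a ~4% GABA+
    decrease and ~2% Glx increase from single to mixed viewing.
    """

    n_subjects: int = 20
    gaba_baseline: float = 0.12
    glx_baseline: float = 0.15
    between_subject_sd: float = 0.10  # fractional SD of baselines across subjects
    within_subject_sd: float = 0.04  # fractional acquisition-to-acquisition jitter
    rest_extra_sd: float = 0.0  # extra fractional SD for rest acquisitions
    gaba_effect: float = -0.04  # (mixed − single) / baseline, GABA+
    glx_effect: float = +0.02  # (mixed − single) / baseline, Glx
    effect_profile: np.ndarray | None = None  # per-window multiplier, dynamic sims
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for s in (self.between_subject_sd, self.within_subject_sd, self.rest_extra_sd):
            if s < 0:
                raise ValueError("SDs must be >= 0")
        if self.gaba_baseline <= 0 or self.glx_baseline <= 0:
            raise ValueError("baseline ratios must be > 0")


CONDITIONS = ("rest1", "single", "mixed", "rest2")


def simulate_cohort_truth(cohort: CohortConfig) -> list[SubjectTruth]:
    """Draw per-subject, per-condition true ratios and condition orders.

    Baselines are lognormal-free: subject baseline = population mean ×
    (1 + N(0, between_subject_sd)), truncated away from zero.  Each
    acquisition adds independent fractional jitter ``within_subject_sd``
    (rest acquisitions additionally ``rest_extra_sd``).  The single→mixed
    effect is a deterministic fractional shift.  Orders alternate so the
    split is exact for even cohorts.
    """
    rng = np.random.default_rng(cohort.seed)
    if cohort.n_subjects % 2:
        warnings.warn(
            "odd n_subjects: counterbalancing split differs by one", stacklevel=2
        )
    subjects = []
    for i in range(cohort.n_subjects):
        order = "single_first" if i % 2 == 0 else "mixed_first"
        truths = {}
        for metab, base, effect in (
            ("gaba", cohort.gaba_baseline, cohort.gaba_effect),
            ("glx", cohort.glx_baseline, cohort.glx_effect),
        ):
            subj_base = base * max(
                1.0 + rng.normal(0.0, cohort.between_subject_sd), 0.05
            )
            per_cond = {}
            for cond in CONDITIONS:
                mean = subj_base
                if cond == "mixed":
                    mean = subj_base * (1.0 + effect)
                sd = cohort.within_subject_sd
                if cond.startswith("rest"):
                    sd = float(np.hypot(sd, cohort.rest_extra_sd))
                per_cond[cond] = mean * max(1.0 + rng.normal(0.0, sd), 0.05)
            truths[metab] = per_cond
        subjects.append(
            SubjectTruth(f"S{i + 1:02d}", order, truths["gaba"], truths["glx"])
        )
    return subjects


def truth_table(subjects: list[SubjectTruth]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for cond in CONDITIONS:
            rows.append(
                {
                    "subject": s.subject_id,
                    "order": s.order,
                    "condition": cond,
                    "true_gaba_tcr": s.gaba_tcr[cond],
                    "true_glx_tcr": s.glx_tcr[cond],
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    cohort: CohortConfig,
    acq_config: AcquisitionConfig | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
):
    """Generate per-subject acquisitions for each condition plus a truth table.

    Yields ``(subject_truth, {condition: SpectralAcquisition})`` lazily so
    callers can quantify acquisitions without holding a whole cohort in
    memory.  The second rest period is half-length (128 transients at the
    default acquisition size).  An ``effect_profile`` modulates the active
    conditions' metabolite amplitudes per ON/OFF pair, enabling
    time-resolved (sliding-window) simulations.
    """
    base_cfg = acq_config or AcquisitionConfig()
    subjects = simulate_cohort_truth(cohort)
    root = np.random.SeedSequence(cohort.seed)
    # one child seed stream per subject, independent of truth draws
    children = root.spawn(cohort.n_subjects + 1)[1:]

    def _iter():
        for s, child in zip(subjects, children):
            rngs = child.spawn(len(conditions))
            acqs = {}
            for cond, cseq in zip(conditions, rngs):
                n_tr = base_cfg.n_transients
                if cond == "rest2":
                    n_tr = max(2, base_cfg.n_transients // 2)
                cfg = replace(base_cfg, n_transients=n_tr)
                rng = np.random.default_rng(cseq)
                profile = None
                if cohort.effect_profile is not None and cond in ("single", "mixed"):
                    profile = np.asarray(cohort.effect_profile, dtype=float)
                acq = _simulate_condition(
                    cfg, s.gaba_tcr[cond], s.glx_tcr[cond], rng, cond, profile
                )
                acqs[cond] = acq
            yield s, acqs

    return subjects, _iter()


def _simulate_condition(
    cfg: AcquisitionConfig,
    gaba_true: float,
    glx_true: float,
    rng: np.random.Generator,
    condition: str,
    profile: np.ndarray | None,
) -> SpectralAcquisition:
    if profile is None:
        acq = simulate_acquisition(cfg, default_peaks(gaba_true, glx_true), rng=rng)
    else:
        # per-pair amplitude modulation: render blocks with scaled edited areas
        n_pairs = cfg.n_transients // 2
        prof = np.interp(
            np.linspace(0, 1, n_pairs), np.linspace(0, 1, profile.size), profile
        )
        blocks, labels = [], []
        shifts, phases = [], []
        for k in range(n_pairs):
            pair_cfg = replace(cfg, n_transients=2, noise_sd=0.0)
            peaks = default_peaks(gaba_true * prof[k], glx_true * prof[k])
            pair = simulate_acquisition(pair_cfg, peaks, rng=rng)
            blocks.append(pair.transients)
            labels.append(pair.edit_labels)
            shifts.append(pair.truth["shifts_hz"])
            phases.append(pair.truth["phases_deg"])
        transients = np.vstack(blocks)
        if cfg.noise_sd > 0:
            transients = transients + rng.normal(0, cfg.noise_sd, transients.shape)
        acq = SpectralAcquisition(
            transients,
            np.concatenate(labels),
            cfg,
            {
                "shifts_hz": np.concatenate(shifts),
                "phases_deg": np.concatenate(phases),
                "profile": prof,
            },
        )
    acq.truth["condition"] = condition
    acq.truth["true_gaba_tcr"] = gaba_true
    acq.truth["true_glx_tcr"] = glx_true
    return acq


def simulate_water_acquisition(
    cfg: AcquisitionConfig, rng: np.random.Generator | None = None
) -> SpectralAcquisition:
    """16 water-unsuppressed transients matching an acquisition's geometry."""
    wcfg = replace(cfg, n_transients=16)
    return simulate_acquisition(wcfg, [water_peak()], rng=rng)


# ---------------------------------------------------------------------------
# Vernier behaviour


def simulate_vernier(
    bias: float,
    sigma: float,
    lapse: float = 0.0,
    offsets: np.ndarray | None = None,
    n_per_offset: int = 30,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate binary left/right Vernier judgements.

    P(respond "right" | offset x) = lapse/2 + (1 − lapse)·Φ((x − bias)/σ).
    ``bias`` and ``sigma`` are in arcmin; the default offset grid is seven
    evenly spaced values spanning ±6.4 arcmin.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0 <= lapse <= 1:
        raise ValueError("lapse must be a probability")
    if offsets is None:
        offsets = np.linspace(-6.4, 6.4, 7)
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.repeat(offsets, n_per_offset)
    p = lapse / 2.0 + (1.0 - lapse) * norm.cdf((x - bias) / sigma)
    resp = rng.random(x.size) < p
    return pd.DataFrame({"offset_arcmin": x, "response_right": resp.astype(int)})
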