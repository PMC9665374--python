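"""Synthetic cohort and signal generator.

Emulates the study's acquisition setup: per subject, three orthogonal
voltage-gradient (OVG) biopotential channels sampled at 8 kHz with a
0.024 µV amplitude quantum, and a two-channel (red / infrared)
photoplethysmogram (PPG) at 500 Hz, acquired for 3.5 minutes.  Subjects
carry an invasively-measured left ventricular end-diastolic pressure
(LVEDP, mmHg) and are stratified as non-elevated (≤12), mid (13–24) or
elevated (≥25 mmHg).

The generator encodes LVEDP into the signals through three latent
"effect parameters", each a monotone function of LVEDP:

* the beat-to-beat jitter SD of the atrial depolarization duration,
* the PPG pulse-base level (the pre-systolic nadir of the pulse wave),
* the dispersion of the ventricular repolarization loop in phase space.

The link is linear in the normalized pressure excess
``e = clip((lvedp - 12) / 13, 0, 1)``, i.e. effects ramp up across the
mid stratum and saturate at the elevated threshold.  Every record keeps
a :class:`GroundTruth` with the realized per-beat quantities so that
downstream feature extractors can be tested by parameter recovery.

Beat morphology is deliberately simple: each cardiac cycle is a sum of
Gaussian bumps (atrial wave, ventricular depolarization, ventricular
repolarization) with a fixed 3-D orientation per wave, which is the
minimal model that produces the loop structure the phase-space features
quantify.  No lead-field physics or electrode geometry is modelled.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "SubjectRecord",
    "AcquisitionRecord",
    "GroundTruth",
    "CohortConfig",
    "SignalConfig",
    "WaveSpec",
    "stratum_of",
    "lvedp_effect",
    "generate_cohort",
    "generate_signals",
    "generate_cohort_signals",
    "inject_noise",
    "NOISE_KINDS",
]

STRATUM_NON_ELEVATED = "non_elevated"
STRATUM_MID = "mid"
STRATUM_ELEVATED = "elevated"

#: Full width of a Gaussian bump measured at 10% of its peak, in sigmas.
#: Atrial "duration" is defined as this width so that signal-side width
#: measurements at a 10% threshold recover the generator's draw.
FWTM10 = 2.0 * np.sqrt(2.0 * np.log(10.0))  # ≈ 4.2919


def stratum_of(lvedp: float) -> str:
    """Deterministic stratum label from LVEDP (mmHg): ≤12 / 13–24 / ≥25."""
    if lvedp <= 12.0:
        return STRATUM_NON_ELEVATED
    if lvedp < 25.0:
        return STRATUM_MID
    return STRATUM_ELEVATED


def lvedp_effect(lvedp: float) -> float:
    """Normalized pressure excess e = clip((lvedp - 12)/13, 0, 1).

    0 for normal pressures (≤12 mmHg), ramping linearly across the mid
    stratum, saturating at 1 from the elevated threshold (25 mmHg) on.
    """
    return float(np.clip((lvedp - 12.0) / 13.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """Demographics and catheterization result for one subject."""

    subject_id: str
    age: float            # years
    gender: str           # "female" | "male"
    bmi: float            # kg/m^2
    ef: float             # ejection fraction, percent
    lvedp: float          # mmHg
    stratum: str          # derived from lvedp
    cad_obstructive: bool
    site_id: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.lvedp <= 45.0):
            raise ConfigurationError(f"lvedp {self.lvedp} outside [0, 45] mmHg")
        if self.age < 18.0:
            raise ConfigurationError("age must be >= 18")
        expected = stratum_of(self.lvedp)
        if self.stratum != expected:
            raise ConfigurationError(
                f"stratum {self.stratum!r} inconsistent with lvedp {self.lvedp}"
            )


@dataclass
class GroundTruth:
    """Generator-side annotations enabling parameter-recovery tests."""

    beat_onsets: np.ndarray          # seconds; ventricular depolarization fiducials
    atrial_durations: np.ndarray     # ms per beat
    pulse_base_values: np.ndarray    # optical units per beat (infrared channel)
    injected_noise: list = field(default_factory=list)   # [(kind, level), ...]
    effect_params: dict = field(default_factory=dict)    # family -> latent value
    ovg_ppg_delay: float = 0.0       # seconds, OVG fiducial -> PPG pulse foot


@dataclass
class AcquisitionRecord:
    """One subject's acquisition: OVG (3 x N, µV) and PPG (2 x M)."""

    ovg: np.ndarray          # (3, n_ovg) float64 µV, quantized
    ppg: np.ndarray          # (2, n_ppg): row 0 red, row 1 infrared
    ovg_rate: float          # Hz
    ppg_rate: float          # Hz
    duration: float          # seconds
    subject_id: str = ""
    truth: GroundTruth | None = None

    @property
    def n_ovg(self) -> int:
        return self.ovg.shape[1]

    @property
    def n_ppg(self) -> int:
        return self.ppg.shape[1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort composition; defaults mirror the validation cohort make-up.

    Stratum proportions default to 258/347/79 of 684; demographic
    moments (age 63±10 y, BMI 32±7 kg/m², EF 60±7%) are modelled as
    truncated normals since only moments are reported, and per-stratum
    LVEDP is a truncated normal with the printed stratum mean/SD.
    """

    stratum_proportions: tuple = (258 / 684, 347 / 684, 79 / 684)
    lvedp_params: dict = field(default_factory=lambda: {
        STRATUM_NON_ELEVATED: (9.0, 3.0, 0.0, 12.0),    # (mean, sd, lo, hi)
        STRATUM_MID: (18.0, 3.0, 13.0, 24.0),
        STRATUM_ELEVATED: (29.0, 4.0, 25.0, 38.0),
    })
    age_params: tuple = (63.0, 10.0, 18.0, 95.0)
    bmi_params: tuple = (32.0, 7.0, 15.0, 60.0)
    ef_params: tuple = (60.0, 7.0, 15.0, 80.0)
    p_female: float = 0.45
    p_cad_by_stratum: dict = field(default_factory=lambda: {
        STRATUM_NON_ELEVATED: 0.43, STRATUM_MID: 0.33, STRATUM_ELEVATED: 0.24,
    })
    n_sites: int = 15


@dataclass
class WaveSpec:
    """One Gaussian bump: amplitude (µV), width sigma (s), centre offset
    relative to the beat fiducial (s), and a 3-D channel orientation."""

    amplitude: float
    sigma: float
    center: float
    orientation: tuple

    def unit_orientation(self) -> np.ndarray:
        v = np.asarray(self.orientation, dtype=float)
        return v / np.linalg.norm(v)


@dataclass
class SignalConfig:
    """Signal morphology, acquisition geometry, and LVEDP effect links."""

    duration: float = 210.0          # seconds (3.5 min acquisition)
    ovg_rate: float = 8000.0         # Hz
    ppg_rate: float = 500.0          # Hz
    ovg_quantum_uv: float = 0.024    # OVG amplitude resolution, µV

    heart_rate_bpm: float = 70.0
    rr_jitter_sd_s: float = 0.02     # beat-to-beat RR SD

    # wave templates (amplitudes in µV; centres relative to fiducial)
    vdep: WaveSpec = field(default_factory=lambda: WaveSpec(
        amplitude=1000.0, sigma=0.012, center=0.0, orientation=(0.8, -0.4, 0.45)))
    vrep: WaveSpec = field(default_factory=lambda: WaveSpec(
        amplitude=250.0, sigma=0.045, center=0.30, orientation=(0.7, 0.5, -0.5)))
    atrial_amplitude_uv: float = 120.0
    atrial_center: float = -0.18     # s before the fiducial
    atrial_orientation: tuple = (0.6, 0.6, 0.53)
    atrial_duration_ms: float = 100.0       # mean width at 10% of peak

    # LVEDP effect links (value = base + slope * e)
    atrial_jitter_base_ms: float = 2.0
    atrial_jitter_slope_ms: float = 6.0
    repol_dispersion_base: float = 0.02     # fractional per-beat perturbation SD
    repol_dispersion_slope: float = 0.15
    ppg_base_slope: float = 80.0            # optical units per unit effect

    # PPG morphology
    ppg_baseline: float = 2000.0            # optical units, infrared channel
    ppg_pulse_amplitude: float = 400.0
    ppg_rise_tau: float = 0.15              # s, foot -> systolic peak
    ovg_ppg_delay: float = 0.20             # s, OVG fiducial -> pulse foot
    ppg_red_gain: float = 0.9               # red channel pulsatile gain
    ppg_red_offset: float = -150.0          # red channel DC offset
    ppg_ceiling: float = 4096.0             # sensor saturation ceiling

    # respiration-like amplitude modulation of the pulse train
    resp_rate_hz: float = 0.25
    resp_mod_depth: float = 0.10

    # noise injection
    powerline_hz: float = 60.0
    highfreq_band: tuple = (200.0, 1500.0)  # band of injected HF noise


NOISE_KINDS = ("powerline60", "highfreq", "ppg_saturation")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(n: int, config: CohortConfig | None = None,
                    seed: int = 0) -> list[SubjectRecord]:
    """Draw ``n`` subjects with stratum-linked LVEDP and demographics.

    Strata are assigned multinomially with ``config.stratum_proportions``
    and LVEDP is drawn from the stratum's truncated normal, so the
    stratum label is always the deterministic function of LVEDP.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    config = config or CohortConfig()
    props = np.asarray(config.stratum_proportions, dtype=float)
    if props.shape != (3,) or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"stratum proportions must be 3 non-negatives summing to 1, got {props}")

    rng = np.random.default_rng(seed)
    strata = [STRATUM_NON_ELEVATED, STRATUM_MID, STRATUM_ELEVATED]
    labels = rng.choice(3, size=n, p=props)
    lvedp = np.empty(n)
    for k, name in enumerate(strata):
        mask = labels == k
        if mask.any():
            mean, sd, lo, hi = config.lvedp_params[name]
            lvedp[mask] = _truncnorm(rng, mean, sd, lo, hi, size=int(mask.sum()))
    age = _truncnorm(rng, *config.age_params, size=n)
    bmi = _truncnorm(rng, *config.bmi_params, size=n)
    ef = _truncnorm(rng, *config.ef_params, size=n)
    female = rng.random(n) < config.p_female
    p_cad = np.array([config.p_cad_by_stratum[strata[k]] for k in labels])
    cad = rng.random(n) < p_cad
    sites = rng.integers(1, config.n_sites + 1, size=n)
    return [
        SubjectRecord(
            subject_id=f"S{i:05d}", age=float(age[i]),
            gender="female" if female[i] else "male",
            bmi=float(bmi[i]), ef=float(ef[i]), lvedp=float(lvedp[i]),
            stratum=strata[labels[i]], cad_obstructive=bool(cad[i]),
            site_id=f"site{int(sites[i]):02d}")
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _add_bump(out: np.ndarray, t: np.ndarray, center: float, sigma: float,
              amp: float, orientation: np.ndarray) -> None:
    """Add amp * exp(-(t-center)^2 / 2 sigma^2) * orientation to 3 channels,
    touching only the +/- 5 sigma window for speed."""
    fs = 1.0 / (t[1] - t[0])
    lo = max(0, int((center - 5 * sigma) * fs))
    hi = min(t.size, int((center + 5 * sigma) * fs) + 1)
    if hi <= lo:
        return
    bump = amp * np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)
    out[:, lo:hi] += orientation[:, None] * bump[None, :]


def _effect_params(lvedp: float, cfg: SignalConfig) -> dict:
    e = lvedp_effect(lvedp)
    return {
        "atrial_jitter_sd_ms": cfg.atrial_jitter_base_ms + cfg.atrial_jitter_slope_ms * e,
        "ppg_pulse_base": cfg.ppg_baseline + cfg.ppg_base_slope * e,
        "repol_dispersion": cfg.repol_dispersion_base + cfg.repol_dispersion_slope * e,
    }


def generate_signals(subject: SubjectRecord, gen_config: SignalConfig | None = None,
                     seed: int = 0) -> AcquisitionRecord:
    """Synthesize one subject's OVG/PPG acquisition with ground truth.

    The beat fiducial is the centre of the ventricular-depolarization
    bump (the landmark a peak detector finds).  The atrial bump is
    centred ``atrial_center`` seconds earlier with a per-beat duration
    drawn N(base, jitter_sd); the repolarization bump follows the
    fiducial with per-beat fractional perturbations of its amplitude
    and orientation (the "loop dispersion" effect).  The PPG pulse foot
    trails the fiducial by ``ovg_ppg_delay``; its per-beat base level
    carries the pulse-base effect plus respiration-like modulation.
    """
    cfg = gen_config or SignalConfig()
    if cfg.duration <= 0 or cfg.heart_rate_bpm <= 0:
        raise ConfigurationError("duration and heart rate must be positive")
    rng = np.random.default_rng(seed)
    eff = _effect_params(subject.lvedp, cfg)

    n_ovg = int(round(cfg.ovg_rate * cfg.duration))
    n_ppg = int(round(cfg.ppg_rate * cfg.duration))
    t_ovg = np.arange(n_ovg) / cfg.ovg_rate
    t_ppg = np.arange(n_ppg) / cfg.ppg_rate

    # beat fiducials: leave margin for the atrial bump before and the
    # repolarization bump / PPG pulse after
    rr_mean = 60.0 / cfg.heart_rate_bpm
    onsets = []
    t = 0.4
    while t < cfg.duration - 0.8:
        onsets.append(t)
        t += rr_mean + rng.normal(0.0, cfg.rr_jitter_sd_s)
    onsets = np.asarray(onsets)
    n_beats = onsets.size

    jitter_sd = eff["atrial_jitter_sd_ms"]
    atrial_dur_ms = cfg.atrial_duration_ms + rng.normal(0.0, jitter_sd, n_beats) \
        if jitter_sd > 0 else np.full(n_beats, cfg.atrial_duration_ms)
    atrial_dur_ms = np.maximum(atrial_dur_ms, 20.0)

    disp = eff["repol_dispersion"]
    rep_amp_fac = 1.0 + rng.normal(0.0, disp, n_beats)
    rep_tilt = rng.normal(0.0, disp, (n_beats, 3))

    ovg = np.zeros((3, n_ovg))
    u_atr = WaveSpec(1, 1, 0, cfg.atrial_orientation).unit_orientation()
    u_dep = cfg.vdep.unit_orientation()
    u_rep = cfg.vrep.unit_orientation()
    for i, ti in enumerate(onsets):
        sigma_a = atrial_dur_ms[i] / 1000.0 / FWTM10
        _add_bump(ovg, t_ovg, ti + cfg.atrial_center, sigma_a,
                  cfg.atrial_amplitude_uv, u_atr)
        _add_bump(ovg, t_ovg, ti + cfg.vdep.center, cfg.vdep.sigma,
                  cfg.vdep.amplitude, u_dep)
        u_r = u_rep + rep_tilt[i]
        u_r = u_r / np.linalg.norm(u_r)
        _add_bump(ovg, t_ovg, ti + cfg.vrep.center, cfg.vrep.sigma,
                  cfg.vrep.amplitude * rep_amp_fac[i], u_r)

    q = cfg.ovg_quantum_uv
    ovg = np.round(ovg / q) * q

    # PPG: baseline + pulse train; pulse foot at fiducial + delay, then a
    # gamma-like rise to the systolic peak and an exponential-ish decay,
    # so the unique per-beat minimum sits at the foot.
    base_level = eff["ppg_pulse_base"]
    pulse = np.zeros(n_ppg)
    feet = onsets + cfg.ovg_ppg_delay
    tau = cfg.ppg_rise_tau
    for i, fi in enumerate(feet):
        amp = cfg.ppg_pulse_amplitude * (
            1.0 + cfg.resp_mod_depth * np.sin(2 * np.pi * cfg.resp_rate_hz * fi))
        lo = int(fi * cfg.ppg_rate)
        hi = min(n_ppg, lo + int(2.0 * cfg.ppg_rate))
        if hi <= lo:
            continue
        s = t_ppg[lo:hi] - fi
        s = np.maximum(s, 0.0)
        pulse[lo:hi] += amp * (s / tau) * np.exp(1.0 - s / tau)
    ir = base_level + pulse
    red = (base_level + cfg.ppg_red_offset) + cfg.ppg_red_gain * pulse
    ppg = np.vstack([red, ir])

    # realized per-beat pulse base: minimum of the infrared channel in a
    # window around the foot (the feature extractor should recover these)
    bases = np.full(n_beats, np.nan)
    for i, fi in enumerate(feet):
        lo = max(0, int((fi - 0.06) * cfg.ppg_rate))
        hi = min(n_ppg, int((fi + 0.04) * cfg.ppg_rate) + 1)
        if hi > lo:
            bases[i] = ir[lo:hi].min()

    truth = GroundTruth(
        beat_onsets=onsets,
        atrial_durations=atrial_dur_ms,
        pulse_base_values=bases,
        injected_noise=[],
        effect_params=eff,
        ovg_ppg_delay=cfg.ovg_ppg_delay,
    )
    return AcquisitionRecord(
        ovg=ovg, ppg=ppg, ovg_rate=cfg.ovg_rate, ppg_rate=cfg.ppg_rate,
        duration=cfg.duration, subject_id=subject.subject_id, truth=truth)


def generate_cohort_signals(subjects: list[SubjectRecord],
                            gen_config: SignalConfig | None = None,
                            seed: int = 0) -> list[AcquisitionRecord]:
    """Per-subject acquisitions with deterministic child seeds."""
    children = np.random.SeedSequence(seed).spawn(len(subjects))
    return [
        generate_signals(s, gen_config, seed=int(c.generate_state(1)[0] % (2 ** 31)))
        for s, c in zip(subjects, children)
    ]


# ---------------------------------------------------------------------------
# noise injection
# ---------------------------------------------------------------------------

def _welch_band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    nper = min(int(4 * fs), x.size)
    f, p = sps.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2)
    mask = (f >= lo) & (f <= hi)
    return float(np.sum(p[mask]) * (f[1] - f[0]))


def inject_noise(record: AcquisitionRecord, kind: str, level: float,
                 gen_config: SignalConfig | None = None,
                 seed: int = 0) -> AcquisitionRecord:
    """Return a copy of ``record`` with clinical-environment noise added.

    * ``powerline60``: adds a 60 Hz sinusoid to each OVG channel whose
      power is ``level`` times that channel's 0.5–40 Hz signal-band
      power (so an injection at level r degrades the powerline SNR to
      about -10*log10(r) dB).
    * ``highfreq``: adds band-limited white noise (``highfreq_band``)
      at ``level`` times the signal-band power.
    * ``ppg_saturation``: clips the top ``level`` fraction of each PPG
      channel's samples to the configured sensor ceiling.

    ``level == 0`` returns an identical copy.  The injection is recorded
    in ``truth.injected_noise``.
    """
    if kind not in NOISE_KINDS:
        raise ConfigurationError(f"unknown noise kind {kind!r}; one of {NOISE_KINDS}")
    if level < 0:
        raise ConfigurationError("level must be >= 0")
    cfg = gen_config or SignalConfig()
    out = copy.deepcopy(record)
    if out.truth is not None:
        out.truth.injected_noise.append((kind, float(level)))
    if level == 0:
        return out

    rng = np.random.default_rng(seed)
    if kind == "powerline60":
        t = np.arange(out.n_ovg) / out.ovg_rate
        for k in range(3):
            p_sig = _welch_band_power(out.ovg[k], out.ovg_rate, 0.5, 40.0)
            amp = np.sqrt(2.0 * level * p_sig)
            out.ovg[k] += amp * np.sin(
                2 * np.pi * cfg.powerline_hz * t + rng.uniform(0, 2 * np.pi))
    elif kind == "highfreq":
        lo, hi = cfg.highfreq_band
        sos = sps.butter(6, [lo, hi], btype="bandpass", fs=out.ovg_rate, output="sos")
        for k in range(3):
            p_sig = _welch_band_power(out.ovg[k], out.ovg_rate, 0.5, 40.0)
            noise = sps.sosfiltfilt(sos, rng.standard_normal(out.n_ovg))
            noise *= np.sqrt(level * p_sig / np.mean(noise ** 2))
            out.ovg[k] += noise
    else:  # ppg_saturation
        frac = min(level, 1.0)
        n = out.n_ppg
        k_clip = int(np.ceil(frac * n))
        for k in range(2):
            idx = np.argpartition(out.ppg[k], n - k_clip)[n - k_clip:]
            out.ppg[k][idx] = cfg.ppg_ceiling
    if kind in ("powerline60", "highfreq"):
        # the acquisition front-end quantizes whatever reaches it
        q = cfg.ovg_quantum_uv
        out.ovg = np.round(out.ovg / q) * q
    return out
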