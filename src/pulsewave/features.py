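"""Cardiac-cycle segmentation and feature extraction.

Beats are detected on the band-passed 3-channel OVG magnitude with
refractory peak picking; each detected cycle is annotated with the
atrial wave window and width, the ventricular depolarization and
repolarization windows, and the PPG pulse base (the pre-systolic nadir
of the pulse wave).  From the annotated cycles, named features are
computed per family:

``time_domain.*``
    atrial depolarization duration mean / SD (the SD is the
    "variation in atrial depolarization duration" feature), RR
    statistics, and the residual RMS of each beat against the
    subject's median-beat template (an interpretation of
    "deviations from subject-specific models").
``phase_space.*``
    atrial-loop vector magnitude / orientation and the ventricular
    repolarization loop dispersion: the mean pairwise distance between
    band-pass-filtered, time-aligned repolarization segments of the
    3-D phase-space trajectory.
``ppg_indicator.*``
    per-beat pulse-base statistics (including the maximum of the pulse
    base, the most contributive named feature) and pulse amplitudes.
``ovg_spectral.*``
    band-power fractions of the OVG signal band.
``sync.*``
    OVG-fiducial-to-PPG-foot delay statistics.
``respiration.*``
    dominant frequency and depth of the low-frequency amplitude
    modulation of the pulse train.

The complete proprietary feature set is not public; each family here
carries a small number of representative, documented members and the
table schema is extensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InsufficientDataError, NoCyclesDetected
from .synthetic import AcquisitionRecord

__all__ = [
    "FeatureConfig", "CycleAnnotation",
    "segment_cycles", "atrial_duration_variation",
    "phase_space_embed", "phase_space_features",
    "ppg_indicators", "spectral_and_sync_features",
    "extract_features", "featurize_cohort", "FEATURE_FAMILIES",
]

FEATURE_FAMILIES = ("time_domain", "phase_space", "ppg_indicator",
                    "ovg_spectral", "sync", "respiration")


@dataclass
class FeatureConfig:
    band: tuple = (0.5, 40.0)          # Hz, analysis band-pass (zero-phase)
    filter_order: int = 4
    refractory_s: float = 0.25         # min beat spacing for peak picking
    min_beats: int = 10
    # windows relative to the beat fiducial (seconds); half-open [start, end)
    atrial_window: tuple = (-0.30, -0.09)
    vdep_window: tuple = (-0.06, 0.06)
    vrep_window: tuple = (0.18, 0.42)
    atrial_width_threshold: float = 0.10   # fraction of peak for width measure
    ppg_peak_window: tuple = (0.05, 0.60)  # systolic peak search after fiducial
    repol_resample: int = 80               # points per aligned repol segment
    spectral_bands: tuple = ((0.5, 5.0), (5.0, 15.0), (15.0, 40.0))
    resp_band: tuple = (0.05, 0.5)         # plausible respiration frequencies
    ppg_pulsatile_band: tuple = (0.5, 5.0)


@dataclass
class CycleAnnotation:
    beat_index: int
    onset: float                  # s, ventricular-depolarization fiducial
    atrial_onset: float           # s
    atrial_offset: float          # s
    atrial_duration_ms: float
    vdep_window: tuple            # [start, end) s
    vrep_window: tuple            # [start, end) s
    ppg_base_time: float          # s, pulse foot
    ppg_base_value: float         # optical units
    ppg_peak_time: float
    ppg_peak_value: float


def _bandpass(x: np.ndarray, fs: float, band, order=4) -> np.ndarray:
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """Linear-interpolated first (rising) / last (falling) crossing of level."""
    above = y >= level
    idx = np.flatnonzero(above[:-1] != above[1:])
    if idx.size == 0:
        return t[0] if rising else t[-1]
    i = idx[0] if rising else idx[-1]
    f = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + f * (t[i + 1] - t[i]))


def segment_cycles(record: AcquisitionRecord,
                   config: FeatureConfig | None = None) -> list[CycleAnnotation]:
    """Detect beats and annotate atrial / ventricular / PPG landmarks.

    Raises :class:`NoCyclesDetected` if fewer than ``config.min_beats``
    beats are found (e.g. a flat-line signal).
    """
    cfg = config or FeatureConfig()
    fs = record.ovg_rate
    filt = np.vstack([_bandpass(ch, fs, cfg.band, cfg.filter_order)
                      for ch in record.ovg])
    mag = np.linalg.norm(filt, axis=0)
    # raw magnitude for width measurements: between-wave background is ~0
    # there, whereas the band-pass leaves slow undershoot from the large
    # ventricular bump that swamps a 10%-of-peak threshold
    mag_raw = np.linalg.norm(record.ovg, axis=0)

    scale = np.percentile(mag, 99)
    if scale <= 0:
        raise NoCyclesDetected("flat-line OVG signal")
    peaks, _ = sps.find_peaks(mag, distance=max(1, int(cfg.refractory_s * fs)),
                              height=0.5 * scale)
    if peaks.size < cfg.min_beats:
        raise NoCyclesDetected(f"only {peaks.size} beats detected")

    t_ppg = np.arange(record.n_ppg) / record.ppg_rate
    ir = record.ppg[1]
    cycles: list[CycleAnnotation] = []
    for bi, p in enumerate(peaks):
        t0 = p / fs
        a_lo, a_hi = t0 + cfg.atrial_window[0], t0 + cfg.atrial_window[1]
        v_lo, v_hi = t0 + cfg.vdep_window[0], t0 + cfg.vdep_window[1]
        r_lo, r_hi = t0 + cfg.vrep_window[0], t0 + cfg.vrep_window[1]
        pk_lo, pk_hi = t0 + cfg.ppg_peak_window[0], t0 + cfg.ppg_peak_window[1]
        if a_lo < 0 or pk_hi >= record.duration or r_hi * fs >= record.n_ovg:
            continue

        # atrial width at a fixed fraction of the local peak, measured on
        # the raw magnitude above the window's baseline
        i0, i1 = int(a_lo * fs), int(a_hi * fs)
        seg_t = np.arange(i0, i1) / fs
        seg = mag_raw[i0:i1] - mag_raw[i0:i1].min()
        apk = seg.max()
        level = cfg.atrial_width_threshold * apk
        on = _crossing(seg_t, seg, level, rising=True)
        off = _crossing(seg_t, seg, level, rising=False)

        # PPG systolic peak, then the pre-systolic nadir (pulse base);
        # ties in the minimum break toward the latest sample so a flat
        # diastolic baseline yields the pulse foot, not the window start
        j0, j1 = int(pk_lo * record.ppg_rate), int(pk_hi * record.ppg_rate)
        jpk = j0 + int(np.argmax(ir[j0:j1]))
        jb0 = int(t0 * record.ppg_rate)
        seg_b = ir[jb0:jpk + 1]
        jb = jb0 + (seg_b.size - 1 - int(np.argmin(seg_b[::-1])))

        cycles.append(CycleAnnotation(
            beat_index=bi, onset=t0,
            atrial_onset=on, atrial_offset=off,
            atrial_duration_ms=1000.0 * (off - on),
            vdep_window=(v_lo, v_hi), vrep_window=(r_lo, r_hi),
            ppg_base_time=t_ppg[jb], ppg_base_value=float(ir[jb]),
            ppg_peak_time=t_ppg[jpk], ppg_peak_value=float(ir[jpk]),
        ))
    if len(cycles) < cfg.min_beats:
        raise NoCyclesDetected(f"only {len(cycles)} annotatable beats")
    return cycles


def atrial_duration_variation(cycles: list[CycleAnnotation]) -> float:
    """Sample SD (n-1 denominator) of per-beat atrial durations, ms."""
    if len(cycles) < 2:
        raise InsufficientDataError("need >= 2 cycles for a sample SD")
    d = np.array([c.atrial_duration_ms for c in cycles])
    return float(np.std(d, ddof=1))


def phase_space_embed(record_or_channels) -> np.ndarray:
    """(N, 3) phase-space trajectory: point i = (ch1[i], ch2[i], ch3[i])."""
    if isinstance(record_or_channels, AcquisitionRecord):
        chans = list(record_or_channels.ovg)
    else:
        chans = [np.asarray(c, dtype=float) for c in record_or_channels]
    if len(chans) != 3 or len({c.shape for c in chans}) != 1 or chans[0].ndim != 1:
        raise ValueError("need 3 equal-length 1-D channels")
    return np.column_stack(chans)


def _repol_segments(traj_filt: np.ndarray, cycles, fs: float, npts: int,
                    edge_guard_s: float = 3.0):
    """Time-aligned repolarization segments, each (npts, 3), by linear
    interpolation at npts equally spaced offsets within the beat's window.

    Beats within ``edge_guard_s`` of either record edge are skipped: the
    zero-phase band-pass has a slow settling response there that would
    register as spurious beat-to-beat dispersion.
    """
    n = traj_filt.shape[0]
    t = np.arange(n) / fs
    t_end = t[-1]
    segs = []
    for c in cycles:
        lo, hi = c.vrep_window
        if lo < edge_guard_s or hi > t_end - edge_guard_s:
            continue
        tt = np.linspace(lo, hi, npts, endpoint=False)
        segs.append(np.column_stack(
            [np.interp(tt, t, traj_filt[:, k]) for k in range(3)]))
    return segs


def repolarization_dispersion(segments) -> float:
    """Mean over all beat pairs of the mean pointwise distance between
    aligned repolarization segments (0 when every beat is identical)."""
    m = len(segments)
    if m < 2:
        raise InsufficientDataError("need >= 2 repolarization segments")
    tot, cnt = 0.0, 0
    for i in range(m):
        for j in range(i + 1, m):
            tot += float(np.mean(np.linalg.norm(segments[i] - segments[j], axis=1)))
            cnt += 1
    return tot / cnt


def phase_space_features(trajectory: np.ndarray, cycles, fs: float,
                         config: FeatureConfig | None = None) -> dict:
    """Atrial-loop vector and repolarization-loop dispersion features."""
    cfg = config or FeatureConfig()
    traj = np.asarray(trajectory, dtype=float)
    mag = np.linalg.norm(traj, axis=1)

    vecs = []
    for c in cycles:
        i0, i1 = int(c.atrial_onset * fs), int(c.atrial_offset * fs) + 1
        if i1 <= i0 or i1 > traj.shape[0]:
            continue
        k = i0 + int(np.argmax(mag[i0:i1]))
        vecs.append(traj[k])
    out: dict[str, float] = {}
    if vecs:
        vecs = np.asarray(vecs)
        mags = np.linalg.norm(vecs, axis=1)
        mean_vec = vecs.mean(axis=0)
        out["phase_space.atrial_vector_mag_mean"] = float(mags.mean())
        out["phase_space.atrial_vector_mag_sd"] = float(mags.std(ddof=1)) if len(mags) > 1 else 0.0
        out["phase_space.atrial_vector_azimuth"] = float(np.arctan2(mean_vec[1], mean_vec[0]))
        out["phase_space.atrial_vector_elevation"] = float(
            np.arctan2(mean_vec[2], np.linalg.norm(mean_vec[:2])))
    else:
        for k in ("atrial_vector_mag_mean", "atrial_vector_mag_sd",
                  "atrial_vector_azimuth", "atrial_vector_elevation"):
            out[f"phase_space.{k}"] = np.nan

    traj_filt = np.column_stack(
        [_bandpass(traj[:, k], fs, cfg.band, cfg.filter_order) for k in range(3)])
    segs = _repol_segments(traj_filt, cycles, fs, cfg.repol_resample)
    out["phase_space.repol_dispersion"] = (
        repolarization_dispersion(segs) if len(segs) >= 2 else np.nan)
    return out


def ppg_indicators(record: AcquisitionRecord, cycles) -> dict:
    """Pulse-base and pulse-amplitude statistics from the annotated beats."""
    base = np.array([c.ppg_base_value for c in cycles])
    amp = np.array([c.ppg_peak_value - c.ppg_base_value for c in cycles])
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {
        "ppg_indicator.base_max": float(base.max()),
        "ppg_indicator.base_mean": float(base.mean()),
        "ppg_indicator.base_sd": sd(base),
        "ppg_indicator.amp_mean": float(amp.mean()),
        "ppg_indicator.amp_sd": sd(amp),
    }


def _dominant_resp_freq(ir: np.ndarray, fs: float, cfg: FeatureConfig):
    """Dominant frequency of the pulse-train amplitude-modulation envelope."""
    ac = _bandpass(ir, fs, cfg.ppg_pulsatile_band, cfg.filter_order)
    env = np.abs(sps.hilbert(ac))
    sos = sps.butter(cfg.filter_order, cfg.resp_band[1], btype="lowpass",
                     fs=fs, output="sos")
    env_lp = sps.sosfiltfilt(sos, env)
    env_lp = env_lp - env_lp.mean()
    f, p = sps.periodogram(env_lp, fs=fs)
    mask = (f >= cfg.resp_band[0]) & (f <= cfg.resp_band[1])
    if not mask.any() or p[mask].max() <= 0:
        return np.nan, np.nan
    fpk = float(f[mask][np.argmax(p[mask])])
    depth = float(np.std(env_lp) / max(np.mean(env), 1e-12))
    return fpk, depth


def spectral_and_sync_features(record: AcquisitionRecord, cycles,
                               config: FeatureConfig | None = None) -> dict:
    """OVG band-power fractions, OVG->PPG delay stats, respiration proxy."""
    cfg = config or FeatureConfig()
    fs = record.ovg_rate
    nper = min(int(4 * fs), record.n_ovg)
    out: dict[str, float] = {}

    powers = np.zeros(len(cfg.spectral_bands))
    for ch in record.ovg:
        f, p = sps.welch(ch, fs=fs, nperseg=nper, noverlap=nper // 2)
        df = f[1] - f[0]
        for b, (lo, hi) in enumerate(cfg.spectral_bands):
            powers[b] += np.sum(p[(f >= lo) & (f < hi)]) * df
    total = powers.sum()
    names = ("lo", "mid", "hi")
    for b, name in enumerate(names):
        out[f"ovg_spectral.band_{name}_frac"] = float(powers[b] / total) if total > 0 else np.nan

    delays = np.array([c.ppg_base_time - c.onset for c in cycles])
    out["sync.delay_mean"] = float(delays.mean())
    out["sync.delay_sd"] = float(np.std(delays, ddof=1)) if delays.size > 1 else 0.0

    fpk, depth = _dominant_resp_freq(record.ppg[1], record.ppg_rate, cfg)
    out["respiration.dominant_freq"] = fpk
    out["respiration.mod_depth"] = depth
    return out


def _template_residual_rms(record: AcquisitionRecord, cycles,
                           cfg: FeatureConfig) -> float:
    """RMS deviation of each beat from the subject's median-beat template,
    normalized by the template RMS (dimensionless)."""
    fs = record.ovg_rate
    mag = np.linalg.norm(
        np.vstack([_bandpass(ch, fs, cfg.band, cfg.filter_order)
                   for ch in record.ovg]), axis=0)
    t = np.arange(mag.size) / fs
    npts = 200
    beats = []
    for c in cycles:
        tt = np.linspace(c.onset - 0.30, c.onset + 0.45, npts)
        if tt[0] < 0 or tt[-1] >= t[-1]:
            continue
        beats.append(np.interp(tt, t, mag))
    if len(beats) < 3:
        return np.nan
    beats = np.asarray(beats)
    template = np.median(beats, axis=0)
    denom = np.sqrt(np.mean(template ** 2))
    resid = np.sqrt(np.mean((beats - template) ** 2, axis=1))
    return float(np.mean(resid) / max(denom, 1e-12))


def extract_features(record: AcquisitionRecord,
                     cycles: list[CycleAnnotation] | None = None,
                     config: FeatureConfig | None = None) -> dict:
    """All named features for one record (deterministic given the record)."""
    cfg = config or FeatureConfig()
    if cycles is None:
        cycles = segment_cycles(record, cfg)
    durations = np.array([c.atrial_duration_ms for c in cycles])
    onsets = np.array([c.onset for c in cycles])
    rr = np.diff(onsets)
    feats = {
        "time_domain.atrial_duration_mean": float(durations.mean()),
        "time_domain.atrial_duration_sd": atrial_duration_variation(cycles),
        "time_domain.rr_mean": float(rr.mean()),
        "time_domain.rr_sd": float(np.std(rr, ddof=1)) if rr.size > 1 else 0.0,
        "time_domain.template_residual_rms": _template_residual_rms(record, cycles, cfg),
    }
    traj = phase_space_embed(record)
    feats.update(phase_space_features(traj, cycles, record.ovg_rate, cfg))
    feats.update(ppg_indicators(record, cycles))
    feats.update(spectral_and_sync_features(record, cycles, cfg))
    return feats


def featurize_cohort(records, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature table (subjects x named features), indexed by subject_id."""
    rows, index = [], []
    for rec in records:
        rows.append(extract_features(rec, config=config))
        index.append(rec.subject_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
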