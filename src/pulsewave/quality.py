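"""Signal-quality gates applied before feature extraction.

Three acceptance checks emulate the device's pre-processing gate:
powerline SNR (signal band vs the 60 Hz mains band), high-frequency SNR
(signal band vs everything above 150 Hz), and PPG sensor saturation
(fraction of optical samples pinned at the ceiling — a fraction, not an
SNR, because saturation is transient).  SNRs are dB band-power ratios
from a Welch periodogram (4 s Hann segments, 50% overlap); the printed
acceptance thresholds of 57 (powerline) and 19 (high-frequency) carry
no units in the source material and are interpreted as dB here — both
are config-overridable, as are the band edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import UndefinedSnrError
from .synthetic import AcquisitionRecord

__all__ = [
    "QualityConfig", "QualityReport",
    "powerline_snr", "highfreq_snr", "ppg_saturation",
    "evaluate_quality", "qc_cohort",
]


@dataclass
class QualityConfig:
    signal_band: tuple = (0.5, 40.0)        # Hz, physiological OVG content
    powerline_band: tuple = (59.5, 60.5)    # Hz
    highfreq_cutoff: float = 150.0          # Hz; noise band = cutoff..Nyquist
    powerline_threshold_db: float = 57.0
    highfreq_threshold_db: float = 19.0
    saturation_tolerance: float = 0.05      # max acceptable clipped fraction
    ppg_ceiling: float = 4096.0             # sensor ceiling, optical units
    welch_segment_s: float = 4.0
    channel_aggregate: str = "mean"         # "mean" | "worst"


@dataclass
class QualityReport:
    subject_id: str
    powerline_snr: float       # dB
    highfreq_snr: float        # dB
    saturation_fraction: float
    pass_powerline: bool
    pass_highfreq: bool
    pass_saturation: bool

    @property
    def overall_pass(self) -> bool:
        return self.pass_powerline and self.pass_highfreq and self.pass_saturation


def _band_powers(x: np.ndarray, fs: float, bands, segment_s: float):
    nper = min(int(segment_s * fs), x.size)
    f, p = sps.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2)
    df = f[1] - f[0]
    return [float(np.sum(p[(f >= lo) & (f <= hi)]) * df) for lo, hi in bands]


def _snr_db(record: AcquisitionRecord, noise_band, config: QualityConfig) -> float:
    if record.ovg.shape[1] < 10 * record.ovg_rate:
        raise UndefinedSnrError("need at least 10 s of OVG signal")
    vals = []
    for k in range(record.ovg.shape[0]):
        p_sig, p_noise = _band_powers(
            record.ovg[k], record.ovg_rate,
            [config.signal_band, noise_band], config.welch_segment_s)
        if p_sig <= 0.0:
            raise UndefinedSnrError("no signal-band power (all-zero channel?)")
        vals.append(np.inf if p_noise <= 0.0 else 10.0 * np.log10(p_sig / p_noise))
    return float(min(vals) if config.channel_aggregate == "worst" else np.mean(vals))


def powerline_snr(record: AcquisitionRecord,
                  config: QualityConfig | None = None) -> float:
    """dB ratio of signal-band to 60 Hz band power; larger = cleaner."""
    config = config or QualityConfig()
    return _snr_db(record, config.powerline_band, config)


def highfreq_snr(record: AcquisitionRecord,
                 config: QualityConfig | None = None) -> float:
    """dB ratio of signal-band to >150 Hz power; larger = cleaner."""
    config = config or QualityConfig()
    nyq = record.ovg_rate / 2.0
    return _snr_db(record, (config.highfreq_cutoff, nyq), config)


def ppg_saturation(record: AcquisitionRecord,
                   config: QualityConfig | None = None) -> tuple[float, bool]:
    """(fraction of PPG samples at/above the ceiling, pass flag)."""
    config = config or QualityConfig()
    if record.ppg.size == 0:
        raise UndefinedSnrError("empty PPG signal")
    frac = float(np.mean(record.ppg >= config.ppg_ceiling))
    return frac, frac <= config.saturation_tolerance


def evaluate_quality(record: AcquisitionRecord,
                     config: QualityConfig | None = None) -> QualityReport:
    config = config or QualityConfig()
    pl = powerline_snr(record, config)
    hf = highfreq_snr(record, config)
    sat, sat_ok = ppg_saturation(record, config)
    return QualityReport(
        subject_id=record.subject_id,
        powerline_snr=pl,
        highfreq_snr=hf,
        saturation_fraction=sat,
        pass_powerline=pl >= config.powerline_threshold_db,
        pass_highfreq=hf >= config.highfreq_threshold_db,
        pass_saturation=sat_ok,
    )


def qc_cohort(records, config: QualityConfig | None = None) -> pd.DataFrame:
    """One QualityReport row per record."""
    rows = []
    for rec in records:
        rep = evaluate_quality(rec, config)
        rows.append({
            "subject_id": rep.subject_id,
            "powerline_snr": rep.powerline_snr,
            "highfreq_snr": rep.highfreq_snr,
            "saturation_fraction": rep.saturation_fraction,
            "pass_powerline": rep.pass_powerline,
            "pass_highfreq": rep.pass_highfreq,
            "pass_saturation": rep.pass_saturation,
            "overall_pass": rep.overall_pass,
        })
    return pd.DataFrame(rows)
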