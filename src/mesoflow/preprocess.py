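"""Spectral MUA estimation and trial preprocessing.

Multiunit activity (MUA) is estimated from the raw broadband signal as
band-averaged normalized spectral power: short-time Fourier power spectra
P(w, t) in 5-ms sliding windows are normalized by their time average over a
long reference window, and the relative spectra R(w, t) = P(w, t)/P_ref(w)
are averaged across the 0.2-1.5 kHz band.  Because the stereotyped spike
waveform cancels in the ratio and high-frequency power is proportional to
the local firing rate, the result tracks the aggregate spiking of the
population near the electrode without spike detection, and the ratio
normalization removes slow gain trends (no further detrending is applied).
Log-scaled MUA is then smoothed by a 40-ms moving average evaluated every
5 ms and interpolated onto a 1-ms grid.

Trial-level utilities implement the outlier-exclusion rule (a trial is
dropped when a nonphysiological peak exceeds mean + 2 SD simultaneously on
more than 80% of channels in any time bin) and the extraction of the 400-ms
analysis epoch: up to movement onset in trials with a generated movement,
and up to stop signal + SSRT in correctly inhibited trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

logger = logging.getLogger("mesoflow.preprocess")

__all__ = [
    "RawRecording",
    "TrialTensor",
    "MUASeries",
    "estimate_mua",
    "smooth_log_mua",
    "exclude_outlier_trials",
    "extract_epoch",
]


@dataclass
class RawRecording:
    """Multichannel raw broadband signal."""

    signal: np.ndarray          # channels x samples
    fs: float = 24400.0
    t0: float = 0.0
    channel_ids: list | None = None

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("raw signal contains non-finite values")
        if self.fs <= 2 * 1500.0:
            raise ValueError("sampling rate must exceed twice the 1.5 kHz band edge")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.signal.shape[0]))


@dataclass
class MUASeries:
    """Band-averaged relative-power MUA per channel on a regular grid."""

    values: np.ndarray          # channels x time
    dt_ms: float
    t0_ms: float = 0.0

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.values.shape[1]) * self.dt_ms


@dataclass
class TrialTensor:
    """channels x time x trials MUA tensor at 1-ms resolution."""

    mua: np.ndarray
    dt_ms: float = 1.0
    time_ms: np.ndarray | None = None
    trial_ids: np.ndarray | None = None
    condition: str = ""
    alignment: str = ""

    def __post_init__(self):
        self.mua = np.asarray(self.mua, dtype=float)
        if self.mua.ndim != 3:
            raise ValueError("trial tensor must be channels x time x trials")
        if not np.all(np.isfinite(self.mua)):
            raise ValueError("trial tensor contains non-finite values")
        if self.time_ms is None:
            self.time_ms = np.arange(self.mua.shape[1]) * self.dt_ms
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.mua.shape[2])
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)

    @property
    def n_channels(self) -> int:
        return self.mua.shape[0]

    @property
    def n_trials(self) -> int:
        return self.mua.shape[2]

    def trial(self, k: int) -> np.ndarray:
        return self.mua[:, :, k]

    def subset(self, mask: np.ndarray) -> "TrialTensor":
        mask = np.asarray(mask, dtype=bool)
        return TrialTensor(
            mua=self.mua[:, :, mask], dt_ms=self.dt_ms, time_ms=self.time_ms,
            trial_ids=self.trial_ids[mask], condition=self.condition,
            alignment=self.alignment,
        )


def estimate_mua(
    raw: RawRecording,
    window_ms: float = 5.0,
    band_hz: tuple[float, float] = (200.0, 1500.0),
    ref_window_s: float = 1800.0,
    hop_ms: float = 1.0,
) -> MUASeries:
    """Band-averaged relative spectral power per channel.

    Short-time Fourier power in Hann-tapered ``window_ms`` windows hopped
    every ``hop_ms``; the reference spectrum P_ref(w) is the time average
    over the first ``ref_window_s`` seconds (the whole recording when
    shorter, the adopted reading of a fixed 30-minute reference window);
    MUA(t) is the mean of P(w, t)/P_ref(w) over the 0.2-1.5 kHz band.
    The ratio makes the estimate invariant to per-channel gain.
    """
    fs = raw.fs
    if band_hz[0] >= band_hz[1] or band_hz[1] > fs / 2:
        raise ValueError("band must be increasing and within Nyquist")
    nperseg = int(round(window_ms * 1e-3 * fs))
    hop = max(1, int(round(hop_ms * 1e-3 * fs)))
    if raw.signal.shape[1] < nperseg:
        raise ValueError("recording shorter than the analysis window")
    stft = ShortTimeFFT(hann(nperseg, sym=False), hop=hop, fs=fs,
                        scale_to="psd")
    freqs = stft.f
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not band.any():
        raise ValueError("no STFT frequency falls inside the band")

    out = []
    for c in range(raw.signal.shape[0]):
        # p1=... restricts to windows fully inside the signal (no padding bias)
        spec = stft.spectrogram(raw.signal[c], p0=0,
                                p1=stft.p_max(raw.signal.shape[1]))
        spec = spec[band]
        t_centers = stft.t(raw.signal.shape[1], p0=0,
                           p1=stft.p_max(raw.signal.shape[1]))
        ref_mask = t_centers <= ref_window_s
        if not ref_mask.any():
            ref_mask[:] = True
        p_ref = spec[:, ref_mask].mean(axis=1)
        if np.any(p_ref <= 0):
            raise ValueError("zero reference power inside the band")
        out.append((spec / p_ref[:, None]).mean(axis=0))
    values = np.asarray(out)
    dt_ms = hop / fs * 1e3
    return MUASeries(values=values, dt_ms=dt_ms,
                     t0_ms=float(t_centers[0] * 1e3) + raw.t0 * 1e3)


def smooth_log_mua(
    mua: MUASeries,
    avg_window_ms: float = 40.0,
    step_ms: float = 5.0,
    out_dt_ms: float = 1.0,
) -> MUASeries:
    """Log-scale, moving-average and resample the MUA.

    The logarithm of the (positive) MUA is averaged in ``avg_window_ms``
    windows evaluated every ``step_ms`` and the coarse series is linearly
    interpolated onto a ``out_dt_ms`` grid — the adopted reading of a 40-ms
    / 5-ms moving average yielding a continuous 1-ms series.
    """
    v = mua.values
    if np.any(v <= 0):
        raise ValueError("MUA must be positive for log scaling")
    logv = np.log(v)
    n = logv.shape[1]
    half = avg_window_ms / 2.0
    t = mua.times_ms
    centers = np.arange(t[0] + half, t[-1] - half + 1e-9, step_ms)
    if len(centers) < 2:
        raise ValueError("series shorter than the smoothing window")
    coarse = np.empty((logv.shape[0], len(centers)))
    for k, c in enumerate(centers):
        m = (t >= c - half) & (t < c + half)
        coarse[:, k] = logv[:, m].mean(axis=1)
    t_out = np.arange(centers[0], centers[-1] + 1e-9, out_dt_ms)
    fine = np.empty((logv.shape[0], len(t_out)))
    for ch in range(logv.shape[0]):
        fine[ch] = np.interp(t_out, centers, coarse[ch])
    return MUASeries(values=fine, dt_ms=out_dt_ms, t0_ms=float(t_out[0]))


def exclude_outlier_trials(
    tensor: TrialTensor,
    sd_mult: float = 2.0,
    channel_frac: float = 0.8,
) -> tuple[np.ndarray, dict]:
    """Mask of trials free of nonphysiological simultaneous peaks.

    A trial is excluded iff in at least one time bin its MUA exceeds the
    per-channel mean + ``sd_mult`` SD (mean and SD across all trials and
    time bins of this tensor, i.e. within condition and epoch) on strictly
    more than ``channel_frac`` of the channels.  With SD = 0 the threshold
    equals the mean and the strict exceedance never fires.
    """
    if tensor.n_trials < 2:
        raise ValueError("outlier detection requires at least 2 trials")
    x = tensor.mua
    mean_c = x.mean(axis=(1, 2), keepdims=True)
    sd_c = x.std(axis=(1, 2), keepdims=True)
    above = x > mean_c + sd_mult * sd_c          # channels x time x trials
    frac_above = above.mean(axis=0)              # time x trials
    bad = (frac_above > channel_frac).any(axis=0)
    keep = ~bad
    report = {
        "n_trials": int(tensor.n_trials),
        "n_excluded": int(bad.sum()),
        "excluded_trial_ids": [int(i) for i in np.asarray(tensor.trial_ids)[bad]],
        "sd_mult": sd_mult,
        "channel_frac": channel_frac,
    }
    if report["n_excluded"]:
        logger.info("excluded %d/%d outlier trial(s)",
                    report["n_excluded"], report["n_trials"])
    return keep, report


def extract_epoch(
    tensor: TrialTensor,
    events: pd.DataFrame,
    ssrt_ms: float,
    epoch_ms: int = 400,
) -> dict[str, TrialTensor]:
    """Per-condition 400-ms analysis epochs (half-open, 1-ms bins).

    ``events`` must carry one row per trial of the tensor with columns
    ``condition`` in {go, correct_stop, wrong_stop} and the alignment times
    (ms on the tensor's time axis): ``movement_onset_ms`` for trials with a
    generated movement and ``stop_signal_ms`` for correct Stops.  Windows:

    * go / wrong_stop:  [movement_onset - epoch, movement_onset)
    * correct_stop:     [stop_signal + SSRT - epoch, stop_signal + SSRT)

    Trials whose window exceeds the recorded extent are dropped with a
    warning.
    """
    if len(events) != tensor.n_trials:
        raise ValueError("one event row per trial is required")
    if abs(tensor.dt_ms - 1.0) > 1e-9:
        raise ValueError("epoch extraction expects a 1-ms time base")
    t0 = float(tensor.time_ms[0])
    n_time = tensor.mua.shape[1]
    out: dict[str, list] = {}
    ids: dict[str, list] = {}
    dropped = 0
    for k, (_, row) in enumerate(events.iterrows()):
        cond = row["condition"]
        if cond in ("go", "wrong_stop"):
            end = float(row["movement_onset_ms"])
        elif cond == "correct_stop":
            end = float(row["stop_signal_ms"]) + ssrt_ms
        else:
            raise ValueError(f"unknown condition {cond!r}")
        i_end = int(round(end - t0))
        i_start = i_end - epoch_ms
        if i_start < 0 or i_end > n_time:
            dropped += 1
            continue
        out.setdefault(cond, []).append(tensor.mua[:, i_start:i_end, k])
        ids.setdefault(cond, []).append(tensor.trial_ids[k])
    if dropped:
        logger.warning("dropped %d trial(s) with windows outside the recording",
                       dropped)
    return {
        cond: TrialTensor(
            mua=np.stack(trials, axis=2), dt_ms=1.0,
            time_ms=np.arange(epoch_ms, dtype=float),
            trial_ids=np.asarray(ids[cond]), condition=cond,
            alignment="movement_onset" if cond != "correct_stop" else "stop+ssrt",
        )
        for cond, trials in out.items()
    }
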