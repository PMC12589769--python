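"""Preprocessing of multichannel extracellular recordings.

The stage turns a raw voltage matrix into the amplitude-modulated (AM) spike
train that feeds the graph forecaster:

1. zero-phase Butterworth band-pass filtering (200-3000 Hz passband, >=60 dB
   stopband attenuation);
2. robust per-channel spike thresholding from 50-ms window standard
   deviations (threshold = 4.5 x ref-value, with a progressive relaxation of
   the factor when a channel is silent);
3. Kaiser (beta = 10) amplitude modulation of a ~20-ms multichannel block
   centred on every detected spike, cropped to the central 18 ms (225 samples
   at 12.5 kHz);
4. chronological concatenation of AM-spike segments and sliding-window
   segmentation into (input, target) forecasting pairs (window T = 56).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError, NoDetectableActivityError

logger = logging.getLogger(__name__)

SESSIONS = ("0h", "30min", "24h", "48h")
CONDITIONS = ("CTRL", "VPA")

#: Passband and stop edges of the spike-band filter (Hz).
DEFAULT_LOW_HZ = 200.0
DEFAULT_HIGH_HZ = 3000.0
DEFAULT_STOP_LOW_HZ = 100.0
DEFAULT_STOP_HIGH_HZ = 4000.0
DEFAULT_STOP_ATTEN_DB = 60.0
DEFAULT_PASS_RIPPLE_DB = 1.0

#: AM-spike timing constants (seconds).
BLOCK_S = 0.020   # Kaiser-modulated multichannel block around a spike
CROP_S = 0.018    # central portion retained as the AM-spike segment
KAISER_BETA = 10.0

#: Forecasting window length (samples); 4.5 ms at 12.5 kHz.
DEFAULT_T = 56


@dataclass
class Recording:
    """A multichannel voltage recording with well metadata.

    voltage is a channels x samples float array in microvolts.
    """

    voltage: np.ndarray
    fs: float
    well_id: str = "W0"
    session: str = "0h"
    condition: str = "CTRL"

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        if self.voltage.ndim != 2:
            raise DataError("voltage must be a channels x samples matrix")
        if not self.fs > 0:
            raise DataError("sampling rate must be positive")
        if self.session not in SESSIONS:
            raise ConfigError(f"unknown session {self.session!r}; expected one of {SESSIONS}")
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    # ---- I/O ------------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("voltage", data=self.voltage.astype(np.float32))
            ds.attrs["units"] = "uV"
            f.attrs["fs"] = float(self.fs)
            f.attrs["well_id"] = self.well_id
            f.attrs["session"] = self.session
            f.attrs["condition"] = self.condition

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                voltage=f["voltage"][...].astype(np.float64),
                fs=float(f.attrs["fs"]),
                well_id=str(f.attrs["well_id"]),
                session=str(f.attrs["session"]),
                condition=str(f.attrs["condition"]),
            )

    @classmethod
    def from_text(cls, path, well_id="W0", session="0h", condition="CTRL") -> "Recording":
        """Read a delimited-text recording: header line ``fs=<Hz>``, then one
        column per channel."""
        with open(path) as f:
            header = f.readline().strip()
        if not header.startswith("fs="):
            raise DataError("text recording must start with an 'fs=<Hz>' header line")
        fs = float(header.split("=", 1)[1])
        data = np.loadtxt(path, skiprows=1)
        if data.ndim == 1:
            data = data[:, None]
        return cls(voltage=data.T, fs=fs, well_id=well_id,
                   session=session, condition=condition)


@dataclass
class NoiseThreshold:
    """Robust spike threshold for one channel.

    md_sd is the median of 50-ms window SDs (the noise level); ref_value is
    the mean of the SDs exceeding it (attributed to signal); th_spike is
    factor x ref_value.
    """

    window_ms: float
    md_sd: float
    ref_value: float
    factor: float
    th_spike: float


@dataclass(order=True)
class SpikeEvent:
    sample: int
    channel: int
    amplitude: float = field(compare=False)

    @property
    def polarity(self) -> int:
        return 1 if self.amplitude >= 0 else -1

    def time_s(self, fs: float) -> float:
        return self.sample / fs


@dataclass
class AMSpikeTrain:
    """Chronological concatenation of Kaiser-modulated multichannel segments.

    data is channels x (n_segments * L); segment i occupies columns
    [boundaries[i], boundaries[i] + L). event_offset is the within-segment
    column index of the triggering spike sample.
    """

    data: np.ndarray
    segment_boundaries: np.ndarray
    events: list
    fs: float
    segment_length: int
    event_offset: int
    well_id: str = "W0"
    session: str = "0h"
    condition: str = "CTRL"
    n_dropped_edge_events: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segment_boundaries)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def segment(self, i: int) -> np.ndarray:
        b = self.segment_boundaries[i]
        return self.data[:, b:b + self.segment_length]


@dataclass
class WindowBatch:
    """Sliding-window forecasting pairs extracted from an AM-spike train.

    X has shape (n_targets, channels, T), y has shape (n_targets, channels).
    time_index is the 1-based within-segment target position (1..L-T), i.e.
    the "graph time point" used for feature selection.
    """

    X: np.ndarray
    y: np.ndarray
    time_index: np.ndarray
    segment_id: np.ndarray
    T: int

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "WindowBatch":
        return WindowBatch(self.X[idx], self.y[idx], self.time_index[idx],
                           self.segment_id[idx], self.T)


# ---------------------------------------------------------------------------
# step 1: band-pass filtering


def design_bandpass(fs: float,
                    low_hz: float = DEFAULT_LOW_HZ,
                    high_hz: float = DEFAULT_HIGH_HZ,
                    stop_low_hz: float = DEFAULT_STOP_LOW_HZ,
                    stop_high_hz: float = DEFAULT_STOP_HIGH_HZ,
                    stop_atten_db: float = DEFAULT_STOP_ATTEN_DB,
                    pass_ripple_db: float = DEFAULT_PASS_RIPPLE_DB) -> np.ndarray:
    """Design the minimal-order Butterworth band-pass meeting the stopband
    attenuation at the stop edges, as second-order sections.

    The filter is applied forward-backward (zero phase), which doubles the
    effective attenuation; the design itself uses the single-pass spec.
    """
    if fs <= 2 * high_hz:
        raise ConfigError(
            f"sampling rate {fs} Hz must exceed twice the upper passband edge {high_hz} Hz")
    order, wn = sps.buttord([low_hz, high_hz], [stop_low_hz, stop_high_hz],
                            gpass=pass_ripple_db, gstop=stop_atten_db, fs=fs)
    return sps.butter(order, wn, btype="bandpass", output="sos", fs=fs)


def bandpass_filter(rec: Recording, low_hz: float = DEFAULT_LOW_HZ,
                    high_hz: float = DEFAULT_HIGH_HZ,
                    stop_atten_db: float = DEFAULT_STOP_ATTEN_DB) -> Recording:
    """Zero-phase band-pass filter every channel of a recording."""
    if not np.all(np.isfinite(rec.voltage)):
        raise DataError("recording contains non-finite samples")
    sos = design_bandpass(rec.fs, low_hz=low_hz, high_hz=high_hz,
                          stop_atten_db=stop_atten_db)
    filtered = sps.sosfiltfilt(sos, rec.voltage, axis=1)
    return replace(rec, voltage=np.ascontiguousarray(filtered))


# ---------------------------------------------------------------------------
# step 2: threshold estimation and spike detection


def estimate_threshold(channel_signal: np.ndarray, fs: float,
                       window_ms: float = 50.0,
                       factor: float = 4.5,
                       factor_decrement: float = 0.9,
                       factor_floor: float = 1.0) -> NoiseThreshold:
    """Estimate the per-channel spike threshold from window SD statistics.

    The signal is split into non-overlapping windows; the median of the
    window SDs (MD_SD) estimates the noise level, and the mean of the SDs
    strictly exceeding the median is the ref-value. th_spike = factor x
    ref-value, with the factor multiplied by ``factor_decrement`` until at
    least one sample crosses the threshold; below ``factor_floor`` the
    channel is declared silent.

    If no window SD strictly exceeds the median (stationary noise), the
    ref-value falls back to MD_SD itself.
    """
    x = np.asarray(channel_signal, dtype=np.float64)
    win = int(round(window_ms * 1e-3 * fs))
    if win < 1 or x.size < 2 * win:
        raise DataError("signal shorter than two threshold-estimation windows")
    n_win = x.size // win
    sds = x[: n_win * win].reshape(n_win, win).std(axis=1)
    md_sd = float(np.median(sds))
    above = sds[sds > md_sd]
    ref_value = float(above.mean()) if above.size else md_sd

    abs_max = float(np.max(np.abs(x))) if x.size else 0.0
    f = factor
    while f >= factor_floor:
        th = f * ref_value
        if th > 0 and abs_max > th:
            return NoiseThreshold(window_ms=window_ms, md_sd=md_sd,
                                  ref_value=ref_value, factor=f, th_spike=th)
        f *= factor_decrement
    raise NoDetectableActivityError(
        "no detectable activity: threshold factor reached its floor without a crossing")


def detect_spikes(rec: Recording, thresholds: list,
                  refractory_ms: float = 1.0) -> list:
    """Detect spikes as contiguous supra-threshold runs of |signal|.

    One event per run, located at the sample of maximum absolute amplitude;
    same-channel events closer than the refractory gap are merged keeping the
    larger amplitude. Events are returned sorted by time, then channel.
    """
    if len(thresholds) != rec.n_channels:
        raise DataError("one threshold per channel is required")
    refractory = int(round(refractory_ms * 1e-3 * rec.fs))
    events: list[SpikeEvent] = []
    for ch in range(rec.n_channels):
        th = thresholds[ch]
        if th is None:
            continue
        x = rec.voltage[ch]
        mask = np.abs(x) > th.th_spike
        if not mask.any():
            continue
        edges = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            ends = np.r_[ends, mask.size]
        ch_events: list[SpikeEvent] = []
        for s, e in zip(starts, ends):
            seg = np.abs(x[s:e])
            peak = s + int(np.argmax(seg))
            ev = SpikeEvent(sample=peak, channel=ch, amplitude=float(x[peak]))
            if ch_events and ev.sample - ch_events[-1].sample < refractory:
                if abs(ev.amplitude) > abs(ch_events[-1].amplitude):
                    ch_events[-1] = ev
            else:
                ch_events.append(ev)
        events.extend(ch_events)
    events.sort(key=lambda e: (e.sample, e.channel))
    return events


def estimate_thresholds(rec: Recording, window_ms: float = 50.0,
                        factor: float = 4.5) -> list:
    """Per-channel thresholds; silent channels yield ``None`` (and a log entry)."""
    out = []
    for ch in range(rec.n_channels):
        try:
            out.append(estimate_threshold(rec.voltage[ch], rec.fs,
                                          window_ms=window_ms, factor=factor))
        except NoDetectableActivityError:
            logger.warning("channel %d: no detectable activity, skipped", ch)
            out.append(None)
    if all(t is None for t in out):
        raise NoDetectableActivityError("no channel has detectable activity")
    return out


# ---------------------------------------------------------------------------
# steps 3-4: Kaiser amplitude modulation and concatenation


def _kaiser_centered(length: int, beta: float) -> tuple[np.ndarray, int]:
    """Kaiser window of the given length whose peak sample equals exactly 1 at
    index length // 2 (the event-centred sample)."""
    center = length // 2
    if length % 2 == 1:
        return np.kaiser(length, beta), center
    # even length: take the first `length` samples of the odd symmetric window
    return np.kaiser(length + 1, beta)[:length], center


def build_am_spike_train(rec: Recording, events: list,
                         block_s: float = BLOCK_S, crop_s: float = CROP_S,
                         beta: float = KAISER_BETA) -> AMSpikeTrain:
    """Build the AM-spike train: per event, modulate the event-centred
    multichannel block by a Kaiser window and keep the central crop.

    Each event produces one segment from its own extracted copy of the
    signal; overlapping events never mutate each other's samples. Events
    whose block does not fit inside the recording are dropped and counted.
    """
    K = int(round(block_s * rec.fs))
    L = int(round(crop_s * rec.fs))
    if L > K:
        raise ConfigError("crop duration exceeds the modulation block")
    window, center = _kaiser_centered(K, beta)
    crop_start = (K - L) // 2
    event_offset = center - crop_start

    events = sorted(events, key=lambda e: (e.sample, e.channel))
    segments = []
    kept = []
    dropped = 0
    for ev in events:
        start = ev.sample - center
        if start < 0 or start + K > rec.n_samples:
            dropped += 1
            continue
        block = rec.voltage[:, start:start + K] * window[None, :]
        segments.append(block[:, crop_start:crop_start + L])
        kept.append(ev)
    if dropped:
        logger.info("dropped %d edge events whose %d-sample block did not fit", dropped, K)
    if segments:
        data = np.concatenate(segments, axis=1)
    else:
        data = np.empty((rec.n_channels, 0))
    boundaries = np.arange(len(segments)) * L
    return AMSpikeTrain(data=data, segment_boundaries=boundaries, events=kept,
                        fs=rec.fs, segment_length=L, event_offset=event_offset,
                        well_id=rec.well_id, session=rec.session,
                        condition=rec.condition, n_dropped_edge_events=dropped)


def segment_windows(train: AMSpikeTrain, T: int = DEFAULT_T, step: int = 1) -> WindowBatch:
    """Cut every AM-spike segment into overlapping (input, target) pairs.

    Targets sit at within-segment offsets T..L-1 (L - T per segment; 169 for
    L = 225, T = 56); windows never straddle a segment boundary. The recorded
    time_index is 1-based (1..L-T), the "graph time point" of the target.
    """
    L = train.segment_length
    if L <= T:
        raise ConfigError(f"segment length {L} must exceed the window T={T}")
    n_seg = train.n_segments
    offsets = np.arange(T, L, step)
    n_per_seg = offsets.size
    C = train.n_channels
    X = np.empty((n_seg * n_per_seg, C, T))
    y = np.empty((n_seg * n_per_seg, C))
    time_index = np.empty(n_seg * n_per_seg, dtype=np.int64)
    segment_id = np.empty(n_seg * n_per_seg, dtype=np.int64)
    k = 0
    for i in range(n_seg):
        b = train.segment_boundaries[i]
        seg = train.data[:, b:b + L]
        for off in offsets:
            X[k] = seg[:, off - T:off]
            y[k] = seg[:, off]
            time_index[k] = off - T + 1
            segment_id[k] = i
            k += 1
    return WindowBatch(X=X, y=y, time_index=time_index, segment_id=segment_id, T=T)


def split_events_by_half(events: list, n_samples: int) -> tuple[list, list]:
    """Split events at the recording midpoint: first half for training the
    forecaster, second half for testing."""
    mid = n_samples // 2
    train = [e for e in events if e.sample < mid]
    test = [e for e in events if e.sample >= mid]
    return train, test


def events_to_table(events: list, fs: float):
    """Event list as a pandas table (channel, sample, time_s, amplitude)."""
    import pandas as pd

    return pd.DataFrame({
        "channel": [e.channel for e in events],
        "sample": [e.sample for e in events],
        "time_s": [e.sample / fs for e in events],
        "amplitude": [e.amplitude for e in events],
    })
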