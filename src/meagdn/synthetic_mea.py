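"""Synthetic multi-electrode-array recordings with known ground truth.

The generator emulates the statistics of extracellular MEA recordings from a
neural culture: band-limited Gaussian background noise, transient biphasic
spikes of both polarities inserted at Poisson times, and delayed
inter-channel spike coupling governed by a ground-truth directed probability
matrix. A "treated" condition multiplies both the coupling probabilities and
the spontaneous firing rate by a treatment factor in [0, 1], emulating a
pharmacological suppression of synaptic transmission and firing.

Every recording comes with its ground-truth spike times so detector recall,
graph recovery and classification can all be scored against a known answer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .preprocessing import Recording

logger = logging.getLogger(__name__)

#: Spike template support (seconds); two lobes of opposite sign.
TEMPLATE_S = 0.0016

#: Session labels in chronological order; treatment acts only after "0h".
DEFAULT_SESSIONS = ("0h", "30min", "24h", "48h")

#: SD of the log-normal per-well firing-rate factor (inter-well heterogeneity).
WELL_RATE_SIGMA = 0.2


@dataclass
class GroundTruthNetwork:
    """Directed coupling between channels.

    coupling[i, j] is the probability that a spontaneous spike on source
    channel i triggers a delayed spike on target channel j. delay_ms /
    delay_jitter_ms give the mean and SD of the transmission delay.
    """

    coupling: np.ndarray
    delay_ms: float = 2.0
    delay_jitter_ms: float = 0.3

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=np.float64)
        n = self.coupling.shape[0]
        if self.coupling.shape != (n, n):
            raise ConfigError("coupling must be square")
        if np.any(np.diag(self.coupling) != 0):
            raise ConfigError("coupling diagonal must be zero (no self-coupling)")
        if np.any((self.coupling < 0) | (self.coupling > 1)):
            raise ConfigError("coupling entries must lie in [0, 1]")
        if np.any(self.coupling > 0) and not self.delay_ms > 0:
            raise ConfigError("transmission delay must be positive where coupling exists")

    @property
    def n_channels(self) -> int:
        return self.coupling.shape[0]

    @classmethod
    def empty(cls, n_channels: int) -> "GroundTruthNetwork":
        return cls(coupling=np.zeros((n_channels, n_channels)))

    @classmethod
    def random(cls, n_channels: int, n_edges: int, strength: float,
               seed: int, delay_ms: float = 2.0,
               delay_jitter_ms: float = 0.3) -> "GroundTruthNetwork":
        """Uniformly sample ``n_edges`` distinct off-diagonal edges of the
        given strength."""
        rng = np.random.default_rng(seed)
        pairs = [(i, j) for i in range(n_channels) for j in range(n_channels) if i != j]
        idx = rng.choice(len(pairs), size=n_edges, replace=False)
        coupling = np.zeros((n_channels, n_channels))
        for k in idx:
            i, j = pairs[k]
            coupling[i, j] = strength
        return cls(coupling=coupling, delay_ms=delay_ms,
                   delay_jitter_ms=delay_jitter_ms)


@dataclass
class SimulationScenario:
    """Generative conditions of a synthetic MEA study.

    Defaults mirror the acquisition geometry of the emulated platform: 16
    electrodes at 12.5 kHz for 5 minutes, with per-channel multi-unit firing
    rates that yield spike-segment counts on the order of 1e5 per recording.
    """

    n_channels: int = 16
    fs: float = 12500.0
    duration_s: float = 300.0
    base_rate_hz: float = 25.0
    spike_amplitude_uv: float = 60.0
    polarity_mix: float = 0.5
    noise_sd_uv: float = 5.0
    network: GroundTruthNetwork | None = None
    treatment_factor: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fs", "duration_s", "base_rate_hz", "spike_amplitude_uv",
                     "polarity_mix", "noise_sd_uv", "treatment_factor"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ConfigError(f"{name} must be finite")
        if self.base_rate_hz < 0:
            raise ConfigError("firing rate must be non-negative")
        if not 0.0 <= self.treatment_factor <= 1.0:
            raise ConfigError("treatment_factor must lie in [0, 1]")
        if self.duration_s * self.fs < round(TEMPLATE_S * self.fs) + 1:
            raise ConfigError("duration too short to contain one spike template")
        # the biphasic template's energy sits well below 3 kHz; require the
        # band-pass design to be realizable
        if self.fs <= 2 * 3000.0:
            raise ConfigError("sampling rate must exceed twice the spike band top (3 kHz)")
        if self.network is None:
            self.network = GroundTruthNetwork.empty(self.n_channels)
        if self.network.n_channels != self.n_channels:
            raise ConfigError("network size does not match n_channels")


@dataclass
class GroundTruth:
    """Per-channel ground-truth spike times (s) and the effective coupling."""

    spike_times: list
    coupling: np.ndarray
    spontaneous_counts: np.ndarray = field(default=None)

    @property
    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_times))

    def to_json(self, path) -> None:
        payload = {
            "spike_times_s": [list(map(float, t)) for t in self.spike_times],
            "coupling": self.coupling.tolist(),
        }
        with open(path, "w") as f:
            json.dump(payload, f)


def spike_template(fs: float, duration_s: float = TEMPLATE_S) -> np.ndarray:
    """Biphasic difference-of-Gaussians spike template, unit peak amplitude.

    The dominant (first) lobe is positive; channel polarity flips the sign.
    """
    n = int(round(duration_s * fs))
    t = (np.arange(n) - n / 2) / fs
    s1 = duration_s / 9.0
    s2 = duration_s / 6.0
    shift = duration_s / 7.0
    w = np.exp(-0.5 * ((t + shift / 2) / s1) ** 2) - 0.8 * np.exp(
        -0.5 * ((t - shift / 2) / s2) ** 2)
    w /= np.max(np.abs(w))
    if abs(w.min()) > w.max():  # ensure the dominant lobe is positive
        w = -w
    return w


def _band_limited_noise(rng: np.random.Generator, n_channels: int,
                        n_samples: int, sd_uv: float, fs: float) -> np.ndarray:
    """White Gaussian noise band-passed to the spike band and rescaled so the
    per-channel SD equals ``sd_uv``."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = sps.butter(4, [200.0, 3000.0], btype="bandpass", output="sos", fs=fs)
    shaped = sps.sosfiltfilt(sos, white, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd * sd_uv


def channel_polarities(n_channels: int, polarity_mix: float) -> np.ndarray:
    """+1 for positive-going channels, -1 otherwise (first fraction positive)."""
    n_pos = int(round(polarity_mix * n_channels))
    pol = np.full(n_channels, -1, dtype=np.int64)
    pol[:n_pos] = 1
    return pol


def simulate_recording(scenario: SimulationScenario, well_id: str = "W0",
                       session: str = "0h", condition: str = "CTRL",
                       rate_factor: float = 1.0,
                       apply_treatment: bool | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[Recording, GroundTruth]:
    """Simulate one recording and return it with its ground truth.

    Spontaneous spikes follow per-channel Poisson processes; each spontaneous
    spike on channel i triggers, with probability coupling[i, j], a delayed
    spike on channel j (triggered spikes never cascade). When treatment is
    applied, both the base rate and the coupling are multiplied by the
    scenario's treatment factor.
    """
    sc = scenario
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    if apply_treatment is None:
        apply_treatment = condition == "VPA"
    tf = sc.treatment_factor if apply_treatment else 1.0

    n_samples = int(round(sc.duration_s * sc.fs))
    rate = sc.base_rate_hz * tf * rate_factor
    coupling = sc.network.coupling * tf

    # spontaneous spikes
    spont = []
    for _ in range(sc.n_channels):
        n = rng.poisson(rate * sc.duration_s)
        spont.append(np.sort(rng.uniform(0.0, sc.duration_s, size=n)))

    # triggered spikes (one generation, no cascades)
    all_times = [list(t) for t in spont]
    targets_of = [np.flatnonzero(coupling[i] > 0) for i in range(sc.n_channels)]
    for i in range(sc.n_channels):
        tgts = targets_of[i]
        if tgts.size == 0 or spont[i].size == 0:
            continue
        for j in tgts:
            fire = rng.random(spont[i].size) < coupling[i, j]
            if not fire.any():
                continue
            delays = rng.normal(sc.network.delay_ms, sc.network.delay_jitter_ms,
                                size=int(fire.sum())) * 1e-3
            delays = np.clip(delays, 0.1e-3, None)
            times = spont[i][fire] + delays
            all_times[j].extend(times[times < sc.duration_s])

    spike_times = [np.sort(np.asarray(t)) for t in all_times]

    # voltage: shaped noise + templates
    voltage = _band_limited_noise(rng, sc.n_channels, n_samples, sc.noise_sd_uv, sc.fs)
    template = spike_template(sc.fs) * sc.spike_amplitude_uv
    half = template.size // 2
    pol = channel_polarities(sc.n_channels, sc.polarity_mix)
    for ch in range(sc.n_channels):
        samples = np.round(spike_times[ch] * sc.fs).astype(np.int64)
        for s in samples:
            a = s - half
            b = a + template.size
            if a < 0 or b > n_samples:
                continue
            voltage[ch, a:b] += pol[ch] * template

    rec = Recording(voltage=voltage, fs=sc.fs, well_id=well_id,
                    session=session, condition=condition)
    gt = GroundTruth(spike_times=spike_times, coupling=coupling,
                     spontaneous_counts=np.array([t.size for t in spont]))
    return rec, gt


def simulate_plate(n_ctrl_wells: int, n_treated_wells: int,
                   sessions=DEFAULT_SESSIONS,
                   scenario: SimulationScenario | None = None,
                   seed: int | None = None) -> list:
    """Simulate a plate: one recording per (well, session) pair.

    Control wells are named B1..Bn, treated wells A1..An. The 0h session is
    generated untreated for every well (treatment is applied only to the
    post-baseline sessions of treated wells). Each well receives a log-normal
    multiplicative rate factor, constant across its sessions, emulating
    inter-culture heterogeneity.

    Returns a list of (Recording, GroundTruth) tuples.
    """
    if not sessions:
        raise ConfigError("session list must be nonempty")
    for s in sessions:
        if s not in DEFAULT_SESSIONS:
            raise ConfigError(f"unknown session label {s!r}")
    if scenario is None:
        scenario = SimulationScenario()
    if seed is None:
        seed = scenario.seed
    if n_ctrl_wells == 0 or n_treated_wells == 0:
        logger.warning("a plate with an empty arm cannot support classification")

    wells = [(f"B{i+1}", "CTRL") for i in range(n_ctrl_wells)]
    wells += [(f"A{i+1}", "VPA") for i in range(n_treated_wells)]

    ss = np.random.SeedSequence(seed)
    well_seeds = ss.spawn(len(wells))
    out = []
    for (well_id, condition), wss in zip(wells, well_seeds):
        well_rng = np.random.default_rng(wss)
        rate_factor = float(np.exp(well_rng.normal(0.0, WELL_RATE_SIGMA)))
        session_rngs = [np.random.default_rng(s) for s in wss.spawn(len(sessions))]
        for session, srng in zip(sessions, session_rngs):
            treated = condition == "VPA" and session != "0h"
            rec, gt = simulate_recording(scenario, well_id=well_id,
                                         session=session, condition=condition,
                                         rate_factor=rate_factor,
                                         apply_treatment=treated, rng=srng)
            out.append((rec, gt))
    return out


def write_plate(recordings: list, out_dir) -> list:
    """Write each recording to HDF5 with a ground-truth JSON sidecar."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec, gt in recordings:
        stem = f"{rec.well_id}_{rec.session}"
        h5 = out_dir / f"{stem}.h5"
        rec.to_hdf5(h5)
        gt.to_json(out_dir / f"{stem}.groundtruth.json")
        paths.append(h5)
    return paths
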