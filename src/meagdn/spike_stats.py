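"""Spike-level complements to the graph pipeline.

Three analyses that use only the spikes themselves, against which the graph
descriptors are benchmarked:

* k-means typology of single-channel AM-spike waveforms (the recordings
  carry two waveform classes, positive- and negative-going spikes);
* a waveform-only classification baseline: LOWO classification from raw
  AM-spike samples, which stays at chance when the experimental perturbation
  alters coupling but not waveform shape;
* standard population activity metrics - mean firing rate (MFR), burst rate
  (BR) and spikes-in-burst (SIB) - over growing windows (20..300 s in 20-s
  steps), with 0h baseline normalization. The burst detector is a simple
  ISI-threshold rule (gap < 100 ms, >= 5 spikes), a documented stand-in and
  not a re-implementation of any external burst-analysis suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DataError
from .preprocessing import AMSpikeTrain
from . import classification as clf_mod

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS_S = tuple(range(20, 301, 20))
BURST_ISI_S = 0.100
BURST_MIN_SPIKES = 5


@dataclass
class WaveformMatrix:
    """Single-channel AM-spike waveforms with metadata.

    waveforms is (n_events, L): the detected channel's own modulated segment
    row for every event.
    """

    waveforms: np.ndarray
    polarity: np.ndarray
    well_id: np.ndarray
    condition: np.ndarray

    def __len__(self) -> int:
        return self.waveforms.shape[0]


def extract_waveforms(train: AMSpikeTrain) -> WaveformMatrix:
    """Pull each event's own-channel AM-spike row out of the train."""
    L = train.segment_length
    rows = np.empty((train.n_segments, L))
    pol = np.empty(train.n_segments, dtype=np.int64)
    for i, ev in enumerate(train.events):
        rows[i] = train.segment(i)[ev.channel]
        pol[i] = ev.polarity
    n = train.n_segments
    return WaveformMatrix(waveforms=rows, polarity=pol,
                          well_id=np.full(n, train.well_id, dtype=object),
                          condition=np.full(n, train.condition, dtype=object))


def concat_waveforms(mats: list) -> WaveformMatrix:
    return WaveformMatrix(
        waveforms=np.concatenate([m.waveforms for m in mats], axis=0),
        polarity=np.concatenate([m.polarity for m in mats]),
        well_id=np.concatenate([m.well_id for m in mats]),
        condition=np.concatenate([m.condition for m in mats]))


def cluster_waveforms(wf: WaveformMatrix, k: int = 2, seed: int = 0) -> dict:
    """k-means waveform typology with k-means++ and 10 restarts.

    Reports the agreement between cluster membership and the spike polarity
    (sign of each centroid's extremum), plus a degeneracy flag when the
    centroids coincide.
    """
    if len(wf) < k:
        raise DataError(f"need at least {k} waveforms for k={k} clustering")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(wf.waveforms)
    centroids = km.cluster_centers_
    degenerate = len(np.unique(labels)) < k or any(
        np.allclose(centroids[i], centroids[j])
        for i in range(k) for j in range(i + 1, k))
    if degenerate:
        logger.warning("degenerate clustering: coincident centroids")
    centroid_sign = np.array([1 if c[np.argmax(np.abs(c))] >= 0 else -1
                              for c in centroids])
    pred_pol = centroid_sign[labels]
    agreement = float(np.mean(pred_pol == wf.polarity))
    return {"labels": labels, "centroids": centroids,
            "polarity_agreement": max(agreement, 1.0 - agreement) if k == 2 else agreement,
            "degenerate": degenerate}


def waveform_pca(wf: WaveformMatrix, n_components: int = 2) -> np.ndarray:
    """First principal-component scores of the centered waveforms."""
    X = wf.waveforms - wf.waveforms.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return X @ vt[:n_components].T


def waveform_baseline_classifier(wf: WaveformMatrix, classifier: str = "lda",
                                 seed: int = 0) -> dict:
    """LOWO classification of the condition from raw waveform samples.

    Returns single-time-point and majority-voting accuracies; used as the
    baseline that the graph-descriptor pipeline must beat.
    """
    wells = np.unique(wf.well_id)
    by_well = {w: wf.condition[wf.well_id == w][0] for w in wells}
    if len(set(by_well.values())) < 2:
        raise DataError("waveform baseline needs both conditions present")
    samples = clf_mod.SampleTable(
        X=pd.DataFrame(wf.waveforms), y=wf.condition.astype(str),
        groups=wf.well_id.astype(str), session="waveform",
        offsets=[0], features=list(range(wf.waveforms.shape[1])))
    folds = clf_mod.lowo_cv(samples, classifier=classifier, seed=seed)
    return {"folds": folds,
            "single_accuracy": clf_mod.pooled_accuracy(folds),
            "majority_accuracy": clf_mod.majority_accuracy(folds)}


# ---------------------------------------------------------------------------
# activity metrics


def detect_bursts(spike_times: np.ndarray, isi_thresh_s: float = BURST_ISI_S,
                  min_spikes: int = BURST_MIN_SPIKES) -> list:
    """Runs of >= min_spikes spikes with consecutive ISIs below the
    threshold; returns (start_time, n_spikes) per burst."""
    t = np.asarray(spike_times, dtype=np.float64)
    if t.size < min_spikes:
        return []
    if np.any(np.diff(t) < 0):
        raise DataError("spike times must be sorted")
    bursts = []
    start = 0
    for i in range(1, t.size + 1):
        if i == t.size or t[i] - t[i - 1] > isi_thresh_s:
            if i - start >= min_spikes:
                bursts.append((float(t[start]), i - start))
            start = i
    return bursts


def activity_metrics(spike_times_per_channel: list, duration_s: float,
                     window_lengths_s=DEFAULT_WINDOWS_S,
                     isi_thresh_s: float = BURST_ISI_S,
                     min_spikes: int = BURST_MIN_SPIKES) -> pd.DataFrame:
    """MFR, BR and SIB over progressively growing windows from time zero.

    MFR (Hz) averages spikes/window over channels; BR (bursts/min) and SIB
    (mean spikes per burst) pool bursts over channels. One row per window
    length.
    """
    if duration_s < max(window_lengths_s):
        raise DataError("recording shorter than the longest analysis window")
    rows = []
    for win in window_lengths_s:
        counts, n_bursts, burst_sizes = [], 0, []
        for t in spike_times_per_channel:
            t = np.asarray(t, dtype=np.float64)
            tw = t[t < win]
            counts.append(tw.size)
            for _, size in detect_bursts(tw, isi_thresh_s, min_spikes):
                n_bursts += 1
                burst_sizes.append(size)
        rows.append({
            "window_s": win,
            "mfr_hz": float(np.mean(counts)) / win,
            "br_per_min": n_bursts / (win / 60.0) / len(spike_times_per_channel),
            "sib": float(np.mean(burst_sizes)) if burst_sizes else 0.0,
        })
    return pd.DataFrame(rows)


def normalize_metrics(metrics: pd.DataFrame, baseline: pd.DataFrame,
                      cols=("mfr_hz", "br_per_min", "sib")) -> pd.DataFrame:
    """Divide session metrics by the matching-window 0h baseline values; a
    zero baseline codes the normalized value NaN."""
    out = metrics.merge(baseline[["window_s", *cols]], on="window_s",
                        suffixes=("", "_0h"))
    for c in cols:
        base = out[f"{c}_0h"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = np.where(base != 0, out[c].to_numpy() / base, np.nan)
        out[f"{c}_norm"] = norm
    return out.drop(columns=[f"{c}_0h" for c in cols])
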