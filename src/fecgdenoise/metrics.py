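"""Denoising evaluation metrics.

Two families:

* divergence vs. ground truth — per-channel input/output SNR, SNR
  improvement (``SNR_imp = SNR_out − SNR_in``), RMSE and percent
  root-mean-square difference (PRD), each computed along each channel and
  then averaged;
* QRS-detection scoring — an adaptive-threshold (Hamilton-style) R-peak
  detector, peak matching against reference annotations within a ±50 ms
  tolerance, and PPV / sensitivity / F1 from the TP/FN/FP counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["ChannelMetrics", "DetectionCounts", "DetectionMetrics",
           "snr_pair", "snr_improvement", "rmse", "prd", "detect_qrs",
           "match_peaks", "detection_metrics", "evaluate_denoising"]

TOLERANCE_MS = 50.0
REFRACTORY_S = 0.200


def _per_channel(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def snr_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-channel SNR of an estimate ``y`` against reference ``x`` in dB:
    ``10·log10(Σx² / Σ(y−x)²)``; exact reconstruction yields +inf."""
    x, y = _per_channel(x), _per_channel(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    sig = np.sum(x ** 2, axis=-1)
    if np.any(sig == 0):
        raise ValueError("zero-energy reference channel")
    err = np.sum((y - x) ** 2, axis=-1)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(sig / err)


def snr_improvement(x: np.ndarray, x_hat: np.ndarray,
                    x_tilde: np.ndarray) -> float:
    """Mean over channels of ``SNR_out − SNR_in``."""
    return float(np.mean(snr_pair(x, x_tilde) - snr_pair(x, x_hat)))


def rmse(x: np.ndarray, x_tilde: np.ndarray) -> float:
    """Root-mean-square error per channel, averaged over channels."""
    x, x_tilde = _per_channel(x), _per_channel(x_tilde)
    if x.shape != x_tilde.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_tilde.shape}")
    return float(np.mean(np.sqrt(np.mean((x - x_tilde) ** 2, axis=-1))))


def prd(x: np.ndarray, x_tilde: np.ndarray) -> float:
    """Percent root-mean-square difference per channel, averaged:
    ``100·sqrt(Σ(x−x̃)² / Σx²)``."""
    x, x_tilde = _per_channel(x), _per_channel(x_tilde)
    if x.shape != x_tilde.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_tilde.shape}")
    sig = np.sum(x ** 2, axis=-1)
    if np.any(sig == 0):
        raise ValueError("zero-energy reference channel")
    err = np.sum((x - x_tilde) ** 2, axis=-1)
    return float(np.mean(100.0 * np.sqrt(err / sig)))


@dataclass(frozen=True)
class ChannelMetrics:
    """Per-channel and channel-averaged divergence metrics."""

    snr_in: np.ndarray
    snr_out: np.ndarray
    snr_imp: np.ndarray
    rmse: np.ndarray
    prd: np.ndarray

    def averaged(self) -> dict:
        return {k: float(np.mean(getattr(self, k)))
                for k in ("snr_in", "snr_out", "snr_imp", "rmse", "prd")}


def evaluate_denoising(x: np.ndarray, x_hat: np.ndarray,
                       x_tilde: np.ndarray) -> ChannelMetrics:
    """All five divergence metrics per channel for one record/window."""
    x, x_hat, x_tilde = map(_per_channel, (x, x_hat, x_tilde))
    s_in = snr_pair(x, x_hat)
    s_out = snr_pair(x, x_tilde)
    ch_rmse = np.sqrt(np.mean((x - x_tilde) ** 2, axis=-1))
    ch_prd = 100.0 * np.sqrt(np.sum((x - x_tilde) ** 2, axis=-1)
                             / np.sum(x ** 2, axis=-1))
    return ChannelMetrics(snr_in=s_in, snr_out=s_out, snr_imp=s_out - s_in,
                          rmse=ch_rmse, prd=ch_prd)


def detect_qrs(signal: np.ndarray, fs: float) -> np.ndarray:
    """Adaptive-threshold QRS detection on a single channel.

    Band-pass (8-30 Hz) filtering, differentiation, squaring and an
    80 ms moving-average envelope, followed by peak picking with an
    adaptive amplitude threshold and a 200 ms refractory period; each
    detection is refined to the local absolute maximum of the band-passed
    signal. Returns strictly increasing sample indices.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.size <= fs:
        raise ValueError("signal must be longer than 1 s for QRS detection")
    if np.all(x == x[0]):
        return np.empty(0, dtype=int)

    hi = min(30.0, 0.45 * fs)
    sos = sps.butter(3, [8.0, hi], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    env = np.convolve(np.abs(np.gradient(bp)) ** 2,
                      np.ones(max(int(0.080 * fs), 1)) / max(int(0.080 * fs), 1),
                      mode="same")
    thr = 0.15 * np.percentile(env, 99.5)
    if thr <= 0:
        return np.empty(0, dtype=int)
    refr = max(int(REFRACTORY_S * fs), 1)
    peaks, _ = sps.find_peaks(env, height=thr, distance=refr)

    # refine each detection to the dominant deflection of the filtered signal
    half = max(int(0.050 * fs), 1)
    refined = []
    for p in peaks:
        lo, hi_i = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi_i]))))
    refined = np.unique(refined)
    if refined.size > 1:  # re-enforce refractory after refinement
        keep = [int(refined[0])]
        for p in refined[1:]:
            if p - keep[-1] >= refr:
                keep.append(int(p))
        refined = np.asarray(keep)
    return refined.astype(int)


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fn: int
    fp: int
    tolerance_ms: float = TOLERANCE_MS

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class DetectionMetrics:
    """PPV, sensitivity and F1 in percent; None marks an undefined
    metric (zero denominator), never silently reported as 0."""

    ppv: float | None
    se: float | None
    f1: float | None


def match_peaks(detected: np.ndarray, reference: np.ndarray, fs: float,
                tolerance_ms: float = TOLERANCE_MS) -> DetectionCounts:
    """Match detections to reference peaks one-to-one within ±tolerance.

    Both index lists are sorted; the optimal (maximum-cardinality)
    matching of two sorted sequences under a window constraint is
    non-crossing, so it is computed exactly by dynamic programming, with
    total matched distance as the tie-break.
    """
    det = np.sort(np.asarray(detected, dtype=float))
    ref = np.sort(np.asarray(reference, dtype=float))
    tol = tolerance_ms * fs / 1000.0
    n_ref, n_det = ref.size, det.size
    if n_ref == 0 or n_det == 0:
        return DetectionCounts(tp=0, fn=n_ref, fp=n_det,
                               tolerance_ms=tolerance_ms)

    # best[i][j]: max matches achievable from ref[i:], det[j:]; dist is the
    # minimal total matched distance among maximizers (tie-break)
    best = np.zeros((n_ref + 1, n_det + 1))
    dist = np.zeros((n_ref + 1, n_det + 1))
    for i in range(n_ref - 1, -1, -1):
        for j in range(n_det - 1, -1, -1):
            m, d = best[i + 1, j], dist[i + 1, j]
            if best[i, j + 1] > m or (best[i, j + 1] == m
                                      and dist[i, j + 1] < d):
                m, d = best[i, j + 1], dist[i, j + 1]
            gap = abs(ref[i] - det[j])
            if gap <= tol:
                mm = best[i + 1, j + 1] + 1
                dd = dist[i + 1, j + 1] + gap
                if mm > m or (mm == m and dd < d):
                    m, d = mm, dd
            best[i, j], dist[i, j] = m, d
    tp = int(best[0, 0])
    return DetectionCounts(tp=tp, fn=n_ref - tp, fp=n_det - tp,
                           tolerance_ms=tolerance_ms)


def detection_metrics(counts: DetectionCounts) -> DetectionMetrics:
    """PPV = TP/(TP+FP), SE = TP/(TP+FN), F1 = harmonic mean, in percent."""
    ppv = se = f1 = None
    if counts.tp + counts.fp > 0:
        ppv = 100.0 * counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn > 0:
        se = 100.0 * counts.tp / (counts.tp + counts.fn)
    if ppv is not None and se is not None and (ppv + se) > 0:
        f1 = 2.0 * ppv * se / (ppv + se)
    elif ppv is not None and se is not None:
        f1 = 0.0
    return DetectionMetrics(ppv=ppv, se=se, f1=f1)
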