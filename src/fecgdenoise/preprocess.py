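"""Raw records → standardized 4×1920 windows.

Pipeline: (optional) maternal-ECG cancellation by synchronized template
subtraction, anti-aliased resampling to 500 Hz, segmentation into
non-overlapping 4×1920 windows, and per-channel standardization to zero
mean / unit standard deviation with the statistics stored for later
de-standardization. Entirely deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = ["SignalWindow", "PairedWindows", "TARGET_FS", "WINDOW_SAMPLES",
           "cancel_maternal", "resample_record", "segment_windows",
           "standardize_window", "destandardize_window",
           "make_paired_windows"]

log = logging.getLogger(__name__)

TARGET_FS = 500.0
WINDOW_SAMPLES = 1920
N_CHANNELS = 4


@dataclass(frozen=True)
class SignalWindow:
    """One 4×1920 segment with its provenance and scaling statistics.

    ``role`` is one of ``clean`` (x), ``noisy`` (x̂) or ``denoised`` (x̃).
    ``mean``/``std`` are per-channel statistics; they are None until
    :func:`standardize_window` fills them.
    """

    values: np.ndarray
    role: str = "noisy"
    offset: int = 0
    fs: float = TARGET_FS
    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != N_CHANNELS or v.shape[1] != WINDOW_SAMPLES:
            raise ValueError(f"window must be {N_CHANNELS}x{WINDOW_SAMPLES}, "
                             f"got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("window contains non-finite values")


def cancel_maternal(abdominal: np.ndarray, maternal_peaks: np.ndarray,
                    min_r2: float = 0.05) -> np.ndarray:
    """Subtract the maternal ECG by synchronized template subtraction.

    An average beat is built per channel around the given maternal R-peak
    sample indices and removed at each peak with a per-beat least-squares
    amplitude fit, which guarantees the residual segment energy never
    exceeds the input segment energy. A segment is only touched when the
    template explains at least ``min_r2`` of its energy, so spurious peak
    lists (e.g. on a record with no maternal component) leave the signal
    essentially unchanged.
    """
    x = np.asarray(abdominal, dtype=float)
    peaks = np.asarray(maternal_peaks, dtype=int)
    if peaks.size < 2:
        raise ValueError("need at least 2 maternal peaks to build a template")
    if peaks.min() < 0 or peaks.max() >= x.shape[-1]:
        raise ValueError("maternal peak index outside record bounds")
    peaks = np.sort(peaks)
    half = int(min(np.median(np.diff(peaks)) // 2, x.shape[-1] // 2))
    if half < 1:
        return x.copy()

    segs = [x[:, p - half:p + half] for p in peaks
            if p - half >= 0 and p + half <= x.shape[-1]]
    if not segs:
        return x.copy()
    template = np.mean(segs, axis=0)  # (channels, 2*half)
    tpl_energy = np.sum(template ** 2, axis=-1)
    tpl_energy[tpl_energy == 0] = 1.0

    out = x.copy()
    for p in peaks:
        lo, hi = p - half, p + half
        lo_c, hi_c = max(lo, 0), min(hi, x.shape[-1])
        tpl = template[:, lo_c - lo: (hi_c - lo)]
        seg = out[:, lo_c:hi_c]
        e = np.sum(tpl ** 2, axis=-1)
        e[e == 0] = 1.0
        proj = np.sum(seg * tpl, axis=-1)
        seg_e = np.sum(seg ** 2, axis=-1)
        seg_e[seg_e == 0] = 1.0
        r2 = proj ** 2 / (e * seg_e)
        alpha = np.where(r2 >= min_r2, proj / e, 0.0)
        out[:, lo_c:hi_c] = seg - alpha[:, None] * tpl
    return out


def resample_record(record: np.ndarray, fs_in: float,
                    fs_out: float = TARGET_FS) -> np.ndarray:
    """Polyphase anti-aliased resampling to ``fs_out`` (500 Hz default);
    the identity rate returns the input unchanged."""
    if fs_in <= 0:
        raise ValueError("fs_in must be positive")
    x = np.asarray(record, dtype=float)
    if fs_in == fs_out:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def segment_windows(record: np.ndarray, role: str = "noisy",
                    fs: float = TARGET_FS,
                    window: int = WINDOW_SAMPLES) -> list[SignalWindow]:
    """Cut a 4×N record into consecutive non-overlapping 4×1920 windows;
    a trailing remainder shorter than one window is dropped."""
    x = np.asarray(record, dtype=float)
    if x.ndim != 2 or x.shape[0] != N_CHANNELS:
        raise ValueError(f"record must have {N_CHANNELS} channels, got {x.shape}")
    n_windows = x.shape[-1] // window
    if n_windows == 0:
        log.warning("record of %d samples is shorter than one %d-sample "
                    "window; returning no windows", x.shape[-1], window)
        return []
    return [SignalWindow(values=x[:, i * window:(i + 1) * window].copy(),
                         role=role, offset=i * window, fs=fs)
            for i in range(n_windows)]


def standardize_window(window: SignalWindow) -> SignalWindow:
    """Scale each channel to zero mean and unit standard deviation,
    recording the statistics for de-standardization."""
    v = window.values
    mean = v.mean(axis=-1)
    std = v.std(axis=-1)
    if np.any(std == 0):
        raise ValueError("cannot standardize a zero-variance channel")
    values = (v - mean[:, None]) / std[:, None]
    return replace(window, values=values, mean=mean, std=std)


def destandardize_window(window: SignalWindow) -> SignalWindow:
    """Invert :func:`standardize_window` using the stored statistics."""
    if window.mean is None or window.std is None:
        raise ValueError("window carries no standardization statistics")
    values = window.values * window.std[:, None] + window.mean[:, None]
    return replace(window, values=values, mean=None, std=None)


@dataclass
class PairedWindows:
    """Aligned standardized clean/noisy window tensors for training.

    ``x_clean``/``x_noisy`` are (n, 4, 1920) standardized arrays;
    ``clean_mean``/``clean_std``/``noisy_mean``/``noisy_std`` are the
    (n, 4) per-channel statistics; ``offsets`` the source sample offsets.
    """

    x_clean: np.ndarray
    x_noisy: np.ndarray
    clean_mean: np.ndarray
    clean_std: np.ndarray
    noisy_mean: np.ndarray
    noisy_std: np.ndarray
    offsets: np.ndarray
    fs: float = TARGET_FS

    def __len__(self) -> int:
        return self.x_clean.shape[0]

    def subset(self, idx) -> "PairedWindows":
        return PairedWindows(self.x_clean[idx], self.x_noisy[idx],
                             self.clean_mean[idx], self.clean_std[idx],
                             self.noisy_mean[idx], self.noisy_std[idx],
                             self.offsets[idx], self.fs)


def make_paired_windows(records, fs_in: float | None = None) -> PairedWindows:
    """Resample paired records to 500 Hz, window and standardize them.

    ``records`` is an iterable of objects with ``clean``/``noisy``/``fs``
    attributes (e.g. :class:`~fecgdenoise.simulator.PairedRecord`).
    Windows whose clean or noisy segment has a zero-variance channel are
    skipped.
    """
    xc, xn, cm, cs, nm, ns, offs = [], [], [], [], [], [], []
    for rec in records:
        fs = fs_in if fs_in is not None else rec.fs
        clean = resample_record(rec.clean, fs)
        noisy = resample_record(rec.noisy, fs)
        for wc, wn in zip(segment_windows(clean, role="clean"),
                          segment_windows(noisy, role="noisy")):
            try:
                swc = standardize_window(wc)
                swn = standardize_window(wn)
            except ValueError:
                log.warning("skipping window at offset %d: zero-variance "
                            "channel", wc.offset)
                continue
            xc.append(swc.values)
            xn.append(swn.values)
            cm.append(swc.mean)
            cs.append(swc.std)
            nm.append(swn.mean)
            ns.append(swn.std)
            offs.append(wc.offset)
    if not xc:
        raise ValueError("no usable windows in the given records")
    return PairedWindows(np.stack(xc), np.stack(xn), np.stack(cm),
                         np.stack(cs), np.stack(nm), np.stack(ns),
                         np.asarray(offs))
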