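"""Readers and writers for records, window containers and checkpoints.

Formats:

* **CSV pair** — the simulator convention: ``<name>_clean.csv`` /
  ``<name>_noisy.csv``, one column per channel, ``#``-prefixed header
  comments carrying fs and case metadata; peak lists as a one-column
  ``sample_index`` CSV. 0-based sample indexing throughout.
* **WFDB format 16** — minimal ``.hea``/``.dat`` support (16-bit
  little-endian interleaved samples, per-signal gain and baseline:
  ``physical = (digital - baseline) / gain``), enough for round-tripping
  multichannel records.
* **window container** — an ``.npz`` archive of the standardized window
  tensors, offsets and per-window statistics.
* **checkpoint** — an ``.npz`` archive of all model weights plus a JSON
  metadata blob (width scale, seed, training config).
"""

from __future__ import annotations

import ast
import json
from pathlib import Path

import numpy as np

from .model import DenoisingModel
from .preprocess import PairedWindows

__all__ = ["write_csv_record", "read_csv_record", "write_csv_pair",
           "read_csv_pair", "write_peaks_csv", "read_peaks_csv",
           "write_wfdb", "read_wfdb", "save_windows", "load_windows",
           "save_checkpoint", "load_checkpoint"]


# ---------------------------------------------------------------- CSV ----

def write_csv_record(path, signal: np.ndarray, fs: float,
                     metadata: dict | None = None) -> None:
    path = Path(path)
    x = np.asarray(signal, dtype=float)
    header = [f"fs={fs!r}"]
    for k, v in (metadata or {}).items():
        header.append(f"{k}={v!r}")
    header.append(",".join(f"ch{i + 1}" for i in range(x.shape[0])))
    np.savetxt(path, x.T, delimiter=",", fmt="%.9e",
               header="\n".join(header))


def read_csv_record(path):
    """Return ``(signal, fs, metadata)`` for a simulator CSV file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                try:
                    metadata[key.strip()] = ast.literal_eval(val.strip())
                except (ValueError, SyntaxError) as exc:
                    raise ValueError(f"{path}:{lineno}: bad metadata "
                                     f"{body!r}") from exc
    try:
        data = np.loadtxt(path, delimiter=",")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed CSV payload: {exc}") from exc
    fs = float(metadata.pop("fs", 0.0))
    if fs <= 0:
        raise ValueError(f"{path}: missing or invalid fs metadata")
    return np.atleast_2d(data).T.astype(float), fs, metadata


def write_csv_pair(basepath, record) -> tuple[Path, Path]:
    """Write a paired record as ``<base>_clean.csv`` / ``<base>_noisy.csv``."""
    base = Path(basepath)
    meta = {"case_id": record.case.case_id, "snr_db": record.case.snr_db,
            "seed": record.case.seed}
    clean_path = base.with_name(base.name + "_clean.csv")
    noisy_path = base.with_name(base.name + "_noisy.csv")
    write_csv_record(clean_path, record.clean, record.fs, meta)
    write_csv_record(noisy_path, record.noisy, record.fs, meta)
    return clean_path, noisy_path


def read_csv_pair(basepath):
    """Return ``(clean, noisy, fs, metadata)`` for a CSV pair."""
    base = Path(basepath)
    clean, fs, meta = read_csv_record(base.with_name(base.name + "_clean.csv"))
    noisy, fs2, _ = read_csv_record(base.with_name(base.name + "_noisy.csv"))
    if fs != fs2 or clean.shape != noisy.shape:
        raise ValueError(f"{base}: clean/noisy pair is inconsistent")
    return clean, noisy, fs, meta


def write_peaks_csv(path, peaks: np.ndarray) -> None:
    np.savetxt(Path(path), np.asarray(peaks, dtype=int)[:, None],
               fmt="%d", header="sample_index")


def read_peaks_csv(path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(Path(path), dtype=int))


# --------------------------------------------------------------- WFDB ----

def write_wfdb(basepath, signal: np.ndarray, fs: float, gain: float = 200.0,
               units: str = "mV") -> tuple[Path, Path]:
    """Write a record in WFDB format 16 (.hea text header + interleaved
    little-endian int16 .dat)."""
    base = Path(basepath)
    x = np.asarray(signal, dtype=float)
    n_sig, n_samp = x.shape
    digital = np.round(x * gain)
    if np.any(np.abs(digital) > 32767):
        raise ValueError("signal exceeds 16-bit range at this gain")
    hea, dat = base.with_suffix(".hea"), base.with_suffix(".dat")
    lines = [f"{base.name} {n_sig} {fs:g} {n_samp}"]
    for i in range(n_sig):
        lines.append(f"{base.name}.dat 16 {gain:g}(0)/{units} 16 0 0 0 0 ch{i + 1}")
    hea.write_text("\n".join(lines) + "\n")
    dat.write_bytes(digital.T.astype("<i2").tobytes())
    return hea, dat


def read_wfdb(basepath):
    """Read a format-16 WFDB record; returns ``(signal, fs, metadata)``
    with the signal in physical units."""
    base = Path(basepath)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    try:
        n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{hea}:1: malformed record line {lines[0]!r}") from exc
    gains = np.ones(n_sig)
    baselines = np.zeros(n_sig)
    dat_name = None
    for i, ln in enumerate(lines[1:1 + n_sig]):
        fields = ln.split()
        try:
            dat_name = fields[0]
            if fields[1] != "16":
                raise ValueError(f"unsupported format {fields[1]}")
            gain_spec = fields[2]
            g = gain_spec.split("/")[0]
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baselines[i] = float(b)
            gains[i] = float(g) if float(g) != 0 else 200.0
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{hea}:{i + 2}: malformed signal line "
                             f"{ln!r}") from exc
    raw = np.frombuffer((base.parent / dat_name).read_bytes(), dtype="<i2")
    digital = raw.reshape(n_samp, n_sig).T.astype(float)
    physical = (digital - baselines[:, None]) / gains[:, None]
    return physical, fs, {"gains": gains, "baselines": baselines}


# ----------------------------------------------- windows & checkpoints ----

def save_windows(path, windows: PairedWindows) -> None:
    np.savez_compressed(Path(path), x_clean=windows.x_clean,
                        x_noisy=windows.x_noisy,
                        clean_mean=windows.clean_mean,
                        clean_std=windows.clean_std,
                        noisy_mean=windows.noisy_mean,
                        noisy_std=windows.noisy_std,
                        offsets=windows.offsets, fs=windows.fs)


def load_windows(path) -> PairedWindows:
    with np.load(Path(path)) as z:
        return PairedWindows(z["x_clean"], z["x_noisy"], z["clean_mean"],
                             z["clean_std"], z["noisy_mean"], z["noisy_std"],
                             z["offsets"], float(z["fs"]))


def save_checkpoint(path, model: DenoisingModel,
                    extra: dict | None = None) -> None:
    meta = {"width_scale": model.spec.width_scale,
            "dtype": np.dtype(model.dtype).name}
    meta.update(extra or {})
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(Path(path), __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[DenoisingModel, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    model = DenoisingModel.build(width_scale=meta["width_scale"], seed=0,
                                 dtype=np.dtype(meta.get("dtype", "float64")).type)
    model.load_state_dict(state)
    return model, meta
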