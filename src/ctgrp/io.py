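"""Readers and writers for FHR records, image datasets and manifests.

Formats supported:

* two-column CSV records (``time_s,fhr_bpm``, comma-delimited, UTF-8);
* WFDB/MIT header + signal pairs as used by the CTU-UHB intrapartum
  database (text ``.hea`` header, format-16 little-endian ``.dat``), with
  clinical notes such as pH read from ``#`` comment lines;
* 8-bit grayscale PNG image datasets with a CSV manifest whose row order
  defines the dataset order.

No function here touches the network; fetching the CTU-UHB database is a
separate documented script.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .records import FHRRecord

logger = logging.getLogger(__name__)

CSV_HEADER = ("time_s", "fhr_bpm")


def write_csv_record(record: FHRRecord, path) -> Path:
    """Write a record as ``time_s,fhr_bpm`` CSV; round-trips with the reader."""
    path = Path(path)
    if len(record) < 1:  # pragma: no cover - FHRRecord forbids this
        raise ValueError("empty record")
    t = np.arange(len(record)) / record.fs
    df = pd.DataFrame({CSV_HEADER[0]: t, CSV_HEADER[1]: record.samples})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_csv_record(path, rtol: float = 0.05) -> FHRRecord:
    """Read a two-column (time_s, bpm) CSV record.

    The sampling rate is inferred from the time column; timestamps must be
    uniform to within ``rtol`` of the median step.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"empty record: {path}")
    if df.shape[1] < 2:
        raise ValueError(f"expected two columns (time, bpm) in {path}")
    t = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    bpm = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    if t.size == 1:
        fs = 4.0
    else:
        dt = np.diff(t)
        step = float(np.median(dt))
        if step <= 0:
            raise ValueError("non-increasing timestamps")
        if np.max(np.abs(dt - step)) > rtol * step:
            raise ValueError(f"non-uniform sampling in {path}: "
                             f"max deviation {np.max(np.abs(dt - step)):.4g} s "
                             f"exceeds {rtol:.0%} of step {step:.4g} s")
        fs = 1.0 / step
    return FHRRecord(record_id=path.stem, samples=bpm, fs=fs)


# ---------------------------------------------------------------------------
# WFDB/MIT format (CTU-UHB layout): minimal reader, format 16 only.
# ---------------------------------------------------------------------------

def _parse_gain_spec(spec: str):
    """Parse a WFDB gain field ``gain(baseline)/units`` -> (gain, baseline, units)."""
    units = None
    if "/" in spec:
        spec, units = spec.split("/", 1)
    baseline = None
    m = re.match(r"^([-+0-9.eE]+)(?:\(([-+0-9]+)\))?$", spec)
    if not m:
        raise ValueError(f"unparseable gain specification {spec!r}")
    gain = float(m.group(1))
    if m.group(2) is not None:
        baseline = int(m.group(2))
    if gain == 0:
        gain = 200.0  # WFDB default for a zero/absent gain
    return gain, baseline, units


def read_physionet_record(path_or_id, ph_key: str = "pH",
                          channel_hint: str = "FHR") -> FHRRecord:
    """Read one local WFDB-format record (CTU-UHB layout).

    ``path_or_id`` names the header file or the record stem. The FHR
    channel is selected by its description (``channel_hint``, default
    ``"FHR"``); the pH is taken from a ``#<ph_key> <value>`` comment line
    when present. Only signal format 16 (little-endian int16) is
    supported, which is what CTU-UHB uses. A header rate other than 4 Hz
    is accepted with a warning.
    """
    header_path = Path(str(path_or_id))
    if header_path.suffix != ".hea":
        header_path = header_path.with_suffix(".hea")
    if not header_path.exists():
        raise FileNotFoundError(f"unreadable header: {header_path}")

    lines = [ln.strip() for ln in header_path.read_text().splitlines() if ln.strip()]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    content = [ln for ln in lines if not ln.startswith("#")]
    if not content:
        raise ValueError(f"unreadable header: {header_path} has no record line")

    rec_fields = content[0].split()
    record_name = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else None
    if fs != 4.0:
        logger.warning("record %s: header sampling rate is %g Hz, not 4 Hz; "
                       "using the header value", record_name, fs)

    sig_lines = content[1:1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ValueError(f"header {header_path} declares {n_sig} signals, "
                         f"found {len(sig_lines)} description lines")

    signals = []
    for ln in sig_lines:
        f = ln.split()
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = _parse_gain_spec(f[2]) if len(f) > 2 else (200.0, None, None)
        adc_zero = int(f[4]) if len(f) > 4 else 0
        desc = " ".join(f[8:]) if len(f) > 8 else ""
        signals.append(dict(file=f[0], fmt=fmt, gain=gain,
                            baseline=baseline if baseline is not None else adc_zero,
                            desc=desc))

    idx = next((i for i, s in enumerate(signals)
                if channel_hint.lower() in s["desc"].lower()), None)
    if idx is None:
        raise ValueError(f"record {record_name}: no channel matching "
                         f"{channel_hint!r} among "
                         f"{[s['desc'] for s in signals]}")
    sig = signals[idx]
    if sig["fmt"] != "16":
        raise ValueError(f"unsupported WFDB signal format {sig['fmt']} "
                         f"(only format 16 is implemented)")

    dat_path = header_path.parent / sig["file"]
    raw = np.fromfile(dat_path, dtype="<i2")
    same_file = [i for i, s in enumerate(signals) if s["file"] == sig["file"]]
    n_interleaved = len(same_file)
    raw = raw[: (raw.size // n_interleaved) * n_interleaved]
    adc = raw.reshape(-1, n_interleaved)[:, same_file.index(idx)]
    if n_samples is not None:
        adc = adc[:n_samples]
    bpm = (adc.astype(float) - sig["baseline"]) / sig["gain"]
    bpm = np.clip(bpm, 0.0, None)  # negative ADC glitches encode missing signal

    ph = None
    pat = re.compile(rf"^{re.escape(ph_key)}\s+([-+0-9.eE]+)$", re.IGNORECASE)
    for c in comments:
        m = pat.match(c)
        if m:
            ph = float(m.group(1))
            break
    return FHRRecord(record_id=record_name, samples=bpm, fs=fs, ph=ph)


# ---------------------------------------------------------------------------
# Image datasets: 8-bit grayscale PNGs + CSV manifest.
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"


def save_image_dataset(images: Sequence, labels: Sequence[str],
                       params: Sequence, out_dir) -> Path:
    """Save recurrence-plot images as 8-bit grayscale PNGs with a manifest.

    ``params`` carries one ``(record_id, m, tau, k)`` tuple (or a mapping
    with those keys) per image. Returns the manifest path; manifest row
    order defines dataset order on reload.
    """
    if not (len(images) == len(labels) == len(params)):
        raise ValueError(f"length mismatch: {len(images)} images, "
                         f"{len(labels)} labels, {len(params)} params")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label, par) in enumerate(zip(images, labels, params)):
        arr = np.asarray(getattr(img, "pixels", img), dtype=float)
        if arr.ndim == 3:  # replicated channels -> store one
            arr = arr[..., 0]
        u8 = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
        fname = f"img_{i:06d}.png"
        Image.fromarray(u8, mode="L").save(out_dir / fname)
        if isinstance(par, dict):
            rid, m, tau, k = par["record_id"], par["m"], par["tau"], par["k"]
        else:
            rid, m, tau, k = par
        rows.append(dict(record_id=rid, path=fname, m=int(m), tau=int(tau),
                         k=int(k), label=label))
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_image_dataset(in_dir):
    """Load an image dataset saved by :func:`save_image_dataset`.

    Returns ``(images, labels, params)``: a float array (n, H, W) with
    intensities in [0, 1] in manifest order, the label list, and the
    parameter table as a DataFrame.
    """
    in_dir = Path(in_dir)
    manifest = in_dir / MANIFEST_NAME
    df = pd.read_csv(manifest)
    images = []
    for fname in df["path"]:
        fpath = in_dir / fname
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing image file: {fpath}")
        images.append(np.asarray(Image.open(fpath), dtype=float) / 255.0)
    labels = df["label"].tolist()
    params = df[["record_id", "m", "tau", "k"]].copy()
    return np.stack(images), labels, params


def write_cohort_manifest(records: Sequence[FHRRecord], paths: Sequence, out_path) -> Path:
    """Write a cohort table (record_id, path, ph, label)."""
    rows = [dict(record_id=r.record_id, path=str(p), ph=r.ph, label=r.label)
            for r, p in zip(records, paths)]
    out_path = Path(out_path)
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path
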