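"""Multichannel body-surface signal container, I/O and preprocessing.

The unit of data throughout the package is a ``MultichannelSignal``: a
T-samples x L-leads potential matrix with a sampling rate and lead labels.
Preprocessing follows the clinical pipeline for fibrillatory-wave analysis:
2-30 Hz band-pass filtering, channel-wise z-score normalization, QRS
detection (Pan-Tompkins), T-wave exclusion by the cross-channel-variance
rule, and extraction of f-wave segments of at least 800 ms. A standard
12-lead ECG can be derived from a body-surface potential map (BSPM) by
referencing a 9-electrode subset to the Wilson Central Terminal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "MultichannelSignal",
    "ElectrodeArray",
    "SegmentSet",
    "SignalFormatError",
    "read_signal",
    "write_signal",
    "bandpass_filter",
    "normalize_channels",
    "detect_qrs",
    "extract_fwave_segments",
    "ecg_from_bspm",
]

#: electrode roles needed to derive the 12-lead ECG
ECG_ROLES = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")


class SignalFormatError(ValueError):
    """Malformed signal file, sidecar, or non-finite data."""


@dataclass(frozen=True)
class MultichannelSignal:
    """Sampled multichannel potentials.

    Parameters
    ----------
    data : ndarray, shape (T, L)
        Potentials in mV (or normalized units once ``normalized`` is set).
    fs : float
        Sampling rate in Hz.
    lead_labels : tuple of str
        One label per lead.
    t0 : float
        Start offset in ms.
    normalized : bool
        True once channels have been z-scored.
    """

    data: np.ndarray
    fs: float
    lead_labels: tuple
    t0: float = 0.0
    normalized: bool = False

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "lead_labels", tuple(self.lead_labels))
        if data.ndim != 2:
            raise SignalFormatError("data must be a 2-D (samples x leads) matrix")
        T, L = data.shape
        if T < 2 or L < 1:
            raise SignalFormatError(f"need T >= 2 and L >= 1, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            t, l = np.argwhere(~np.isfinite(data))[0]
            raise SignalFormatError(
                f"non-finite sample at row {t}, lead {self.lead_labels[l]!r}"
            )
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise SignalFormatError(f"sampling rate must be positive, got {self.fs}")
        if len(self.lead_labels) != L:
            raise SignalFormatError(
                f"{len(self.lead_labels)} labels for {L} leads"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_leads(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def lead(self, label: str) -> np.ndarray:
        """Return one lead's samples by label."""
        try:
            idx = self.lead_labels.index(label)
        except ValueError:
            raise KeyError(f"no lead labelled {label!r}") from None
        return self.data[:, idx]

    def crop_ms(self, start_ms: float, end_ms: float) -> "MultichannelSignal":
        """Half-open crop [start_ms, end_ms) relative to t0."""
        i0 = int(round((start_ms - self.t0) * self.fs / 1000.0))
        i1 = int(round((end_ms - self.t0) * self.fs / 1000.0))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        if i1 - i0 < 2:
            raise ValueError("crop would leave fewer than 2 samples")
        return replace(self, data=self.data[i0:i1], t0=start_ms)


@dataclass(frozen=True)
class ElectrodeArray:
    """Electrode geometry: L x 3 positions in cm plus the ECG role mapping."""

    positions: np.ndarray
    labels: tuple
    ecg_subset: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be L x 3")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("label count does not match position count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        for role, idx in self.ecg_subset.items():
            if not 0 <= idx < pos.shape[0]:
                raise ValueError(f"ecg_subset[{role!r}] = {idx} out of range")

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SegmentSet:
    """Sorted, non-overlapping half-open [start, end) intervals in ms."""

    segments: tuple
    kind: str  # fwave | qrs | twave

    def __post_init__(self):
        segs = tuple((float(a), float(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        if self.kind not in ("fwave", "qrs", "twave"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        prev_end = -np.inf
        for a, b in segs:
            if b <= a:
                raise ValueError(f"empty or inverted interval ({a}, {b})")
            if a < prev_end:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = b
        if self.kind == "fwave":
            for a, b in segs:
                if b - a < 800.0:
                    raise ValueError(
                        f"f-wave segment ({a}, {b}) shorter than 800 ms"
                    )

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def total_ms(self) -> float:
        return sum(b - a for a, b in self.segments)


# ---------------------------------------------------------------------------
# I/O


def read_signal(path, sidecar) -> MultichannelSignal:
    """Read a delimited signal matrix plus its JSON sidecar.

    The matrix file has a header row of lead labels; the sidecar carries at
    least ``fs`` (Hz) and optionally ``t0`` (ms) and ``units``.
    """
    path, sidecar = Path(path), Path(sidecar)
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise SignalFormatError(f"sidecar {sidecar} is not valid JSON: {e}") from e
    if "fs" not in meta:
        raise SignalFormatError(f"sidecar {sidecar} lacks required field 'fs'")
    fs = float(meta["fs"])
    if fs <= 0:
        raise SignalFormatError(f"sidecar field fs must be > 0, got {fs}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except Exception as e:  # header/parse problems
        raise SignalFormatError(f"cannot parse {path}: {e}") from e
    if frame.shape[1] < 1 or frame.shape[0] < 2:
        raise SignalFormatError(f"{path}: need >= 2 rows and >= 1 lead column")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col].map(
                lambda v: not isinstance(v, (int, float, np.number))
            )
            row = int(np.argmax(bad.to_numpy())) if bad.any() else 0
            raise SignalFormatError(
                f"{path}: non-numeric cell at row {row}, lead {col!r}"
            )
    data = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        t, l = np.argwhere(~np.isfinite(data))[0]
        raise SignalFormatError(
            f"{path}: non-finite value at row {t}, lead {frame.columns[l]!r}"
        )
    return MultichannelSignal(
        data=data,
        fs=fs,
        lead_labels=tuple(str(c) for c in frame.columns),
        t0=float(meta.get("t0", 0.0)),
        normalized=bool(meta.get("normalized", False)),
    )


def write_signal(sig: MultichannelSignal, path, sidecar) -> None:
    """Write a signal matrix (CSV/TSV by extension) and its JSON sidecar."""
    path, sidecar = Path(path), Path(sidecar)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    pd.DataFrame(sig.data, columns=list(sig.lead_labels)).to_csv(
        path, sep=sep, index=False, float_format="%.12g"
    )
    sidecar.write_text(
        json.dumps(
            {"fs": sig.fs, "t0": sig.t0, "normalized": sig.normalized},
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Preprocessing


def bandpass_filter(
    sig: MultichannelSignal,
    lo_hz: float = 2.0,
    hi_hz: float = 30.0,
    order: int = 2,
) -> MultichannelSignal:
    """Zero-phase Butterworth band-pass, applied channel-wise.

    Defaults to the 2-30 Hz second-order band used to suppress baseline
    wander and high-frequency noise in f-wave analysis. Forward-backward
    filtering doubles the effective order but keeps ACF lags undistorted.
    """
    if sig.fs <= 2.0 * hi_hz:
        raise ValueError(
            f"fs = {sig.fs} Hz too low for a band up to {hi_hz} Hz"
        )
    if not 0 < lo_hz < hi_hz:
        raise ValueError(f"need 0 < lo_hz < hi_hz, got ({lo_hz}, {hi_hz})")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=sig.fs, output="sos")
    out = sps.sosfiltfilt(sos, sig.data, axis=0)
    return replace(sig, data=out)


def normalize_channels(sig: MultichannelSignal) -> MultichannelSignal:
    """Z-score each channel; constant channels map to zero with a warning."""
    mu = sig.data.mean(axis=0, keepdims=True)
    sd = sig.data.std(axis=0, ddof=0, keepdims=True)
    const = sd[0] == 0.0
    if np.any(const):
        labels = [sig.lead_labels[i] for i in np.flatnonzero(const)]
        warnings.warn(f"constant channel(s) set to zero: {labels}", stacklevel=2)
    sd = np.where(sd == 0.0, 1.0, sd)
    out = (sig.data - mu) / sd
    out[:, const] = 0.0
    return replace(sig, data=out, normalized=True)


def detect_qrs(
    sig: MultichannelSignal,
    lead: str,
    pre_ms: float = 60.0,
    post_ms: float = 100.0,
) -> SegmentSet:
    """Pan-Tompkins QRS detection on one lead.

    Returns QRS intervals [R - pre_ms, R + post_ms) around each detected
    R peak. The classic stages are applied: 5-15 Hz band-pass, derivative,
    squaring, 150 ms moving-window integration, then adaptive thresholding
    with a 200 ms refractory period.
    """
    if sig.fs < 200:
        raise ValueError(f"Pan-Tompkins needs fs >= 200 Hz, got {sig.fs}")
    if sig.duration_ms < 2000.0:
        raise ValueError(
            "insufficient data: Pan-Tompkins needs >= 2 s for threshold training"
        )
    x = sig.lead(lead)
    fs = sig.fs
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(squared, np.ones(win) / win, mode="same")

    # adaptive threshold trained on the first 2 s
    train = integ[: int(2.0 * fs)]
    thr = 0.25 * float(np.max(train)) + 0.75 * float(np.mean(train))
    refractory = int(round(0.200 * fs))
    peaks, _ = sps.find_peaks(integ, height=thr, distance=refractory)
    # reject residual low peaks: below 15% of the global maximum the
    # integrated envelope is f-wave activity, not a ventricular complex
    if peaks.size:
        peaks = peaks[integ[peaks] >= 0.15 * integ.max()]
    # ventricular complexes tower over the envelope mean; a pure f-wave
    # trace has peaks within a few times its own mean energy
    if peaks.size:
        peaks = peaks[integ[peaks] >= 3.0 * float(np.mean(integ))]

    segs = []
    for p in peaks:
        # refine R-peak to the local band-passed extremum
        lo = max(p - win, 0)
        hi = min(p + win, sig.n_samples)
        r = lo + int(np.argmax(np.abs(bp[lo:hi])))
        a = max(sig.t0 + (r / fs) * 1000.0 - pre_ms, sig.t0)
        b = min(sig.t0 + (r / fs) * 1000.0 + post_ms, sig.t0 + sig.duration_ms)
        segs.append((a, b))
    # merge overlaps from closely spaced detections
    merged: list[list[float]] = []
    for a, b in sorted(segs):
        if merged and a < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return SegmentSet(segments=tuple((a, b) for a, b in merged), kind="qrs")


def _twave_window(
    sig: MultichannelSignal, start_ms: float, end_ms: float, win_ms: float
) -> tuple[float, float] | None:
    """Sliding window of maximal cross-channel variance inside a gap."""
    fs = sig.fs
    i0 = int(round((start_ms - sig.t0) * fs / 1000.0))
    i1 = int(round((end_ms - sig.t0) * fs / 1000.0))
    w = int(round(win_ms * fs / 1000.0))
    if i1 - i0 <= w or w < 1:
        return None
    # variance across channels at each sample, summed over the window
    v = sig.data[i0:i1].var(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    scores = csum[w:] - csum[:-w]
    j = int(np.argmax(scores))  # ties -> earliest window
    a = sig.t0 + (i0 + j) / fs * 1000.0
    return a, a + win_ms


def extract_fwave_segments(
    sig: MultichannelSignal,
    qrs: SegmentSet,
    twave_win_ms: float = 200.0,
    min_fwave_ms: float = 800.0,
) -> SegmentSet:
    """Excise T waves between QRS complexes; keep gaps >= ``min_fwave_ms``.

    In each inter-QRS gap the sliding window with maximal cross-channel
    variance is marked as the T wave and removed; the surviving pieces of
    at least ``min_fwave_ms`` are the f-wave segments.
    """
    if qrs.kind != "qrs":
        raise ValueError("second argument must be a QRS segment set")
    t_end = sig.t0 + sig.duration_ms
    # gaps between QRS intervals
    gaps = []
    cursor = sig.t0
    for a, b in qrs:
        if a > cursor:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < t_end:
        gaps.append((cursor, t_end))

    pieces = []
    for ga, gb in gaps:
        # T-wave excision applies only between two QRS complexes
        interior = any(ga >= b for _, b in qrs) and any(gb <= a for a, _ in qrs)
        tw = _twave_window(sig, ga, gb, twave_win_ms) if interior else None
        if tw is None:
            pieces.append((ga, gb))
        else:
            ta, tb = tw
            if ta > ga:
                pieces.append((ga, ta))
            if tb < gb:
                pieces.append((tb, gb))
    keep = tuple((a, b) for a, b in pieces if b - a >= min_fwave_ms)
    return SegmentSet(segments=keep, kind="fwave")


# ---------------------------------------------------------------------------
# 12-lead ECG from a BSPM

_STANDARD_12 = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")


def ecg_from_bspm(sig: MultichannelSignal, arr: ElectrodeArray) -> MultichannelSignal:
    """Derive the standard 12-lead ECG from a vest recording.

    Limb leads follow Einthoven (I = LA-RA, II = LL-RA, III = LL-LA),
    augmented leads follow Goldberger, and precordial leads are referenced
    to the Wilson Central Terminal WCT = (RA + LA + LL)/3.
    """
    missing = [r for r in ECG_ROLES if r not in arr.ecg_subset]
    if missing:
        raise KeyError(f"ecg_subset missing role(s): {missing}")
    pot = {role: sig.data[:, arr.ecg_subset[role]] for role in ECG_ROLES}
    ra, la, ll = pot["RA"], pot["LA"], pot["LL"]
    wct = (ra + la + ll) / 3.0
    leads = {
        "I": la - ra,
        "II": ll - ra,
        "III": ll - la,
        "aVR": ra - (la + ll) / 2.0,
        "aVL": la - (ra + ll) / 2.0,
        "aVF": ll - (ra + la) / 2.0,
    }
    for v in ("V1", "V2", "V3", "V4", "V5", "V6"):
        leads[v] = pot[v] - wct
    data = np.column_stack([leads[name] for name in _STANDARD_12])
    return MultichannelSignal(
        data=data,
        fs=sig.fs,
        lead_labels=_STANDARD_12,
        t0=sig.t0,
        normalized=False,
    )
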