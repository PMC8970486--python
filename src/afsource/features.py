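"""Classifier feature vectors and baseline AF-complexity metrics.

Three feature families feed the classifiers:

* per-source (CL_i, MaxAC_i) pairs — the 2K-dimensional vector describing
  the cycle lengths and periodicity of the extracted sources;
* the s1-to-leads contribution — the mixing column of the most periodic
  source, sign-canonicalized and min-max rescaled, a spatial fingerprint
  used to lateralize the focal site;
* two baseline complexity metrics for comparison: AFFTr2DF (fraction of
  normalized V1 spectral power at or below twice the dominant frequency)
  and NDI (fraction of lead-space variance outside the top three
  principal components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import MultichannelSignal
from .sobss import (
    DegenerateSignalError,
    LagSet,
    SourceDecomposition,
    dominant_cl,
    source_cls,
)

__all__ = [
    "SourceFeatures",
    "BaselineFeatures",
    "build_cl_maxac_vector",
    "s1_to_leads",
    "afft_r2df",
    "ndi",
]


@dataclass(frozen=True)
class SourceFeatures:
    """Per-episode feature bundle for the classifiers."""

    cls: np.ndarray  # K cycle lengths in ms, rank order
    maxacs: np.ndarray  # K MaxAC values in [-1, 1]
    dominant_cl: float | None
    s1_contrib: np.ndarray | None  # L values in [0, 1], or None
    K: int
    lead_count: int

    def cl_maxac_vector(self) -> np.ndarray:
        """Interleaved (CL_1, MaxAC_1, ..., CL_K, MaxAC_K) classifier input."""
        return np.column_stack([self.cls, self.maxacs]).ravel()


@dataclass(frozen=True)
class BaselineFeatures:
    df_hz: float
    afftr_2df: float
    ndi: float | None = None


def build_cl_maxac_vector(
    dec: SourceDecomposition, lags: LagSet | None = None
) -> SourceFeatures:
    """Estimate (CL, MaxAC) for each ranked source and the dominant CL."""
    if lags is None:
        lags = LagSet()
    pairs = source_cls(dec, lags)
    return SourceFeatures(
        cls=np.array([p[0] for p in pairs]),
        maxacs=np.array([p[1] for p in pairs]),
        dominant_cl=dominant_cl(dec, lags),
        s1_contrib=s1_to_leads(dec),
        K=dec.K,
        lead_count=dec.n_leads,
    )


def s1_to_leads(dec: SourceDecomposition) -> np.ndarray:
    """Canonical per-lead contribution of the most periodic source.

    The mixing column of s_1 is sign-agnostic; the sign is fixed so that a
    majority of coefficients are positive (an exact tie keeps the original
    sign), then the column is min-max rescaled to [0, 1]. A constant
    column carries no spatial information and maps to all 0.5.
    """
    col = np.asarray(dec.mixing[:, 0], dtype=float).copy()
    n_pos = int(np.sum(col > 0))
    n_neg = int(np.sum(col < 0))
    if n_neg > n_pos:
        col = -col
    lo, hi = col.min(), col.max()
    if hi == lo:
        warnings.warn("constant s1 mixing column; contributions set to 0.5",
                      stacklevel=2)
        return np.full(col.shape, 0.5)
    return (col - lo) / (hi - lo)


def afft_r2df(
    v1: np.ndarray,
    fs: float,
    df_band_hz: tuple[float, float] = (3.0, 10.0),
) -> BaselineFeatures:
    """Dominant frequency and AFFTr2DF of a single (V1) lead.

    The power spectrum is the squared-magnitude FFT of the mean-removed
    signal (rectangular window), normalized to unit sum over positive
    frequencies up to Nyquist. DF is the frequency of maximal power in
    ``df_band_hz``, and AFFTr2DF is the summed normalized power over the
    bins in (0, 2*DF].
    """
    v1 = np.asarray(v1, dtype=float).ravel()
    if v1.size < fs:
        raise ValueError("need at least 1 s of signal for a spectral estimate")
    x = v1 - v1.mean()
    if not np.any(x):
        raise DegenerateSignalError("all-zero signal has no spectrum")
    psd = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    pos = freqs > 0
    psd = psd[pos] / psd[pos].sum()
    freqs = freqs[pos]
    band = (freqs >= df_band_hz[0]) & (freqs <= df_band_hz[1])
    if not np.any(band):
        raise ValueError(f"no FFT bin falls in the DF band {df_band_hz}")
    df = float(freqs[band][np.argmax(psd[band])])
    ratio = float(psd[freqs <= 2.0 * df].sum())
    return BaselineFeatures(df_hz=df, afftr_2df=ratio)


def feature_matrices(
    signals,
    k_grid,
    lags: LagSet | None = None,
    kind: str = "cl_maxac",
    normalize: bool = True,
):
    """Per-K classifier feature matrices for a list of signals.

    Each signal is channel-wise z-scored (unless already normalized),
    decomposed with every K in ``k_grid``, and summarized as either the
    2K-dimensional (CL, MaxAC) vector (``kind='cl_maxac'``) or the
    L-dimensional s1-to-leads contribution (``kind='s1'``). Returns a
    dict ``{K: (n_signals, dim) ndarray}``.
    """
    from .signal_io import normalize_channels
    from .sobss import extract_sources

    if lags is None:
        lags = LagSet()
    if kind not in ("cl_maxac", "s1"):
        raise ValueError(f"unknown feature kind {kind!r}")
    out = {}
    for K in k_grid:
        rows = []
        for sig in signals:
            s = normalize_channels(sig) if (normalize and not sig.normalized) else sig
            dec = extract_sources(s, K, lags)
            if kind == "cl_maxac":
                feats = build_cl_maxac_vector(dec, lags).cl_maxac_vector()
            else:
                feats = s1_to_leads(dec)
            rows.append(feats)
        out[K] = np.vstack(rows)
    return out


def ndi(bspm: MultichannelSignal) -> float:
    """Nondipolar component index of a multichannel recording.

    PCA of the centered lead-space covariance; NDI is the fraction of
    total variance not captured by the top three principal components.
    Rank <= 3 data has NDI 0 (fully dipolar in this sense).
    """
    if bspm.n_leads < 4:
        raise ValueError(f"NDI needs >= 4 leads, got {bspm.n_leads}")
    X = bspm.data - bspm.data.mean(axis=0, keepdims=True)
    # singular values give lead-space eigenvalues without forming L x L cov
    svals = np.linalg.svd(X, compute_uv=False)
    var = svals**2
    total = var.sum()
    if total == 0.0:
        raise DegenerateSignalError("signal has zero variance")
    return float(1.0 - var[:3].sum() / total)
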