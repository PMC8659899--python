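"""Seven pulse-extraction algorithms plus shared preprocessing and BPM estimation.

Every method takes a raw :class:`~roipulse.geometry.RGBTrace` (mean color per
frame, 0-255 scale) and returns a zero-mean :class:`BVPSignal` band-limited to
the pulse band.  Methods needing intact channel means (CHROM, POS, PBV)
normalise internally before filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import signal as sps

from roipulse.geometry import RGBTrace
from roipulse.rppg.jade import DecompositionError, jade

__all__ = [
    "BVPSignal",
    "BPMSeries",
    "preprocess",
    "green",
    "ica_jade",
    "chrom",
    "pos",
    "ssr",
    "pbv",
    "lgi",
    "estimate_bpm",
    "extract",
    "METHODS",
    "PULSE_BAND",
    "PBV_SIGNATURE",
]

#: Pulse band in Hz (39-240 BPM).
PULSE_BAND = (0.65, 4.0)

#: Default pulse "blood volume" color signature (literature value), unit norm.
PBV_SIGNATURE = np.array([0.33, 0.78, 0.53]) / np.linalg.norm([0.33, 0.78, 0.53])

#: CHROM/POS sliding-window length in seconds.
WINDOW_SECONDS = 1.6

_EPS = 1e-12


class RPPGError(ValueError):
    pass


class InsufficientDataError(RPPGError):
    pass


class NormalizationError(RPPGError):
    pass


class DegenerateCorrelationError(DecompositionError):
    pass


@dataclass
class BVPSignal:
    """A 1-D pulse estimate (arbitrary scale, zero mean)."""

    samples: np.ndarray
    fps: float
    method: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()


@dataclass
class BPMSeries:
    """Windowed heart-rate estimates."""

    window_centers: np.ndarray  # seconds
    bpm: np.ndarray
    band: tuple[float, float] = PULSE_BAND


def _bandpass_sos(fps: float) -> np.ndarray:
    return sps.butter(4, PULSE_BAND, btype="bandpass", fs=fps, output="sos")


def _bandpass(x: np.ndarray, fps: float, axis: int = -1) -> np.ndarray:
    return sps.sosfiltfilt(_bandpass_sos(fps), x, axis=axis)


def _finalize(samples: np.ndarray, fps: float, method: str) -> BVPSignal:
    samples = np.asarray(samples, dtype=float).ravel()
    return BVPSignal(samples=samples - samples.mean(), fps=fps, method=method)


def preprocess(trace: RGBTrace) -> RGBTrace:
    """Per-channel linear detrend followed by zero-phase band-pass filtering."""
    if trace.n_frames < 2 * trace.fps:
        raise InsufficientDataError(
            f"need >= 2 s of samples, got {trace.n_frames} at {trace.fps} fps")
    x = sps.detrend(trace.values, axis=0, type="linear")
    y = _bandpass(x, trace.fps, axis=0)
    return RGBTrace(values=y, fps=trace.fps, region_id=trace.region_id,
                    pixel_samples=trace.pixel_samples, held_frames=list(trace.held_frames))


def green(trace: RGBTrace) -> BVPSignal:
    """Green channel of the preprocessed trace."""
    return _finalize(preprocess(trace).values[:, 1], trace.fps, "GREEN")


def ica_jade(trace: RGBTrace, select: str = "spectral_peak") -> BVPSignal:
    """JADE ICA on the three channels; pick a component.

    ``select``: "spectral_peak" (component with the largest normalised
    in-band spectral peak, deterministic default) or "second" (the second
    component, the classic empirical rule).
    """
    if trace.n_frames < 10 * trace.fps:
        raise InsufficientDataError("ICA needs >= 10 s of samples")
    pp = preprocess(trace)
    S, _ = jade(pp.values.T)
    if select == "second":
        comp = S[1]
    elif select == "spectral_peak":
        best, best_score = 0, -np.inf
        for i in range(S.shape[0]):
            f, p = sps.periodogram(S[i], fs=trace.fps)
            band = (f >= PULSE_BAND[0]) & (f <= PULSE_BAND[1])
            if p[band].sum() <= _EPS:
                continue
            score = p[band].max() / (p[band].sum() + _EPS)
            if score > best_score:
                best, best_score = i, score
        comp = S[best]
    else:
        raise RPPGError(f"unknown ICA selection rule {select!r}")
    return _finalize(comp, trace.fps, "ICA")


def _window_starts(T: int, win: int, hop: int) -> list[int]:
    starts = list(range(0, max(T - win, 0) + 1, hop))
    if not starts:
        starts = [0]
    return starts


def chrom(trace: RGBTrace) -> BVPSignal:
    """Chrominance-based pulse: X=3R-2G, Y=1.5R+G-1.5B on mean-normalised windows."""
    vals = trace.values
    mean = vals.mean(axis=0)
    if np.any(mean <= _EPS):
        raise NormalizationError(f"channel means must be positive, got {mean}")
    fps = trace.fps
    T = vals.shape[0]
    win = min(T, max(2, int(round(WINDOW_SECONDS * fps)) & ~1))
    hop = max(1, win // 2)
    out = np.zeros(T)
    weight = np.zeros(T)
    hann = np.hanning(win)
    for s in _window_starts(T, win, hop):
        seg = vals[s:s + win]
        w = seg.shape[0]
        m = seg.mean(axis=0)
        if np.any(m <= _EPS):
            raise NormalizationError("window channel mean is non-positive")
        cn = seg / m
        X = 3.0 * cn[:, 0] - 2.0 * cn[:, 1]
        Y = 1.5 * cn[:, 0] + cn[:, 1] - 1.5 * cn[:, 2]
        sy = Y.std()
        h = X - (X.std() / sy) * Y if sy > _EPS else X
        h = h - h.mean()
        taper = hann[:w] if w == win else np.hanning(max(w, 2))[:w]
        out[s:s + w] += h * taper
        weight[s:s + w] += taper
    out = np.where(weight > _EPS, out / np.maximum(weight, _EPS), 0.0)
    return _finalize(_bandpass(out, fps), fps, "CHROM")


def pos(trace: RGBTrace) -> BVPSignal:
    """Plane-orthogonal-to-skin projection with per-sample sliding windows."""
    vals = trace.values
    mean = vals.mean(axis=0)
    if np.any(mean <= _EPS):
        raise NormalizationError(f"channel means must be positive, got {mean}")
    fps = trace.fps
    T = vals.shape[0]
    w = min(T, max(2, int(round(WINDOW_SECONDS * fps))))
    P = np.array([[0.0, 1.0, -1.0], [-2.0, 1.0, 1.0]])
    H = np.zeros(T)
    for n in range(w - 1, T):
        m = n - w + 1
        seg = vals[m:n + 1]
        mu = seg.mean(axis=0)
        if np.any(np.abs(mu) <= _EPS):
            raise NormalizationError("window channel mean is zero")
        cn = seg / mu
        S = cn @ P.T  # (w, 2)
        s2 = S[:, 1].std()
        h = S[:, 0] + (S[:, 0].std() / s2) * S[:, 1] if s2 > _EPS else S[:, 0]
        H[m:n + 1] += h - h.mean()
    return _finalize(_bandpass(H, fps), fps, "POS")


def ssr(pixel_samples: Sequence[np.ndarray], fps: float,
        stride_s: float = 1.0) -> BVPSignal:
    """Spatial subspace rotation on retained per-frame pixel colors."""
    if pixel_samples is None or len(pixel_samples) < 2 * fps:
        raise InsufficientDataError("SSR needs >= 2 s of per-frame pixel samples")
    T = len(pixel_samples)
    lam = np.zeros((T, 3))
    U = np.zeros((T, 3, 3))
    for k, V in enumerate(pixel_samples):
        V = np.asarray(V, dtype=float)
        if V.ndim != 2 or V.shape[1] != 3 or V.shape[0] < 3:
            raise DegenerateCorrelationError(
                f"frame {k}: need >= 3 pixels with 3 channels, got {V.shape}")
        C = (V.T @ V) / V.shape[0]
        d, E = np.linalg.eigh(C)
        order = np.argsort(d)[::-1]
        d, E = d[order], E[:, order]
        if d[2] <= 1e-9 * max(d[0], _EPS):
            raise DegenerateCorrelationError(
                f"frame {k}: pixel-color correlation is (near) rank-deficient")
        lam[k], U[k] = d, E
    stride = max(2, int(round(stride_s * fps)))
    pulse = np.zeros(T)
    for k in range(stride - 1, T):
        tau = k - stride + 1
        u2, u3 = U[tau, :, 1], U[tau, :, 2]
        block = np.zeros((stride, 3))
        for j, t in enumerate(range(tau, k + 1)):
            u1t = U[t, :, 0]
            block[j] = (
                np.sqrt(lam[t, 0] / lam[tau, 1]) * (u1t @ u2) * u2
                + np.sqrt(lam[t, 0] / lam[tau, 2]) * (u1t @ u3) * u3
            )
        s1 = block[:, 1].std()
        p = block[:, 0] - (block[:, 0].std() / s1) * block[:, 1] if s1 > _EPS else block[:, 0]
        pulse[tau:k + 1] += p - p.mean()
    return _finalize(_bandpass(pulse, fps), fps, "SSR")


def pbv(trace: RGBTrace, signature: Optional[np.ndarray] = None) -> BVPSignal:
    """Signature-directed weighting: solve (Cn Cn^T) w = signature, pulse = w^T Cn."""
    sig = PBV_SIGNATURE if signature is None else np.asarray(signature, dtype=float)
    nrm = np.linalg.norm(sig)
    if nrm <= _EPS:
        raise RPPGError("signature must be non-zero")
    sig = sig / nrm
    vals = trace.values
    mean = vals.mean(axis=0)
    cn = np.where(np.abs(mean) > _EPS, vals / np.where(np.abs(mean) > _EPS, mean, 1.0) - 1.0, vals)
    cn = _bandpass(cn, trace.fps, axis=0).T  # (3, T)
    Q = cn @ cn.T
    cond = np.linalg.cond(Q)
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn("near-singular channel covariance; regularizing PBV solve",
                      RuntimeWarning, stacklevel=2)
        Q = Q + 1e-9 * np.trace(Q) * np.eye(3) + 1e-18 * np.eye(3)
    w = np.linalg.solve(Q, sig)
    return _finalize(w @ cn, trace.fps, "PBV")


def lgi(trace: RGBTrace, out_channel: int = 1) -> BVPSignal:
    """Local group invariance: project out the dominant singular direction."""
    pp = preprocess(trace)
    X = pp.values.T  # (3, T)
    if np.linalg.norm(X) <= _EPS:
        raise DecompositionError("zero-energy trace")
    Um, s, _ = np.linalg.svd(X, full_matrices=False)
    u1 = Um[:, 0:1]
    Y = (np.eye(3) - u1 @ u1.T) @ X
    return _finalize(Y[out_channel], trace.fps, "LGI")


def estimate_bpm(bvp: BVPSignal, window_s: float = 10.0, hop_s: float = 1.0,
                 band: tuple[float, float] = PULSE_BAND) -> BPMSeries:
    """Welch-peak heart rate per sliding window, restricted to ``band``."""
    x = bvp.samples
    fps = bvp.fps
    win = int(round(window_s * fps))
    if win > x.size:
        raise InsufficientDataError(
            f"window of {win} samples exceeds signal length {x.size}")
    hop = max(1, int(round(hop_s * fps)))
    nfft = int(2 ** np.ceil(np.log2(max(win * 8, 4096))))
    centers, bpms = [], []
    for s in range(0, x.size - win + 1, hop):
        seg = x[s:s + win]
        f, p = sps.welch(seg, fs=fps, nperseg=min(win, seg.size), nfft=nfft)
        sel = (f >= band[0]) & (f <= band[1])
        fpk = f[sel][np.argmax(p[sel])]
        centers.append((s + win / 2.0) / fps)
        bpms.append(60.0 * fpk)
    return BPMSeries(window_centers=np.array(centers), bpm=np.array(bpms), band=band)


def _ssr_from_trace(trace: RGBTrace) -> BVPSignal:
    if trace.pixel_samples is None:
        raise RPPGError("SSR requires a trace extracted with keep_pixels=True")
    return ssr(trace.pixel_samples, trace.fps)


METHODS: dict[str, Callable[[RGBTrace], BVPSignal]] = {
    "GREEN": green,
    "ICA": ica_jade,
    "CHROM": chrom,
    "POS": pos,
    "SSR": _ssr_from_trace,
    "PBV": pbv,
    "LGI": lgi,
}


def extract(method: str, trace: RGBTrace, **kwargs) -> BVPSignal:
    """Run one registered method by name on a raw RGB trace."""
    key = method.upper()
    if key not in METHODS:
        raise RPPGError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return METHODS[key](trace, **kwargs)
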