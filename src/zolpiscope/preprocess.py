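"""Deterministic preprocessing: FIR filtering, resampling, bad-channel
spherical interpolation, and common-average re-referencing.

Filters are Hamming-windowed linear-phase FIRs applied zero-phase by
group-delay compensation, independently per continuity segment (artifact
cuts create discontinuities a filter must not smear across). The standard
study configuration is a 45 Hz low-pass (order 660, 5 Hz transition) at the
acquisition rate, downsampling to 250 Hz, then a 0.5 Hz high-pass
(order 826, 1 Hz transition).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from . import _spherical
from .io_montage import Montage, Recording

__all__ = [
    "FilterSpec",
    "fir_filter",
    "resample",
    "interpolate_channels",
    "rereference_average",
    "standard_preprocess",
    "LOWPASS",
    "HIGHPASS",
    "FS_TARGET",
]

FS_TARGET = 250.0


@dataclass(frozen=True)
class FilterSpec:
    """Hamming-window FIR design. ``cutoff_6db`` is the half-amplitude
    (-6 dB) frequency — the firwin convention. ``order`` is taps - 1 and
    must be even so the compensated delay is an integer."""

    kind: str  # lowpass | highpass | bandpass
    order: int
    transition_width: float
    cutoff_6db: float | tuple[float, float]
    window: str = "hamming"

    def __post_init__(self):
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order % 2 != 0:
            raise ValueError("order must be even (linear-phase type I)")

    def taps(self, fs: float) -> np.ndarray:
        cut = self.cutoff_6db
        cuts = np.atleast_1d(cut).astype(float)
        if np.any(cuts <= 0) or np.any(cuts >= fs / 2):
            raise ValueError(f"cutoff {cut} outside (0, {fs / 2}) at fs={fs}")
        pass_zero = {"lowpass": True, "highpass": False, "bandpass": False}[self.kind]
        return signal.firwin(self.order + 1, cuts, window=self.window,
                             pass_zero=pass_zero, fs=fs)


LOWPASS = FilterSpec("lowpass", order=660, transition_width=5.0, cutoff_6db=45.0)
HIGHPASS = FilterSpec("highpass", order=826, transition_width=1.0, cutoff_6db=0.5)


def fir_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase FIR filtering, applied per continuity segment.

    The linear-phase filter's group delay (order/2 samples) is compensated,
    so the output is aligned with the input and has the same shape.
    """
    taps = spec.taps(rec.fs)
    out = rec.data.copy()
    for a, b in rec.segments:
        if b - a <= 3 * spec.order:
            raise ValueError(
                f"segment [{a}, {b}) too short for order-{spec.order} filter"
            )
        seg = rec.data[:, a:b]
        # 'same' mode on odd-length symmetric taps == group-delay compensation
        out[:, a:b] = signal.fftconvolve(seg, taps[None, :], mode="same", axes=1)
    return rec.copy_with(data=out)


def resample(rec: Recording, fs_new: float) -> Recording:
    """Resample to ``fs_new``; anti-alias filtering is the caller's duty.

    Each continuity segment is resampled independently (polyphase) to
    ``floor(len * fs_new / fs)`` samples and the segments are re-laid
    contiguously; boundaries rescale accordingly.
    """
    if fs_new <= 0:
        raise ValueError("fs_new must be positive")
    if fs_new == rec.fs:
        return rec.copy_with()
    ratio = Fraction(fs_new / rec.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    chunks, segments, pos = [], [], 0
    for a, b in rec.segments:
        n_new = int(np.floor((b - a) * fs_new / rec.fs))
        res = signal.resample_poly(rec.data[:, a:b], up, down, axis=1)
        res = res[:, :n_new]
        if res.shape[1] < n_new:  # pad edge (off-by-one from polyphase length)
            res = np.pad(res, ((0, 0), (0, n_new - res.shape[1])), mode="edge")
        chunks.append(res)
        segments.append((pos, pos + n_new))
        pos += n_new
    return rec.copy_with(data=np.concatenate(chunks, axis=1),
                         segments=segments, fs=float(fs_new))


def interpolate_channels(rec: Recording, bad: set[str] | list[str],
                         montage: Montage) -> Recording:
    """Replace ``bad`` channels by spherical-spline interpolation.

    Spline order m=4, 50 Legendre terms, regularization 1e-5. Good channels
    are untouched; a constant field is reproduced exactly on the bad
    channels.
    """
    bad = set(bad)
    if not bad:
        return rec.copy_with()
    unknown = bad - set(rec.labels)
    if unknown:
        raise ValueError(f"unknown channel(s) {sorted(unknown)}")
    good_idx = [i for i, l in enumerate(rec.labels) if l not in bad]
    bad_idx = [i for i, l in enumerate(rec.labels) if l in bad]
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    pos_good = montage.position_array([rec.labels[i] for i in good_idx])
    pos_bad = montage.position_array([rec.labels[i] for i in bad_idx])
    W = _spherical.interpolation_matrix(pos_good, pos_bad)
    out = rec.data.copy()
    out[bad_idx] = W @ rec.data[good_idx]
    return rec.copy_with(data=out)


def rereference_average(rec: Recording) -> Recording:
    """Common-average reference: per-sample channel mean becomes zero."""
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=out, reference="common_average")


def standard_preprocess(rec: Recording, montage: Montage | None = None,
                        bad: set[str] | None = None,
                        fs_target: float = FS_TARGET) -> Recording:
    """The study's preprocessing chain.

    Low-pass (45 Hz) -> downsample to ``fs_target`` -> high-pass (0.5 Hz)
    -> optional bad-channel interpolation -> common-average reference.
    Artifact-component removal (ICA) is a manual step outside this package.
    """
    out = fir_filter(rec, LOWPASS)
    out = resample(out, fs_target)
    out = fir_filter(out, HIGHPASS)
    if bad:
        if montage is None:
            raise ValueError("montage required to interpolate bad channels")
        out = interpolate_channels(out, bad, montage)
    return rereference_average(out)
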