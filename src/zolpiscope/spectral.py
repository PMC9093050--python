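"""Welch spectra, relative band power, and brain symmetry indices.

Relative power in a band is the summed PSD over that band's inclusive
0.5 Hz bins divided by the summed PSD over 1.0-42.0 Hz. Global band power
averages the channel-level fractions across channels. Two left-right
asymmetry summaries are provided: pdBSI averages the normalized asymmetry
|(R-L)/(R+L)| over homologous channel pairs and band bins, while rBSI
first averages the PSD within each hemisphere and then computes the same
normalized asymmetry per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_montage import BandScheme, Montage, Recording, PRIMARY_BANDS

__all__ = ["PsdEstimate", "SymmetryIndices", "welch_psd", "relative_power",
           "symmetry_indices", "PRIMARY_BANDS"]


@dataclass
class PsdEstimate:
    """Channel-wise Welch PSD on a regular frequency grid (uV^2/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs
    n_windows: int
    labels: list[str]

    def band_mask(self, low: float, high: float) -> np.ndarray:
        """Inclusive-edge mask of bins in [low, high]."""
        return (self.freqs >= low - 1e-9) & (self.freqs <= high + 1e-9)


def welch_psd(rec: Recording, window_s: float = 2.0,
              overlap: float = 0.5) -> PsdEstimate:
    """Hamming-window Welch periodogram respecting continuity segments.

    Windows are tiled within each continuity segment with the given overlap
    and never span a segment break; all windows are averaged with equal
    weight. The default 2 s window at 250 Hz gives 500-sample windows and
    0.5 Hz resolution.
    """
    nper = int(round(window_s * rec.fs))
    step = nper - int(round(nper * overlap))
    win = signal.get_window("hamming", nper)
    scale = 1.0 / (rec.fs * (win ** 2).sum())
    acc = None
    n_windows = 0
    for a, b in rec.segments:
        start = a
        while start + nper <= b:
            seg = rec.data[:, start:start + nper] * win[None, :]
            spec = np.fft.rfft(seg, axis=1)
            p = (spec.real ** 2 + spec.imag ** 2) * scale
            p[:, 1:-1] *= 2.0  # one-sided
            acc = p if acc is None else acc + p
            n_windows += 1
            start += step
    if n_windows == 0:
        raise ValueError("no full window fits inside any continuity segment")
    freqs = np.fft.rfftfreq(nper, d=1.0 / rec.fs)
    return PsdEstimate(freqs=freqs, psd=acc / n_windows,
                       n_windows=n_windows, labels=list(rec.labels))


def relative_power(psd: PsdEstimate, scheme: BandScheme):
    """Channel and global relative band power plus the global relative PSD.

    Returns ``(channel_rel, global_rel, global_rel_psd)`` where
    ``channel_rel[band]`` is a per-channel vector of fractions,
    ``global_rel[band]`` is the channel-mean fraction, and
    ``global_rel_psd`` is the channel-mean PSD normalized to unit sum over
    the scheme's total range.
    """
    lo, hi = scheme.total_range
    total_mask = psd.band_mask(lo, hi)
    total = psd.psd[:, total_mask].sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total power in the reference range")
    channel_rel, global_rel = {}, {}
    for name, blo, bhi in scheme.bands:
        frac = psd.psd[:, psd.band_mask(blo, bhi)].sum(axis=1) / total
        channel_rel[name] = frac
        global_rel[name] = float(frac.mean())
    mean_psd = psd.psd.mean(axis=0)
    global_rel_psd = mean_psd[total_mask] / mean_psd[total_mask].sum()
    return channel_rel, global_rel, global_rel_psd


@dataclass
class SymmetryIndices:
    """Per-band left-right asymmetry in [0, 1] (0 = perfect symmetry)."""

    pdbsi: dict[str, float]
    rbsi: dict[str, float]


def symmetry_indices(psd: PsdEstimate, montage: Montage,
                     scheme: BandScheme) -> SymmetryIndices:
    """Pairwise-derived and revised brain symmetry indices.

    Midline channels are excluded. Bins where R + L = 0 are skipped; a band
    with no usable bin is an error.
    """
    idx = {l: i for i, l in enumerate(psd.labels)}
    pairs = [(idx[l], idx[r]) for l, r in montage.homologous_pairs
             if l in idx and r in idx]
    if not pairs:
        raise ValueError("montage pairing covers no PSD channels")
    left = psd.psd[[p[0] for p in pairs]]
    right = psd.psd[[p[1] for p in pairs]]
    lbar, rbar = left.mean(axis=0), right.mean(axis=0)
    pdbsi, rbsi = {}, {}
    for name, blo, bhi in scheme.bands:
        mask = psd.band_mask(blo, bhi)
        L, R = left[:, mask], right[:, mask]
        denom = R + L
        ok = denom > 0
        if not np.any(ok):
            raise ValueError(f"all bins degenerate in band {name}")
        pdbsi[name] = float((np.abs(R - L)[ok] / denom[ok]).mean())
        lb, rb = lbar[mask], rbar[mask]
        denom_h = rb + lb
        ok_h = denom_h > 0
        if not np.any(ok_h):
            raise ValueError(f"all hemisphere bins degenerate in band {name}")
        rbsi[name] = float((np.abs(rb - lb)[ok_h] / denom_h[ok_h]).mean())
    return SymmetryIndices(pdbsi=pdbsi, rbsi=rbsi)
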