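"""Phase-locking-value connectivity after a surface-Laplacian transform.

The pipeline is: common-average-referenced EEG -> spherical-spline surface
Laplacian (current source density, to reduce volume conduction) ->
band-pass FIR -> Hilbert analytic phase per continuity segment -> trim 10%
per segment side against filter/Hilbert edge effects -> tile 2 s
non-overlapping epochs -> PLV.

For channels i, j with per-epoch phases phi_i, phi_j over N samples and M
epochs::

    PLV_ij = (1/M) sum_m | (1/N) sum_n exp(-i (phi_j - phi_i)) |

i.e. the per-epoch magnitude of the mean phase-difference phasor, averaged
over epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import _spherical
from .io_montage import Montage, Recording
from .preprocess import FilterSpec, fir_filter

__all__ = ["EpochedPhase", "ConnectivityMatrix", "surface_laplacian",
           "extract_phase", "plv", "mean_fcscc", "band_filter_spec"]


@dataclass
class EpochedPhase:
    """Instantaneous phases in (-pi, pi], shaped epochs x channels x samples."""

    phases: np.ndarray
    band: str
    epoch_s: float
    labels: list[str]

    @property
    def n_epochs(self) -> int:
        return self.phases.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel PLV matrix in [0, 1], unit diagonal."""

    values: np.ndarray
    band: str
    labels: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v

    def edge_values(self, edges) -> np.ndarray:
        idx = {l: i for i, l in enumerate(self.labels)}
        out = []
        for a, b in edges:
            i = idx[a] if isinstance(a, str) else a
            j = idx[b] if isinstance(b, str) else b
            out.append(self.values[i, j])
        return np.array(out)


def surface_laplacian(rec: Recording, montage: Montage) -> Recording:
    """Spherical-spline surface Laplacian (CSD) of an average-referenced
    recording. Spline order 4, lambda 1e-5, unit-sphere head radius."""
    if rec.reference != "common_average":
        raise ValueError("surface_laplacian expects a common-average reference")
    missing = [l for l in rec.labels if l not in montage.positions]
    if missing:
        raise ValueError(f"labels missing from montage: {missing}")
    pos = montage.position_array(rec.labels)
    L = _spherical.csd_matrix(pos)
    return rec.copy_with(data=L @ rec.data, reference="laplacian")


def band_filter_spec(low: float, high: float, fs: float) -> FilterSpec:
    """Hamming-FIR band-pass for phase extraction.

    The transition width is low/2 clipped to [1, 2] Hz, so
    neighbouring-band power leaks only marginally into the pass-band (wide
    transitions would let spectral shifts in adjacent bands masquerade as
    phase-locking changes); the order additionally spans at least 3 cycles
    of the low edge."""
    tw = float(np.clip(low / 2.0, 1.0, 2.0))
    order = max(int(np.ceil(3.3 * fs / tw)), int(np.ceil(3.0 * fs / low)))
    order += order % 2  # keep linear-phase type I
    return FilterSpec("bandpass", order=order,
                      transition_width=tw, cutoff_6db=(low, high))


def extract_phase(rec: Recording, band: tuple[float, float],
                  epoch_s: float = 2.0, edge_trim: float = 0.10,
                  band_name: str = "") -> EpochedPhase:
    """Band-limited Hilbert phases, epoched within continuity segments.

    Per segment: band-pass -> analytic signal -> drop ``edge_trim`` of the
    samples on each side -> tile non-overlapping ``epoch_s`` epochs from
    the trimmed start (tail shorter than one epoch is dropped).
    """
    if rec.reference != "laplacian":
        raise ValueError("extract_phase expects surface-Laplacian signals")
    low, high = band
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(f"band {band} outside (0, {rec.fs / 2})")
    spec = band_filter_spec(low, high, rec.fs)
    filtered = fir_filter(rec, spec)
    nper = int(round(epoch_s * rec.fs))
    epochs = []
    for a, b in rec.segments:
        seg = filtered.data[:, a:b]
        phase = np.angle(sps.hilbert(seg, axis=1))
        trim = int(np.floor(edge_trim * seg.shape[1]))
        usable = phase[:, trim:seg.shape[1] - trim]
        n_ep = usable.shape[1] // nper
        for k in range(n_ep):
            epochs.append(usable[:, k * nper:(k + 1) * nper])
    if not epochs:
        raise ValueError("no trimmed segment fits a full epoch")
    return EpochedPhase(phases=np.stack(epochs), band=band_name or f"{low}-{high}Hz",
                        epoch_s=epoch_s, labels=list(rec.labels))


def plv(phase: EpochedPhase) -> ConnectivityMatrix:
    """Epoch-averaged phase-locking value matrix."""
    M, C, N = phase.phases.shape
    if M < 1 or N < 2:
        raise ValueError("need at least one epoch of at least two samples")
    acc = np.zeros((C, C))
    for m in range(M):
        Z = np.exp(1j * phase.phases[m])  # C x N
        cross = (Z @ Z.conj().T) / N      # mean_n e^{i(phi_i - phi_j)}
        acc += np.abs(cross)
    values = acc / M
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(values=values, band=phase.band,
                              labels=list(phase.labels))


def mean_fcscc(conn: ConnectivityMatrix, component) -> float:
    """Mean functional connectivity strength over a connected component's
    edges (FCSCC). ``component`` is an iterable of (label_or_index, ...)
    channel pairs."""
    edges = list(component)
    if not edges:
        raise ValueError("empty component")
    return float(conn.edge_values(edges).mean())
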