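"""Recordings, montage geometry, and frequency-band schemes.

This module owns the in-memory containers every pipeline stage consumes: the
:class:`Recording` (channels x samples with continuity bookkeeping), the
:class:`Montage` (10-10 electrode geometry with homologous-pair and midline
bookkeeping used by the symmetry indices), and the :class:`BandScheme`
(named frequency bands on a fixed Hz grid).

Readers cover BrainVision and EDF (via :mod:`mne`) plus a plain-text matrix
format used for synthetic data exchange.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "Montage",
    "BandScheme",
    "read_recording",
    "write_matrix_text",
    "default_montage",
    "spectral_bands",
    "connectivity_bands",
    "canonical_maps",
]

_LABEL_NUM = re.compile(r"^([A-Za-z]+)(\d+)$")


@dataclass
class Recording:
    """A multichannel EEG signal with continuity-segment bookkeeping.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Ordered channel names; must be unique.
    segments : list of (int, int)
        Half-open sample intervals ``[start, stop)`` of continuous data.
        Artifact-removal cut points break continuity; filtering, Welch
        windows, and phase epochs never cross a segment boundary.
    reference : str
        One of ``original``, ``common_average``, ``laplacian``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    segments: list[tuple[int, int]] = field(default=None)  # type: ignore[assignment]
    reference: str = "original"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if self.reference not in ("original", "common_average", "laplacian"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.segments is None:
            self.segments = [(0, self.data.shape[1])]
        self.segments = [(int(a), int(b)) for a, b in self.segments]
        n = self.data.shape[1]
        prev = 0
        for a, b in self.segments:
            if not (0 <= a < b <= n):
                raise ValueError(f"segment ({a}, {b}) outside [0, {n})")
            if a < prev:
                raise ValueError("segments must be sorted and disjoint")
            prev = b

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "Recording":
        if "data" in kw and "segments" not in kw:
            kw["segments"] = [tuple(s) for s in self.segments]
        return replace(self, **kw)

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Reorder/subset channels to ``labels``."""
        idx = [self.labels.index(l) for l in labels]
        return self.copy_with(data=self.data[idx], labels=list(labels))


@dataclass(frozen=True)
class Montage:
    """Electrode geometry with left/right bookkeeping.

    ``positions`` maps each label to a 3-D unit-sphere coordinate
    (+x right, +y anterior, +z superior). Every non-midline channel belongs
    to exactly one homologous (left, right) pair; midline channels are the
    labels ending in ``z``.
    """

    labels: tuple[str, ...]
    positions: dict[str, np.ndarray]
    homologous_pairs: tuple[tuple[str, str], ...]
    midline: tuple[str, ...]

    def __post_init__(self):
        paired = [l for p in self.homologous_pairs for l in p]
        cover = set(paired) | set(self.midline)
        if len(paired) != len(set(paired)):
            raise ValueError("channel in more than one homologous pair")
        if cover != set(self.labels):
            raise ValueError("pairs + midline do not cover the montage")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def n_connections(self) -> int:
        """Number of undirected channel pairs, C(n, 2)."""
        n = self.n_channels
        return n * (n - 1) // 2

    def homologue(self, label: str) -> str | None:
        """Mirror channel of ``label`` (None for midline channels)."""
        for left, right in self.homologous_pairs:
            if label == left:
                return right
            if label == right:
                return left
        if label in self.midline:
            return None
        raise KeyError(label)

    def position_array(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labels = self.labels if labels is None else labels
        return np.array([self.positions[l] for l in labels])


@dataclass(frozen=True)
class BandScheme:
    """Ordered named frequency bands with inclusive Hz edges."""

    bands: tuple[tuple[str, float, float], ...]
    total_range: tuple[float, float]

    def __post_init__(self):
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name}: low must be < high")

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return (lo, hi)
        raise KeyError(name)


def _split_label(label: str) -> tuple[str, int] | None:
    m = _LABEL_NUM.match(label)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def pair_by_parity(labels: Sequence[str]) -> tuple[list[tuple[str, str]], list[str]]:
    """Derive homologous pairs from 10-10 label parity.

    Odd trailing digits are left hemisphere, even are right; the homologue
    of e.g. C3 is C4. Labels ending in ``z`` are midline.
    """
    pairs, midline, seen = [], [], set(labels)
    for label in labels:
        if label.lower().endswith("z"):
            midline.append(label)
            continue
        parsed = _split_label(label)
        if parsed is None:
            raise ValueError(f"cannot parse 10-10 label {label!r}")
        prefix, num = parsed
        if num % 2 == 1:
            mate = f"{prefix}{num + 1}"
            if mate not in seen:
                raise ValueError(f"no right homologue for {label}")
            pairs.append((label, mate))
        else:
            mate = f"{prefix}{num - 1}"
            if mate not in seen:
                raise ValueError(f"no left homologue for {label}")
    return pairs, midline


def _data_path(name: str):
    return resources.files("zolpiscope.data").joinpath(name)


def default_montage() -> Montage:
    """The packaged 59-channel 10-10 montage.

    A faithful 10-10 reconstruction (27 homologous pairs + 5 midline
    channels) with unit-sphere positions; the reference study's exact label
    list is not published in full, and any 10-10 subset with complete
    homologous pairing is accepted by the pipeline.
    """
    labels, positions = [], {}
    with _data_path("montage_1010_59.csv").open() as f:
        for row in csv.DictReader(f):
            labels.append(row["label"])
            positions[row["label"]] = np.array(
                [float(row["x"]), float(row["y"]), float(row["z"])]
            )
    pairs, midline = pair_by_parity(labels)
    return Montage(
        labels=tuple(labels),
        positions=positions,
        homologous_pairs=tuple(pairs),
        midline=tuple(midline),
    )


def canonical_maps(labels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Packaged normative A-D template maps (synthetic reconstruction).

    These are smooth synthetic stand-ins for the four classic normative
    topographies (two diagonal axes, an anterior-posterior gradient, and a
    fronto-central focus), built from the packaged montage geometry. They
    serve only to give group templates a canonical A-D labelling by maximal
    absolute spatial correlation.

    Returns ``(maps, class_names)`` with ``maps`` of shape (4, n_channels),
    rows average-referenced and unit-norm, in the requested channel order
    (default: the packaged montage's order). Subsetting to fewer channels
    re-references and re-normalizes over that subset.
    """
    table = {}
    with _data_path("canonical_maps_synthetic.csv").open() as f:
        for row in csv.DictReader(f):
            table[row["label"]] = [float(row[k]) for k in ("A", "B", "C", "D")]
    if labels is None:
        labels = default_montage().labels
    missing = [l for l in labels if l not in table]
    if missing:
        raise KeyError(f"labels not in the canonical map table: {missing}")
    maps = np.array([table[l] for l in labels]).T
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    return maps, ["A", "B", "C", "D"]


def spectral_bands() -> BandScheme:
    """Eight-band scheme for relative power and symmetry indices.

    The five primary bands (delta/theta/alpha/beta/gamma) tile the 0.5 Hz
    grid of 1.0-42.0 Hz under inclusive edges; the three beta sub-bands
    coexist with broadband beta.
    """
    return BandScheme(
        bands=(
            ("delta", 1.0, 3.5),
            ("theta", 4.0, 7.5),
            ("alpha", 8.0, 12.5),
            ("low_beta", 13.0, 15.5),
            ("middle_beta", 16.0, 20.5),
            ("high_beta", 21.0, 29.5),
            ("beta", 13.0, 29.5),
            ("gamma", 30.0, 42.0),
        ),
        total_range=(1.0, 42.0),
    )


PRIMARY_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


def connectivity_bands() -> BandScheme:
    """Five contiguous canonical bands used for phase-locking connectivity."""
    return BandScheme(
        bands=(
            ("delta", 1.0, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 13.0),
            ("beta", 13.0, 30.0),
            ("gamma", 30.0, 42.0),
        ),
        total_range=(1.0, 42.0),
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    montage: Montage | None = None,
) -> Recording:
    """Read an EEG file into a :class:`Recording`.

    Parameters
    ----------
    path : str or Path
        For BrainVision, the ``.vhdr`` header file.
    format : {"brainvision", "edf", "matrix_text"}, optional
        Inferred from the suffix when omitted.
    fs : float, optional
        Required for ``matrix_text`` (the format stores no rate).
    montage : Montage, optional
        When given, channels present in the montage are reordered to the
        montage's canonical order (missing montage channels are an error).

    The returned recording has a single continuity segment spanning all
    samples and ``reference = "original"``.
    """
    path = Path(path)
    if format is None:
        format = {
            ".vhdr": "brainvision",
            ".edf": "edf",
            ".csv": "matrix_text",
            ".txt": "matrix_text",
        }.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from {path.suffix!r}")

    if format == "matrix_text":
        if fs is None:
            raise ValueError("matrix_text requires an explicit fs")
        rec = _read_matrix_text(path, fs)
    elif format in ("brainvision", "edf"):
        import mne

        if format == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            _check_edf_labels(path)
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels in file header")
        data = raw.get_data() * 1e6  # mne uses volts internally
        rec = Recording(data=data, fs=float(raw.info["sfreq"]), labels=labels)
    else:
        raise ValueError(f"unknown format {format!r}")

    if montage is not None:
        missing = [l for l in montage.labels if l not in rec.labels]
        if missing:
            raise ValueError(f"recording lacks montage channels {missing}")
        rec = rec.pick(list(montage.labels))
    return rec


def _check_edf_labels(path: Path) -> None:
    """Reject EDF files with duplicate signal labels (readers that rename
    them silently would break montage bookkeeping)."""
    with open(path, "rb") as f:
        header = f.read(256)
        ns = int(header[252:256].decode("ascii").strip())
        labels = [f.read(16).decode("ascii", "replace").strip()
                  for _ in range(ns)]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels in EDF header")


def _read_matrix_text(path: Path, fs: float) -> Recording:
    with open(path) as f:
        header = f.readline().strip()
        labels = header.split("\t") if "\t" in header else header.split(",")
        labels = [l.strip() for l in labels]
        data = np.loadtxt(f, delimiter="\t" if "\t" in header else ",", ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError("header/data column count mismatch")
    if labels and all(not l for l in labels):
        labels = [f"CH{i + 1}" for i in range(data.shape[1])]
    return Recording(data=data.T, fs=fs, labels=labels)


def write_matrix_text(rec: Recording, path: str | Path) -> None:
    """Write a recording in the plain-text matrix format (lossless repr).

    One header row of tab-separated labels, then one row per sample. Values
    use ``repr``-exact float formatting so a read round-trips bit-exactly.
    Continuity segments are not stored; a side-channel (JSON) is used by the
    synthetic study writer where they matter.
    """
    with open(path, "w") as f:
        f.write("\t".join(rec.labels) + "\n")
        for row in rec.data.T:
            f.write("\t".join(np.format_float_scientific(v, unique=True) for v in row) + "\n")


def make_matrix_recording(data: np.ndarray, fs: float) -> Recording:
    """Construct a Recording with synthetic CH1..CHn labels."""
    data = np.asarray(data, dtype=float)
    labels = [f"CH{i + 1}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, labels=labels)
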