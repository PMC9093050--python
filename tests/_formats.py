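"""Hand-crafted minimal EEG files per the public format specifications.

Used only to exercise the readers; files are written into pytest tmp
directories at test time.
"""

from pathlib import Path

import numpy as np


def write_edf(path, data, fs, labels, phys=200.0):
    """Minimal EDF: 256-byte header + per-signal headers (field-major) +
    int16 little-endian records of 1 s each."""
    data = np.asarray(data, dtype=float)
    ns, n = data.shape
    spr = int(fs)
    nrec = n // spr

    def f(s, w):
        return str(s).ljust(w)[:w].encode("ascii")

    hdr = f("0", 8) + f("X", 80) + f("X", 80)
    hdr += f("01.01.20", 8) + f("00.00.00", 8)
    hdr += f(256 * (ns + 1), 8) + f("", 44)
    hdr += f(nrec, 8) + f("1", 8) + f(ns, 4)
    columns = [(labels, 16), ([""] * ns, 80), (["uV"] * ns, 8),
               ([f"{-phys:g}"] * ns, 8), ([f"{phys:g}"] * ns, 8),
               (["-32768"] * ns, 8), (["32767"] * ns, 8),
               ([""] * ns, 80), ([spr] * ns, 8), ([""] * ns, 32)]
    for values, width in columns:
        for v in values:
            hdr += f(v, width)
    scale = 32767.0 / phys
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(nrec):
            chunk = data[:, r * spr:(r + 1) * spr]
            fh.write(np.round(chunk * scale).astype("<i2").tobytes())
    return path


def write_brainvision(directory, name, data, fs, labels):
    """Minimal BrainVision triplet: .vhdr/.vmrk text + float32 .eeg."""
    directory = Path(directory)
    data = np.asarray(data, dtype=np.float32)
    vhdr = directory / f"{name}.vhdr"
    vmrk = directory / f"{name}.vmrk"
    eeg = directory / f"{name}.eeg"
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(labels)}",
        f"SamplingInterval={1e6 / fs:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(labels, start=1):
        lines.append(f"Ch{i}={lab},,1")
    vhdr.write_text("\n".join(lines) + "\n")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={name}.eeg\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n")
    eeg.write_bytes(data.T.astype("<f4").tobytes())  # multiplexed
    return vhdr
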