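"""Synthetic resting-state EEG with known ground truth.

The clinical recordings this pipeline was designed around cannot be
shared, so every downstream stage is exercised against generated data
with planted, recoverable structure:

* :func:`gen_oscillatory` — per-channel band-limited oscillatory power
  with controllable five-band ratios and planted inter-channel phase
  coupling. Oscillators are band-pass-filtered white noise (not
  sinusoids), so spectral and Hilbert stages face realistic spectra;
  coupling is planted by mixing a shared narrowband source into both
  channels of a pair.
* :func:`gen_microstate_eeg` — topographic switching among K templates
  with controllable segment durations, amplitude envelope, and SNR.
* :func:`gen_paired_study` — a paired two-condition (T0/T1) multi-subject
  study with planted spectral and coupling effects and outcome scores
  linearly coupled to a baseline connectivity summary.

All randomness flows from one seeded generator; the same seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .io_montage import (Recording, connectivity_bands, default_montage)

__all__ = ["MicrostateGroundTruth", "StudyDesign", "gen_oscillatory",
           "gen_microstate_eeg", "gen_paired_study", "PLANTED_COMPONENT"]

# A connected 6-edge path across the scalp used for planted coupling
# effects; interior nodes carry two shared sources, so per-node coupling
# budgets stay below 1.
PLANTED_COMPONENT = (("F3", "C3"), ("C3", "P3"), ("P3", "Pz"),
                     ("Pz", "P4"), ("P4", "C4"), ("C4", "F4"))


@dataclass
class MicrostateGroundTruth:
    templates: np.ndarray           # K x channels, unit-norm
    label_sequence: np.ndarray      # per-sample class index
    segment_durations: np.ndarray   # per-segment ms
    amplitude_envelope: np.ndarray  # per-sample positive scale


@dataclass
class StudyDesign:
    """A paired T0/T1 study with planted effects.

    ``theta_effect`` shifts the theta relative-power target at T1 (e.g.
    -0.07 lowers theta by 7 points in every subject); the freed mass is
    redistributed proportionally over the other bands.
    ``coupling_effect`` shifts the planted coupling strength of the
    ``component`` edges at T1. Outcome scores are
    ``outcome_intercept + outcome_slope * coupling_t0(subject) + noise``.
    """

    n_subjects: int = 8
    duration_s: float = 60.0
    fs: float = 250.0
    labels: tuple[str, ...] | None = None   # default: packaged 59-ch montage
    base_power: dict = field(default_factory=lambda: {
        "delta": 0.30, "theta": 0.25, "alpha": 0.20,
        "beta": 0.15, "gamma": 0.10})
    power_jitter: float = 0.02
    theta_effect: float = -0.07
    component: tuple = PLANTED_COMPONENT
    coupling_band: str = "alpha"
    coupling_t0: float = 0.42
    coupling_jitter: float = 0.05
    coupling_effect: float = -0.25
    outcome_intercept: float = 4.0
    outcome_slope: float = 25.0
    outcome_noise: float = 0.5
    seed: int = 0


def _band_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                low: float, high: float, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise per channel."""
    order = min(int(np.ceil(4 * fs / low)) | 1, n_samp // 3 | 1)
    taps = sps.firwin(order, [low, high], pass_zero=False, fs=fs,
                      window="hamming")
    pad = order
    x = rng.standard_normal((n_ch, n_samp + 2 * pad))
    y = sps.fftconvolve(x, taps[None, :], mode="same", axes=1)[:, pad:-pad]
    sd = y.std(axis=1, keepdims=True)
    return y / np.maximum(sd, 1e-12)


def gen_oscillatory(recipe: dict[str, float],
                    coupling: dict[tuple[str, str], float] | None = None,
                    labels=None, duration_s: float = 60.0, fs: float = 250.0,
                    seed: int | np.random.Generator = 0,
                    rereference: bool = True) -> Recording:
    """Band-limited oscillatory EEG with planted pairwise phase coupling.

    ``recipe`` maps the five primary band names to relative-power targets
    summing to 1; band edges follow the connectivity scheme (contiguous
    1-42 Hz). ``coupling`` maps (label, label) pairs to strengths in
    [0, 1]: each pair's channels receive a shared narrowband source with
    variance weight equal to the strength, in every band. The per-channel
    coupling budget (sum of its pairs' strengths) must stay at most 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scheme = connectivity_bands()
    targets = np.array([recipe.get(name, 0.0) for name in scheme.names])
    if abs(targets.sum() - 1.0) > 1e-6:
        raise ValueError("relative-power targets must sum to 1")
    if labels is None:
        labels = list(default_montage().labels)
    labels = list(labels)
    n_ch = len(labels)
    n_samp = int(round(duration_s * fs))
    coupling = dict(coupling or {})
    idx = {l: i for i, l in enumerate(labels)}

    lowest = min(lo for (_n, lo, _h), t in zip(scheme.bands, targets) if t > 0)
    if duration_s < 3.0 / lowest:
        raise ValueError("duration too short for the lowest active band")

    budget = np.zeros(n_ch)
    pairs = []
    for (a, b), c in coupling.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError("coupling strengths must lie in [0, 1]")
        if a not in idx or b not in idx:
            raise ValueError(f"coupling pair ({a}, {b}) not in the labels")
        ia, ib = idx[a], idx[b]
        budget[ia] += c
        budget[ib] += c
        pairs.append((ia, ib, c))
    if np.any(budget > 1.0 + 1e-9):
        raise ValueError("per-channel coupling budget exceeds 1")

    data = np.zeros((n_ch, n_samp))
    for (name, lo, hi), target in zip(scheme.bands, targets):
        if target <= 0:
            continue
        own = _band_noise(rng, n_ch, n_samp, lo, hi, fs)
        mix = np.sqrt(np.maximum(0.0, 1.0 - budget))[:, None] * own
        for ia, ib, c in pairs:
            if c > 0:
                shared = _band_noise(rng, 1, n_samp, lo, hi, fs)[0]
                mix[ia] += np.sqrt(c) * shared
                mix[ib] += np.sqrt(c) * shared
        data += np.sqrt(target) * mix
    if rereference and n_ch >= 3:
        data = data - data.mean(axis=0, keepdims=True)
        ref = "common_average"
    else:
        ref = "common_average" if rereference else "original"
    return Recording(data=data, fs=fs, labels=labels, reference=ref)


def _random_templates(rng: np.random.Generator, k: int, n_ch: int,
                      max_corr: float = 0.95) -> np.ndarray:
    for _ in range(200):
        t = rng.standard_normal((k, n_ch))
        t -= t.mean(axis=1, keepdims=True)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        c = np.abs(t @ t.T - np.eye(k))
        if c.max() < max_corr:
            return t
    raise RuntimeError("could not draw sufficiently distinct templates")


def gen_microstate_eeg(k: int = 4, mean_duration_ms: float = 100.0,
                       snr: float = 5.0, duration_s: float = 40.0,
                       fs: float = 250.0, seed: int | np.random.Generator = 0,
                       labels=None, templates: np.ndarray | None = None,
                       min_duration_ms: float = 40.0):
    """Microstate-switching EEG: active template x amplitude envelope plus
    spatially white noise at the stated SNR (signal/noise variance ratio).

    Returns ``(Recording, MicrostateGroundTruth)``. The label sequence
    switches uniformly among the other classes; segment durations are
    gamma-distributed with the requested mean and a hard minimum.
    """
    if k < 2:
        raise ValueError("need at least 2 microstate classes")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if mean_duration_ms < min_duration_ms:
        raise ValueError(f"mean duration below the {min_duration_ms} ms floor")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = list(default_montage().labels)
    labels = list(labels)
    n_ch = len(labels)
    n_samp = int(round(duration_s * fs))
    if templates is None:
        templates = _random_templates(rng, k, n_ch)
    else:
        templates = np.asarray(templates, dtype=float)
        templates = templates - templates.mean(axis=1, keepdims=True)
        templates = templates / np.linalg.norm(templates, axis=1, keepdims=True)

    min_samples = int(np.ceil(min_duration_ms * fs / 1000.0))
    mean_samples = mean_duration_ms * fs / 1000.0
    seq = np.empty(n_samp, dtype=int)
    durations = []
    pos, cur = 0, int(rng.integers(k))
    while pos < n_samp:
        extra = rng.gamma(shape=2.0, scale=max(mean_samples - min_samples, 1e-9) / 2.0)
        dur = min_samples + int(round(extra))
        dur = min(dur, n_samp - pos)
        seq[pos:pos + dur] = cur
        durations.append(dur / fs * 1000.0)
        pos += dur
        nxt = int(rng.integers(k - 1))
        cur = nxt if nxt < cur else nxt + 1

    # smooth positive amplitude envelope, mean ~1
    env = gaussian_filter1d(np.abs(rng.standard_normal(n_samp)) + 0.3,
                            sigma=0.05 * fs)
    env = env / env.mean()
    sig = templates[seq].T * env[None, :]
    sig_var = sig.var()
    noise = rng.standard_normal((n_ch, n_samp))
    noise -= noise.mean(axis=0, keepdims=True)  # keep the average reference
    noise *= np.sqrt(sig_var / snr) / noise.std()
    data = sig + noise
    rec = Recording(data=data, fs=fs, labels=labels,
                    reference="common_average")
    truth = MicrostateGroundTruth(templates=templates, label_sequence=seq,
                                  segment_durations=np.array(durations),
                                  amplitude_envelope=env)
    return rec, truth


def gen_paired_study(design: StudyDesign):
    """Generate a paired T0/T1 study with planted effects.

    Returns ``(recordings, truth)`` where ``recordings[(subject, cond)]``
    is a Recording (cond in {"T0", "T1"}) and ``truth`` is a dict with the
    per-subject power targets, coupling strengths, and outcome scores.
    """
    if design.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(design.seed)
    labels = list(design.labels) if design.labels is not None \
        else list(default_montage().labels)
    names = list(design.base_power)
    base = np.array([design.base_power[n] for n in names])
    base = base / base.sum()
    theta_i = names.index("theta")

    recordings = {}
    truth = {"subjects": [], "power_t0": [], "power_t1": [],
             "coupling_t0": [], "coupling_t1": [], "outcome": [],
             "component": list(design.component),
             "coupling_band": design.coupling_band, "band_names": names}
    for s in range(design.n_subjects):
        jitter = rng.normal(0.0, design.power_jitter, size=len(names))
        p0 = np.clip(base + jitter, 0.02, None)
        p0 = p0 / p0.sum()
        p1 = p0.copy()
        p1[theta_i] += design.theta_effect
        if p1[theta_i] <= 0 or p1[theta_i] >= 1:
            raise ValueError("theta effect drives the target outside (0, 1)")
        others = np.arange(len(names)) != theta_i
        p1[others] += -design.theta_effect * p0[others] / p0[others].sum()
        p1 = p1 / p1.sum()

        c0 = float(np.clip(design.coupling_t0
                           + rng.normal(0.0, design.coupling_jitter), 0.05, 0.49))
        c1 = float(np.clip(c0 + design.coupling_effect, 0.0, 0.49))
        coup0 = {e: c0 for e in design.component}
        coup1 = {e: c1 for e in design.component}

        rec0 = gen_oscillatory(dict(zip(names, p0)), coup0, labels=labels,
                               duration_s=design.duration_s, fs=design.fs,
                               seed=rng)
        rec1 = gen_oscillatory(dict(zip(names, p1)), coup1, labels=labels,
                               duration_s=design.duration_s, fs=design.fs,
                               seed=rng)
        recordings[(s, "T0")] = rec0
        recordings[(s, "T1")] = rec1
        outcome = (design.outcome_intercept + design.outcome_slope * c0
                   + rng.normal(0.0, design.outcome_noise))
        truth["subjects"].append(s)
        truth["power_t0"].append(p0)
        truth["power_t1"].append(p1)
        truth["coupling_t0"].append(c0)
        truth["coupling_t1"].append(c1)
        truth["outcome"].append(outcome)
    for key in ("power_t0", "power_t1"):
        truth[key] = np.array(truth[key])
    for key in ("coupling_t0", "coupling_t1", "outcome"):
        truth[key] = np.array(truth[key])
    return recordings, truth
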