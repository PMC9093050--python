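"""Shared configuration for the numbered analysis drivers.

The study is fully determined by a seed: recordings are regenerated on
demand rather than stored (10 min of 59-channel EEG per recording would
be ~100 MB of text each). Heavy intermediates (PLV stacks) are cached
under scratch/ so later stages can reuse them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from zolpiscope import synthetic as syn
from zolpiscope.io_montage import default_montage
from zolpiscope.pipeline import extract_recording_features

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "study"
CACHE = ROOT / "scratch" / "study_cache"

DEFAULT_SEED = 5
BANDS = ("delta", "theta", "alpha", "beta", "gamma")


def study_design(seed: int = DEFAULT_SEED) -> syn.StudyDesign:
    """The demo cohort: 8 paired subjects, 60 s of 59-channel EEG per
    condition, a -7-point theta relative-power shift and an alpha-path
    coupling drop at T1, outcomes linear in baseline coupling."""
    return syn.StudyDesign(n_subjects=8, duration_s=60.0, seed=seed)


def generate(seed: int = DEFAULT_SEED):
    design = study_design(seed)
    recordings, truth = syn.gen_paired_study(design)
    return design, recordings, truth


def features_and_plv(seed: int = DEFAULT_SEED, use_laplacian: bool = True):
    """Per-recording scalar features and PLV stacks, cached by seed."""
    CACHE.mkdir(parents=True, exist_ok=True)
    cache = CACHE / f"plv_seed{seed}_lap{int(use_laplacian)}.npz"
    montage = default_montage()
    design, recordings, truth = generate(seed)
    keys = sorted(recordings.keys())
    if cache.exists():
        arr = np.load(cache, allow_pickle=True)
        scalars = {k: dict(zip(arr["names"].tolist(), row))
                   for k, row in zip(keys, arr["scalars"])}
        plv = {k: {b: arr[f"plv_{b}"][i] for b in BANDS}
               for i, k in enumerate(keys)}
        return design, recordings, truth, scalars, plv
    scalars, plv = {}, {}
    for key in keys:
        sc, bands = extract_recording_features(recordings[key], montage,
                                               use_laplacian=use_laplacian)
        scalars[key] = sc
        plv[key] = {b: bands[b].values for b in BANDS}
    names = sorted(scalars[keys[0]])
    np.savez(cache,
             names=np.array(names),
             scalars=np.array([[scalars[k][n] for n in names] for k in keys]),
             **{f"plv_{b}": np.stack([plv[k][b] for k in keys]) for b in BANDS})
    return design, recordings, truth, scalars, plv


def save_json(obj, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=float)
    print(f"wrote {path.relative_to(ROOT)}")
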