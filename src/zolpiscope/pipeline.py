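"""End-to-end study orchestration.

``run_study`` drives the full analysis over a paired two-condition study:
preprocessing -> spectral features and symmetry indices -> surface
Laplacian + band PLV matrices -> two-level microstate analysis ->
within-subject permutation tests and band-wise NBS -> FCSCC features ->
nested-LOOCV classification (T0 vs T1) and outcome regression. Outputs are
a JSON report plus CSV feature tables; the seeds and parameters used are
embedded in the report for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, microstate, models, perm_stats, spectral
from .io_montage import (Montage, Recording, connectivity_bands,
                         default_montage, read_recording, spectral_bands,
                         PRIMARY_BANDS)
from .preprocess import rereference_average

__all__ = ["StudyConfig", "run_study", "extract_recording_features",
           "microstate_stage"]


@dataclass
class StudyConfig:
    """Configuration for a paired T0/T1 study run.

    ``manifest`` maps ``(subject, condition)`` to a Recording or a file
    path (matrix_text assumed for paths, with ``fs`` taken from the
    config). ``outcomes`` optionally maps subject -> outcome score for the
    regression stage.
    """

    manifest: dict
    outcomes: dict | None = None
    fs: float = 250.0
    preprocessed: bool = True       # inputs already filtered/referenced
    use_laplacian: bool = True
    microstate_k: int = 4
    min_duration_ms: float = 30.0
    edge_alpha: float = 0.05
    n_perm: int = 2000
    seed: int = 0
    svm_by_subject: bool = False
    bands: tuple[str, ...] = PRIMARY_BANDS


def _load(entry, fs: float, montage: Montage) -> Recording:
    if isinstance(entry, Recording):
        rec = entry
    else:
        rec = read_recording(entry, fs=fs, montage=montage)
    if rec.reference == "original":
        rec = rereference_average(rec)
    return rec


def extract_recording_features(rec: Recording, montage: Montage,
                               use_laplacian: bool = True):
    """Spectral features and band PLV matrices for one recording.

    Returns ``(scalars, plv_by_band)``: scalar features are the global
    relative powers and symmetry indices per band.
    """
    scheme = spectral_bands()
    psd = spectral.welch_psd(rec)
    _chan, global_rel, _grp = spectral.relative_power(psd, scheme)
    sym = spectral.symmetry_indices(psd, montage, scheme)
    scalars = {}
    for name in scheme.names:
        scalars[f"relpower_{name}"] = global_rel[name]
        scalars[f"pdbsi_{name}"] = sym.pdbsi[name]
        scalars[f"rbsi_{name}"] = sym.rbsi[name]

    source = connectivity.surface_laplacian(rec, montage) if use_laplacian \
        else rec.copy_with(reference="laplacian")
    plv_by_band = {}
    for name, lo, hi in connectivity_bands().bands:
        phase = connectivity.extract_phase(source, (lo, hi), band_name=name)
        plv_by_band[name] = connectivity.plv(phase)
    return scalars, plv_by_band


def microstate_stage(recs: dict, k: int, seed: int, min_duration_ms: float):
    """Two-level microstate analysis over all recordings.

    Per-recording modified k-means templates are pooled into a group-level
    clustering labelled A-D; the group templates are then back-fitted to
    every recording and the per-recording features are returned.
    """
    rng = np.random.default_rng(seed)
    per_rec_templates = []
    keys = sorted(recs.keys(), key=str)
    for key in keys:
        rec = recs[key]
        g = microstate.gfp(rec)
        maps, _idx = microstate.select_peak_maps(g, rec)
        tmpl, _a, _gev = microstate.modified_kmeans(
            maps, k=k, restarts=10, seed=int(rng.integers(2 ** 31)))
        per_rec_templates.append(tmpl)
    from .io_montage import canonical_maps
    labels = recs[keys[0]].labels
    try:
        canon = canonical_maps(labels)
    except KeyError:  # non-montage channels: skip normative A-D labelling
        canon = False
    group = microstate.group_templates(per_rec_templates,
                                       seed=int(rng.integers(2 ** 31)),
                                       canonical=canon)
    features = {}
    for key in keys:
        rec = recs[key]
        g = microstate.gfp(rec)
        seq = microstate.backfit_smooth(rec, group, min_dur_ms=min_duration_ms)
        feats = microstate.microstate_features(seq, g, group, rec)
        features[key] = feats.as_dict()
    return group, features


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full study pipeline; returns (and optionally writes) the report."""
    montage = default_montage()
    subjects = sorted({s for s, _c in config.manifest})
    for s in subjects:
        for cond in ("T0", "T1"):
            if (s, cond) not in config.manifest:
                raise ValueError(f"subject {s!r} lacks a {cond} recording")

    recs = {key: _load(entry, config.fs, montage)
            for key, entry in config.manifest.items()}

    # --- per-recording features -------------------------------------------
    scalar_rows, plv = {}, {}
    for key, rec in recs.items():
        scalars, plv_by_band = extract_recording_features(
            rec, montage, use_laplacian=config.use_laplacian)
        scalar_rows[key] = scalars
        plv[key] = plv_by_band

    # --- microstates -------------------------------------------------------
    _group_templates, micro_feats = microstate_stage(
        recs, config.microstate_k, config.seed, config.min_duration_ms)
    for key in recs:
        scalar_rows[key].update(micro_feats[key])

    feature_names = sorted(scalar_rows[next(iter(recs))].keys())

    # --- within-subject permutation tests on scalar features ---------------
    rng = np.random.default_rng(config.seed)
    scalar_tests = {}
    for name in feature_names:
        d = np.array([scalar_rows[(s, "T1")][name] - scalar_rows[(s, "T0")][name]
                      for s in subjects])
        if np.any(~np.isfinite(d)):
            continue
        res = perm_stats.perm_test_scalar(
            d, design="within", max_perm=config.n_perm,
            seed=int(rng.integers(2 ** 31)))
        scalar_tests[name] = {"statistic": res.statistic, "p": res.p,
                              "n_perm": res.n_perm, "exhaustive": res.exhaustive}

    # --- NBS per band -------------------------------------------------------
    nbs_results, fcscc = {}, {}
    labels = list(montage.labels)
    for band in config.bands:
        A = np.stack([plv[(s, "T1")][band].values for s in subjects])
        B = np.stack([plv[(s, "T0")][band].values for s in subjects])
        comps = perm_stats.nbs_test(A, B, design="within",
                                    edge_alpha=config.edge_alpha,
                                    n_perm=config.n_perm,
                                    seed=int(rng.integers(2 ** 31)))
        nbs_results[band] = [
            {"p": c.p, "size": c.size, "sign": c.sign,
             "edges": c.labelled_edges(labels)} for c in comps]
        if comps:
            best = comps[0]
            for s in subjects:
                for cond in ("T0", "T1"):
                    fcscc[(s, cond, band)] = connectivity.mean_fcscc(
                        plv[(s, cond)][band], best.edges)

    # FCSCC columns join the scalar feature table where available
    fcscc_bands = sorted({b for (_s, _c, b) in fcscc})
    for band in fcscc_bands:
        name = f"fcscc_{band}"
        for s in subjects:
            for cond in ("T0", "T1"):
                scalar_rows[(s, cond)][name] = fcscc[(s, cond, band)]
        d = np.array([scalar_rows[(s, "T1")][name] - scalar_rows[(s, "T0")][name]
                      for s in subjects])
        res = perm_stats.perm_test_scalar(
            d, design="within", max_perm=config.n_perm,
            seed=int(rng.integers(2 ** 31)))
        scalar_tests[name] = {"statistic": res.statistic, "p": res.p,
                              "n_perm": res.n_perm, "exhaustive": res.exhaustive}
        feature_names.append(name)

    # --- classification: T0 vs T1 ------------------------------------------
    p_values = {k: v["p"] for k, v in scalar_tests.items()}
    selected = models.select_features(list(p_values), p_values)
    rows, subj_col, target = [], [], []
    for s in subjects:
        for cond, label in (("T0", 0), ("T1", 1)):
            rows.append([scalar_rows[(s, cond)][c] for c in selected])
            subj_col.append(s)
            target.append(label)
    table = models.FeatureTable(np.array(rows), selected,
                                np.array(subj_col), np.array(target))
    svm_eval = models.nested_loocv_svm(table, by_subject=config.svm_by_subject,
                                       seed=config.seed)

    # --- outcome regression --------------------------------------------------
    svr_report = None
    if config.outcomes is not None and fcscc_bands:
        y = np.array([config.outcomes[s] for s in subjects], dtype=float)
        corr_p = {}
        for band in fcscc_bands:
            x = np.array([fcscc[(s, "T0", band)] for s in subjects])
            res = perm_stats.perm_corr(x, y, max_perm=config.n_perm,
                                       seed=int(rng.integers(2 ** 31)))
            corr_p[f"fcscc_{band}_T0"] = res.p
        best = models.select_features(list(corr_p), corr_p)
        cols = []
        for name in best:
            band = name.split("_")[1]
            cols.append(np.array([fcscc[(s, "T0", band)] for s in subjects]))
        reg_table = models.FeatureTable(np.column_stack(cols), best,
                                        np.array(subjects), y)
        svr_eval = models.nested_loocv_svr(reg_table, seed=config.seed)
        svr_report = {"selected": best, "rmse": svr_eval.rmse,
                      "correlation": svr_eval.correlation,
                      "corr_p": corr_p}

    report = {
        "seed": config.seed,
        "n_subjects": len(subjects),
        "parameters": {"edge_alpha": config.edge_alpha,
                       "n_perm": config.n_perm,
                       "microstate_k": config.microstate_k,
                       "min_duration_ms": config.min_duration_ms,
                       "use_laplacian": config.use_laplacian},
        "scalar_tests": scalar_tests,
        "nbs": nbs_results,
        "svm": {"selected": selected, "auc": svm_eval.auc},
        "svr": svr_report,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for (s, cond), feats in scalar_rows.items():
            row = {"subject": s, "condition": cond}
            row.update(feats)
            rows.append(row)
        pd.DataFrame(rows).sort_values(["subject", "condition"]).to_csv(
            out_dir / "features.csv", index=False)
        with open(out_dir / "report.json", "w") as f:
            json.dump(report, f, indent=2, default=float)
    return report
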