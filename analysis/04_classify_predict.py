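"""Classification and outcome prediction from the selected features.

SVM: classify T0 vs T1 rows from the features that reached the smallest
permutation p (nested LOOCV, scaling -> PCA(2) -> linear SVM, AUC of the
pooled decision scores). SVR: predict each subject's outcome score from
the baseline FCSCC feature most correlated with it (permutation Spearman
selection, nested LOOCV, PCA(1) -> linear SVR).

Writes results/study/models.json.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from zolpiscope import models, perm_stats as ps


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=common.DEFAULT_SEED)
    args = ap.parse_args()

    _design, _recordings, truth, _scalars, _plv = common.features_and_plv(args.seed)
    feats = pd.read_csv(common.RESULTS / "features.csv")
    fc = pd.read_csv(common.RESULTS / "fcscc.csv")
    stats = json.loads((common.RESULTS / "stats.json").read_text())
    subjects = sorted(feats["subject"].unique())

    # fold FCSCC into the wide feature table
    for band in fc["band"].unique():
        wide = fc[fc["band"] == band].pivot(index="subject",
                                            columns="condition", values="fcscc")
        for cond in ("T0", "T1"):
            feats.loc[feats["condition"] == cond, f"fcscc_{band}"] = \
                feats.loc[feats["condition"] == cond, "subject"].map(wide[cond])

    p_values = {k: v["p"] for k, v in stats["scalar"].items()}
    p_values.update({k: v["p"] for k, v in stats["fcscc"].items()})
    selected = models.select_features(list(p_values), p_values)
    print(f"features at the smallest p ({min(p_values.values()):.3f}): "
          f"{len(selected)} selected")

    rows, subj_col, target = [], [], []
    for s in subjects:
        for cond, lab in (("T0", 0), ("T1", 1)):
            r = feats[(feats["subject"] == s) & (feats["condition"] == cond)]
            rows.append([float(r[c].iloc[0]) for c in selected])
            subj_col.append(s)
            target.append(lab)
    table = models.FeatureTable(np.array(rows), selected,
                                np.array(subj_col), np.array(target))
    svm_eval = models.nested_loocv_svm(table, seed=args.seed)
    print(f"SVM (T0 vs T1): AUC = {svm_eval.auc:.3f} over "
          f"{len(svm_eval.fold_params)} outer folds")

    # outcome prediction from baseline FCSCC features
    y = np.array([truth["outcome"][truth["subjects"].index(s)]
                  for s in subjects])
    rng = np.random.default_rng(args.seed)
    corr_p = {}
    for band in fc["band"].unique():
        wide = fc[fc["band"] == band].pivot(index="subject",
                                            columns="condition", values="fcscc")
        x = wide["T0"].loc[subjects].to_numpy()
        res = ps.perm_corr(x, y, seed=int(rng.integers(2 ** 31)))
        corr_p[band] = res.p
    best_band = min(corr_p, key=corr_p.get)
    print(f"baseline FCSCC most correlated with outcome: {best_band} "
          f"(perm p = {corr_p[best_band]:.4f})")
    wide = fc[fc["band"] == best_band].pivot(index="subject",
                                             columns="condition", values="fcscc")
    x = wide["T0"].loc[subjects].to_numpy()
    reg = models.FeatureTable(x[:, None], [f"fcscc_{best_band}_T0"],
                              np.array(subjects), y)
    svr_eval = models.nested_loocv_svr(reg, seed=args.seed)
    print(f"SVR (outcome): RMSE = {svr_eval.rmse:.3f}, "
          f"predicted-actual r = {svr_eval.correlation:.3f}")

    common.save_json({
        "seed": args.seed,
        "svm": {"selected": selected, "auc": svm_eval.auc},
        "svr": {"band": best_band, "rmse": svr_eval.rmse,
                "correlation": svr_eval.correlation,
                "selection_p": corr_p},
    }, common.RESULTS / "models.json")


if __name__ == "__main__":
    main()
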