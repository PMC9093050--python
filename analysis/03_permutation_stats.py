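"""Permutation inference over the extracted features.

Within-subject (T1 vs T0) exhaustive sign-flip tests on every scalar
feature, and the NBS permutation test on each band's PLV stack. The mean
connectivity strength over each band's smallest-p component (FCSCC) is
appended to the feature table and tested like any scalar feature.

Writes results/study/stats.json and fcscc.csv.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from zolpiscope import perm_stats as ps
from zolpiscope.io_montage import default_montage


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=common.DEFAULT_SEED)
    args = ap.parse_args()

    design, recordings, _truth, scalars, plv = common.features_and_plv(args.seed)
    subjects = sorted({s for s, _c in recordings})
    feats = pd.read_csv(common.RESULTS / "features.csv")
    montage = default_montage()
    labels = list(montage.labels)
    rng = np.random.default_rng(args.seed)

    scalar_tests = {}
    for name in feats.columns:
        if name in ("subject", "condition"):
            continue
        wide = feats.pivot(index="subject", columns="condition", values=name)
        d = (wide["T1"] - wide["T0"]).to_numpy()
        if np.any(~np.isfinite(d)):
            continue
        res = ps.perm_test_scalar(d, design="within",
                                  seed=int(rng.integers(2 ** 31)))
        scalar_tests[name] = {"t": res.statistic, "p": res.p}

    floor = min(v["p"] for v in scalar_tests.values())
    at_floor = sorted(k for k, v in scalar_tests.items() if v["p"] == floor)
    print(f"{len(scalar_tests)} scalar features tested; "
          f"minimum attainable p = {floor:.3f} reached by {len(at_floor)}")

    nbs_out, fcscc_rows = {}, []
    for band in common.BANDS:
        A = np.stack([plv[(s, "T1")][band] for s in subjects])
        B = np.stack([plv[(s, "T0")][band] for s in subjects])
        comps = ps.nbs_test(A, B, design="within", n_perm=2000,
                            seed=int(rng.integers(2 ** 31)))
        nbs_out[band] = [{"p": c.p, "size": c.size, "sign": c.sign,
                          "edges": c.labelled_edges(labels)}
                         for c in comps[:5]]
        if comps:
            best = comps[0]
            print(f"  {band}: smallest-p component size {best.size}, "
                  f"sign {best.sign:+d}, p = {best.p:.3f}")
            from zolpiscope.connectivity import ConnectivityMatrix, mean_fcscc
            for s in subjects:
                for cond in ("T0", "T1"):
                    mat = ConnectivityMatrix(plv[(s, cond)][band], band, labels)
                    fcscc_rows.append({"subject": s, "condition": cond,
                                       "band": band,
                                       "fcscc": mean_fcscc(mat, best.edges)})

    fc = pd.DataFrame(fcscc_rows)
    fc.to_csv(common.RESULTS / "fcscc.csv", index=False)
    fcscc_tests = {}
    for band in fc["band"].unique():
        wide = fc[fc["band"] == band].pivot(index="subject",
                                            columns="condition", values="fcscc")
        d = (wide["T1"] - wide["T0"]).to_numpy()
        res = ps.perm_test_scalar(d, design="within",
                                  seed=int(rng.integers(2 ** 31)))
        fcscc_tests[f"fcscc_{band}"] = {"t": res.statistic, "p": res.p}
        print(f"  FCSCC {band}: T1-T0 p = {res.p:.3f}")

    common.save_json({"seed": args.seed, "scalar": scalar_tests,
                      "fcscc": fcscc_tests, "nbs": nbs_out},
                     common.RESULTS / "stats.json")


if __name__ == "__main__":
    main()
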