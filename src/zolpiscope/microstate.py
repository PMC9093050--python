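"""EEG microstate segmentation and features.

The microstate model treats the average-referenced scalp map as switching
among K quasi-stable template topographies (canonically labelled A-D,
K = 4 by default), ignoring map polarity. The stages here:

1. Global field power (GFP) and GFP-peak map selection.
2. Polarity-invariant modified k-means at the recording level.
3. A second-level modified k-means over pooled recording templates with
   canonical A-D labelling by maximal absolute spatial correlation.
4. Back-fitting every sample to the templates, with temporal smoothing
   until no (non-truncated) segment is shorter than a minimum duration.
5. Feature extraction: GEV, mean duration, occurrence, coverage, mean
   interval (mean gap between successive same-class segments), mean GFP,
   the spatial-correlation matrix SC, and transition probabilities TP.

Spatial correlation between maps is the Pearson correlation across
channels of average-referenced maps; assignments always use its absolute
value, so flipping the polarity of the whole recording changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import linear_sum_assignment

from .io_montage import Recording, canonical_maps

__all__ = [
    "MicrostateTemplates", "MicrostateSequence", "MicrostateFeatures",
    "gfp", "select_peak_maps", "modified_kmeans", "group_templates",
    "backfit_smooth", "microstate_features", "spatial_correlation",
]


@dataclass
class MicrostateTemplates:
    """K unit-norm average-referenced template maps (rows)."""

    maps: np.ndarray
    class_names: list[str]
    gev: float | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        norms = np.linalg.norm(self.maps, axis=1, keepdims=True)
        self.maps = self.maps / norms

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateSequence:
    """Per-sample class labels plus the derived segment list.

    ``labels`` uses -1 for samples outside continuity segments. Each entry
    of ``segments`` is (start, end, class) in half-open samples;
    ``truncated`` flags the first/last segment of each continuity segment,
    whose true extent is unknown.
    """

    labels: np.ndarray
    segments: list[tuple[int, int, int]]
    truncated: list[bool]
    fs: float
    k: int


@dataclass
class MicrostateFeatures:
    """Per-class microstate features (arrays indexed by class).

    Segment-based features (duration, occurrence, coverage, interval,
    mean GFP, SC, TP) exclude truncated segments; GEV is computed over all
    labelled samples. Absent classes are reported as NaN, not zero.
    """

    class_names: list[str]
    gev: np.ndarray
    mean_duration: np.ndarray      # ms
    occurrence: np.ndarray         # segments / s
    coverage: np.ndarray           # fraction
    mean_interval: np.ndarray      # ms
    mean_gfp: np.ndarray           # uV
    sc: np.ndarray                 # K x K, sc[X, Y] = mean |corr(tmpl_X, maps of Y)|
    tp: np.ndarray                 # K x K transition probabilities

    def as_dict(self) -> dict[str, float]:
        out = {}
        for i, name in enumerate(self.class_names):
            out[f"gev_{name}"] = float(self.gev[i])
            out[f"duration_{name}"] = float(self.mean_duration[i])
            out[f"occurrence_{name}"] = float(self.occurrence[i])
            out[f"coverage_{name}"] = float(self.coverage[i])
            out[f"interval_{name}"] = float(self.mean_interval[i])
            out[f"mean_gfp_{name}"] = float(self.mean_gfp[i])
        for i, a in enumerate(self.class_names):
            for j, b in enumerate(self.class_names):
                out[f"sc_{a}{b}"] = float(self.sc[i, j])
                if i != j:
                    out[f"tp_{a}{b}"] = float(self.tp[i, j])
        return out


def gfp(rec: Recording) -> np.ndarray:
    """Global field power: per-sample population standard deviation of the
    average-referenced potentials across channels."""
    if rec.reference != "common_average":
        raise ValueError("gfp expects a common-average reference")
    return rec.data.std(axis=0, ddof=0)


def spatial_correlation(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between each map (row) and each
    template (row); maps are demeaned across channels first."""
    X = maps - maps.mean(axis=1, keepdims=True)
    T = templates - templates.mean(axis=1, keepdims=True)
    Xn = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-300)
    Tn = T / np.maximum(np.linalg.norm(T, axis=1, keepdims=True), 1e-300)
    return Xn @ Tn.T


def select_peak_maps(gfp_values: np.ndarray, rec: Recording,
                     low_discard: float = 0.15, high_sd: float = 3.0):
    """Maps at surviving GFP peaks ("original maps").

    Local GFP maxima are located within each continuity segment. The lowest
    ``low_discard`` fraction of peaks (by GFP, ties broken by time) is
    discarded first; then peaks whose GFP exceeds the surviving peaks' mean
    by more than ``high_sd`` standard deviations are discarded.

    Returns ``(maps, indices)`` with maps shaped n_peaks x channels.
    """
    peak_idx = []
    for a, b in rec.segments:
        loc, _ = sps.find_peaks(gfp_values[a:b])
        peak_idx.extend(loc + a)
    peak_idx = np.array(sorted(peak_idx), dtype=int)
    if peak_idx.size < 10:
        raise ValueError(f"only {peak_idx.size} GFP peaks found (need >= 10)")
    values = gfp_values[peak_idx]
    n_drop = int(np.floor(low_discard * peak_idx.size))
    order = np.lexsort((peak_idx, values))  # ascending GFP, ties by time
    keep = np.sort(order[n_drop:])
    peak_idx, values = peak_idx[keep], values[keep]
    sd = values.std(ddof=0)
    ok = values <= values.mean() + high_sd * sd
    peak_idx = peak_idx[ok]
    if peak_idx.size == 0:
        raise ValueError("all GFP peaks discarded")
    return rec.data[:, peak_idx].T.copy(), peak_idx


def _principal_map(maps: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the (channel) covariance of a set of maps —
    the polarity-free cluster centroid."""
    S = maps.T @ maps
    w, v = np.linalg.eigh(S)
    t = v[:, -1]
    return t / np.linalg.norm(t)


def _gev(maps: np.ndarray, templates: np.ndarray,
         assign: np.ndarray) -> float:
    g = maps.std(axis=1, ddof=0)
    corr = spatial_correlation(maps, templates)
    best = corr[np.arange(maps.shape[0]), assign]
    denom = float((g ** 2).sum())
    if denom == 0:
        return 0.0
    return float(((g * best) ** 2).sum() / denom)


def modified_kmeans(maps: np.ndarray, k: int = 4, restarts: int = 10,
                    seed: int | np.random.Generator | None = 0,
                    max_iter: int = 200, tol: float = 1e-7):
    """Polarity-invariant modified k-means over topographic maps.

    Assignment maximizes the squared spatial correlation; the template
    update is the dominant eigenvector of the covariance of the assigned
    maps. Iterations stop when the relative GEV change drops below ``tol``;
    the best of ``restarts`` seeded initializations (by GEV) is returned.

    Returns ``(MicrostateTemplates, assignment, gev)``.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} maps, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best = None
    for _ in range(max(1, restarts)):
        init = rng.choice(n, size=k, replace=False)
        templates = maps[init] / np.linalg.norm(maps[init], axis=1, keepdims=True)
        prev_gev = -np.inf
        for _it in range(max_iter):
            corr = spatial_correlation(maps, templates)
            assign = np.argmax(corr ** 2, axis=1)
            # re-seed empty clusters from the currently worst-fit map
            fit = np.abs(corr[np.arange(n), assign])
            for kk in range(k):
                if not np.any(assign == kk):
                    worst = int(np.argmin(fit))
                    assign[worst] = kk
                    fit[worst] = 1.0
            templates = np.vstack([
                _principal_map(maps[assign == kk]) for kk in range(k)
            ])
            cur_gev = _gev(maps, templates, np.argmax(
                spatial_correlation(maps, templates) ** 2, axis=1))
            if prev_gev > -np.inf and abs(cur_gev - prev_gev) <= tol * max(prev_gev, 1e-300):
                break
            prev_gev = cur_gev
        corr = spatial_correlation(maps, templates)
        assign = np.argmax(corr ** 2, axis=1)
        g = _gev(maps, templates, assign)
        if best is None or g > best[2]:
            best = (templates, assign, g)
    templates, assign, g = best
    names = [chr(ord("A") + i) for i in range(k)]
    return MicrostateTemplates(maps=templates, class_names=names, gev=g), assign, g


def group_templates(per_recording: list[MicrostateTemplates],
                    seed: int | None = 0,
                    canonical: tuple[np.ndarray, list[str]] | None = None,
                    restarts: int = 20) -> MicrostateTemplates:
    """Second-level modified k-means over pooled recording templates.

    The group templates are labelled against the packaged canonical A-D
    maps (or ``canonical`` when given) by a one-to-one assignment that
    maximizes total absolute spatial correlation (Hungarian algorithm).
    ``canonical=False`` skips the normative labelling (clusters are named
    A.. in arbitrary order) — for montages with no canonical-map entry.
    """
    if len(per_recording) < 2:
        raise ValueError("need templates from at least 2 recordings")
    k = per_recording[0].k
    pooled = np.vstack([t.maps for t in per_recording])
    templates, _, g = modified_kmeans(pooled, k=k, restarts=restarts, seed=seed)
    if canonical is False:
        names = [chr(ord("A") + i) for i in range(k)]
        return MicrostateTemplates(maps=templates.maps, class_names=names, gev=g)
    ref_maps, ref_names = canonical_maps() if canonical is None else canonical
    if ref_maps.shape[0] < k:
        raise ValueError("fewer canonical maps than clusters")
    if ref_maps.shape[1] != templates.maps.shape[1]:
        raise ValueError("canonical maps do not match the channel count")
    corr = np.abs(spatial_correlation(templates.maps, ref_maps))
    row, col = linear_sum_assignment(-corr)
    order = np.argsort(col)
    maps = templates.maps[row[order]]
    names = [ref_names[c] for c in col[order]]
    return MicrostateTemplates(maps=maps, class_names=names, gev=g)


def _segment_arrays(labels: np.ndarray, continuity: list[tuple[int, int]]):
    """Vectorized segment extraction: (starts, ends, classes, truncated)."""
    all_s, all_e, all_t = [], [], []
    for a, b in continuity:
        lab = labels[a:b]
        cuts = np.flatnonzero(lab[1:] != lab[:-1]) + 1
        starts = np.concatenate(([0], cuts)) + a
        ends = np.concatenate((cuts, [b - a])) + a
        trunc = np.zeros(starts.size, dtype=bool)
        trunc[0] = True
        trunc[-1] = True
        all_s.append(starts)
        all_e.append(ends)
        all_t.append(trunc)
    starts = np.concatenate(all_s)
    ends = np.concatenate(all_e)
    trunc = np.concatenate(all_t)
    return starts, ends, labels[starts], trunc


def _segments_from_labels(labels: np.ndarray,
                          continuity: list[tuple[int, int]]):
    segs, trunc = [], []
    for a, b in continuity:
        lab = labels[a:b]
        cuts = np.flatnonzero(lab[1:] != lab[:-1]) + 1
        starts = np.concatenate(([0], cuts)) + a
        ends = np.concatenate((cuts, [b - a])) + a
        n_before = len(segs)
        segs.extend((int(s), int(e), int(labels[s]))
                    for s, e in zip(starts, ends))
        flags = [False] * (len(segs) - n_before)
        if flags:
            flags[0] = True
            flags[-1] = True
        trunc.extend(flags)
    return segs, trunc


def backfit_smooth(rec: Recording, templates: MicrostateTemplates,
                   min_dur_ms: float = 30.0) -> MicrostateSequence:
    """Label every sample by maximal |spatial correlation| with the
    templates, then smooth short segments away.

    While any non-truncated segment is shorter than
    ``ceil(min_dur_ms * fs / 1000)`` samples, the shortest such segment's
    samples are reassigned, sample by sample, to whichever neighbouring
    segment's class correlates better with that sample's map.
    """
    if rec.reference != "common_average":
        raise ValueError("backfit expects a common-average reference")
    min_samples = int(np.ceil(min_dur_ms * rec.fs / 1000.0))
    corr = np.abs(spatial_correlation(rec.data.T, templates.maps))
    labels = np.full(rec.n_samples, -1, dtype=int)
    for a, b in rec.segments:
        labels[a:b] = np.argmax(corr[a:b], axis=1)

    guard = 0
    max_guard = 200 * max(1, rec.n_samples // max(1, min_samples))
    while True:
        starts, ends, classes, trunc_f = _segment_arrays(labels, rec.segments)
        lens = ends - starts
        cand = np.flatnonzero(~trunc_f & (lens < min_samples))
        if cand.size == 0:
            break
        guard += 1
        if guard > max_guard:
            raise RuntimeError("temporal smoothing failed to converge")
        i = cand[np.argmin(lens[cand])]
        s, e = int(starts[i]), int(ends[i])
        left_class, right_class = int(classes[i - 1]), int(classes[i + 1])
        take_left = corr[s:e, left_class] >= corr[s:e, right_class]
        labels[s:e] = np.where(take_left, left_class, right_class)
    segs, trunc = _segments_from_labels(labels, rec.segments)
    return MicrostateSequence(labels=labels, segments=segs, truncated=trunc,
                              fs=rec.fs, k=templates.k)


def microstate_features(seq: MicrostateSequence, gfp_values: np.ndarray,
                        templates: MicrostateTemplates,
                        rec: Recording) -> MicrostateFeatures:
    """All eight feature families for one labelled recording.

    Truncated first/last segments of each continuity segment are excluded
    from every segment-based feature. The mean interval of class X averages
    the gaps between the end of one X segment and the start of the next
    within the same continuity segment. GEV is computed over all labelled
    samples. Classes with no usable segment come out as NaN.
    """
    k = seq.k
    fs = seq.fs
    corr = spatial_correlation(rec.data.T, templates.maps)
    labeled = seq.labels >= 0
    total_time_s = labeled.sum() / fs

    keep = [i for i, t in enumerate(seq.truncated) if not t]
    segs_nt = [seq.segments[i] for i in keep]

    # continuity-segment id per segment index (for interval/TP locality)
    def _cont_id(sample: int) -> int:
        for ci, (a, b) in enumerate(rec.segments):
            if a <= sample < b:
                return ci
        raise ValueError("segment outside continuity bounds")

    seg_cont = [_cont_id(s) for s, _e, _c in seq.segments]
    nt_flags = [not t for t in seq.truncated]

    mean_duration = np.full(k, np.nan)
    occurrence = np.full(k, np.nan)
    coverage = np.full(k, np.nan)
    mean_interval = np.full(k, np.nan)
    mean_gfp = np.full(k, np.nan)
    gev = np.full(k, np.nan)
    sc = np.full((k, k), np.nan)
    tp = np.zeros((k, k))

    total_nt_samples = sum(e - s for s, e, _c in segs_nt)
    gfp_sq_total = float((gfp_values[labeled] ** 2).sum())

    for c in range(k):
        own = [(s, e) for s, e, cc in segs_nt if cc == c]
        if own:
            durs = np.array([e - s for s, e in own], dtype=float)
            mean_duration[c] = durs.mean() / fs * 1000.0
            occurrence[c] = len(own) / total_time_s if total_time_s > 0 else np.nan
            coverage[c] = durs.sum() / total_nt_samples if total_nt_samples else np.nan
            samp = np.concatenate([np.arange(s, e) for s, e in own])
            mean_gfp[c] = float(gfp_values[samp].mean())
        # intervals: successive non-truncated X segments in one continuity segment
        gaps = []
        per_cont: dict[int, list[tuple[int, int]]] = {}
        for i, (s, e, cc) in enumerate(seq.segments):
            if cc == c and nt_flags[i]:
                per_cont.setdefault(seg_cont[i], []).append((s, e))
        for lst in per_cont.values():
            for (s1, e1), (s2, e2) in zip(lst, lst[1:]):
                gaps.append(s2 - e1)
        if gaps:
            mean_interval[c] = float(np.mean(gaps)) / fs * 1000.0
        # GEV over all labelled samples of the class
        mask = seq.labels == c
        if gfp_sq_total > 0:
            num = float(((gfp_values[mask] * corr[mask, c]) ** 2).sum())
            gev[c] = num / gfp_sq_total

    # SC[X, Y]: template X vs maps assigned to Y (non-truncated segments)
    for y in range(k):
        own = [(s, e) for s, e, cc in segs_nt if cc == y]
        if not own:
            continue
        samp = np.concatenate([np.arange(s, e) for s, e in own])
        sc[:, y] = np.abs(corr[samp]).mean(axis=0)

    # TP: transitions between consecutive non-truncated segments in the
    # same continuity segment
    counts = np.zeros((k, k))
    for i in range(len(seq.segments) - 1):
        if (nt_flags[i] and nt_flags[i + 1]
                and seg_cont[i] == seg_cont[i + 1]):
            counts[seq.segments[i][2], seq.segments[i + 1][2]] += 1
    for c in range(k):
        row = counts[c].sum()
        tp[c] = counts[c] / row if row > 0 else np.nan

    return MicrostateFeatures(
        class_names=list(templates.class_names),
        gev=gev, mean_duration=mean_duration, occurrence=occurrence,
        coverage=coverage, mean_interval=mean_interval, mean_gfp=mean_gfp,
        sc=sc, tp=tp,
    )
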