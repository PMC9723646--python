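"""Recovery benchmarks run on synthetic data with known ground truth.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline, and returns the measured quantities (error rates,
recall/precision, p-values). They back both the acceptance test suite
and the ``scripts/acceptance.py`` reporting script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from ms2burst.burst_call import (
    BurstCallConfig,
    call_traceset,
    default_start_threshold,
    detect_bursts,
    smooth_trace,
)
from ms2burst.chip import CoverageTrack, GeneRecord, pausing_index, peak_fold_change
from ms2burst.segmentation import SegmentationConfig, segment_movie
from ms2burst.spot_quant import extract_traces, fit_gaussian2d
from ms2burst.stats import compare_conditions, wilcoxon_rank_sum
from ms2burst.synth import SceneConfig, simulate_scene, simulate_telegraph
from ms2burst.tracking import track_movie


def _render_gaussian_window(i0, sx, sy, alpha, cx, cy, shape=(11, 11)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return alpha + i0 * np.exp(
        -((xx - cx) ** 2 / (2 * sx**2) + (yy - cy) ** 2 / (2 * sy**2))
    )


def gaussian_fit_benchmark(seed: int, n_noiseless: int = 200, n_poisson: int = 500) -> dict:
    """Fit fidelity on rendered spots.

    Noise-free: worst relative error of the fitted integral against the
    analytic value 2*pi*sx*sy*I0, plus the exact integral-identity
    residual. Poisson noise at SNR ~10: median relative error and mean
    bias over replicates.
    """
    rng = np.random.default_rng(seed)
    worst_rel = 0.0
    worst_identity = 0.0
    for _ in range(n_noiseless):
        i0 = rng.uniform(50, 500)
        sx, sy = rng.uniform(1.0, 2.5, 2)
        alpha = rng.uniform(0, 50)
        cx, cy = rng.uniform(4.0, 6.0, 2)
        win = _render_gaussian_window(i0, sx, sy, alpha, cx, cy)
        fit = fit_gaussian2d(win)
        truth = 2 * np.pi * sx * sy * i0
        if fit.fit_ok:
            worst_rel = max(worst_rel, abs(fit.integral - truth) / truth)
            worst_identity = max(
                worst_identity,
                abs(fit.integral - 2 * np.pi * fit.sigma_x * fit.sigma_y * fit.amplitude),
            )

    i0, sx, sy, alpha = 100.0, 1.5, 1.5, 10.0
    clean = _render_gaussian_window(i0, sx, sy, alpha, 5.0, 5.0)
    truth = 2 * np.pi * sx * sy * i0
    errs = []
    for _ in range(n_poisson):
        fit = fit_gaussian2d(rng.poisson(clean).astype(float))
        if fit.fit_ok:
            errs.append((fit.integral - truth) / truth)
    errs = np.asarray(errs)
    return {
        "noiseless_max_rel_err": float(worst_rel),
        "integral_identity_max_residual": float(worst_identity),
        "poisson_median_rel_err": float(np.median(np.abs(errs))),
        "poisson_bias": float(errs.mean()),
        "poisson_n_ok": int(errs.size),
    }


def demo_scene(seed: int, n_nuclei: int = 50, frame_count: int = 200) -> SceneConfig:
    """The standard benchmark scene: drifting nuclei, noise on."""
    return SceneConfig(
        n_nuclei=n_nuclei,
        frame_count=frame_count,
        image_shape=(3, 220, 300),
        drift_sigma=0.5,
        seed=seed,
    )


def segmentation_tracking_benchmark(
    seed: int, n_nuclei: int = 50, frame_count: int = 200, match_radius: float = 3.0
) -> dict:
    """Per-frame nuclei recall/precision and track-identity agreement
    against the simulator's ground truth on the demo scene."""
    scene = demo_scene(seed, n_nuclei, frame_count)
    movie, truth = simulate_scene(scene)
    frames = segment_movie(movie, SegmentationConfig())
    tracks = track_movie(frames)

    recalls, precisions = [], []
    for lf in frames:
        got = np.array([lf.centroids[i] for i in lf.region_labels]).reshape(-1, 2)
        if got.size == 0:
            recalls.append(0.0)
            precisions.append(0.0)
            continue
        d = cdist(truth.centroids[lf.frame_index], got)
        recalls.append(float((d.min(axis=1) < match_radius).mean()))
        precisions.append(float((d.min(axis=0) < match_radius).mean()))

    consistent = 0
    for tid in tracks.track_ids:
        sub = tracks.table[tracks.table["track_id"] == tid]
        followed = set()
        for row in sub.itertuples():
            d = np.hypot(
                truth.centroids[row.frame][:, 0] - row.centroid_row,
                truth.centroids[row.frame][:, 1] - row.centroid_col,
            )
            followed.add(int(np.argmin(d)))
        consistent += len(followed) == 1 and len(sub) == frame_count
    return {
        "recall": float(min(recalls)),
        "precision": float(min(precisions)),
        "n_tracks": len(tracks.track_ids),
        "track_identity_agreement": consistent / max(len(tracks.track_ids), 1),
    }


def burst_recovery_benchmark(
    seed: int, n_traces: int = 100, snr: float = 10.0
) -> dict:
    """Burst recall/precision on constructed ON/OFF traces.

    Traces carry rectangular ON intervals of >= 8 frames separated by
    >= 10 OFF frames, measurement noise at the given SNR and a zero
    floor (as produced by failed fits on empty windows); a detection
    counts when it overlaps a true interval by >= 50% of the shorter.
    """
    rng = np.random.default_rng(seed)
    height = 1000.0
    noise_sd = height / snr
    config = BurstCallConfig(start_threshold=0.3 * height)
    hits = n_true = n_det = 0
    for _ in range(n_traces):
        n = 150
        intervals = []
        t = int(rng.integers(5, 15))
        while t + 8 < n - 5:
            length = int(rng.integers(8, 16))
            end = min(t + length - 1, n - 1)
            intervals.append((t, end))
            t = end + 1 + int(rng.integers(10, 25))
        raw = np.zeros(n)
        for s, e in intervals:
            raw[s : e + 1] = height
        raw = np.clip(raw + rng.normal(0, noise_sd, n), 0.0, None)
        raw -= raw.min()
        detected = [
            (b.start_frame, b.end_frame)
            for b in detect_bursts(smooth_trace(raw, 5), config)
        ]
        n_true += len(intervals)
        n_det += len(detected)
        for s, e in intervals:
            for ds, de in detected:
                ov = min(e, de) - max(s, ds) + 1
                if ov >= 0.5 * min(e - s + 1, de - ds + 1):
                    hits += 1
                    break
    return {
        "recall": hits / n_true,
        "precision": hits / n_det if n_det else 0.0,
        "n_true_bursts": n_true,
        "n_detected": n_det,
    }


WEAKENED = dict(k_on_factor=0.5, loading_factor=0.5)


def effect_detection_benchmark(
    seed: int, n_nuclei: int = 100, frame_count: int = 120
) -> dict:
    """Full-pipeline two-condition comparison.

    Condition B halves both ``k_on`` and ``loading_rate`` relative to
    control A; both conditions are rendered, segmented, tracked, fit and
    burst-called with one shared threshold derived from the control, and
    total output compared by the two-sided rank-sum test.
    """
    base = SceneConfig(
        n_nuclei=n_nuclei, frame_count=frame_count, image_shape=(3, 220, 300)
    )
    weak_params = dataclasses.replace(
        base.telegraph,
        k_on=base.telegraph.k_on * WEAKENED["k_on_factor"],
        loading_rate=base.telegraph.loading_rate * WEAKENED["loading_factor"],
    )
    summaries = {}
    threshold = None
    for name, params, s in (
        ("control", base.telegraph, seed),
        ("weakened", weak_params, seed + 1),
    ):
        scene = dataclasses.replace(base, telegraph=params, seed=s)
        movie, _ = simulate_scene(scene)
        frames = segment_movie(movie, SegmentationConfig())
        tracks = track_movie(frames)
        traces, _ = extract_traces(movie, frames, tracks)
        if threshold is None:  # one threshold per experiment set
            threshold = default_start_threshold(
                [traces.baseline_sub[t] for t in traces.track_ids]
            )
        cfg = BurstCallConfig(start_threshold=threshold)
        _, _, _, summary = call_traceset(traces, cfg)
        summaries[name] = summary
    comps, _ = compare_conditions(summaries, "control")
    by = {(c.metric, c.condition): c for c in comps}
    c = by[("total_output", "weakened")]
    return {
        "total_output_median_ratio": c.median_ratio,
        "total_output_p": c.p_value,
        "n_control": c.n_control,
        "n_weakened": c.n_condition,
        "start_threshold": threshold,
    }


def type_one_error_benchmark(
    seed: int, n_replicates: int = 100, n_nuclei: int = 100, frame_count: int = 120
) -> dict:
    """Null calibration: two identically distributed conditions per
    replicate (telegraph traces, default kinetics), total output tested
    at nominal 0.05. Reports the rejection fraction."""
    params = SceneConfig().telegraph
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for rep_seed in ss.spawn(n_replicates):
        rng = np.random.default_rng(rep_seed)
        totals = {"a": [], "b": []}
        for name in totals:
            for _ in range(n_nuclei):
                res = simulate_telegraph(params, frame_count, 16.8, rng=rng)
                totals[name].append(res.trace.sum())
        _, p = wilcoxon_rank_sum(totals["a"], totals["b"])
        rejections += p < 0.05
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}


def pausing_benchmark(seed: int, n_genes: int = 40) -> dict:
    """Analytic uniform-coverage case, brute-force oracle agreement on a
    random toy genome, and minus-strand mirror invariance."""
    cov = CoverageTrack({"chr1": np.full(10_000, 2.0)})
    uniform = pausing_index(cov, [GeneRecord("chr1", 4000, 7000, "+", "g")])
    uniform_index = float(uniform["pausing_index"].iloc[0])

    rng = np.random.default_rng(seed)
    v = rng.gamma(2.0, 1.0, 60_000)
    track = CoverageTrack({"c": v})
    genes = []
    for k in range(n_genes):
        start = int(rng.integers(0, 50_000))
        length = int(rng.integers(1500, 6000))
        genes.append(GeneRecord("c", start, start + length, "+-"[k % 2], f"g{k}"))
    df = pausing_index(track, genes).set_index("gene_id")
    worst = 0.0
    for g in genes:
        tss = g.start if g.strand == "+" else g.end
        promoter = v[max(0, tss - 250) : min(v.size, tss + 250)].sum()
        body = v[g.start + 500 : g.end - 500].sum()
        worst = max(
            worst,
            abs(df.loc[g.gene_id, "promoter_signal"] - promoter),
            abs(df.loc[g.gene_id, "body_signal"] - body),
        )

    mirrored = [
        GeneRecord("c", v.size - g.end, v.size - g.start, "-" if g.strand == "+" else "+", g.gene_id)
        for g in genes
    ]
    df2 = pausing_index(CoverageTrack({"c": v[::-1].copy()}), mirrored).set_index("gene_id")
    flip = float(
        np.nanmax(np.abs(df["pausing_index"].sort_index() - df2["pausing_index"].sort_index()))
    )
    return {
        "uniform_3000bp_index": uniform_index,
        "oracle_max_abs_diff": float(worst),
        "strand_flip_max_abs_diff": flip,
        "n_genes": n_genes,
    }


def peak_classification_benchmark(seed: int = 0) -> dict:
    """Printed toy peak set exercising the RPM filter and log2FC cutoff."""
    # (control max, treatment max, expected class)
    cases = [
        (10.0, 10.0, "associated"),
        (4.9, 100.0, "filtered"),  # below the 5 RPM control gate
        (8.0, 6.0, "diminished"),  # log2(0.75) ~ -0.415
        (20.0, 19.0, "associated"),  # log2(0.95) ~ -0.074 > -0.1
        (50.0, 40.0, "diminished"),  # log2(0.8) ~ -0.32
        (5.0, 5.0, "associated"),  # exactly at the gate: kept
        (6.0, 0.0, "filtered"),  # zero treatment maximum
    ]
    n = 1000
    ca, cb = np.zeros(n), np.zeros(n)
    peaks = []
    pos = 10
    for k, (a, b, _) in enumerate(cases):
        ca[pos], cb[pos] = a, b
        peaks.append(GeneRecord("c", pos - 5, pos + 5, "+", f"p{k}"))
        pos += 50
    df = peak_fold_change(CoverageTrack({"c": ca}), CoverageTrack({"c": cb}), peaks)
    correct = sum(
        df["class"].iloc[k] == expected for k, (_, _, expected) in enumerate(cases)
    )
    return {
        "n_peaks": len(cases),
        "n_correctly_classified": int(correct),
        "n_filtered": int(df["filtered"].sum()),
        "n_diminished": int((df["class"] == "diminished").sum()),
    }


def ranksum_sweep_benchmark(seed: int, n_cases: int = 200) -> dict:
    """Worst disagreement between the implementation and a full
    enumeration of the permutation distribution, over random small
    samples (min(n) <= 8) with and without ties."""
    from itertools import combinations

    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_cases):
        n1 = int(rng.integers(1, 9))
        n2 = int(rng.integers(1, 11))
        if k % 2:
            a = rng.integers(0, 4, n1).astype(float)
            b = rng.integers(0, 4, n2).astype(float)
        else:
            a, b = rng.normal(size=n1), rng.normal(size=n2)
        _, p = wilcoxon_rank_sum(a, b)
        combined = np.concatenate([a, b])
        order = np.argsort(combined, kind="mergesort")
        ranks = np.empty(combined.size)
        sv = combined[order]
        i = 0
        while i < sv.size:
            j = i
            while j + 1 < sv.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        w_obs = ranks[:n1].sum()
        mu = n1 * (combined.size + 1) / 2
        hits = total = 0
        for idx in combinations(range(combined.size), n1):
            w = ranks[list(idx)].sum()
            hits += abs(w - mu) >= abs(w_obs - mu) - 1e-9
            total += 1
        worst = max(worst, abs(p - hits / total))
    return {"max_abs_p_diff": float(worst), "n_cases": n_cases}
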