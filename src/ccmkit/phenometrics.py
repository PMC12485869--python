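"""Per-field phenotype metrics for collective cell migration.

Four metrics summarise each imaging field:

* **cell_count_norm** — cells per frame normalised by the T0 count
  (proliferation proxy).
* **msd_slope** — ordinary-least-squares slope of the ensemble
  time-averaged mean squared displacement against lag time, over lags
  from 30 min to 6 h by default.  For 2D Brownian motion the MSD is
  ``4*D*tau``, so the slope estimates ``4D`` (px^2/min).
* **nn_index** — mean distance to each cell's k-th nearest neighbour,
  normalised by its expectation under complete spatial randomness at the
  same density (a Clark–Evans-style index; < 1 indicates clustering).
* **cosine_similarity** — mean cosine between each cell's frame-to-frame
  displacement and the displacements of its nearest neighbours
  (an order parameter for collective, co-directed motion; ~0 for
  independent walkers, -> 1 for shared drift).

Quality control: tracks containing any single-interval jump above a
threshold (200 px per 30 min by default) are treated as tracking errors
and excluded from the displacement-based metrics (MSD, cosine).  Counts
and nearest-neighbour distances are position-based and use all cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import gammaln

from .trackio import TrackSet

log = logging.getLogger(__name__)

__all__ = [
    "MetricParams", "qc_filter_tracks", "normalized_cell_count",
    "expected_nn_distance", "nn_distance_index", "msd_curve", "msd_slope",
    "per_track_msd_slopes", "collectivity_cosine", "compute_phenotype_table",
]


@dataclass(frozen=True)
class MetricParams:
    """Fixed quantification constants.

    ``jump_threshold``: px per frame interval above which a step flags the
    whole track as a tracking error (strict inequality).
    ``msd_min_lag``/``msd_max_lag``: lag window in minutes for the MSD fit.
    ``n_neighbors_cosine``: neighbours per focal cell for the cosine metric.
    ``nn_order``: neighbour rank whose observed distance is measured
    (2 = second-nearest cell).
    ``nn_expectation_order``: ``"first"`` normalises by the expected
    *nearest*-neighbour distance under CSR (the literal published rule;
    on CSR the order-2 index then converges to 3/2), ``"matched"``
    normalises by the expectation of the same order (index -> 1 on CSR).
    """

    jump_threshold: float = 200.0
    msd_min_lag: float = 30.0
    msd_max_lag: float = 360.0
    n_neighbors_cosine: int = 10
    nn_order: int = 2
    nn_expectation_order: str = "first"
    frame_interval: float = 30.0

    def __post_init__(self) -> None:
        if self.jump_threshold <= 0:
            raise ValueError("jump_threshold must be > 0")
        if self.msd_min_lag > self.msd_max_lag:
            raise ValueError("msd_min_lag must be <= msd_max_lag")
        if self.n_neighbors_cosine < 1 or self.nn_order < 1:
            raise ValueError("n_neighbors_cosine and nn_order must be >= 1")
        if self.nn_expectation_order not in ("first", "matched"):
            raise ValueError("nn_expectation_order must be 'first' or 'matched'")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")


def _consecutive_steps(df: pd.DataFrame) -> pd.DataFrame:
    """Frame-to-frame displacement rows (only consecutive-frame pairs)."""
    d = df.sort_values(["track_id", "frame"], kind="mergesort")
    same = d["track_id"].to_numpy()[1:] == d["track_id"].to_numpy()[:-1]
    dframe = np.diff(d["frame"].to_numpy())
    dx = np.diff(d["x"].to_numpy())
    dy = np.diff(d["y"].to_numpy())
    ok = same & (dframe == 1)
    return pd.DataFrame({
        "track_id": d["track_id"].to_numpy()[:-1][ok],
        "frame": d["frame"].to_numpy()[:-1][ok],   # start frame of the step
        "dx": dx[ok], "dy": dy[ok],
    })


def qc_filter_tracks(ts: TrackSet, params: MetricParams) -> tuple[TrackSet, list]:
    """Drop whole tracks containing any step longer than the jump threshold.

    Returns the filtered TrackSet and the sorted list of excluded ids.
    A track is excluded if *any* consecutive-frame displacement strictly
    exceeds ``params.jump_threshold``.
    """
    steps = _consecutive_steps(ts.data)
    if steps.empty:
        return ts.with_data(ts.data.copy()), []
    norm = np.hypot(steps["dx"], steps["dy"])
    bad = steps.loc[norm > params.jump_threshold, "track_id"].unique()
    excluded = sorted(bad.tolist())
    kept = ts.data[~ts.data["track_id"].isin(bad)].copy()
    return ts.with_data(kept), excluded


def normalized_cell_count(ts: TrackSet) -> pd.Series:
    """Cells observed per frame, divided by the frame-0 count."""
    counts = ts.counts_per_frame()
    if 0 not in counts.index or counts.loc[0] == 0:
        raise ValueError("frame 0 is empty: cannot normalise cell counts")
    return counts / counts.loc[0]


def expected_nn_distance(intensity: float, order: int = 1) -> float:
    """E[distance to the k-th nearest point] under CSR at the given intensity.

    For a homogeneous Poisson process of intensity rho in the plane,
    ``E[r_k] = Gamma(k + 1/2) / (Gamma(k) * sqrt(pi * rho))``;
    k=1 gives the Clark–Evans ``1 / (2*sqrt(rho))``, k=2 gives
    ``3 / (4*sqrt(rho))``.
    """
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    k = order
    return float(np.exp(gammaln(k + 0.5) - gammaln(k)) / np.sqrt(np.pi * intensity))


def nn_distance_index(points: np.ndarray, area: float,
                      params: MetricParams = MetricParams()) -> float:
    """Observed mean k-th-nearest-neighbour distance / CSR expectation.

    ``points`` is an (n, 2) array of one frame's cell centroids.  The
    observed distance uses rank ``params.nn_order``; the CSR expectation
    uses rank 1 (mode ``"first"``) or the same rank (mode ``"matched"``).
    Returns NaN with a warning when fewer than ``nn_order + 1`` cells are
    present.  No edge correction is applied.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < params.nn_order + 1:
        warnings.warn(f"nn_distance_index undefined: {n} cells < order+1")
        return float("nan")
    if area <= 0:
        raise ValueError("area must be > 0")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=params.nn_order + 1)
    observed = float(dist[:, params.nn_order].mean())
    exp_order = 1 if params.nn_expectation_order == "first" else params.nn_order
    expected = expected_nn_distance(n / area, order=exp_order)
    return observed / expected


def msd_curve(ts: TrackSet, params: MetricParams = MetricParams()) -> pd.DataFrame:
    """Ensemble time-averaged MSD per lag within the configured window.

    All overlapping start points of every gap-free consecutive run
    contribute; displacements spanning a frame gap are never used.
    Columns: ``lag`` (minutes), ``msd`` (px^2), ``n_pairs``.
    """
    dt = params.frame_interval
    min_f = max(1, int(np.ceil(params.msd_min_lag / dt)))
    max_f = int(np.floor(params.msd_max_lag / dt))
    sums = np.zeros(max_f + 1)
    counts = np.zeros(max_f + 1, dtype=int)
    for _, sub in ts.data.groupby("track_id"):
        frames = sub["frame"].to_numpy()
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        # split the track into runs of strictly consecutive frames
        breaks = np.flatnonzero(np.diff(frames) != 1) + 1
        for run in np.split(np.arange(len(frames)), breaks):
            if len(run) < 2:
                continue
            p = xy[run]
            top = min(max_f, len(p) - 1)
            for lag in range(min_f, top + 1):
                d = p[lag:] - p[:-lag]
                sums[lag] += float(np.einsum("ij,ij->", d, d))
                counts[lag] += len(d)
    lags = np.arange(min_f, max_f + 1)
    usable = counts[lags] > 0
    lags = lags[usable]
    if len(lags) == 0:
        raise ValueError("no usable lag pairs for MSD")
    return pd.DataFrame({
        "lag": lags * dt,
        "msd": sums[lags] / counts[lags],
        "n_pairs": counts[lags],
    })


def msd_slope(ts: TrackSet, params: MetricParams = MetricParams()) -> float:
    """OLS slope (with intercept) of MSD against lag time, in px^2/min."""
    curve = msd_curve(ts, params)
    if len(curve) == 1:
        # single lag: slope through the origin is the only estimate
        return float(curve["msd"].iloc[0] / curve["lag"].iloc[0])
    slope, _ = np.polyfit(curve["lag"], curve["msd"], 1)
    return float(slope)


def per_track_msd_slopes(ts: TrackSet, params: MetricParams = MetricParams()) -> pd.Series:
    """Diagnostic per-track MSD slopes (NaN where a track has no usable lags)."""
    out = {}
    for tid in ts.track_ids:
        single = ts.with_data(ts.data[ts.data["track_id"] == tid])
        try:
            out[tid] = msd_slope(single, params)
        except ValueError:
            out[tid] = float("nan")
    return pd.Series(out, name="msd_slope")


def collectivity_cosine(ts: TrackSet, params: MetricParams = MetricParams()) -> float:
    """Mean cosine between neighbouring cells' frame-to-frame displacements.

    For every consecutive frame pair, each cell with a nonzero
    displacement is compared with its ``n_neighbors_cosine`` nearest
    cells (positions at the pair's first frame; fewer when the field has
    fewer cells; zero-length displacement vectors are excluded).  Returns
    the grand mean over all (focal, neighbour, frame) triples; NaN with a
    warning when no triple is defined.
    """
    steps = _consecutive_steps(ts.data)
    if steps.empty:
        warnings.warn("collectivity_cosine undefined: no consecutive steps")
        return float("nan")
    pos = ts.data.set_index(["frame", "track_id"])[["x", "y"]]
    total, count = 0.0, 0
    n_zero = 0
    for frame, sub in steps.groupby("frame"):
        disp = sub[["dx", "dy"]].to_numpy(dtype=float)
        norms = np.linalg.norm(disp, axis=1)
        nz = norms > 0
        n_zero += int((~nz).sum())
        if nz.sum() < 2:
            continue
        ids = sub["track_id"].to_numpy()[nz]
        units = disp[nz] / norms[nz, None]
        pts = pos.loc[[(frame, tid) for tid in ids]].to_numpy(dtype=float)
        k = min(params.n_neighbors_cosine + 1, len(pts))
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k)
        # drop self by identity: with coincident points the self column is
        # not guaranteed to be first
        neigh = np.array([[j for j in row if j != i][: k - 1]
                          for i, row in enumerate(idx)])
        cos = np.einsum("ij,ikj->ik", units, units[neigh])
        total += float(cos.sum())
        count += cos.size
    if n_zero:
        log.info("collectivity_cosine: excluded %d zero-length displacement(s)", n_zero)
    if count == 0:
        warnings.warn("collectivity_cosine undefined: all displacements zero")
        return float("nan")
    return total / count


def compute_phenotype_table(tracksets, params: MetricParams = MetricParams()) -> pd.DataFrame:
    """One phenotype-score row per TrackSet.

    ``cell_count_norm`` is the final-frame normalised count; ``nn_index``
    is the time-average of the per-frame index, with the final-frame
    value reported alongside (``nn_index_final``); MSD slope and cosine
    similarity are computed on jump-filtered tracks.  Per-metric failures
    yield NaN without aborting the table.
    """
    rows = []
    for ts in tracksets:
        area = ts.field_width * ts.field_height
        filtered, excluded = qc_filter_tracks(ts, params)

        try:
            counts = normalized_cell_count(ts)
            count_norm = float(counts.iloc[-1])
            n_t0 = int(ts.counts_per_frame().loc[0])
        except (ValueError, KeyError):
            count_norm, n_t0 = float("nan"), 0

        nn_vals = []
        if area > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for frame in ts.frames:
                    nn_vals.append(nn_distance_index(ts.positions_at(frame), area, params))
        nn_series = pd.Series(nn_vals, dtype=float)
        nn_mean = float(nn_series.mean()) if nn_series.notna().any() else float("nan")
        nn_final = float(nn_series.iloc[-1]) if len(nn_series) else float("nan")

        try:
            slope = msd_slope(filtered, params)
        except ValueError:
            slope = float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cosine = collectivity_cosine(filtered, params)

        rows.append({
            "field_id": ts.field_id, "condition": ts.condition,
            "knockdown": ts.knockdown, "replicate": ts.replicate,
            "cell_count_norm": count_norm, "msd_slope": slope,
            "nn_index": nn_mean, "nn_index_final": nn_final,
            "cosine_similarity": cosine,
            "n_cells_t0": n_t0,
            "n_tracks_used": filtered.n_tracks,
            "n_tracks_excluded": len(excluded),
        })
    columns = ["field_id", "condition", "knockdown", "replicate",
               "cell_count_norm", "msd_slope", "nn_index", "nn_index_final",
               "cosine_similarity", "n_cells_t0", "n_tracks_used",
               "n_tracks_excluded"]
    return pd.DataFrame(rows, columns=columns)
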