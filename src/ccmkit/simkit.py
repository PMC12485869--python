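"""Synthetic tracks, point patterns, phenotype tables and network pairs.

Everything here carries a known ground truth so that every downstream
metric can be verified against a closed form or a construction oracle:

* :func:`simulate_tracks` — 2D agent tracks at a fixed frame interval.
  Per-frame displacement is an isotropic Gaussian step (per-axis variance
  ``2 * D * dt``, the Brownian law), plus optional persistent per-cluster
  drift and an attraction toward the cluster centroid.  Cell division and
  tracking-error jump artifacts can be injected, with the affected track
  ids reported as ground truth.
* :func:`simulate_point_pattern` — CSR, Thomas-cluster and square-lattice
  point patterns for validating the nearest-neighbor clustering index.
* :func:`simulate_condition_networks` — a pair of typed directed networks
  where network B is network A with a known set of per-node edge edits.
* :func:`simulate_phenotype_table` — replicate-level phenotype scores with
  planted multiplicative effects for screen statistics.

The three regime presets emulate the phenotypic regimes of an epithelial
ligand experiment imaged every 30 minutes for 48 h: a baseline dispersed
Brownian regime (EGF-like), a fast dispersed regime (IFNG-like, higher
diffusion), and a cohesive clustered co-drifting regime (OSM-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trackio import TrackSet

__all__ = [
    "SimulationConfig", "GroundTruth", "PointPattern", "ConditionNetwork",
    "REGIME_PRESETS", "preset_config",
    "simulate_tracks", "simulate_tracks_with_truth", "simulate_point_pattern",
    "simulate_condition_networks", "simulate_planted_rewiring",
    "simulate_phenotype_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic imaging field.

    Units: lengths in px, times in minutes, ``diffusion_coefficient`` in
    px^2/min (per-axis step variance ``2*D*dt``), ``drift_speed`` in
    px/min along a fixed per-cluster heading, ``cohesion_strength`` in
    px/min of attraction toward the cell's cluster centroid (the step is
    capped at the remaining distance to avoid overshoot),
    ``division_rate`` in divisions/cell/hour, ``jump_fraction`` the
    probability that a track receives one injected artifact jump of
    magnitude in (200, 400] px.
    """

    field_width: float = 2000.0
    field_height: float = 2000.0
    n_cells_t0: int = 250
    n_frames: int = 96
    frame_interval: float = 30.0
    diffusion_coefficient: float = 5.0
    drift_speed: float = 0.0
    cohesion_strength: float = 0.0
    n_clusters: int = 1
    division_rate: float = 0.0
    jump_fraction: float = 0.0
    init_cluster_sd: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        numeric = {
            "field_width": self.field_width, "field_height": self.field_height,
            "n_cells_t0": self.n_cells_t0, "n_frames": self.n_frames,
            "frame_interval": self.frame_interval,
            "diffusion_coefficient": self.diffusion_coefficient,
            "drift_speed": self.drift_speed,
            "cohesion_strength": self.cohesion_strength,
            "n_clusters": self.n_clusters, "division_rate": self.division_rate,
            "jump_fraction": self.jump_fraction,
            "init_cluster_sd": self.init_cluster_sd,
        }
        for name, v in numeric.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_cells_t0 < 1 or self.n_clusters < 1:
            raise ValueError("n_cells_t0 and n_clusters must be >= 1")
        if self.jump_fraction > 1:
            raise ValueError("jump_fraction must be in [0, 1]")
        if self.jump_fraction > 0 and min(self.field_width, self.field_height) <= 800:
            # jump magnitudes up to 400 px are steered toward the field
            # center; fields narrower than 800 px cannot contain them
            raise ValueError("jump injection requires min(field dims) > 800 px")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually did: the oracle for downstream tests."""

    jump_track_ids: frozenset
    cluster_of: dict            # track_id -> cluster index
    parent_of: dict             # daughter track_id -> parent track_id
    cluster_headings: np.ndarray  # (n_clusters, 2) unit vectors


#: phenotypic regime presets (baseline / fast-dispersed / cohesive-collective)
REGIME_PRESETS: dict[str, SimulationConfig] = {
    "EGF_like": SimulationConfig(diffusion_coefficient=5.0, drift_speed=0.0,
                                 cohesion_strength=0.0, n_clusters=1,
                                 division_rate=0.01, jump_fraction=0.02),
    "IFNG_like": SimulationConfig(diffusion_coefficient=25.0, drift_speed=0.0,
                                  cohesion_strength=0.0, n_clusters=1,
                                  division_rate=0.01, jump_fraction=0.02),
    "OSM_like": SimulationConfig(diffusion_coefficient=5.0, drift_speed=0.3,
                                 cohesion_strength=0.3, n_clusters=5,
                                 division_rate=0.01, jump_fraction=0.02),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A regime preset with its seed (and optionally other fields) replaced."""
    if name not in REGIME_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(REGIME_PRESETS)}")
    return replace(REGIME_PRESETS[name], seed=seed, **overrides)


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangular fold, 1-Lipschitz)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def simulate_tracks_with_truth(
    config: SimulationConfig,
    *,
    field_id: str = "sim",
    condition: str = "synthetic",
    knockdown: str | None = None,
    replicate: int = 1,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate one field of cell tracks and return the ground truth too.

    Dynamics per frame: Gaussian step with per-axis variance ``2*D*dt``,
    plus ``drift_speed*dt`` along the cell's cluster heading (fixed per
    cluster, drawn uniformly on the circle at T0), plus a pull of at most
    ``cohesion_strength*dt`` toward the current cluster centroid.
    Reflecting field boundaries.  Divisions spawn a new track at the
    parent position, first observed on the next frame.  Jump artifacts
    re-point one step of the affected track to a magnitude in (200, 400] px.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h, dt = config.field_width, config.field_height, config.frame_interval
    n0, k = config.n_cells_t0, config.n_clusters

    headings_angle = rng.uniform(0.0, 2.0 * math.pi, size=k)
    headings = np.column_stack([np.cos(headings_angle), np.sin(headings_angle)])

    if k == 1:
        pos = np.column_stack([rng.uniform(0, w, n0), rng.uniform(0, h, n0)])
        cluster = np.zeros(n0, dtype=int)
    else:
        margin = min(0.25 * min(w, h), 400.0)
        centers = np.column_stack([
            rng.uniform(margin, w - margin, k),
            rng.uniform(margin, h - margin, k),
        ])
        cluster = rng.integers(0, k, size=n0)
        pos = centers[cluster] + rng.normal(0.0, config.init_cluster_sd, size=(n0, 2))
        pos[:, 0] = _fold(pos[:, 0], 0.0, w)
        pos[:, 1] = _fold(pos[:, 1], 0.0, h)

    ids = np.arange(n0)
    next_id = n0
    parent_of: dict = {}
    step_sd = math.sqrt(2.0 * config.diffusion_coefficient * dt)
    p_div = config.division_rate * dt / 60.0
    max_pull = config.cohesion_strength * dt

    rec_ids = [ids.copy()]
    rec_frames = [np.zeros(n0, dtype=int)]
    rec_pos = [pos.copy()]

    for frame in range(1, config.n_frames):
        # divisions decided on the previous frame; daughters step with everyone
        if p_div > 0:
            dividing = rng.random(len(ids)) < p_div
            n_new = int(dividing.sum())
            if n_new:
                new_ids = np.arange(next_id, next_id + n_new)
                for pid, did in zip(ids[dividing], new_ids):
                    parent_of[int(did)] = int(pid)
                next_id += n_new
                ids = np.concatenate([ids, new_ids])
                pos = np.vstack([pos, pos[dividing]])
                cluster = np.concatenate([cluster, cluster[dividing]])

        step = rng.normal(0.0, step_sd, size=pos.shape) if step_sd > 0 else np.zeros_like(pos)
        if config.drift_speed > 0:
            step += config.drift_speed * dt * headings[cluster]
        if max_pull > 0:
            centroids = np.zeros((k, 2))
            counts = np.bincount(cluster, minlength=k).astype(float)
            np.add.at(centroids, cluster, pos)
            nonzero = counts > 0
            centroids[nonzero] /= counts[nonzero, None]
            delta = centroids[cluster] - pos
            dist = np.linalg.norm(delta, axis=1)
            pull = np.minimum(max_pull, dist)
            safe = dist > 0
            step[safe] += (pull[safe] / dist[safe])[:, None] * delta[safe]

        pos = pos + step
        pos[:, 0] = _fold(pos[:, 0], 0.0, w)
        pos[:, 1] = _fold(pos[:, 1], 0.0, h)

        rec_ids.append(ids.copy())
        rec_frames.append(np.full(len(ids), frame, dtype=int))
        rec_pos.append(pos.copy())

    df = pd.DataFrame({
        "track_id": np.concatenate(rec_ids),
        "frame": np.concatenate(rec_frames),
        "x": np.concatenate(rec_pos)[:, 0],
        "y": np.concatenate(rec_pos)[:, 1],
    })

    jump_ids: set = set()
    if config.jump_fraction > 0:
        center = np.array([w / 2.0, h / 2.0])
        df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
        for tid, sub in df.groupby("track_id", sort=True):
            if len(sub) < 2 or rng.random() >= config.jump_fraction:
                continue
            jump_ids.add(int(tid))
            idx = sub.index.to_numpy()
            j = int(rng.integers(1, len(idx)))          # step (j-1) -> j
            xy = df.loc[idx, ["x", "y"]].to_numpy()
            u = 200.0 + 200.0 * (1.0 - rng.random())    # (200, 400]
            origin = xy[j - 1]
            d = center - origin
            nd = np.linalg.norm(d)
            direction = d / nd if nd > 0 else np.array([1.0, 0.0])
            target = origin + u * direction             # in bounds by construction
            shift = target - xy[j]
            tail = xy[j:] + shift
            tail[:, 0] = _fold(tail[:, 0], 0.0, w)
            tail[:, 1] = _fold(tail[:, 1], 0.0, h)
            tail[0] = target                            # never needs folding
            df.loc[idx[j:], ["x", "y"]] = tail

    ts = TrackSet(
        df, field_id=field_id, condition=condition, knockdown=knockdown,
        replicate=replicate, field_width=w, field_height=h, frame_interval=dt,
    )
    cluster_of = {int(t): int(c) for t, c in zip(rec_ids[-1], cluster)}
    truth = GroundTruth(
        jump_track_ids=frozenset(jump_ids),
        cluster_of=cluster_of,
        parent_of=parent_of,
        cluster_headings=headings,
    )
    return ts, truth


def simulate_tracks(config: SimulationConfig, **meta) -> TrackSet:
    """Simulate one field of cell tracks (see :func:`simulate_tracks_with_truth`)."""
    return simulate_tracks_with_truth(config, **meta)[0]


# ---------------------------------------------------------------------------
# spatial point patterns


@dataclass(frozen=True)
class PointPattern:
    points: np.ndarray          # (n, 2)
    width: float
    height: float
    kind: str

    @property
    def intensity(self) -> float:
        return len(self.points) / (self.width * self.height)


def simulate_point_pattern(
    kind: str, n_points: int, width: float, height: float,
    params: dict | None = None, seed: int = 0,
) -> PointPattern:
    """Generate a planar point pattern.

    ``CSR`` is complete spatial randomness (independent uniforms),
    ``Thomas_cluster`` scatters daughters with Gaussian spread ``sigma``
    around uniformly placed parents (``n_parents``), ``square_lattice``
    is a regular grid (``n_points`` must be a perfect square).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "CSR":
        pts = np.column_stack([rng.uniform(0, width, n_points),
                               rng.uniform(0, height, n_points)])
    elif kind == "Thomas_cluster":
        n_parents = int(params.get("n_parents", max(1, n_points // 20)))
        sigma = float(params.get("sigma", 0.02 * min(width, height)))
        parents = np.column_stack([rng.uniform(0, width, n_parents),
                                   rng.uniform(0, height, n_parents)])
        which = rng.integers(0, n_parents, size=n_points)
        pts = parents[which] + rng.normal(0.0, sigma, size=(n_points, 2))
        pts[:, 0] = _fold(pts[:, 0], 0.0, width)
        pts[:, 1] = _fold(pts[:, 1], 0.0, height)
    elif kind == "square_lattice":
        m = math.isqrt(n_points)
        if m * m != n_points:
            raise ValueError("square_lattice requires n_points to be a perfect square")
        sx, sy = width / m, height / m
        gx, gy = np.meshgrid((np.arange(m) + 0.5) * sx, (np.arange(m) + 0.5) * sy)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return PointPattern(points=pts, width=float(width), height=float(height), kind=kind)


# ---------------------------------------------------------------------------
# condition-network pairs with known per-node edits


@dataclass(frozen=True)
class ConditionNetwork:
    """Typed directed interaction network for one treatment condition.

    Edges are (source, relation, target) triples; edge identity includes
    the relation label and orientation.
    """

    condition: str
    edges: frozenset

    @property
    def nodes(self) -> frozenset:
        return frozenset(n for s, _, t in self.edges for n in (s, t))

    def incident_edges(self, node) -> frozenset:
        return frozenset(e for e in self.edges if node in (e[0], e[2]))


_RELATIONS = ("upregulates-expression", "downregulates-expression",
              "phosphorylates", "dephosphorylates")


def _random_edges(nodes, m, rng, forbidden=frozenset()):
    edges = set()
    names = list(nodes)
    while len(edges) < m:
        s, t = rng.choice(len(names), size=2, replace=False)
        rel = _RELATIONS[int(rng.integers(len(_RELATIONS)))]
        e = (names[s], rel, names[t])
        if e not in forbidden:
            edges.add(e)
    return edges


def simulate_condition_networks(
    n_nodes: int, rewired_fraction: float, seed: int = 0,
    mean_degree: float = 4.0,
    conditions: tuple[str, str] = ("IFNG", "OSM"),
) -> tuple[ConditionNetwork, ConditionNetwork, pd.Series]:
    """A network pair where B is A with a known set of edge edits.

    Returns ``(net_a, net_b, truth)`` where ``truth[node]`` is the exact
    number of incident-edge additions + deletions applied to that node
    (each edited edge counts once for each endpoint it touches).
    """
    if not 0.0 <= rewired_fraction <= 1.0:
        raise ValueError("rewired_fraction must be in [0, 1]")
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [f"G{i:03d}" for i in range(n_nodes)]
    m = max(1, round(mean_degree * n_nodes / 2))
    edges_a = _random_edges(nodes, m, rng)

    n_edits = round(rewired_fraction * m)
    n_del = n_edits // 2
    n_add = n_edits - n_del
    edge_list = sorted(edges_a)
    del_idx = rng.choice(len(edge_list), size=n_del, replace=False) if n_del else []
    deleted = {edge_list[i] for i in del_idx}
    added = _random_edges(nodes, n_add, rng, forbidden=frozenset(edges_a)) if n_add else set()
    edges_b = (edges_a - deleted) | added

    truth = pd.Series(0, index=pd.Index(nodes, name="node"), dtype=int)
    for s, _, t in deleted | added:
        truth[s] += 1
        truth[t] += 1

    return (
        ConditionNetwork(conditions[0], frozenset(edges_a)),
        ConditionNetwork(conditions[1], frozenset(edges_b)),
        truth,
    )


def simulate_planted_rewiring(
    n_nodes: int = 50, planted_edits: int = 10,
    background_fraction: float = 0.05, seed: int = 0,
) -> tuple[ConditionNetwork, ConditionNetwork, pd.DataFrame, str, pd.Series]:
    """Network pair with one heavily rewired, strongly upregulated node.

    The planted node receives ``planted_edits`` extra incident edge
    additions in network B and the largest log-fold change; background
    nodes get mild rewiring and LFCs uniform in [0, 1.5].  Returns
    ``(net_a, net_b, lfc_table, planted_node, truth)``.
    """
    rng = np.random.default_rng(seed)
    net_a, net_b, truth = simulate_condition_networks(
        n_nodes, background_fraction, seed=int(rng.integers(2**31)))
    nodes = sorted({*net_a.nodes, *net_b.nodes} | set(truth.index))
    planted = nodes[int(rng.integers(len(nodes)))]

    others = [n for n in truth.index if n != planted]
    edges_b = set(net_b.edges)
    existing = edges_b | set(net_a.edges)
    n_added = 0
    while n_added < planted_edits:
        partner = others[int(rng.integers(len(others)))]
        rel = _RELATIONS[int(rng.integers(len(_RELATIONS)))]
        e = (planted, rel, partner) if rng.random() < 0.5 else (partner, rel, planted)
        if e in existing:
            continue
        edges_b.add(e)
        existing.add(e)
        truth[planted] += 1
        truth[partner] += 1
        n_added += 1
    net_b = ConditionNetwork(net_b.condition, frozenset(edges_b))

    lfc = pd.Series(rng.uniform(0.0, 1.5, size=len(truth)), index=truth.index)
    lfc[planted] = 2.5
    lfc_table = pd.DataFrame({
        "node": lfc.index, "assay": "protein",
        "condition": net_b.condition, "lfc": lfc.to_numpy(),
    }).reset_index(drop=True)
    return net_a, net_b, lfc_table, planted, truth


# ---------------------------------------------------------------------------
# phenotype-score tables for screen statistics

PHENOTYPE_METRICS = ("cell_count_norm", "msd_slope", "nn_index", "cosine_similarity")

#: plausible control-condition means per metric (arbitrary but fixed scale)
_BASELINES = {"cell_count_norm": 2.0, "msd_slope": 60.0,
              "nn_index": 1.2, "cosine_similarity": 0.15}


def simulate_phenotype_table(
    n_knockdowns: int = 14,
    effect_matrix: np.ndarray | dict | None = None,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    treatments: tuple = ("EGF", "OSM", "IFNG"),
    metrics: tuple = PHENOTYPE_METRICS,
    control_knockdown: str = "siSCR",
) -> pd.DataFrame:
    """Long-format phenotype scores: knockdown x treatment x metric x replicate.

    Scores are ``baseline * (1 + effect) + N(0, (noise_sd*baseline)^2)``;
    ``noise_sd`` is relative to the control mean of each metric.  The
    control knockdown always has effect 0.  ``effect_matrix`` may be a
    ``(n_knockdowns, n_treatments, n_metrics)`` array or a dict keyed by
    ``(knockdown, treatment, metric)``; missing entries are 0.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    knockdowns = [control_knockdown] + [f"siKD{i+1:02d}" for i in range(n_knockdowns)]

    eff = np.zeros((len(knockdowns), len(treatments), len(metrics)))
    if isinstance(effect_matrix, np.ndarray):
        if effect_matrix.shape != (n_knockdowns, len(treatments), len(metrics)):
            raise ValueError("effect_matrix has wrong shape")
        eff[1:] = effect_matrix
    elif isinstance(effect_matrix, dict):
        for (kd, tr, me), v in effect_matrix.items():
            eff[knockdowns.index(kd), treatments.index(tr), metrics.index(me)] = v

    rows = []
    for i, kd in enumerate(knockdowns):
        for j, tr in enumerate(treatments):
            for l, me in enumerate(metrics):
                base = _BASELINES.get(me, 1.0)
                mean = base * (1.0 + eff[i, j, l])
                vals = mean + rng.normal(0.0, noise_sd * base, size=n_replicates)
                for r, v in enumerate(vals, start=1):
                    rows.append((kd, tr, me, r, v))
    return pd.DataFrame(rows, columns=["knockdown", "treatment", "metric",
                                       "replicate", "value"])
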