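"""Synthetic occurrence data, habitat-suitability tables, and rule-governed
image sequences.

Real invasive-species occurrence archives are accumulations of decades of
presence-only surveys: dense knots of points along wetland and riverside
corridors, sparse scatter elsewhere.  The generator emulates exactly the
statistical structure the pipeline assumes — spatially separated clusters
with known membership, per-cluster habitat-suitability scalars in (0, 1),
and image sequences evolved under a *known* automaton rule — so every
downstream stage can be tested end-to-end without any survey download.

The point model is a mixture of isotropic Gaussian blobs, with an optional
fraction of each blob's points jittered along a random line segment through
its centre ("corridor" points mimicking riverside concentration).  Cluster
centres are rejection-sampled to keep a minimum pairwise separation, so the
divisive clustering stage can provably recover the truth.  This is a testing
device, not a fitted point-process model of any real survey.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eca_engine
from .rasterization import GridSpec, ImageSequence

__all__ = [
    "SyntheticConfig",
    "generate_occurrences",
    "generate_hs_table",
    "generate_rule_sequence",
]

# Beta(a, b) for habitat suitability: mean 0.57, sd 0.12, matching the
# 0.33-0.80 spread typical of per-cluster Maxent summaries.
_HS_BETA_A = 9.1
_HS_BETA_B = 6.9

#: factor of cluster_spread_deg kept between cluster centres (>= the 4x
#: separation the recovery contract requires; 8x keeps misassignment
#: probability per point well under 1%)
_SEPARATION_FACTOR = 8.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults mirror the study conditions: 25 clusters whose point counts
    span the 30-267 range observed in the survey data, scattered over a
    roughly 2° × 2° coastal study window.
    """

    n_clusters: int = 25
    points_per_cluster: int | tuple[int, int] = (30, 267)
    cluster_spread_deg: float = 0.03
    bbox: tuple[float, float, float, float] = (126.11, 128.2, 34.58, 36.71)
    corridor_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.bbox
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ValueError(f"bbox must be well-ordered, got {self.bbox}")
        if self.n_clusters < 1:
            raise ValueError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if self.cluster_spread_deg <= 0:
            raise ValueError("cluster_spread_deg must be positive")
        if not 0 <= self.corridor_fraction <= 1:
            raise ValueError("corridor_fraction must be in [0, 1]")
        ppc = self.points_per_cluster
        if isinstance(ppc, tuple):
            lo, hi = ppc
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid points_per_cluster range {ppc}")
        elif ppc < 1:
            raise ValueError(f"points_per_cluster must be positive, got {ppc}")


def _sample_centers(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lon_min, lon_max, lat_min, lat_max = config.bbox
    margin = 4.0 * config.cluster_spread_deg
    min_sep = _SEPARATION_FACTOR * config.cluster_spread_deg
    lo = np.array([lon_min + margin, lat_min + margin])
    hi = np.array([lon_max - margin, lat_max - margin])
    if (hi <= lo).any():
        raise ValueError(
            "bbox too small for the requested cluster spread: "
            f"{config.bbox} with spread {config.cluster_spread_deg}"
        )
    centers: list[np.ndarray] = []
    for _ in range(20000):
        if len(centers) == config.n_clusters:
            break
        cand = lo + rng.random(2) * (hi - lo)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    else:
        raise ValueError(
            f"could not place {config.n_clusters} centres with pairwise "
            f"separation {min_sep:.3g}° inside {config.bbox}"
        )
    return np.array(centers)


def _cluster_points(
    center: np.ndarray, n: int, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    sigma = config.cluster_spread_deg
    n_corridor = int(round(config.corridor_fraction * n))
    # blob component: isotropic Gaussian scatter
    blob = center + rng.normal(scale=sigma, size=(n - n_corridor, 2))
    # corridor component: jitter along a random segment through the centre
    theta = rng.uniform(0, np.pi)
    direction = np.array([np.cos(theta), np.sin(theta)])
    t = rng.uniform(-3.0 * sigma, 3.0 * sigma, size=n_corridor)
    lateral = rng.normal(scale=sigma / 3.0, size=(n_corridor, 2))
    corridor = center + t[:, None] * direction + lateral
    pts = np.concatenate([blob, corridor])
    # resample any point that escaped the bbox (keeps the containment contract)
    lon_min, lon_max, lat_min, lat_max = config.bbox
    lo = np.array([lon_min, lat_min])
    hi = np.array([lon_max, lat_max])
    out = ((pts < lo) | (pts > hi)).any(axis=1)
    while out.any():
        pts[out] = center + rng.normal(scale=sigma, size=(int(out.sum()), 2))
        out = ((pts < lo) | (pts > hi)).any(axis=1)
    return pts


def generate_occurrences(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a synthetic occurrence set with known cluster membership.

    Returns
    -------
    occurrences : pandas.DataFrame
        Columns ``id, lon, lat``; all points inside ``config.bbox``.
    true_labels : numpy.ndarray
        0-based generating-cluster id per point.

    Cluster centres are pairwise separated by at least 4 × the point-scatter
    standard deviation (8 × by default), so the divisive clustering stage
    can recover the membership.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    centers = _sample_centers(config, rng)
    ppc = config.points_per_cluster
    if isinstance(ppc, tuple):
        counts = rng.integers(ppc[0], ppc[1] + 1, size=config.n_clusters)
    else:
        counts = np.full(config.n_clusters, ppc)
    pts_list = [
        _cluster_points(centers[i], int(counts[i]), config, rng)
        for i in range(config.n_clusters)
    ]
    pts = np.concatenate(pts_list)
    labels = np.repeat(np.arange(config.n_clusters), counts)
    occurrences = pd.DataFrame(
        {"id": np.arange(len(pts)), "lon": pts[:, 0], "lat": pts[:, 1]}
    )
    return occurrences, labels


def generate_hs_table(cluster_ids, seed: int = 0) -> pd.DataFrame:
    """Per-cluster habitat-suitability scalars drawn from Beta(9.1, 6.9).

    The Beta parameters give mean ≈ 0.57 and spread matching the 0.33-0.80
    range that per-cluster species-distribution-model summaries typically
    occupy; values are strictly inside (0, 1) by construction.
    """
    ids = list(cluster_ids)
    if not ids:
        raise ValueError("cluster_ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("cluster_ids contains duplicates")
    rng = np.random.default_rng(seed)
    hs = rng.beta(_HS_BETA_A, _HS_BETA_B, size=len(ids))
    return pd.DataFrame({"cluster_id": ids, "hs": hs})


def generate_rule_sequence(
    rule: int,
    n_initial_ones: int = 100,
    n_steps: int = 5,
    seed: int = 0,
    gridspec: GridSpec | None = None,
) -> ImageSequence:
    """An image sequence evolved from a random start under a known even rule.

    The first image has exactly ``n_initial_ones`` cells set at uniformly
    random positions; each later image is the exact one-step evolution of its
    predecessor, so every consecutive pair is a ground-truth training/test
    example for rule inference.
    """
    rule_obj = eca_engine.rule_outputs(rule)
    if not rule_obj.is_even:
        raise ValueError(f"rule {rule} is odd; only even rules are admissible")
    if gridspec is None:
        gridspec = GridSpec(0.0, 1.0, 0.0, 1.0)
    n_cells = gridspec.nx * gridspec.ny
    if not 0 <= n_initial_ones <= n_cells:
        raise ValueError(f"n_initial_ones must be in [0, {n_cells}]")
    rng = np.random.default_rng(seed)
    state = eca_engine.random_state(n_cells, n_initial_ones, rng)
    traj = eca_engine.evolve(state, rule_obj, n_steps)
    images = [eca_engine.unflatten(s, gridspec) for s in traj]
    return ImageSequence(images=images)
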