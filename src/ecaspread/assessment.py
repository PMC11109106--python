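"""Spreading-intensity statistic, habitat-suitability weighting, and the
end-to-end assessment pipeline.

Spreading intensity (SI) for a cluster is the rule-distribution-weighted
mean of per-rule normalized presence counts::

    SI = sum_i  P(rule x_i) * mean_presence(x_i) / n_initial

so a cluster inferred to follow the identity rule 204 exactly scores 1, and
rules whose simulated presence count grows score above 1.  Spreading
assessment (SA) weights SI by the cluster's habitat suitability HS in
[0, 1]: SA = SI × HS.  Clusters are binned into four groups:

    I   SA > 2.0     rapid continued spread
    II  1.5 < SA ≤ 2.0   continued spread
    III 1.0 < SA ≤ 1.5   stable population
    IV  SA ≤ 1.0     possible decline

Boundary values go to the lower (less-spreading) group — the conservative
labelling; the printed interval endpoints are otherwise unassigned.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eca_engine, rule_learning
from .eca_engine import PerRuleIntensity, SimConfig
from .rasterization import bounding_box, sequence_to_images
from .regional_clustering import agglomerative_order, divisive_cluster
from .rule_learning import RuleClassifier, RuleDistribution

__all__ = [
    "SpreadGroup",
    "AssessmentRecord",
    "PipelineConfig",
    "spreading_intensity",
    "spreading_assessment",
    "classify_group",
    "collinearity_filter",
    "run_pipeline",
    "read_hs_table",
]

logger = logging.getLogger(__name__)

_SA_AUDIT_RTOL = 1e-12


class SpreadGroup(str, enum.Enum):
    """Four-level spreading assessment."""

    I = "I"  # noqa: E741 - the group labels are roman numerals
    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True)
class AssessmentRecord:
    """One assessment row: cluster id, final presence-cell count, SI, HS,
    SA = SI × HS, group, and centroid."""

    cluster_id: int
    n_presence: int
    si: float
    hs: float
    sa: float
    group: SpreadGroup
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if abs(self.sa - self.si * self.hs) > _SA_AUDIT_RTOL * max(1.0, abs(self.sa)):
            raise ValueError(
                f"cluster {self.cluster_id}: SA={self.sa} is not SI*HS={self.si * self.hs}"
            )
        if self.group != classify_group(self.sa):
            raise ValueError(
                f"cluster {self.cluster_id}: group {self.group} inconsistent with SA={self.sa}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run settings.

    ``k`` regional clusters; ``linkage`` for the within-cluster ordering;
    ``inference_mode`` for how pair softmaxes combine; ``sim`` is the
    Monte-Carlo protocol for per-rule intensities; ``seed`` drives every
    stochastic stage.
    """

    k: int = 25
    nx: int = 20
    ny: int = 20
    linkage: str = "single"
    inference_mode: str = "aggregate"
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0


def _intensity_value(v) -> float:
    return v.intensity if isinstance(v, PerRuleIntensity) else float(v)


def spreading_intensity(dist: RuleDistribution, intensities) -> float:
    """SI = Σ_i P(rule x_i) · intensity(x_i).

    ``intensities`` maps rule number → per-rule intensity (already the mean
    presence count divided by the initial count), either as plain floats or
    :class:`~ecaspread.eca_engine.PerRuleIntensity` records.  Every rule in
    the distribution's support must be covered.
    """
    missing = [r for r in dist.support if r not in intensities]
    if missing:
        raise KeyError(f"no per-rule intensity for rules {missing}")
    return float(
        sum(dist[r] * _intensity_value(intensities[r]) for r in dist.support)
    )


def spreading_assessment(si: float, hs: float, *, strict: bool = True) -> float:
    """SA = SI × HS.  HS outside [0, 1] errors (or warns if strict=False)."""
    if si < 0:
        raise ValueError(f"SI must be non-negative, got {si}")
    if not 0 <= hs <= 1:
        msg = f"HS must be in [0, 1], got {hs}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    return si * hs


def classify_group(sa: float) -> SpreadGroup:
    """Bin an SA score into the four-level assessment; ties go downward."""
    if sa < 0 or not np.isfinite(sa):
        raise ValueError(f"SA must be a finite non-negative number, got {sa}")
    if sa > 2.0:
        return SpreadGroup.I
    if sa > 1.5:
        return SpreadGroup.II
    if sa > 1.0:
        return SpreadGroup.III
    return SpreadGroup.IV


def collinearity_filter(corr: pd.DataFrame, threshold: float = 0.80) -> list[str]:
    """Greedy collinearity pruning of an environmental-variable set.

    While any retained pair has |r| > threshold, drop the variable with the
    largest mean absolute off-diagonal correlation (ties: variable-name
    order).  Returns the retained variable names in input order.
    """
    if corr.shape[0] != corr.shape[1] or list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    m = corr.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if np.abs(m).max() > 1 + 1e-12 or not np.allclose(np.diag(m), 1.0):
        raise ValueError("correlation entries must be in [-1, 1] with unit diagonal")
    retained = list(corr.columns)
    while len(retained) > 1:
        sub = corr.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= threshold:
            break
        mean_abs = sub.sum(axis=0) / (len(retained) - 1)
        # ties broken toward the earlier variable in table order
        worst = max(range(len(retained)), key=lambda i: (mean_abs[i], -i))
        retained.pop(worst)
    return retained


def read_hs_table(path: str | Path) -> pd.DataFrame:
    """Read a ``cluster_id,hs`` delimited habitat-suitability table."""
    df = pd.read_csv(path)
    missing = {"cluster_id", "hs"} - set(df.columns)
    if missing:
        raise ValueError(f"HS table {path} lacks columns: {sorted(missing)}")
    return df[["cluster_id", "hs"]]


def run_pipeline(
    occurrences,
    hs_table: pd.DataFrame,
    classifier: RuleClassifier,
    config: PipelineConfig = PipelineConfig(),
    intensities: dict[int, PerRuleIntensity] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrences + HS table + trained classifier → assessment tables.

    Stages: divisive clustering into ``config.k`` regions; per cluster, the
    agglomerative inclusion sequence is rasterized on the cluster's own
    20×20 grid and the classifier infers a rule distribution from the image
    transitions; SI weights the per-rule simulated intensities by that
    distribution; SA = SI × HS; clusters are binned into the four groups.

    ``intensities`` (rule → PerRuleIntensity) may be precomputed and passed
    in; otherwise all 128 even rules are simulated under ``config.sim``.

    Returns ``(assessment, groups)``: the per-cluster table with columns
    cluster_id, n_presence, si, hs, sa, group, lon, lat; and the four-row
    group listing.

    Clusters whose inclusion sequence yields fewer than two images (a
    singleton cluster) show no transition at all; they are assigned a point
    mass on the identity rule 204, with a warning.
    """
    hs_map = dict(
        zip(hs_table["cluster_id"].astype(int), hs_table["hs"].astype(float))
    )
    clusters = divisive_cluster(occurrences, config.k, seed=config.seed)
    missing_hs = [c.cluster_id for c in clusters if c.cluster_id not in hs_map]
    if missing_hs:
        raise ValueError(f"HS table is missing cluster ids {missing_hs}")

    if intensities is None:
        sim = SimConfig(
            n_cells=config.nx * config.ny,
            n_initial_ones=config.sim.n_initial_ones,
            generations=config.sim.generations,
            repetitions=config.sim.repetitions,
            seed=config.sim.seed,
        )
        logger.info("simulating per-rule intensities for 128 even rules")
        intensities = eca_engine.all_rule_intensities(sim)

    records = []
    for cluster in clusters:
        seq = agglomerative_order(cluster, linkage=config.linkage)
        gridspec = bounding_box(cluster.points, nx=config.nx, ny=config.ny)
        images = sequence_to_images(seq, gridspec)
        if len(images) >= 2:
            dist = rule_learning.cluster_rule_distribution(
                classifier, images, mode=config.inference_mode
            )
        else:
            warnings.warn(
                f"cluster {cluster.cluster_id} has no image transition; "
                "assuming the identity rule (204)"
            )
            dist = RuleDistribution(probs={204: 1.0})
        si = spreading_intensity(dist, intensities)
        hs = hs_map[cluster.cluster_id]
        sa = spreading_assessment(si, hs)
        records.append(
            AssessmentRecord(
                cluster_id=cluster.cluster_id,
                n_presence=images[-1].presence_count,
                si=si,
                hs=hs,
                sa=sa,
                group=classify_group(sa),
                centroid=cluster.centroid,
            )
        )

    assessment = pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in records],
            "n_presence": [r.n_presence for r in records],
            "si": [r.si for r in records],
            "hs": [r.hs for r in records],
            "sa": [r.sa for r in records],
            "group": [r.group.value for r in records],
            "lon": [r.centroid[0] for r in records],
            "lat": [r.centroid[1] for r in records],
        }
    )
    groups = pd.DataFrame(
        {
            "group": [g.value for g in SpreadGroup],
            "sa_range": ["SA > 2.0", "1.5 < SA <= 2.0", "1.0 < SA <= 1.5", "SA <= 1.0"],
            "clusters": [
                ", ".join(
                    str(cid)
                    for cid in assessment.loc[
                        assessment["group"] == g.value, "cluster_id"
                    ]
                )
                for g in SpreadGroup
            ],
        }
    )
    return assessment, groups
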