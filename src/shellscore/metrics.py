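"""Ranking and regression metrics for docked pose scoring.

A scorer predicts RMSD, so *lower* scores rank better.  For a test set of M
complexes, with near-native meaning true RMSD below a threshold (2 A by
default):

* Docking power  = m(k)/M, the fraction of complexes whose top-k scored poses
  include at least one near-native pose.
* Hit rate       = mean over complexes of h(k)/P, the fraction of a complex's
  P near-native poses recovered among its top k.
* Enrichment factor = mean over complexes of h(k) / (P * alpha(k)) with
  alpha(k) = k / (number of poses of that complex); a random ranking gives
  EF ~= 1.

Regression quality is RMSE plus Pearson and Spearman correlations between
predicted and true RMSD.  Distribution shift between RMSD label sets is
quantified by the Jensen-Shannon divergence with base-2 logarithms, which is
0 for identical histograms and 1 for disjoint ones.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr, spearmanr

logger = logging.getLogger(__name__)

__all__ = [
    "PoseRanking", "MetricsReport", "regression_metrics", "docking_power",
    "hit_rate", "enrichment_factor", "js_divergence", "compute_metrics",
    "read_rankings_tsv", "write_rankings_tsv",
]


@dataclass
class PoseRanking:
    """Per-complex scored poses: (pose_id, score, true RMSD in Angstrom)."""

    complex_id: str
    entries: list[tuple[str, float, float]]

    def __post_init__(self):
        if not self.entries:
            raise ValueError(f"complex {self.complex_id}: no poses")
        for _, _, rmsd in self.entries:
            if rmsd < 0:
                raise ValueError("true RMSD must be >= 0")

    def sorted_entries(self) -> list[tuple[str, float, float]]:
        """Ascending by score; infinite scores last; ties keep input order."""
        order = sorted(range(len(self.entries)),
                       key=lambda i: (math.isinf(self.entries[i][1]),
                                      self.entries[i][1]))
        scores = [self.entries[i][1] for i in order]
        n_ties = len(scores) - len(set(scores))
        if n_ties:
            logger.debug("complex %s: %d tied scores broken by input order",
                         self.complex_id, n_ties)
        return [self.entries[i] for i in order]

    def near_native_total(self, threshold: float) -> int:
        return sum(1 for _, _, r in self.entries if r < threshold)

    def near_native_in_top(self, k: int, threshold: float) -> int:
        top = self.sorted_entries()[:k]
        return sum(1 for _, _, r in top if r < threshold)


def regression_metrics(predicted, truth) -> tuple[float, float, float]:
    """(rmse, pearson_r, spearman_rho); NaN correlations for constant input."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("need equal-length non-empty arrays")
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(truth))):
        raise ValueError("finite values required; filter infinities first")
    rmse = float(np.sqrt(np.mean((predicted - truth) ** 2)))
    if predicted.size < 2 or np.ptp(predicted) == 0 or np.ptp(truth) == 0:
        warnings.warn("correlation undefined for constant/short input")
        return rmse, float("nan"), float("nan")
    r = float(pearsonr(predicted, truth).statistic)
    rho = float(spearmanr(predicted, truth).statistic)
    return rmse, r, rho


def _check_rankings(rankings: list[PoseRanking], k: int, threshold: float):
    if not rankings:
        raise ValueError("empty ranking list")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not threshold > 0:
        raise ValueError("near-native threshold must be > 0")


def docking_power(rankings: list[PoseRanking], k: int = 1,
                  threshold: float = 2.0) -> float:
    """Fraction of complexes with a near-native pose among their top k."""
    _check_rankings(rankings, k, threshold)
    m_k = sum(1 for r in rankings if r.near_native_in_top(k, threshold) >= 1)
    return m_k / len(rankings)


def hit_rate(rankings: list[PoseRanking], k: int = 10,
             threshold: float = 2.0) -> float:
    """Mean recovered fraction h(k)/P; complexes with P = 0 are excluded."""
    _check_rankings(rankings, k, threshold)
    fractions = []
    for r in rankings:
        p = r.near_native_total(threshold)
        if p == 0:
            continue
        fractions.append(r.near_native_in_top(k, threshold) / p)
    if not fractions:
        warnings.warn("no complex has any near-native pose; hit rate undefined")
        return float("nan")
    return float(np.mean(fractions))


def enrichment_factor(rankings: list[PoseRanking], k: int = 10,
                      threshold: float = 2.0) -> float:
    """Mean h(k) / (P * alpha(k)); ~1 for random rankings."""
    _check_rankings(rankings, k, threshold)
    values = []
    for r in rankings:
        p = r.near_native_total(threshold)
        if p == 0:
            continue
        alpha = k / len(r.entries)
        values.append(r.near_native_in_top(k, threshold) / (p * alpha))
    if not values:
        warnings.warn("no complex has any near-native pose; EF undefined")
        return float("nan")
    return float(np.mean(values))


def js_divergence(histogram_p, histogram_q) -> float:
    """Jensen-Shannon divergence (base 2) between two aligned histograms."""
    p = np.asarray(histogram_p, dtype=float)
    q = np.asarray(histogram_q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("histograms must share one set of bins")
    if p.sum() <= 0 or q.sum() <= 0 or (p < 0).any() or (q < 0).any():
        raise ValueError("histograms must be nonnegative with positive mass")
    d = jensenshannon(p / p.sum(), q / q.sum(), base=2) ** 2
    return float(np.clip(d, 0.0, 1.0))


@dataclass
class MetricsReport:
    rmse: float
    pearson_r: float
    spearman_rho: float
    docking_power: float
    hit_rate: float
    enrichment_factor: float
    k_dock: int
    k_hit: int
    threshold: float
    n_complexes: int
    n_poses: int
    n_infinite: int = 0
    near_native_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse, "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "docking_power": self.docking_power, "hit_rate": self.hit_rate,
            "enrichment_factor": self.enrichment_factor,
            "k_dock": self.k_dock, "k_hit": self.k_hit,
            "threshold": self.threshold, "n_complexes": self.n_complexes,
            "n_poses": self.n_poses, "n_infinite": self.n_infinite,
        }

    def text(self) -> str:
        d = self.as_dict()
        width = max(len(k) for k in d)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in d.items())


def compute_metrics(rankings: list[PoseRanking], k_dock: int = 1,
                    k_hit: int = 10, threshold: float = 2.0) -> MetricsReport:
    """All six metrics; infinite scores are excluded from the regression part
    but still rank (last) in the ordering metrics."""
    _check_rankings(rankings, k_dock, threshold)
    preds, truths = [], []
    n_poses = n_inf = 0
    for r in rankings:
        for _, score, rmsd in r.entries:
            n_poses += 1
            if math.isinf(score):
                n_inf += 1
            else:
                preds.append(score)
                truths.append(rmsd)
    if preds:
        rmse, r_pearson, rho = regression_metrics(preds, truths)
    else:
        rmse = r_pearson = rho = float("nan")
    return MetricsReport(
        rmse=rmse, pearson_r=r_pearson, spearman_rho=rho,
        docking_power=docking_power(rankings, k_dock, threshold),
        hit_rate=hit_rate(rankings, k_hit, threshold),
        enrichment_factor=enrichment_factor(rankings, k_hit, threshold),
        k_dock=k_dock, k_hit=k_hit, threshold=threshold,
        n_complexes=len(rankings), n_poses=n_poses, n_infinite=n_inf,
        near_native_counts={r.complex_id: r.near_native_total(threshold)
                            for r in rankings})


def read_rankings_tsv(path) -> list[PoseRanking]:
    """TSV with columns complex_id, pose_id, score, rmsd -> PoseRanking list."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"complex_id", "pose_id", "score", "rmsd"}
    if not required.issubset(df.columns):
        raise ValueError(f"rankings table needs columns {sorted(required)}")
    rankings = []
    for cid, group in df.groupby("complex_id", sort=False):
        entries = [(str(row.pose_id), float(row.score), float(row.rmsd))
                   for row in group.itertuples()]
        rankings.append(PoseRanking(str(cid), entries))
    return rankings


def write_rankings_tsv(rankings: list[PoseRanking], path) -> None:
    import pandas as pd

    rows = [{"complex_id": r.complex_id, "pose_id": pid, "score": score,
             "rmsd": rmsd}
            for r in rankings for pid, score, rmsd in r.entries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
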