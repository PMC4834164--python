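"""Screening-efficiency metrics: enrichment factor, ROC curve, AUC.

The enrichment factor at sampling fraction s compares the active hit-rate in
the top-ranked s of a screen with the hit-rate of random selection:

    EF(s) = (Hits_s / N_s) / (Hit_t / N_t),   N_s = ceil(s * N_t),

so EF = 1 for a random ranking in expectation and is bounded above by both
N_t/N_s and N_t/Hit_t.  Ranking is by score descending with a stable
tie-break on input order (EF is tie-sensitive; the policy is part of the
contract).  The ROC curve plots true-positive rate against false-positive
rate over all score thresholds (tied scores move together) and the AUC is its
trapezoidal integral, which equals the pairwise Mann-Whitney statistic
P(score_active > score_decoy) + P(tie)/2.

Poses can be aggregated to compounds (max score over poses) before ranking
when a screen carries several docking poses per compound.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateDataError

__all__ = [
    "RankedScreen",
    "MetricReport",
    "enrichment_factor",
    "roc_curve",
    "auc",
    "evaluate",
    "aggregate_trials",
    "pose_to_compound",
    "plot_roc",
]


@dataclass
class RankedScreen:
    """Scores and +1/-1 labels for a screened library (optionally pose->compound)."""

    scores: np.ndarray
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)
    compound_of: dict[str, str] | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        self.labels = np.asarray(self.labels, int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not self.ids:
            self.ids = [f"s{i}" for i in range(len(self.scores))]
        if len(self.ids) != len(self.scores):
            raise ValueError("ids length mismatch")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")

    @property
    def n_actives(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_decoys(self) -> int:
        return int((self.labels == -1).sum())

    def _require_both_classes(self):
        if self.n_actives == 0 or self.n_decoys == 0:
            raise DegenerateDataError(
                "metric needs at least one active and one decoy")


@dataclass
class MetricReport:
    """EF values by fraction, AUC, ROC points; means +- std when aggregated."""

    ef: dict[float, float] = field(default_factory=dict)
    auc: float = float("nan")
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    n_trials: int = 1
    ef_mean: dict[float, float] | None = None
    ef_std: dict[float, float] | None = None
    auc_mean: float | None = None
    auc_std: float | None = None

    def to_json(self, **kwargs) -> str:
        doc = {
            "ef": {str(k): v for k, v in self.ef.items()},
            "auc": self.auc,
            "n_trials": self.n_trials,
        }
        if self.ef_mean is not None:
            doc["ef_mean"] = {str(k): v for k, v in self.ef_mean.items()}
            doc["ef_std"] = {str(k): v for k, v in self.ef_std.items()}
            doc["auc_mean"] = self.auc_mean
            doc["auc_std"] = self.auc_std
        return json.dumps(doc, **kwargs)


def _ranking(screen: RankedScreen) -> np.ndarray:
    """Indices sorted by score descending, stable on input order for ties."""
    return np.argsort(-screen.scores, kind="stable")


def enrichment_factor(screen: RankedScreen, fraction: float = 0.1) -> float:
    """EF at sampling fraction s in (0, 1]; N_s = ceil(s * N_t)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    screen._require_both_classes()
    n_total = len(screen.scores)
    n_sample = math.ceil(fraction * n_total)
    top = _ranking(screen)[:n_sample]
    hits_s = int((screen.labels[top] == 1).sum())
    hit_t = screen.n_actives
    return (hits_s / n_sample) / (hit_t / n_total)


def roc_curve(screen: RankedScreen) -> list[tuple[float, float]]:
    """ROC points (FPR, TPR) from (0,0) to (1,1), tied scores grouped."""
    screen._require_both_classes()
    fpr, tpr, _ = _sk_roc_curve(screen.labels, screen.scores, pos_label=1,
                                drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc(roc: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a monotone ROC polyline."""
    pts = np.asarray(roc, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (FPR, TPR) points")
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def evaluate(screen: RankedScreen,
             fractions: Sequence[float] = (0.1,)) -> MetricReport:
    """EF at each fraction plus ROC/AUC in one report."""
    roc = roc_curve(screen)
    return MetricReport(
        ef={f: enrichment_factor(screen, f) for f in fractions},
        auc=auc(roc),
        roc_points=roc,
    )


def aggregate_trials(reports: Sequence[MetricReport]) -> MetricReport:
    """Mean and sample std of EF/AUC over repeated trials (order-independent)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    keys = set(reports[0].ef)
    if any(set(r.ef) != keys for r in reports):
        raise ValueError("reports carry different EF fractions")

    def mean_std(vals):
        vals = np.asarray(vals, float)
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    ef_mean, ef_std = {}, {}
    for k in sorted(keys):
        ef_mean[k], ef_std[k] = mean_std([r.ef[k] for r in reports])
    auc_mean, auc_std = mean_std([r.auc for r in reports])
    return MetricReport(
        ef=dict(ef_mean), auc=auc_mean, roc_points=[],
        n_trials=len(reports),
        ef_mean=ef_mean, ef_std=ef_std, auc_mean=auc_mean, auc_std=auc_std,
    )


def pose_to_compound(screen: RankedScreen,
                     rule: str = "MAX_SCORE") -> RankedScreen:
    """Aggregate pose rows to one row per compound (score = max over poses)."""
    if rule != "MAX_SCORE":
        raise ValueError(f"unknown aggregation rule {rule!r}")
    if screen.compound_of is None:
        raise ValueError("screen has no pose->compound map")
    best: dict[str, tuple[float, int]] = {}
    order: list[str] = []
    for i, sid in enumerate(screen.ids):
        comp = screen.compound_of.get(sid, sid)
        score, label = float(screen.scores[i]), int(screen.labels[i])
        if comp in best:
            if label != best[comp][1]:
                raise ValueError(
                    f"compound {comp!r} has poses with conflicting labels")
            if score > best[comp][0]:
                best[comp] = (score, label)
        else:
            best[comp] = (score, label)
            order.append(comp)
    return RankedScreen(
        scores=np.array([best[c][0] for c in order]),
        labels=np.array([best[c][1] for c in order]),
        ids=order,
    )


def plot_roc(rocs, path, labels=None) -> None:
    """Write a ROC plot (one or more curves) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if rocs and isinstance(rocs[0], tuple):
        rocs = [rocs]
    fig, ax = plt.subplots(figsize=(5, 5))
    for i, roc in enumerate(rocs):
        pts = np.asarray(roc, float)
        name = labels[i] if labels else f"model {i + 1}"
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC {auc(roc):.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="random")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
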