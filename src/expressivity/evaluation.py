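"""Classification metrics, bootstrap CIs, and expressivity profiling.

AUROC follows the Mann-Whitney convention (ties get half credit); AUPRC
is step-wise average precision with no interpolation. Confidence
intervals are seeded nonparametric percentile bootstraps over (score,
label) pairs. The expressivity profile composes feature extraction with
the MINE estimator over a (layer stage x attribute) grid; each cell's
seed is derived from the cell's coordinates, so results are independent
of the order in which cells are computed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

from . import mine
from .mine import AttributeVector, ExpressivityResult, MineTrainConfig, StatisticsNetConfig
from .representation import LayerTag, extract_features

__all__ = [
    "MetricReport",
    "ExpressivityProfile",
    "auroc",
    "auprc",
    "bootstrap_ci",
    "metric_report",
    "expressivity_profile",
    "ordering_check",
]


def derive_seed(master: int, *labels) -> int:
    """Deterministic per-component seed below 2**31, hashed from labels."""
    blob = "/".join([str(int(master)), *map(str, labels)])
    return int.from_bytes(hashlib.sha256(blob.encode()).digest()[:4], "big") % (2 ** 31)


def _check_scores_labels(scores, labels, need_both=True):
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    if need_both and np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def auroc(scores, labels) -> float:
    """P(score+ > score-) + 0.5 * P(tie), exactly (Mann-Whitney)."""
    scores, labels = _check_scores_labels(scores, labels)
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Average precision: step-wise PR integral, no interpolation."""
    scores, labels = _check_scores_labels(scores, labels, need_both=False)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined without positive samples")
    return float(average_precision_score(labels, scores))


def bootstrap_ci(metric, scores, labels, n_boot: int = 2000, level: float = 0.95,
                 seed: int = 0, max_redraws: int = 1000) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a metric(scores, labels).

    Resamples (score, label) pairs with replacement; single-class
    resamples are redrawn (up to ``max_redraws`` extra draws in total,
    after which an error is raised).
    """
    scores, labels = _check_scores_labels(scores, labels)
    n = scores.size
    if n < 10:
        raise ValueError("bootstrap needs n >= 10")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(labels[idx]).size == 2:
                break
            redraws += 1
            if redraws > max_redraws:
                raise ValueError("could not draw a two-class bootstrap resample")
        vals[i] = metric(scores[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class MetricReport:
    """AUROC/AUPRC with 95% bootstrap CIs and the underlying curves."""

    auroc: float
    auprc: float
    auroc_ci: tuple[float, float]
    auprc_ci: tuple[float, float]
    n_boot: int
    seed: int
    roc_curve: dict[str, list[float]]
    pr_curve: dict[str, list[float]]

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc, "auprc": self.auprc,
            "auroc_ci": list(self.auroc_ci), "auprc_ci": list(self.auprc_ci),
            "n_boot": self.n_boot, "seed": self.seed,
            "roc_curve": self.roc_curve, "pr_curve": self.pr_curve,
        }

    def curves_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (pd.DataFrame(self.roc_curve), pd.DataFrame(self.pr_curve))


def metric_report(scores, labels, n_boot: int = 2000, level: float = 0.95,
                  seed: int = 0) -> MetricReport:
    """Point estimates, bootstrap CIs and curve coordinates in one record."""
    scores, labels = _check_scores_labels(scores, labels)
    a_roc = auroc(scores, labels)
    a_prc = auprc(scores, labels)
    roc_lo, roc_hi = bootstrap_ci(auroc, scores, labels, n_boot, level,
                                  derive_seed(seed, "auroc"))
    prc_lo, prc_hi = bootstrap_ci(auprc, scores, labels, n_boot, level,
                                  derive_seed(seed, "auprc"))
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return MetricReport(
        auroc=a_roc, auprc=a_prc,
        auroc_ci=(min(roc_lo, a_roc), max(roc_hi, a_roc)),
        auprc_ci=(min(prc_lo, a_prc), max(prc_hi, a_prc)),
        n_boot=n_boot, seed=seed,
        roc_curve={"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        pr_curve={"recall": rec.tolist(), "precision": prec.tolist()})


# ---------------------------------------------------------------------------
# Expressivity profiles
# ---------------------------------------------------------------------------

@dataclass
class ExpressivityProfile:
    """Complete (layer stage x attribute) grid of expressivity results."""

    cells: dict[tuple[str, str], ExpressivityResult]
    stages: list[str]
    attributes: list[str]

    def mean(self, stage: str, attribute: str) -> float:
        return self.cells[(stage, attribute)].mean_estimate

    def to_frame(self) -> pd.DataFrame:
        data = {a: [self.mean(s, a) for s in self.stages] for a in self.attributes}
        return pd.DataFrame(data, index=self.stages)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "attributes": self.attributes,
                "cells": {f"{s}|{a}": r.to_dict()
                          for (s, a), r in sorted(self.cells.items())}}

    @classmethod
    def from_dict(cls, d: dict) -> "ExpressivityProfile":
        cells = {}
        for key, rec in d["cells"].items():
            s, a = key.split("|", 1)
            cells[(s, a)] = ExpressivityResult(**rec)
        return cls(cells=cells, stages=d["stages"], attributes=d["attributes"])


def expressivity_profile(model, images: np.ndarray, attribute_table: pd.DataFrame,
                         stages=("early", "mid", "final"),
                         attributes=("age", "sex", "IVSDd", "LVPWDd", "LVIDd"),
                         net_cfg: StatisticsNetConfig | None = None,
                         train_cfg: MineTrainConfig | None = None,
                         base_seed: int = 0) -> ExpressivityProfile:
    """Expressivity of every (stage, attribute) cell of a trained model.

    Features are extracted once per stage; each cell runs the multi-seed
    MINE protocol with a seed derived from (base_seed, stage, attribute),
    making cell values independent of evaluation order.
    """
    for a in attributes:
        if a not in attribute_table.columns:
            raise KeyError(f"attribute column {a!r} missing from table")
    cells = {}
    for stage in stages:
        fm = extract_features(model, images, stage)
        for attr in attributes:
            col = attribute_table[attr].to_numpy(dtype=float)
            kind = "binary" if set(np.unique(col)) <= {0.0, 1.0} else "continuous"
            av = AttributeVector(col, kind=kind, name=attr)
            cells[(stage, attr)] = mine.expressivity(
                fm, av, net_cfg, train_cfg,
                base_seed=derive_seed(base_seed, stage, attr))
    return ExpressivityProfile(cells=cells, stages=list(stages),
                               attributes=list(attributes))


def ordering_check(profile: ExpressivityProfile, stage: str,
                   expected_ranking: list[str]) -> dict:
    """Compare estimated attribute ranking at a stage to an expected one.

    ``expected_ranking`` lists attribute names from most to least
    expressive. Returns a dict with ``match`` (exact-order flag),
    ``kendall_tau``, the estimated ranking, and ``ties`` (exact ties in
    means force match=False).
    """
    means = {a: profile.mean(stage, a) for a in expected_ranking}
    est_rank = sorted(means, key=means.get, reverse=True)
    vals = np.array([means[a] for a in expected_ranking])
    ties = np.unique(vals).size < vals.size
    # expected position vs estimated position, Kendall over attribute pairs
    exp_pos = np.arange(len(expected_ranking))
    est_pos = np.array([est_rank.index(a) for a in expected_ranking])
    tau = round(float(kendalltau(exp_pos, est_pos).statistic), 10)
    return {"match": bool(not ties and est_rank == list(expected_ranking)),
            "kendall_tau": tau,
            "estimated_ranking": est_rank,
            "ties": bool(ties)}
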