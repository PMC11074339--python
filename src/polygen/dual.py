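"""Dual-target (polypharmacology) activity benchmark.

Compounds assayed against exactly two targets are classified as
dual-active when both measured (or both predicted) affinities fall
strictly below an activity threshold (1 uM by default). Observed and
predicted labels are cross-tabulated; association is summarized by the
Fisher exact odds ratio and a chi-squared p-value, and a threshold sweep
traces precision-recall and ROC points.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ActivityRecord, LigandEfficiencyScorer

DEFAULT_THRESHOLD = 1e-6  # molar; "active" means affinity strictly below


@dataclass(frozen=True)
class DualTriplet:
    """A compound with observed and predicted affinities on two targets."""

    smiles: str
    target1: str
    target2: str
    observed_affinity1: float
    observed_affinity2: float
    predicted_affinity1: float
    predicted_affinity2: float

    def __post_init__(self):
        if self.target1 == self.target2:
            raise ValueError("targets of a triplet must differ")
        for v in (self.observed_affinity1, self.observed_affinity2,
                  self.predicted_affinity1, self.predicted_affinity2):
            if v is None or not np.isfinite(v):
                raise ValueError("all four affinities must be present/finite")
            if v <= 0:
                raise ValueError("affinities must be positive (molar)")


def _combine(values: list[float], how: str) -> float:
    if how == "geometric_mean":
        return float(np.exp(np.mean(np.log(values))))
    if how == "min":
        return float(min(values))
    if how == "median":
        return float(np.median(values))
    raise ValueError(f"unknown replicate combiner {how!r}")


def filter_dual_assayed(records: list[ActivityRecord],
                        scorer_pair: tuple[LigandEfficiencyScorer,
                                           LigandEfficiencyScorer] | None = None,
                        training_smiles: frozenset | None = None,
                        replicate_combiner: str = "geometric_mean",
                        ) -> list[tuple[str, str, str, float, float]]:
    """Keep compounds assayed against two and only two distinct targets.

    Compounds whose canonical SMILES appears in the scorers' training
    sets are removed (held-out evaluation). Replicate measurements per
    (compound, target) are combined by geometric mean (configurable).
    Returns (smiles, target1, target2, observed1, observed2) tuples with
    targets in sorted order.
    """
    if training_smiles is None:
        training_smiles = frozenset()
        if scorer_pair is not None:
            training_smiles = (scorer_pair[0].training_smiles_
                               | scorer_pair[1].training_smiles_)
    by_compound: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for rec in records:
        by_compound[rec.smiles][rec.target_id].append(rec.affinity_value)
    out = []
    for smiles, per_target in sorted(by_compound.items()):
        if len(per_target) != 2 or smiles in training_smiles:
            continue
        (t1, v1), (t2, v2) = sorted(per_target.items())
        out.append((smiles, t1, t2, _combine(v1, replicate_combiner),
                    _combine(v2, replicate_combiner)))
    return out


def predict_triplets(pairs, scorers: dict[str, LigandEfficiencyScorer]
                     ) -> list[DualTriplet]:
    """Attach predicted affinities (10^-pIC50, molar) to filtered pairs."""
    triplets = []
    for smiles, t1, t2, o1, o2 in pairs:
        p1 = 10.0 ** (-scorers[t1].predict_pic50(smiles))
        p2 = 10.0 ** (-scorers[t2].predict_pic50(smiles))
        triplets.append(DualTriplet(smiles, t1, t2, o1, o2, p1, p2))
    return triplets


def classify_dual(t: DualTriplet,
                  threshold: float = DEFAULT_THRESHOLD) -> tuple[bool, bool]:
    """Dual-active iff BOTH affinities are strictly below the threshold."""
    observed = (t.observed_affinity1 < threshold
                and t.observed_affinity2 < threshold)
    predicted = (t.predicted_affinity1 < threshold
                 and t.predicted_affinity2 < threshold)
    return observed, predicted


@dataclass(frozen=True)
class ContingencyTable:
    """Observed-vs-predicted dual-activity 2x2 table with association stats."""

    tp: int
    fp: int
    fn: int
    tn: int
    odds_ratio: float
    fisher_p: float
    chi2_p: float
    continuity_corrected: bool = False

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def balanced_accuracy(self) -> float:
        tpr = self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan
        tnr = self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan
        return float(np.mean([tpr, tnr]))

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")


def tabulate(classified: list[tuple[bool, bool]]) -> ContingencyTable:
    """Cross-tabulate (observed_dual, predicted_dual) pairs.

    The odds ratio is the cross-product ratio (tp*tn)/(fp*fn), the point
    estimate reported by the two-sided Fisher exact test; with a zero
    cell a Haldane-Anscombe +0.5 correction is applied and flagged.
    """
    if not classified:
        raise ValueError("no classified triplets to tabulate")
    tp = sum(o and p for o, p in classified)
    fp = sum((not o) and p for o, p in classified)
    fn = sum(o and (not p) for o, p in classified)
    tn = sum((not o) and (not p) for o, p in classified)
    table = np.array([[tp, fn], [fp, tn]], dtype=float)
    corrected = False
    if tp * tn == 0 or fp * fn == 0:
        corrected = True
        odds = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
    else:
        odds = (tp * tn) / (fp * fn)
    fisher = stats.fisher_exact(table, alternative="two-sided")
    try:
        chi2_p = float(stats.chi2_contingency(table, correction=True)[1])
    except ValueError:  # a zero margin: chi-squared undefined
        chi2_p = float("nan")
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn,
                            odds_ratio=float(odds),
                            fisher_p=float(fisher.pvalue), chi2_p=chi2_p,
                            continuity_corrected=corrected)


def evaluate_triplets(triplets: list[DualTriplet],
                      threshold: float = DEFAULT_THRESHOLD) -> ContingencyTable:
    return tabulate([classify_dual(t, threshold) for t in triplets])


def threshold_sweep(triplets: list[DualTriplet], thresholds=None,
                    observed_threshold: float | None = DEFAULT_THRESHOLD
                    ) -> pd.DataFrame:
    """Precision/recall and ROC points across activity thresholds
    (default decades 1e-5 M down to 1e-10 M).

    Observed labels are fixed at `observed_threshold` (1 uM) while the
    prediction threshold sweeps, tracing a proper PR/ROC curve; pass
    observed_threshold=None to redefine "active" on both sides at each
    sweep threshold instead.
    """
    if thresholds is None:
        thresholds = [10.0 ** (-e) for e in range(5, 11)]
    thresholds = list(thresholds)
    if len(set(thresholds)) != len(thresholds) or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive and distinct")
    rows = []
    for thr in thresholds:
        obs_thr = thr if observed_threshold is None else observed_threshold
        classified = [(classify_dual(t, obs_thr)[0], classify_dual(t, thr)[1])
                      for t in triplets]
        tp = sum(o and p for o, p in classified)
        fp = sum((not o) and p for o, p in classified)
        fn = sum(o and (not p) for o, p in classified)
        tn = sum((not o) and (not p) for o, p in classified)
        rows.append({
            "threshold": thr,
            "n_predicted_positive": tp + fp,
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "tpr": tp / (tp + fn) if tp + fn else float("nan"),
            "fpr": fp / (fp + tn) if fp + tn else float("nan"),
            "accuracy": (tp + tn) / len(classified),
        })
    return pd.DataFrame(rows)
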