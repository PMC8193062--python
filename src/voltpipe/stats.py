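"""Group statistics and detection scoring.

Cohorts are compared with an unpaired two-tailed Student's t test
(pooled variance), reported as mean ± SD with the usual significance
tiers (*p < 0.05, **p < 0.01, ***p < 0.001).  Detection scoring matches
detected spike times against ground truth one-to-one within a tolerance
and reports precision/recall/F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "GroupComparison",
    "DetectionScore",
    "group_compare",
    "significance_tier",
    "score_detection",
    "match_rois",
]


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    tier: str  # ns | * | ** | ***
    welch: bool = False
    degenerate: bool = False  # zero pooled variance with unequal means

    def summary(self) -> str:
        return (
            f"{self.label_a}: {self.mean_a:.3g} ± {self.sd_a:.3g} (n={self.n_a})  vs  "
            f"{self.label_b}: {self.mean_b:.3g} ± {self.sd_b:.3g} (n={self.n_b})  "
            f"t={self.t_statistic:.3f}, p={self.p_value:.3g} [{self.tier}]"
        )


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_compare(
    values_a,
    values_b,
    label_a: str = "A",
    label_b: str = "B",
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed t test between two groups.

    Pooled-variance Student's test by default; Welch's correction by
    flag.  Degenerate zero-variance groups: equal means → t = 0, p = 1;
    unequal means → p = 0 with the ``degenerate`` flag set.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n ≥ 2")
    degenerate = False
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
            degenerate = True
    else:
        t_stat, p = sstats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(t_stat), float(p)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=a.size,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=b.size,
        t_statistic=t_stat,
        p_value=p,
        tier=significance_tier(p),
        welch=welch,
        degenerate=degenerate,
    )


@dataclass
class DetectionScore:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    match_tolerance_ms: float
    undefined: bool = False  # precision or recall had a 0/0 convention applied

    @property
    def n_detected(self) -> int:
        return self.true_positives + self.false_positives

    @property
    def n_truth(self) -> int:
        return self.true_positives + self.false_negatives


def score_detection(
    detected, truth, tolerance_ms: float = 6.0
) -> DetectionScore:
    """Score detected spike times against ground truth.

    One-to-one greedy nearest-neighbour matching: candidate pairs within
    the tolerance are matched in order of increasing time difference.
    Unmatched detections are false positives, unmatched truth spikes are
    false negatives.  Empty-side conventions report 0 with the
    ``undefined`` flag.
    """
    det = np.sort(np.asarray(detected, dtype=float))
    tru = np.sort(np.asarray(truth, dtype=float))
    tol = tolerance_ms / 1000.0
    pairs = []
    for i, td in enumerate(det):
        j0 = np.searchsorted(tru, td - tol)
        j1 = np.searchsorted(tru, td + tol, side="right")
        for j in range(j0, j1):
            pairs.append((abs(td - tru[j]), i, j))
    pairs.sort()
    used_d, used_t = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    fp = det.size - tp
    fn = tru.size - tp
    undefined = det.size == 0 or tru.size == 0
    precision = tp / det.size if det.size else 0.0
    recall = tp / tru.size if tru.size else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return DetectionScore(
        true_positives=tp,
        false_positives=int(fp),
        false_negatives=int(fn),
        precision=precision,
        recall=recall,
        f1=f1,
        match_tolerance_ms=tolerance_ms,
        undefined=undefined,
    )


def match_rois(masks_pred: np.ndarray, masks_true: np.ndarray,
               min_jaccard: float = 0.2) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of recovered masks to truth masks.

    Returns ``(pred_index, true_index, jaccard)`` triples sorted by
    decreasing overlap; pairs below ``min_jaccard`` are not matched.
    """
    cands = []
    for i, mp in enumerate(masks_pred):
        for j, mt in enumerate(masks_true):
            inter = np.logical_and(mp, mt).sum()
            if inter == 0:
                continue
            jac = inter / np.logical_or(mp, mt).sum()
            if jac >= min_jaccard:
                cands.append((jac, i, j))
    cands.sort(reverse=True)
    used_p, used_t = set(), set()
    matches = []
    for jac, i, j in cands:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches.append((i, j, float(jac)))
    return matches
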