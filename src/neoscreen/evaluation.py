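"""Rank-based benchmark statistics for neoantigen prediction lists.

Given a ranked prediction list of size T with experimentally labelled
positive and negative peptides mapped into it:

* rank coverage score (RCS), a signed score in [-1, 1] rewarding lists
  that push negatives down (large ranks) and positives up:

      RCS = [Σ_n rank_n / (T·num(n))]·coverage(n)
          - [Σ_p rank_p / (T·num(p))]·coverage(p),
      coverage(k) = max(rank_k) / T

* ranking score (RS) per peptide: rank / T, in [1/T, 1]; a peptide the
  tool failed to detect scores 1;
* sensitivity, specificity and balanced accuracy from a confusion
  table, plus the Mann–Whitney (tie-corrected) AUC and the
  balanced-accuracy-maximising score cutoff.

Peptide↔label matching elsewhere in the package is exact identity after
case-folding, taking the first (best) rank for per-allele duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes and one is empty."""


def rank_coverage_score(
    ranks_positive: Sequence[int],
    ranks_negative: Sequence[int],
    t_total: int,
) -> float:
    """Rank coverage score of a prediction list of size ``t_total``.

    Undetected peptides should be assigned rank ``t_total`` (worst)
    before calling, mirroring the RS convention for undetected peptides.
    """
    rp = np.asarray(ranks_positive, dtype=float)
    rn = np.asarray(ranks_negative, dtype=float)
    if rp.size == 0 or rn.size == 0:
        raise UndefinedMetricError("RCS needs at least one positive and one negative")
    for r in (rp, rn):
        if np.any((r < 1) | (r > t_total)):
            raise ValueError(f"ranks must lie in 1..{t_total}")
    coverage_n = rn.max() / t_total
    coverage_p = rp.max() / t_total
    neg_term = rn.sum() / (t_total * rn.size) * coverage_n
    pos_term = rp.sum() / (t_total * rp.size) * coverage_p
    return float(neg_term - pos_term)


def ranking_score(rank: Optional[int], t_total: int) -> float:
    """RS = rank / T in (0, 1]; an undetected peptide (rank None) scores 1."""
    if t_total < 1:
        raise ValueError("list size must be >= 1")
    if rank is None:
        return 1.0
    if not 1 <= rank <= t_total:
        raise ValueError(f"rank {rank} outside 1..{t_total}")
    return rank / t_total


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy) from a confusion table.

    Sen = TP/(TP+FN); Spe = TN/(TN+FP); BA = (Sen+Spe)/2.  BA is the
    mean of the class-conditional recalls and therefore invariant to
    class prevalence.
    """
    if counts.tp + counts.fn < 1 or counts.tn + counts.fp < 1:
        raise UndefinedMetricError("confusion metrics need both classes populated")
    sen = counts.tp / (counts.tp + counts.fn)
    spe = counts.tn / (counts.tn + counts.fp)
    return sen, spe, (sen + spe) / 2


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """BA = (sensitivity + specificity) / 2."""
    return (sensitivity + specificity) / 2


def auc_and_cutoff(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Tie-corrected AUC and the balanced-accuracy-maximising cutoff.

    Higher scores are treated as more positive.  The AUC is the
    rank-based Mann–Whitney estimator.  The cutoff scans every distinct
    score as a ``score >= cutoff → positive`` rule and returns the one
    maximising balanced accuracy; ties prefer the smaller cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    auc = float(roc_auc_score(y, s))

    best_cut, best_ba = None, -1.0
    for cut in np.sort(np.unique(s)):
        pred = s >= cut
        sen = float((pred & (y == 1)).sum()) / n_pos
        spe = float((~pred & (y == 0)).sum()) / n_neg
        ba = (sen + spe) / 2
        if ba > best_ba:  # strict: keeps the smallest cutoff on ties
            best_ba, best_cut = ba, float(cut)
    return auc, best_cut


def evaluate_ranked_list(
    ranked_peptides: Sequence[str],
    labels: dict[str, int],
) -> dict:
    """Score a ranked peptide list against peptide→{0,1} labels.

    Peptides are matched by exact identity after case-folding; a
    labelled peptide absent from the list is treated as undetected
    (rank T for RCS, RS = 1).  Duplicated peptides in the list keep
    their first (best) rank.  Returns RCS, per-peptide RS, AUC on
    ``1 - RS`` (so that better ranks score higher) and the confusion
    metrics at the BA-optimal cutoff.
    """
    t_total = len(ranked_peptides)
    if t_total == 0:
        raise ValueError("empty ranked list")
    first_rank: dict[str, int] = {}
    for i, pep in enumerate(ranked_peptides, start=1):
        first_rank.setdefault(pep.strip().upper(), i)

    norm_labels = {p.strip().upper(): int(v) for p, v in labels.items()}
    ranks_p, ranks_n, rs, y = [], [], [], []
    for pep, lab in norm_labels.items():
        rank = first_rank.get(pep)
        (ranks_p if lab == 1 else ranks_n).append(
            rank if rank is not None else t_total
        )
        rs.append(ranking_score(rank, t_total))
        y.append(lab)

    rcs = rank_coverage_score(ranks_p, ranks_n, t_total)
    score = 1.0 - np.asarray(rs)
    auc, cutoff = auc_and_cutoff(score, y)
    pred = score >= cutoff
    y_arr = np.asarray(y)
    counts = ConfusionCounts(
        tp=int((pred & (y_arr == 1)).sum()),
        tn=int((~pred & (y_arr == 0)).sum()),
        fp=int((pred & (y_arr == 0)).sum()),
        fn=int((~pred & (y_arr == 1)).sum()),
    )
    sen, spe, ba = confusion_metrics(counts)
    return {
        "t_total": t_total,
        "rcs": rcs,
        "rs": dict(zip(norm_labels, rs)),
        "auc": auc,
        "cutoff": cutoff,
        "sensitivity": sen,
        "specificity": spe,
        "balanced_accuracy": ba,
        "counts": counts,
    }
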