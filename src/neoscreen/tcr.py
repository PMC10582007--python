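"""TCR recognition probability and peptide–CDR3 interaction scoring.

The probability ``R`` that a candidate core is recognised by the T-cell
receptor repertoire is modelled as a partition-function transform of its
local-alignment similarity to a pool of experimentally validated
epitopes (typically IEDB-derived):

    R = S / (1 + S),   S = sum over pool entries e of exp(-k (a - |s,e|))

where ``|s,e|`` is the Smith–Waterman local-alignment score under
BLOSUM62 with affine gaps (opening penalty 11, extension 1: a gap of
length g costs 11 + g), ``a`` is the horizontal displacement of the
binding curve (default 26) and ``k`` its slope (default 1).  R lies in
[0, 1), increases with every pool similarity, and equals 1/2 when a
single pool entry scores exactly ``a``.

The alignment is exact dynamic programming rather than heuristic
BLASTp: deterministic, and never below the heuristic's score.  Raw
Smith–Waterman scores are the default scale for ``a = 26``; bit scores
(BLOSUM62 gapped Karlin–Altschul parameters) are available via
``score_kind="bit"``.

The module also aggregates binary peptide–CDR3 calls from three
independent predictors into a pair score in {0, 0.25, 0.75, 1} and the
per-peptide T-cell interaction score (TIS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.special import expit, logsumexp

from neoscreen.peptides import CANONICAL_RESIDUES

DEFAULT_A = 26.0
DEFAULT_K = 1.0
GAP_OPEN = 11.0   # charged once per gap
GAP_EXTEND = 1.0  # charged per gapped residue, including the first

# Karlin-Altschul parameters for gapped BLOSUM62 (11, 1), used only for
# the optional bit-score scale.
_KA_LAMBDA = 0.267
_KA_LOGK = math.log(0.041)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_SUB = np.asarray(_BLOSUM62, dtype=np.float64)


def _encode(peptide: str) -> np.ndarray:
    bad = set(peptide) - CANONICAL_RESIDUES
    if bad or not peptide:
        raise ValueError(
            f"peptide {peptide!r} is empty or has non-canonical residues {sorted(bad)}"
        )
    return np.fromiter((_INDEX[aa] for aa in peptide), dtype=np.intp, count=len(peptide))


def local_align_score(
    s: str,
    e: str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    score_kind: str = "raw",
) -> float:
    """Optimal Smith–Waterman local alignment score of two peptides.

    Affine gap accounting: a gap of length g costs
    ``gap_open + g * gap_extend`` (the first gapped residue costs
    open + extend, the common BLASTp convention).  Substitution scores
    come from BLOSUM62.  ``score_kind="bit"`` rescales the raw score to
    BLAST bit units.
    """
    si = _encode(s.strip().upper())
    ei = _encode(e.strip().upper())
    open_cost = gap_open + gap_extend
    neg = -np.inf
    m, n = len(si), len(ei)
    # Gotoh recurrences, row-wise over the query.
    h_prev = np.zeros(n + 1)
    e_prev = np.full(n + 1, neg)
    best = 0.0
    for i in range(1, m + 1):
        h_cur = np.zeros(n + 1)
        e_cur = np.full(n + 1, neg)
        f = neg
        sub_row = _SUB[si[i - 1]]
        for j in range(1, n + 1):
            e_cur[j] = max(h_prev[j] - open_cost, e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - open_cost, f - gap_extend)
            h = max(0.0, h_prev[j - 1] + sub_row[ei[j - 1]], e_cur[j], f)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    if score_kind == "bit":
        return (_KA_LAMBDA * best - _KA_LOGK) / math.log(2)
    if score_kind != "raw":
        raise ValueError(f"score_kind must be 'raw' or 'bit', got {score_kind!r}")
    return float(best)


@dataclass(frozen=True)
class EpitopePool:
    """Deduplicated pool of validated epitope peptides."""

    entries: tuple[str, ...]

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "EpitopePool":
        """Case-fold, strip, drop non-canonical entries, deduplicate (order kept)."""
        seen: dict[str, None] = {}
        for raw in sequences:
            pep = raw.strip().upper()
            if pep and set(pep) <= CANONICAL_RESIDUES:
                seen.setdefault(pep, None)
        return cls(entries=tuple(seen))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, peptide: str) -> bool:
        return peptide.strip().upper() in set(self.entries)


def pool_similarities(s: str, pool: EpitopePool, **align_kwargs) -> np.ndarray:
    """|s,e| for every pool entry, in pool order."""
    return np.array([local_align_score(s, e, **align_kwargs) for e in pool.entries])


def recognition_probability(
    s: str,
    pool: EpitopePool,
    a: float = DEFAULT_A,
    k: float = DEFAULT_K,
    similarities: Optional[Sequence[float]] = None,
) -> float:
    """TCR recognition probability R = S / (1 + S), S = Σ_e exp(-k (a - |s,e|)).

    Computed through log-sum-exp so very large similarity scores do not
    overflow; R is exactly 0 for an empty pool and strictly below 1
    always.  Pass precomputed ``similarities`` to skip the alignments.
    """
    if k <= 0:
        raise ValueError("slope k must be positive")
    sims = (
        np.asarray(similarities, dtype=float)
        if similarities is not None
        else pool_similarities(s, pool)
    )
    if sims.size == 0:
        return 0.0
    log_s = logsumexp(-k * (a - sims))
    # S/(1+S) = sigmoid(log S); clamp one ulp below 1 so the analytic
    # strict bound R < 1 survives float64 saturation at huge similarities
    return min(float(expit(log_s)), float(np.nextafter(1.0, 0.0)))


def identity_lookup(s: str, pool: EpitopePool) -> tuple[bool, list[str]]:
    """Exact full-length, case-normalised match of ``s`` against the pool."""
    query = s.strip().upper()
    matches = [e for e in pool.entries if e == query]
    return bool(matches), matches


_PAIR_SCORE = {3: 1.0, 2: 0.75, 1: 0.25, 0: 0.0}


def pair_score(calls: Sequence[bool]) -> float:
    """Map three binary predictor calls to the {0, 0.25, 0.75, 1} pair score.

    Three independent peptide–CDR3 binding predictors each vote
    positive/negative; the pair score depends only on the number of
    positive votes: 3 → 1, 2 → 0.75, 1 → 0.25, 0 → 0.
    """
    if len(calls) != 3:
        raise ValueError(f"exactly three predictor calls required, got {len(calls)}")
    return _PAIR_SCORE[sum(bool(c) for c in calls)]


def tis(
    pair_scores: Sequence[float],
    threshold: float = 0.75,
    method: str = "fraction_positive",
) -> float:
    """T-cell interaction score for one peptide over a CDR3 panel.

    Default reading (``fraction_positive``): the fraction of CDR3
    sequences whose pair score reaches ``threshold`` (default 0.75,
    i.e. at least two of three predictors positive).  The alternative
    reading ``mean_pair_score`` averages the pair scores instead; the
    choice is explicit because the aggregation is a modelling
    convention, not a derived quantity.
    """
    if len(pair_scores) == 0:
        raise ValueError("at least one CDR3 pair score required")
    scores = np.asarray(pair_scores, dtype=float)
    if method == "fraction_positive":
        return float(np.mean(scores >= threshold))
    if method == "mean_pair_score":
        return float(scores.mean())
    raise ValueError(f"unknown TIS method {method!r}")
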