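"""Neoantigen probability score (NPS) and candidate ranking.

Class I combines every presentation stage:

    NPS_I  = TS * PHS * A * R / TIC

class II omits the proteasome and TAP stages:

    NPS_II = TS * A * R

where TS and PHS are the binary expression and proteasome gates, A the
wild-type/mutant affinity ratio, R the TCR recognition probability and
TIC the shifted TAP binding score.  Either gate at 0 forces NPS = 0;
otherwise NPS grows with A and R and shrinks with TIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

TIC_EPSILON = 1e-6


def nps_class1(
    ts: int, phs: int, a: float, r: float, tic: float, epsilon: float = TIC_EPSILON
) -> float:
    """Class I NPS = TS * PHS * A * R / TIC.

    A TIC below ``epsilon`` (the core attaining the sample minimum TBS
    has TIC = 0 by construction) is replaced by ``epsilon`` to avoid a
    division blow-up; callers flag such candidates in the output.
    """
    if a <= 0:
        raise ValueError("affinity ratio A must be positive")
    return ts * phs * a * r / max(tic, epsilon)


def nps_class2(ts: int, a: float, r: float) -> float:
    """Class II NPS = TS * A * R (no proteasome or TAP stage)."""
    if a <= 0:
        raise ValueError("affinity ratio A must be positive")
    return ts * a * r


@dataclass(frozen=True)
class CandidateScore:
    """Fully scored (core, allele) candidate for one MHC class."""

    mhc_class: str
    peptide: str
    wt_peptide: Optional[str]
    protein_id: str
    gene_id: str
    mutation_position: int
    allele: str
    ts: int
    a: float
    r: float
    nps: float
    phs: Optional[int] = None      # class I only
    tbs: Optional[float] = None    # class I only
    tic: Optional[float] = None    # class I only
    aff_wt: Optional[float] = None
    aff_mut: Optional[float] = None
    flags: tuple[str, ...] = field(default_factory=tuple)
    rank: Optional[int] = None


def rank_candidates(
    candidates: Sequence[CandidateScore], top_k: Optional[int] = None
) -> tuple[list[CandidateScore], list[CandidateScore]]:
    """Rank candidates by descending NPS; return (full table, top-k slice).

    Gated-out candidates (NPS = 0) stay in the table, after every
    positive-NPS candidate, so that rank-based evaluation can score the
    complete list.  Ties break by higher affinity ratio, then lower
    mutant IC50, then lexicographic peptide — the ordering is a total
    order, so reruns are byte-identical.
    """
    if not candidates:
        raise ValueError("no candidates to rank")

    def sort_key(c: CandidateScore):
        return (
            -c.nps,
            -c.a,
            c.aff_mut if c.aff_mut is not None else float("inf"),
            c.peptide,
        )

    ordered = sorted(candidates, key=sort_key)
    ranked = [replace(c, rank=i) for i, c in enumerate(ordered, start=1)]
    top = ranked[:top_k] if top_k is not None else list(ranked)
    return ranked, top
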