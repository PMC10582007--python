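"""MHC binding candidacy filter and wild-type/mutant affinity ratio.

A mutant core is a candidate only when its best predicted MHC IC50 is
below 500 nM (strict).  The affinity ratio ``A = Aff(WT) / Aff(mutant)``
measures the fold-change in MHC binding caused by the mutation: A > 1
means the mutation strengthened binding.  Default allele sets are the
mouse H2 panels (class I: Dd, Kd, Ld, Db, Kb; class II: IAb, IAd).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from neoscreen.peptides import CorePair

AFFINITY_CUTOFF_NM = 500.0

MHC1_ALLELES = ("H2-Db", "H2-Dd", "H2-Kb", "H2-Kd", "H2-Ld")
MHC2_ALLELES = ("H2-IAb", "H2-IAd")


@dataclass(frozen=True)
class BindingPair:
    """Best-allele binding record for one core pair."""

    core: CorePair
    allele: str
    aff_wt: float
    aff_mut: float
    ratio: float
    passes_filter: bool
    wt_imputed: bool = False  # Aff_WT fell back to the candidacy bound


def candidacy_filter(aff_mut: float, cutoff: float = AFFINITY_CUTOFF_NM) -> bool:
    """True iff the mutant core binds below the candidacy cutoff (strict <500 nM)."""
    if aff_mut <= 0:
        raise ValueError("mutant affinity must be positive (nM)")
    return aff_mut < cutoff


def affinity_ratio(
    aff_wt: Optional[float],
    aff_mut: float,
    wt_fallback: float = AFFINITY_CUTOFF_NM,
) -> float:
    """A = Aff(WT) / Aff(mutant), both in nM.

    When no wild-type counterpart exists (frameshift cores), Aff(WT) is
    imputed as the 500 nM candidacy bound, so A >= 1 exactly when the
    mutant passes the filter.  The ratio is unit-free and invariant to a
    common rescaling of both affinities.
    """
    if aff_mut <= 0:
        raise ValueError("mutant affinity must be positive (nM)")
    if aff_wt is None:
        return wt_fallback / aff_mut
    if aff_wt <= 0:
        raise ValueError("wild-type affinity must be positive (nM)")
    return aff_wt / aff_mut


def best_allele_binding(
    core: CorePair,
    per_allele: Mapping[str, tuple[Optional[float], float]],
    cutoff: float = AFFINITY_CUTOFF_NM,
) -> BindingPair:
    """Select the allele with the strongest (minimum) mutant IC50.

    ``per_allele`` maps allele name to ``(Aff_WT, Aff_mut)``; Aff_WT may
    be ``None`` for cores with no wild-type counterpart.  Ties on the
    mutant IC50 break lexicographically by allele name.  Presentation is
    assumed to be dominated by the strongest binder; per-allele records
    are still available upstream for the detailed output table.
    """
    if not per_allele:
        raise ValueError("no allele records supplied")
    allele = min(per_allele, key=lambda a: (per_allele[a][1], a))
    aff_wt, aff_mut = per_allele[allele]
    return BindingPair(
        core=core,
        allele=allele,
        aff_wt=aff_wt if aff_wt is not None else cutoff,
        aff_mut=aff_mut,
        ratio=affinity_ratio(aff_wt, aff_mut, wt_fallback=cutoff),
        passes_filter=candidacy_filter(aff_mut, cutoff),
        wt_imputed=aff_wt is None,
    )
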