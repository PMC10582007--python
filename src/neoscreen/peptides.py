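"""Mutant protein construction and mutation-containing peptide extraction.

A somatic variant observed at protein position ``m`` defines a
mutation-containing peptide (MCP): the window ``[m - n, m + n]`` on the
mutant protein, clipped at the termini.  The flank ``n`` is 22 for MHC
class I (45-mer MCP) and 27 for class II (55-mer MCP).  Candidate core
peptides — 9-mers (class I) or 15-mers (class II) — are enumerated from
the MCP with a step-1 sliding window, each paired with the same-offset
wild-type core so that downstream stages can compare mutant and
wild-type binding.

All coordinates are 1-based and inclusive, the usual protein convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

logger = logging.getLogger(__name__)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: 'X' is tolerated in input sequences but disqualifies any core containing it.
ALLOWED_RESIDUES = CANONICAL_RESIDUES | {"X"}

#: Flank width n per MHC class: window spans [m-n, m+n].
FLANK = {"I": 22, "II": 27}
#: Core (scored epitope segment) length per MHC class.
CORE_LENGTH = {"I": 9, "II": 15}


class VariantClass(str, Enum):
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"
    FRAMESHIFT = "frameshift"


class CoordinateError(ValueError):
    """Variant position falls outside the wild-type sequence."""


class ConsistencyError(ValueError):
    """Variant reference residues disagree with the wild-type sequence."""


@dataclass(frozen=True)
class Variant:
    """Protein-level variant descriptor.

    ``ref`` is the wild-type residue string starting at ``position``
    (may be empty for a pure insertion); ``alt`` replaces it.  For
    frameshifts the entire mutant tail from ``position`` onward is
    supplied in ``mutant_tail`` — no CDS translation is attempted.
    """

    protein_id: str
    gene_id: str
    position: int
    ref: str
    alt: str
    variant_class: VariantClass
    mutant_tail: Optional[str] = None


@dataclass
class MutationContext:
    """One somatic variant with its wild-type and mutant proteins.

    ``mutated_positions`` are 1-based positions on the *mutant* protein
    that carry the mutation: the substituted residue for a SNP, the
    inserted residues for an insertion, the junction residue for a
    deletion, every position from the edit onward for a frameshift.
    """

    protein_id: str
    gene_id: str
    position: int
    variant_class: VariantClass
    wt_sequence: str
    mut_sequence: str
    mutated_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 1 <= self.position <= len(self.wt_sequence):
            raise CoordinateError(
                f"position {self.position} outside WT sequence of length "
                f"{len(self.wt_sequence)} ({self.protein_id})"
            )
        for name, seq in (("wt", self.wt_sequence), ("mut", self.mut_sequence)):
            bad = set(seq) - ALLOWED_RESIDUES
            if bad:
                raise ValueError(
                    f"non-canonical residues {sorted(bad)} in {name} sequence "
                    f"of {self.protein_id}"
                )


@dataclass(frozen=True)
class McpWindow:
    """Mutation-containing peptide: a clipped 2n+1 window on the mutant protein."""

    mhc_class: str
    protein_id: str
    gene_id: str
    mutation_position: int
    start: int
    end: int
    sequence: str       # P_M, slice of the mutant protein
    wt_sequence: str    # same-coordinate slice of the WT protein, clipped
    mutated_offsets: frozenset[int]  # 1-based offsets within this window
    variant_class: VariantClass = VariantClass.SNP

    @property
    def peptide_id(self) -> str:
        return (
            f"{self.protein_id}|{self.mutation_position}|{self.mhc_class}"
            f"|{self.start}-{self.end}"
        )


@dataclass(frozen=True)
class CorePair:
    """A candidate core and its same-offset wild-type counterpart.

    ``wt_core`` is ``None`` when no meaningful wild-type segment exists
    (frameshift cores, or cores running past the wild-type terminus).
    """

    mhc_class: str
    offset: int  # 1-based offset of the core within the MCP
    mutant_core: str
    wt_core: Optional[str]
    contains_mutation: bool
    mcp: McpWindow

    @property
    def core_length(self) -> int:
        return len(self.mutant_core)


def build_mutant_protein(wt_sequence: str, variant: Variant) -> str:
    """Apply a protein-level variant to the wild-type sequence.

    SNPs substitute one residue, insertions/deletions perform a local
    ref→alt edit at ``variant.position``, and frameshifts replace the
    suffix from ``position`` onward with the supplied mutant tail.

    Raises
    ------
    CoordinateError
        If the position lies outside the sequence.
    ConsistencyError
        If ``variant.ref`` does not match the wild-type residues there.
    """
    pos = variant.position
    if not 1 <= pos <= len(wt_sequence):
        raise CoordinateError(
            f"variant position {pos} outside sequence of length {len(wt_sequence)}"
        )
    if variant.variant_class is VariantClass.FRAMESHIFT:
        if not variant.mutant_tail:
            raise ValueError("frameshift variant requires an explicit mutant_tail")
        return wt_sequence[: pos - 1] + variant.mutant_tail

    observed = wt_sequence[pos - 1 : pos - 1 + len(variant.ref)]
    if observed != variant.ref:
        raise ConsistencyError(
            f"ref mismatch at position {pos}: variant says {variant.ref!r}, "
            f"sequence has {observed!r}"
        )
    if variant.variant_class is VariantClass.SNP and (
        len(variant.ref) != 1 or len(variant.alt) != 1
    ):
        raise ValueError("SNP must have single-residue ref and alt")
    return wt_sequence[: pos - 1] + variant.alt + wt_sequence[pos - 1 + len(variant.ref) :]


def mutation_context(wt_sequence: str, variant: Variant) -> MutationContext:
    """Build the full mutation context (mutant protein + mutated positions)."""
    mut = build_mutant_protein(wt_sequence, variant)
    pos = variant.position
    vc = variant.variant_class
    if vc is VariantClass.SNP:
        mutated = {pos}
    elif vc is VariantClass.INSERTION:
        mutated = set(range(pos, pos + max(len(variant.alt), 1)))
    elif vc is VariantClass.DELETION:
        # junction residue: the first residue that newly abuts the upstream flank
        mutated = {min(pos, len(mut))} if mut else set()
    else:  # frameshift: everything from the edit onward is novel
        mutated = set(range(pos, len(mut) + 1))
    return MutationContext(
        protein_id=variant.protein_id,
        gene_id=variant.gene_id,
        position=pos,
        variant_class=vc,
        wt_sequence=wt_sequence,
        mut_sequence=mut,
        mutated_positions=frozenset(p for p in mutated if 1 <= p <= len(mut)),
    )


def extract_mcp(ctx: MutationContext, mhc_class: str) -> McpWindow:
    """Extract the mutation-containing peptide window for one MHC class.

    The window spans ``[max(1, m-n), min(L, m+n)]`` on the mutant
    protein (length 2n+1 unless clipped by a terminus).  The wild-type
    sequence is the identical coordinate slice of the WT protein,
    additionally clipped to the WT length when an indel shortened it.
    """
    if mhc_class not in FLANK:
        raise ValueError(f"mhc_class must be 'I' or 'II', got {mhc_class!r}")
    n = FLANK[mhc_class]
    m = ctx.position
    length = len(ctx.mut_sequence)
    if not 1 <= m <= length:
        raise CoordinateError(
            f"mutation position {m} outside mutant protein of length {length}"
        )
    start = max(1, m - n)
    end = min(length, m + n)
    wt_end = min(end, len(ctx.wt_sequence))
    return McpWindow(
        mhc_class=mhc_class,
        protein_id=ctx.protein_id,
        gene_id=ctx.gene_id,
        mutation_position=m,
        start=start,
        end=end,
        sequence=ctx.mut_sequence[start - 1 : end],
        wt_sequence=ctx.wt_sequence[start - 1 : wt_end] if wt_end >= start else "",
        mutated_offsets=frozenset(
            p - start + 1 for p in ctx.mutated_positions if start <= p <= end
        ),
        variant_class=ctx.variant_class,
    )


def enumerate_cores(mcp: McpWindow) -> list[CorePair]:
    """Slide a step-1 window of the class core length across the MCP.

    Returns one :class:`CorePair` per offset; the wild-type core is the
    same-offset slice of the MCP's wild-type sequence, or ``None`` when
    that slice is incomplete or the core overlaps a frameshifted region
    (where the wild-type residues are not a meaningful counterpart).
    Cores containing 'X' or other non-canonical residues are dropped
    with a log message — binding predictors and BLOSUM62 are undefined
    for them.
    """
    c = CORE_LENGTH[mcp.mhc_class]
    if len(mcp.sequence) < c:
        logger.warning(
            "MCP %s shorter than core length %d; no cores", mcp.peptide_id, c
        )
        return []
    cores: list[CorePair] = []
    for i in range(1, len(mcp.sequence) - c + 2):
        mut_core = mcp.sequence[i - 1 : i - 1 + c]
        if not set(mut_core) <= CANONICAL_RESIDUES:
            logger.info(
                "core at offset %d of %s disqualified (non-canonical residue)",
                i, mcp.peptide_id,
            )
            continue
        contains = any(i <= off <= i + c - 1 for off in mcp.mutated_offsets)
        wt_core: Optional[str] = mcp.wt_sequence[i - 1 : i - 1 + c]
        if len(wt_core) < c or not set(wt_core) <= CANONICAL_RESIDUES:
            wt_core = None
        elif mcp.variant_class is VariantClass.FRAMESHIFT and contains:
            wt_core = None
        cores.append(
            CorePair(
                mhc_class=mcp.mhc_class,
                offset=i,
                mutant_core=mut_core,
                wt_core=wt_core,
                contains_mutation=contains,
                mcp=mcp,
            )
        )
    return cores
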