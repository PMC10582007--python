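"""Gating and transform scores of the presentation cascade.

Three stages precede MHC binding for class I candidates:

* expression gate ``TS`` — 1 iff the host gene's TPM exceeds 3;
* proteasome gate ``PHS`` — 1 iff the cleavage probability at the
  residue preceding the core's N-terminus or at its C-terminal residue
  exceeds 0.7;
* TAP transport — the TAP binding score ``TBS = log10(IC50)`` shifted to
  the non-negative ``TIC = TBS + |TBS_min|``, where ``TBS_min`` is the
  minimum over all candidate cores of the run.

Class II candidates use only the expression gate.  External cleavage /
TAP / MHC predictors are consumed through a canonical-TSV backend
contract; a seeded hash-based surrogate backend is shipped so the whole
pipeline runs offline.  Surrogate scores are deterministic pseudo-values
with no biological meaning.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from neoscreen.binding import MHC1_ALLELES, MHC2_ALLELES

TPM_THRESHOLD = 3.0
CLEAVAGE_THRESHOLD = 0.7
TBS_LOG_BASE = 10.0


def fpkm_to_tpm(fpkm_table: Mapping[str, float]) -> dict[str, float]:
    """Convert per-gene FPKM to TPM.

    FPKM is already length-normalised, so TPM is the FPKM share rescaled
    to parts per million: ``TPM_i = FPKM_i / sum(FPKM) * 1e6``.  The
    result sums to 1e6 by construction.
    """
    if any(v < 0 for v in fpkm_table.values()):
        raise ValueError("FPKM values must be non-negative")
    total = sum(fpkm_table.values())
    if total <= 0:
        raise ValueError("degenerate expression table: all FPKM are zero")
    return {g: v / total * 1e6 for g, v in fpkm_table.items()}


def tpm_score(tpm: float, threshold: float = TPM_THRESHOLD) -> int:
    """Expression gate TS: 1 iff TPM strictly exceeds the threshold (default 3)."""
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    return 1 if tpm > threshold else 0


def hydrolysis_score(
    n_prime_p: float, c_prime_p: float, threshold: float = CLEAVAGE_THRESHOLD
) -> int:
    """Proteasome gate PHS: 1 iff either terminal cleavage probability > 0.7.

    ``n_prime_p`` is the cleavage probability at the residue immediately
    preceding the core's N-terminus (1.0 for a core flush with the MCP
    N-terminus: a free terminus needs no upstream cut); ``c_prime_p`` at
    the core's C-terminal residue.
    """
    for name, p in (("N'", n_prime_p), ("C'", c_prime_p)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} cleavage probability {p} outside [0, 1]")
    return 1 if (n_prime_p > threshold or c_prime_p > threshold) else 0


def tap_transform(
    ic50_values: Sequence[float], log_base: float = TBS_LOG_BASE
) -> list[tuple[float, float]]:
    """TAP transform: TBS = log10(IC50); TIC = TBS + |TBS_min|.

    ``TBS_min`` is taken over the supplied candidate set, so the shift
    is sample-level: call once per run with every candidate core's TAP
    IC50.  The transform is order-preserving — ranking by TIC equals
    ranking by TBS.
    """
    if len(ic50_values) == 0:
        raise ValueError("empty IC50 list")
    if any(v <= 0 for v in ic50_values):
        raise ValueError("TAP IC50 values must be positive (nM)")
    tbs = [math.log(v, log_base) for v in ic50_values]
    shift = abs(min(tbs))
    return [(b, b + shift) for b in tbs]


@dataclass(frozen=True)
class CleavageProfile:
    """Per-residue cleavage probabilities over one MCP (1-based indexing)."""

    peptide_id: str
    probabilities: tuple[float, ...]

    def core_terminal_probs(self, offset: int, core_length: int) -> tuple[float, float]:
        """(N', C') probabilities for the core at the given MCP offset.

        N' is read at residue ``offset - 1`` (1.0 when the core starts at
        the MCP N-terminus), C' at residue ``offset + core_length - 1``.
        """
        if offset < 1 or offset + core_length - 1 > len(self.probabilities):
            raise IndexError(
                f"core [{offset}, {offset + core_length - 1}] outside profile "
                f"of length {len(self.probabilities)}"
            )
        n_prime = 1.0 if offset == 1 else self.probabilities[offset - 2]
        c_prime = self.probabilities[offset + core_length - 2]
        return n_prime, c_prime


# ---------------------------------------------------------------------------
# Predictor backend contract + deterministic surrogate
# ---------------------------------------------------------------------------

BACKEND_KINDS = ("cleavage", "tap", "mhc1", "mhc2")
_MHC_CORE_LENGTH = {"mhc1": 9, "mhc2": 15}
_KNOWN_ALLELES = {"mhc1": tuple(MHC1_ALLELES), "mhc2": tuple(MHC2_ALLELES)}

IC50_MIN_NM = 1.0
IC50_MAX_NM = 5e4


class SurrogateBackend:
    """Seeded hash-based stand-in for an external predictor.

    Emits deterministic pseudo-scores keyed on (kind, seed, peptide,
    allele): cleavage probabilities in [0, 1], TAP/MHC IC50 values
    log-uniform in [1, 5e4] nM.  The values carry no biological signal;
    the backend exists so that every stage of the pipeline has a
    concrete, reproducible input when no external tool output is
    available.  Real predictor output enters through the same canonical
    TSV schema (see :mod:`neoscreen.io`).
    """

    def __init__(self, kind: str, seed: int = 0, name: str = "surrogate"):
        if kind not in BACKEND_KINDS:
            raise ValueError(f"unknown backend kind {kind!r}; one of {BACKEND_KINDS}")
        self.kind = kind
        self.seed = int(seed)
        self.name = name

    def _unit(self, *fields: str) -> float:
        """Deterministic uniform(0,1) from a hash of the key fields."""
        key = "\x1f".join((self.name, self.kind, str(self.seed), *fields))
        digest = hashlib.sha256(key.encode()).digest()
        return int.from_bytes(digest[:8], "big") / 2**64

    def _ic50(self, *fields: str) -> float:
        u = self._unit(*fields)
        return IC50_MIN_NM * (IC50_MAX_NM / IC50_MIN_NM) ** u

    def cleavage_profile(self, peptide_id: str, sequence: str) -> CleavageProfile:
        if self.kind != "cleavage":
            raise ValueError(f"{self.kind} backend cannot produce cleavage profiles")
        probs = tuple(
            self._unit(peptide_id, str(i)) for i in range(1, len(sequence) + 1)
        )
        return CleavageProfile(peptide_id=peptide_id, probabilities=probs)

    def tap_ic50(self, peptides: Iterable[str]) -> dict[str, float]:
        if self.kind != "tap":
            raise ValueError(f"{self.kind} backend cannot produce TAP IC50")
        return {p: self._ic50(p) for p in peptides}

    def mhc_ic50(
        self, peptides: Iterable[str], alleles: Sequence[str]
    ) -> dict[tuple[str, str], float]:
        if self.kind not in _MHC_CORE_LENGTH:
            raise ValueError(f"{self.kind} backend cannot produce MHC IC50")
        want = _MHC_CORE_LENGTH[self.kind]
        known = _KNOWN_ALLELES[self.kind]
        out: dict[tuple[str, str], float] = {}
        for allele in alleles:
            if allele not in known:
                raise ValueError(
                    f"allele {allele!r} not in the configured {self.kind} set {known}"
                )
        for pep in peptides:
            if len(pep) != want:
                raise ValueError(
                    f"{self.kind} backend requires {want}-mers, got {len(pep)}-mer {pep!r}"
                )
            for allele in alleles:
                out[(pep, allele)] = self._ic50(pep, allele)
        return out
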