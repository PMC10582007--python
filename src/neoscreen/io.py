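"""Readers and writers for the pipeline's file formats.

All tables are tab-separated UTF-8.  Lines starting with ``#`` are
comments; every writer emits one stating the table kind and the
coordinate convention (1-based, inclusive).  Canonical predictor tables
are the integration boundary with external tools: adapters for vendor
formats should emit these schemas.

================  =====================================================
table             columns
================  =====================================================
variants          protein_id, gene_id, position, ref, alt,
                  variant_class, mutant_tail (optional)
expression        gene_id, fpkm
cleavage          peptide_id, residue_index, probability
tap               peptide, ic50_nM
mhc               peptide, allele, ic50_nM, wt_peptide, wt_ic50_nM
labels            peptide, label  (label in {0, 1})
ranked            rank, mhc_class, peptide, wt_peptide, gene_id,
                  allele, TS, PHS, TBS, TIC, Aff_WT, Aff_M, A, R, NPS,
                  flags
================  =====================================================
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from neoscreen.peptides import McpWindow, Variant, VariantClass
from neoscreen.ranking import CandidateScore
from neoscreen.stage_scores import CleavageProfile
from neoscreen.tcr import EpitopePool

_COMMENT = "# neoscreen {kind} table; coordinates 1-based inclusive\n"


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_proteome(path: str | Path) -> dict[str, str]:
    """FASTA → {protein_id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_proteome(proteome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_variants(path: str | Path) -> list[Variant]:
    df = _read_tsv(
        path, ["protein_id", "gene_id", "position", "ref", "alt", "variant_class"]
    )
    variants = []
    for idx, row in df.iterrows():
        try:
            variants.append(
                Variant(
                    protein_id=row["protein_id"],
                    gene_id=row["gene_id"],
                    position=int(row["position"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    variant_class=VariantClass(row["variant_class"]),
                    mutant_tail=row.get("mutant_tail") or None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: bad variant record at data row {idx + 1}: {exc}")
    return variants


def write_variants(variants: Sequence[Variant], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT.format(kind="variants"))
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["protein_id", "gene_id", "position", "ref", "alt", "variant_class",
             "mutant_tail"]
        )
        for v in variants:
            w.writerow(
                [v.protein_id, v.gene_id, v.position, v.ref, v.alt,
                 v.variant_class.value, v.mutant_tail or ""]
            )


def read_expression(path: str | Path) -> dict[str, float]:
    df = _read_tsv(path, ["gene_id", "fpkm"])
    return {row["gene_id"]: float(row["fpkm"]) for _, row in df.iterrows()}


def write_expression(fpkm: dict[str, float], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT.format(kind="expression"))
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "fpkm"])
        for gene, value in fpkm.items():
            w.writerow([gene, repr(value)])


def read_epitope_pool(path: str | Path) -> EpitopePool:
    """Epitope pool from FASTA or a single-column (``peptide``) TSV."""
    path = Path(path)
    head = path.read_text().lstrip()
    if head.startswith(">"):
        seqs = (str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
        return EpitopePool.from_sequences(seqs)
    df = _read_tsv(path, ["peptide"])
    return EpitopePool.from_sequences(df["peptide"])


def write_epitope_pool(pool: EpitopePool, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT.format(kind="epitope pool"))
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide"])
        for pep in pool.entries:
            w.writerow([pep])


def read_cleavage(path: str | Path) -> dict[str, CleavageProfile]:
    df = _read_tsv(path, ["peptide_id", "residue_index", "probability"])
    profiles: dict[str, CleavageProfile] = {}
    for pid, group in df.groupby("peptide_id", sort=False):
        idx = group["residue_index"].astype(int)
        probs = group["probability"].astype(float)
        ordered = [p for _, p in sorted(zip(idx, probs))]
        if sorted(idx) != list(range(1, len(ordered) + 1)):
            raise ValueError(f"{path}: non-contiguous residue indices for {pid}")
        profiles[pid] = CleavageProfile(peptide_id=pid, probabilities=tuple(ordered))
    return profiles


def write_cleavage(profiles: dict[str, CleavageProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT.format(kind="cleavage"))
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide_id", "residue_index", "probability"])
        for pid, prof in profiles.items():
            for i, p in enumerate(prof.probabilities, start=1):
                w.writerow([pid, i, repr(p)])


def read_tap(path: str | Path) -> dict[str, float]:
    df = _read_tsv(path, ["peptide", "ic50_nM"])
    return {row["peptide"]: float(row["ic50_nM"]) for _, row in df.iterrows()}


def write_tap(tap: dict[str, float], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT.format(kind="tap"))
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide", "ic50_nM"])
        for pep, ic50 in tap.items():
            w.writerow([pep, repr(ic50)])


def read_mhc(path: str | Path) -> dict[tuple[str, str], tuple[float, Optional[float]]]:
    """MHC table → {(mutant peptide, allele): (mutant IC50, WT IC50 or None)}."""
    df = _read_tsv(path, ["peptide", "allele", "ic50_nM", "wt_peptide", "wt_ic50_nM"])
    records: dict[tuple[str, str], tuple[float, Optional[float]]] = {}
    for _, row in df.iterrows():
        wt = float(row["wt_ic50_nM"]) if row["wt_ic50_nM"] != "" else None
        records[(row["peptide"], row["allele"])] = (float(row["ic50_nM"]), wt)
    return records


def write_mhc(
    records: dict[tuple[str, str], tuple[float, Optional[float], Optional[str]]],
    path: str | Path,
) -> None:
    """Write {(peptide, allele): (ic50, wt_ic50 or None, wt_peptide or None)}."""
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT.format(kind="mhc"))
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide", "allele", "ic50_nM", "wt_peptide", "wt_ic50_nM"])
        for (pep, allele), (ic50, wt_ic50, wt_pep) in records.items():
            w.writerow(
                [pep, allele, repr(ic50), wt_pep or "",
                 repr(wt_ic50) if wt_ic50 is not None else ""]
            )


def read_labels(path: str | Path) -> dict[str, int]:
    df = _read_tsv(path, ["peptide", "label"])
    return {row["peptide"]: int(row["label"]) for _, row in df.iterrows()}


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT.format(kind="labels"))
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide", "label"])
        for pep, lab in labels.items():
            w.writerow([pep, lab])


def write_mcp_fasta(mcps: Sequence[McpWindow], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=m.peptide_id, description="") for m in mcps
    ]
    SeqIO.write(records, str(path), "fasta")


RANKED_COLUMNS = [
    "rank", "mhc_class", "peptide", "wt_peptide", "gene_id", "allele",
    "TS", "PHS", "TBS", "TIC", "Aff_WT", "Aff_M", "A", "R", "NPS", "flags",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return format(x, ".10g")
    return str(x)


def write_ranked(candidates: Sequence[CandidateScore], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT.format(kind="ranked candidates"))
        w = csv.writer(fh, delimiter="\t")
        w.writerow(RANKED_COLUMNS)
        for c in candidates:
            w.writerow(
                [
                    c.rank, c.mhc_class, c.peptide, c.wt_peptide or "", c.gene_id,
                    c.allele, c.ts, _fmt(c.phs), _fmt(c.tbs), _fmt(c.tic),
                    _fmt(c.aff_wt), _fmt(c.aff_mut), _fmt(c.a), _fmt(c.r),
                    _fmt(c.nps), ";".join(c.flags),
                ]
            )


def read_ranked(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
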