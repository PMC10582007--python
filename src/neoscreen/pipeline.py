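"""End-to-end orchestration: variants → MCPs → cores → stage scores → ranked lists.

For each somatic variant and each MHC class the pipeline

1. builds the mutant protein and extracts the mutation-containing
   peptide (MCP) window;
2. enumerates mutation-containing candidate cores (9-mer / 15-mer);
3. applies the expression gate (TS) from the gene's TPM;
4. class I only: reads per-residue cleavage probabilities over the MCP
   (proteasome gate PHS) and the TAP IC50 per core (TBS → TIC, shifted
   by the run-level minimum TBS);
5. looks up mutant and wild-type MHC IC50 per configured allele, keeps
   the best (minimum mutant IC50) allele, and drops cores at or above
   the 500 nM candidacy cutoff;
6. computes the TCR recognition probability R against the epitope pool;
7. combines everything into the NPS and ranks candidates, both per core
   and per mutation (best core).

Candidates missing predictor records are dropped with a logged reason;
per-stage survivor counts are recorded and written to the run log.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from neoscreen import io
from neoscreen.binding import best_allele_binding
from neoscreen.config import RunConfig
from neoscreen.peptides import (
    CORE_LENGTH,
    CorePair,
    enumerate_cores,
    extract_mcp,
    mutation_context,
)
from neoscreen.ranking import CandidateScore, nps_class1, nps_class2, rank_candidates
from neoscreen.stage_scores import fpkm_to_tpm, hydrolysis_score, tpm_score
from neoscreen.tcr import EpitopePool, recognition_probability

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    per_core: dict[str, list[CandidateScore]] = field(default_factory=dict)
    per_mutation: dict[str, list[CandidateScore]] = field(default_factory=dict)
    top: dict[str, list[CandidateScore]] = field(default_factory=dict)
    stage_counts: dict[str, "OrderedDict[str, int]"] = field(default_factory=dict)


def _mutation_key(c: CandidateScore) -> tuple[str, int]:
    return (c.protein_id, c.mutation_position)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the staged presentation model for both MHC classes.

    Reads every input named in ``config``, scores and ranks candidates,
    and (unless ``write_outputs`` is false) writes per-core and
    per-mutation ranked TSVs, a config echo and a plain-text run log to
    ``config.out_dir``.
    """
    proteome = io.read_proteome(config.proteome_fasta)
    variants = io.read_variants(config.variants_tsv)
    fpkm = io.read_expression(config.expression_tsv)
    pool = (
        io.read_epitope_pool(config.epitope_pool)
        if config.epitope_pool
        else EpitopePool(entries=())
    )
    cleavage = io.read_cleavage(config.cleavage_tsv) if config.cleavage_tsv else {}
    tap = io.read_tap(config.tap_tsv) if config.tap_tsv else {}
    mhc_records = {
        "I": io.read_mhc(config.mhc1_tsv) if config.mhc1_tsv else {},
        "II": io.read_mhc(config.mhc2_tsv) if config.mhc2_tsv else {},
    }
    alleles = {"I": config.mhc1_alleles, "II": config.mhc2_alleles}

    tpm = fpkm_to_tpm(fpkm) if fpkm else {}

    result = PipelineResult()
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    contexts = []
    for var in variants:
        if var.protein_id not in proteome:
            logger.warning("variant on unknown protein %s dropped", var.protein_id)
            continue
        contexts.append(mutation_context(proteome[var.protein_id], var))

    log_lines: list[str] = []
    for mhc_class in ("I", "II"):
        counts: OrderedDict[str, int] = OrderedDict()
        counts["variants"] = len(contexts)

        mcps = [extract_mcp(ctx, mhc_class) for ctx in contexts]
        counts["mcps"] = len(mcps)

        cores: list[CorePair] = []
        for mcp in mcps:
            cores.extend(c for c in enumerate_cores(mcp) if c.contains_mutation)
        counts["mutation_containing_cores"] = len(cores)

        # --- stage scores -------------------------------------------------
        scored: list[dict] = []
        for core in cores:
            rec: dict = {"core": core}
            rec["ts"] = tpm_score(
                tpm.get(core.mcp.gene_id, 0.0), threshold=config.tpm_threshold
            )
            if mhc_class == "I":
                profile = cleavage.get(core.mcp.peptide_id)
                if profile is None:
                    logger.info(
                        "no cleavage profile for %s; core at offset %d dropped",
                        core.mcp.peptide_id, core.offset,
                    )
                    continue
                n_p, c_p = profile.core_terminal_probs(core.offset, core.core_length)
                rec["phs"] = hydrolysis_score(
                    n_p, c_p, threshold=config.cleavage_threshold
                )
                ic50_tap = tap.get(core.mutant_core)
                if ic50_tap is None:
                    logger.info("no TAP record for %s; dropped", core.mutant_core)
                    continue
                rec["tbs"] = math.log(ic50_tap, config.log_base)
            scored.append(rec)
        counts["with_stage_records"] = len(scored)

        if mhc_class == "I" and scored:
            tbs_min = min(rec["tbs"] for rec in scored)
            for rec in scored:
                rec["tic"] = rec["tbs"] + abs(tbs_min)
            log_lines.append(f"class I TBS_min = {tbs_min:.6g}")

        # --- MHC binding + candidacy -------------------------------------
        bound: list[dict] = []
        for rec in scored:
            core = rec["core"]
            per_allele = {}
            for allele in alleles[mhc_class]:
                entry = mhc_records[mhc_class].get((core.mutant_core, allele))
                if entry is None:
                    continue
                mut_ic50, wt_ic50 = entry
                per_allele[allele] = (
                    wt_ic50 if core.wt_core is not None else None,
                    mut_ic50,
                )
            if not per_allele:
                logger.info("no MHC records for %s; dropped", core.mutant_core)
                continue
            pair = best_allele_binding(
                core, per_allele, cutoff=config.affinity_cutoff_nm
            )
            if not pair.passes_filter:
                continue
            rec["pair"] = pair
            bound.append(rec)
        counts["pass_candidacy"] = len(bound)

        # --- TCR recognition + NPS ----------------------------------------
        candidates: list[CandidateScore] = []
        for rec in bound:
            core: CorePair = rec["core"]
            pair = rec["pair"]
            r = recognition_probability(
                core.mutant_core, pool, a=config.a, k=config.k
            )
            flags = []
            if pair.wt_imputed:
                flags.append("wt_affinity_imputed")
            if mhc_class == "I":
                if rec["tic"] < config.tic_epsilon:
                    flags.append("tic_epsilon_guard")
                nps = nps_class1(
                    rec["ts"], rec["phs"], pair.ratio, r, rec["tic"],
                    epsilon=config.tic_epsilon,
                )
            else:
                nps = nps_class2(rec["ts"], pair.ratio, r)
            candidates.append(
                CandidateScore(
                    mhc_class=mhc_class,
                    peptide=core.mutant_core,
                    wt_peptide=core.wt_core,
                    protein_id=core.mcp.protein_id,
                    gene_id=core.mcp.gene_id,
                    mutation_position=core.mcp.mutation_position,
                    allele=pair.allele,
                    ts=rec["ts"],
                    a=pair.ratio,
                    r=r,
                    nps=nps,
                    phs=rec.get("phs"),
                    tbs=rec.get("tbs"),
                    tic=rec.get("tic"),
                    aff_wt=pair.aff_wt,
                    aff_mut=pair.aff_mut,
                    flags=tuple(flags),
                )
            )
        counts["scored_candidates"] = len(candidates)

        if candidates:
            per_core_ranked, _ = rank_candidates(candidates)
            # per-mutation: best core of each mutation drives the headline list
            best: dict[tuple[str, int], CandidateScore] = {}
            for cand in per_core_ranked:  # already in rank order
                best.setdefault(_mutation_key(cand), cand)
            per_mut_ranked, top = rank_candidates(
                list(best.values()), top_k=config.top_k
            )
        else:
            per_core_ranked, per_mut_ranked, top = [], [], []
        counts["ranked_mutations"] = len(per_mut_ranked)

        result.per_core[mhc_class] = per_core_ranked
        result.per_mutation[mhc_class] = per_mut_ranked
        result.top[mhc_class] = top
        result.stage_counts[mhc_class] = counts

        label = "mhc1" if mhc_class == "I" else "mhc2"
        if write_outputs:
            io.write_ranked(per_core_ranked, out_dir / f"ranked_cores_{label}.tsv")
            io.write_ranked(per_mut_ranked, out_dir / f"ranked_mutations_{label}.tsv")
        log_lines.append(f"[class {mhc_class}] " + ", ".join(
            f"{k}={v}" for k, v in counts.items()
        ))

    if write_outputs:
        config.to_yaml(out_dir / "config_echo.yaml")
        (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return result
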