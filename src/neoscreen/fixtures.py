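"""Seeded synthetic fixture bundles for offline end-to-end runs.

The generator emits every input the pipeline consumes — proteome FASTA,
variant / expression / predictor TSVs and an epitope pool — together
with a truth annotation naming the planted positives.  Planted variants
are constructed to clear every presentation stage:

* their gene receives a high FPKM (TPM well above 3);
* the cleavage probability at the planted core's C-terminal residue
  exceeds 0.7 (all other residues stay at or below it);
* the planted mutant core binds one allele below 100 nM with a
  wild-type/mutant affinity ratio of at least 10;
* the planted core itself is placed in the epitope pool, so its
  self-alignment score exceeds the recognition displacement ``a``.

Every non-planted mutation-containing core is written with a mutant MHC
IC50 of at least 1000 nM, so it fails the 500 nM candidacy filter — by
construction only planted candidates can reach the ranked list.  All
values are drawn from a single seeded generator: the same seed and
sizes reproduce the bundle byte for byte.  The scores are synthetic and
carry no biological meaning beyond these planted contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from neoscreen import io
from neoscreen.binding import MHC1_ALLELES, MHC2_ALLELES
from neoscreen.config import RunConfig
from neoscreen.peptides import (
    Variant,
    VariantClass,
    enumerate_cores,
    extract_mcp,
    mutation_context,
)
from neoscreen.stage_scores import CleavageProfile
from neoscreen.tcr import EpitopePool

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureBundle:
    out_dir: Path
    seed: int
    planted_variants: list[str]          # "protein_id:position"
    planted_cores: dict[str, list[str]]  # mhc class -> planted core peptides

    def make_config(self, **overrides) -> RunConfig:
        d = self.out_dir
        defaults = dict(
            proteome_fasta=str(d / "proteome.fasta"),
            variants_tsv=str(d / "variants.tsv"),
            expression_tsv=str(d / "expression.tsv"),
            epitope_pool=str(d / "epitope_pool.tsv"),
            cleavage_tsv=str(d / "cleavage_mhc1.tsv"),
            tap_tsv=str(d / "tap_mhc1.tsv"),
            mhc1_tsv=str(d / "mhc1.tsv"),
            mhc2_tsv=str(d / "mhc2.tsv"),
            out_dir=str(d / "run"),
            seed=self.seed,
        )
        defaults.update(overrides)
        return RunConfig(**defaults)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo * (hi / lo) ** rng.random())


def generate_fixtures(
    seed: int,
    out_dir: str | Path,
    n_proteins: int = 8,
    n_variants: int = 24,
    fraction_planted: float = 0.25,
) -> FixtureBundle:
    """Write a complete, seeded fixture bundle under ``out_dir``."""
    if n_proteins < 1 or n_variants < 1:
        raise ValueError("sizes must be >= 1")
    if not 0.0 <= fraction_planted <= 1.0:
        raise ValueError("fraction_planted must lie in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    proteome = {
        f"P{i:04d}": _random_protein(rng, int(rng.integers(120, 200)))
        for i in range(1, n_proteins + 1)
    }
    gene_of = {pid: pid.replace("P", "G", 1) for pid in proteome}

    n_planted = round(fraction_planted * n_variants)
    planted_idx = set(range(n_planted))  # deterministic: first variants are planted

    variants: list[Variant] = []
    protein_ids = sorted(proteome)
    for i in range(n_variants):
        pid = protein_ids[i % n_proteins]
        seq = proteome[pid]
        # keep the full 55-mer window inside the protein (flank 27)
        pos = int(rng.integers(28, len(seq) - 27))
        ref = seq[pos - 1]
        alt = str(rng.choice([a for a in _AA if a != ref]))
        variants.append(
            Variant(
                protein_id=pid, gene_id=gene_of[pid], position=pos,
                ref=ref, alt=alt, variant_class=VariantClass.SNP,
            )
        )

    # expression: planted genes strongly expressed, others weak
    fpkm = {gene_of[pid]: float(rng.uniform(0.5, 5.0)) for pid in protein_ids}
    for i in planted_idx:
        fpkm[variants[i].gene_id] = float(rng.uniform(50.0, 150.0))

    cleavage: dict[str, CleavageProfile] = {}
    tap: dict[str, float] = {}
    mhc1: dict[tuple[str, str], tuple[float, float, str]] = {}
    mhc2: dict[tuple[str, str], tuple[float, float, str]] = {}
    planted_cores: dict[str, list[str]] = {"I": [], "II": []}
    pool_entries: list[str] = []

    for i, var in enumerate(variants):
        planted = i in planted_idx
        ctx = mutation_context(proteome[var.protein_id], var)
        for mhc_class, table, alleles in (
            ("I", mhc1, MHC1_ALLELES),
            ("II", mhc2, MHC2_ALLELES),
        ):
            mcp = extract_mcp(ctx, mhc_class)
            cores = [c for c in enumerate_cores(mcp) if c.contains_mutation]
            local_m = mcp.mutation_position - mcp.start + 1
            c_len = cores[0].core_length
            centre_offset = local_m - c_len // 2
            planted_core = next(
                (c for c in cores if c.offset == centre_offset), cores[0]
            )

            if mhc_class == "I":
                # per-residue cleavage over the MCP: below threshold everywhere,
                # except the planted core's C-terminal residue
                probs = rng.uniform(0.0, 0.65, size=len(mcp.sequence))
                if planted:
                    probs[planted_core.offset + c_len - 2] = rng.uniform(0.85, 0.99)
                cleavage[mcp.peptide_id] = CleavageProfile(
                    peptide_id=mcp.peptide_id,
                    probabilities=tuple(float(p) for p in probs),
                )
                for c in cores:
                    if planted and c is planted_core:
                        tap[c.mutant_core] = _log_uniform(rng, 100.0, 1000.0)
                    else:
                        tap.setdefault(c.mutant_core, _log_uniform(rng, 100.0, 5e4))

            best_allele = str(rng.choice(alleles))
            for c in cores:
                for allele in alleles:
                    if planted and c is planted_core and allele == best_allele:
                        mut_ic50 = float(rng.uniform(20.0, 80.0))
                        wt_ic50 = mut_ic50 * float(rng.uniform(15.0, 40.0))
                    else:
                        mut_ic50 = _log_uniform(rng, 1000.0, 5e4)
                        wt_ic50 = _log_uniform(rng, 1000.0, 5e4)
                    table.setdefault(
                        (c.mutant_core, allele), (mut_ic50, wt_ic50, c.wt_core)
                    )
            if planted:
                planted_cores[mhc_class].append(planted_core.mutant_core)
                pool_entries.append(planted_core.mutant_core)

    # decoy pool entries keep the recognition stage non-trivial
    for _ in range(10):
        pool_entries.append(_random_protein(rng, 9))
        pool_entries.append(_random_protein(rng, 15))

    io.write_proteome(proteome, out_dir / "proteome.fasta")
    io.write_variants(variants, out_dir / "variants.tsv")
    io.write_expression(fpkm, out_dir / "expression.tsv")
    io.write_epitope_pool(
        EpitopePool.from_sequences(pool_entries), out_dir / "epitope_pool.tsv"
    )
    io.write_cleavage(cleavage, out_dir / "cleavage_mhc1.tsv")
    io.write_tap(tap, out_dir / "tap_mhc1.tsv")
    io.write_mhc(mhc1, out_dir / "mhc1.tsv")
    io.write_mhc(mhc2, out_dir / "mhc2.tsv")

    planted_variants = [
        f"{variants[i].protein_id}:{variants[i].position}" for i in sorted(planted_idx)
    ]
    truth = {
        "seed": seed,
        "n_proteins": n_proteins,
        "n_variants": n_variants,
        "planted_variants": planted_variants,
        "planted_cores": planted_cores,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    bundle = FixtureBundle(
        out_dir=out_dir,
        seed=seed,
        planted_variants=planted_variants,
        planted_cores=planted_cores,
    )
    # ready-to-run configuration (absolute paths, so location-dependent)
    bundle.make_config().to_yaml(out_dir / "config.yaml")
    return bundle
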