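"""Run configuration: thresholds, model constants, allele sets, paths."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from neoscreen.binding import MHC1_ALLELES, MHC2_ALLELES


@dataclass
class RunConfig:
    # stage thresholds
    tpm_threshold: float = 3.0
    cleavage_threshold: float = 0.7
    affinity_cutoff_nm: float = 500.0
    # recognition model constants
    a: float = 26.0
    k: float = 1.0
    tic_epsilon: float = 1e-6
    log_base: float = 10.0
    # allele panels (mouse H2 defaults)
    mhc1_alleles: tuple[str, ...] = MHC1_ALLELES
    mhc2_alleles: tuple[str, ...] = MHC2_ALLELES
    top_k: int = 10
    seed: int = 0
    # input paths (all TSV/FASTA; see neoscreen.io for schemas)
    proteome_fasta: Optional[str] = None
    variants_tsv: Optional[str] = None
    expression_tsv: Optional[str] = None
    epitope_pool: Optional[str] = None
    cleavage_tsv: Optional[str] = None
    tap_tsv: Optional[str] = None
    mhc1_tsv: Optional[str] = None
    mhc2_tsv: Optional[str] = None
    out_dir: str = "neoscreen_out"
    flags: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["mhc1_alleles"] = list(self.mhc1_alleles)
        data["mhc2_alleles"] = list(self.mhc2_alleles)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("mhc1_alleles", "mhc2_alleles"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
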