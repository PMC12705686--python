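"""Run configuration with species presets and the printed default thresholds.

Every threshold used anywhere in the pipeline has its default recorded
here, so a config serialized to JSON documents the exact analysis
parameters; the config round-trips through JSON losslessly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ArgumentError

__all__ = ["RunConfig", "SPECIES_PRESETS", "derive_seed"]

#: per-cell-line exclusions (karyotypically abnormal chromosomes plus X)
#: and the informative-gene read threshold
SPECIES_PRESETS = {
    "human_rpe1": {"exclude_chroms": ["chr10", "chrX"], "allelic_min_total": 6},
    "human_hap1": {"exclude_chroms": ["chr1", "chr15", "chrX"], "allelic_min_total": 6},
    "mouse_cbms1": {"exclude_chroms": ["chr8", "chrX"], "allelic_min_total": 10},
}


@dataclass
class RunConfig:
    # data geometry
    bin_size: int = 40_000
    allelic_bin_size: int = 400_000
    cnv_bin_sizes: tuple[int, ...] = (50_000, 100_000, 200_000, 500_000)
    species: str = "human_rpe1"
    exclude_chroms: list[str] = field(default_factory=lambda: ["chr10", "chrX"])

    # DNA QC
    mad_g1_max: float = 0.3
    mad_mids_range: tuple[float, float] = (0.4, 0.8)
    mad_g1_contaminant_max: float = 0.39
    score_range: tuple[float, float] = (10.0, 90.0)
    manhattan_k_neighbors: int = 4

    # RT
    mid_s_window: tuple[float, float] = (40.0, 70.0)
    hmm_mean_separation: float = 0.1
    log2_pseudocount: float = 0.5

    # markers
    marker_alpha: float = 0.05
    marker_min_tpm: float = 1.0
    marker_min_frac: float = 0.2
    marker_basis_dim: int = 10
    marker_n_clusters: int = 3

    # allelic
    allelic_min_total: int = 6
    allelic_min_cell_frac: float = 0.5
    fisher_max_missing_frac: float = 0.2
    fisher_alpha: float = 0.05

    # copy/expression
    downsample_target: int = 1_000_000
    copy_max_consistency: float = 0.8
    copy_min_expr_frac: float = 0.5
    copy_alpha: float = 0.05
    copy_min_group: int = 5

    # CNV
    cnv_ploidy: int = 2
    cnv_min_seg: int = 10
    cnv_penalty: float = 4.0
    region_min_expr_frac: float = 0.5

    # QC (RNA)
    ercc_r_threshold: float = 0.8

    seed: int = 0

    @classmethod
    def for_species(cls, species: str, **overrides) -> "RunConfig":
        if species not in SPECIES_PRESETS:
            raise ArgumentError(f"unknown species preset {species!r}")
        preset = SPECIES_PRESETS[species]
        return cls(species=species, **{**preset, **overrides})

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        # JSON has no tuples; restore them
        for key in ("cnv_bin_sizes", "mad_mids_range", "score_range", "mid_s_window"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage child seed: stages are independently reproducible."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)
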