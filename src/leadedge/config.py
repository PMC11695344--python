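"""Run configuration.

A single flat structure holds every tunable constant of the pipeline:
QC thresholds for single-cell filtering, the 26-cell neighborhood window,
the 60% deconvolution-fraction rule for spot region labeling, differential
expression cutoffs, the permutation budget of the ligand-receptor test, and
the exponent of the single-sample enrichment walk.  It serializes to YAML
losslessly so a run is fully described by (config file, seed).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """All pipeline constants with their defaults.

    Attributes
    ----------
    seed
        Master seed; every stochastic operation also accepts an explicit seed.
    arcsinh_cofactor
        Cofactor of the arcsinh variance-stabilizing transform applied to raw
        marker intensities (ion-count imaging convention: 1.0).
    window_k
        Neighborhood window size: one central cell plus ``window_k - 1``
        nearest neighbors (default 26, i.e. 25 neighbors).
    region_fraction_threshold
        A spot is assigned to a region when that cell type's deconvolution
        fraction strictly exceeds this value (default 0.60).  Values <= 0.5
        are rejected because label uniqueness would no longer be guaranteed.
    de_lfc_threshold, de_padj_threshold
        Differential-expression significance rules: |log2FC| >= 0.25 and
        BH-adjusted p < 0.05.
    qc_min_genes, qc_max_mito, qc_min_cells_per_gene
        Single-cell QC: drop cells with fewer than 200 detected genes or more
        than 10% mitochondrial counts, then genes seen in fewer than 3 cells.
    n_permutations
        Label permutations of the ligand-receptor interaction test.
    ssgsea_alpha
        Rank-weight exponent of the single-sample enrichment score.
    n_signature_genes
        Number of top-importance genes kept for the prognostic signature.
    """

    seed: int = 0
    arcsinh_cofactor: float = 1.0
    window_k: int = 26
    region_fraction_threshold: float = 0.60
    de_lfc_threshold: float = 0.25
    de_padj_threshold: float = 0.05
    qc_min_genes: int = 200
    qc_max_mito: float = 0.10
    qc_min_cells_per_gene: int = 3
    n_permutations: int = 1000
    ssgsea_alpha: float = 0.25
    n_signature_genes: int = 20

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ConfigError("arcsinh_cofactor must be positive")
        if self.window_k < 2:
            raise ConfigError("window_k must be >= 2")
        if not 0.0 < self.region_fraction_threshold < 1.0:
            raise ConfigError("region_fraction_threshold must lie in (0, 1)")
        if self.region_fraction_threshold <= 0.5:
            raise ConfigError(
                "region_fraction_threshold must exceed 0.5 so that at most "
                "one cell type can pass it per spot"
            )
        if self.de_lfc_threshold < 0:
            raise ConfigError("de_lfc_threshold must be non-negative")
        if not 0.0 < self.de_padj_threshold <= 1.0:
            raise ConfigError("de_padj_threshold must lie in (0, 1]")
        if self.qc_min_genes < 0 or self.qc_min_cells_per_gene < 0:
            raise ConfigError("QC count thresholds must be non-negative")
        if not 0.0 <= self.qc_max_mito <= 1.0:
            raise ConfigError("qc_max_mito must lie in [0, 1]")
        if self.n_permutations < 100:
            raise ConfigError(
                "n_permutations must be >= 100 for usable p-value resolution"
            )
        if self.ssgsea_alpha < 0:
            raise ConfigError("ssgsea_alpha must be non-negative")
        if self.n_signature_genes < 1:
            raise ConfigError("n_signature_genes must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
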