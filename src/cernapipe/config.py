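"""Pipeline configuration: every published cut-off in one place.

The defaults are the thresholds the analysis is defined by: DEGs at
FDR < 0.05 and |log2FC| > 1; gene-set terms at P < 0.05 and fold
enrichment > 5; PPI edges at combined score >= 0.9 (highest confidence);
circRNA-miRNA predictions within the 90th percentile; ceRNA mRNA nodes at
FDR < 1%, |log2FC| > 2 and P < 0.01.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages.

    Attributes
    ----------
    deg_fdr_max : float
        BH-adjusted p-value cut-off for calling a gene differentially
        expressed.
    deg_abs_logfc_min : float
        Minimum |log2 fold change| for a DEG, in log2 units.
    enrich_p_max : float
        Enrichment p-value cut-off.
    enrich_fold_min : float
        Minimum fold enrichment ((k/n)/(K/N)) for a significant term.
    ppi_score_min : float
        Minimum combined interaction score, on the 0-1 scale.
    top_k : int
        Size of the per-metric top lists used for core-protein selection.
    percentile_min : float
        Minimum percentile score for retaining a circRNA-miRNA pair
        (inclusive).
    cerna_abs_log2fc_min : float
        |log2FC| cut-off applied to mRNA nodes of the ceRNA network.
    cerna_p_max : float
        Raw p-value cut-off applied to mRNA nodes of the ceRNA network.
    cerna_fdr_max : float
        FDR cut-off applied to mRNA nodes of the ceRNA network.
    seed : int
        Seed for every stochastic component.
    """

    deg_fdr_max: float = 0.05
    deg_abs_logfc_min: float = 1.0
    enrich_p_max: float = 0.05
    enrich_fold_min: float = 5.0
    ppi_score_min: float = 0.9
    top_k: int = 20
    percentile_min: float = 90.0
    cerna_abs_log2fc_min: float = 2.0
    cerna_p_max: float = 0.01
    cerna_fdr_max: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_fdr_max", "enrich_p_max", "ppi_score_min",
                     "cerna_p_max", "cerna_fdr_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k!r}")
        if not 0.0 <= self.percentile_min <= 100.0:
            raise ValueError(
                f"percentile_min must be in [0, 100], got {self.percentile_min!r}")
        for name in ("deg_abs_logfc_min", "cerna_abs_log2fc_min",
                     "enrich_fold_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_config(path: str | Path) -> PipelineConfig:
    """Read a ``key: value`` text config; unknown keys are rejected.

    Lines that are blank or start with ``#`` are ignored.
    """
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        caster = int if key in ("top_k", "seed") else float
        kwargs[key] = caster(value)
    return PipelineConfig(**kwargs)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    lines = [f"{k}: {v}" for k, v in config.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")
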