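"""Pipeline configuration: one structured object, round-trippable YAML.

Collects every tunable of the pipeline — error model, alignment scoring
and P-value calibration, staged assembly cutoffs, SV-calling thresholds
— plus bookkeeping values such as the genome size used for
effective-coverage accounting (3.2 Gbp when emulating human samples).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from omsv.assembler import AssemblyParams
from omsv.map_align import ScoringParams
from omsv.molecule_sim import ErrorModel
from omsv.sv_caller import TranslocationRule

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; serializes losslessly to/from YAML."""

    error_model: ErrorModel = field(default_factory=ErrorModel)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    translocation: TranslocationRule = field(
        default_factory=TranslocationRule)
    align_cutoff: float = 1e-12      # consensus-to-reference P cutoff
    outlier_p: float = 3e-3          # indel outlier P cutoff
    min_indel_size: float = 11_000.0  # bp; smallest emitted indel
    genome_size: float = 3.2e9       # bp; human-scale coverage accounting
    coverage: float = 40.0           # simulated raw coverage (fold)
    null_draws: int = 1400           # draws for the alignment null fit
    seed: int = 0

    def __post_init__(self) -> None:
        # keep the scoring model consistent across stages: the assembler
        # shares the alignment scoring and the optical resolution
        self.assembly.scoring = self.scoring
        self.assembly.resolution_limit = self.error_model.resolution_limit
        self.scoring.resolution_limit = self.error_model.resolution_limit
        if not 0 < self.align_cutoff < 1 or not 0 < self.outlier_p < 1:
            raise ValueError("P cutoffs must be in (0, 1)")
        if self.genome_size <= 0:
            raise ValueError("genome size must be positive")

    def to_yaml(self, path) -> None:
        doc = {
            "error_model": asdict(self.error_model),
            "scoring": asdict(self.scoring),
            "assembly": {f.name: getattr(self.assembly, f.name)
                         for f in fields(self.assembly)
                         if f.name != "scoring"},
            "translocation": asdict(self.translocation),
            "align_cutoff": self.align_cutoff,
            "outlier_p": self.outlier_p,
            "min_indel_size": self.min_indel_size,
            "genome_size": self.genome_size,
            "coverage": self.coverage,
            "null_draws": self.null_draws,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError("config file must contain a mapping")
        kwargs = {}
        if "error_model" in doc:
            kwargs["error_model"] = ErrorModel(**doc["error_model"])
        if "scoring" in doc:
            kwargs["scoring"] = ScoringParams(**doc["scoring"])
        if "assembly" in doc:
            kwargs["assembly"] = AssemblyParams(**doc["assembly"])
        if "translocation" in doc:
            kwargs["translocation"] = TranslocationRule(
                **doc["translocation"])
        for key in ("align_cutoff", "outlier_p", "min_indel_size",
                    "genome_size", "coverage", "null_draws", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)
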