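"""Analysis thresholds, collected in one place.

The defaults are the thresholds the analysis runs on: GRO-seq RPKM >= 0.025
marks a gene transcriptionally active and RPKM >= 0.0025 (but < 0.025)
ambiguous, both inclusive at the lower bound; promoters are TSS +/- 2 kb;
junction-peak proximity uses a 2 kb window; transcription matching treats
rates within +/-5% as similar.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .core import ValidationError


@dataclass
class AnalysisConfig:
    active_threshold: float = 0.025        # RPKM; >= is active
    ambiguous_threshold: float = 0.0025    # RPKM; >= (and < active) is ambiguous
    promoter_halfwidth: int = 2000         # bp around the TSS
    tts_halfwidth: int = 1000              # bp around the TES
    junction_window: int = 2000            # bp for junction-peak proximity
    similar_transcription_tolerance: float = 0.05   # fractional
    match_log10_cap: float = 0.5           # max |delta log10 RPKM| for a match
    bin_size: int = 500                    # peak-HMM bin width, bp
    min_bins: int = 3                      # minimum peak length in bins
    merge_gap_bins: int = 1                # background bins bridged when merging
    skew_stringency: str = "stringent"     # model used for gene classification
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ambiguous_threshold < self.active_threshold):
            raise ValidationError(
                "require 0 < ambiguous_threshold < active_threshold"
            )
        for name in ("promoter_halfwidth", "tts_halfwidth", "junction_window",
                     "bin_size", "min_bins"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.merge_gap_bins < 0:
            raise ValidationError("merge_gap_bins must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
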