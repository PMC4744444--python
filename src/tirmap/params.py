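"""Alignment parameter set shared by every pipeline stage.

All scores/penalties are non-negative magnitudes: a mismatch contributes
``-mismatch_penalty``, a gap of length k contributes
``-(gap_open + k * gap_extend)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class AlignmentParams:
    match: float = 2.0
    mismatch_penalty: float = 1.0
    gap_open: float = 3.0
    gap_extend: float = 1.0
    window_threshold: float = 0.0       # SW1 gliding-window cutoff
    max_diagonal_drift: int = 15        # EI -> MEI diagonal tolerance (nt)
    nucleus_min_run: int = 10           # consecutive matches defining a nucleus
    nucleus_max_overlap_frac: float = 0.40
    bonus: float = 500.0                # per transposon-genome border
    bonus_enabled: bool = False
    preset: str = "short"               # short | long
    # minimum reportable partial-alignment score per preset; "short" keeps
    # short genomic fragments (common with close restriction sites)
    min_pa_score_presets: dict = field(
        default_factory=lambda: {"short": 20.0, "long": 40.0}
    )
    max_candidates: int = 30            # PAs entering chain enumeration
    max_unaligned_gap: int = 20         # query nt allowed between chained PAs
    min_chain_segment: int = 20         # shortest PA allowed inside a multi-PA chain

    def __post_init__(self) -> None:
        for name in ("match", "mismatch_penalty", "gap_open", "gap_extend", "bonus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.preset not in self.min_pa_score_presets:
            raise ValueError(f"unknown preset {self.preset!r}")

    @property
    def min_pa_score(self) -> float:
        return self.min_pa_score_presets[self.preset]

    def with_(self, **kwargs) -> "AlignmentParams":
        return replace(self, **kwargs)


DEFAULT_PARAMS = AlignmentParams()
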