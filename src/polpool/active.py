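"""Pool 1: genes with significant active transcription.

A gene is kept when its strongest non-input sample either exceeds the
absolute peak threshold (default 0.500) or exceeds the input control, and —
unless disabled — at least one non-input sample carries a SICER significance
call.  Genes never analyzed by SICER count as not significant in any sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .tables_io import Condition, GenePeakRecord, NON_INPUT_CONDITIONS

__all__ = ["ActiveFilterConfig", "is_active", "build_pool1"]


@dataclass
class ActiveFilterConfig:
    min_peak: float = 0.500
    require_sicer: bool = True

    def __post_init__(self) -> None:
        if not self.min_peak > 0:
            raise ValueError("min_peak must be > 0")


def is_active(record: GenePeakRecord, config: ActiveFilterConfig | None = None) -> bool:
    """True iff the gene shows significant active transcription in >=1 sample.

    Keep-rule: (max non-input peak > min_peak OR max non-input peak > input)
    AND (if require_sicer) >=1 non-input SICER flag set.  "Above" is strict.
    """
    config = config or ActiveFilterConfig()
    top = record.max_noninput_peak()
    signal = top > config.min_peak or top > record.peak[Condition.INPUT]
    if not signal:
        return False
    if config.require_sicer:
        return any(record.sicer_significant[c] for c in NON_INPUT_CONDITIONS)
    return True


def build_pool1(
    records: Sequence[GenePeakRecord], config: ActiveFilterConfig | None = None
) -> set[str]:
    """Apply :func:`is_active` to every record; gene_ids must be unique."""
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
    return {rec.gene_id for rec in records if is_active(rec, config)}
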