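"""Fold-change decision tree assigning Pool 1 genes to dependence pools.

Pool 2 collects genes whose Pol II signal depends on PARP-14: a WT/KO ratio
above 1.4 (positive regulation) or below 0.7 (negative), with a rescue band
(1.2–1.4 resp. 0.7–0.83) admitted only when the stronger sample's average
peak exceeds 2, and the stronger sample must carry a SICER call.  Pool 2 is
split on the WT vs WT+PJ34 ratio into ART-independent (Pool 4, ratio within
0.83–1.2) and ART-dependent (Pool 3); Pool 3 splits on KO vs KO+PJ34 into
PARP-14-only ART (Pool 5, within the band) and multi-PARP ART (Pool 6).

Band endpoints: the no-change band [0.83, 1.2] is closed and takes
precedence, so a ratio of exactly 1.2 (or 0.83) is "no change"; the rescue
bands are open at those shared endpoints.  Only exact ties are affected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .active import ActiveFilterConfig, is_active
from .tables_io import Condition, GenePeakRecord

__all__ = [
    "ClassifierConfig",
    "PoolAssignment",
    "PoolSummary",
    "compute_ratio",
    "classify_parp14_dependence",
    "classify_art_dependence",
    "classify_parp14_specific_art",
    "assign_pools",
    "assignments_to_frame",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"


@dataclass
class ClassifierConfig:
    up_ratio: float = 1.4
    down_ratio: float = 0.7
    band_up: tuple[float, float] = (1.2, 1.4)
    band_down: tuple[float, float] = (0.7, 0.83)
    band_min_peak: float = 2.0
    no_change_band: tuple[float, float] = (0.83, 1.2)
    pseudocount: float = 0.01
    require_sicer_on_higher: bool = True

    def __post_init__(self) -> None:
        ok = (
            0
            < self.down_ratio
            <= self.band_down[1]
            <= self.no_change_band[0]
            < 1
            < self.no_change_band[1]
            <= self.band_up[0]
            <= self.up_ratio
        )
        if not ok or self.pseudocount <= 0:
            raise ValueError("inconsistent classifier thresholds")


@dataclass
class PoolAssignment:
    """One gene's membership across Pools 1–6 plus its regulation sign and
    the three ratios the decisions were made on."""

    gene_id: str
    in_pool1: bool = False
    in_pool2: bool = False
    in_pool3: bool = False
    in_pool4: bool = False
    in_pool5: bool = False
    in_pool6: bool = False
    regulation_sign: str = NONE
    wt_ko_ratio: float = float("nan")
    wt_wtpj_ratio: float = float("nan")
    ko_kopj_ratio: float = float("nan")

    def check_invariants(self) -> None:
        assert not self.in_pool2 or self.in_pool1
        if self.in_pool2:
            assert self.in_pool3 != self.in_pool4
            assert self.regulation_sign in (POSITIVE, NEGATIVE)
        else:
            assert not (self.in_pool3 or self.in_pool4)
            assert self.regulation_sign == NONE
        if self.in_pool3:
            assert self.in_pool5 != self.in_pool6
        else:
            assert not (self.in_pool5 or self.in_pool6)


@dataclass
class PoolSummary:
    n_input: int
    pool1: int
    pool2: int
    pool3: int
    pool4: int
    pool5: int
    pool6: int
    positive: int
    negative: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def compute_ratio(numerator: float, denominator: float, pseudocount: float = 0.01) -> float:
    """(n + c)/(d + c) with c = pseudocount only when the denominator is 0."""
    if numerator < 0 or denominator < 0:
        raise ValueError("peak values must be non-negative")
    c = pseudocount if denominator == 0 else 0.0
    return (numerator + c) / (denominator + c)


def _in_closed(x: float, band: tuple[float, float]) -> bool:
    return band[0] <= x <= band[1]


def classify_parp14_dependence(
    record: GenePeakRecord, config: ClassifierConfig | None = None
) -> str:
    """Sign of PARP-14 dependence from the WT/KO ratio (Pool 2 membership).

    Positive above ``up_ratio`` (or in the upper rescue band with the
    stronger sample's peak above ``band_min_peak``); negative symmetric
    below; the higher-signal sample must be SICER-significant when
    ``require_sicer_on_higher`` is set, applied after the band rescue.
    """
    config = config or ClassifierConfig()
    wt, ko = record.peak[Condition.WT], record.peak[Condition.KO]
    r = compute_ratio(wt, ko, config.pseudocount)
    top = max(wt, ko)

    if _in_closed(r, config.no_change_band):
        return NONE
    if r > config.up_ratio or (
        config.band_up[0] <= r < config.band_up[1] and top > config.band_min_peak
    ):
        sign = POSITIVE
    elif r < config.down_ratio or (
        config.band_down[0] < r <= config.band_down[1] and top > config.band_min_peak
    ):
        sign = NEGATIVE
    else:
        return NONE

    if config.require_sicer_on_higher:
        higher = Condition.WT if sign == POSITIVE else Condition.KO
        if not record.sicer_significant[higher]:
            return NONE
    return sign


def classify_art_dependence(
    record: GenePeakRecord, config: ClassifierConfig | None = None
) -> str:
    """Pool 2 split: 'pool4' (ART-independent) when WT/WT+PJ34 sits in the
    no-change band, else 'pool3'."""
    config = config or ClassifierConfig()
    if classify_parp14_dependence(record, config) == NONE:
        raise ValueError(f"gene {record.gene_id!r} is not in Pool 2")
    r = compute_ratio(
        record.peak[Condition.WT], record.peak[Condition.WT_PJ34], config.pseudocount
    )
    return "pool4" if _in_closed(r, config.no_change_band) else "pool3"


def classify_parp14_specific_art(
    record: GenePeakRecord, config: ClassifierConfig | None = None
) -> str:
    """Pool 3 split: 'pool5' (PARP-14-only ART) when KO/KO+PJ34 sits in the
    no-change band, else 'pool6' (ART of other PARPs as well)."""
    config = config or ClassifierConfig()
    if classify_art_dependence(record, config) != "pool3":
        raise ValueError(f"gene {record.gene_id!r} is not in Pool 3")
    r = compute_ratio(
        record.peak[Condition.KO], record.peak[Condition.KO_PJ34], config.pseudocount
    )
    return "pool5" if _in_closed(r, config.no_change_band) else "pool6"


def assign_pools(
    records: Sequence[GenePeakRecord],
    active_config: ActiveFilterConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
) -> tuple[list[PoolAssignment], PoolSummary]:
    """Run the full decision tree over all records, deterministically.

    Returns one assignment per input record (order preserved) plus summary
    counts satisfying the partition identities |P3|+|P4|=|P2|,
    |P5|+|P6|=|P3| and #positive+#negative=|P2|.
    """
    active_config = active_config or ActiveFilterConfig()
    classifier_config = classifier_config or ClassifierConfig()
    seen: set[str] = set()
    out: list[PoolAssignment] = []
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        pc = classifier_config.pseudocount
        a = PoolAssignment(
            rec.gene_id,
            wt_ko_ratio=compute_ratio(rec.peak[Condition.WT], rec.peak[Condition.KO], pc),
            wt_wtpj_ratio=compute_ratio(
                rec.peak[Condition.WT], rec.peak[Condition.WT_PJ34], pc
            ),
            ko_kopj_ratio=compute_ratio(
                rec.peak[Condition.KO], rec.peak[Condition.KO_PJ34], pc
            ),
        )
        a.in_pool1 = is_active(rec, active_config)
        if a.in_pool1:
            sign = classify_parp14_dependence(rec, classifier_config)
            if sign != NONE:
                a.in_pool2 = True
                a.regulation_sign = sign
                branch = classify_art_dependence(rec, classifier_config)
                if branch == "pool4":
                    a.in_pool4 = True
                else:
                    a.in_pool3 = True
                    leaf = classify_parp14_specific_art(rec, classifier_config)
                    if leaf == "pool5":
                        a.in_pool5 = True
                    else:
                        a.in_pool6 = True
        a.check_invariants()
        out.append(a)

    summary = PoolSummary(
        n_input=len(out),
        pool1=sum(a.in_pool1 for a in out),
        pool2=sum(a.in_pool2 for a in out),
        pool3=sum(a.in_pool3 for a in out),
        pool4=sum(a.in_pool4 for a in out),
        pool5=sum(a.in_pool5 for a in out),
        pool6=sum(a.in_pool6 for a in out),
        positive=sum(a.regulation_sign == POSITIVE for a in out),
        negative=sum(a.regulation_sign == NEGATIVE for a in out),
    )
    return out, summary


def assignments_to_frame(assignments: Sequence[PoolAssignment]):
    """Pool report as a DataFrame (gene_id, pool flags, sign, three ratios)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assignments],
            "pool1": [int(a.in_pool1) for a in assignments],
            "pool2": [int(a.in_pool2) for a in assignments],
            "pool3": [int(a.in_pool3) for a in assignments],
            "pool4": [int(a.in_pool4) for a in assignments],
            "pool5": [int(a.in_pool5) for a in assignments],
            "pool6": [int(a.in_pool6) for a in assignments],
            "sign": [a.regulation_sign for a in assignments],
            "wt_ko_ratio": [a.wt_ko_ratio for a in assignments],
            "wt_wtpj_ratio": [a.wt_wtpj_ratio for a in assignments],
            "ko_kopj_ratio": [a.ko_kopj_ratio for a in assignments],
        }
    )
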