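"""Three-set overlap (Venn) analysis of gene lists.

Used to intersect PARP-14 regulation lists with externally supplied STAT6
regulation/binding lists; the module is generic set algebra plus an id
harmonizer for lists coming from different platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = ["VennPartition", "venn3", "harmonize_ids", "AliasCollisionError"]

REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


class AliasCollisionError(ValueError):
    """An alias table maps distinct sources onto a colliding target."""


@dataclass
class VennPartition:
    """The seven disjoint membership regions of three sets.

    Keys name exclusive regions: ``"A"`` is A-only, ``"AB"`` is (A∩B)−C,
    ``"ABC"`` the triple intersection.  Member lists are kept sorted.
    """

    region_members: dict[str, list[str]]

    @property
    def region_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def __getitem__(self, region: str) -> list[str]:
        return self.region_members[region]

    def total(self) -> int:
        return sum(self.region_counts.values())


def venn3(a: Iterable[str], b: Iterable[str], c: Iterable[str]) -> VennPartition:
    """Exact 7-region partition of A, B, C with lexicographic member order."""
    sa, sb, sc = set(a), set(b), set(c)
    members = {
        "A": sa - sb - sc,
        "B": sb - sa - sc,
        "C": sc - sa - sb,
        "AB": (sa & sb) - sc,
        "AC": (sa & sc) - sb,
        "BC": (sb & sc) - sa,
        "ABC": sa & sb & sc,
    }
    return VennPartition({k: sorted(v) for k, v in members.items()})


def harmonize_ids(
    list_a: Iterable[str],
    list_b: Iterable[str],
    mapping: Mapping[str, str] | None = None,
) -> tuple[set[str], set[str], dict[str, list[str]]]:
    """Reconcile two gene-symbol lists into a shared namespace.

    Matching is case-insensitive after optional alias substitution.  Returns
    the two canonicalized sets plus a report of ids with no counterpart in
    the other list (never silently dropped).  An alias table in which two
    distinct sources collapse onto one target raises
    :class:`AliasCollisionError`.
    """
    alias: dict[str, str] = {}
    if mapping:
        seen_targets: dict[str, str] = {}
        for src, dst in mapping.items():
            key, val = src.casefold(), dst.casefold()
            if key in alias and alias[key] != val:
                raise AliasCollisionError(f"alias {src!r} maps to both {alias[key]!r} and {val!r}")
            if val in seen_targets and seen_targets[val] != key:
                raise AliasCollisionError(
                    f"aliases {seen_targets[val]!r} and {key!r} collide on target {dst!r}"
                )
            alias[key] = val
            seen_targets[val] = key

    def canon(x: str) -> str:
        k = x.casefold()
        return alias.get(k, k)

    ca = {canon(x) for x in list_a}
    cb = {canon(x) for x in list_b}
    report = {
        "unmapped_a": sorted(ca - cb),
        "unmapped_b": sorted(cb - ca),
    }
    return ca, cb, report
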