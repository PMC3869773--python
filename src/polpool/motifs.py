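"""Motif machinery: promoter extraction, mismatch-tolerant Hamming scanning,
ZOOPS counting, and simplified exhaustive k-mer de novo discovery.

The discovery routine enumerates every k-mer present in the target
promoters, counts ZOOPS occurrences (zero-or-one per sequence) in targets
and background allowing a Hamming mismatch budget, scores each candidate
with the upper-tail hypergeometric over the target ∪ background urn, and
reports candidates passing a fold-enrichment cut (default 3.5) and a
Benjamini–Hochberg q cut, after suppressing low-complexity repeats and
near-duplicate (within-budget) neighbors of already-reported motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import hypergeom

from .enrichment import EnrichmentResult, benjamini_hochberg
from .tables_io import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "Motif",
    "MotifHit",
    "PromoterWindow",
    "LocusWindow",
    "reverse_complement",
    "hamming",
    "extract_promoters",
    "scan_sequence",
    "scan_locus",
    "zoops_count",
    "denovo_discover",
    "repeat_filter",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_BASE = "ACGT"
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def redundancy_distance(a: str, b: str, max_shift: int) -> int:
    """Mismatches between two equal-length words, minimized over small
    relative shifts; each shifted position costs one.

    Shifted variants of the same planted word (which share a long exact
    overlap) score low, unrelated words score near 0.75·k.  Used to collapse
    a discovered motif's shifted/near-duplicate satellites.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    k = len(a)
    best = k
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            ov_a, ov_b = a[s:], b[: k - s]
        else:
            ov_a, ov_b = a[: k + s], b[-s:]
        mism = sum(x != y for x, y in zip(ov_a, ov_b))
        best = min(best, mism + abs(s))
    return best


_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"illegal base {bad!r} in sequence")
    return arr


def _uniq(a: np.ndarray) -> np.ndarray:
    """Sorted unique values (sort-based; avoids numpy's hash path)."""
    if a.size == 0:
        return a
    a = np.sort(a)
    keep = np.empty(a.size, dtype=bool)
    keep[0] = True
    np.not_equal(a[1:], a[:-1], out=keep[1:])
    return a[keep]


def _uniq_counts(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique values with multiplicities."""
    if a.size == 0:
        return a, np.zeros(0, dtype=np.int64)
    a = np.sort(a)
    keep = np.empty(a.size, dtype=bool)
    keep[0] = True
    np.not_equal(a[1:], a[:-1], out=keep[1:])
    starts = np.nonzero(keep)[0]
    counts = np.diff(np.append(starts, a.size))
    return a[keep], counts


def default_mismatch_budget(length: int) -> int:
    """Budget scaling with length: 1 for 10-mers, 2 for 12-mers (len // 6)."""
    return max(0, length // 6)


@dataclass
class Motif:
    """A fixed-length DNA word (6–20 bp over ACGT) with a mismatch budget."""

    motif_id: str
    sequence: str
    max_mismatches: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not (6 <= len(self.sequence) <= 20):
            raise ValueError(f"motif {self.motif_id!r}: length must be 6-20")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"motif {self.motif_id!r}: sequence must be over ACGT")
        if self.max_mismatches is None:
            self.max_mismatches = default_mismatch_budget(len(self.sequence))
        if not 0 <= self.max_mismatches < len(self.sequence):
            raise ValueError(f"motif {self.motif_id!r}: bad mismatch budget")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifHit:
    """An occurrence: 0-based offset in the scanned sequence, strand relative
    to that sequence, and the Hamming mismatch count."""

    seq_id: str
    offset: int
    strand: str
    mismatches: int


@dataclass
class PromoterWindow:
    """Strand-aware promoter span around the TSS (defaults −1000/+100)."""

    upstream: int = 1000
    downstream: int = 100

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be >= 0")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream


@dataclass
class LocusWindow:
    """Flank added to each side of the gene body for locus scans (±10 kb)."""

    flank: int = 10_000

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


# ---------------------------------------------------------------------------
# extraction


def extract_promoters(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    window: PromoterWindow | None = None,
) -> dict[str, str]:
    """Promoter sequence per gene, in the gene's 5'→3' orientation.

    For + strand genes the genomic span is [tss−upstream, tss+downstream);
    for − strand genes [tss−downstream+1, tss+upstream+1), reverse
    complemented.  Spans are clipped at contig edges with a warning.
    """
    window = window or PromoterWindow()
    out: dict[str, str] = {}
    for m in models:
        if m.chrom not in genome:
            raise KeyError(f"chromosome {m.chrom!r} not in genome")
        contig = genome[m.chrom]
        if m.strand == "+":
            lo, hi = m.tss - window.upstream, m.tss + window.downstream
        else:
            lo, hi = m.tss - window.downstream + 1, m.tss + window.upstream + 1
        clo, chi = max(0, lo), min(len(contig), hi)
        if (clo, chi) != (lo, hi):
            logger.warning("promoter of %s clipped at contig edge", m.gene_id)
        seq = contig[clo:chi]
        out[m.gene_id] = seq if m.strand == "+" else reverse_complement(seq)
    return out


# ---------------------------------------------------------------------------
# scanning


def scan_sequence(
    seq: str, motif: Motif, both_strands: bool = True, seq_id: str = ""
) -> list[MotifHit]:
    """All offsets where the motif matches within its mismatch budget.

    N bases never match.  A − strand hit at offset o means the reverse
    complement of the motif matches seq[o:o+k].  Hits are sorted by offset,
    + before − at equal offsets.
    """
    k = len(motif)
    if len(seq) < k:
        return []
    arr = _encode(seq.upper())
    win = sliding_window_view(arr, k)
    hits: list[MotifHit] = []
    strands = [("+", motif.sequence)]
    if both_strands:
        strands.append(("-", reverse_complement(motif.sequence)))
    for strand, word in strands:
        mm = (win != _encode(word)).sum(axis=1)
        for off in np.nonzero(mm <= motif.max_mismatches)[0]:
            hits.append(MotifHit(seq_id, int(off), strand, int(mm[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_locus(
    model: GeneModel,
    genome: Mapping[str, str],
    motif: Motif,
    window: LocusWindow | None = None,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan the gene body ± flank; offsets are absolute genomic positions."""
    window = window or LocusWindow()
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} not in genome")
    contig = genome[model.chrom]
    lo = max(0, model.start - window.flank)
    hi = min(len(contig), model.end + window.flank)
    hits = scan_sequence(contig[lo:hi], motif, both_strands, seq_id=model.chrom)
    for h in hits:
        h.offset += lo
    return hits


def zoops_count(seqs: Mapping[str, str], motif: Motif, both_strands: bool = True) -> int:
    """Number of sequences with at least one hit (multiple hits count once)."""
    return sum(
        1 for sid, s in seqs.items() if scan_sequence(s, motif, both_strands, sid)
    )


# ---------------------------------------------------------------------------
# low-complexity filter


def repeat_filter(motif_sequence: str) -> bool:
    """True when a motif should be rejected as a repeat / low complexity.

    Rejects tandem repeats with unit length <= 3 covering >= 80% of the
    word, and words with mononucleotide Shannon entropy below 1.0 bits.
    """
    s = motif_sequence.upper()
    n = len(s)
    for unit in (1, 2, 3):
        if n <= unit:
            continue
        matches = sum(s[i] == s[i - unit] for i in range(unit, n))
        if matches / (n - unit) >= 0.8:
            return True
    counts = np.array([s.count(b) for b in "ACGT"], dtype=float)
    freqs = counts[counts > 0] / n
    entropy = float(-(freqs * np.log2(freqs)).sum())
    return entropy < 1.0


# ---------------------------------------------------------------------------
# de novo discovery


def _window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer codes of all N-free k-windows of an encoded sequence."""
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(arr, k).astype(np.int64)
    weights = (4 ** np.arange(k, dtype=np.int64))[::-1]
    codes = win @ weights
    return codes[(win != 4).all(axis=1)]


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code % 4])
        code //= 4
    return "".join(reversed(out))


def _expand_once(codes: np.ndarray, k: int) -> np.ndarray:
    """All codes at Hamming distance <= 1 from the inputs (with duplicates)."""
    pieces = [codes]
    for j in range(k):
        shift = 4 ** np.int64(j)
        digit = (codes // shift) % 4
        base = codes - digit * shift
        for d in range(4):
            pieces.append(base + d * shift)
    return np.concatenate(pieces)


def _neighborhood(codes: np.ndarray, k: int, max_mm: int) -> np.ndarray:
    """Unique codes within Hamming distance <= max_mm of any input code."""
    out = _uniq(codes)
    for _ in range(max_mm):
        out = _uniq(_expand_once(out, k))
    return out


def _zoops_maps(
    seqs: Sequence[str], k: int, max_mm: int, both_strands: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-collection ZOOPS tallies.

    Returns (codes, counts) over the mismatch-tolerant per-sequence hit sets
    and (exact_codes, exact_counts) over exact forward-strand k-mer presence
    (used for orientation-stable tie-breaking).
    """
    hit_sets, exact_sets = [], []
    for s in seqs:
        arr = _encode(s.upper())
        codes = _window_codes(arr, k)
        strand_codes = [codes]
        if both_strands:
            rc = 3 - arr[::-1]
            rc[arr[::-1] == 4] = 4
            strand_codes.append(_window_codes(rc, k))
        hit_sets.append(_neighborhood(np.concatenate(strand_codes), k, max_mm))
        exact_sets.append(_uniq(codes))
    all_hits = np.concatenate(hit_sets) if hit_sets else np.empty(0, dtype=np.int64)
    all_exact = np.concatenate(exact_sets) if exact_sets else np.empty(0, dtype=np.int64)
    codes, counts = _uniq_counts(all_hits)
    ecodes, ecounts = _uniq_counts(all_exact)
    return codes, counts, ecodes, ecounts


def _lookup(keys: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(codes, keys)
    idx = np.clip(idx, 0, max(0, codes.size - 1))
    found = (codes.size > 0) & (codes[idx] == keys) if codes.size else np.zeros(keys.shape, bool)
    return np.where(found, counts[idx] if counts.size else 0, 0)


def denovo_discover(
    target_seqs: Mapping[str, str],
    background_seqs: Mapping[str, str],
    k: int = 10,
    max_mm: int = 1,
    min_fold: float = 3.5,
    max_motifs: int | None = None,
    max_q: float = 0.05,
    both_strands: bool = True,
) -> list[tuple[Motif, EnrichmentResult]]:
    """Exhaustive k-mer ZOOPS discovery of motifs enriched in the targets.

    Every k-mer present in a target sequence is a candidate.  Candidates are
    scored by the upper-tail hypergeometric on ZOOPS counts (population =
    targets ∪ background) and reported when fold enrichment >= ``min_fold``
    and BH-adjusted q <= ``max_q``, ranked by p-value.  Repeats and
    candidates within the mismatch budget of an already-reported motif (or
    its reverse complement) are suppressed.
    """
    if not 8 <= k <= 14:
        raise ValueError("k must be in 8..14")
    if not target_seqs or not background_seqs:
        raise ValueError("both sequence collections must be non-empty")
    shortest = min(len(s) for s in list(target_seqs.values()) + list(background_seqs.values()))
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest sequence length {shortest}")

    tgt = list(target_seqs.values())
    bkg = list(background_seqs.values())
    n_t, n_b = len(tgt), len(bkg)

    t_codes, t_counts, te_codes, te_counts = _zoops_maps(tgt, k, max_mm, both_strands)
    b_codes, b_counts, _, _ = _zoops_maps(bkg, k, max_mm, both_strands)

    candidates = te_codes  # k-mers actually present in the targets
    if candidates.size == 0:
        return []
    k_t = _lookup(candidates, t_codes, t_counts).astype(np.int64)
    k_b = _lookup(candidates, b_codes, b_counts).astype(np.int64)
    exact_t = _lookup(candidates, te_codes, te_counts).astype(np.int64)

    N = n_t + n_b
    p = hypergeom.sf(k_t - 1, N, k_t + k_b, n_t)
    p = np.clip(p, 0.0, 1.0)
    q = np.asarray(benjamini_hochberg(p))
    with np.errstate(divide="ignore"):
        fold = np.where(
            k_b > 0, (k_t / n_t) / np.maximum(k_b, 1) * n_b, np.where(k_t > 0, np.inf, 1.0)
        )

    passing = np.nonzero((q <= max_q) & (fold >= min_fold))[0]
    order = sorted(passing, key=lambda i: (p[i], -exact_t[i], _decode(int(candidates[i]), k)))
    words = {int(i): _decode(int(candidates[i]), k) for i in order}
    slack = max_mm + 1

    reported: list[tuple[Motif, EnrichmentResult]] = []
    remaining = list(order)
    while remaining:
        seed_word = words[int(remaining[0])]
        # collapse the seed's cluster of shifted / within-budget variants and
        # represent it by the member with the strongest exact target support
        cluster = [
            i for i in remaining if redundancy_distance(seed_word, words[int(i)], slack) <= slack
        ]
        remaining = [i for i in remaining if i not in set(cluster)]
        rep = min(cluster, key=lambda i: (-exact_t[i], p[i], words[int(i)]))
        seq = words[int(rep)]
        if repeat_filter(seq):
            continue
        close = any(
            redundancy_distance(seq, m.sequence, slack) <= slack
            or redundancy_distance(seq, reverse_complement(m.sequence), slack) <= slack
            for m, _ in reported
        )
        if close:
            continue
        flag = "infinite" if k_b[rep] == 0 and k_t[rep] > 0 else "ok"
        result = EnrichmentResult(
            item_id=f"denovo_{len(reported) + 1}",
            k_target=int(k_t[rep]),
            n_target=n_t,
            k_background=int(k_b[rep]),
            n_background=n_b,
            fold=float(fold[rep]),
            p_value=float(p[rep]),
            bh_q=float(q[rep]),
            fold_flag=flag,
        )
        reported.append((Motif(result.item_id, seq, max_mm), result))
        if max_motifs is not None and len(reported) >= max_motifs:
            break
    return reported
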