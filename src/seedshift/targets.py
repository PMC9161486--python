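"""5'-shift-aware miRNA target prediction.

Target prediction for a 5'isomiR proceeds in three steps:

1. restrict to *expressed* 3'UTR sequence (union of read alignments
   intersected with the annotated UTR, merged where overlapping);
2. scan for canonical seed-match site types of the shifted seed
   (8mer > 7mer-m8 > 7mer-A1 > 6mer, in that priority);
3. score miRNA:site duplex complementarity with a local-alignment scorer
   (Watson-Crick matches rewarded, G:U wobbles weakly rewarded, seed
   positions up-weighted) as a second, independent predictor.

A transcript enters the consensus target set only if *both* predictors
fire — a seed site of at least the minimum type and a duplex score above
threshold — mirroring the intersect-two-algorithms strategy used to
suppress false positives in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .isomir import IsomirKey, SeedPolicy, normalize_rna, reverse_complement, seed_sequence

SITE_TYPES = ("6mer", "7mer_A1", "7mer_m8", "8mer")
SITE_PRIORITY = {t: i for i, t in enumerate(SITE_TYPES)}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a reference sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


def expressed_utr_regions(
    read_intervals: Iterable[GenomicInterval],
    utr_annotation: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Per annotated UTR, the merged union of read coverage within it.

    Reads are clipped to each UTR; overlapping or book-ended clipped
    intervals are merged, and each maximal merged run becomes one
    expressed region.  Non-overlapping runs in the same UTR stay separate.
    Output is sorted and independent of input order.
    """
    reads = sorted(read_intervals)
    out: list[GenomicInterval] = []
    for utr in sorted(utr_annotation):
        clipped = sorted(
            (max(r.start, utr.start), min(r.end, utr.end))
            for r in reads
            if r.seq_id == utr.seq_id and r.strand == utr.strand
            and r.start < utr.end and r.end > utr.start
        )
        cur: list[int] | None = None
        for s, e in clipped:
            if cur is not None and s <= cur[1]:  # overlap or book-ended
                cur[1] = max(cur[1], e)
            else:
                if cur is not None:
                    out.append(GenomicInterval(utr.seq_id, cur[0], cur[1], utr.strand))
                cur = [s, e]
        if cur is not None:
            out.append(GenomicInterval(utr.seq_id, cur[0], cur[1], utr.strand))
    return sorted(out)


@dataclass(frozen=True, order=True)
class SiteMatch:
    """A seed-match site on a 3'UTR, 0-based half-open mRNA coordinates."""

    utr_id: str
    start: int
    end: int
    site_type: str
    seed_pairs: int

    def __post_init__(self) -> None:
        expected = {"8mer": 8, "7mer_m8": 7, "7mer_A1": 7, "6mer": 6}
        if self.site_type not in expected:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != expected[self.site_type]:
            raise ValueError(f"{self.site_type} site must span {expected[self.site_type]} nt")
        if self.seed_pairs not in (6, 7):
            raise ValueError("seed_pairs must be 6 or 7")


def seed_site_scan(
    utr_seq: str,
    mirna_seq: str,
    offset5: int = 0,
    policy: SeedPolicy = SeedPolicy(),
    utr_id: str = "",
    upstream: str = "",
) -> list[SiteMatch]:
    """All canonical seed-match sites of the shifted miRNA in a UTR.

    Site definitions (rc = reverse complement of the seed on the mRNA):
    8mer = rc(m2..m8) followed by A; 7mer-m8 = rc(m2..m8); 7mer-A1 =
    rc(m2..m7) followed by A; 6mer = rc(m2..m7).  Every match location is
    reported exactly once with its highest-priority type, anchored on the
    6mer core (the pairing to miRNA positions 2-7).
    """
    utr = normalize_rna(utr_seq)
    seed7 = seed_sequence(mirna_seq, offset5, policy=policy, upstream=upstream)
    rc7 = reverse_complement(seed7)   # rc(m2..m8): m8-complement first
    core6 = rc7[1:]                   # rc(m2..m7)
    sites: list[SiteMatch] = []
    i = utr.find(core6)
    while i != -1:
        m8 = i > 0 and utr[i - 1] == rc7[0]
        a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if m8 and a1:
            sites.append(SiteMatch(utr_id, i - 1, i + 7, "8mer", 7))
        elif m8:
            sites.append(SiteMatch(utr_id, i - 1, i + 6, "7mer_m8", 7))
        elif a1:
            sites.append(SiteMatch(utr_id, i, i + 7, "7mer_A1", 6))
        else:
            sites.append(SiteMatch(utr_id, i, i + 6, "6mer", 6))
        i = utr.find(core6, i + 1)
    return sorted(sites)


@dataclass(frozen=True)
class DuplexParams:
    """Scoring scheme of the simplified miRNA:target duplex aligner."""

    match: float = 5.0
    gu_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_scale: float = 2.0
    score_threshold: float = 80.0

    def __post_init__(self) -> None:
        if not (self.match > self.gu_wobble > 0 > self.mismatch > self.gap_open):
            raise ValueError("require match > gu_wobble > 0 > mismatch > gap_open")


_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}


def _pair_score(a: str, b: str, params: DuplexParams) -> float:
    if (a, b) in _WC_PAIRS:
        return params.match
    if (a, b) in _GU_PAIRS:
        return params.gu_wobble
    return params.mismatch


def duplex_score(
    mirna_seq: str,
    utr_window: str,
    params: DuplexParams = DuplexParams(),
    policy: SeedPolicy = SeedPolicy(),
) -> float:
    """Best local complementarity score of a miRNA against a UTR window.

    The miRNA (5'->3') is aligned against the window read 3'->5' so that
    aligned positions correspond to antiparallel base pairs.  Affine-gap
    Smith-Waterman with pair scores from ``params``; pair scores at miRNA
    seed positions are multiplied by ``seed_scale``.  The local-alignment
    floor makes the score non-negative.
    """
    mir = normalize_rna(mirna_seq)
    window = normalize_rna(utr_window)
    if not (15 <= len(window) <= 40):
        raise ValueError(f"window length {len(window)} outside [15, 40]")
    return _local_alignment_score(mir, window[::-1], params, policy)


def _local_alignment_score(
    mir: str, target: str, params: DuplexParams, policy: SeedPolicy
) -> float:
    """Affine-gap Smith-Waterman over a miRNA and a 3'->5' target string."""
    n, m = len(mir), len(target)
    seed_lo, seed_hi = policy.seed_start - 1, policy.seed_end - 1  # 0-based inclusive
    NEG = -1e18
    # M = aligned pair; X = gap in target (miRNA base unpaired); Y = gap in miRNA
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[:, 0] = M[0, :] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _pair_score(mir[i - 1], target[j - 1], params)
            if seed_lo <= i - 1 <= seed_hi:
                s *= params.seed_scale
            prev = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = prev + s
            X[i, j] = max(M[i - 1, j] + params.gap_open, X[i - 1, j] + params.gap_extend)
            Y[i, j] = max(M[i, j - 1] + params.gap_open, Y[i, j - 1] + params.gap_extend)
            if M[i, j] > best:
                best = M[i, j]
    return float(best)


@dataclass(frozen=True)
class TargetPair:
    """A consensus miRNA-transcript prediction (both predictors fired)."""

    isomir: IsomirKey
    utr_id: str
    sites: tuple[SiteMatch, ...]
    best_duplex_score: float


def _site_window(utr: str, site: SiteMatch, window_len: int = 30) -> str | None:
    """Window of ~window_len nt centred on a site, clipped to the UTR."""
    if len(utr) < 15:
        return None
    pad = max(0, window_len - (site.end - site.start))
    start = max(0, site.start - pad // 2)
    end = min(len(utr), start + max(window_len, site.end - site.start))
    start = max(0, min(start, end - 15))
    return utr[start : min(end, start + 40)]


def consensus_targets(
    utrs: Mapping[str, str],
    isomir: IsomirKey,
    mirna_seq: str,
    params: DuplexParams = DuplexParams(),
    policy: SeedPolicy = SeedPolicy(),
    min_site_type: str = "7mer_A1",
    upstream: str = "",
) -> list[TargetPair]:
    """Intersection of the seed predictor and the duplex predictor.

    A UTR is emitted iff it carries at least one seed site of type >=
    ``min_site_type`` *and* the best duplex score over windows centred on
    those sites reaches ``params.score_threshold``.  Output is sorted by
    ``utr_id``.
    """
    if not utrs:
        return []
    if min_site_type not in SITE_PRIORITY:
        raise ValueError(f"unknown site type {min_site_type!r}")
    min_rank = SITE_PRIORITY[min_site_type]
    pairs: list[TargetPair] = []
    for utr_id in sorted(utrs):
        utr = normalize_rna(utrs[utr_id])
        sites = [
            s
            for s in seed_site_scan(
                utr, mirna_seq, isomir.offset5, policy=policy,
                utr_id=utr_id, upstream=upstream,
            )
            if SITE_PRIORITY[s.site_type] >= min_rank
        ]
        if not sites:
            continue
        mir = normalize_rna(mirna_seq)
        up = normalize_rna(upstream) if upstream else ""
        if isomir.offset5 < 0 and len(up) < -isomir.offset5:
            raise ValueError("negative offset needs upstream hairpin context")
        query = (up + mir)[len(up) + isomir.offset5 :]
        best = 0.0
        for site in sites:
            window = _site_window(utr, site)
            if window is None:
                continue
            best = max(best, duplex_score(query, window, params=params, policy=policy))
        if best >= params.score_threshold:
            pairs.append(TargetPair(isomir, utr_id, tuple(sites), best))
    return pairs


def target_overlap(sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Venn-partition counts over >= 2 target sets.

    Region labels join the names of the sets a member belongs to with
    ``'&'`` (e.g. ``'A'`` = only in A, ``'A&B'`` = in exactly A and B).
    Counts over all regions sum to the size of the union.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    members = {n: set(sets[n]) for n in names}
    universe = set().union(*members.values())
    counts: dict[str, int] = {}
    # enumerate every non-empty membership pattern so the partition is complete
    for mask in range(1, 2 ** len(names)):
        pattern = [n for i, n in enumerate(names) if mask >> i & 1]
        counts["&".join(pattern)] = 0
    for element in universe:
        pattern = [n for n in names if element in members[n]]
        counts["&".join(pattern)] += 1
    return counts
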