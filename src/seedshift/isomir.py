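"""5'isomiR classification and quantification.

Small-RNA reads are classified against a pre-miRNA hairpin by exact
substring matching.  A read assigned to a mature arm carries two offsets:

* ``offset5`` — shift of the read's 5' end relative to the canonical mature
  start (positive = trimmed / shifted downstream, negative = extended
  upstream).  The 5' offset determines the seed sequence and therefore the
  target spectrum, so it is the identity-defining coordinate.
* ``offset3`` — shift of the 3' end (within a tolerance, default +-3 nt).
  3'-end heterogeneity does not touch the seed; reads that differ only in
  ``offset3`` are aggregated into the same 5'isomiR.

IsomiR labels follow the ``name|offset`` convention, e.g. ``miR-183-5p|+2``
for the variant whose 5' end starts two bases downstream of the canonical
miR-183-5p start.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_VALID_RNA = re.compile(r"^[ACGU]+$")

#: minimal mature length left after a 5' shift — anything shorter has no
#: complete seed (positions 2-8) and cannot act as a miRNA.
MIN_MATURE_AFTER_SHIFT = 8

#: 5' offsets beyond this magnitude are biologically implausible
#: (Drosha/Dicer cleavage heterogeneity is local); they are still reported
#: but flagged in logs.
MAX_PLAUSIBLE_OFFSET5 = 5


def normalize_rna(seq: str) -> str:
    """Uppercase, map T->U and validate the RNA alphabet."""
    s = str(seq).upper().replace("T", "U")
    if not _VALID_RNA.match(s):
        bad = sorted(set(s) - set("ACGU"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedPolicy:
    """Seed definition (1-based miRNA positions) and 3'-end tolerance."""

    seed_start: int = 2
    seed_end: int = 8
    tol3: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.seed_start < self.seed_end):
            raise ValueError("require 1 <= seed_start < seed_end")
        if self.tol3 < 0:
            raise ValueError("tol3 must be >= 0")


@dataclass(frozen=True)
class MatureArm:
    """Canonical mature product, 0-based half-open on the hairpin."""

    arm_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PremirnaReference:
    """A pre-miRNA hairpin with its annotated canonical mature arm(s)."""

    premirna_id: str
    sequence: str
    mature_arms: tuple[MatureArm, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        arms = tuple(self.mature_arms)
        object.__setattr__(self, "mature_arms", arms)
        n = len(self.sequence)
        for arm in arms:
            if not (0 <= arm.start < arm.end <= n):
                raise ValueError(f"arm {arm.arm_id} out of bounds for {self.premirna_id}")
            if arm.length < 16:
                raise ValueError(f"arm {arm.arm_id} shorter than 16 nt")
        for a in arms:
            for b in arms:
                if a is not b and a.start < b.end and b.start < a.end:
                    raise ValueError("mature arms overlap")

    def arm(self, arm_id: str) -> MatureArm:
        for arm in self.mature_arms:
            if arm.arm_id == arm_id:
                return arm
        raise LookupError(f"unknown arm {arm_id!r} in {self.premirna_id}")

    def mature_sequence(self, arm_id: str) -> str:
        arm = self.arm(arm_id)
        return self.sequence[arm.start : arm.end]


@dataclass(frozen=True, order=True)
class IsomirKey:
    """Identity of a 5'isomiR: the miRNA arm plus the 5' offset."""

    mirna_id: str
    offset5: int

    @property
    def label(self) -> str:
        return format_label(self)


_LABEL_RE = re.compile(r"^(?P<name>.+)\|(?P<off>0|[+-]\d+)$")


def format_label(key: IsomirKey) -> str:
    """``IsomirKey('miR-183-5p', 2)`` -> ``'miR-183-5p|+2'`` (0 -> ``'|0'``)."""
    if key.offset5 == 0:
        return f"{key.mirna_id}|0"
    return f"{key.mirna_id}|{key.offset5:+d}"


def parse_label(label: str) -> IsomirKey:
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"malformed isomiR label: {label!r}")
    return IsomirKey(m.group("name"), int(m.group("off")))


@dataclass(frozen=True)
class ReadAssignment:
    """Result of classifying one read; ``key is None`` means unassigned."""

    key: IsomirKey | None
    offset3: int | None

    @property
    def assigned(self) -> bool:
        return self.key is not None


UNASSIGNED = ReadAssignment(None, None)


def _occurrences(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def classify_read(
    read_seq: str,
    ref: PremirnaReference,
    arm_id: str,
    policy: SeedPolicy = SeedPolicy(),
    trim_nontemplated: int = 0,
) -> ReadAssignment:
    """Assign a read to a 5'isomiR of ``arm_id`` by exact substring matching.

    The read must occur verbatim in the hairpin (3' extensions must be
    templated).  ``trim_nontemplated`` optionally allows removing up to that
    many terminal 3' bases before giving up, to tolerate non-templated
    additions; it defaults to 0 (off).  When the read occurs at multiple
    hairpin positions the occurrence with minimal ``|offset5|`` wins, ties
    going to the smaller signed offset.
    """
    seq = normalize_rna(read_seq)
    if len(seq) < 15:
        raise ValueError(f"read shorter than 15 nt ({len(seq)})")
    if trim_nontemplated < 0 or trim_nontemplated > 2:
        raise ValueError("trim_nontemplated must be in [0, 2]")
    arm = ref.arm(arm_id)
    for trim in range(trim_nontemplated + 1):
        sub = seq[: len(seq) - trim] if trim else seq
        candidates: list[tuple[int, int, int, int]] = []
        for pos in _occurrences(ref.sequence, sub):
            off5 = pos - arm.start
            off3 = (pos + len(sub)) - arm.end
            if abs(off3) > policy.tol3:
                continue
            if arm.length - off5 < MIN_MATURE_AFTER_SHIFT:
                continue
            candidates.append((abs(off5), off5, off3, pos))
        if candidates:
            _, off5, off3, _ = min(candidates)
            if abs(off5) > MAX_PLAUSIBLE_OFFSET5:
                logger.warning(
                    "implausibly large 5' offset %+d for %s read", off5, arm_id
                )
            return ReadAssignment(IsomirKey(arm_id, off5), off3)
    return UNASSIGNED


def collapse_5p(
    assignments: Iterable[tuple[ReadAssignment, int]],
    sample_id: str = "sample",
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Aggregate read counts over 3'-end variation into 5'isomiR counts.

    Reads sharing the same 5' end (and hence the same seed) are summed
    regardless of their 3' offset.  Unassigned reads are excluded from the
    matrix but tallied in the returned summary.
    """
    counts: dict[str, int] = {}
    summary = {"assigned": 0, "unassigned": 0}
    for assignment, n in assignments:
        if n < 0:
            raise ValueError("negative read count")
        if assignment.assigned:
            label = assignment.key.label
            counts[label] = counts.get(label, 0) + n
            summary["assigned"] += n
        else:
            summary["unassigned"] += n
    logger.info(
        "collapse_5p[%s]: %d reads assigned, %d unassigned",
        sample_id, summary["assigned"], summary["unassigned"],
    )
    df = pd.DataFrame({sample_id: pd.Series(counts, dtype=np.int64)})
    df = df.sort_index()
    return ExpressionMatrix(df, unit="count"), summary


def counts_matrix(per_sample: Mapping[str, ExpressionMatrix]) -> ExpressionMatrix:
    """Join per-sample count columns on the union of isomiR labels (fill 0)."""
    cols = {sid: m.data.iloc[:, 0] for sid, m in per_sample.items()}
    df = pd.DataFrame(cols).fillna(0).sort_index()
    return ExpressionMatrix(df, unit="count")


def rpm_normalize(
    counts: ExpressionMatrix,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Reads-per-million: ``count / library_size * 1e6`` per sample.

    ``library_sizes`` should be the total sequenced reads per sample
    (including unassigned ones); when omitted, the column sums of the
    matrix are used.
    """
    if counts.unit != "count":
        raise ValueError("rpm_normalize expects a count matrix")
    if library_sizes is None:
        sizes = counts.data.sum(axis=0).astype(float)
    else:
        sizes = pd.Series(library_sizes, dtype=float).reindex(counts.sample_ids)
    if sizes.isna().any():
        missing = list(sizes.index[sizes.isna()])
        raise ValueError(f"missing library size for samples {missing}")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    rpm = counts.data.astype(float).div(sizes, axis=1) * 1e6
    return ExpressionMatrix(rpm, unit="rpm")


def filter_expressed(
    matrix: ExpressionMatrix,
    threshold: float = 15.0,
    summary: str = "median",
) -> ExpressionMatrix:
    """Keep features whose per-feature summary RPM is strictly > threshold."""
    if matrix.unit != "rpm":
        raise ValueError("filter_expressed expects an RPM matrix")
    if summary == "median":
        stat = matrix.data.median(axis=1)
    elif summary == "mean":
        stat = matrix.data.mean(axis=1)
    else:
        raise ValueError("summary must be 'median' or 'mean'")
    kept = matrix.data.loc[stat > threshold]
    logger.info(
        "filter_expressed: kept %d/%d features (%s > %g RPM)",
        len(kept), matrix.shape[0], summary, threshold,
    )
    return ExpressionMatrix(kept, unit="rpm")


def seed_sequence(
    mature_seq: str,
    offset5: int,
    policy: SeedPolicy = SeedPolicy(),
    upstream: str = "",
) -> str:
    """Seed (positions ``seed_start..seed_end``) of the offset-applied miRNA.

    A negative ``offset5`` extends the 5' end upstream and therefore needs
    hairpin context via ``upstream`` (the bases immediately preceding the
    canonical mature start).
    """
    mature = normalize_rna(mature_seq)
    up = normalize_rna(upstream) if upstream else ""
    if offset5 < 0 and len(up) < -offset5:
        raise ValueError(
            f"offset5={offset5} needs {-offset5} upstream bases, got {len(up)}"
        )
    full = up + mature
    shifted = full[len(up) + offset5 :]
    if len(shifted) < policy.seed_end:
        raise ValueError(
            f"shifted sequence of length {len(shifted)} has no complete seed "
            f"(need >= {policy.seed_end})"
        )
    return shifted[policy.seed_start - 1 : policy.seed_end]
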