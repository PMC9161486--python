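"""Synthetic data generators for every pipeline input.

Each generator is seeded, bit-reproducible, and returns a machine-readable
truth table alongside its output so downstream recovery can be checked:

* error-free small-RNA read libraries over a hairpin with a specified
  (offset5, offset3) distribution;
* matched tumor/normal isomiR count matrices (negative-binomial counts
  around log-normal baselines) with planted fold changes;
* patient mRNA cohorts in which a latent activity drives a designated
  gene set and, through a Gaussian copula, a miRNA with a target Spearman
  correlation;
* proteome log-intensity matrices with a group shift concentrated in one
  protein set and missingness concentrated at low intensity
  (left-censoring);
* 3'UTR sequences with exhaustively-known planted seed sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isomir import (
    IsomirKey,
    PremirnaReference,
    SeedPolicy,
    normalize_rna,
    reverse_complement,
    seed_sequence,
)
from .matrix import ExpressionMatrix
from .stats import GroupDesign
from .targets import SITE_PRIORITY, seed_site_scan

_RNA = np.array(list("ACGU"))


@dataclass(frozen=True)
class ReadSimSpec:
    """Read library over one hairpin arm with given offset proportions."""

    premirna: PremirnaReference
    arm_id: str
    offset5_probs: Mapping[int, float]
    offset3_probs: Mapping[int, float]
    n_reads: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        for probs, name in ((self.offset5_probs, "offset5"), (self.offset3_probs, "offset3")):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative {name} probability")
        if any(abs(o3) > 3 for o3 in self.offset3_probs):
            raise ValueError("offset3 support must lie in [-3, 3]")


def _read_for_offsets(spec: ReadSimSpec, o5: int, o3: int) -> str:
    arm = spec.premirna.arm(spec.arm_id)
    start, end = arm.start + o5, arm.end + o3
    if not (0 <= start < end <= len(spec.premirna.sequence)):
        raise ValueError(f"offsets ({o5:+d},{o3:+d}) leave the hairpin")
    read = spec.premirna.sequence[start:end]
    if len(read) < 15:
        raise ValueError(f"offsets ({o5:+d},{o3:+d}) give a read shorter than 15 nt")
    return read


def simulate_reads(spec: ReadSimSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample reads i.i.d. from the offset distribution.

    Returns ``(records, truth)`` where records are (read_id, RNA sequence)
    pairs and truth holds the per-read offsets.
    """
    combos = [
        (o5, o3)
        for o5 in sorted(spec.offset5_probs)
        for o3 in sorted(spec.offset3_probs)
    ]
    seqs = {c: _read_for_offsets(spec, *c) for c in combos}
    probs = np.array(
        [spec.offset5_probs[o5] * spec.offset3_probs[o3] for o5, o3 in combos]
    )
    rng = np.random.default_rng(spec.seed)
    choice = rng.choice(len(combos), size=spec.n_reads, p=probs / probs.sum())
    records, rows = [], []
    for i, ci in enumerate(choice):
        o5, o3 = combos[ci]
        read_id = f"read{i:06d}"
        records.append((read_id, seqs[(o5, o3)]))
        rows.append((read_id, o5, o3))
    truth = pd.DataFrame(rows, columns=["read_id", "offset5", "offset3"])
    return records, truth


@dataclass(frozen=True)
class CohortSimSpec:
    """Tumor/normal count cohort with planted log2 fold changes.

    Baseline expression is log-normal over features; counts are
    negative-binomial with variance ``m + dispersion * m**2``.  Planted
    features get their tumor mean scaled by ``2**log2fc``; their baselines
    are drawn above ``min_planted_rpm`` so the planted effects live in the
    expressed stratum the downstream RPM filter keeps.
    """

    n_tumor: int = 20
    n_normal: int = 20
    n_features: int = 500
    planted: tuple[tuple[str, float], ...] = ()
    dispersion: float = 0.1
    library_size: int = 2_000_000
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.5
    min_planted_rpm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        names = self.feature_names()
        for f, _ in self.planted:
            if f not in names:
                raise ValueError(f"planted feature {f!r} outside the universe")

    def feature_names(self) -> list[str]:
        width = len(str(self.n_features - 1))
        return [f"isomiR{str(i).zfill(width)}" for i in range(self.n_features)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[ExpressionMatrix, GroupDesign, pd.DataFrame]:
    """Counts matrix + design + planted-effect truth table."""
    rng = np.random.default_rng(spec.seed)
    features = spec.feature_names()
    base_rpm = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_features)
    planted = dict(spec.planted)
    for i, f in enumerate(features):
        if f in planted:
            while base_rpm[i] < spec.min_planted_rpm:
                base_rpm[i] = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd)
    tumor_rpm = base_rpm.copy()
    for i, f in enumerate(features):
        if f in planted:
            tumor_rpm[i] = base_rpm[i] * 2.0 ** planted[f]
    scale = spec.library_size / 1e6
    tumor_ids = [f"tumor{i:03d}" for i in range(spec.n_tumor)]
    normal_ids = [f"normal{i:03d}" for i in range(spec.n_normal)]
    cols = {}
    for sid in tumor_ids:
        cols[sid] = _nb_counts(rng, tumor_rpm * scale, spec.dispersion)
    for sid in normal_ids:
        cols[sid] = _nb_counts(rng, base_rpm * scale, spec.dispersion)
    matrix = ExpressionMatrix(pd.DataFrame(cols, index=features), unit="count")
    design = GroupDesign(
        {**{s: "tumor" for s in tumor_ids}, **{s: "normal" for s in normal_ids}}
    )
    truth = pd.DataFrame(
        {
            "feature_id": features,
            "baseline_rpm": base_rpm,
            "log2fc": [planted.get(f, 0.0) for f in features],
        }
    )
    return matrix, design, truth


@dataclass(frozen=True)
class ActivitySimSpec:
    """Patient cohort where a latent activity drives a gene set and a miRNA.

    Per patient, latent activity ``A ~ N(0,1)``; each set gene is
    ``baseline + loading*A + noise``; background genes are baseline plus
    noise.  The miRNA couples to A through a Gaussian copula calibrated
    so that the population Spearman correlation equals ``mir_rho``; a
    monotone (exp) transform puts it on an expression-like scale without
    touching ranks.
    """

    n_patients: int = 300
    n_genes: int = 1000
    n_set_genes: int = 200
    loading: float = 1.0
    mir_rho: float = 0.4
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= abs(self.mir_rho) <= 1):
            raise ValueError("mir_rho must lie in [-1, 1]")
        if self.n_set_genes > self.n_genes:
            raise ValueError("set larger than the gene universe")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"gene{str(i).zfill(width)}" for i in range(self.n_genes)]

    def e2f_set(self) -> list[str]:
        return self.gene_names()[: self.n_set_genes]


def simulate_activity_cohort(
    spec: ActivitySimSpec,
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """(mRNA matrix, miRNA expression vector, latent activity truth)."""
    rng = np.random.default_rng(spec.seed)
    patients = [f"patient{i:04d}" for i in range(spec.n_patients)]
    genes = spec.gene_names()
    activity = rng.standard_normal(spec.n_patients)
    baselines = rng.normal(8.0, 2.0, spec.n_genes)
    noise = rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.n_patients))
    expr = baselines[:, None] + noise
    expr[: spec.n_set_genes] += spec.loading * activity[None, :]
    # Gaussian copula: Pearson rho on latent normals that yields the target
    # Spearman rho after any monotone marginal transform
    rho_p = 2.0 * np.sin(np.pi * spec.mir_rho / 6.0)
    eps = rng.standard_normal(spec.n_patients)
    mir_latent = rho_p * activity + np.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
    mir = pd.Series(np.exp(2.0 + 0.5 * mir_latent), index=patients, name="mirna_rpm")
    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=patients), unit="log_intensity"
    )
    truth = pd.Series(activity, index=patients, name="latent_activity")
    return matrix, mir, truth


@dataclass(frozen=True)
class ProteomeSimSpec:
    """Two-group proteome with one depleted set and left-censored missing.

    Missingness probability decreases with true intensity through a
    logistic curve anchored at the ``missing_rate`` quantile of all true
    intensities, emulating detection-limit censoring.
    """

    groups: tuple[tuple[str, int], ...] = (("control", 4), ("treated", 4))
    n_proteins: int = 1000
    n_shifted: int = 50
    shift: float = 1.0
    shifted_group: str = "treated"
    missing_rate: float = 0.15
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    sample_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shifted_group not in {g for g, _ in self.groups}:
            raise ValueError("shifted_group must be one of the groups")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_shifted > self.n_proteins:
            raise ValueError("shifted set larger than the protein universe")

    def protein_names(self) -> list[str]:
        width = len(str(self.n_proteins - 1))
        return [f"prot{str(i).zfill(width)}" for i in range(self.n_proteins)]

    def shifted_set(self) -> list[str]:
        return self.protein_names()[: self.n_shifted]


def simulate_proteome(
    spec: ProteomeSimSpec,
) -> tuple[ExpressionMatrix, GroupDesign, pd.DataFrame]:
    """(log-intensity matrix with NaN, design, per-cell truth table)."""
    rng = np.random.default_rng(spec.seed)
    proteins = spec.protein_names()
    base = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_proteins)
    sample_ids, group_of = [], {}
    for group, n in spec.groups:
        for i in range(n):
            sid = f"{group}{i:02d}"
            sample_ids.append(sid)
            group_of[sid] = group
    true = np.empty((spec.n_proteins, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        mu = base.copy()
        if group_of[sid] == spec.shifted_group:
            mu[: spec.n_shifted] -= spec.shift
        true[:, j] = mu + rng.normal(0.0, spec.sample_noise_sd, spec.n_proteins)
    if spec.missing_rate > 0:
        threshold = np.quantile(true, spec.missing_rate)
        slope = 1.5 / spec.baseline_sd
        p_missing = 1.0 / (1.0 + np.exp(slope * (true - threshold)))
        missing = rng.random(true.shape) < p_missing
    else:
        missing = np.zeros(true.shape, dtype=bool)
    observed = true.copy()
    observed[missing] = np.nan
    matrix = ExpressionMatrix(
        pd.DataFrame(observed, index=proteins, columns=sample_ids),
        unit="log_intensity",
    )
    design = GroupDesign(group_of)
    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "baseline": base,
            "shifted": [p in set(spec.shifted_set()) for p in proteins],
            "n_missing": missing.sum(axis=1),
        }
    )
    truth.attrs["true_intensities"] = pd.DataFrame(
        true, index=proteins, columns=sample_ids
    )
    truth.attrs["missing_mask"] = pd.DataFrame(
        missing, index=proteins, columns=sample_ids
    )
    return matrix, design, truth


def _site_string(
    mirna_seq: str, offset5: int, site_type: str, policy: SeedPolicy
) -> str:
    seed7 = seed_sequence(mirna_seq, offset5, policy=policy)
    rc7 = reverse_complement(seed7)
    core6 = rc7[1:]
    if site_type == "8mer":
        return rc7 + "A"
    if site_type == "7mer_m8":
        return rc7
    if site_type == "7mer_A1":
        return core6 + "A"
    if site_type == "6mer":
        return core6
    raise ValueError(f"unknown site type {site_type!r}")


def simulate_utrs(
    n_utrs: int,
    length_range: tuple[int, int],
    planted_sites: Sequence[tuple[int, IsomirKey, str]],
    mirna_seqs: Mapping[str, str],
    seed: int = 0,
    policy: SeedPolicy = SeedPolicy(),
    min_reject_type: str = "6mer",
    max_attempts: int = 10_000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random-background UTRs with exhaustively-known planted seed sites.

    Backgrounds are rejection-sampled so they carry no accidental site of
    type >= ``min_reject_type`` for any queried isomiR, then the planted
    site strings are written in at recorded positions (with guard bases so
    a planted site cannot silently upgrade to a higher type) and verified
    by re-scanning.  The returned truth table is therefore exhaustive.
    """
    lo, hi = length_range
    if lo > hi or lo < 20:
        raise ValueError("length_range must satisfy 20 <= lo <= hi")
    for utr_idx, key, site_type in planted_sites:
        if not (0 <= utr_idx < n_utrs):
            raise ValueError(f"planted UTR index {utr_idx} out of range")
        if site_type not in SITE_PRIORITY:
            raise ValueError(f"unknown site type {site_type!r}")
        if len(_site_string(mirna_seqs[key.mirna_id], key.offset5, site_type, policy)) + 4 > lo:
            raise ValueError("planted site does not fit within length_range")
    rng = np.random.default_rng(seed)
    queried = sorted(
        {(key.mirna_id, key.offset5) for _, key, _ in planted_sites}
        | {(mid, 0) for mid in mirna_seqs}
    )
    min_rank = SITE_PRIORITY[min_reject_type]
    by_utr: dict[int, list[tuple[IsomirKey, str]]] = {}
    for utr_idx, key, site_type in planted_sites:
        by_utr.setdefault(utr_idx, []).append((key, site_type))

    def has_accidental(seq: str, expected: set[tuple[str, int, int, str]]) -> bool:
        for mid, off in queried:
            for s in seed_site_scan(seq, mirna_seqs[mid], off, policy=policy):
                if SITE_PRIORITY[s.site_type] >= min_rank:
                    if (mid, off, s.start, s.site_type) not in expected:
                        return True
        return False

    utrs: dict[str, str] = {}
    rows = []
    width = len(str(max(n_utrs - 1, 1)))
    for utr_idx in range(n_utrs):
        utr_id = f"UTR{str(utr_idx).zfill(width)}"
        length = int(rng.integers(lo, hi + 1))
        plants = by_utr.get(utr_idx, [])
        for attempt in range(max_attempts):
            seq = "".join(rng.choice(_RNA, size=length))
            expected: set[tuple[str, int, int, str]] = set()
            placed = []
            ok = True
            occupied: list[tuple[int, int]] = []
            for key, site_type in plants:
                site = _site_string(mirna_seqs[key.mirna_id], key.offset5, site_type, policy)
                span = len(site) + 2  # one guard base each side
                pos = int(rng.integers(1, length - span))
                if any(pos < e and pos + span > s for s, e in occupied):
                    ok = False
                    break
                occupied.append((pos, pos + span))
                guard = {"A": "C", "C": "A", "G": "A", "U": "A"}
                rc7 = reverse_complement(
                    seed_sequence(mirna_seqs[key.mirna_id], key.offset5, policy=policy)
                )
                left = guard[rc7[0]] if site_type in ("7mer_A1", "6mer") else seq[pos - 1]
                right = "C" if site_type in ("7mer_m8", "6mer") else seq[pos + len(site)]
                seq = seq[: pos - 1] + left + site + right + seq[pos + len(site) + 1 :]
                site_start = pos if site_type in ("7mer_A1", "6mer") else pos
                placed.append((key, site_type, site_start, site_start + len(site)))
                expected.add((key.mirna_id, key.offset5, site_start, site_type))
            if not ok or has_accidental(seq, expected):
                continue
            # verify every planted site is found exactly as recorded
            verified = True
            for key, site_type, s_start, s_end in placed:
                found = seed_site_scan(seq, mirna_seqs[key.mirna_id], key.offset5, policy=policy)
                if not any(
                    f.start == s_start and f.site_type == site_type for f in found
                ):
                    verified = False
                    break
            if verified:
                break
        else:
            raise RuntimeError(
                f"could not build {utr_id} in {max_attempts} attempts; try longer UTRs"
            )
        utrs[utr_id] = seq
        for key, site_type, s_start, s_end in placed:
            rows.append((utr_id, key.label, site_type, s_start, s_end))
    truth = pd.DataFrame(
        rows, columns=["utr_id", "isomir", "site_type", "start", "end"]
    )
    return utrs, truth
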