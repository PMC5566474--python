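"""UMI extraction, duplicate-family clustering, and Bayesian consensus calling.

The error-correction contract: reads sharing exact fragment coordinates and
a UMI within one mismatch of a family representative are PCR copies of a
single source molecule; a per-position Bayesian consensus (uniform prior,
Phred-derived symmetric error likelihood) recovers the molecule's sequence.
All families are retained regardless of size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class UmiSpec:
    """UMI layout and acceptance thresholds.

    The UMI occupies the first ``umi_length`` bases of read 1, optionally
    followed by a fixed ``spacer``.  Reads whose mean UMI Phred is not
    strictly above ``min_mean_phred``, or whose spacer exceeds
    ``max_spacer_mismatches``, are rejected.  Families cluster UMIs within
    ``max_umi_mismatches`` at identical fragment coordinates.
    """

    umi_length: int = 13
    min_mean_phred: float = 20.0
    spacer: Optional[str] = None
    max_spacer_mismatches: int = 2
    max_umi_mismatches: int = 1

    def __post_init__(self) -> None:
        if self.umi_length <= 0:
            raise ValueError("umi_length must be positive")
        if self.max_umi_mismatches > self.umi_length:
            raise ValueError("mismatch limit exceeds UMI length")
        if self.spacer is not None and self.max_spacer_mismatches > len(self.spacer):
            raise ValueError("spacer mismatch limit exceeds spacer length")


@dataclass(slots=True)
class TaggedRead:
    """A read carrying fragment coordinates and a UMI — clustering input."""

    contig: str
    start: int
    end: int
    umi: str
    sequence: str
    qualities: np.ndarray
    identifier: str = ""
    truth: Optional[str] = None  # error-free sequence, when simulated


@dataclass
class UmiFamily:
    """Reads sharing exact fragment coordinates and a clustered UMI."""

    key: tuple[str, int, int, str]  # contig, start, end, representative UMI
    members: list[TaggedRead]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(slots=True)
class ConsensusRead:
    sequence: str
    qualities: np.ndarray
    family_size: int
    key: tuple[str, int, int, str] = ("", 0, 0, "")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Extraction


def extract_umi(
    read1_seq: str,
    read1_quals: np.ndarray,
    spec: UmiSpec,
) -> tuple[Optional[str], Optional[str], Optional[np.ndarray], str]:
    """Split the UMI (and spacer) off read 1.

    Returns (umi, trimmed sequence, trimmed qualities, reason); on
    rejection the first three are None and ``reason`` names the cause
    ('too_short', 'low_umi_quality', 'spacer_mismatch'); 'ok' otherwise.
    """
    read1_quals = np.asarray(read1_quals)
    prefix = spec.umi_length + (len(spec.spacer) if spec.spacer else 0)
    if len(read1_seq) <= prefix:
        return None, None, None, "too_short"
    umi = read1_seq[: spec.umi_length]
    mean_q = float(read1_quals[: spec.umi_length].mean())
    if not mean_q > spec.min_mean_phred:  # strict >
        return None, None, None, "low_umi_quality"
    if spec.spacer:
        observed = read1_seq[spec.umi_length : prefix]
        if hamming(observed, spec.spacer) > spec.max_spacer_mismatches:
            return None, None, None, "spacer_mismatch"
    return umi, read1_seq[prefix:], read1_quals[prefix:], "ok"


def tag_identifier(identifier: str, umi: str) -> str:
    """Attach the UMI to a read identifier (suffix convention)."""
    return f"{identifier}_{umi}"


# ---------------------------------------------------------------------------
# Clustering


def cluster_families(
    reads: Sequence[TaggedRead], spec: UmiSpec
) -> list[UmiFamily]:
    """Partition reads into UMI families.

    Reads first group by exact fragment coordinates; within a coordinate
    group, UMIs are greedily seeded in descending frequency (ties broken
    lexicographically) and each UMI joins the first seed within the
    Hamming mismatch limit.  Every read is assigned exactly once; all
    families are retained regardless of size.
    """
    lengths = {len(r.umi) for r in reads}
    if len(lengths) > 1:
        raise ValueError(f"mixed UMI lengths: {sorted(lengths)}")
    by_coord: dict[tuple[str, int, int], list[TaggedRead]] = {}
    for r in reads:
        by_coord.setdefault((r.contig, r.start, r.end), []).append(r)

    families: list[UmiFamily] = []
    for coord in sorted(by_coord):
        group = by_coord[coord]
        counts = Counter(r.umi for r in group)
        ordered = sorted(counts, key=lambda u: (-counts[u], u))
        seeds: list[str] = []
        assignment: dict[str, str] = {}
        for umi in ordered:
            for seed in seeds:
                if hamming(umi, seed) <= spec.max_umi_mismatches:
                    assignment[umi] = seed
                    break
            else:
                seeds.append(umi)
                assignment[umi] = umi
        members_by_seed: dict[str, list[TaggedRead]] = {s: [] for s in seeds}
        for r in group:
            members_by_seed[assignment[r.umi]].append(r)
        for seed in seeds:
            families.append(UmiFamily(key=(*coord, seed), members=members_by_seed[seed]))
    return families


# ---------------------------------------------------------------------------
# Consensus


def consensus_call(family: UmiFamily, max_quality: int = 60) -> ConsensusRead:
    """Bayesian per-position consensus over a UMI family.

    Uniform prior over {A,C,G,T}; each member base contributes likelihood
    1 - eps for its called base and eps/3 for the others, eps from the
    member's Phred.  The consensus base is the posterior argmax (ties:
    highest summed member quality, then lexicographic); its quality is
    Phred(1 - posterior_max) capped at ``max_quality``.  Members are
    harmonized to the modal length: longer members are clipped, shorter
    ones contribute nothing beyond their end.
    """
    if not family.members:
        raise ValueError("empty UMI family")
    if family.size == 1:
        r = family.members[0]
        return ConsensusRead(r.sequence, np.asarray(r.qualities).copy(), 1, family.key)

    length_counts = Counter(len(r.sequence) for r in family.members)
    target = sorted(length_counts, key=lambda L: (-length_counts[L], L))[0]

    loglik = np.zeros((target, 4))
    qual_support = np.zeros((target, 4))
    n_at = np.zeros(target, dtype=int)
    for r in family.members:
        L = min(len(r.sequence), target)
        quals = np.asarray(r.qualities)[:L].astype(float)
        eps = np.power(10.0, -quals / 10.0)
        eps = np.clip(eps, 1e-10, 0.75)
        log_hit = np.log1p(-eps)
        log_miss = np.log(eps / 3.0)
        for i in range(L):
            b = _BASE_INDEX.get(r.sequence[i])
            if b is None:  # N contributes no information
                continue
            loglik[i] += log_miss[i]
            loglik[i, b] += log_hit[i] - log_miss[i]
            qual_support[i, b] += quals[i]
            n_at[i] += 1

    seq = []
    out_q = np.zeros(target, dtype=np.int32)
    for i in range(target):
        if n_at[i] == 0:
            seq.append("N")
            out_q[i] = 0
            continue
        ll = loglik[i]
        post = np.exp(ll - ll.max())
        post /= post.sum()
        best = np.flatnonzero(post >= post.max() - 1e-12)
        if len(best) > 1:
            support = qual_support[i, best]
            best = best[np.flatnonzero(support >= support.max())]
        b = int(best[0])  # lexicographic final tie-break (bases sorted)
        seq.append(_BASES[b])
        err = max(1.0 - float(post[b]), 10.0 ** (-max_quality / 10.0))
        out_q[i] = min(int(round(-10.0 * np.log10(err))), max_quality)
    return ConsensusRead("".join(seq), out_q, family.size, family.key)


@dataclass
class CorrectionReport:
    n_reads: int = 0
    n_families: int = 0
    pre_mismatches: int = 0
    post_mismatches: int = 0
    pre_bases: int = 0
    post_bases: int = 0
    family_sizes: list[int] = field(default_factory=list)

    @property
    def pre_rate(self) -> float:
        return self.pre_mismatches / max(self.pre_bases, 1)

    @property
    def post_rate(self) -> float:
        return self.post_mismatches / max(self.post_bases, 1)


def correct_collection(
    reads: Sequence[TaggedRead], spec: UmiSpec
) -> tuple[list[ConsensusRead], CorrectionReport]:
    """Cluster reads into UMI families and emit one consensus per family.

    When members carry a ``truth`` sequence (from the simulator's ledger),
    the report accumulates mismatch counts against truth before and after
    consensus, so the error-correction gain is measured on known errors.
    """
    families = cluster_families(reads, spec)
    report = CorrectionReport(n_reads=len(reads), n_families=len(families))
    out = []
    for fam in families:
        cons = consensus_call(fam)
        out.append(cons)
        report.family_sizes.append(fam.size)
        truths = [r.truth for r in fam.members if r.truth is not None]
        if truths:
            for r in fam.members:
                if r.truth is None:
                    continue
                L = min(len(r.sequence), len(r.truth))
                report.pre_bases += L
                report.pre_mismatches += sum(
                    a != b for a, b in zip(r.sequence[:L], r.truth[:L])
                )
            t = truths[0]
            L = min(len(cons.sequence), len(t))
            report.post_bases += L
            report.post_mismatches += sum(
                a != b for a, b in zip(cons.sequence[:L], t[:L])
            )
    return out, report
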