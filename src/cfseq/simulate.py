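"""Synthetic plasma-cfDNA data generator.

Emulates the statistical structure of single-stranded cfDNA sequencing so
every downstream stage can be tested against a known ground truth:

* nucleosome-protected ~167-bp fragments on an ~180-bp spacing grid, with
  end trimming at ~10.4-bp helical-turn nick positions (endogenous DNase
  nicking in the exposed minor groove of nucleosomal DNA);
* short (35-80 nt) fragments protected by bound transcription factors;
* 5' ligation end bias applied by acceptance sampling;
* UMI-tagged paired reads with PCR duplication, uniform substitution
  errors and homopolymer-slippage indels (deletions at T-runs, insertions
  at A-runs), with a full injected-error ledger;
* bisulfite per-CpG methylation calls drawn from a known tissue mixture.

Every generator is deterministic under a fixed seed and returns a
:class:`GroundTruth` sufficient to score recovery without re-reading the
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Fragment, GenomeSequence, find_runs

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class TfSite:
    """A transcription-factor binding site emitting short protected fragments."""

    position: int  # footprint midpoint
    footprint: int  # protected length, 35-80 bp
    occupancy: float = 1.0


@dataclass
class EndBiasProfile:
    """Position-specific base preference weights at fragment termini.

    ``five_prime[p]`` maps a 1-based position from the 5' end to per-base
    weights; ``three_prime[p]`` counts 1-based positions from the 3' end.
    Unspecified positions are unbiased (weight 1 for every base).
    """

    five_prime: dict[int, dict[str, float]] = field(default_factory=dict)
    three_prime: dict[int, dict[str, float]] = field(default_factory=dict)

    def is_uniform(self) -> bool:
        return not self.five_prime and not self.three_prime

    def _weight(self, table: dict[int, dict[str, float]], seq: str) -> float:
        w = 1.0
        for pos, prefs in table.items():
            if pos - 1 < len(seq):
                w *= prefs.get(seq[pos - 1], 1.0)
        return w

    def fragment_weight(self, five_seq: str, three_seq_rev: str) -> float:
        """Acceptance weight from the 5'-end sequence and the reversed
        3'-end sequence (terminal base first)."""
        for table in (self.five_prime, self.three_prime):
            for prefs in table.values():
                if prefs and max(prefs.values()) <= 0:
                    raise ValueError("all-zero end-bias weight row")
        return self._weight(self.five_prime, five_seq) * self._weight(
            self.three_prime, three_seq_rev
        )

    def max_weight(self) -> float:
        w = 1.0
        for table in (self.five_prime, self.three_prime):
            for prefs in table.values():
                w *= max(max(prefs.values(), default=1.0), 1.0)
        return w


def _default_slippage() -> dict[int, float]:
    # per-traversal slippage probability, exponential in run length
    return {L: min(0.25, 2e-4 * math.exp(0.75 * (L - 2))) for L in range(4, 13)}


@dataclass
class SimConfig:
    """All generative parameters for a synthetic cfDNA cohort.

    Defaults encode the canonical plasma picture: chromatosome protection
    of 167 bp, ~180-bp nucleosome spacing, ~10.4-bp nick sub-periodicity,
    13-base UMIs and modest PCR duplication.
    """

    seed: int = 0
    genome_length: int = 100_000
    gc_content: float | list[tuple[int, float]] = 0.45  # scalar or (length, gc) segments
    nucleosome_spacing: int = 180
    protection_length: int = 167
    nick_periodicity: float = 10.4
    nick_sigma: float = 1.0
    linker_accessibility: float = 0.5  # P(fragment end at the protected-core edge)
    nick_decay: float = 0.75  # geometric decay of successive helical-turn nicks
    max_nick_turns: int = 12
    placement_jitter: int = 10  # nucleosome center jitter, +/- bp
    tf_sites: list[TfSite] = field(default_factory=list)
    tf_fraction: float = 0.05  # fraction of fragments from occupied TF sites
    tf_length_jitter: int = 3
    end_bias: Optional[EndBiasProfile] = None
    n_fragments: int = 100_000
    duplication_mean: float = 3.0  # mean PCR family size per molecule
    substitution_rate: float = 1e-3
    t_run_deletion: dict[int, float] = field(default_factory=_default_slippage)
    a_run_insertion: dict[int, float] = field(default_factory=_default_slippage)
    umi_length: int = 13
    read_length: int = 75

    def __post_init__(self) -> None:
        for p in (self.linker_accessibility, self.nick_decay, self.tf_fraction,
                  self.substitution_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for table in (self.t_run_deletion, self.a_run_insertion):
            if any(not 0 <= v <= 1 for v in table.values()):
                raise ValueError("slippage probabilities must lie in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


@dataclass
class GroundTruth:
    """Recovery targets emitted alongside every synthetic dataset."""

    nucleosome_centers: np.ndarray = field(default_factory=lambda: np.array([], int))
    tf_occupied: list[TfSite] = field(default_factory=list)
    fragment_source: Optional[np.ndarray] = None  # 'nuc'/'tf' per fragment
    tissue_mixture: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.tissue_mixture is not None:
            total = float(self.tissue_mixture.sum())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"tissue mixture sums to {total}, not 1")


# ---------------------------------------------------------------------------
# Genome


def make_genome(
    config: SimConfig, contig: str = "sim1"
) -> tuple[GenomeSequence, list[tuple[int, int, str]]]:
    """Random genome with a piecewise GC landscape plus its run census.

    The census lists all mononucleotide runs of length >= 4 (slippage
    opportunities for the read simulator and the error metrics).
    """
    if config.genome_length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = config.rng(stream=1)
    segments = config.gc_content
    if isinstance(segments, (int, float)):
        segments = [(config.genome_length, float(segments))]
    total = sum(length for length, _ in segments)
    if total != config.genome_length:
        raise ValueError("GC landscape segment lengths must sum to genome length")
    parts = []
    for length, gc in segments:
        if not 0.0 <= gc <= 1.0:
            raise ValueError(f"GC target {gc} outside [0, 1]")
        # per-base: choose GC vs AT, then the base within the pair
        is_gc = rng.random(length) < gc
        pick = rng.integers(0, 2, size=length)
        codes = np.where(is_gc, 1 + pick, 3 * pick)  # 0=A,1=C,2=G,3=T
        parts.append(codes)
    codes = np.concatenate(parts)
    seq = "".join(_BASES[codes])
    return GenomeSequence(contig, seq), find_runs(seq, min_length=4)


# ---------------------------------------------------------------------------
# Fragments


def _draw_end_offsets(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Offsets of fragment ends inward from the protected-core edge.

    With probability ``linker_accessibility`` the cut falls at the core
    edge (offset ~ 0); otherwise at the k-th helical-turn nick position,
    k geometric with ratio ``nick_decay``, blurred by ``nick_sigma``.
    """
    at_edge = rng.random(n) < config.linker_accessibility
    k = np.minimum(
        rng.geometric(1.0 - config.nick_decay, size=n), config.max_nick_turns
    )
    centers = np.where(at_edge, 0.0, k * config.nick_periodicity)
    offsets = np.rint(centers + rng.normal(0.0, config.nick_sigma, size=n))
    return np.maximum(offsets, 0).astype(np.int64)


def simulate_cfdna_fragments(
    config: SimConfig,
    genome: GenomeSequence,
    n_fragments: Optional[int] = None,
) -> tuple[list[Fragment], GroundTruth]:
    """Draw a cfDNA fragment population from planted nucleosomes/TF sites."""
    n = config.n_fragments if n_fragments is None else n_fragments
    G = len(genome)
    if G < 3 * config.nucleosome_spacing:
        raise ValueError("genome shorter than 3x nucleosome spacing")
    rng = config.rng(stream=2)

    half = config.protection_length // 2
    margin = half + 2 * config.placement_jitter + 20
    grid = np.arange(margin, G - margin, config.nucleosome_spacing)
    jitter = rng.integers(
        -config.placement_jitter, config.placement_jitter + 1, size=len(grid)
    )
    centers = grid + jitter

    occupied = [s for s in config.tf_sites if rng.random() < s.occupancy]
    tf_frac = config.tf_fraction if occupied else 0.0
    if len(centers) == 0 and not occupied:
        raise ValueError("no fragment sources: zero occupancy everywhere")

    from_tf = rng.random(n) < tf_frac
    n_tf = int(from_tf.sum())
    n_nuc = n - n_tf

    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    source = np.where(from_tf, "tf", "nuc")

    if n_nuc:
        which = rng.integers(0, len(centers), size=n_nuc)
        c = centers[which]
        core_start = c - half
        core_end = core_start + config.protection_length
        left = _draw_end_offsets(config, rng, n_nuc)
        right = _draw_end_offsets(config, rng, n_nuc)
        s = core_start + left
        e = core_end - right
        bad = e - s < 25  # over-trimmed molecules are not recovered
        while bad.any():
            idx = np.nonzero(bad)[0]
            left2 = _draw_end_offsets(config, rng, len(idx))
            right2 = _draw_end_offsets(config, rng, len(idx))
            s[idx] = core_start[idx] + left2
            e[idx] = core_end[idx] - right2
            bad = e - s < 25
        starts[~from_tf] = s
        ends[~from_tf] = e

    if n_tf:
        which = rng.integers(0, len(occupied), size=n_tf)
        mids = np.array([occupied[i].position for i in which])
        feet = np.array([occupied[i].footprint for i in which])
        lengths = feet + rng.integers(
            -config.tf_length_jitter, config.tf_length_jitter + 1, size=n_tf
        )
        lengths = np.clip(lengths, 35, 80)
        s = mids - lengths // 2
        starts[from_tf] = s
        ends[from_tf] = s + lengths

    starts = np.clip(starts, 0, G - 1)
    ends = np.clip(ends, starts + 1, G)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    fragments = [
        Fragment(genome.contig, int(s), int(e), str(st))
        for s, e, st in zip(starts, ends, strands)
    ]
    truth = GroundTruth(
        nucleosome_centers=centers,
        tf_occupied=occupied,
        fragment_source=source,
    )
    if config.end_bias is not None and not config.end_bias.is_uniform():
        fragments = apply_end_bias(
            fragments, genome, config.end_bias, rng=config.rng(stream=3)
        )
        truth.fragment_source = None  # resampling breaks per-fragment indexing
    return fragments, truth


def apply_end_bias(
    fragments: Sequence[Fragment],
    genome: GenomeSequence,
    profile: EndBiasProfile,
    rng: np.random.Generator,
    k: int = 4,
) -> list[Fragment]:
    """Acceptance-sample fragments by their terminal-base preference weights.

    The retained set is an ordinary fragment collection (no weights), so
    downstream pipelines need no special handling.  A uniform profile
    retains everything.
    """
    if profile.is_uniform():
        return list(fragments)
    wmax = profile.max_weight()
    out = []
    u = rng.random(len(fragments))
    for frag, ui in zip(fragments, u):
        five, three_rev = _terminal_sequences(frag, genome, k)
        w = profile.fragment_weight(five, three_rev)
        if ui * wmax < w:
            out.append(frag)
    return out


def _terminal_sequences(frag: Fragment, genome: GenomeSequence, k: int) -> tuple[str, str]:
    """(5'-end sequence, reversed 3'-end sequence) in molecule orientation."""
    from .core import reverse_complement

    head = genome.sequence[frag.start : min(frag.end, frag.start + k)]
    tail = genome.sequence[max(frag.start, frag.end - k) : frag.end]
    if frag.strand == "-":
        # molecule sequence is revcomp(genome[start:end])
        return reverse_complement(tail), reverse_complement(head)[::-1]
    return head, tail[::-1]


def random_fragments_matched(
    observed: Sequence[Fragment],
    genome: GenomeSequence,
    profile: Optional[EndBiasProfile],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[Fragment]:
    """Null fragment set: identical length multiset, positions uniform over
    the genome subject to the same end-bias acceptance rule.

    This is the resampling null for the template-reutilization chi-square
    diagnostic: it preserves fragment-length structure and ligation bias
    while destroying any molecular identity.
    """
    if not observed:
        raise ValueError("observed fragment collection is empty")
    G = len(genome)
    lengths = np.array([f.length for f in observed])
    if lengths.max() > G:
        raise ValueError("genome shorter than the longest observed fragment")
    uniform = profile is None or profile.is_uniform()
    wmax = None if uniform else profile.max_weight()
    starts = rng.integers(0, G - lengths + 1)
    out: list[Fragment] = []
    for frag, ell, s in zip(observed, lengths, starts):
        if uniform:
            out.append(Fragment(genome.contig, int(s), int(s + ell), frag.strand))
            continue
        for _ in range(max_tries):
            cand = Fragment(genome.contig, int(s), int(s + ell), frag.strand)
            five, three_rev = _terminal_sequences(cand, genome, 4)
            if rng.random() * wmax < profile.fragment_weight(five, three_rev):
                out.append(cand)
                break
            s = int(rng.integers(0, G - ell + 1))
        else:  # pragma: no cover - pathological profiles only
            out.append(Fragment(genome.contig, int(s), int(s + ell), frag.strand))
    return out


# ---------------------------------------------------------------------------
# Reads


@dataclass(slots=True)
class SimulatedRead:
    """A simulated aligned read: reference-orientation sequence + CIGAR.

    ``cigar`` is a list of (op, length) with op in {'M','I','D'}; ``start``
    is the 0-based leftmost aligned reference position.
    """

    identifier: str
    contig: str
    start: int
    sequence: str
    qualities: np.ndarray
    cigar: list[tuple[str, int]]
    molecule: int
    mate: int
    umi: str
    fragment: tuple[int, int]
    truncated: bool = False

    @property
    def aligned_end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op in "MD")


@dataclass
class ErrorLedger:
    """Exact record of injected sequencing/PCR errors for recovery tests."""

    substitutions: list[tuple[str, int]] = field(default_factory=list)  # read id, ref pos
    insertions: list[tuple[str, int, int]] = field(default_factory=list)  # id, ref pos, run len
    deletions: list[tuple[str, int, int]] = field(default_factory=list)
    aligned_bases: int = 0
    n_molecules: int = 0
    family_sizes: list[int] = field(default_factory=list)

    @property
    def substitution_rate(self) -> float:
        return len(self.substitutions) / max(self.aligned_bases, 1)


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reads(
    fragments: Sequence[Fragment],
    genome: GenomeSequence,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SimulatedRead], ErrorLedger]:
    """Paired reads per molecule with PCR duplication and injected errors.

    Each source molecule gets a random UMI shared by all its PCR
    duplicates; family size is 1 + Poisson(duplication_mean - 1).  Reads
    are emitted in reference orientation (as an aligner would report
    them): read 1 covers the fragment 5'-most ``read_length`` bases on
    the reference, read 2 the 3'-most.  Substitutions are uniform per
    base; slippage indels occur only inside mononucleotide runs
    (deletion at T-runs, insertion at A-runs) with run-length-dependent
    probability, and every injected event is ledgered.
    """
    if rng is None:
        rng = config.rng(stream=4)
    ledger = ErrorLedger(n_molecules=len(fragments))
    reads: list[SimulatedRead] = []
    runs = find_runs(genome.sequence, min_length=min(
        list(config.t_run_deletion) + list(config.a_run_insertion), default=4
    ))
    run_starts = np.array([r[0] for r in runs]) if runs else np.array([], int)

    lam = max(config.duplication_mean - 1.0, 0.0)
    for mol, frag in enumerate(fragments):
        if frag.end > len(genome):
            raise ValueError("fragment outside genome")
        umi = _random_umi(rng, config.umi_length)
        fam = 1 + int(rng.poisson(lam))
        ledger.family_sizes.append(fam)
        rl = config.read_length
        truncated = frag.length < rl
        windows = [
            (frag.start, min(frag.end, frag.start + rl), 1),
            (max(frag.start, frag.end - rl), frag.end, 2),
        ]
        for dup in range(fam):
            for wstart, wend, mate in windows:
                ident = f"mol{mol}.d{dup}/{mate}"
                read = _make_read(
                    ident, genome, wstart, wend, config, rng, runs, run_starts,
                    ledger, mol, mate, umi, (frag.start, frag.end), truncated,
                )
                reads.append(read)
    return reads, ledger


def _make_read(
    ident: str,
    genome: GenomeSequence,
    wstart: int,
    wend: int,
    config: SimConfig,
    rng: np.random.Generator,
    runs: list[tuple[int, int, str]],
    run_starts: np.ndarray,
    ledger: ErrorLedger,
    mol: int,
    mate: int,
    umi: str,
    fragment: tuple[int, int],
    truncated: bool,
) -> SimulatedRead:
    seq = list(genome.sequence[wstart:wend])
    cigar: list[tuple[str, int]] = [("M", len(seq))]

    # slippage indels at runs fully inside the read window
    events: list[tuple[int, str, int]] = []  # (ref pos, kind, run length)
    if len(run_starts):
        lo = int(np.searchsorted(run_starts, wstart))
        for rstart, rlen, base in runs[lo:]:
            if rstart + rlen > wend:
                if rstart >= wend:
                    break
                continue
            if base == "T":
                p = config.t_run_deletion.get(rlen, 0.0)
                if p and rng.random() < p:
                    events.append((rstart + rlen - 1, "D", rlen))
            elif base == "A":
                p = config.a_run_insertion.get(rlen, 0.0)
                if p and rng.random() < p:
                    events.append((rstart + rlen - 1, "I", rlen))
    if events:
        seq, cigar = _apply_indels(seq, wstart, events)
        for pos, kind, rlen in events:
            if kind == "D":
                ledger.deletions.append((ident, pos, rlen))
            else:
                ledger.insertions.append((ident, pos, rlen))

    # uniform substitutions on read bases (not inside insertions: positions
    # are tracked on the reference-aligned bases for the ledger)
    n_aligned = sum(n for op, n in cigar if op == "M")
    ledger.aligned_bases += n_aligned
    if config.substitution_rate > 0:
        ref_positions = _aligned_ref_positions(wstart, cigar)
        read_positions = _aligned_read_positions(cigar)
        hits = np.nonzero(rng.random(n_aligned) < config.substitution_rate)[0]
        for h in hits:
            i = read_positions[h]
            old = seq[i]
            # uniform over the three alternative bases
            alts = [b for b in "ACGT" if b != old] or list("ACGT")
            seq[i] = alts[rng.integers(0, len(alts))]
            ledger.substitutions.append((ident, int(ref_positions[h])))

    q = int(round(-10 * math.log10(config.substitution_rate))) if config.substitution_rate > 0 else 40
    quals = np.full(len(seq), min(q, 40), dtype=np.int32)
    return SimulatedRead(
        identifier=ident, contig=genome.contig, start=wstart,
        sequence="".join(seq), qualities=quals, cigar=cigar,
        molecule=mol, mate=mate, umi=umi, fragment=fragment, truncated=truncated,
    )


def _apply_indels(
    seq: list[str], wstart: int, events: list[tuple[int, str, int]]
) -> tuple[list[str], list[tuple[str, int]]]:
    """Apply D/I events (sorted by reference position) and build the CIGAR."""
    events = sorted(events)
    out: list[str] = []
    cigar: list[tuple[str, int]] = []
    cursor = 0  # index into the original window

    def emit(op: str, n: int) -> None:
        if n == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    for pos, kind, _rlen in events:
        i = pos - wstart
        if kind == "D":
            emit("M", i - cursor)
            out.extend(seq[cursor:i])
            emit("D", 1)
            cursor = i + 1
        else:  # insertion of one extra run base after pos
            emit("M", i + 1 - cursor)
            out.extend(seq[cursor : i + 1])
            out.append(seq[i])
            emit("I", 1)
            cursor = i + 1
    emit("M", len(seq) - cursor)
    out.extend(seq[cursor:])
    return out, cigar


def _aligned_ref_positions(start: int, cigar: list[tuple[str, int]]) -> np.ndarray:
    pos, out = start, []
    for op, n in cigar:
        if op == "M":
            out.append(np.arange(pos, pos + n))
            pos += n
        elif op == "D":
            pos += n
    return np.concatenate(out) if out else np.array([], int)


def _aligned_read_positions(cigar: list[tuple[str, int]]) -> np.ndarray:
    pos, out = 0, []
    for op, n in cigar:
        if op == "M":
            out.append(np.arange(pos, pos + n))
            pos += n
        elif op == "I":
            pos += n
    return np.concatenate(out) if out else np.array([], int)


def write_fastq_pairs(
    reads: Sequence[SimulatedRead], path_r1: str, path_r2: str
) -> None:
    """Write simulated pairs as FASTQ, prepending the UMI to read 1."""
    r1 = {r.identifier.rsplit("/", 1)[0]: r for r in reads if r.mate == 1}
    r2 = {r.identifier.rsplit("/", 1)[0]: r for r in reads if r.mate == 2}
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for key in r1:
            a, b = r1[key], r2.get(key)
            if b is None:
                continue
            useq = a.umi + a.sequence
            uq = np.concatenate((np.full(len(a.umi), 37), a.qualities))
            f1.write(f"@{key}\n{useq}\n+\n{_phred_str(uq)}\n")
            f2.write(f"@{key}\n{b.sequence}\n+\n{_phred_str(b.qualities)}\n")


def _phred_str(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


# ---------------------------------------------------------------------------
# Bisulfite methylation calls


def make_reference_matrix(
    n_regions: int,
    tissues: Sequence[str],
    rng: np.random.Generator,
    bimodality: float = 0.2,
) -> pd.DataFrame:
    """Random biomarker-panel reference methylation matrix.

    Biomarker regions are selected in practice because they discriminate
    tissues, so reference densities are strongly bimodal (tissue-specific
    regions sit near 0 or 1).  Densities are drawn Beta(b, b) with
    ``bimodality`` b < 1 pushing mass to the extremes.
    """
    vals = rng.beta(bimodality, bimodality, size=(n_regions, len(tissues)))
    index = [f"region{i + 1}" for i in range(n_regions)]
    return pd.DataFrame(vals, index=index, columns=list(tissues))


def simulate_bisulfite_calls(
    reference: pd.DataFrame,
    mixture: pd.Series,
    depth: int,
    conversion_error: float,
    rng: np.random.Generator,
    cpgs_per_region: int = 10,
    region_size: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-CpG methylation calls for a plasma sample of known tissue mixture.

    The true methylation density of biomarker region r is the mixture
    combination sum_t p_t * M[r, t]; each CpG's methylated count is
    Binomial(depth, d') where d' folds in a symmetric conversion/call
    error: d' = d (1 - e) + (1 - d) e.

    Returns (calls table, regions table, ground truth).  Calls columns:
    contig, position, methylated, total; regions columns: contig, start,
    end, region, type.
    """
    if not np.isclose(float(mixture.sum()), 1.0, atol=1e-8):
        raise ValueError("mixture must lie on the simplex")
    if ((reference.values < 0) | (reference.values > 1)).any():
        raise ValueError("reference densities must lie in [0, 1]")
    mixture = mixture.reindex(reference.columns)
    if mixture.isna().any():
        raise ValueError("mixture tissues must match reference columns")
    true_density = reference.values @ mixture.values
    e = conversion_error
    obs_density = true_density * (1 - e) + (1 - true_density) * e

    calls, regions = [], []
    for i, region in enumerate(reference.index):
        rstart = i * (region_size + 100)
        regions.append(("simMeth", rstart, rstart + region_size, region, "I"))
        if cpgs_per_region == 0:
            continue
        positions = rstart + np.linspace(
            10, region_size - 10, cpgs_per_region
        ).astype(int)
        meth = rng.binomial(depth, obs_density[i], size=cpgs_per_region)
        for pos, m in zip(positions, meth):
            calls.append(("simMeth", int(pos), int(m), depth))
    calls_df = pd.DataFrame(calls, columns=["contig", "position", "methylated", "total"])
    regions_df = pd.DataFrame(
        regions, columns=["contig", "start", "end", "region", "type"]
    )
    truth = GroundTruth(tissue_mixture=mixture)
    return calls_df, regions_df, truth
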