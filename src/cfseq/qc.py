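"""DNA-seq quality metrics: coverage uniformity, GC bias, error rates.

Covers the genomic-DNA benchmarking battery: agreement of the base-coverage
histogram with a Poisson expectation, normalized coverage versus GC content
in 100-nt sliding windows, Lorenz/Gini coverage inequality, substitution
and indel rates with mononucleotide-run masking, fragment end-composition
bias, and the template-reutilization chi-square diagnostic based on
resampled length-matched fragments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import CoverageTrack, Fragment, GenomeSequence, find_runs, reverse_complement
from .simulate import EndBiasProfile, SimulatedRead, random_fragments_matched

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Subsampling


def subsample_fragments(
    fragments: Sequence[Fragment],
    genome_size: int,
    target_coverage: float,
    seed: int,
    replicates: int = 1,
) -> list[list[Fragment]]:
    """Uniform without-replacement subsets at a target fold-coverage.

    Subset size is round(target * G / mean fragment length); each replicate
    draws an independent subset from the same seed stream.
    """
    if not fragments:
        raise ValueError("no fragments to subsample")
    mean_len = float(np.mean([f.length for f in fragments]))
    k = int(round(target_coverage * genome_size / mean_len))
    if k > len(fragments):
        raise ValueError(
            f"target coverage {target_coverage} needs {k} fragments, "
            f"only {len(fragments)} available"
        )
    rng = np.random.default_rng((seed, 17))
    out = []
    for _ in range(replicates):
        idx = rng.choice(len(fragments), size=k, replace=False)
        out.append([fragments[i] for i in np.sort(idx)])
    return out


# ---------------------------------------------------------------------------
# Coverage vs Poisson


@dataclass
class CoverageHistogram:
    """Base counts per depth value, with the Poisson-agreement statistic."""

    depths: np.ndarray
    counts: np.ndarray
    mean_depth: float
    r_squared: Optional[float] = None

    @classmethod
    def from_track(cls, track: CoverageTrack) -> "CoverageHistogram":
        counts = np.bincount(track.depth.astype(np.int64))
        depths = np.arange(len(counts))
        mean = float(track.depth.mean())
        return cls(depths, counts, mean)


def poisson_fit(hist: CoverageHistogram, min_expected: float = 1e-6) -> float:
    """R-squared between the observed per-depth base fractions and the
    Poisson mass function at the observed mean depth.

    Computed on the fraction scale over depths whose Poisson expectation
    is at least ``min_expected`` (tail truncation stabilizes SS_tot).
    """
    if hist.mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("degenerate single-depth histogram: R^2 undefined")
    lam = hist.mean_depth
    dmax = int(stats.poisson.ppf(1 - 1e-12, lam)) + 1
    depths = np.arange(max(len(hist.counts), dmax))
    observed = np.zeros(len(depths))
    observed[: len(hist.counts)] = hist.counts / hist.counts.sum()
    expected = stats.poisson.pmf(depths, lam)
    keep = expected >= min_expected
    obs, exp = observed[keep], expected[keep]
    ss_res = float(np.sum((obs - exp) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# GC bias


@dataclass
class GcBiasCurve:
    gc_percent: np.ndarray  # occupied GC bins (integer percent)
    normalized_coverage: np.ndarray  # mean normalized coverage per bin
    window_fraction: np.ndarray  # fraction of windows in each bin
    slope: float
    intercept: float
    r_squared: float
    window: int
    step: int


def _window_stats(
    depth: np.ndarray, gc_mask: np.ndarray, window: int, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (GC count, mean depth) via cumulative sums."""
    n = len(depth)
    if window > n:
        raise ValueError("window longer than contig")
    starts = np.arange(0, n - window + 1, step)
    cd = np.concatenate(([0], np.cumsum(depth)))
    cg = np.concatenate(([0], np.cumsum(gc_mask)))
    mean_depth = (cd[starts + window] - cd[starts]) / window
    gc = (cg[starts + window] - cg[starts]) / window
    return gc, mean_depth


def gc_bias(
    track: CoverageTrack,
    genome: GenomeSequence,
    window: int = 100,
    step: int = 50,
) -> GcBiasCurve:
    """Normalized coverage as a function of GC content in sliding windows.

    Normalization divides each window's mean depth by the genome-wide mean
    window depth, so 1.0 is the no-bias line.  A linear regression of
    normalized coverage on GC fraction summarizes the trend.
    """
    if len(track.depth) != len(genome):
        raise ValueError("coverage track and genome lengths differ")
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    gc_mask = (seq == ord("G")) | (seq == ord("C"))
    gc, mean_depth = _window_stats(track.depth.astype(float), gc_mask, window, step)
    overall = mean_depth.mean()
    if overall <= 0:
        raise ValueError("zero overall coverage")
    norm = mean_depth / overall
    gc_pct = np.rint(gc * 100).astype(int)
    bins = np.unique(gc_pct)
    per_bin = np.array([norm[gc_pct == b].mean() for b in bins])
    frac = np.array([(gc_pct == b).mean() for b in bins])
    fit = stats.linregress(gc, norm)
    return GcBiasCurve(
        gc_percent=bins, normalized_coverage=per_bin, window_fraction=frac,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), window=window, step=step,
    )


# ---------------------------------------------------------------------------
# Lorenz / Gini


@dataclass
class LorenzResult:
    cum_window_fraction: np.ndarray  # x: 0..1, n+1 points
    cum_coverage_fraction: np.ndarray  # y: Lorenz curve values
    gini: float


def lorenz_gini(window_depths: Iterable[float]) -> LorenzResult:
    """Lorenz curve and Gini coefficient of per-window mean depths.

    The Gini is computed two independent ways — trapezoidal area between
    the Lorenz curve and the diagonal, and the pairwise mean-absolute-
    difference identity sum_ij |x_i - x_j| / (2 n^2 mu) — which must agree
    to 1e-9; disagreement indicates numeric trouble and raises.
    """
    x = np.sort(np.asarray(list(window_depths), dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 windows")
    if (x < 0).any():
        raise ValueError("negative depths")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero depths")
    cum = np.concatenate(([0.0], np.cumsum(x) / total))
    xs = np.linspace(0.0, 1.0, n + 1)
    area = float(np.trapezoid(cum, xs))
    gini_lorenz = 1.0 - 2.0 * area
    # mean absolute difference via the sorted-rank identity (exact, O(n))
    i = np.arange(1, n + 1)
    gini_mad = float((2.0 * np.sum(i * x) / (n * total)) - (n + 1.0) / n)
    if abs(gini_lorenz - gini_mad) > 1e-9:
        raise ArithmeticError(
            f"Gini formulas disagree: {gini_lorenz} vs {gini_mad}"
        )
    return LorenzResult(xs, cum, gini_mad)


def gini_pairwise(values: Iterable[float]) -> float:
    """Brute-force pairwise-difference Gini (quadratic; oracle use)."""
    x = np.asarray(list(values), dtype=float)
    n = len(x)
    mu = x.mean()
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * mu))


# ---------------------------------------------------------------------------
# Error rates


@dataclass
class ErrorRateReport:
    substitution_rate: float
    insertion_rate: float
    deletion_rate: float
    aligned_bases: int
    mask_mode: str  # 'whole-genome' or 'excluding runs >= r'
    n_substitutions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0


def _run_mask(genome: GenomeSequence, min_run: int, flank: int = 1) -> np.ndarray:
    """Boolean mask over the genome: True inside runs >= min_run, +/- flank."""
    mask = np.zeros(len(genome), dtype=bool)
    for start, length, _base in find_runs(genome.sequence, min_length=min_run):
        mask[max(0, start - flank) : min(len(genome), start + length + flank)] = True
    return mask


def error_rates(
    reads: Sequence[SimulatedRead],
    genome: GenomeSequence,
    mask_runs_ge: Optional[int] = None,
) -> ErrorRateReport:
    """Substitution/insertion/deletion rates from aligned reads.

    Rates are events per aligned base.  With ``mask_runs_ge`` set,
    positions inside mononucleotide runs of that length or longer (plus
    one flanking base each side) are excluded from both numerator and
    denominator, and indel events anchored there are dropped.
    """
    mask = _run_mask(genome, mask_runs_ge) if mask_runs_ge else None
    aligned = 0
    subs = ins = dels = 0
    gseq = genome.sequence
    for read in reads:
        ref = read.start
        qry = 0
        for op, n in read.cigar:
            if op == "M":
                for j in range(n):
                    p = ref + j
                    if mask is not None and mask[p]:
                        continue
                    aligned += 1
                    if read.sequence[qry + j] != gseq[p]:
                        subs += 1
                ref += n
                qry += n
            elif op == "I":
                if mask is None or not mask[min(ref, len(gseq) - 1)]:
                    ins += 1
                qry += n
            elif op == "D":
                if mask is None or not mask[ref]:
                    dels += 1
                ref += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")
    if aligned == 0:
        raise ValueError("zero aligned bases")
    mode = "whole-genome" if mask_runs_ge is None else f"excluding runs >= {mask_runs_ge}"
    return ErrorRateReport(
        substitution_rate=subs / aligned,
        insertion_rate=ins / aligned,
        deletion_rate=dels / aligned,
        aligned_bases=aligned,
        mask_mode=mode,
        n_substitutions=subs, n_insertions=ins, n_deletions=dels,
    )


def indel_by_run_length(
    reads: Sequence[SimulatedRead],
    genome: GenomeSequence,
    min_run: int = 2,
) -> dict[int, float]:
    """Indel frequency per mononucleotide run length.

    frequency(L) = indel events attributed to runs of length L divided by
    aligned traversals of such runs (a traversal = a read whose aligned
    span fully covers the run).  An event is attributed to a run when its
    reference anchor lies within the run or immediately adjacent to it.
    """
    runs = find_runs(genome.sequence, min_length=min_run)
    if not runs:
        return {}
    run_starts = np.array([r[0] for r in runs])
    run_ends = np.array([r[0] + r[1] for r in runs])
    run_lengths = np.array([r[1] for r in runs])

    traversals: dict[int, int] = {}
    events: dict[int, int] = {}
    for read in reads:
        lo = int(np.searchsorted(run_ends, read.start, side="right"))
        hi = int(np.searchsorted(run_starts, read.aligned_end, side="left"))
        for ri in range(lo, hi):
            if run_starts[ri] >= read.start and run_ends[ri] <= read.aligned_end:
                L = int(run_lengths[ri])
                traversals[L] = traversals.get(L, 0) + 1
        ref = read.start
        for op, n in read.cigar:
            if op == "M":
                ref += n
            elif op in "ID":
                pos = ref
                sel = np.nonzero(
                    (run_starts - 1 <= pos) & (pos <= run_ends)
                )[0]
                if len(sel):
                    L = int(run_lengths[sel[0]])
                    events[L] = events.get(L, 0) + 1
                if op == "D":
                    ref += n
    return {
        L: events.get(L, 0) / t for L, t in sorted(traversals.items()) if t > 0
    }


# ---------------------------------------------------------------------------
# End composition


@dataclass
class EndBiasObserved:
    """Observed base-frequency matrices at fragment termini.

    Rows A,C,G,T; columns are positions 1..k from the respective end, in
    molecule orientation (strand-resolved when strand is known).
    """

    five_prime: np.ndarray  # 4 x k
    three_prime: np.ndarray  # 4 x k, column j = position j from the 3' end
    k: int
    n_fragments: int


def end_composition(
    fragments: Sequence[Fragment],
    genome: GenomeSequence,
    k: int = 10,
) -> EndBiasObserved:
    five = np.zeros((4, k))
    three = np.zeros((4, k))
    idx = {b: i for i, b in enumerate(_BASES)}
    for frag in fragments:
        seq = genome.sequence[frag.start : frag.end]
        if frag.strand == "-":
            seq = reverse_complement(seq)
        for j in range(min(k, len(seq))):
            b = idx.get(seq[j])
            if b is not None:
                five[b, j] += 1
            b2 = idx.get(seq[len(seq) - 1 - j])
            if b2 is not None:
                three[b2, j] += 1
    five_sum = five.sum(axis=0, keepdims=True)
    three_sum = three.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        five = np.where(five_sum > 0, five / five_sum, 0.0)
        three = np.where(three_sum > 0, three / three_sum, 0.0)
    return EndBiasObserved(five, three, k, len(fragments))


# ---------------------------------------------------------------------------
# Template-reutilization chi-square


@dataclass
class ResamplingTestResult:
    statistic: float
    p_value: float
    observed_duplicate_pct: float
    expected_duplicate_pct: float
    n_fragments: int
    exact_fallback: bool = False


def count_coordinate_duplicates_with_different_umi(
    fragments: Sequence[Fragment],
) -> int:
    """Fragments whose exact coordinates recur with a different UMI."""
    groups: dict[tuple[str, int, int], list[Optional[str]]] = {}
    for f in fragments:
        groups.setdefault((f.contig, f.start, f.end), []).append(f.umi)
    n = 0
    for umis in groups.values():
        if len(umis) < 2:
            continue
        for i, u in enumerate(umis):
            if any(v != u for j, v in enumerate(umis) if j != i):
                n += 1
    return n


def _count_duplicate_events(fragments: Sequence[Fragment]) -> tuple[int, int]:
    """(# coordinate positions with >= 2 distinct UMIs, # positions).

    Counting at the position level rather than the fragment level keeps
    the two-category chi-square calibrated: a coordinate collision is a
    single event, whereas fragment-level counting increments by two per
    collision and doubles the variance relative to the Poisson reference.
    """
    groups: dict[tuple[str, int, int], set] = {}
    for f in fragments:
        groups.setdefault((f.contig, f.start, f.end), set()).add(f.umi)
    events = sum(1 for umis in groups.values() if len(umis) >= 2)
    return events, len(groups)


def one_way_chi2(observed: Sequence[float], expected: Sequence[float]) -> tuple[float, float]:
    """One-way chi-square: sum (O-E)^2/E with df = len(categories) - 1."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if (e <= 0).any():
        raise ValueError("expected counts must be positive")
    stat = float(np.sum((o - e) ** 2 / e))
    return stat, float(stats.chi2.sf(stat, df=len(o) - 1))


def umi_resampling_test(
    observed: Sequence[Fragment],
    genome: GenomeSequence,
    profile: Optional[EndBiasProfile],
    seed: int,
    replicates: int = 20,
    umi_assignment: str = "permute",
) -> ResamplingTestResult:
    """One-way chi-square test for template reutilization.

    Molecules with identical fragment coordinates but different UMIs could
    be independent ligations of distinct templates of the same length
    (expected under fragmentation/ligation bias alone) or reutilization of
    one template.  The expected count comes from length-matched fragments
    resampled uniformly over the genome under the same end-bias rule, with
    UMIs reassigned ('permute': shuffle the observed UMIs; 'random':
    fresh uniform UMIs).  Statistic: sum (O-E)^2/E over the two categories
    {coordinate-duplicate with different UMI, everything else}; one-sided
    p from chi-square with 1 df.  If the expected duplicate count is
    below 5 an exact binomial fallback is used (with a warning).
    """
    if any(f.umi is None for f in observed):
        raise ValueError("observed fragments must carry UMIs")
    n = len(observed)
    rng = np.random.default_rng((seed, 23))
    obs_umis = [f.umi for f in observed]
    umi_len = len(obs_umis[0])
    null_e1, null_e2 = [], []
    for _ in range(replicates):
        null_frags = random_fragments_matched(observed, genome, profile, rng)
        if umi_assignment == "permute":
            perm = rng.permutation(n)
            umis = [obs_umis[i] for i in perm]
        elif umi_assignment == "random":
            letters = np.array(list(_BASES))
            umis = [
                "".join(letters[rng.integers(0, 4, size=umi_len)]) for _ in range(n)
            ]
        else:
            raise ValueError(f"unknown UMI assignment model {umi_assignment!r}")
        tagged = [
            Fragment(f.contig, f.start, f.end, f.strand, u)
            for f, u in zip(null_frags, umis)
        ]
        ev, npos = _count_duplicate_events(tagged)
        null_e1.append(ev)
        null_e2.append(npos - ev)
    e1 = float(np.mean(null_e1))
    e2 = float(np.mean(null_e2))
    o1, npos_obs = _count_duplicate_events(observed)
    o2 = npos_obs - o1
    obs_frag_dups = count_coordinate_duplicates_with_different_umi(observed)

    if e1 < 5:
        warnings.warn(
            "expected duplicate count < 5; using exact binomial fallback",
            stacklevel=2,
        )
        p = stats.binomtest(
            o1, npos_obs, max(e1 / (e1 + e2), 1e-12), alternative="greater"
        ).pvalue
        return ResamplingTestResult(
            float("nan"), float(p), 100 * obs_frag_dups / n,
            100 * e1 / (e1 + e2), n, True,
        )
    stat, p = one_way_chi2([o1, o2], [e1, e2])
    return ResamplingTestResult(
        stat, p, 100 * obs_frag_dups / n, 100 * e1 / (e1 + e2), n
    )
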