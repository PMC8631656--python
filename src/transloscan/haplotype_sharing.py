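"""Pairwise K81 gene distances around a focal locus, shared-block delimitation,
and a random-window permutation test of local identity.

The Kimura (1981) three-substitution-type model distinguishes transitions
(A<->G, C<->T), A<->T / G<->C transversions, and A<->C / G<->T transversions.
With observed site proportions P, Q, R in those classes the distance is

    d = -(1/4) [ ln(1 - 2P - 2Q) + ln(1 - 2P - 2R) + ln(1 - 2Q - 2R) ]

in expected substitutions per site; any non-positive log argument marks the
pair as saturated. Evidence that two strains share a recent haplotype around
the focal gene is quantified by comparing the per-gene distances of the focal
window against distances pooled from randomly placed gene windows elsewhere
in the genome (Mann-Whitney rank test plus an empirical window-mean p).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .genome_io import AnnotatedGenome, GeneFeature, OrthologMap

__all__ = [
    "K81Result",
    "k81_distance",
    "align_pair",
    "ProfileRecord",
    "DistanceProfile",
    "gene_profile",
    "SharedBlock",
    "shared_block",
    "NullSample",
    "random_window_null",
    "focal_window_distances",
    "PermutationResult",
    "window_significance",
    "mannwhitney",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# partner tables indexed by base code: transition, A<->T/G<->C, A<->C/G<->T
_TS = np.array([2, 3, 0, 1])
_TV1 = np.array([3, 2, 1, 0])
_TV2 = np.array([1, 0, 3, 2])


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3, anything else (N, gaps) to 255."""
    table = np.full(256, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class K81Result:
    distance: float  # nan when saturated
    saturated: bool
    n_sites: int
    mismatches: int
    p_transition: float
    q_transversion: float  # A<->T, G<->C
    r_transversion: float  # A<->C, G<->T


def k81_distance(seq_a: str, seq_b: str) -> K81Result:
    """K81 distance between two aligned, equal-length sequences.

    Sites where either sequence is not A/C/G/T (N or alignment gap) are
    excluded. Raises ValueError on length mismatch or zero comparable sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = _encode(seq_a)
    b = _encode(seq_b)
    ok = (a != 255) & (b != 255)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites (all N or gaps)")
    a, b = a[ok].astype(np.intp), b[ok].astype(np.intp)
    diff = a != b
    p = int((_TS[a] == b)[diff].sum())
    q = int((_TV1[a] == b)[diff].sum())
    r = int((_TV2[a] == b)[diff].sum())
    mism = int(diff.sum())
    P, Q, R = p / n, q / n, r / n
    args = (1 - 2 * P - 2 * Q, 1 - 2 * P - 2 * R, 1 - 2 * Q - 2 * R)
    if min(args) <= 0:
        return K81Result(float("nan"), True, n, mism, P, Q, R)
    d = -0.25 * sum(np.log(x) for x in args)
    return K81Result(float(d), False, n, mism, P, Q, R)


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global end-to-end alignment of an ortholog pair.

    Equal-length sequences are compared positionally (substitution-only
    divergence needs no gaps); unequal lengths go through a Needleman-Wunsch
    alignment (match +1, mismatch -1, gap open -4, gap extend -1). Gap
    columns are later excluded from site counting by :func:`k81_distance`.
    """
    if len(seq_a) == len(seq_b):
        return seq_a, seq_b
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


# -- per-gene profile ------------------------------------------------------


@dataclass
class ProfileRecord:
    ortholog_id: str
    rank: int  # 0 = focal gene; negative = left of it on strain A
    chromosome: str
    start: int  # strain A coordinates
    end: int
    present: bool  # ortholog present in both strains
    length: int = 0  # aligned comparable length
    mismatches: int = 0
    distance: float | None = None  # None when absent or saturated
    saturated: bool = False


@dataclass
class DistanceProfile:
    strain_a: str
    strain_b: str
    focal_ortholog: str
    records: list[ProfileRecord] = field(default_factory=list)

    def record_at(self, rank: int) -> ProfileRecord | None:
        for r in self.records:
            if r.rank == rank:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ortholog_id": r.ortholog_id,
                    "rank": r.rank,
                    "chromosome": r.chromosome,
                    "length": r.length,
                    "mismatches": r.mismatches,
                    "k81": r.distance,
                    "saturated": r.saturated,
                    "present": r.present,
                }
                for r in self.records
            ]
        )


def _pair_stats(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    gene_a: GeneFeature,
    gene_b: GeneFeature,
) -> K81Result:
    sa, sb = align_pair(
        genome_a.gene_sequence(gene_a), genome_b.gene_sequence(gene_b)
    )
    return k81_distance(sa, sb)


def gene_profile(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    orthologs: OrthologMap,
    focal: str,
    flank: int,
) -> DistanceProfile:
    """K81 distances of the orthologs within +/- ``flank`` ranks of the focal
    gene on strain A's focal chromosome, rank 0 being the focal gene itself.

    Ranks follow strain A gene order (negative = decreasing coordinates);
    orthologs missing from strain B are recorded as gaps (present=False).
    """
    focal_gene = genome_a.find_ortholog(focal)
    if focal_gene is None:
        raise KeyError(f"{genome_a.strain_id}: focal ortholog {focal} absent")
    on_chrom = genome_a.genes_on(focal_gene.chromosome)
    idx = on_chrom.index(focal_gene)
    profile = DistanceProfile(
        strain_a=genome_a.strain_id, strain_b=genome_b.strain_id, focal_ortholog=focal
    )
    for rank in range(-flank, flank + 1):
        j = idx + rank
        if j < 0 or j >= len(on_chrom):
            continue
        gene_a = on_chrom[j]
        rec = ProfileRecord(
            ortholog_id=gene_a.ortholog_id or gene_a.gene_id,
            rank=rank,
            chromosome=gene_a.chromosome,
            start=gene_a.start,
            end=gene_a.end,
            present=False,
        )
        gene_b = (
            genome_b.find_ortholog(gene_a.ortholog_id)
            if gene_a.ortholog_id
            else None
        )
        if gene_b is not None:
            res = _pair_stats(genome_a, genome_b, gene_a, gene_b)
            rec.present = True
            rec.length = res.n_sites
            rec.mismatches = res.mismatches
            rec.saturated = res.saturated
            rec.distance = None if res.saturated else res.distance
        profile.records.append(rec)
    return profile


# -- shared block ----------------------------------------------------------


@dataclass
class SharedBlock:
    left: int  # identical genes left of the focal gene (excluded)
    right: int
    left_boundary: str | None
    right_boundary: str | None
    span_kb: float
    chromosome: str | None = None
    interval: tuple[int, int] | None = None  # strain A coordinates


def shared_block(profile: DistanceProfile) -> SharedBlock:
    """Maximal run of zero-mismatch orthologs around rank 0.

    Identity means raw mismatch count 0, not a rounded model distance; a
    missing ortholog terminates the walk, as does the profile's flank edge.
    A non-identical focal gene yields a (0, 0) block with span 0.
    """
    focal = profile.record_at(0)
    if focal is None:
        raise ValueError("profile does not contain rank 0")
    if not focal.present or focal.mismatches != 0:
        return SharedBlock(0, 0, None, None, 0.0)
    counts = {}
    bounds = {}
    for direction in (-1, +1):
        n = 0
        boundary = focal
        while True:
            rec = profile.record_at(direction * (n + 1))
            if rec is None or not rec.present or rec.mismatches != 0:
                break
            n += 1
            boundary = rec
        counts[direction] = n
        bounds[direction] = boundary
    lo = min(bounds[-1].start, focal.start)
    hi = max(bounds[+1].end, focal.end)
    return SharedBlock(
        left=counts[-1],
        right=counts[+1],
        left_boundary=bounds[-1].ortholog_id if counts[-1] else None,
        right_boundary=bounds[+1].ortholog_id if counts[+1] else None,
        span_kb=(hi - lo + 1) / 1000.0,
        chromosome=focal.chromosome,
        interval=(lo, hi),
    )


# -- permutation null ------------------------------------------------------


@dataclass
class NullSample:
    distances: np.ndarray  # pooled per-gene distances (saturated excluded)
    window_means: np.ndarray
    n_windows: int
    window_size: int
    seed: int
    n_saturated: int = 0


def _shared_runs(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    exclusion: tuple[str, int, int] | None,
) -> list[list[GeneFeature]]:
    """Maximal runs of consecutive strain-A genes whose orthologs exist in
    strain B; a missing ortholog breaks a run, as does overlap with the
    exclusion interval."""
    b_orthologs = {g.ortholog_id for g in genome_b.genes if g.ortholog_id}
    runs: list[list[GeneFeature]] = []
    for chrom in genome_a.chromosomes:
        run: list[GeneFeature] = []
        for g in genome_a.genes_on(chrom):
            excluded = (
                exclusion is not None
                and chrom == exclusion[0]
                and g.end >= exclusion[1]
                and g.start <= exclusion[2]
            )
            if g.ortholog_id in b_orthologs and not excluded:
                run.append(g)
            else:
                if run:
                    runs.append(run)
                run = []
        if run:
            runs.append(run)
    return runs


def random_window_null(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    orthologs: OrthologMap,
    window_size: int = 20,
    n_windows: int = 1000,
    seed: int = 0,
    exclusion: tuple[str, int, int] | None = None,
) -> NullSample:
    """Null distribution from randomly placed windows of consecutive shared
    orthologs, sampled uniformly over valid start positions with replacement.

    ``exclusion`` is a (chromosome, start, end) interval on strain A (e.g.
    the focal shared block); windows never include a gene overlapping it.
    Per-ortholog distances are computed once and cached, so repeated draws of
    the same gene are free. Saturated distances are dropped from the pools
    with a count kept in the result.
    """
    runs = _shared_runs(genome_a, genome_b, exclusion)
    starts: list[tuple[int, int]] = []
    for ri, run in enumerate(runs):
        for j in range(0, len(run) - window_size + 1):
            starts.append((ri, j))
    if not starts:
        raise ValueError(
            f"no run of {window_size} consecutive shared orthologs outside "
            "the exclusion interval"
        )
    rng = np.random.default_rng(seed)
    cache: dict[str, K81Result] = {}

    def dist_of(gene_a: GeneFeature) -> K81Result:
        key = gene_a.ortholog_id or gene_a.gene_id
        if key not in cache:
            gene_b = genome_b.find_ortholog(gene_a.ortholog_id)
            cache[key] = _pair_stats(genome_a, genome_b, gene_a, gene_b)
        return cache[key]

    pooled: list[float] = []
    means: list[float] = []
    n_sat = 0
    picks = rng.integers(0, len(starts), size=n_windows)
    for pick in picks:
        ri, j = starts[pick]
        vals = []
        for gene_a in runs[ri][j : j + window_size]:
            res = dist_of(gene_a)
            if res.saturated:
                n_sat += 1
                continue
            vals.append(res.distance)
        pooled.extend(vals)
        if vals:
            means.append(float(np.mean(vals)))
    return NullSample(
        distances=np.asarray(pooled),
        window_means=np.asarray(means),
        n_windows=n_windows,
        window_size=window_size,
        seed=seed,
        n_saturated=n_sat,
    )


def focal_window_distances(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    orthologs: OrthologMap,
    focal: str,
    window_size: int = 20,
) -> list[float]:
    """Distances of the focal gene plus its window_size−1 nearest shared
    orthologs by rank (ties broken toward the left flank)."""
    profile = gene_profile(genome_a, genome_b, orthologs, focal, flank=2 * window_size)
    usable = [r for r in profile.records if r.present and not r.saturated]
    usable.sort(key=lambda r: (abs(r.rank), r.rank))
    chosen = usable[:window_size]
    if len(chosen) < window_size:
        raise ValueError("not enough shared orthologs around the focal gene")
    return [r.distance for r in chosen]


# -- significance ----------------------------------------------------------


@dataclass
class PermutationResult:
    u_statistic: float
    p_value: float  # two-sided Mann-Whitney (primary)
    empirical_p: float  # window-mean rank among null windows
    focal_mean: float
    null_mean: float
    n_focal: int
    n_null: int
    n_windows: int
    window_size: int
    seed: int | None
    method: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def mannwhitney(x, y) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both samples have n <= 8 and no ties straddle
    the groups (matching the exact null distribution); otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return float(len(x) * len(y) / 2), 1.0, "degenerate"
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    if len(x) <= 8 and len(y) <= 8 and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "asymptotic"


def window_significance(
    focal: list[float] | np.ndarray,
    null: NullSample | np.ndarray,
    window_means: np.ndarray | None = None,
    n_windows: int | None = None,
    window_size: int | None = None,
    seed: int | None = None,
) -> PermutationResult:
    """Compare the focal window's per-gene distances against the pooled null.

    Primary statistic: two-sided Mann-Whitney U of focal vs pooled null
    distances. Also reported: the empirical window-mean p-value
    (1 + #{null window means <= focal mean}) / (n_windows + 1).
    """
    focal = np.asarray(focal, dtype=float)
    if len(focal) == 0:
        raise ValueError("focal window is empty")
    if isinstance(null, NullSample):
        pooled = null.distances
        window_means = null.window_means
        n_windows = null.n_windows
        window_size = null.window_size
        seed = null.seed if seed is None else seed
    else:
        pooled = np.asarray(null, dtype=float)
    if len(pooled) == 0:
        raise ValueError("null sample is empty")
    u, p, method = mannwhitney(focal, pooled)
    focal_mean = float(focal.mean())
    if window_means is not None and len(window_means):
        k = int(np.sum(window_means <= focal_mean))
        emp = (1 + k) / (len(window_means) + 1)
    else:
        emp = float("nan")
    return PermutationResult(
        u_statistic=u,
        p_value=p,
        empirical_p=emp,
        focal_mean=focal_mean,
        null_mean=float(pooled.mean()),
        n_focal=len(focal),
        n_null=len(pooled),
        n_windows=n_windows or 0,
        window_size=window_size or len(focal),
        seed=seed,
        method=method,
    )


def write_profile(profile: DistanceProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def write_block(block: SharedBlock, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "left": block.left,
                "right": block.right,
                "left_boundary": block.left_boundary,
                "right_boundary": block.right_boundary,
                "span_kb": block.span_kb,
                "chromosome": block.chromosome,
                "interval": list(block.interval) if block.interval else None,
            },
            indent=2,
        )
    )
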