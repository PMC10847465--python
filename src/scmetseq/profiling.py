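"""Single-cell copy-number profiling from bin counts.

The per-cell path is: GC lowess normalization -> bin ratios / log2 ratios
-> MAPD noise QC -> circular binary segmentation (CBS) -> diploid
anchoring and integer copy numbers -> CNA burden.  A cell passes QC when
its MAPD is at or below the configured threshold (0.45 at 500 kb bins)
and any externally supplied QC-PCR flag is not negative.

CNA burden is the fraction of the autosomal genome covered by segments
whose anchored copy number differs from 2; a cell has "detectable CNAs"
when its burden strictly exceeds the configured threshold (0.02).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import t as _tdist
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .binning import BinGrid

logger = logging.getLogger("scmetseq")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the profiling pipeline.

    Defaults follow the study conditions: 500 kb bins, MAPD gate 0.45,
    detectable-CNA burden threshold 0.02 (strict), CBS alpha 0.0001 with
    prune 0.05.
    """

    bin_width: int = 500_000
    mapd_threshold: float = 0.45
    burden_threshold: float = 0.02
    cbs_alpha: float = 1e-4
    cbs_prune: float = 0.05
    gain_log2_cut: float = 0.25
    loss_log2_cut: float = -0.25
    lowess_span: float = 0.3
    n_permutations: int = 10_000
    seed: int = 0
    min_mapq: int = 30
    pseudocount: float = 0.5
    mapd_statistic: str = "median"  # "median" (standard) or "mean" (literal name)

    def __post_init__(self):
        for name in ("bin_width", "mapd_threshold", "cbs_alpha", "cbs_prune",
                     "lowess_span", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.burden_threshold < 1:
            raise ValueError("burden_threshold must be in (0, 1)")


@dataclass(frozen=True)
class Segment:
    """A constant-copy-number stretch of consecutive bins (inclusive ends)."""

    start_bin: int
    end_bin: int
    mean_log2: float
    copy_number: int
    state: str  # loss | neutral | gain
    length_bp: int


@dataclass
class CellCountProfile:
    cell_id: str
    raw_counts: np.ndarray
    norm_counts: np.ndarray
    ratios: np.ndarray
    log2_ratios: np.ndarray
    mapd: float
    total_reads: int
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class SegmentedProfile:
    """Per-cell segmented, diploid-anchored copy-number profile."""

    cell_id: str
    segments: list[Segment]
    cna_burden: float
    mapd: float
    qc_pass: bool
    qc_pcr_pass: bool | None
    log2_ratios: np.ndarray
    detectable: bool
    diploid_confident: bool = True
    anchor_ratio: float = 1.0
    total_reads: int = 0

    def segment_log2_per_bin(self) -> np.ndarray:
        """Per-bin vector of segment-mean log2 ratios (segment granularity)."""
        out = np.empty_like(self.log2_ratios)
        for seg in self.segments:
            out[seg.start_bin:seg.end_bin + 1] = seg.mean_log2
        return out


# ----------------------------------------------------------------------
# GC normalization and ratios
# ----------------------------------------------------------------------

def gc_normalize(
    raw_counts: np.ndarray,
    gc: np.ndarray,
    lowess_span: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove multiplicative GC bias with a lowess fit of count ~ GC.

    Each bin's count is rescaled by (global mean count / lowess-fitted
    count at its GC).  Bins with undefined GC are passed through unchanged
    and returned in the mask.

    Returns (norm_counts, masked) where ``masked`` flags bins excluded
    from the fit.
    """
    raw_counts = np.asarray(raw_counts, dtype=float)
    if np.any(raw_counts < 0):
        raise ValueError("counts must be nonnegative")
    if raw_counts.sum() == 0:
        raise ValueError("all-zero counts: cell failed sequencing")
    gc = np.asarray(gc, dtype=float)
    masked = ~np.isfinite(gc)
    usable = ~masked
    if usable.sum() < 50:
        raise ValueError("need >= 50 bins with defined GC for lowess normalization")

    x, y = gc[usable], raw_counts[usable]
    fit = _lowess(y, x, frac=lowess_span, return_sorted=True)
    mean_count = y.mean()
    fitted = np.interp(x, fit[:, 0], fit[:, 1])
    # keep the correction bounded; a near-zero fit would explode the ratio
    fitted = np.maximum(fitted, 0.05 * mean_count)

    norm = raw_counts.copy()
    norm[usable] = y * (mean_count / fitted)
    return norm, masked


def compute_ratios(
    norm_counts: np.ndarray,
    pseudocount: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-normalized bin ratios and their log2.

    Ratios divide by the sample mean bin count so they average exactly 1.
    Zero-count bins get ``log2(pseudocount / mean)`` instead of -inf.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    nonzero = np.count_nonzero(norm_counts)
    if nonzero < 10:
        raise ValueError(f"only {nonzero} nonzero bins; too few for a profile")
    mean = norm_counts.mean()
    if mean <= 0:
        raise ValueError("mean of normalized counts must be positive")
    ratios = norm_counts / mean
    floor = pseudocount / mean
    log2 = np.log2(np.maximum(ratios, floor))
    return ratios, log2


def mapd(
    log2_ratios: np.ndarray,
    chrom_bounds: Sequence[tuple[int, int]] | None = None,
    statistic: str = "median",
) -> float:
    """Adjacent-bin absolute-difference noise statistic.

    The median (default) of |log2[i+1] - log2[i]| taken within chromosomes;
    no pair spans a chromosome boundary.  ``statistic="mean"`` gives the
    literal mean form.
    """
    x = np.asarray(log2_ratios, dtype=float)
    if chrom_bounds is None:
        chrom_bounds = [(0, len(x))]
    diffs = []
    for lo, hi in chrom_bounds:
        if hi - lo >= 2:
            diffs.append(np.abs(np.diff(x[lo:hi])))
    if not diffs:
        raise ValueError("no adjacent-bin pairs (all chromosomes single-bin)")
    d = np.concatenate(diffs)
    if statistic == "median":
        return float(np.median(d))
    if statistic == "mean":
        return float(np.mean(d))
    raise ValueError(f"unknown MAPD statistic {statistic!r}")


# ----------------------------------------------------------------------
# Circular binary segmentation
# ----------------------------------------------------------------------

def _arc_stats_max(S: np.ndarray, sst: float, n: int, min_width: int):
    """Max two-sample t over all circular arcs of a segment.

    ``S`` is the cumulative sum with a leading zero (length n+1).  Returns
    (t_max, i, j) where the arc is bins [i, j) against the rest; the split
    never makes a side smaller than ``min_width``.
    """
    total = S[n]
    best = (0.0, 0, n)
    for m in range(min_width, n - min_width + 1):
        arc = S[m:n + 1] - S[: n - m + 1]
        d = arc / m - (total - arc) / (n - m)
        between = d * d * (m * (n - m) / n)
        ssw = np.maximum(sst - between, 0.0)
        denom = ssw / max(n - 2, 1) * (1.0 / m + 1.0 / (n - m))
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(denom > 0, d * d / denom, np.inf * (between > 0))
        k = int(np.argmax(t2))
        if t2[k] > best[0]:
            best = (float(t2[k]), k, k + m)
    return np.sqrt(best[0]), best[1], best[2]


def _perm_max_stats(X: np.ndarray, min_width: int) -> np.ndarray:
    """Max circular-arc t statistic for each row of a permutation batch."""
    B, n = X.shape
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(X, axis=1)], axis=1)
    total = S[:, -1:]
    sst = np.sum((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1, keepdims=True)
    best = np.zeros(B)
    for m in range(min_width, n - min_width + 1):
        arc = S[:, m:n + 1] - S[:, : n - m + 1]
        d = arc / m - (total - arc) / (n - m)
        between = d * d * (m * (n - m) / n)
        ssw = np.maximum(sst - between, 0.0)
        denom = ssw / max(n - 2, 1) * (1.0 / m + 1.0 / (n - m))
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(denom > 0, d * d / denom,
                          np.where(between > 0, np.inf, 0.0))
        best = np.maximum(best, t2.max(axis=1))
    return np.sqrt(best)


def _perm_test(x, t_obs, n_perm, alpha, rng, min_width):
    """Curtailed permutation p-value for the max arc statistic.

    Uses the add-one estimator (k+1)/(B+1); stops early as soon as the
    estimate can no longer fall at or below alpha (first exceedance, for
    alpha * n_perm ~ 1) or finishes all draws.  Permutations are drawn in
    vectorized batches.
    """
    k = 0
    done = 0
    batch = 64
    while done < n_perm:
        b = min(batch, n_perm - done)
        X = np.array([rng.permutation(x) for _ in range(b)])
        k += int(np.count_nonzero(_perm_max_stats(X, min_width) >= t_obs))
        done += b
        if (k + 1) / (n_perm + 1) > alpha:
            return False  # cannot reach significance; curtail
        batch = min(batch * 4, 2048)
    return (k + 1) / (n_perm + 1) <= alpha


def _split_once(x, alpha, n_perm, rng, min_width=2):
    """Find the best circular split of x; return (i, j) if significant."""
    n = len(x)
    if n < 2 * min_width:
        return None
    S = np.concatenate(([0.0], np.cumsum(x)))
    sst = float(np.sum((x - x.mean()) ** 2))
    if sst == 0.0:
        return None
    t_obs, i, j = _arc_stats_max(S, sst, n, min_width)
    if not np.isfinite(t_obs):
        return (i, j)
    if t_obs <= 0:
        return None
    # Bonferroni-style fast accept: the union bound over all tested arcs is
    # an upper bound on the permutation p; when even that clears alpha the
    # permutations cannot disagree in the rejecting direction.
    n_arcs = (n - 2 * min_width + 1) * n  # loose count of tested (i, j)
    p_upper = n_arcs * 2.0 * _tdist.sf(t_obs, max(n - 2, 1))
    if p_upper < alpha:
        return (i, j)
    if _perm_test(x, t_obs, n_perm, alpha, rng, min_width):
        return (i, j)
    return None


def _segment_series(x, alpha, n_perm, rng):
    """Recursive CBS on one chromosome; returns sorted interior breakpoints."""
    breakpoints: set[int] = set()
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        res = _split_once(x[lo:hi], alpha, n_perm, rng)
        if res is None:
            continue
        i, j = res
        cuts = [lo + c for c in (i, j) if 0 < c < hi - lo]
        if not cuts:
            continue
        breakpoints.update(c for c in cuts if 0 < c < len(x))
        edges = sorted({lo, *cuts, hi})
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a >= 4:
                stack.append((a, b))
    return sorted(breakpoints)


def _prune_breakpoints(x, breakpoints, prune):
    """DNAcopy-style undo: drop cuts whose removal barely raises the RSS.

    Iteratively removes the breakpoint with the smallest relative RSS
    increase while that increase is below ``prune`` of the current total
    residual sum of squares.
    """
    bps = sorted(breakpoints)

    def rss(edges):
        tot = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            seg = x[a:b]
            tot += float(np.sum((seg - seg.mean()) ** 2))
        return tot

    while bps:
        edges = [0, *bps, len(x)]
        base = rss(edges)
        if base <= 0:
            break
        deltas = []
        for b in bps:
            trial = [e for e in edges if e != b]
            deltas.append(rss(trial) - base)
        k = int(np.argmin(deltas))
        if deltas[k] / base < prune:
            bps.pop(k)
        else:
            break
    return bps


def segment_cbs(
    log2_ratios: np.ndarray,
    chrom_bounds: Sequence[tuple[int, int]],
    alpha: float = 1e-4,
    prune: float = 0.05,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Circular binary segmentation of a per-bin log2-ratio series.

    Each chromosome is segmented independently (breakpoints never cross a
    chromosome boundary).  At every step the arc maximizing the two-sample
    t statistic over circular splits is tested against a seeded permutation
    null; the split is accepted iff the permutation p-value is below
    ``alpha``.  Accepted cuts are then pruned: a breakpoint is undone when
    removing it increases the residual sum of squares by a proportion
    below ``prune``.

    Returns the segmentation as a list of half-open global (start, end)
    bin-index pairs.
    """
    x = np.asarray(log2_ratios, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = np.flatnonzero(~np.isfinite(x))
        raise ValueError(f"non-finite log2 ratios at bins {bad[:10].tolist()}")
    rng = np.random.default_rng(0) if rng is None else rng

    segments: list[tuple[int, int]] = []
    for lo, hi in chrom_bounds:
        series = x[lo:hi]
        bps = _segment_series(series, alpha, n_permutations, rng)
        bps = _prune_breakpoints(series, bps, prune)
        edges = [0, *bps, hi - lo]
        segments.extend((lo + a, lo + b) for a, b in zip(edges[:-1], edges[1:]))
    return segments


# ----------------------------------------------------------------------
# Diploid anchoring, copy numbers, burden
# ----------------------------------------------------------------------

def anchor_diploid(
    seg_bounds: Sequence[tuple[int, int]],
    ratios: np.ndarray,
    widths: np.ndarray,
    gain_log2_cut: float = 0.25,
    loss_log2_cut: float = -0.25,
    merge_tol: float = 0.15,
    min_diploid_frac: float = 0.10,
) -> tuple[float, np.ndarray, list[str], bool]:
    """Anchor the dominant ratio cluster to copy number 2.

    Segment mean ratios are clustered in one dimension (sorted, greedy
    merge of neighbours within ``merge_tol`` relative distance); the
    cluster covering the largest total genomic length is declared diploid
    and its length-weighted mean ratio becomes the anchor.  Every segment
    then gets ``round(2 * ratio / anchor)`` copies (floored at 0), with
    log2 guard cutoffs pulling sub-threshold jitter back to neutral.

    Returns (anchor_ratio, copy_numbers, states, confident) where
    ``confident`` is False when the anchor cluster covers less than
    ``min_diploid_frac`` of the genome.
    """
    if len(seg_bounds) == 0:
        raise ValueError("need at least one segment")
    seg_ratio = np.array([
        np.average(ratios[a:b], weights=widths[a:b]) for a, b in seg_bounds
    ])
    seg_len = np.array([widths[a:b].sum() for a, b in seg_bounds], dtype=float)

    order = np.argsort(seg_ratio)
    clusters: list[list[int]] = []
    c_mean = 0.0
    for idx in order:
        r = seg_ratio[idx]
        if clusters and c_mean > 0 and (r - c_mean) / c_mean <= merge_tol:
            clusters[-1].append(idx)
            members = clusters[-1]
            c_mean = np.average(seg_ratio[members], weights=seg_len[members])
        else:
            clusters.append([idx])
            c_mean = r
    totals = [seg_len[c].sum() for c in clusters]
    best = clusters[int(np.argmax(totals))]
    anchor = float(np.average(seg_ratio[best], weights=seg_len[best]))
    confident = seg_len[best].sum() >= min_diploid_frac * seg_len.sum()
    if not confident:
        logger.warning("no confident diploid baseline (anchor cluster < %.0f%% of genome)",
                       100 * min_diploid_frac)
    if anchor <= 0:
        raise ValueError("non-positive anchor ratio")

    rel = seg_ratio / anchor
    cn = np.maximum(np.rint(2.0 * rel), 0).astype(int)
    with np.errstate(divide="ignore"):
        l2 = np.log2(np.maximum(rel, 1e-6))
    # guard band: a provisional gain/loss within the jitter band stays neutral
    cn[(cn > 2) & (l2 < gain_log2_cut)] = 2
    cn[(cn < 2) & (l2 > loss_log2_cut)] = 2
    states = ["neutral" if c == 2 else ("gain" if c > 2 else "loss") for c in cn]
    return anchor, cn, states, confident


def cna_burden(
    segments: Sequence[Segment],
    autosome_length: int,
    burden_threshold: float = 0.02,
) -> tuple[float, bool]:
    """Fraction of the autosomal genome in non-neutral segments.

    A profile has "detectable CNAs" iff its burden strictly exceeds the
    threshold; a burden of exactly 0.02 is not detectable.
    """
    altered = sum(s.length_bp for s in segments if s.state != "neutral")
    burden = altered / autosome_length
    return burden, burden > burden_threshold


# ----------------------------------------------------------------------
# Composition
# ----------------------------------------------------------------------

def profile_cell(
    raw_counts: np.ndarray,
    grid: BinGrid,
    config: PipelineConfig = PipelineConfig(),
    cell_id: str = "cell",
    qc_pcr_pass: bool | None = None,
) -> SegmentedProfile:
    """Full per-cell pipeline from raw bin counts to a segmented profile.

    Runs normalization, ratio computation, MAPD QC, CBS, diploid anchoring
    and burden in sequence; stage failures are re-raised with the stage
    name.  With an identical grid, counts, and config the result is
    deterministic (the CBS permutation stream is seeded from the config).
    """
    raw_counts = np.asarray(raw_counts)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    if np.any(np.isfinite(grid.gc)):
        norm, masked = _stage("gc_normalize", gc_normalize,
                              raw_counts, grid.gc, config.lowess_span)
    else:  # no GC annotation at all: skip the correction rather than fail
        if raw_counts.sum() == 0:
            raise ValueError("[gc_normalize] all-zero counts: cell failed sequencing")
        norm = raw_counts.astype(float)
        masked = np.zeros(grid.n_bins, dtype=bool)
    ratios, log2 = _stage("compute_ratios", compute_ratios, norm, config.pseudocount)
    bounds = grid.chrom_bounds
    noise = _stage("mapd", mapd, log2, bounds, config.mapd_statistic)

    rng = np.random.default_rng(config.seed)
    seg_bounds = _stage("segment_cbs", segment_cbs, log2, bounds,
                        config.cbs_alpha, config.cbs_prune,
                        config.n_permutations, rng)
    widths = grid.widths
    anchor, cns, states, confident = _stage(
        "anchor_diploid", anchor_diploid, seg_bounds, ratios, widths,
        config.gain_log2_cut, config.loss_log2_cut)

    segments = []
    for (a, b), cn, state in zip(seg_bounds, cns, states):
        segments.append(Segment(
            start_bin=a,
            end_bin=b - 1,
            mean_log2=float(np.mean(log2[a:b])),
            copy_number=int(cn) if state != "neutral" else 2,
            state=state,
            length_bp=int(widths[a:b].sum()),
        ))
    burden, detectable = cna_burden(segments, grid.autosome_length,
                                    config.burden_threshold)
    qc = (noise <= config.mapd_threshold) and (qc_pcr_pass is not False)
    return SegmentedProfile(
        cell_id=cell_id,
        segments=segments,
        cna_burden=burden,
        mapd=noise,
        qc_pass=qc,
        qc_pcr_pass=qc_pcr_pass,
        log2_ratios=log2,
        detectable=detectable,
        diploid_confident=confident,
        anchor_ratio=anchor,
        total_reads=int(raw_counts.sum()),
    )


# ----------------------------------------------------------------------
# On-disk profile dialects
# ----------------------------------------------------------------------

def write_profile(profile: SegmentedProfile, grid: BinGrid, out_prefix) -> None:
    """Write a profile as a BED-like segments TSV plus a summary JSON."""
    import json
    from pathlib import Path

    out_prefix = Path(out_prefix)
    with open(out_prefix.with_suffix(".segments.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tmean_log2\tcopy_number\tstate\n")
        for s in profile.segments:
            fh.write(
                f"{grid.chroms[s.start_bin]}\t{grid.starts[s.start_bin]}\t"
                f"{grid.ends[s.end_bin]}\t{s.mean_log2:.6f}\t"
                f"{s.copy_number}\t{s.state}\n"
            )
    summary = {
        "cell_id": profile.cell_id,
        "mapd": profile.mapd,
        "cna_burden": profile.cna_burden,
        "detectable": profile.detectable,
        "qc_pass": profile.qc_pass,
        "qc_pcr_pass": profile.qc_pcr_pass,
        "total_reads": profile.total_reads,
    }
    with open(out_prefix.with_suffix(".summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
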