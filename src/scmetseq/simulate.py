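"""Synthetic study data: clonal CNA truths, low-pass counts, fluids, cohorts.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes:

* clonal copy-number truths shared by all tumor cells of a sample, with
  burden regimes spanning what solid tumors show;
* 0.2x mean-depth per-cell bin counts with multiplicative GC bias and
  gamma-Poisson (negative binomial) amplification overdispersion — the
  two-parameter family spans the MAPD range (~0.1-0.7) needed to
  exercise the 0.45 QC gate;
* immunofluorescence intensity tables with leukocyte / epithelial /
  tumor populations, benign samples carrying occasional bright false
  positives whose genomes are diploid or hold one sporadic low-burden
  event (non-recurrent across cells);
* two-arm cohorts whose sCTC density distributions match the published
  medians/IQRs (malignant lognormal with median 5.8/ml and IQR
  2.5-11.5/ml; benign counts with median 0.1/ml and a point mass at 0).

All randomness flows through one seeded ``numpy.random.Generator``; equal
seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .binning import BinGrid, hg19_autosome_sizes, make_bin_grid

# copy-number states available to simulated events, with sampling weights
_EVENT_CN = np.array([0, 1, 3, 4, 5])
_EVENT_CN_W = np.array([0.05, 0.30, 0.40, 0.15, 0.10])


@dataclass(frozen=True)
class GcBiasModel:
    """Multiplicative GC bias g(gc) = exp(b1*z + b2*z**2), z = gc - center."""

    linear: float = 1.0
    quad: float = -10.0
    center: float = 0.40

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        z = np.where(np.isfinite(gc), gc, self.center) - self.center
        return np.exp(self.linear * z + self.quad * z * z)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    ``dispersion`` is the gamma-Poisson overdispersion (variance =
    mean + dispersion * mean**2).  The default 0.01 emulates passing-
    quality single-cell WGS at 0.2x depth: per-cell MAPD lands near 0.15
    (well inside the <= 0.45 gate) and within-clone bin-level profile
    correlations sit around 0.9, the regime reported for genuine CTCs.
    The noisy preset 0.2 lands MAPD near 0.65 (failing the gate).
    """

    mean_depth: float = 0.2            # genome-fold coverage
    read_length: int = 100             # bp per counted read
    dispersion: float = 0.01
    gc_bias: GcBiasModel = GcBiasModel()
    n_tumor_cells: int = 10
    n_normal_cells: int = 4000         # background cells in the intensity table
    frac_epithelial: float = 0.15      # benign epithelial share of background
    sporadic_cna_rate: float = 0.15    # normal cells carrying one random event
    tumor_burden_range: tuple[float, float] = (0.15, 0.5)
    n_sequence_max: int = 8            # bright cells given WGS counts per sample
    ascites_volume_ml: float = 10.0
    blood_volume_ml: float = 5.0
    # malignant sCTC density: lognormal matched to median 5.8, IQR 2.5-11.5
    malignant_density_mu: float = math.log(5.8)
    malignant_density_sigma: float = 1.1313
    # benign bright-cell count per ascites sample: Poisson, median 1 (0.1/ml)
    benign_flag_mean: float = 1.2

    def total_reads(self, autosome_length: int) -> int:
        return int(self.mean_depth * autosome_length / self.read_length)


NOISY_DISPERSION = 0.2  # preset that fails the MAPD <= 0.45 gate


# ----------------------------------------------------------------------
# Grids
# ----------------------------------------------------------------------

def _synthetic_gc(grid: BinGrid) -> np.ndarray:
    """Deterministic smooth GC curve keyed to genomic position.

    Synthetic stand-in used when no reference FASTA is available; it has
    the spatially autocorrelated, isochore-scale (~5 Mb period) shape of
    real GC tracks but carries no sequence information.  The short period
    matters: every GC value is visited by bins scattered across the whole
    genome, so a contiguous CNA event cannot dominate any GC stratum of
    the lowess fit.
    """
    mid = (grid.starts + grid.ends) / 2
    phase = np.zeros(grid.n_bins)
    for k, (lo, hi) in enumerate(grid.chrom_bounds):
        phase[lo:hi] = mid[lo:hi] / 5e6 + k * 0.7
    return 0.41 + 0.06 * np.sin(2 * np.pi * phase) + 0.02 * np.cos(5.1 * phase)


def toy_grid(n_chroms: int = 2, bins_per_chrom: int = 50, bin_width: int = 500_000) -> BinGrid:
    """Small preset genome (default 2 x 50 bins) for fast tests."""
    sizes = {f"chr{i + 1}": bins_per_chrom * bin_width for i in range(n_chroms)}
    grid = make_bin_grid(sizes, target_width=bin_width)
    return BinGrid(grid.chroms, grid.starts, grid.ends, _synthetic_gc(grid))


def hg19_grid(target_width: int = 500_000) -> BinGrid:
    """Full-size grid from the standard hg19 autosome table, synthetic GC."""
    grid = make_bin_grid(hg19_autosome_sizes(), target_width=target_width)
    return BinGrid(grid.chroms, grid.starts, grid.ends, _synthetic_gc(grid))


# ----------------------------------------------------------------------
# Clonal truths
# ----------------------------------------------------------------------

@dataclass
class ClonalTruth:
    clone_id: str
    cn_per_bin: np.ndarray
    burden_true: float


def _realized_burden(cn: np.ndarray, widths: np.ndarray) -> float:
    return float(widths[cn != 2].sum() / widths.sum())


def simulate_clone(
    grid: BinGrid,
    target_burden: float,
    rng: np.random.Generator,
    clone_id: str = "clone",
    event_size_dist: Callable[[np.random.Generator], float] | None = None,
    max_events: int = 200,
    rel_tol: float = 0.10,
) -> ClonalTruth:
    """Place non-overlapping gain/loss events until the burden hits target.

    Events draw copy numbers from {0, 1, 3, 4, 5} and sizes from
    ``event_size_dist`` (default: uniform 10-40 Mb, the chromosome-arm
    scale of clonal CNAs in solid tumors, independent of genome size).
    The realized burden lands within ``rel_tol`` relative of the target
    (exact 0 for target 0); the last event is trimmed to close the gap.
    """
    if not 0 <= target_burden <= 0.9:
        raise ValueError("target_burden must be in [0, 0.9]")
    widths = grid.widths
    L = grid.autosome_length
    cn = np.full(grid.n_bins, 2, dtype=np.int16)
    if target_burden == 0:
        return ClonalTruth(clone_id, cn, 0.0)

    if event_size_dist is None:

        def event_size_dist(r):
            return r.uniform(10e6, 40e6)

    free = np.ones(grid.n_bins, dtype=bool)
    for _ in range(max_events):
        burden = _realized_burden(cn, widths)
        gap = target_burden - burden
        if abs(gap) <= rel_tol * target_burden:
            return ClonalTruth(clone_id, cn, burden)
        size_bp = min(event_size_dist(rng), gap * L * 1.05)
        n_bins = max(int(round(size_bp / float(np.median(widths)))), 1)
        placed = False
        for attempt in range(200):
            if attempt and attempt % 50 == 0:
                n_bins = max(n_bins // 2, 1)  # crowded genome: shrink and retry
            start = int(rng.integers(0, grid.n_bins))
            end = start + n_bins
            # stay inside one chromosome and on free bins
            for lo, hi in grid.chrom_bounds:
                if lo <= start < hi:
                    end = min(end, hi)
                    break
            if end - start < 1 or not free[start:end].all():
                continue
            cn[start:end] = rng.choice(_EVENT_CN, p=_EVENT_CN_W)
            free[start:end] = False
            placed = True
            break
        if not placed:
            break
    burden = _realized_burden(cn, widths)
    if abs(burden - target_burden) > rel_tol * target_burden:
        raise ValueError(
            f"could not reach burden {target_burden} (got {burden:.3f}) "
            "with the given event sizes"
        )
    return ClonalTruth(clone_id, cn, burden)


def sporadic_truth(grid: BinGrid, rng: np.random.Generator, clone_id: str = "sporadic") -> ClonalTruth:
    """One random low-burden event, as seen in rare normal cells.

    Sized at 0.3-1.2% of the autosome so the typical benign burden stays
    below the 0.02 detectability threshold; positions are random, hence
    non-recurrent across cells.
    """
    widths = grid.widths
    cn = np.full(grid.n_bins, 2, dtype=np.int16)
    size_bp = rng.uniform(0.003, 0.012) * grid.autosome_length
    n_bins = max(int(round(size_bp / float(np.median(widths)))), 1)
    lo, hi = grid.chrom_bounds[int(rng.integers(len(grid.chrom_bounds)))]
    start = int(rng.integers(lo, max(hi - n_bins, lo + 1)))
    cn[start:min(start + n_bins, hi)] = rng.choice([1, 3])
    return ClonalTruth(clone_id, cn, _realized_burden(cn, widths))


# ----------------------------------------------------------------------
# Counts
# ----------------------------------------------------------------------

def simulate_cell_counts(
    truth: ClonalTruth | np.ndarray,
    grid: BinGrid,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-bin read counts for one cell.

    Expected counts are proportional to bin width x (copy number / 2) x
    GC bias, normalized so their sum equals the depth-implied total read
    count; draws are gamma-Poisson with the configured overdispersion
    (Poisson in the limit dispersion -> 0).
    """
    cn = truth.cn_per_bin if isinstance(truth, ClonalTruth) else np.asarray(truth)
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    total = config.total_reads(grid.autosome_length)
    lam = grid.widths.astype(float) * (cn / 2.0) * config.gc_bias(grid.gc)
    s = lam.sum()
    if s <= 0:
        return np.zeros(grid.n_bins, dtype=np.int64)
    lam *= total / s
    if config.dispersion <= 1e-12:
        return rng.poisson(lam).astype(np.int64)
    shape = 1.0 / config.dispersion
    mixed = rng.gamma(shape, lam * config.dispersion)
    return rng.poisson(mixed).astype(np.int64)


# ----------------------------------------------------------------------
# Intensity tables and samples
# ----------------------------------------------------------------------

def _background_intensities(n: int, cfg: SimConfig, rng, source: str) -> pd.DataFrame:
    n_epi = int(round(cfg.frac_epithelial * n)) if source == "ascites" else 0
    n_leuk = n - n_epi
    rows = []
    hk2 = rng.lognormal(math.log(400 if source == "ascites" else 300), 0.25, n_leuk)
    ck = rng.uniform(0, 200 if source == "ascites" else 150, n_leuk)
    cd45 = np.clip(rng.normal(1500, 200, n_leuk), 200, None)
    rows.append(pd.DataFrame({"hk2": hk2, "ck": ck, "cd45": cd45, "kind": "leukocyte"}))
    if n_epi:
        rows.append(pd.DataFrame({
            "hk2": rng.lognormal(math.log(450), 0.3, n_epi),
            "ck": np.clip(rng.normal(900, 150, n_epi), 400.0, None),
            "cd45": np.clip(rng.normal(60, 20, n_epi), 0, None),
            "kind": "epithelial",
        }))
    df = pd.concat(rows, ignore_index=True)
    df["dapi_pos"] = rng.random(len(df)) < 0.98
    return df


def _bright_intensities(n: int, rng, source: str, kind: str) -> pd.DataFrame:
    """HK2-high (or HK2+CK-high) CD45- cells: tumor cells or false positives."""
    if source == "ascites":
        hk2 = np.clip(rng.normal(1800, 250, n), 1200, None)
        ck = np.clip(rng.normal(1000, 150, n), 450, None)
    else:
        hk2 = np.clip(rng.normal(1500, 220, n), 1000, None)
        ck = np.clip(rng.normal(800, 150, n), 300, None)
    return pd.DataFrame({
        "hk2": hk2, "ck": ck,
        "cd45": np.clip(rng.normal(60, 20, n), 0, None),
        "kind": kind,
        "dapi_pos": True,
    })


@dataclass
class SimSample:
    sample_id: str
    source: str
    label: str  # malignant | benign
    volume_ml: float
    intensities: pd.DataFrame  # cell_id, hk2, ck, cd45, dapi_pos
    counts_by_cell: dict[str, np.ndarray]
    truth_by_cell: dict[str, ClonalTruth]
    clone: ClonalTruth | None


def simulate_sample(
    kind: str,
    config: SimConfig,
    rng: np.random.Generator,
    grid: BinGrid | None = None,
    sample_id: str = "S1",
    source: str = "ascites",
    n_bright: int | None = None,
) -> SimSample:
    """One body-fluid sample: intensity table plus WGS counts for bright cells.

    Malignant samples carry tumor cells sharing one clonal truth at a
    density drawn from the published malignant distribution; benign
    samples carry a small Poisson number of bright false positives whose
    genomes are diploid or hold one sporadic event.  Counts are generated
    for up to ``n_sequence_max`` bright cells (the cells a micromanipulator
    would retrieve).
    """
    if kind not in ("malignant", "benign"):
        raise ValueError("kind must be malignant or benign")
    grid = toy_grid() if grid is None else grid
    volume = config.ascites_volume_ml if source == "ascites" else config.blood_volume_ml

    clone = None
    if kind == "malignant":
        target = rng.uniform(*config.tumor_burden_range)
        clone = simulate_clone(grid, target, rng, clone_id=f"{sample_id}-clone")
        if n_bright is None:
            density = rng.lognormal(config.malignant_density_mu,
                                    config.malignant_density_sigma)
            n_bright = int(rng.poisson(density * volume))
    elif n_bright is None:
        n_bright = int(rng.poisson(config.benign_flag_mean))

    bg = _background_intensities(config.n_normal_cells, config, rng, source)
    bright = _bright_intensities(n_bright, rng, source,
                                 "tumor" if kind == "malignant" else "false_positive")
    table = pd.concat([bg, bright], ignore_index=True)
    table.insert(0, "cell_id", [f"{sample_id}_c{i:05d}" for i in range(len(table))])

    counts: dict[str, np.ndarray] = {}
    truths: dict[str, ClonalTruth] = {}
    bright_ids = table.loc[table["kind"].isin(["tumor", "false_positive"]), "cell_id"]
    for cell_id in bright_ids.head(config.n_sequence_max):
        if kind == "malignant":
            truth = clone
        elif rng.random() < config.sporadic_cna_rate:
            truth = sporadic_truth(grid, rng, clone_id=f"{cell_id}-sporadic")
        else:
            truth = ClonalTruth(f"{cell_id}-diploid",
                                np.full(grid.n_bins, 2, dtype=np.int16), 0.0)
        truths[cell_id] = truth
        counts[cell_id] = simulate_cell_counts(truth, grid, config, rng)

    return SimSample(
        sample_id=sample_id, source=source, label=kind, volume_ml=volume,
        intensities=table.drop(columns="kind"),
        counts_by_cell=counts, truth_by_cell=truths, clone=clone,
    )


@dataclass
class CohortBundle:
    samples: list[SimSample]
    truth: pd.DataFrame  # sample_id, label
    grid: BinGrid


def simulate_cohort(
    n_malignant: int,
    n_benign: int,
    config: SimConfig,
    seed: int,
    grid: BinGrid | None = None,
    source: str = "ascites",
    outdir: str | Path | None = None,
) -> CohortBundle:
    """Generate a two-arm cohort; optionally write it as pipeline inputs.

    When ``outdir`` is given, each sample gets an intensity TSV, a counts
    TSV and a metadata JSON; the bin grid (BED) and truth table (TSV) sit
    at the top level, ready for the command-line pipeline.
    """
    if n_malignant <= 0 or n_benign <= 0:
        raise ValueError("cohort arms must be non-empty")
    grid = toy_grid() if grid is None else grid
    rng = np.random.default_rng(seed)
    samples = []
    for k in range(n_malignant + n_benign):
        kind = "malignant" if k < n_malignant else "benign"
        samples.append(simulate_sample(kind, config, rng, grid,
                                       sample_id=f"{source[:2].upper()}{k + 1:03d}",
                                       source=source))
    truth = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "label": [s.label for s in samples],
    })
    bundle = CohortBundle(samples=samples, truth=truth, grid=grid)
    if outdir is not None:
        _write_cohort(bundle, Path(outdir))
    return bundle


def _write_cohort(bundle: CohortBundle, outdir: Path) -> None:
    import json

    outdir.mkdir(parents=True, exist_ok=True)
    bundle.grid.to_bed(outdir / "bins.bed")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    names = bundle.grid.bin_names()
    for s in bundle.samples:
        d = outdir / s.sample_id
        d.mkdir(exist_ok=True)
        s.intensities.to_csv(d / "intensities.tsv", sep="\t", index=False)
        with open(d / "meta.json", "w") as fh:
            json.dump({"sample_id": s.sample_id, "source": s.source,
                       "volume_ml": s.volume_ml}, fh)
        if s.counts_by_cell:
            df = pd.DataFrame.from_dict(
                {c: v for c, v in s.counts_by_cell.items()}, orient="index",
                columns=names,
            )
            from .binning import write_counts_table
            write_counts_table(df, d / "counts.tsv")
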