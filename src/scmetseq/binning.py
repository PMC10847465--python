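"""Autosomal bin grids and per-cell bin counts.

The coordinate frame of every copy-number profile is a :class:`BinGrid`:
the 22 human autosomes tiled with fixed, near-equal-width bins averaging
~500 kb.  Reads from low-pass single-cell WGS (or precomputed count
tables) are reduced to one integer count per bin; everything downstream
(normalization, segmentation, burden) works on these vectors.

Coordinates are 0-based half-open throughout; BED is the on-disk dialect.
Sex chromosomes are excluded so that CNA burden denominators refer to the
autosomal genome only.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("scmetseq")

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9][0-9]?)$")

#: Chromosomes shorter than half the target width cannot be tiled while
#: keeping every bin within +/-50% of the target.
_MIN_CHROM_FACTOR = 0.5


def is_autosome(name: str) -> bool:
    """True for chr1..chr22 (with or without the ``chr`` prefix)."""
    m = _AUTOSOME_RE.match(name)
    return bool(m) and 1 <= int(m.group(2)) <= 22


def _autosome_sort_key(name: str) -> int:
    return int(_AUTOSOME_RE.match(name).group(2))


@dataclass(frozen=True)
class BinGrid:
    """Ordered autosomal genomic bins with optional GC fractions.

    Attributes
    ----------
    chroms : array of str, one entry per bin
    starts, ends : int arrays, 0-based half-open
    gc : float array; ``nan`` marks bins whose GC is unavailable or masked
        (e.g. >50% N in the reference).
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    gc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.gc is None:
            object.__setattr__(self, "gc", np.full(len(self.starts), np.nan))
        widths = self.ends - self.starts
        if np.any(widths <= 0):
            raise ValueError("bins must have positive width")

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def autosome_length(self) -> int:
        """Sum of bin widths == total autosomal genome length (exact tiling)."""
        return int(self.widths.sum())

    @property
    def chrom_bounds(self) -> list[tuple[int, int]]:
        """Half-open global bin-index ranges, one per chromosome, in order."""
        bounds = []
        lo = 0
        for i in range(1, self.n_bins + 1):
            if i == self.n_bins or self.chroms[i] != self.chroms[lo]:
                bounds.append((lo, i))
                lo = i
        return bounds

    @property
    def chrom_names(self) -> list[str]:
        return [self.chroms[lo] for lo, _ in self.chrom_bounds]

    def bin_names(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)]

    # -- BED round trip ------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """Write the grid as BED with bin name and GC fraction columns."""
        with open(path, "w") as fh:
            for k in range(self.n_bins):
                gc = "." if np.isnan(self.gc[k]) else f"{self.gc[k]:.6f}"
                fh.write(
                    f"{self.chroms[k]}\t{self.starts[k]}\t{self.ends[k]}"
                    f"\tbin_{k:05d}\t{gc}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path) -> "BinGrid":
        tab = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "gc"],
            dtype={"chrom": str}, na_values=".",
        )
        return cls(
            chroms=tab["chrom"].to_numpy(dtype=object),
            starts=tab["start"].to_numpy(dtype=np.int64),
            ends=tab["end"].to_numpy(dtype=np.int64),
            gc=tab["gc"].to_numpy(dtype=float),
        )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table (UCSC chrom.sizes dialect)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


def hg19_autosome_sizes() -> dict[str, int]:
    """The standard hg19 autosome lengths shipped with the package."""
    here = Path(__file__).parent / "data" / "hg19.chrom.sizes"
    return read_chrom_sizes(here)


def gc_fraction(seq: str) -> float:
    """GC over A/C/G/T, ignoring N; nan when >50% of the bin is N."""
    s = seq.upper()
    n_count = s.count("N")
    acgt = len(s) - n_count
    if len(s) == 0 or n_count > 0.5 * len(s) or acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


def make_bin_grid(
    chrom_sizes: Mapping[str, int] | str | Path,
    target_width: int = 500_000,
    reference: str | Path | None = None,
) -> BinGrid:
    """Tile each autosome with near-equal fixed bins covering its full length.

    Each autosome of length ``L`` receives ``floor(L / target_width)`` bins;
    the remainder is spread one base at a time over the leading bins so the
    tiling is exact and every width stays within +/-50% of the target.  GC
    fractions are computed from ``reference`` (FASTA, via pyfaidx) when
    given, else marked unavailable.

    Raises
    ------
    ValueError
        For non-positive lengths/width, or chromosomes too short to tile.
    KeyError
        When the reference is missing a requested chromosome (named).
    """
    if isinstance(chrom_sizes, (str, Path)):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if target_width <= 0:
        raise ValueError("target_width must be positive")

    autosomes = sorted((c for c in chrom_sizes if is_autosome(c)), key=_autosome_sort_key)
    if not autosomes:
        raise ValueError("no autosomes found in chrom_sizes")
    dropped = set(chrom_sizes) - set(autosomes)
    if dropped:
        logger.info("excluding non-autosomal chromosomes: %s", sorted(dropped))
    logger.info(
        "equal-width tiling: per-chromosome width = length / floor(length/%d) "
        "(sub-width terminal bins are merged, not emitted)", target_width
    )

    fasta = None
    if reference is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(reference))

    chroms, starts, ends, gcs = [], [], [], []
    for chrom in autosomes:
        length = int(chrom_sizes[chrom])
        if length <= 0:
            raise ValueError(f"zero-length chromosome: {chrom}")
        n = length // target_width
        if n == 0:
            if length < _MIN_CHROM_FACTOR * target_width:
                raise ValueError(
                    f"chromosome {chrom} ({length} bp) too short for "
                    f"target width {target_width}"
                )
            n = 1
        base, rem = divmod(length, n)
        if fasta is not None and chrom not in fasta:
            raise KeyError(f"reference FASTA is missing chromosome {chrom}")
        pos = 0
        for k in range(n):
            w = base + (1 if k < rem else 0)
            chroms.append(chrom)
            starts.append(pos)
            ends.append(pos + w)
            if fasta is not None:
                gcs.append(gc_fraction(str(fasta[chrom][pos:pos + w])))
            else:
                gcs.append(float("nan"))
            pos += w
        assert pos == length

    grid = BinGrid(
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        gc=np.array(gcs, dtype=float),
    )
    widths = grid.widths
    if np.any(widths < 0.5 * target_width) or np.any(widths > 1.5 * target_width):
        raise ValueError("tiling produced a bin outside +/-50% of the target width")
    return grid


# ----------------------------------------------------------------------
# Read counting
# ----------------------------------------------------------------------

def assign_bins(grid: BinGrid, chroms: Iterable[str], positions: np.ndarray) -> np.ndarray:
    """Map leftmost mapped bases to global bin indices (-1 = off-grid).

    Vectorized helper behind :func:`count_reads`; also convenient for
    counting synthetic read placements without going through SAM.
    """
    positions = np.asarray(positions, dtype=np.int64)
    chroms = np.asarray(list(chroms), dtype=object)
    out = np.full(len(positions), -1, dtype=np.int64)
    for (lo, hi) in grid.chrom_bounds:
        name = grid.chroms[lo]
        sel = chroms == name
        if not sel.any():
            continue
        pos = positions[sel]
        idx = np.searchsorted(grid.starts[lo:hi], pos, side="right") - 1
        length = grid.ends[hi - 1]
        ok = (pos >= 0) & (pos < length) & (idx >= 0)
        res = np.where(ok, idx + lo, -1)
        out[sel] = res
    return out


def count_reads(
    alignments,
    grid: BinGrid,
    min_mapq: int = 30,
    drop_duplicates: bool = True,
) -> tuple[np.ndarray, int]:
    """Count retained primary alignments per bin by leftmost mapped base.

    Parameters
    ----------
    alignments : path to SAM/BAM, an open ``pysam.AlignmentFile``, or an
        iterable of aligned-segment records.  Files are streamed without
        an index.
    min_mapq : minimum mapping quality (the aligner is run with default
        options upstream, so the filter lives here and is logged).
    drop_duplicates : skip reads flagged as PCR/optical duplicates.

    Returns
    -------
    (counts, n_retained) — counts has one entry per grid bin; alignments
    on chromosomes outside the grid are ignored.
    """
    import pysam

    own = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    reads = alignments.fetch(until_eof=True) if hasattr(alignments, "fetch") else alignments

    logger.debug("counting reads with min_mapq=%d drop_duplicates=%s", min_mapq, drop_duplicates)
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    lookup = {}
    for lo, hi in grid.chrom_bounds:
        lookup[grid.chroms[lo]] = (lo, grid.starts[lo:hi], grid.ends[hi - 1])
    retained = 0
    saw_any = False
    try:
        for read in reads:
            saw_any = True
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_qcfail or (drop_duplicates and read.is_duplicate):
                continue
            if read.mapping_quality < min_mapq:
                continue
            entry = lookup.get(read.reference_name)
            if entry is None:
                continue
            lo, starts, length = entry
            pos = read.reference_start
            if pos < 0 or pos >= length:
                continue
            k = int(np.searchsorted(starts, pos, side="right")) - 1
            counts[lo + k] += 1
            retained += 1
    finally:
        if own:
            alignments.close()
    if saw_any and retained == 0:
        warnings.warn("no alignments retained (unmapped/filtered input); counts are all zero")
    return counts, retained


# ----------------------------------------------------------------------
# Count tables
# ----------------------------------------------------------------------

def write_counts_table(counts: pd.DataFrame, path: str | Path, long_format: bool = False) -> None:
    """Write per-cell raw counts as TSV.

    Wide format: one row per cell (``cell_id`` + one column per bin, in grid
    order).  Long format: ``cell_id, bin, count`` rows.
    """
    counts = counts.rename_axis("cell_id")
    if long_format:
        long = counts.stack().rename("count").reset_index()
        long.columns = ["cell_id", "bin", "count"]
        long.to_csv(path, sep="\t", index=False)
    else:
        counts.to_csv(path, sep="\t")


def read_counts_table(path: str | Path, grid: BinGrid | None = None) -> pd.DataFrame:
    """Read a per-cell counts TSV (wide or long), validating against ``grid``.

    Returns a DataFrame indexed by cell_id with one integer column per bin.
    A cell whose bin vector does not match the grid size is rejected by name.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    if set(tab.columns) >= {"cell_id", "bin", "count"}:  # long format
        wide = tab.pivot(index="cell_id", columns="bin", values="count")
        # restore file order of bins, not lexicographic pivot order
        order = list(dict.fromkeys(tab["bin"]))
        wide = wide[order]
    else:
        wide = tab.set_index("cell_id")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"cell {bad!r}: missing bin counts")
    if grid is not None and wide.shape[1] != grid.n_bins:
        bad = wide.index[0] if len(wide) else "<empty>"
        raise ValueError(
            f"cell {bad!r}: {wide.shape[1]} bins in table but grid has {grid.n_bins}"
        )
    if grid is not None:
        expected = grid.bin_names()
        if list(wide.columns) != expected and set(wide.columns) == set(expected):
            wide = wide[expected]
    return wide.astype(np.int64)
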