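"""Suspicious-CTC calling from per-cell immunofluorescence intensities.

Ascites rule: a cell is a suspicious CTC (sCTC) when its HK2 intensity is
at or above the HK2-high threshold — the mean HK2 of CK-negative cells
(CK < 400 a.u.) plus k standard deviations (k = 5) — and it is CK+,
DAPI+ and (by default) CD45-.

Blood rule: the combined HK2+CK signal (stained in one color) is compared
with mean + 5 SD of CD45+ leukocytes; flagged cells must be CD45- and
DAPI+.

sCTC density is flagged cells per ml of body fluid; densities at or above
2.0/ml (ascites) or 3.0/ml (blood) trigger single-cell WGS downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

logger = logging.getLogger("scmetseq")

MIN_REFERENCE_CELLS = 20


@dataclass
class SctcCallResult:
    """Outcome of one sample's sCTC call."""

    threshold_value: float
    reference_n: int
    reference_mean: float
    reference_sd: float
    flags: pd.Series  # boolean, indexed by cell_id
    density_per_ml: float
    volume_ml: float
    cd45_cut: float | None = None

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def _as_frame(cells) -> pd.DataFrame:
    df = pd.DataFrame(cells)
    required = {"cell_id", "hk2", "ck", "cd45", "dapi_pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    for col in ("hk2", "ck", "cd45"):
        v = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError(f"{col} intensities must be nonnegative and finite")
    return df.set_index("cell_id")


def _cd45_cut(cd45: np.ndarray, cd45_cut: float | None) -> float:
    """CD45 positivity split: configured value, else Otsu on the channel."""
    if cd45_cut is not None:
        return float(cd45_cut)
    if np.ptp(cd45) == 0:
        return float(cd45[0]) + 1.0  # degenerate channel: nobody is CD45+
    return float(threshold_otsu(np.asarray(cd45, dtype=float)))


def sctc_density(n_flagged: int, volume_ml: float) -> float:
    """Flagged-cell density per ml of fluid."""
    if volume_ml <= 0:
        raise ValueError("volume_ml must be positive")
    return n_flagged / volume_ml


def call_sctcs_ascites(
    cells,
    volume_ml: float,
    ck_neg_cut: float = 400.0,
    k_sd: float = 5.0,
    ck_pos_cut: float | None = None,
    cd45_cut: float | None = None,
    require_cd45_neg: bool = True,
) -> SctcCallResult:
    """Call sCTCs in ascites: HK2-high / CK+ / DAPI+ (/ CD45-).

    The HK2-high threshold is mean + ``k_sd`` * SD (population SD) of the
    HK2 intensity among CK- reference cells (CK < ``ck_neg_cut``); at
    least 20 reference cells are required.  CK positivity defaults to the
    same 400 a.u. cut used for the reference gate.  The CD45- gate is on
    by default (the stricter of the two published phenotype definitions)
    and configurable.
    """
    df = _as_frame(cells)
    ref = df["hk2"].to_numpy(dtype=float)[df["ck"].to_numpy(dtype=float) < ck_neg_cut]
    if len(ref) < MIN_REFERENCE_CELLS:
        raise ValueError(
            f"only {len(ref)} CK- reference cells; need >= {MIN_REFERENCE_CELLS}"
        )
    mean, sd = float(ref.mean()), float(ref.std(ddof=0))
    threshold = mean + k_sd * sd

    if ck_pos_cut is None:
        ck_pos_cut = ck_neg_cut
    flags = (df["hk2"] >= threshold) & (df["ck"] >= ck_pos_cut) & df["dapi_pos"].astype(bool)
    cut = None
    if require_cd45_neg:
        cut = _cd45_cut(df["cd45"].to_numpy(dtype=float), cd45_cut)
        flags &= df["cd45"] < cut
        logger.debug("ascites sCTC call uses the CD45- gate (cut %.1f a.u.)", cut)

    return SctcCallResult(
        threshold_value=threshold,
        reference_n=len(ref),
        reference_mean=mean,
        reference_sd=sd,
        flags=flags,
        density_per_ml=sctc_density(int(flags.sum()), volume_ml),
        volume_ml=volume_ml,
        cd45_cut=cut,
    )


def call_sctcs_blood(
    cells,
    volume_ml: float,
    k_sd: float = 5.0,
    cd45_cut: float | None = None,
) -> SctcCallResult:
    """Call sCTCs in blood: HK2+CK high / CD45- / DAPI+.

    The combined signal s = HK2 + CK (single-channel sum, as stained) is
    thresholded at mean + ``k_sd`` * SD of s among CD45+ leukocytes.
    """
    df = _as_frame(cells)
    s = df["hk2"].to_numpy(dtype=float) + df["ck"].to_numpy(dtype=float)
    cd45 = df["cd45"].to_numpy(dtype=float)
    cut = _cd45_cut(cd45, cd45_cut)
    ref = s[cd45 >= cut]
    if len(ref) < MIN_REFERENCE_CELLS:
        raise ValueError(
            f"only {len(ref)} CD45+ leukocytes; need >= {MIN_REFERENCE_CELLS}"
        )
    mean, sd = float(ref.mean()), float(ref.std(ddof=0))
    threshold = mean + k_sd * sd

    flags = pd.Series(
        (s >= threshold) & (cd45 < cut) & df["dapi_pos"].to_numpy(dtype=bool),
        index=df.index,
    )
    return SctcCallResult(
        threshold_value=threshold,
        reference_n=len(ref),
        reference_mean=mean,
        reference_sd=sd,
        flags=flags,
        density_per_ml=sctc_density(int(flags.sum()), volume_ml),
        volume_ml=volume_ml,
        cd45_cut=cut,
    )
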