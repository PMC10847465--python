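"""Sample-level test: genuine-CTC determination by CNA concordance.

A sample is positive iff (1) its sCTC density reaches the fluid-specific
threshold (2.0/ml ascites, 3.0/ml blood), and (2) at least two QC-passing
sequenced sCTCs have detectable CNAs (burden > 0.02) and a pair of them
shows concordant genome-wide CNA profiles (Pearson r of per-bin log2
ratios at or above the concordance cut, default 0.8).  Benign cells carry
at most sporadic, non-recurrent CNAs, so requiring a concordant pair is
what removes false-positive sCTCs and drives specificity/PPV to ~100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .binning import BinGrid
from .profiling import PipelineConfig, SegmentedProfile, profile_cell
from .sctc import call_sctcs_ascites, call_sctcs_blood

logger = logging.getLogger("scmetseq")

DENSITY_THRESHOLDS = {"ascites": 2.0, "blood": 3.0}


@dataclass(frozen=True)
class DecisionConfig:
    ascites_density_threshold: float = 2.0
    blood_density_threshold: float = 3.0
    concordance_cut: float = 0.8
    burden_threshold: float = 0.02
    granularity: str = "bin"  # "bin" or "segment"
    max_cells: int | None = None  # cap on sequenced sCTCs per sample

    def density_threshold(self, source: str) -> float:
        if source == "ascites":
            return self.ascites_density_threshold
        if source == "blood":
            return self.blood_density_threshold
        raise ValueError(f"unknown source {source!r}")


@dataclass
class SampleTest:
    """One body-fluid sample's scMet-Seq verdict and its evidence."""

    sample_id: str
    source: str
    density_per_ml: float
    density_threshold: float
    profiles: list[SegmentedProfile]
    concordance: np.ndarray | None
    evidence_pairs: list[tuple[str, str, float]]
    call: str  # positive | negative
    reason: str  # below_count_threshold | no_detectable_cna | no_concordant_pair | positive

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "source": self.source,
            "call": self.call,
            "reason": self.reason,
            "density_per_ml": self.density_per_ml,
            "density_threshold": self.density_threshold,
            "evidence_pairs": [
                {"cell_i": a, "cell_j": b, "r": r} for a, b, r in self.evidence_pairs
            ],
        }


def concordance_matrix(
    profiles: list[SegmentedProfile],
    granularity: str = "bin",
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Pearson correlation of per-bin copy-number signal.

    ``bin`` granularity correlates raw per-bin log2 ratios (the richer
    signal at 0.2x depth); ``segment`` correlates per-bin segment-mean
    log2.  A zero-variance profile has undefined correlations, recorded
    as 0 and reported in the returned flag list.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    n_bins = {len(p.log2_ratios) for p in profiles}
    if len(n_bins) != 1:
        raise ValueError("profiles are on different grids")
    if granularity == "bin":
        vectors = [p.log2_ratios for p in profiles]
    elif granularity == "segment":
        vectors = [p.segment_log2_per_bin() for p in profiles]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")

    m = len(vectors)
    mat = np.eye(m)
    degenerate = [p.cell_id for p, v in zip(profiles, vectors) if np.ptp(v) == 0]
    for i in range(m):
        for j in range(i + 1, m):
            vi, vj = vectors[i], vectors[j]
            if np.ptp(vi) == 0 or np.ptp(vj) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(vi, vj)[0, 1])
            mat[i, j] = mat[j, i] = r
    if degenerate:
        logger.warning("zero-variance profiles (correlation recorded as 0): %s", degenerate)
    return mat, degenerate


def classify_sample(
    sample_id: str,
    source: str,
    density_per_ml: float,
    profiles: list[SegmentedProfile],
    config: DecisionConfig = DecisionConfig(),
) -> SampleTest:
    """Apply the positivity rule; ``reason`` is the first failing branch.

    Branch order: density threshold -> at least two QC-passing cells with
    detectable CNAs (burden strictly > threshold) -> at least one
    concordant pair among them.
    """
    threshold = config.density_threshold(source)
    if profiles:
        n_bins = {len(p.log2_ratios) for p in profiles}
        if len(n_bins) != 1:
            raise ValueError("profiles are on different grids")

    def verdict(call, reason, conc=None, pairs=()):
        return SampleTest(
            sample_id=sample_id, source=source,
            density_per_ml=density_per_ml, density_threshold=threshold,
            profiles=list(profiles), concordance=conc,
            evidence_pairs=list(pairs), call=call, reason=reason,
        )

    if density_per_ml < threshold:
        return verdict("negative", "below_count_threshold")

    eligible = [
        p for p in profiles
        if p.qc_pass and p.cna_burden > config.burden_threshold
    ]
    if len(eligible) < 2:
        return verdict("negative", "no_detectable_cna")

    conc, _ = concordance_matrix(eligible, config.granularity)
    pairs = [
        (eligible[i].cell_id, eligible[j].cell_id, float(conc[i, j]))
        for i in range(len(eligible))
        for j in range(i + 1, len(eligible))
        if conc[i, j] >= config.concordance_cut
    ]
    if not pairs:
        return verdict("negative", "no_concordant_pair", conc)
    return verdict("positive", "positive", conc, pairs)


def success_rate(profiles_attempted: int, profiles_passing_qc: int) -> float | None:
    """Fraction of sequenced sCTCs passing the two-step QC (None for 0/0)."""
    if profiles_passing_qc > profiles_attempted:
        raise ValueError("passing cannot exceed attempted")
    if profiles_attempted < 0 or profiles_passing_qc < 0:
        raise ValueError("counts must be nonnegative")
    if profiles_attempted == 0:
        return None
    return profiles_passing_qc / profiles_attempted


def run_sample_test(
    sample_id: str,
    source: str,
    intensities,
    volume_ml: float,
    counts_by_cell: dict[str, np.ndarray],
    grid: BinGrid,
    pipeline_config: PipelineConfig = PipelineConfig(),
    decision_config: DecisionConfig = DecisionConfig(),
) -> SampleTest:
    """End-to-end single-sample test: sCTC call -> WGS profiling -> verdict.

    ``counts_by_cell`` holds bin counts for the cells that were retrieved
    for sequencing; only flagged cells with counts are profiled, and only
    when the density reaches the threshold (below it the sample is
    negative without sequencing, mirroring the clinical workflow).
    """
    call = (call_sctcs_ascites if source == "ascites" else call_sctcs_blood)(
        intensities, volume_ml=volume_ml
    )
    density = call.density_per_ml
    profiles: list[SegmentedProfile] = []
    if density >= decision_config.density_threshold(source):
        flagged = [c for c in call.flags.index[call.flags] if c in counts_by_cell]
        if decision_config.max_cells is not None:
            flagged = flagged[: decision_config.max_cells]
        for cell_id in flagged:
            profiles.append(
                profile_cell(counts_by_cell[cell_id], grid, pipeline_config, cell_id)
            )
    return classify_sample(sample_id, source, density, profiles, decision_config)
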