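"""Per-plate normalisation, QC and primary hit calling for a high-content
RNAi screen of DiI-LDL uptake.

The primary readout is a per-well mean centre fluorescence intensity.  Each
384-well plate is normalised independently with the robust z-score
``(x - median) / (1.4826 * MAD)`` computed over its *sample* wells; control
wells (non-targeting siRNA as negative, DNM2 siRNA as positive control) are
reserved for the Z'-factor plate-quality gate and for percent-effect
normalisation of follow-up screens.  Genes are called hits from the median
robust z across replicates at a two-sided threshold of 2.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePlateError,
    DivisionByZeroControlError,
    InsufficientControlsError,
)

log = logging.getLogger(__name__)

#: consistency factor making the MAD an unbiased s.d. estimate under normality
MAD_SCALE = 1.4826

ROLES = ("sample", "neg_control", "pos_control", "empty")
PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well geometry, rows A-P
PLATE_COLS = range(1, 25)


@dataclass
class Well:
    """One well of a screening plate.

    ``intensity`` is the mean centre DiI intensity in arbitrary fluorescence
    units; ``dead_fraction`` is the fraction of dead cells in the image.
    """

    plate_id: str
    row: str
    col: int
    role: str
    intensity: float
    cell_count: int = 0
    dead_fraction: float = 0.0
    gene_id: str | None = None
    sirna_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.role == "sample" and not self.gene_id:
            raise ValueError("sample wells must carry a gene_id")
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(f"intensity must be finite and >= 0, got {self.intensity}")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError(f"dead_fraction must lie in [0, 1], got {self.dead_fraction}")

    @property
    def label(self) -> str:
        return f"{self.row}{self.col:02d}"


@dataclass
class Plate:
    """A 384-well screening plate: wells plus the replicate it belongs to."""

    plate_id: str
    wells: list[Well]
    replicate_id: int = 1

    def __post_init__(self) -> None:
        for w in self.wells:
            if w.row not in PLATE_ROWS or w.col not in PLATE_COLS:
                raise ValueError(f"well {w.label} outside 384-well geometry (A-P, 1-24)")

    def intensities(self, role: str) -> np.ndarray:
        return np.array([w.intensity for w in self.wells if w.role == role], dtype=float)


@dataclass
class PlateQCReport:
    plate_id: str
    zprime: float
    accepted: bool
    n_wells_failed_qc: int


@dataclass
class GeneScore:
    gene_id: str
    z_by_replicate: list[float] = field(default_factory=list)
    z_aggregate: float = float("nan")
    qc_pass: bool = True
    hit: str = "none"  # {"decrease", "increase", "none"}


def robust_zscore(values: np.ndarray) -> np.ndarray:
    """Robust z-score of ``values`` against their own median and MAD.

    Raises :class:`DegeneratePlateError` when the MAD is zero *and* the data
    are not constant — a scale floor is never applied silently.  A fully
    constant input returns all-zero scores (zero deviation from the median).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError(f"need >= 8 finite sample intensities, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("sample intensities must be finite")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    dev = values - med
    if mad == 0.0:
        if np.all(dev == 0.0):
            return np.zeros_like(values)
        raise DegeneratePlateError(
            "plate MAD is zero while intensities vary; robust scale undefined"
        )
    return dev / (MAD_SCALE * mad)


def score_plate(plate: Plate) -> pd.DataFrame:
    """Robust z per sample well of one plate.

    Control wells are excluded from the median/MAD estimate and receive no
    score.  Returns a frame with well label, gene and the per-well z.
    """
    samples = [w for w in plate.wells if w.role == "sample"]
    z = robust_zscore(np.array([w.intensity for w in samples]))
    return pd.DataFrame(
        {
            "plate_id": plate.plate_id,
            "replicate": plate.replicate_id,
            "well": [w.label for w in samples],
            "gene_id": [w.gene_id for w in samples],
            "intensity": [w.intensity for w in samples],
            "cell_count": [w.cell_count for w in samples],
            "dead_fraction": [w.dead_fraction for w in samples],
            "z": z,
        }
    )


def zprime_factor(neg_intensities, pos_intensities) -> float:
    """Z'-factor 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg| (sample s.d.)."""
    neg = np.asarray(neg_intensities, dtype=float)
    pos = np.asarray(pos_intensities, dtype=float)
    neg = neg[np.isfinite(neg)]
    pos = pos[np.isfinite(pos)]
    if neg.size < 3 or pos.size < 3:
        raise InsufficientControlsError(
            f"need >= 3 finite control values per group, got {neg.size} neg / {pos.size} pos"
        )
    sep = abs(pos.mean() - neg.mean())
    if sep == 0.0:
        raise DivisionByZeroControlError("control group means coincide; Z' undefined")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def percent_effect(x, neg_mean: float, pos_mean: float):
    """Signal expressed as percent of the positive-control (DNM2) effect.

    0% at the negative-control level, 100% at the positive-control level;
    values outside [0, 100] are legitimate (weaker or stronger than DNM2).
    """
    if neg_mean == pos_mean:
        raise DivisionByZeroControlError("neg and pos control means coincide")
    return 100.0 * (np.asarray(x, dtype=float) - neg_mean) / (pos_mean - neg_mean)


def well_qc(cell_count: int, dead_fraction: float) -> bool:
    """Image QC: at least 100 cells and cell death not over 20%."""
    return cell_count >= 100 and dead_fraction <= 0.20


def plate_qc(plate: Plate, zprime_min: float = 0.2) -> PlateQCReport:
    """Plate acceptance: Z' strictly greater than ``zprime_min`` (0.2)."""
    zp = zprime_factor(plate.intensities("neg_control"), plate.intensities("pos_control"))
    n_failed = sum(
        1 for w in plate.wells if w.role == "sample" and not well_qc(w.cell_count, w.dead_fraction)
    )
    return PlateQCReport(plate.plate_id, zp, zp > zprime_min, n_failed)


def aggregate_and_call(
    scores: pd.DataFrame,
    threshold: float = 2.5,
    agg: str = "median",
    mode: str = "aggregate",
) -> pd.DataFrame:
    """Combine per-replicate robust z into one score per gene and call hits.

    Parameters
    ----------
    scores
        Long frame with columns ``gene_id``, ``replicate``, ``z`` (one row per
        surviving well score; QC-failed wells must be excluded upstream).
    threshold
        Two-sided hit threshold on the aggregated z (2.5).
    agg
        ``"median"`` (default, robust) or ``"mean"``.
    mode
        ``"aggregate"`` calls hits on the combined score; ``"any"`` calls a
        hit when any single replicate crosses the threshold (the alternative
        reading of the primary-screen hit count).

    Returns a frame with one row per gene: ``z_aggregate``, ``n_replicates``,
    ``qc_pass`` (False for genes with zero surviving replicates → unscorable,
    never a hit) and ``hit`` in {decrease, increase, none}.
    """
    if agg not in ("median", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    if mode not in ("aggregate", "any"):
        raise ValueError(f"unknown calling mode {mode!r}")

    rows = []
    for gene, grp in scores.groupby("gene_id", sort=True):
        z = grp["z"].to_numpy(dtype=float)
        z = z[np.isfinite(z)]
        if z.size == 0:
            rows.append((gene, float("nan"), 0, False, "none"))
            continue
        z_agg = float(np.median(z)) if agg == "median" else float(np.mean(z))
        if mode == "aggregate":
            basis = z_agg
            decrease = basis <= -threshold
            increase = basis >= threshold
        else:
            decrease = bool(np.any(z <= -threshold))
            increase = bool(np.any(z >= threshold))
            if decrease and increase:  # conflicting replicates: no call
                decrease = increase = False
        hit = "decrease" if decrease else ("increase" if increase else "none")
        rows.append((gene, z_agg, int(z.size), True, hit))
    return pd.DataFrame(
        rows, columns=["gene_id", "z_aggregate", "n_replicates", "qc_pass", "hit"]
    )


def run_screen(
    plates: list[Plate],
    threshold: float = 2.5,
    zprime_min: float = 0.2,
    agg: str = "median",
    mode: str = "aggregate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full primary-screen pipeline: plate QC → robust z → well QC → calling.

    Plates failing the Z' gate are dropped entirely; individual wells failing
    image QC are dropped before aggregation.  Returns ``(gene_scores,
    plate_reports)``.
    """
    reports = []
    kept = []
    for plate in plates:
        rep = plate_qc(plate, zprime_min=zprime_min)
        reports.append(rep)
        if not rep.accepted:
            log.warning("plate %s rejected: Z'=%.3f", plate.plate_id, rep.zprime)
            continue
        sc = score_plate(plate)
        ok = [well_qc(c, d) for c, d in zip(sc["cell_count"], sc["dead_fraction"])]
        kept.append(sc[np.asarray(ok)])
    plate_df = pd.DataFrame(
        [(r.plate_id, r.zprime, r.accepted, r.n_wells_failed_qc) for r in reports],
        columns=["plate_id", "zprime", "accepted", "n_wells_failed_qc"],
    )
    if not kept:
        return (
            pd.DataFrame(columns=["gene_id", "z_aggregate", "n_replicates", "qc_pass", "hit"]),
            plate_df,
        )
    scores = pd.concat(kept, ignore_index=True)
    return aggregate_and_call(scores, threshold=threshold, agg=agg, mode=mode), plate_df
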