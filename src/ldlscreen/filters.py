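"""Deconvolution and specificity filter cascade for primary screen hits.

Each candidate gene is re-tested with its four individual siRNAs, in
duplicate (set 1 and set 2), across follow-up assays:

- ``dil_ldl_eahy``   — DiI-LDL uptake in EA.hy926 (confirmation assay)
- ``tf_fitc_eahy``   — transferrin-FITC uptake (clathrin-cargo specificity)
- ``dil_ldl_ldlr_high`` / ``dil_ldl_ldlr_low`` — uptake under high vs low
  LDLR expression (LDLR-dependence exclusion)
- ``dil_ldl_huvec``  — re-confirmation in primary HUVEC

Values are percent inhibition relative to the positive-control (DNM2)
effect.  The rules, applied in cascade:

1. confirmed iff >= 2 siRNAs inhibit DiI-LDL uptake >= 50% in *both* sets;
2. transferrin-clean iff >= 2 siRNAs show < 30% Tf-FITC inhibition in both
   sets (by default at least one of them must also be DiI-active);
3. LDLR-independent unless >= 2 siRNAs show a >= 2-fold high/low ratio
   (either direction);
4. HUVEC-confirmed under the same rule as step 1 on the HUVEC assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ASSAYS = (
    "dil_ldl_eahy",
    "tf_fitc_eahy",
    "dil_ldl_huvec",
    "dil_ldl_ldlr_high",
    "dil_ldl_ldlr_low",
)

#: default cascade order (confirmation, specificity, LDLR exclusion, HUVEC)
DEFAULT_STAGE_ORDER = ("dil", "tf", "ldlr", "huvec")


@dataclass
class FilterVerdict:
    gene_id: str
    confirmed_dil: bool = False
    transferrin_clean: bool = False
    ldlr_independent: bool = False
    huvec_confirmed: bool = False
    n_active_sirnas: int = 0

    @property
    def final_hit(self) -> bool:
        return (
            self.confirmed_dil
            and self.transferrin_clean
            and self.ldlr_independent
            and self.huvec_confirmed
        )


def _duplicate_values(gene_df: pd.DataFrame, assay: str) -> dict[str, tuple[float, float]]:
    """Per-siRNA (set1, set2) percent-inhibition pairs for one assay.

    siRNAs with a missing duplicate are dropped (counted inactive) and
    logged, per the stated missing-data rule.
    """
    sub = gene_df[gene_df["assay"] == assay]
    out: dict[str, tuple[float, float]] = {}
    for sirna, grp in sub.groupby("sirna_id", sort=True):
        by_set = {int(s): float(v) for s, v in zip(grp["set_id"], grp["percent_inhibition"])}
        if 1 in by_set and 2 in by_set and np.isfinite(by_set[1]) and np.isfinite(by_set[2]):
            out[str(sirna)] = (by_set[1], by_set[2])
        else:
            log.warning(
                "gene %s siRNA %s assay %s: missing duplicate, counted inactive",
                gene_df["gene_id"].iloc[0] if len(gene_df) else "?", sirna, assay,
            )
    return out


def confirm_dil_uptake(
    gene_df: pd.DataFrame,
    assay: str = "dil_ldl_eahy",
    threshold: float = 50.0,
    min_active: int = 2,
) -> tuple[bool, int, set[str]]:
    """DiI-LDL confirmation: an siRNA is active iff inhibition >= ``threshold``
    in both sets; the gene is confirmed iff >= ``min_active`` siRNAs are
    active.  Returns (confirmed, n_active, active siRNA ids)."""
    pairs = _duplicate_values(gene_df, assay)
    active = {s for s, (a, b) in pairs.items() if a >= threshold and b >= threshold}
    return len(active) >= min_active, len(active), active


def transferrin_specificity(
    gene_df: pd.DataFrame,
    dil_active: set[str] | None = None,
    threshold: float = 30.0,
    min_clean: int = 2,
    min_overlap: int = 1,
) -> bool:
    """Specificity counter-screen: clean iff >= ``min_clean`` siRNAs show
    Tf-FITC inhibition strictly below ``threshold`` in both sets.

    When ``dil_active`` is given, at least ``min_overlap`` of the clean
    siRNAs must also be DiI-active (set ``min_overlap=0`` to evaluate the
    rule over all siRNAs independently of the confirmation assay).
    """
    pairs = _duplicate_values(gene_df, "tf_fitc_eahy")
    clean = {s for s, (a, b) in pairs.items() if a < threshold and b < threshold}
    if len(clean) < min_clean:
        return False
    if dil_active and min_overlap > 0:  # vacuous when no siRNA was DiI-active
        return len(clean & dil_active) >= min_overlap
    return True


def ldlr_independence(
    gene_df: pd.DataFrame, fold: float = 2.0, min_dependent: int = 2
) -> bool:
    """LDLR-dependence exclusion.

    Per siRNA, the ratio of percent effect between LDLR-high and LDLR-low
    conditions is computed; a gene is LDLR-*dependent* (returns False) iff
    >= ``min_dependent`` siRNAs show a >= ``fold`` difference in either
    direction (ratio >= fold or <= 1/fold).  A zero denominator is treated
    as a >= fold difference and logged.
    """
    high = _duplicate_mean(gene_df, "dil_ldl_ldlr_high")
    low = _duplicate_mean(gene_df, "dil_ldl_ldlr_low")
    n_dep = 0
    for sirna in sorted(set(high) & set(low)):
        h, lo = high[sirna], low[sirna]
        if lo == 0.0:
            log.warning("gene %s siRNA %s: zero LDLR-low effect, treated as >=%g-fold",
                        gene_df["gene_id"].iloc[0] if len(gene_df) else "?", sirna, fold)
            n_dep += 1
            continue
        ratio = h / lo
        if ratio >= fold or ratio <= 1.0 / fold:
            n_dep += 1
    return n_dep < min_dependent


def _duplicate_mean(gene_df: pd.DataFrame, assay: str) -> dict[str, float]:
    """Mean of the two set values per siRNA; single-set values pass through."""
    sub = gene_df[gene_df["assay"] == assay]
    return {
        str(sirna): float(grp["percent_inhibition"].mean())
        for sirna, grp in sub.groupby("sirna_id", sort=True)
    }


def run_cascade(
    records: pd.DataFrame,
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER,
    dil_threshold: float = 50.0,
    tf_threshold: float = 30.0,
    ldlr_fold: float = 2.0,
    tf_min_overlap: int = 1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four filters in ``stage_order`` and count survivors per stage.

    ``records`` is the long-format deconvolution table (columns ``gene_id``,
    ``sirna_id``, ``assay``, ``set_id``, ``percent_inhibition``).  Genes
    missing an entire assay fail (and are logged) at that stage.  Returns a
    verdict frame (one row per gene) and an ordered stage-count dict whose
    first entry is the number of input genes.
    """
    if set(stage_order) != set(DEFAULT_STAGE_ORDER):
        raise ValueError(f"stage_order must be a permutation of {DEFAULT_STAGE_ORDER}")
    required = {"gene_id", "sirna_id", "assay", "set_id", "percent_inhibition"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")

    verdicts: list[FilterVerdict] = []
    counts: dict[str, int] = {"input": records["gene_id"].nunique()}
    surviving: dict[str, FilterVerdict] = {}

    for gene, gene_df in records.groupby("gene_id", sort=True):
        v = FilterVerdict(gene_id=str(gene))
        confirmed, n_active, active = confirm_dil_uptake(gene_df, threshold=dil_threshold)
        v.confirmed_dil, v.n_active_sirnas = confirmed, n_active
        v.transferrin_clean = transferrin_specificity(
            gene_df, dil_active=active, threshold=tf_threshold, min_overlap=tf_min_overlap
        )
        v.ldlr_independent = ldlr_independence(gene_df, fold=ldlr_fold)
        huvec_ok, _, _ = confirm_dil_uptake(
            gene_df, assay="dil_ldl_huvec", threshold=dil_threshold
        )
        v.huvec_confirmed = huvec_ok
        verdicts.append(v)
        surviving[str(gene)] = v

    stage_attr = {
        "dil": "confirmed_dil",
        "tf": "transferrin_clean",
        "ldlr": "ldlr_independent",
        "huvec": "huvec_confirmed",
    }
    alive = set(surviving)
    for stage in stage_order:
        alive = {g for g in alive if getattr(surviving[g], stage_attr[stage])}
        counts[stage] = len(alive)

    frame = pd.DataFrame(
        [
            (
                v.gene_id,
                v.confirmed_dil,
                v.transferrin_clean,
                v.ldlr_independent,
                v.huvec_confirmed,
                v.final_hit,
                v.n_active_sirnas,
            )
            for v in verdicts
        ],
        columns=[
            "gene_id",
            "confirmed_dil",
            "transferrin_clean",
            "ldlr_independent",
            "huvec_confirmed",
            "final_hit",
            "n_active_sirnas",
        ],
    )
    return frame, counts
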