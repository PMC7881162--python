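"""Percent-spliced-in quantification from capillary-electrophoresis peaks.

PSI = L/(L+S) where L and S are the measured concentrations of the long
(inclusion) and short (exclusion) amplicons. For each assay (primer pair)
the isoform pair is chosen once, as the two most abundant amplicon sizes
summed over all samples of the assay.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd


class UncallableAssayError(ValueError):
    """Fewer than two distinct amplicon sizes with signal for an assay."""


class UndefinedPsiError(ValueError):
    """Both isoform concentrations are zero."""


def select_isoforms(peaks: pd.DataFrame) -> Tuple[float, float]:
    """Pick (long_size, short_size) for one assay across all its samples.

    Concentrations are totalled per amplicon size over every sample; the
    two largest totals win. Ties on total are broken toward the larger
    size. Long is the larger size of the chosen pair.
    """
    totals = peaks.groupby("size_bp")["concentration"].sum()
    totals = totals[totals > 0]
    if len(totals) < 2:
        raise UncallableAssayError(
            f"assay needs >=2 distinct amplicon sizes with signal, got {len(totals)}")
    ranked = totals.reset_index().sort_values(
        ["concentration", "size_bp"], ascending=[False, False])
    top2 = ranked["size_bp"].iloc[:2].to_numpy(dtype=float)
    return float(max(top2)), float(min(top2))


def compute_psi(long_conc: float, short_conc: float) -> float:
    if long_conc < 0 or short_conc < 0:
        raise ValueError("concentrations must be non-negative")
    total = long_conc + short_conc
    if total == 0:
        raise UndefinedPsiError("PSI undefined: L + S = 0")
    return long_conc / total


def psi_table(peaks: pd.DataFrame, control_condition: str
              ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """PSI per assay x sample plus dPSI versus the control condition.

    Returns ``(psi, dpsi)`` DataFrames indexed by assay with one column per
    sample; entries are NaN where both isoform peaks are absent. dPSI is
    PSI minus the mean control-condition PSI of the assay.
    """
    psi_rows = {}
    conditions = peaks.drop_duplicates(["sample_id"]).set_index(
        "sample_id")["condition"]
    for assay_id, assay_peaks in peaks.groupby("assay_id"):
        long_size, short_size = select_isoforms(assay_peaks)
        row = {}
        for sample_id, sp in assay_peaks.groupby("sample_id"):
            long_c = sp.loc[sp["size_bp"] == long_size, "concentration"].sum()
            short_c = sp.loc[sp["size_bp"] == short_size, "concentration"].sum()
            try:
                row[sample_id] = compute_psi(float(long_c), float(short_c))
            except UndefinedPsiError:
                row[sample_id] = np.nan
        psi_rows[assay_id] = row
    psi = pd.DataFrame(psi_rows).T.sort_index()
    psi.index.name = "assay_id"

    control_samples = conditions[conditions == control_condition].index
    missing = set(psi.columns) & set(control_samples)
    if not missing:
        raise ValueError(
            f"control condition {control_condition!r} has no samples in the table")
    control_mean = psi[[c for c in psi.columns if c in set(control_samples)]].mean(axis=1)
    dpsi = psi.sub(control_mean, axis=0)
    return psi, dpsi
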