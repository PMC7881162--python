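"""Baseline splicing-response signature.

From a baseline (untreated) PSI matrix and good/poor responder labels, a
signature event must (1) be quantified in at least 75% of all samples,
(2) vary less within groups than between them (intra-group sd < inter-group
sd), and (3) separate the group means by at least 0.20 PSI. Events are
ranked by |dPSI| (good minus poor), descending.

The inter-group sd is the standard deviation of the two group means
(= |dPSI|/sqrt(2)); the intra-group sd is the root of the average of the
two within-group variances. Both are reported on every selected event so
the criterion is auditable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig


@dataclass
class SignatureEvent:
    event_id: str
    n_quantified: int
    fraction_quantified: float
    mean_good: float
    mean_poor: float
    sd_good: float
    sd_poor: float
    intra: float
    inter: float
    dpsi: float  # mean_good - mean_poor

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.mean_good + self.mean_poor)


def derive_signature(psi: pd.DataFrame, labels: pd.Series,
                     config: Optional[PipelineConfig] = None,
                     rank_key: str = "abs_dpsi",
                     ) -> Tuple[List[SignatureEvent], Dict[str, str]]:
    """Select and rank signature events; also report per-event skip reasons.

    ``psi`` is events x samples with NaN for unquantified entries; ``labels``
    maps sample id to 'good' or 'poor'. Returns ``(signature, skipped)``.
    """
    cfg = config or PipelineConfig()
    labels = labels.reindex(psi.columns)
    if labels.isna().any():
        missing = list(psi.columns[labels.isna()])
        raise ValueError(f"samples without responder label: {missing}")
    good_cols = psi.columns[labels == "good"]
    poor_cols = psi.columns[labels == "poor"]
    if len(good_cols) < 2 or len(poor_cols) < 2:
        raise ValueError("need >= 2 samples per responder group")

    n_samples = psi.shape[1]
    selected: List[SignatureEvent] = []
    skipped: Dict[str, str] = {}
    quant = psi.notna()
    for event_id in psi.index:
        row = psi.loc[event_id]
        n_q = int(quant.loc[event_id].sum())
        frac = n_q / n_samples
        if frac < cfg.min_fraction_quantified:
            continue
        g = row[good_cols].dropna()
        p = row[poor_cols].dropna()
        if len(g) < 2 or len(p) < 2:
            skipped[event_id] = "fewer than 2 quantified samples in a group"
            continue
        mean_g, mean_p = float(g.mean()), float(p.mean())
        sd_g, sd_p = float(g.std(ddof=1)), float(p.std(ddof=1))
        intra = math.sqrt(0.5 * (sd_g ** 2 + sd_p ** 2))
        inter = float(np.std([mean_g, mean_p], ddof=1))
        dpsi = mean_g - mean_p
        if intra >= inter:
            continue
        if abs(dpsi) < cfg.min_signature_dpsi:
            continue
        selected.append(SignatureEvent(
            event_id=str(event_id), n_quantified=n_q, fraction_quantified=frac,
            mean_good=mean_g, mean_poor=mean_p, sd_good=sd_g, sd_poor=sd_p,
            intra=intra, inter=inter, dpsi=dpsi))

    if rank_key == "abs_dpsi":
        selected.sort(key=lambda ev: (-abs(ev.dpsi), ev.event_id))
    elif rank_key == "inter_over_intra":
        selected.sort(key=lambda ev: (-(ev.inter / ev.intra if ev.intra else
                                        math.inf), ev.event_id))
    else:
        raise ValueError(f"unknown rank key {rank_key!r}")
    return selected, skipped


def signature_counts(signature: Sequence[SignatureEvent],
                     event_genes: Optional[Dict[str, str]] = None
                     ) -> Tuple[int, int, int, int]:
    """(n_total, n_dpsi_positive, n_dpsi_negative, n_distinct_genes).

    Without an event->gene map, each event counts as its own gene.
    """
    n_pos = sum(1 for ev in signature if ev.dpsi > 0)
    n_neg = sum(1 for ev in signature if ev.dpsi < 0)
    if event_genes is None:
        n_genes = len({ev.event_id for ev in signature})
    else:
        n_genes = len({event_genes.get(ev.event_id, ev.event_id)
                       for ev in signature})
    return len(signature), n_pos, n_neg, n_genes


def score_sample(psi_vector: pd.Series,
                 signature: Sequence[SignatureEvent]) -> float:
    """Signature score for one sample; positive predicts a good responder.

    Mean over quantified signature events of
    sign(dpsi) * (psi - midpoint(mean_good, mean_poor)).
    """
    terms = []
    for ev in signature:
        v = psi_vector.get(ev.event_id)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        terms.append(math.copysign(1.0, ev.dpsi) * (float(v) - ev.midpoint))
    if not terms:
        raise ValueError("no signature event quantified in the sample")
    return float(np.mean(terms))


def signature_to_frame(signature: Sequence[SignatureEvent]) -> pd.DataFrame:
    cols = ["event_id", "n_quantified", "fraction_quantified", "mean_good",
            "mean_poor", "sd_good", "sd_poor", "intra", "inter", "dpsi"]
    return pd.DataFrame([{c: getattr(ev, c) for c in cols} for ev in signature],
                        columns=cols)
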