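"""Dose-response scoring: normalization, AAC, EC50 Hill fits, sensitivity
calls and responder labels.

The area above the curve (AAC) is the trapezoidal integral of
(1 - response) over log10(dose) across the observed points, normalized by
the tested log-dose range, so a fully resistant line scores 0 and a fully
killed one scores 1. Responses are fractions of the DMSO control, clipped
to [0,1] before integration. A sample is called sensitive when its fitted
EC50 falls below the configured threshold (default 250 nM).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats


@dataclass
class DoseResponseSeries:
    """Replicate-averaged fraction-of-control response at each dose (molar)."""

    sample_id: str
    compound: str
    doses: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.doses.size < 2:
            raise ValueError("a dose-response series needs >= 2 doses")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.response < 0):
            raise ValueError("responses must be >= 0")


@dataclass
class DoseResponseSummary:
    sample_id: str
    compound: str
    aac: float
    ec50: Optional[float]          # molar; None when flat / at the bound
    hill: Optional[float] = None
    e_inf: Optional[float] = None
    sensitive: bool = False
    responder_label: Optional[str] = None
    diagnostics: Dict[str, object] = field(default_factory=dict)


def select_timepoint(dmso_series: Sequence[Tuple[np.ndarray, np.ndarray]]
                     ) -> float:
    """Timepoint at which dose-response is read out.

    For each DMSO control well (``(times, confluence)`` pair, confluence in
    percent), take the first time at which confluence reaches 100% (or the
    last observed time if it never does, with a warning). Return the 95th
    percentile (nearest-rank) of those times, snapped to the nearest
    observed timepoint at or before it.
    """
    if not dmso_series:
        raise ValueError("no DMSO control series supplied")
    crossings = []
    all_times: set = set()
    never = 0
    for times, conf in dmso_series:
        times = np.asarray(times, dtype=float)
        conf = np.asarray(conf, dtype=float)
        all_times.update(times.tolist())
        hit = np.nonzero(conf >= 100.0)[0]
        if hit.size:
            crossings.append(times[hit[0]])
        else:
            crossings.append(times[-1])
            never += 1
    if never == len(dmso_series):
        warnings.warn("no DMSO well reached 100% confluence; "
                      "using last observed timepoint")
    crossings.sort()
    rank = math.ceil(0.95 * len(crossings))       # nearest-rank percentile
    t95 = crossings[rank - 1]
    observed = np.array(sorted(all_times))
    at_or_before = observed[observed <= t95]
    return float(at_or_before[-1]) if at_or_before.size else float(observed[0])


def normalize(raw: np.ndarray, dmso_mean: float
              ) -> Tuple[np.ndarray, bool]:
    """Fraction-of-control responses, clipped to [0,1] for AAC.

    Returns ``(response, clipped)`` where ``clipped`` records whether any
    readout exceeded the control mean.
    """
    if dmso_mean <= 0:
        raise ValueError("DMSO control mean must be positive")
    response = np.asarray(raw, dtype=float) / dmso_mean
    clipped = bool(np.any(response > 1.0))
    return np.clip(response, 0.0, 1.0), clipped


def compute_aac(series: DoseResponseSeries) -> float:
    """Normalized area above the response curve over log10(dose), in [0,1]."""
    x = np.log10(series.doses)
    y = 1.0 - np.clip(series.response, 0.0, 1.0)
    area = np.trapezoid(y, x)
    return float(area / (x[-1] - x[0]))


def _hill(dose: np.ndarray, log10_ec50: float, hill: float, e_inf: float
          ) -> np.ndarray:
    return e_inf + (1.0 - e_inf) / (1.0 + (dose / 10.0 ** log10_ec50) ** hill)


def fit_hill(series: DoseResponseSeries, flat_range: float = 0.1
             ) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """Least-squares Hill fit with the top fixed at 1.

    Returns ``(ec50, hill, e_inf)``; EC50 is None for flat curves
    (response range < ``flat_range``), fits that hit the upper dose bound
    (EC50 beyond 10x the largest tested dose), or non-convergence.
    """
    if series.doses.size < 4:
        raise ValueError("Hill fit needs >= 4 doses")
    y = np.clip(series.response, 0.0, None)
    if float(np.max(y) - np.min(y)) < flat_range:
        return None, None, None
    lo = math.log10(series.doses[0]) - 1.0
    hi = math.log10(series.doses[-1]) + 1.0
    # initialize EC50 at the dose closest to the half-effect level
    half = (1.0 + float(np.min(y))) / 2.0
    x0 = float(np.log10(series.doses[np.argmin(np.abs(y - half))]))
    p0 = [min(max(x0, lo), hi), 1.0, min(max(float(np.min(y)), 0.0), 1.0)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _hill, series.doses, y, p0=p0,
                bounds=([lo, 0.1, 0.0], [hi, 10.0, 1.0]),
                maxfev=50000, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    except RuntimeError:
        return None, None, None
    log10_ec50, hill, e_inf = (float(v) for v in popt)
    if log10_ec50 >= hi - 1e-6:
        return None, hill, e_inf
    return 10.0 ** log10_ec50, hill, e_inf


def summarize(series: DoseResponseSeries) -> DoseResponseSummary:
    ec50, hill, e_inf = fit_hill(series)
    return DoseResponseSummary(
        sample_id=series.sample_id, compound=series.compound,
        aac=compute_aac(series), ec50=ec50, hill=hill, e_inf=e_inf)


def classify_and_label(summaries: Sequence[DoseResponseSummary],
                       ec50_sensitive: float = 250e-9,
                       aac_threshold: Optional[float] = None
                       ) -> Sequence[DoseResponseSummary]:
    """Sensitivity flags (EC50 < threshold) and good/poor responder labels.

    The responder split defaults to the cohort median AAC: ``good`` when
    AAC >= threshold, ``poor`` otherwise. Mutates and returns ``summaries``.
    """
    if aac_threshold is None:
        aac_threshold = float(np.median([s.aac for s in summaries]))
    for s in summaries:
        s.sensitive = s.ec50 is not None and s.ec50 < ec50_sensitive
        s.responder_label = "good" if s.aac >= aac_threshold else "poor"
    return summaries


def compound_correlation(aac_a: Sequence[float], aac_b: Sequence[float]
                         ) -> Tuple[float, float]:
    """Pearson correlation (r, two-sided p) of paired per-sample AACs."""
    a = np.asarray(aac_a, dtype=float)
    b = np.asarray(aac_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired AAC vectors with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in an AAC vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
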