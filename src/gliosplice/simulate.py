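"""Synthetic-data generators with planted ground truth.

Each generator emulates one input shape of the pipeline at the study's own
design points: the nine half-log compound doses from 3 nM to 30 uM, the
ten limiting-dilution cell numbers (2000 down to 4, six wells each), the
five splicing-event classes, and a good/poor responder cohort. All
generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseSeries
from .events import EVENT_CLASSES, SpliceEvent
from .lda import LdaDesign

# nine half-log doses, 3 nM .. 30 uM, in molar
DEFAULT_DOSES_M = np.array([3e-9, 1e-8, 3e-8, 1e-7, 3e-7, 1e-6, 3e-6, 1e-5, 3e-5])
# limiting-dilution seeding scheme: cells per well, six replicates each
DEFAULT_LDA_DOSES = np.array([2000, 1000, 500, 250, 125, 63, 31, 16, 8, 4])
DEFAULT_LDA_WELLS = 6


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, for recovery tests."""

    signature_event_ids: Set[str] = field(default_factory=set)
    shared_significant_event_ids: Set[str] = field(default_factory=set)
    true_psi_means: Dict[str, Dict[str, float]] = field(default_factory=dict)
    true_ec50: Dict[str, float] = field(default_factory=dict)
    true_frequency: Dict[str, float] = field(default_factory=dict)
    enriched_gene_ids: Set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Per-sample differential-splicing tables
# ---------------------------------------------------------------------------

_FILTER_BREAKS = ("p_value", "no_inclusion", "no_exclusion",
                  "low_total", "small_dpsi")


def _planted_event(rng: np.random.Generator, event_id: str, chrom: str,
                   start: int, length: int, strand: str, klass: str,
                   sign: float) -> SpliceEvent:
    p = 0.05 * rng.beta(0.5, 5.0)          # concentrated near 0, <= 0.05
    inc = int(rng.integers(5, 100))
    exc = int(rng.integers(5, 100))
    mag = rng.uniform(0.10, 0.60)
    psi_control = rng.uniform(0.0, 1.0 - mag) if sign > 0 else rng.uniform(mag, 1.0)
    psi_treated = psi_control + sign * mag
    return SpliceEvent(event_id=event_id, gene=f"GENE_{event_id}",
                       event_class=klass, chrom=chrom, start=start,
                       end=start + length, strand=strand, p_value=float(p),
                       inclusion_reads=inc, exclusion_reads=exc,
                       psi_treated=float(psi_treated),
                       psi_control=float(psi_control))


def _background_event(rng: np.random.Generator, event_id: str) -> SpliceEvent:
    """An event guaranteed to fail at least one significance filter."""
    chrom = f"chr{int(rng.integers(1, 23))}"
    start = int(rng.integers(10_000, 100_000_000))
    length = int(rng.integers(30, 3000))
    strand = "+" if rng.random() < 0.5 else "-"
    klass = str(rng.choice(EVENT_CLASSES))
    # start from a passing draw, then break one filter at random
    p = float(0.05 * rng.beta(0.5, 5.0))
    inc = int(rng.integers(5, 100))
    exc = int(rng.integers(5, 100))
    dpsi = float(rng.uniform(-0.6, 0.6))
    if abs(dpsi) < 0.10:
        dpsi = float(np.sign(dpsi) or 1.0) * rng.uniform(0.10, 0.60)
    violation = rng.choice(_FILTER_BREAKS)
    if violation == "p_value":
        p = float(rng.uniform(0.05 + 1e-9, 1.0))
    elif violation == "no_inclusion":
        inc = 0
        exc = max(exc, 10)
    elif violation == "no_exclusion":
        exc = 0
        inc = max(inc, 10)
    elif violation == "low_total":
        inc = int(rng.integers(1, 5))
        exc = int(rng.integers(1, 9 - inc))
    else:
        dpsi = float(rng.uniform(-0.0999, 0.0999))
    psi_control = float(rng.uniform(max(0.0, -dpsi), min(1.0, 1.0 - dpsi)))
    return SpliceEvent(event_id=event_id, gene=f"GENE_{event_id}",
                       event_class=klass, chrom=chrom, start=start,
                       end=start + length, strand=strand, p_value=p,
                       inclusion_reads=inc, exclusion_reads=exc,
                       psi_treated=float(psi_control + dpsi),
                       psi_control=psi_control)


def gen_ase_tables(n_events: int, n_samples: int,
                   frac_shared_significant: float, seed: int
                   ) -> Tuple[Dict[str, List[SpliceEvent]], PlantedTruth]:
    """Per-sample event tables with a planted shared-significant subset.

    Planted events pass every significance filter in every sample, share
    coordinates (and class/strand) across samples, and carry |dPSI| >= 0.10;
    background events fail at least one filter at random.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0.0 <= frac_shared_significant <= 1.0:
        raise ValueError("frac_shared_significant must lie in [0,1]")
    rng = np.random.default_rng(seed)
    n_planted = int(round(frac_shared_significant * n_events))
    truth = PlantedTruth()
    tables: Dict[str, List[SpliceEvent]] = {
        f"sample{i + 1}": [] for i in range(n_samples)}

    planted_specs = []
    for j in range(n_planted):
        event_id = f"planted_{j:05d}"
        spec = dict(
            event_id=event_id,
            chrom=f"chr{int(rng.integers(1, 23))}",
            start=int(rng.integers(10_000, 100_000_000)),
            length=int(rng.integers(60, 3000)),
            strand="+" if rng.random() < 0.5 else "-",
            klass=str(rng.choice(EVENT_CLASSES)),
            sign=1.0 if rng.random() < 0.5 else -1.0,
        )
        planted_specs.append(spec)
        truth.shared_significant_event_ids.add(event_id)

    for name in tables:
        for spec in planted_specs:
            tables[name].append(_planted_event(rng, **spec))
        for j in range(n_events - n_planted):
            tables[name].append(_background_event(rng, f"{name}_bg_{j:05d}"))
    return tables, truth


# ---------------------------------------------------------------------------
# Baseline PSI matrix for the signature
# ---------------------------------------------------------------------------

def gen_baseline_psi(n_events: int, n_good: int, n_poor: int,
                     n_signature: int, delta: float, within_sd: float,
                     missing_rate: float, seed: int,
                     frac_positive: float = 0.5,
                     ) -> Tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Baseline PSI matrix with planted group-separated signature events.

    Signature events have good/poor group means separated by ``delta``
    (sign per event, a ``frac_positive`` share with higher inclusion in
    good responders); all other events share one mean. Gaussian noise with
    sd ``within_sd`` is clipped to [0,1]; entries go missing independently
    at ``missing_rate``. Returns ``(psi_matrix, labels, truth)``.
    """
    if n_signature > n_events:
        raise ValueError("n_signature must be <= n_events")
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must lie in (0,1]")
    if within_sd < 0:
        raise ValueError("within_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples = [f"good{i + 1}" for i in range(n_good)] + \
              [f"poor{i + 1}" for i in range(n_poor)]
    labels = pd.Series(["good"] * n_good + ["poor"] * n_poor, index=samples,
                       name="label")
    truth = PlantedTruth()

    means = np.empty((n_events, 2))  # columns: good, poor
    event_ids = []
    n_positive = int(round(frac_positive * n_signature))
    for i in range(n_events):
        if i < n_signature:
            event_id = f"sig_{i:05d}"
            sign = 1.0 if i < n_positive else -1.0
            center = rng.uniform(delta / 2, 1.0 - delta / 2)
            good_mean = center + sign * delta / 2
            poor_mean = center - sign * delta / 2
            truth.signature_event_ids.add(event_id)
        else:
            event_id = f"bg_{i:05d}"
            good_mean = poor_mean = rng.uniform(0.0, 1.0)
        means[i] = (good_mean, poor_mean)
        event_ids.append(event_id)
        truth.true_psi_means[event_id] = {"good": float(good_mean),
                                          "poor": float(poor_mean)}

    group_idx = np.array([0] * n_good + [1] * n_poor)
    base = means[:, group_idx]
    noise = rng.normal(0.0, within_sd, size=base.shape) if within_sd else 0.0
    values = np.clip(base + noise, 0.0, 1.0)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)
    psi = pd.DataFrame(values, index=event_ids, columns=samples)
    psi.index.name = "event_id"
    return psi, labels, truth


# ---------------------------------------------------------------------------
# Dose-response, proteome, limiting dilution, amplicons
# ---------------------------------------------------------------------------

def gen_dose_response(ec50: float, hill: float, e_inf: float, noise_sd: float,
                      seed: int, sample_id: str = "sim", compound: str = "drug",
                      n_replicates: int = 3,
                      doses: Optional[np.ndarray] = None
                      ) -> Tuple[DoseResponseSeries, PlantedTruth]:
    """Hill-curve response at the nine half-log doses with Gaussian noise.

    response = e_inf + (1 - e_inf)/(1 + (dose/ec50)^hill) + N(0, noise_sd),
    averaged over replicates and floored at 0.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if not 0.0 <= e_inf <= 1.0:
        raise ValueError("e_inf must lie in [0,1]")
    rng = np.random.default_rng(seed)
    d = DEFAULT_DOSES_M if doses is None else np.asarray(doses, dtype=float)
    clean = e_inf + (1.0 - e_inf) / (1.0 + (d / ec50) ** hill)
    reps = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, d.size))
    response = np.clip(reps.mean(axis=0), 0.0, None)
    truth = PlantedTruth(true_ec50={sample_id: float(ec50)})
    return DoseResponseSeries(sample_id=sample_id, compound=compound,
                              doses=d, response=response), truth


def gen_proteome(n_universe: int, ase_genes: Set[str],
                 frac_depleted_in_set: float, seed: int,
                 null_sd: float = 0.5, depletion_shift: float = 2.0,
                 undetected_rate: float = 0.05
                 ) -> Tuple[pd.DataFrame, PlantedTruth]:
    """Protein fold-change table with a planted depleted subset of a gene set.

    log2FC is drawn from N(0, ``null_sd``); a ``frac_depleted_in_set``
    share of ``ase_genes`` is shifted down by ``depletion_shift`` so those
    genes concentrate in the bottom ranks. Undetected rows carry NaN
    log2FC (assigned 0 downstream).
    """
    if len(ase_genes) > n_universe:
        raise ValueError("gene set larger than universe")
    rng = np.random.default_rng(seed)
    ase_sorted = sorted(ase_genes)
    other = [f"P{i:05d}" for i in range(n_universe - len(ase_sorted))]
    genes = ase_sorted + other
    lfc = rng.normal(0.0, null_sd, size=n_universe)
    n_dep = int(round(frac_depleted_in_set * len(ase_sorted)))
    depleted = list(rng.choice(ase_sorted, size=n_dep, replace=False)) if n_dep else []
    dep_set = set(depleted)
    for i, g in enumerate(genes):
        if g in dep_set:
            lfc[i] -= depletion_shift
    detected = rng.random(n_universe) >= undetected_rate
    table = pd.DataFrame({
        "gene": genes,
        "log2fc": np.where(detected, lfc, np.nan),
        "detected": detected,
    })
    table = table.sample(frac=1.0, random_state=int(seed) % (2 ** 31)
                         ).reset_index(drop=True)
    return table, PlantedTruth(enriched_gene_ids=dep_set)


def gen_lda(true_f: float, seed: int, arm: str = "sim",
            doses: Optional[np.ndarray] = None, wells_per_dose: int = DEFAULT_LDA_WELLS
            ) -> Tuple[LdaDesign, PlantedTruth]:
    """Bernoulli well positivity, P(positive) = 1 - exp(-f * cells)."""
    if not 0.0 < true_f <= 1.0:
        raise ValueError("true_f must lie in (0,1]")
    rng = np.random.default_rng(seed)
    d = DEFAULT_LDA_DOSES if doses is None else np.asarray(doses)
    p_pos = 1.0 - np.exp(-true_f * d.astype(float))
    positives = rng.binomial(wells_per_dose, p_pos)
    design = LdaDesign(arm=arm, doses=d,
                       wells=np.full(d.size, wells_per_dose),
                       positives=positives)
    return design, PlantedTruth(true_frequency={arm: float(true_f)})


def gen_amplicons(true_psi: float, total_conc: float, n_noise_peaks: int,
                  seed: int, assay_id: str = "assay1", sample_id: str = "s1",
                  condition: str = "treated", long_size: float = 300.0,
                  short_size: float = 200.0) -> pd.DataFrame:
    """Amplicon peak table: long = psi*total, short = (1-psi)*total, plus
    spurious peaks each below 10% of the total concentration."""
    if not 0.0 <= true_psi <= 1.0:
        raise ValueError("true_psi must lie in [0,1]")
    if total_conc <= 0:
        raise ValueError("total_conc must be positive")
    rng = np.random.default_rng(seed)
    rows = [
        {"assay_id": assay_id, "sample_id": sample_id, "condition": condition,
         "size_bp": long_size, "concentration": true_psi * total_conc},
        {"assay_id": assay_id, "sample_id": sample_id, "condition": condition,
         "size_bp": short_size, "concentration": (1.0 - true_psi) * total_conc},
    ]
    used = {long_size, short_size}
    for _ in range(n_noise_peaks):
        size = float(rng.integers(50, 1000))
        while size in used:
            size = float(rng.integers(50, 1000))
        used.add(size)
        rows.append({"assay_id": assay_id, "sample_id": sample_id,
                     "condition": condition, "size_bp": size,
                     "concentration": float(rng.uniform(0.0, 0.1) * total_conc)})
    return pd.DataFrame(rows)
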