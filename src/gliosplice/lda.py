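"""Limiting-dilution analysis under the single-hit Poisson model.

A well seeded with d cells is negative with probability exp(-f*d), where f
is the frequency of sphere-initiating cells. Equivalently, well positivity
follows a binomial GLM with complementary log-log link and log(dose) as an
offset; the intercept is log f. Confidence intervals are Wald on log f,
exponentiated. Group inequality is a likelihood-ratio chi-square between a
shared-frequency fit and per-group frequencies; single-hit adequacy frees
the log(dose) slope and tests slope = 1 (Wald).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class NonIdentifiableError(ValueError):
    """All wells positive or all negative: f cannot be estimated.

    Re-plate with a wider dilution range (or score later/earlier) so that
    both positive and negative wells are observed.
    """


@dataclass
class LdaDesign:
    arm: str
    doses: np.ndarray      # cells per well
    wells: np.ndarray      # wells per dose
    positives: np.ndarray  # positive wells per dose

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.wells = np.asarray(self.wells, dtype=int)
        self.positives = np.asarray(self.positives, dtype=int)
        if len(set(self.doses.tolist())) != self.doses.size:
            raise ValueError("doses must be distinct")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(self.positives < 0) or np.any(self.positives > self.wells):
            raise ValueError("positives must lie in [0, wells] at each dose")

    def check_identifiable(self) -> None:
        if self.positives.sum() == 0:
            raise NonIdentifiableError(
                f"arm {self.arm!r}: no positive wells at any dose")
        if (self.positives == self.wells).all():
            raise NonIdentifiableError(
                f"arm {self.arm!r}: every well positive at every dose")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "arm": self.arm, "cells_per_well": self.doses.astype(int),
            "wells": self.wells, "positive_wells": self.positives})


@dataclass
class LdaFit:
    arm: str
    log_f: float
    f: float
    ci95: Tuple[float, float]
    deviance: float

    @property
    def one_in(self) -> float:
        """Frequency expressed as '1 in N cells'."""
        return 1.0 / self.f


def _glm_endog_exog(designs: Sequence[LdaDesign]):
    frames = [d.to_frame() for d in designs]
    df = pd.concat(frames, ignore_index=True)
    endog = np.column_stack([df["positive_wells"],
                             df["wells"] - df["positive_wells"]])
    offset = np.log(df["cells_per_well"].to_numpy(dtype=float))
    return df, endog, offset


def _fit_cloglog(endog, exog, offset=None):
    model = sm.GLM(endog, exog,
                   family=sm.families.Binomial(link=sm.families.links.CLogLog()),
                   offset=offset)
    with np.errstate(divide="ignore", invalid="ignore"):  # saturated designs
        return model.fit(maxiter=200, tol=1e-10)


def fit_single_hit(design: LdaDesign) -> LdaFit:
    """Maximum-likelihood single-hit frequency with a Wald 95% CI."""
    design.check_identifiable()
    _, endog, offset = _glm_endog_exog([design])
    exog = np.ones((endog.shape[0], 1))
    res = _fit_cloglog(endog, exog, offset=offset)
    log_f = float(res.params[0])
    se = float(res.bse[0])
    z = stats.norm.ppf(0.975)
    return LdaFit(
        arm=design.arm, log_f=log_f, f=math.exp(log_f),
        ci95=(math.exp(log_f - z * se), math.exp(log_f + z * se)),
        deviance=float(res.deviance))


def test_frequency_difference(*designs: LdaDesign
                              ) -> Tuple[float, int, float]:
    """Likelihood-ratio test of equal frequency across arms.

    Returns ``(chi2, df, p)`` with df = number of arms - 1.
    """
    if len(designs) < 2:
        raise ValueError("need >= 2 arms")
    for d in designs:
        d.check_identifiable()
    df, endog, offset = _glm_endog_exog(designs)
    shared = _fit_cloglog(endog, np.ones((len(df), 1)), offset=offset)
    arm_dummies = pd.get_dummies(df["arm"], dtype=float).to_numpy()
    separate = _fit_cloglog(endog, arm_dummies, offset=offset)
    chi2 = float(shared.deviance - separate.deviance)
    chi2 = max(chi2, 0.0)
    k = len(designs) - 1
    return chi2, k, float(stats.chi2.sf(chi2, k))


def test_single_hit_adequacy(design: LdaDesign) -> Tuple[float, float]:
    """Wald test of slope = 1 for log(dose) on the cloglog scale.

    Under the single-hit model the slope is exactly 1; a slope near 2
    indicates two-hit (cooperative) behaviour. Returns ``(slope, p)``;
    a p near 1 supports single-hit adequacy.
    """
    if design.doses.size < 3:
        raise ValueError("adequacy test needs >= 3 doses")
    design.check_identifiable()
    df, endog, _ = _glm_endog_exog([design])
    exog = np.column_stack([np.ones(len(df)),
                            np.log(df["cells_per_well"].to_numpy(dtype=float))])
    res = _fit_cloglog(endog, exog)
    slope = float(res.params[1])
    se = float(res.bse[1])
    z = (slope - 1.0) / se
    return slope, float(2.0 * stats.norm.sf(abs(z)))


def relative_change(fit_treated: LdaFit, fit_control: LdaFit) -> float:
    """Percent change in sphere-forming frequency relative to control."""
    return 100.0 * (fit_treated.f - fit_control.f) / fit_control.f
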