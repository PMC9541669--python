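"""Harvest estimation from partially returned hunter questionnaires.

Hunters buy class-specific tags (bull, cow, calf) and a fraction return
their questionnaire.  The harvest by respondents is known exactly; the
harvest by the remaining tag holders is a binomial draw at the respondents'
success rate:

    E = sum_k Eo_k + Binomial(n_k, s_k),   k in {bull, cow, calf}

where Eo_k is the known (reported) harvest, n_k the tags issued minus the
number of reporting hunters, and s_k the reported success rate.  Within the
Bayesian fit the binomial components are latent; here the same rule serves
as the generative model for synthetic data and as a moment calculator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, InvalidProbabilityError

CLASSES = ("bull", "cow", "calf")


@dataclass(frozen=True)
class HarvestReport:
    """One unit-year of questionnaire aggregates, indexed bull/cow/calf."""

    known_harvest: tuple[float, float, float]
    tags_minus_reporters: tuple[float, float, float]
    reported_success: tuple[float, float, float]

    def __post_init__(self) -> None:
        eo = np.asarray(self.known_harvest, float)
        n = np.asarray(self.tags_minus_reporters, float)
        s = np.asarray(self.reported_success, float)
        if eo.shape != (3,) or n.shape != (3,) or s.shape != (3,):
            raise InvalidParameterError("exactly 3 harvest classes required")
        if np.any(eo < 0) or np.any(n < 0):
            raise InvalidParameterError("negative harvest or tag count")
        if np.any((s < 0) | (s > 1)):
            raise InvalidProbabilityError("success rate outside [0, 1]")

    @property
    def eo(self) -> np.ndarray:
        return np.asarray(self.known_harvest, float)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.tags_minus_reporters, float)

    @property
    def s(self) -> np.ndarray:
        return np.asarray(self.reported_success, float)


def unknown_harvest_moments(report: HarvestReport) -> tuple[float, float]:
    """Mean and variance of the latent (unreported) harvest component.

    These are the moments of sum_k Binomial(n_k, s_k); the normal
    approximation with these moments stands in for the latent binomials when
    the fit marginalizes them (n_k * s_k is large in practice).
    """
    m = float(np.sum(report.n * report.s))
    v = float(np.sum(report.n * report.s * (1.0 - report.s)))
    return m, v


def total_harvest(report: HarvestReport, mode: str = "expectation",
                  seed: int | np.random.Generator | None = None) -> float:
    """Total harvest E for one unit-year.

    mode="expectation" returns sum(Eo) + sum(n * s); mode="sample" draws the
    binomial components (returns an integer-valued float).
    """
    known = float(np.sum(report.eo))
    if mode == "expectation":
        m, _ = unknown_harvest_moments(report)
        return known + m
    if mode == "sample":
        rng = np.random.default_rng(seed)
        draws = rng.binomial(report.n.astype(int), report.s)
        return known + float(np.sum(draws))
    raise InvalidParameterError(f"unknown mode {mode!r}")


def harvest_proportion(harvest: float, preharvest: float) -> float:
    """Proportion of the preharvest population removed by hunters."""
    if preharvest <= 0:
        raise InvalidParameterError("preharvest abundance must be > 0")
    if harvest < 0:
        raise InvalidParameterError("harvest must be >= 0")
    if harvest > preharvest:
        warnings.warn("harvest exceeds preharvest abundance; proportion > 1",
                      RuntimeWarning, stacklevel=2)
    return harvest / preharvest


def pooled_success_rates(reports: list[HarvestReport]) -> np.ndarray:
    """Per-class success pooled across years of one unit.

    Fallback for unit-years where a class had zero respondents: weight each
    year's reported success by its known harvest plus outstanding tags.
    """
    if not reports:
        raise InvalidParameterError("no reports to pool")
    eo = np.sum([r.eo for r in reports], axis=0)
    n_resp_times_s = eo  # Eo_k = respondents_k * s_k by construction
    denom = np.sum([r.eo / np.where(r.s > 0, r.s, 1.0) for r in reports], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(denom > 0, n_resp_times_s / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(pooled, 0.0, 1.0)
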