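"""Observed- to liability-scale conversion of SNP-based heritability.

For a binary disease analysed as a 0/1 trait in an ascertained case-control
sample, the heritability estimated on the observed scale (``h2_obs``) is
converted to the population liability scale with the classic
ascertainment-corrected transform

    h2_liab = h2_obs * [K(1-K)/z^2] * [K(1-K)/(P(1-P))]

where ``K`` is the (age-appropriate) population prevalence, ``P`` the case
proportion in the analysed sample, ``t = Phi^{-1}(1-K)`` the liability
threshold and ``z`` the standard normal density at ``t``.

For late-onset diseases prevalence rises steeply with age, so ``K`` must be
chosen for the ages actually studied, and when controls are *not* screened
(some will develop disease later) the sample case proportion is uplifted to

    P_actual = P + f * (1 - P)

with ``f`` the fraction of controls expected to convert. This module also
hosts :class:`AgeOnsetModel`, a piecewise log-linear age -> cumulative
prevalence curve used both to pick ``K`` for a cohort's age and as the
age-varying liability threshold of the cohort simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "AgeOnsetModel",
    "LiabilitySpec",
    "DEFAULT_ANCHORS",
    "observed_to_liability",
    "liability_to_observed",
    "uplift_case_proportion",
    "prevalence_for_age",
]

#: Default (age, cumulative prevalence) anchors: 2% at 65, 5% at 75, 15% at 85,
#: matching the three prevalence thresholds used throughout the analyses.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = ((65.0, 0.02), (75.0, 0.05), (85.0, 0.15))


def _check_open_unit(x: float, name: str) -> None:
    if not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1); got {x!r}")


def threshold_and_density(K: float) -> tuple[float, float]:
    """Liability threshold ``t = Phi^{-1}(1-K)`` and normal density ``z`` at it."""
    _check_open_unit(K, "K")
    t = norm.isf(K)
    z = norm.pdf(t)
    return t, z


def observed_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Convert observed-scale heritability to the liability scale.

    Parameters
    ----------
    h2_obs : float
        Heritability of the 0/1 disease indicator in the analysed sample.
    K : float
        Population prevalence appropriate for the ages studied, in (0, 1).
    P : float
        Case proportion in the sample, in (0, 1). Use the *uplifted*
        proportion (:func:`uplift_case_proportion`) when controls are
        unscreened for a late-onset disease.

    Returns
    -------
    float
        Heritability of the underlying continuous liability. Equals the
        unascertained ``h2_obs * K(1-K)/z^2`` rescaling when ``P == K``.
    """
    if h2_obs < 0:
        raise ValueError(f"h2_obs must be non-negative; got {h2_obs!r}")
    _check_open_unit(K, "K")
    _check_open_unit(P, "P")
    _, z = threshold_and_density(K)
    return h2_obs * (K * (1 - K)) ** 2 / (z * z * P * (1 - P))


def liability_to_observed(h2_liab: float, K: float, P: float) -> float:
    """Algebraic inverse of :func:`observed_to_liability`."""
    if h2_liab < 0:
        raise ValueError(f"h2_liab must be non-negative; got {h2_liab!r}")
    _check_open_unit(K, "K")
    _check_open_unit(P, "P")
    _, z = threshold_and_density(K)
    return h2_liab * z * z * P * (1 - P) / (K * (1 - K)) ** 2


def uplift_case_proportion(P: float, f: float) -> float:
    """Uplifted case proportion ``P + f*(1-P)`` for unscreened controls.

    ``f`` is the fraction of sampled controls expected to develop the disease
    given time (latent cases), so the effective case proportion of the sample
    is larger than the labelled one.
    """
    _check_open_unit(P, "P")
    if not (0.0 <= f < 1.0):
        raise ValueError(f"control conversion fraction f must be in [0, 1); got {f!r}")
    return P + f * (1.0 - P)


@dataclass(frozen=True)
class LiabilitySpec:
    """Prevalence/ascertainment context for one liability-scale conversion.

    Attributes
    ----------
    K : population prevalence in (0, 1) appropriate for the cohort's age.
    P : labelled case proportion of the sample.
    control_conversion : fraction ``f`` in [0, 1) of controls expected to
        develop the disease; 0 for screened (e.g. pathologically confirmed)
        controls.
    """

    K: float
    P: float
    control_conversion: float = 0.0
    t: float = field(init=False)
    z: float = field(init=False)

    def __post_init__(self) -> None:
        t, z = threshold_and_density(self.K)
        _check_open_unit(self.P, "P")
        if not (0.0 <= self.control_conversion < 1.0):
            raise ValueError("control_conversion must be in [0, 1)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "z", z)

    @property
    def P_actual(self) -> float:
        """Case proportion after counting latent cases among controls."""
        return uplift_case_proportion(self.P, self.control_conversion)

    def convert(self, h2_obs: float, uplift: bool = True) -> float:
        """Observed -> liability-scale h2 under this spec.

        With ``uplift=True`` the uplifted case proportion is used; with
        ``uplift=False`` the raw labelled proportion. Both are reported by the
        pipeline since published figures do not always state which was used.
        """
        P = self.P_actual if uplift else self.P
        return observed_to_liability(h2_obs, self.K, P)


class AgeOnsetModel:
    """Age-varying cumulative prevalence K(a) and liability threshold t(a).

    K(a) is interpolated log-linearly between anchor (age, prevalence) points
    and is non-decreasing in age; the corresponding liability threshold
    ``t(a) = Phi^{-1}(1 - K(a))`` is non-increasing. Outside the anchor range
    the curve is clamped to the nearest anchor (with a warning), since the
    anchors are the only empirical constraint.
    """

    def __init__(self, anchor_points: Sequence[tuple[float, float]] = DEFAULT_ANCHORS):
        pts = sorted((float(a), float(k)) for a, k in anchor_points)
        if len(pts) < 1:
            raise ValueError("need at least one (age, prevalence) anchor")
        ages = np.array([p[0] for p in pts])
        ks = np.array([p[1] for p in pts])
        if np.any((ks <= 0) | (ks >= 1)):
            raise ValueError("anchor prevalences must lie in (0, 1)")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("anchor ages must be distinct")
        if np.any(np.diff(ks) < 0):
            raise ValueError("K(a) must be non-decreasing in age")
        self.anchor_ages = ages
        self.anchor_K = ks

    @property
    def anchor_points(self) -> list[tuple[float, float]]:
        return list(zip(self.anchor_ages.tolist(), self.anchor_K.tolist()))

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.anchor_ages[0]), float(self.anchor_ages[-1])

    def prevalence(self, age) -> np.ndarray | float:
        """Cumulative prevalence K(age), log-linear between anchors, clamped outside."""
        a = np.asarray(age, dtype=float)
        lo, hi = self.age_range
        if np.any(a < lo) or np.any(a > hi):
            warnings.warn(
                f"age outside anchor range [{lo}, {hi}]; prevalence clamped to nearest anchor",
                stacklevel=2,
            )
        logk = np.interp(np.clip(a, lo, hi), self.anchor_ages, np.log(self.anchor_K))
        out = np.exp(logk)
        return float(out) if np.isscalar(age) else out

    def threshold(self, age) -> np.ndarray | float:
        """Liability threshold t(age) = Phi^{-1}(1 - K(age))."""
        return norm.isf(self.prevalence(age))

    def onset_age(self, liability) -> np.ndarray:
        """Youngest age at which a unit-variance liability exceeds t(a).

        Returns NaN where the liability never exceeds the threshold within the
        anchor range; liabilities above the youngest-anchor threshold onset at
        the youngest anchor age (earlier ages are outside the model).
        """
        L = np.atleast_1d(np.asarray(liability, dtype=float))
        target = norm.sf(L)  # K(a) at which L sits exactly on the threshold
        out = np.full(L.shape, np.nan)
        kmin, kmax = self.anchor_K[0], self.anchor_K[-1]
        ever = target <= kmax
        out[ever] = np.interp(
            np.log(np.clip(target[ever], kmin, kmax)),
            np.log(self.anchor_K),
            self.anchor_ages,
        )
        return out


def prevalence_for_age(onset_model: AgeOnsetModel, age) -> np.ndarray | float:
    """Prevalence K(age) from an :class:`AgeOnsetModel` (clamped outside anchors)."""
    return onset_model.prevalence(age)
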