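"""Parameter containers for the nine-state CRC natural-history model.

The model splits its inputs into *calibrated* parameters (``CalibratedParams``,
the nine quantities estimated by Bayesian calibration) and *fixed* parameters
(``FixedParams``, stage-specific CRC mortality and the preclinical prevalences
at age 50, which in practice are available from cancer registries).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import IntEnum

import numpy as np


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates its support constraints."""


class HealthState(IntEnum):
    """The nine health states of the natural-history model.

    ``CRC_DEATH`` and ``OTHER_DEATH`` are absorbing. The integer values fix
    the row/column order of every matrix in the package.
    """

    NORMAL = 0
    SMALL_ADENOMA = 1
    LARGE_ADENOMA = 2
    PRECLIN_EARLY = 3
    PRECLIN_LATE = 4
    CLIN_EARLY = 5
    CLIN_LATE = 6
    CRC_DEATH = 7
    OTHER_DEATH = 8


N_STATES = len(HealthState)

#: States in which a person is alive.
ALIVE_STATES = tuple(s for s in HealthState if s < HealthState.CRC_DEATH)
#: Alive states without clinical CRC — the denominator for incidence rates.
AT_RISK_STATES = tuple(s for s in HealthState if s < HealthState.CLIN_EARLY)
ADENOMA_STATES = (HealthState.SMALL_ADENOMA, HealthState.LARGE_ADENOMA)


@dataclass(frozen=True)
class CalibratedParams:
    """The nine unknown natural-history parameters (theta_u).

    Attributes
    ----------
    padeno : float
        Adenoma prevalence at age 50, in (0, 1).
    psmall : float
        Proportion of prevalent adenomas at 50 that are small, in (0, 1).
    l, gamma : float
        Scale and shape of the Weibull adenoma-onset hazard
        ``lambda1(a) = l * gamma * a**(gamma - 1)``.
    lambda2 ... lambda6 : float
        Constant annual transition rates (1/year): small->large adenoma,
        large adenoma->preclinical early CRC, preclinical early->preclinical
        late, preclinical early->clinical early, preclinical late->clinical
        late.
    """

    padeno: float
    psmall: float
    l: float
    gamma: float
    lambda2: float
    lambda3: float
    lambda4: float
    lambda5: float
    lambda6: float

    #: canonical parameter order used by every array/matrix in the package
    NAMES = ("padeno", "psmall", "l", "gamma",
             "lambda2", "lambda3", "lambda4", "lambda5", "lambda6")

    def __post_init__(self) -> None:
        for name in ("padeno", "psmall"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidParameterError(f"{name}={v} outside (0, 1)")
        for name in self.NAMES[2:]:
            v = getattr(self, name)
            if not v > 0.0:
                raise InvalidParameterError(f"{name}={v} must be > 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "CalibratedParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(cls.NAMES),):
            raise InvalidParameterError(f"expected {len(cls.NAMES)} values, got shape {x.shape}")
        return cls(*x)


@dataclass(frozen=True)
class FixedParams:
    """External natural-history parameters (theta_k) not subject to calibration.

    ``lambda7``/``lambda8`` are annual CRC mortality rates from the early and
    late clinical stages; the two prevalences seed the preclinical CRC states
    of the age-50 cohort.
    """

    lambda7: float = 0.0302
    lambda8: float = 0.2099
    p_preclin_early_50: float = 0.0012
    p_preclin_late_50: float = 0.0008

    def __post_init__(self) -> None:
        if self.lambda7 <= 0 or self.lambda8 <= 0:
            raise InvalidParameterError("CRC mortality rates must be > 0")
        for name in ("p_preclin_early_50", "p_preclin_late_50"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise InvalidParameterError(f"{name}={v} outside [0, 1)")
        if self.p_preclin_early_50 + self.p_preclin_late_50 >= 1.0:
            raise InvalidParameterError("preclinical prevalences sum to >= 1")


def params_from_dict(d) -> CalibratedParams:
    return CalibratedParams(**{k: float(d[k]) for k in CalibratedParams.NAMES})


def fixed_from_dict(d) -> FixedParams:
    names = [f.name for f in fields(FixedParams)]
    return FixedParams(**{k: float(d[k]) for k in names})
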