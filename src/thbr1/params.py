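"""Biophysical parameter set shared by all forward computations.

The transient-hydrogen-bond (THB) channel is governed by the coupling
strength ``lambdaA`` [1/s^2] and bond lifetime ``tauA`` [s] together with the
proton fractions ``nbA`` (bound protons engaged in water coupling) and
``nwA`` (water protons engaged in bound coupling).  The bound-pool
lateral-diffusion channel is governed by the strength ``Lambda`` [1/s] and
the dimensionless frequency ``Omega0`` quoted at the reference field.  The
mixing fraction ``zeta`` weights the bound-pool rate into the single
apparent R1, and ``r1w`` is the water-water relaxation contribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

#: Published posterior means of the shared fit parameters (in vivo WM).
PUBLISHED_MEANS = {
    "nbA": 0.54,
    "nwA": 0.035,
    "Lambda": 23.1,  # 1/s
    "Omega0": 9.1,   # at 3 T
    "zeta": 0.0025,
}

#: Published per-field isotropic rates R1I [1/s], keyed by nominal tesla.
PUBLISHED_R1I = {1.5: 1.56, 3.0: 1.14, 7.0: 1.03}

#: Default THB lifetime [s] (long-lived anisotropic pool, tens of ns).
DEFAULT_TAU_A = 70e-9

#: Default target for the lambdaA calibration: peak-to-trough R1app
#: anisotropy at 3 T as a fraction of R1I (the observed anisotropy is a few
#: percent of the mean rate).
DEFAULT_ANISOTROPY_FRACTION = 0.04


@dataclass(frozen=True)
class BiophysParams:
    """THB + lateral-diffusion parameter set.

    All fields accept scalars; array-valued fields broadcast through the
    forward model (used by the vectorised likelihood).
    """

    nbA: float
    nwA: float
    lambdaA: float
    tauA: float
    Lambda: float
    Omega0: float
    zeta: float
    r1w: float = 0.0

    def __post_init__(self) -> None:
        checks = [
            (np.all((np.asarray(self.nbA) >= 0) & (np.asarray(self.nbA) <= 1)),
             "nbA must lie in [0, 1]"),
            (np.all((np.asarray(self.nwA) >= 0) & (np.asarray(self.nwA) <= 1)),
             "nwA must lie in [0, 1]"),
            (np.all((np.asarray(self.zeta) >= 0) & (np.asarray(self.zeta) <= 1)),
             "zeta must lie in [0, 1]"),
            (np.all(np.asarray(self.lambdaA) >= 0), "lambdaA must be >= 0"),
            (np.all(np.asarray(self.tauA) > 0), "tauA must be > 0"),
            (np.all(np.asarray(self.Lambda) >= 0), "Lambda must be >= 0"),
            (np.all(np.asarray(self.Omega0) > 0), "Omega0 must be > 0"),
            (np.all(np.asarray(self.r1w) >= 0), "r1w must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidParameterError(msg)

    def replace(self, **kwargs) -> "BiophysParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_params(lambdaA: float | None = None,
                   tauA: float = DEFAULT_TAU_A,
                   r1w: float = 0.0,
                   anisotropy_fraction: float = DEFAULT_ANISOTROPY_FRACTION,
                   ) -> BiophysParams:
    """Published shared parameters with a calibrated ``lambdaA``.

    When ``lambdaA`` is None it is set so that the peak-to-trough R1app
    anisotropy at 3 T equals ``anisotropy_fraction`` of R1I(3 T); see
    :func:`thbr1.physics.calibrate_lambda`.
    """
    base = BiophysParams(lambdaA=0.0, tauA=tauA, r1w=r1w, **PUBLISHED_MEANS)
    if lambdaA is None:
        from .physics import calibrate_lambda  # deferred: avoids import cycle

        lambdaA = calibrate_lambda(base, target_fraction=anisotropy_fraction)
    return base.replace(lambdaA=float(lambdaA))
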