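"""Magnetic-field contexts.

A :class:`FieldContext` carries the static field strength ``B`` [T], the
proton Larmor angular frequency ``omega`` [rad/s] and the reference field
``B_ref`` [T] at which the dimensionless lateral-diffusion frequency
``Omega0`` is quoted (the field scaling is ``Omega = (B/B_ref) * Omega0``).

The three study fields ship with their exact scanner Larmor frequencies
(63.661, 123.174 and 297.208 MHz for 1.5, 3 and 7 T); arbitrary fields can
be built from ``B`` alone via the proton gyromagnetic ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidParameterError

#: Proton gyromagnetic ratio [rad s^-1 T^-1].
GAMMA_PROTON = 2.675e8

#: Reduced Planck constant [J s].
HBAR = 1.054571817e-34

#: Default reference field for Omega0 [T].
DEFAULT_B_REF = 3.0

#: Exact scanner Larmor frequencies [MHz] keyed by nominal field [T].
LARMOR_MHZ = {1.5: 63.661, 3.0: 123.174, 7.0: 297.208}


@dataclass(frozen=True)
class FieldContext:
    """Static magnetic field description.

    Parameters
    ----------
    B : float
        Field strength [T].
    omega : float
        Proton Larmor angular frequency [rad/s].
    B_ref : float
        Reference field at which Omega0 is defined [T].
    """

    B: float
    omega: float
    B_ref: float = DEFAULT_B_REF

    def __post_init__(self) -> None:
        if not (self.B > 0 and self.B_ref > 0):
            raise InvalidParameterError("B and B_ref must be positive")
        if not self.omega > 0:
            raise InvalidParameterError("omega must be positive")

    @classmethod
    def from_tesla(cls, B: float, gamma: float = GAMMA_PROTON,
                   B_ref: float = DEFAULT_B_REF) -> "FieldContext":
        """Build from field strength using ``omega = gamma * B``."""
        return cls(B=B, omega=gamma * B, B_ref=B_ref)

    @classmethod
    def from_larmor_mhz(cls, f_mhz: float, B: float | None = None,
                        B_ref: float = DEFAULT_B_REF) -> "FieldContext":
        """Build from a stated Larmor frequency, ``omega = 2*pi*f``.

        ``B`` defaults to ``omega / gamma`` when not given.
        """
        omega = 2.0 * math.pi * f_mhz * 1e6
        if B is None:
            B = omega / GAMMA_PROTON
        return cls(B=B, omega=omega, B_ref=B_ref)

    def Omega(self, Omega0: float):
        """Dimensionless diffusion frequency at this field: (B/B_ref)*Omega0."""
        return (self.B / self.B_ref) * Omega0


def study_field(tesla: float, B_ref: float = DEFAULT_B_REF) -> FieldContext:
    """FieldContext for a nominal study field (1.5, 3 or 7 T).

    Uses the exact scanner Larmor frequency when the field is one of the
    study's three; otherwise falls back to ``gamma * B``.
    """
    key = float(tesla)
    if key in LARMOR_MHZ:
        return FieldContext.from_larmor_mhz(LARMOR_MHZ[key], B=key, B_ref=B_ref)
    return FieldContext.from_tesla(key, B_ref=B_ref)


def study_fields(teslas=(1.5, 3.0, 7.0)) -> dict[float, FieldContext]:
    """The default per-field contexts keyed by nominal tesla."""
    return {float(t): study_field(t) for t in teslas}
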