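"""Blood constitutive model: shear-thinning Carreau viscosity.

Whole blood is a suspension of erythrocytes in plasma and behaves as a
shear-thinning fluid: its apparent viscosity falls from a zero-shear plateau
``mu_zero`` to an infinite-shear plateau ``mu_inf`` as the strain rate grows.
The Carreau model interpolates between the plateaus,

    mu(g) = mu_inf + (mu_zero - mu_inf) * [1 + (lambda * g)^2]^((n - 1) / 2),

with relaxation time ``lambda`` and power index ``n < 1``. The reduced-order
flow solver closes this constitutive law with a single characteristic shear
rate per vessel segment — the Poiseuille wall shear rate of the equivalent
circular (or annular) section at the current flow iterate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BloodModel",
    "CARREAU_HUMAN_BLOOD",
    "apparent_viscosity",
    "wall_shear_rate_tube",
]

# log-form guard: above this value of lambda*gamma the bracket is evaluated
# as exp(((n-1)) * log(lambda*gamma)) to avoid squaring overflow
_LOG_FORM_THRESHOLD = 1e6


@dataclass(frozen=True)
class BloodModel:
    """Carreau coefficients and mass density of blood.

    Defaults are the human whole-blood fit used throughout the package:
    mu_zero = 0.055 Pa.s, mu_inf = 0.00339 Pa.s, lambda = 9.56 s, n = 0.2,
    rho = 1050 kg/m^3. Setting ``mu_zero == mu_inf`` degenerates the model
    to a Newtonian fluid with that viscosity.
    """

    mu_zero: float = 0.055
    mu_inf: float = 0.00339
    lambda_time: float = 9.56
    power_index: float = 0.2
    density: float = 1050.0

    def __post_init__(self) -> None:
        if self.mu_inf <= 0:
            raise ValueError("mu_inf must be positive")
        if self.mu_zero < self.mu_inf:
            raise ValueError("mu_zero must be >= mu_inf")
        if self.lambda_time < 0:
            raise ValueError("lambda_time must be non-negative")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def is_newtonian(self) -> bool:
        return self.mu_zero == self.mu_inf

    @classmethod
    def newtonian(cls, viscosity: float = 0.0035,
                  density: float = 1050.0) -> "BloodModel":
        """Constant-viscosity blood (the Newtonian limit of the model)."""
        return cls(mu_zero=viscosity, mu_inf=viscosity,
                   lambda_time=0.0, power_index=1.0, density=density)


CARREAU_HUMAN_BLOOD = BloodModel()


def apparent_viscosity(model: BloodModel, shear_rate):
    """Carreau apparent viscosity at strain rate ``shear_rate`` (1/s).

    Accepts scalars or arrays; the result is clamped by construction to
    [mu_inf, mu_zero]. Negative shear rates are rejected.
    """
    gamma = np.asarray(shear_rate, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("shear_rate must be non-negative")
    if model.is_newtonian:
        out = np.full_like(gamma, model.mu_zero)
        return float(out) if gamma.ndim == 0 else out

    lg = model.lambda_time * gamma
    expo = 0.5 * (model.power_index - 1.0)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        factor = np.where(
            lg > _LOG_FORM_THRESHOLD,
            np.exp(2.0 * expo * np.log(np.maximum(lg, 1.0))),
            np.power(1.0 + lg * lg, expo),
        )
    mu = model.mu_inf + (model.mu_zero - model.mu_inf) * factor
    return float(mu) if gamma.ndim == 0 else mu


def wall_shear_rate_tube(flow: float, diameter: float) -> float:
    """Poiseuille wall shear rate 32|Q|/(pi d^3) of a circular tube.

    ``flow`` in m^3/s, ``diameter`` in m. This is the characteristic shear
    rate used to couple the Carreau law to the lumped resistance solve.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return 32.0 * abs(flow) / (math.pi * diameter ** 3)
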