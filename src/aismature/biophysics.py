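"""Derived quantities linking AIS morphology and cell physiology.

Three small but load-bearing computations: the AIS membrane capacitance from
cylinder geometry (C_AIS = pi * d * L * c_specific), the estimated AIS
inward current (Est I_In-AIS = C_AIS * IS component, pF x V/s = pA), and the
one-parameter Ohm's-law hyperbola rheobase = V / R_In fitted across cells,
whose parameter V is the depolarization needed to reach threshold from rest
(empirically: AP threshold - E_rest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import AismatureWarning, InsufficientDataError, ParameterError

__all__ = [
    "AISCapacitanceResult",
    "EstimatedAISCurrent",
    "HyperbolaFit",
    "ais_capacitance",
    "estimate_ais_current",
    "fit_rheobase_hyperbola",
    "depolarization_at_rheobase",
]

#: 1 uF/cm^2 expressed in pF/um^2.
_UF_PER_CM2_TO_PF_PER_UM2 = 0.01


@dataclass
class AISCapacitanceResult:
    c_ais: float  # pF
    length_um: float
    diameter_um: float
    specific_capacitance: float  # uF/cm^2


@dataclass
class EstimatedAISCurrent:
    i_in_ais: float  # pA
    c_ais: float  # pF
    is_component: float  # V/s


@dataclass
class HyperbolaFit:
    V: float  # mV
    rss: float  # pA^2
    n: int

    def predict(self, rin_Mohm) -> np.ndarray:
        """Rheobase (pA) predicted at the given input resistances (MOhm)."""
        return self.V / (np.asarray(rin_Mohm, float) * 1e-3)


def ais_capacitance(
    length_um: float, diameter_um: float, specific_capacitance: float = 1.0
) -> AISCapacitanceResult:
    """AIS capacitance for an open cylinder of the given length and diameter.

    ``specific_capacitance`` is in uF/cm^2 (default 1.0, the textbook
    membrane value); the lateral area is pi * d * L with no end caps.
    """
    if length_um <= 0 or diameter_um <= 0 or specific_capacitance <= 0:
        raise ParameterError("length, diameter and specific capacitance must be > 0")
    area_um2 = np.pi * diameter_um * length_um
    c_ais = area_um2 * specific_capacitance * _UF_PER_CM2_TO_PF_PER_UM2
    return AISCapacitanceResult(
        c_ais=float(c_ais), length_um=length_um, diameter_um=diameter_um,
        specific_capacitance=specific_capacitance,
    )


def estimate_ais_current(c_ais_pF: float, is_component_Vps: float) -> EstimatedAISCurrent:
    """Estimated AIS inward current: I = C * dV/dt, with pF x V/s = pA exactly."""
    if c_ais_pF <= 0 or is_component_Vps <= 0:
        raise ParameterError("c_ais and is_component must be > 0")
    return EstimatedAISCurrent(
        i_in_ais=float(c_ais_pF * is_component_Vps),
        c_ais=c_ais_pF,
        is_component=is_component_Vps,
    )


def fit_rheobase_hyperbola(pairs) -> HyperbolaFit:
    """Least-squares fit of rheobase = V / R_In over (R_In MOhm, rheobase pA) pairs.

    The single parameter V (mV) has the closed-form solution
    V = sum(I_i / R_i) / sum(1 / R_i^2), minimizing the residual sum of
    squares in current space.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise InsufficientDataError("need >= 2 (Rin, rheobase) pairs")
    rin, rheo = pairs[:, 0], pairs[:, 1]
    if np.any(rin <= 0):
        raise ParameterError("all Rin must be > 0")
    inv_r = 1.0 / rin  # 1/MOhm
    v = float(np.sum(rheo * inv_r) / np.sum(inv_r**2))  # pA*MOhm = uV
    resid = rheo - v * inv_r
    return HyperbolaFit(V=v * 1e-3, rss=float(np.sum(resid**2)), n=pairs.shape[0])


def depolarization_at_rheobase(erest_mV: float, threshold_mV: float) -> float:
    """Depolarization needed to reach AP threshold from rest: threshold - Erest (mV)."""
    if threshold_mV < erest_mV:
        raise ParameterError("threshold below resting potential: check inputs")
    if threshold_mV == erest_mV:
        warnings.warn("threshold equals Erest: zero depolarization at rheobase",
                      AismatureWarning, stacklevel=2)
    return float(threshold_mV - erest_mV)
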