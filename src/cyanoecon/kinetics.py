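"""Rate laws of the coarse-grained model, kept in one pluggable layer.

All process rates used by the steady-state solver live here so that
alternative kinetic forms can be substituted without touching the solver:

* passive carbon diffusion         vd = kdiff * (cix - ci)
* active carbon import             vt = kcat_T * [T] * cix / (Km_T + cix)
* carbon -> amino-acid metabolism  vm = kcat_M * [M] * ci / (Km_M + ci)
  * Ki_aa / (Ki_aa + aa)   (end-product inhibition)
* photosynthesis (two-state PSU)   v1, v2, vi -- see :func:`psu_rates`
* translation                      gamma = kcat_R * [R] * f(aa) * f(e)
"""

from __future__ import annotations

import math
from typing import NamedTuple

from .params import AVOGADRO, EnvironmentalCondition, ModelParameters

NM2_TO_M2 = 1.0e-18


def photon_flux(I: float) -> float:
    """Photon flux (photons m^-2 s^-1) for intensity ``I`` in umol m^-2 s^-1.

    Unit bridge so that sigma [nm^2 -> m^2] times the flux has units s^-1.
    """
    if I < 0:
        raise ValueError(f"light intensity must be >= 0, got {I}")
    return I * 1.0e-6 * AVOGADRO


def excitation_rate(I: float, params: ModelParameters) -> float:
    """Per-PSU excitation rate k_exc = sigma * photon flux (s^-1)."""
    return params.sigma * NM2_TO_M2 * photon_flux(I)


class PSURates(NamedTuple):
    v1: float  #: excitation flux (events per Dc per s)
    v2: float  #: energy-production flux (turnovers per Dc per s)
    vi: float  #: photodamage flux (PSU molecules per Dc per s)


def psu_rates(P_conc: float, env: EnvironmentalCondition,
              params: ModelParameters) -> PSURates:
    """Quasi-steady-state fluxes of the two-state photosynthetic-unit cycle.

    Ground-state units are excited by photon capture (rate ``k_exc`` per
    unit), excited units relax with the turnover rate ``tau`` releasing one
    energy unit.  Photodamage removes units with probability ``kd`` per
    excitation; by default it acts on the *excited* state (a second photon
    hit on a busy unit), which makes the damage flux grow super-linearly
    relative to energy production and is what produces photoinhibition.
    The ``"ground"`` variant (damage on idle units) is kept switchable.

    Always ``v2 <= tau * P_conc``.
    """
    if P_conc < 0:
        raise ValueError("PSU concentration must be >= 0")
    kexc = excitation_rate(env.I, params)
    tau, kd = params.tau, params.kd
    if kexc == 0.0 or P_conc == 0.0:
        return PSURates(0.0, 0.0, 0.0)
    if params.damage_target == "excited":
        # P0 --kexc--> P1 ; P1 --tau--> P0 + e ; P1 --kd*kexc--> damaged
        p1 = P_conc * kexc / (kexc + tau + kd * kexc)
        v2 = tau * p1
        vi = kd * kexc * p1
        v1 = kexc * (P_conc - p1)
    else:
        # photon hit on a ground-state unit excites with prob (1-kd),
        # damages with prob kd
        p0 = P_conc * tau / (tau + (1.0 - kd) * kexc)
        v1 = (1.0 - kd) * kexc * p0
        v2 = v1
        vi = kd * kexc * p0
    return PSURates(v1, v2, vi)


def transport_rate(T_conc: float, env: EnvironmentalCondition,
                   params: ModelParameters) -> float:
    """Active carbon import flux (carbon units per Dc per s)."""
    return params.kcat_T * T_conc * env.cix / (params.Km_T + env.cix)


def diffusion_rate(ci: float, env: EnvironmentalCondition,
                   params: ModelParameters) -> float:
    """Passive carbon diffusion flux, positive into the cell."""
    return params.kdiff * (env.cix - ci)


def metabolic_rate(M_conc: float, ci: float, aa: float,
                   params: ModelParameters) -> float:
    """Amino-acid synthesis flux (aa per Dc per s).

    Michaelis-Menten in the internal carbon pool with end-product
    inhibition by the amino-acid pool (throttles biosynthesis when the
    pool accumulates, so idle metabolic capacity does not run futilely).
    """
    inhibition = params.Ki_aa / (params.Ki_aa + aa)
    return params.kcat_M * M_conc * ci / (params.Km_M + ci) * inhibition


def translation_capacity(R_conc: float, aa: float, e: float,
                         params: ModelParameters) -> float:
    """Total translation flux gamma (aa per Dc per s) at full allocation."""
    f_aa = aa / (params.Km_aa + aa)
    f_e = e / (params.Km_e + e)
    return params.kcat_R * R_conc * f_aa * f_e


def saturating_mu(params: ModelParameters) -> float:
    """Crude upper bound on mu (s^-1): full budget translating at kcat_R."""
    return params.kcat_R * (1.0 - params.phi_Q) * params.Dc / params.n_R
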