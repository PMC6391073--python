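"""Steady-state growth-rate maximization for the allocation model.

The cell chooses how to partition the adjustable half of its proteome
(mass fractions phi_T, phi_M, phi_R, phi_P; Q is pinned at phi_Q) so as to
maximize the specific growth rate mu subject to steady-state mass balance
of the internal carbon, amino-acid and energy pools and of every protein
class, with total protein density fixed at Dc.

The solver exploits the model structure: for a *fixed* partition the
balances reduce to two nested scalar root problems (internal carbon from
the carbon balance, then mu from the energy balance), which are solved by
safeguarded bisection to near machine precision.  The outer maximization
over the 3-dimensional allocation simplex uses SLSQP with deterministic
multi-start; a brute-force simplex enumeration is available as an
independent route (``method="enumerate"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from . import kinetics
from .params import (GROWTH_CLASSES, PROTEIN_CLASSES, Allocation,
                     EnvironmentalCondition, ModelParameters)

SECONDS_PER_HOUR = 3600.0
_PHI_MIN = 1.0e-4


class SolverError(RuntimeError):
    """Steady-state solver failure, carrying the best iterate found."""

    def __init__(self, message: str, best=None, residuals=None):
        super().__init__(message)
        self.best = best
        self.residuals = residuals


class InfeasibleConstraintError(ValueError):
    """A requested fixed proteome fraction exceeds the mass budget."""


@dataclass(frozen=True)
class ConstraintSpec:
    """Fix the mass fraction of one protein class (R, P or M).

    The concentration is pinned at ``phi_Z * Dc / n_Z`` and the active
    fraction ``alpha_Z`` in [0, 1] becomes a free optimization variable.
    """

    class_id: str
    phi_Z: float

    def __post_init__(self) -> None:
        if self.class_id not in ("R", "P", "M"):
            raise ValueError("class_id must be one of 'R', 'P', 'M'")
        if not 0.0 < self.phi_Z < 1.0:
            raise ValueError("phi_Z must lie in (0, 1)")


@dataclass
class SteadyState:
    """One solved operating point of the allocation model.

    ``mu`` is reported in h^-1; all fluxes are per Dc per second.
    ``conc`` maps each protein class to its concentration in amino-acid
    equivalents per dry mass (so the class values sum to Dc); pools
    ``ci``, ``aa``, ``e`` share the same normalized unit.
    """

    mu: float
    ci: float
    aa: float
    e: float
    conc: dict[str, float]
    fluxes: dict[str, float]
    allocation: Allocation
    alpha: dict[str, float]
    env: EnvironmentalCondition
    residuals: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    status: str = "optimal"

    @property
    def mu_per_second(self) -> float:
        return self.mu / SECONDS_PER_HOUR

    @property
    def mass_fractions(self) -> dict[str, float]:
        total = sum(self.conc.values())
        if total == 0:
            return {z: 0.0 for z in self.conc}
        return {z: v / total for z, v in self.conc.items()}

    def molecules(self, params: ModelParameters) -> dict[str, float]:
        """Molecule-number concentration per class ([Z] = conc_Z / n_Z)."""
        return {z: v / params.protein_length(z) for z, v in self.conc.items()}


# ---------------------------------------------------------------------------
# inner solve: steady state at a fixed proteome partition
# ---------------------------------------------------------------------------

def _solve_fixed_partition(phi: dict[str, float], env: EnvironmentalCondition,
                           params: ModelParameters,
                           alpha: dict[str, float] | None = None):
    """Solve the steady-state balances for a fixed mass partition.

    Returns ``("ok", (mu_per_s, ci, aa, e))`` or ``("infeasible", deficit)``
    when no steady state with mu > 0 exists (e.g. maintenance cannot be
    covered); ``deficit`` is the energy shortfall at mu -> 0.

    The reduction: photosynthetic fluxes depend only on phi_P, so the
    required translation flux is gamma(mu) = mu*Dc + n_P*vi.  At a trial
    mu the amino-acid balance fixes vm = mu*(Dc + aa); combined with the
    product-inhibited metabolic rate law this yields aa in closed form for
    any internal carbon pool ci, the carbon balance then pins ci (scalar
    monotone root), the ribosome capacity yields the energy saturation and
    hence the e pool, and the energy balance closes as a scalar equation
    F(mu) = 0 solved by safeguarded bisection.
    """
    alpha = alpha or {}
    p = params
    Dc = p.Dc
    conc = {z: phi[z] * Dc for z in PROTEIN_CLASSES}  # aa-equivalents
    act = {z: alpha.get(z, 1.0) * conc[z] / p.protein_length(z)
           for z in PROTEIN_CLASSES}  # active molecule concentrations

    psu = kinetics.psu_rates(act["P"], env, p)
    v1, v2, vi = psu
    vt = kinetics.transport_rate(act["T"], env, p)
    damage_mass = p.n_P * vi  # aa-equivalents of P degraded per second
    cap_M = p.kcat_M * act["M"]
    cap_R = p.kcat_R * act["R"]
    maintenance = p.m * Dc
    recov = p.energy_recovery * p.b_r * damage_mass
    c_hi = env.cix + (vt / p.kdiff if p.kdiff > 0 else 0.0) + 1.0

    def aa_of_c(mu: float, c: float) -> float:
        """aa pool satisfying aa balance + inhibited metabolic rate law.

        mu*(Dc + aa)*(Ki + aa) = cap_M*f_c(c)*Ki ; unique root aa >= 0,
        or -1 when metabolism cannot meet the demand mu*Dc even at aa=0.
        """
        K = cap_M * (c / (p.Km_M + c)) * p.Ki_aa
        if K <= mu * Dc * p.Ki_aa:
            return -1.0
        b = mu * (p.Ki_aa + Dc)
        disc = b * b - 4.0 * mu * (mu * Dc * p.Ki_aa - K)
        return (-b + math.sqrt(disc)) / (2.0 * mu)

    def carbon_root(mu: float) -> tuple[float, float] | None:
        """(ci, aa) from the carbon balance, or None if carbon-limited."""
        def H(c):
            aa = aa_of_c(mu, c)
            if aa < 0:
                return math.inf  # metabolism short: push c upward
            vm = mu * (Dc + aa)
            return (kinetics.diffusion_rate(c, env, p) + vt
                    - p.b_c * vm - mu * c)
        top = H(c_hi)
        if top == math.inf:
            return None  # metabolism cannot meet demand at any carbon level
        if top >= 0:  # supply never exhausted: c pegs at the top
            return c_hi, max(aa_of_c(mu, c_hi), 0.0)
        lo, hi = 0.0, c_hi
        if not H(lo) > 0:
            # find a lower bracket just above the metabolic-feasibility edge
            if cap_M <= 0:
                return None
            x = mu * Dc / cap_M
            if x >= 1.0:
                return None
            lo = (p.Km_M * x / (1.0 - x)) * (1.0 + 1e-10) + 1e-300
            if lo >= c_hi or not H(lo) > 0:
                return None  # carbon supply insufficient at this mu
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if H(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-14 * c_hi:
                break
        c = 0.5 * (lo + hi)
        return c, max(aa_of_c(mu, c), 0.0)

    def F(mu: float) -> float | None:
        """Energy-balance residual at growth rate mu; None if infeasible."""
        gamma = mu * Dc + damage_mass
        if cap_R <= 0 or gamma >= cap_R:
            return None
        ca = carbon_root(mu)
        if ca is None:
            return None
        c, aa = ca
        vm = mu * (Dc + aa)
        f_aa = aa / (p.Km_aa + aa)
        sat = gamma / cap_R
        if f_aa <= 0 or sat / f_aa >= 1.0:
            return None
        f_e = sat / f_aa
        e = p.Km_e * f_e / (1.0 - f_e)
        return (v2 + recov - p.b_e * vm - p.b_t * vt - p.b_r * gamma
                - maintenance - mu * e)

    def recover(mu: float):
        gamma = mu * Dc + damage_mass
        c, aa = carbon_root(mu)
        f_aa = aa / (p.Km_aa + aa)
        f_e = min((gamma / cap_R) / max(f_aa, 1e-300), 1.0 - 1e-12)
        e = p.Km_e * f_e / (1.0 - f_e)
        return mu, c, aa, e

    mu_lo = 1e-12
    v_lo = F(mu_lo)
    if v_lo is None or v_lo <= 0:
        # maintenance (or translation) cannot be covered; report the
        # energy deficit so the outer optimizer has a descent direction
        deficit = -v_lo if v_lo is not None else maintenance + damage_mass
        return ("infeasible", deficit)
    mu_hi = (cap_R - damage_mass) / Dc
    if mu_hi <= mu_lo:
        return ("infeasible", maintenance)
    # find an upper bracket where F < 0 (or infeasible)
    hi = mu_hi * (1.0 - 1e-9)
    v_hi = F(hi)
    lo = mu_lo
    # safeguarded bisection treating infeasible evaluations as negative
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v = F(mid)
        if v is not None and v > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-16 + 1e-13 * hi:
            break
    return ("ok", recover(lo))


def _assemble_state(phi: dict[str, float], sol, env: EnvironmentalCondition,
                    params: ModelParameters,
                    alpha: dict[str, float] | None = None,
                    status: str = "optimal") -> SteadyState:
    p = params
    alpha = {z: (alpha or {}).get(z, 1.0) for z in PROTEIN_CLASSES}
    mu_s, c, aa, e = sol
    conc = {z: phi[z] * p.Dc for z in PROTEIN_CLASSES}
    act = {z: alpha[z] * conc[z] / p.protein_length(z) for z in PROTEIN_CLASSES}
    v1, v2, vi = kinetics.psu_rates(act["P"], env, p)
    vt = kinetics.transport_rate(act["T"], env, p)
    vd = kinetics.diffusion_rate(c, env, p)
    vm = kinetics.metabolic_rate(act["M"], c, aa, p)
    gamma_tot = mu_s * p.Dc + p.n_P * vi
    # per-class translation flux (aa-equivalents per second)
    gamma = {z: mu_s * conc[z] for z in PROTEIN_CLASSES}
    gamma["P"] += p.n_P * vi
    beta = {z: (gamma[z] / gamma_tot if gamma_tot > 0 else 0.0)
            for z in PROTEIN_CLASSES}
    fluxes = {"vd": vd, "vt": vt, "vm": vm, "v1": v1, "v2": v2, "vi": vi,
              "mv": p.m * p.Dc}
    fluxes.update({f"gamma_{z}": gamma[z] for z in PROTEIN_CLASSES})
    residuals = {
        "ci": vd + vt - p.b_c * vm - mu_s * c,
        "aa": vm + p.n_P * vi - gamma_tot - mu_s * aa,
        "e": (v2 + p.energy_recovery * p.b_r * p.n_P * vi - p.b_e * vm
              - p.b_t * vt - p.b_r * gamma_tot - p.m * p.Dc - mu_s * e),
    }
    residuals.update({z: gamma[z] - (mu_s * conc[z]
                                     + (p.n_P * vi if z == "P" else 0.0))
                      for z in PROTEIN_CLASSES})
    residuals["density"] = sum(conc.values()) - p.Dc
    allocation = Allocation(beta_T=beta["T"], beta_M=beta["M"],
                            beta_R=beta["R"], beta_P=beta["P"],
                            beta_Q=beta["Q"])
    scale = max(abs(f) for f in fluxes.values()) or 1.0
    converged = max(abs(r) for r in residuals.values()) < 1e-6 * scale
    return SteadyState(mu=mu_s * SECONDS_PER_HOUR, ci=c, aa=aa, e=e,
                       conc=conc, fluxes=fluxes, allocation=allocation,
                       alpha=alpha, env=env, residuals=residuals,
                       converged=converged, status=status)


def _zero_state(phi: dict[str, float], env: EnvironmentalCondition,
                params: ModelParameters, status: str) -> SteadyState:
    conc = {z: phi[z] * params.Dc for z in PROTEIN_CLASSES}
    fluxes = {k: 0.0 for k in ("vd", "vt", "vm", "v1", "v2", "vi", "mv")}
    fluxes.update({f"gamma_{z}": 0.0 for z in PROTEIN_CLASSES})
    return SteadyState(mu=0.0, ci=0.0, aa=0.0, e=0.0, conc=conc,
                       fluxes=fluxes,
                       allocation=Allocation(0.0, 0.0, 0.0, 0.0, 0.0),
                       alpha={z: 1.0 for z in PROTEIN_CLASSES}, env=env,
                       residuals={}, converged=True, status=status)


def _balanced_phi(params: ModelParameters) -> dict[str, float]:
    budget = 1.0 - params.phi_Q
    phi = {z: budget / 4.0 for z in GROWTH_CLASSES}
    phi["Q"] = params.phi_Q
    return phi


# ---------------------------------------------------------------------------
# outer optimization
# ---------------------------------------------------------------------------

_DEFICIT_WEIGHT = 0.02  # maps an energy deficit onto the mu scale


def _score_partition(phi: dict[str, float], env, params, alpha=None) -> float:
    """Objective for the outer search: mu (s^-1), or a smooth negative
    penalty proportional to the energy deficit where no steady state
    exists (both vanish at the feasibility boundary)."""
    status, payload = _solve_fixed_partition(phi, env, params, alpha=alpha)
    if status == "ok":
        return payload[0]
    return -_DEFICIT_WEIGHT * payload


def _analytic_start(env: EnvironmentalCondition,
                    params: ModelParameters) -> dict[str, float]:
    """Near-optimal partition from the linearized budget balance.

    Treats pools as saturated and books, per unit growth rate, the energy
    demand against the photosynthetic supply per unit phi_P, the repair
    load from photodamage against ribosome capacity, and the carbon demand
    against transporter capacity; solving the resulting linear budget for
    mu gives an excellent warm start for the NLP at every light intensity.
    """
    p = params
    budget = (1.0 - p.phi_Q)
    kexc = kinetics.excitation_rate(env.I, p)
    if p.damage_target == "excited":
        s = kexc / (kexc + p.tau + p.kd * kexc)
        dmg = p.kd * kexc * s
    else:
        s = (1.0 - p.kd) * kexc / (p.tau + (1.0 - p.kd) * kexc)
        dmg = p.kd * kexc * p.tau / (p.tau + (1.0 - p.kd) * kexc)
    q_P = p.tau * s / p.n_P          # energy supply per phi_P
    if q_P <= 0:
        return _balanced_phi(p)
    r = p.n_R / (p.kcat_R * 0.8)     # ribosome mass per unit synthesis flux
    G_M = 2.0 * p.n_M / p.kcat_M     # metabolic mass per unit mu
    f_T = env.cix / (p.Km_T + env.cix) if env.cix > 0 else 1.0
    vd_typ = p.kdiff * env.cix * 0.5
    G_T = p.b_c * p.n_T / (p.kcat_T * max(f_T, 1e-9))
    v_T = vd_typ * p.n_T / (p.kcat_T * max(f_T, 1e-9))
    B = p.b_e + p.b_r + p.b_c * p.b_t
    rD = r * dmg
    denom = (B / q_P) * (1.0 + rD) + r + G_M + G_T
    mu = (budget + v_T - (p.m * p.Dc / q_P) * (1.0 + rD)) / denom
    mu = max(mu, 1e-8)
    phi_P = (B * mu + p.m * p.Dc) / q_P
    phi_R = r * (mu + dmg * phi_P)
    phi_M = G_M * mu
    phi_T = max(G_T * mu - v_T, _PHI_MIN * 2)
    raw = {"T": phi_T, "M": phi_M, "R": phi_R, "P": phi_P}
    total = sum(raw.values())
    phi = {z: max(budget * v / total, _PHI_MIN * 2) for z, v in raw.items()}
    # renormalize exactly onto the budget
    excess = sum(phi.values()) - budget
    phi["P"] -= excess
    phi["Q"] = p.phi_Q
    return phi


def _optimize_partition(env: EnvironmentalCondition, params: ModelParameters,
                        fixed: dict[str, float] | None = None,
                        alpha_class: str | None = None,
                        phi_start: dict[str, float] | None = None):
    """Maximize mu over the free proteome fractions (and alpha if present).

    Returns ``(phi, alpha, sol)``.  Deterministic multi-start SLSQP.
    """
    p = params
    fixed = dict(fixed or {})
    fixed["Q"] = p.phi_Q
    free_names = [z for z in GROWTH_CLASSES if z not in fixed]
    budget_free = 1.0 - sum(fixed.values())
    if budget_free <= len(free_names) * _PHI_MIN:
        raise InfeasibleConstraintError(
            f"fixed fractions {fixed} leave no mass budget for classes "
            f"{free_names}")
    nfree = len(free_names) - 1
    has_alpha = alpha_class is not None

    def unpack(x):
        free = x[:nfree]
        alpha = {alpha_class: float(x[-1])} if has_alpha else None
        return free, alpha

    def phi_of(x):
        phi = dict(fixed)
        phi.update(dict(zip(free_names[:-1], x[:nfree])))
        phi[free_names[-1]] = budget_free - sum(x[:nfree])
        return phi

    def neg_mu(x):
        # scored in h^-1 so the objective is O(0.1) for finite differencing
        phi = phi_of(x)
        if phi[free_names[-1]] < _PHI_MIN * 0.5:
            return 1.0
        _, alpha = unpack(x)
        return -SECONDS_PER_HOUR * _score_partition(phi, env, p, alpha=alpha)

    guesses: list[dict[str, float]] = []
    base = _analytic_start(env, p)
    if phi_start is not None:
        # warm start from a neighbouring solution: two starts suffice
        guesses = [dict(phi_start), base]
    else:
        guesses = [base,
                   {z: (0.7 * v if z == "P" else 1.3 * v)
                    for z, v in base.items()},
                   {"T": 0.1, "M": 0.1, "R": 0.3, "P": 0.5, "Q": p.phi_Q}]

    starts = []
    for g in guesses:
        tot = sum(max(g.get(z, _PHI_MIN), _PHI_MIN) for z in free_names)
        x0 = [max(g.get(z, _PHI_MIN), _PHI_MIN) * budget_free / tot
              for z in free_names[:-1]]
        if has_alpha:
            x0.append(1.0)
        starts.append(np.asarray(x0, dtype=float))

    bounds = [(_PHI_MIN, budget_free - nfree * _PHI_MIN)] * nfree
    if has_alpha:
        bounds.append((0.0, 1.0))
    constraints = []
    if nfree > 1:
        constraints.append({
            "type": "ineq",
            "fun": lambda x: budget_free - _PHI_MIN - sum(x[:nfree]),
        })

    best_x, best_val = None, math.inf
    for x0 in starts:
        res = minimize(neg_mu, x0, method="SLSQP", bounds=bounds,
                       constraints=constraints,
                       options={"maxiter": 300, "ftol": 1e-10})
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    if best_x is None:
        raise SolverError("allocation optimization failed at "
                          f"I={env.I}, cix={env.cix}")
    _, alpha = unpack(best_x)
    phi = phi_of(best_x)
    status, payload = _solve_fixed_partition(phi, env, p, alpha=alpha)
    return phi, alpha, (payload if status == "ok" else None)


def steady_state_growth(params: ModelParameters, env: EnvironmentalCondition,
                        method: str = "nlp", step: float = 0.05,
                        phi_start: dict[str, float] | None = None
                        ) -> SteadyState:
    """Solve the growth-rate-maximizing steady state at one condition.

    Parameters
    ----------
    params, env
        Model constants and external condition.
    method
        ``"nlp"`` (SLSQP over the allocation simplex, default) or
        ``"enumerate"`` (brute-force grid over the simplex with the given
        ``step``; independent cross-check route).
    step
        Grid resolution (fraction of Dc) for ``method="enumerate"``.
    phi_start
        Optional warm-start partition (used by :func:`light_response`).
    """
    if env.I == 0.0:
        # dark limit: photosynthesis is the only energy source, so the
        # maintenance drain precludes any steady state with mu > 0
        return _zero_state(_balanced_phi(params), env, params, status="dark")
    if method == "enumerate":
        phi, sol = _enumerate_partitions(params, env, step)
        if sol is None:
            return _zero_state(phi or _balanced_phi(params), env, params,
                               status="infeasible")
        return _assemble_state(phi, sol, env, params, status="enumerated")
    if method != "nlp":
        raise ValueError(f"unknown method {method!r}")
    phi, alpha, sol = _optimize_partition(env, params, phi_start=phi_start)
    if sol is None:
        return _zero_state(phi, env, params, status="infeasible")
    return _assemble_state(phi, sol, env, params)


def _enumerate_partitions(params: ModelParameters,
                          env: EnvironmentalCondition, step: float):
    """Exhaustive search over the allocation simplex at resolution ``step``."""
    budget = 1.0 - params.phi_Q
    n = int(round(budget / step))
    best_phi, best_sol = None, None
    best_mu = -math.inf
    for i in range(n + 1):
        for j in range(n + 1 - i):
            for k in range(n + 1 - i - j):
                ell = n - i - j - k
                phi = {"T": i * step, "M": j * step, "R": k * step,
                       "P": ell * step, "Q": params.phi_Q}
                if min(phi["T"], phi["M"], phi["R"], phi["P"]) <= 0:
                    continue
                status, payload = _solve_fixed_partition(phi, env, params)
                if status == "ok" and payload[0] > best_mu:
                    best_mu, best_phi, best_sol = payload[0], phi, payload
    return best_phi, best_sol


def constrained_growth(params: ModelParameters, env: EnvironmentalCondition,
                       constraint: ConstraintSpec) -> SteadyState:
    """Maximize mu with one protein class pinned at a fixed mass fraction.

    The pinned class keeps concentration ``phi_Z * Dc / n_Z``; its active
    fraction alpha_Z in [0, 1] is optimized together with the remaining
    free fractions.  By optimization dominance the constrained optimum
    never exceeds the unconstrained one (up to solver tolerance).
    """
    if constraint.phi_Z >= 1.0 - params.phi_Q:
        raise InfeasibleConstraintError(
            f"phi_{constraint.class_id}={constraint.phi_Z} exceeds the "
            f"adjustable budget {1.0 - params.phi_Q}")
    if env.I == 0.0:
        phi = _balanced_phi(params)
        phi[constraint.class_id] = constraint.phi_Z
        return _zero_state(phi, env, params, status="dark")
    phi, alpha, sol = _optimize_partition(
        env, params, fixed={constraint.class_id: constraint.phi_Z},
        alpha_class=constraint.class_id)
    if sol is None:
        return _zero_state(phi, env, params, status="infeasible")
    return _assemble_state(phi, sol, env, params, alpha=alpha,
                           status="constrained")


def light_response(params: ModelParameters, I_grid: Iterable[float],
                   cix: float = 100.0, method: str = "nlp",
                   constraint: ConstraintSpec | None = None
                   ) -> list[SteadyState]:
    """Solve one steady state per light intensity, warm-starting along the grid.

    Solver failures at single grid points are recorded in the per-point
    ``status`` ("failed") and do not abort the sweep.
    """
    I_grid = list(I_grid)
    if not I_grid:
        raise ValueError("I_grid must be nonempty")
    if any(b < a for a, b in zip(I_grid, I_grid[1:])):
        raise ValueError("I_grid must be nondecreasing")
    states: list[SteadyState] = []
    phi_prev: dict[str, float] | None = None
    for I in I_grid:
        env = EnvironmentalCondition(I=I, cix=cix)
        try:
            if constraint is None:
                st = steady_state_growth(params, env, method=method,
                                         phi_start=phi_prev)
            else:
                st = constrained_growth(params, env, constraint)
            phi_prev = st.mass_fractions
        except (SolverError, InfeasibleConstraintError) as exc:
            st = _zero_state(phi_prev or _balanced_phi(params), env, params,
                             status="failed")
            st.converged = False
            st.residuals["error"] = float("nan")
        states.append(st)
    return states


def light_response_frame(states: Sequence[SteadyState]):
    """Tabulate a light-response sweep (one row per intensity)."""
    import pandas as pd

    rows = []
    for st in states:
        row = {"I": st.env.I, "mu": st.mu, "status": st.status}
        row.update({f"fraction_{z}": st.mass_fractions[z]
                    for z in PROTEIN_CLASSES})
        row.update(st.fluxes)
        rows.append(row)
    return pd.DataFrame(rows)
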