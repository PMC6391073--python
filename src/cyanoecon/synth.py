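"""Synthetic-data generators with planted ground truth.

Every input the analysis consumes can be generated here under a fixed
seed: turbidostat OD680 sawtooth traces, dissolved-O2 traces with
alternating 5-min light/dark phases, a proteins x samples intensity
matrix with planted growth-dependent archetype profiles, and light-growth
observations produced by the allocation model itself.  Ground-truth
labels are returned alongside every dataset and are never consumed by the
pipeline under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import GrowthObservation
from .growth import light_response
from .params import ModelParameters
from .physiology import ODTrace
from .proteome import IntensityMatrix

#: condition labels: the six proteomics light intensities
DEFAULT_GROUPS = ("27.5", "55", "110", "220", "440", "1100")

def _shape(direction: Sequence[float], amplitude: float = 0.5) -> np.ndarray:
    v = np.asarray(direction, dtype=float)
    return 1.0 + amplitude * v / np.linalg.norm(v)


#: archetype profiles over the six light groups, emulating the observed
#: cluster shapes: monotone up and down, a photoinhibition spike, a
#: mid-intensity peak, an up-then-kink-down and a down-then-recovery
#: profile, and a low-light-only profile.  The shapes are zero-sum
#: deviations of equal amplitude around the mean so that the planted
#: clusters are comparably separated.
ARCHETYPES: dict[str, np.ndarray] = {
    "monotone_up": _shape([-5, -3, -1, 1, 3, 5]),
    "monotone_down": _shape([5, 3, 1, -1, -3, -5]),
    "spike_high": _shape([-1, -1, -1, -1, -1, 5]),
    "mid_peak": _shape([-5, 1, 4, 4, 1, -5]),
    "up_kink_down": _shape([-2, -1, 0, 2, 4, -3]),
    "down_recover": _shape([3, 1, 0, -2, -4, 2]),
    "low_light_only": _shape([5, -1, -1, -1, -1, -1]),
}

#: default share of dependent proteins per archetype (the observed size
#: proportions of the seven expression clusters, matched by shape)
DEFAULT_ARCHETYPE_WEIGHTS = (192, 65, 2, 124, 41, 79, 218)


@dataclass
class SyntheticSpec:
    """Configuration of the synthetic study (defaults = study conditions).

    Six light-intensity groups with five biological replicates, 1356
    identified proteins of which ~57% are growth dependent, log-normal
    replicate noise and intensity-dependent (left-censoring-like)
    missingness; the turbidostat band is OD680 0.60-0.66.
    """

    seed: int = 0
    n_proteins: int = 1356
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates: int = 5
    dependent_fraction: float = 779 / 1356
    archetype_weights: tuple[float, ...] = DEFAULT_ARCHETYPE_WEIGHTS
    noise_cv: float = 0.15
    missing_rate: float = 0.10
    missing_width: float = 1.5    # logistic width in log2-intensity units
    n_contaminants: int = 20
    n_reverse: int = 10
    n_low_evidence: int = 25
    od_bounds: tuple[float, float] = (0.60, 0.66)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dependent_fraction <= 1.0:
            raise ValueError("dependent_fraction must lie in [0, 1]")
        if self.replicates < 3:
            raise ValueError("need at least 3 replicates per group")
        if self.noise_cv < 0 or not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("invalid noise_cv or missing_rate")
        if self.od_bounds[0] <= 0 or self.od_bounds[1] <= self.od_bounds[0]:
            raise ValueError("od_bounds must be an increasing positive pair")


# ---------------------------------------------------------------------------
# turbidostat OD trace
# ---------------------------------------------------------------------------

def simulate_turbidostat(mu_true: float, spec: SyntheticSpec,
                         duration: float, sample_interval: float = 1.0 / 12.0,
                         sensor_noise_cv: float = 0.0) -> ODTrace:
    """Exponential sawtooth OD680 trace between the turbidostat bounds.

    Growth segments follow ``OD(t) = lo * exp(mu (t - t0))``; when the
    next sample would exceed the upper bound the culture is instantly
    diluted back to the lower bound (event recorded).  Optional
    multiplicative log-normal sensor noise.  Noiseless traces round-trip
    the planted rate exactly through the OD-based estimator.
    """
    if mu_true <= 0:
        raise ValueError("mu_true must be > 0")
    lo, hi = spec.od_bounds
    if duration < math.log(hi / lo) / mu_true:
        import warnings
        warnings.warn("duration shorter than one pass through the OD band")
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, duration + 1e-12, sample_interval)
    od = np.empty_like(times)
    events = []
    t_seg = times[0]
    for i, t in enumerate(times):
        value = lo * math.exp(mu_true * (t - t_seg))
        if value > hi + 1e-12:
            events.append(t)
            t_seg = t
            value = lo
        od[i] = value
    if sensor_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + sensor_noise_cv ** 2))
        od = od * rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                size=od.shape)
    return ODTrace(time=times, od680=od,
                   dilution_events=np.asarray(events))


# ---------------------------------------------------------------------------
# dissolved-O2 trace
# ---------------------------------------------------------------------------

def simulate_gas_trace(NP: float, R_dark: float, spec: SyntheticSpec,
                       n_cycles: int = 1, phase_s: float = 300.0,
                       dt_s: float = 5.0, noise_sd: float = 0.0,
                       ) -> tuple[np.ndarray, np.ndarray,
                                  list[tuple[float, float, str]]]:
    """Piecewise-linear dO2 trace with annotated 5-min light/dark phases.

    The light-phase slope is ``NP`` and the dark-phase slope ``-R_dark``
    (per second, in whatever rate unit the caller uses), plus Gaussian
    sensor noise.  Returns ``(time_s, dO2, phases)``.
    """
    if NP < 0 or R_dark < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(spec.seed)
    times, values, phases = [], [], []
    t = 0.0
    level = 100.0  # arbitrary starting concentration
    for _ in range(n_cycles):
        for kind, slope in (("light", NP), ("dark", -R_dark)):
            start = t
            n = int(round(phase_s / dt_s))
            for _ in range(n):
                times.append(t)
                values.append(level)
                level += slope * dt_s
                t += dt_s
            phases.append((start, t - dt_s, kind))
    time_s = np.asarray(times)
    dO2 = np.asarray(values)
    if noise_sd > 0:
        dO2 = dO2 + rng.normal(0.0, noise_sd, size=dO2.shape)
    return time_s, dO2, phases


# ---------------------------------------------------------------------------
# proteomics intensity matrix
# ---------------------------------------------------------------------------

def simulate_proteomics(spec: SyntheticSpec
                        ) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Proteins x samples LFQ/iBAQ matrix with planted ground truth.

    Intensities are log-normal around a per-protein baseline, multiplied
    by the archetype profile across groups for dependent proteins (flat
    for independent ones) and by replicate noise of coefficient of
    variation ``noise_cv``.  Missingness is logistic in log2 intensity
    (lower intensities are more likely missing).  Contaminant, reverse
    and single-peptide decoy entries are appended; they carry intensities
    but are expected to be removed by the filters.

    Returns the matrix and a truth table (dependent flag, archetype,
    baseline) indexed like the matrix.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(ARCHETYPES)
    n_dep = int(round(spec.dependent_fraction * spec.n_proteins))
    if 0 < n_dep < len(names):
        raise ValueError(
            f"dependent_fraction places {n_dep} proteins over "
            f"{len(names)} archetypes; increase n_proteins or the fraction")
    weights = np.asarray(spec.archetype_weights, dtype=float)
    if len(weights) != len(names) or np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("archetype_weights must be nonnegative, one per "
                         f"archetype ({len(names)})")
    samples = [f"I{g}_r{r + 1}" for g in spec.groups
               for r in range(spec.replicates)]
    groups = {f"I{g}_r{r + 1}": g for g in spec.groups
              for r in range(spec.replicates)}
    n_groups = len(spec.groups)

    def profile_for(archetype: str | None) -> np.ndarray:
        if archetype is None:
            return np.ones(n_groups)
        prof = ARCHETYPES[archetype]
        if len(prof) == n_groups:
            return prof
        # resample the canonical 6-point shape onto the group count
        x = np.linspace(0.0, 1.0, len(prof))
        return np.interp(np.linspace(0.0, 1.0, n_groups), x, prof)

    ids, rows, truth = [], [], []
    arche_choices = rng.choice(len(names), size=n_dep,
                               p=weights / weights.sum())
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2)) \
        if spec.noise_cv > 0 else 0.0
    for i in range(spec.n_proteins):
        pid = f"SYN{i:04d}"
        dependent = i < n_dep
        archetype = names[arche_choices[i]] if dependent else None
        baseline = 2.0 ** rng.normal(23.0, 2.0)
        prof = profile_for(archetype)
        means = baseline * np.repeat(prof, spec.replicates)
        if sigma > 0:
            noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                  size=means.size)
        else:
            noise = 1.0
        ids.append(pid)
        rows.append(means * noise)
        truth.append({"protein_id": pid, "dependent": dependent,
                      "archetype": archetype or "", "baseline": baseline})
    lfq = pd.DataFrame(np.vstack(rows), index=ids, columns=samples)

    # intensity-dependent missingness (left-censoring-like)
    if spec.missing_rate > 0:
        logv = np.log2(lfq.to_numpy())
        t0 = np.quantile(logv, spec.missing_rate)
        p_miss = 1.0 / (1.0 + np.exp((logv - t0) / spec.missing_width))
        p_miss *= spec.missing_rate / max(p_miss.mean(), 1e-12)
        mask = rng.random(logv.shape) < np.clip(p_miss, 0.0, 0.95)
        arr = lfq.to_numpy()
        arr[mask] = np.nan
        lfq = pd.DataFrame(arr, index=ids, columns=samples)

    peptides = pd.Series(rng.poisson(8, size=len(ids)) + 2, index=ids)
    contaminant = pd.Series(False, index=ids)
    reverse = pd.Series(False, index=ids)

    # decoys: contaminants, reverse hits, single-peptide identifications
    decoy_rows, decoy_ids = [], []
    decoy_meta = []
    for j in range(spec.n_contaminants):
        decoy_ids.append(f"CON_{j:03d}")
        decoy_meta.append((True, False, int(rng.integers(2, 12))))
    for j in range(spec.n_reverse):
        decoy_ids.append(f"REV_{j:03d}")
        decoy_meta.append((False, True, int(rng.integers(2, 12))))
    for j in range(spec.n_low_evidence):
        decoy_ids.append(f"LOWPEP{j:03d}")
        decoy_meta.append((False, False, 1))
    for _ in decoy_ids:
        base = 2.0 ** rng.normal(21.0, 2.0)
        decoy_rows.append(base * rng.lognormal(0.0, 0.3, size=len(samples)))
    if decoy_ids:
        decoy_lfq = pd.DataFrame(np.vstack(decoy_rows), index=decoy_ids,
                                 columns=samples)
        lfq = pd.concat([lfq, decoy_lfq])
        peptides = pd.concat([
            peptides, pd.Series([m[2] for m in decoy_meta], index=decoy_ids)])
        contaminant = pd.concat([
            contaminant, pd.Series([m[0] for m in decoy_meta],
                                   index=decoy_ids)])
        reverse = pd.concat([
            reverse, pd.Series([m[1] for m in decoy_meta], index=decoy_ids)])
        for pid, meta in zip(decoy_ids, decoy_meta):
            truth.append({"protein_id": pid, "dependent": False,
                          "archetype": "decoy", "baseline": float("nan")})

    # iBAQ: LFQ scaled by the per-protein count of observable peptides
    observable = pd.Series(rng.integers(6, 31, size=len(lfq)),
                           index=lfq.index)
    ibaq = lfq.div(observable, axis=0)

    matrix = IntensityMatrix(lfq=lfq, ibaq=ibaq, peptide_counts=peptides,
                             contaminant=contaminant, reverse=reverse,
                             groups=groups)
    truth_df = pd.DataFrame(truth).set_index("protein_id")
    return matrix, truth_df


# ---------------------------------------------------------------------------
# light--growth observations from the model
# ---------------------------------------------------------------------------

def simulate_growth_observations(theta_true: tuple[float, float, float],
                                 params: ModelParameters,
                                 I_grid: Sequence[float],
                                 noise_sds: Sequence[float] | float = 0.002,
                                 seed: int = 0,
                                 noise_scale: float = 1.0,
                                 cix: float = 100.0
                                 ) -> list[GrowthObservation]:
    """Growth observations from the model at a known parameter triple.

    ``noise_sds`` provides the per-point uncertainty e_i (scalar or one
    per intensity); Gaussian noise of that SD (times ``noise_scale``;
    0 for noiseless) is added to the model's growth rates.  Negative
    draws are clipped at 0.
    """
    tau, kd, sigma = theta_true
    p = params.with_theta(tau=tau, kd=kd, sigma=sigma)
    I_grid = list(I_grid)
    if np.isscalar(noise_sds):
        noise_sds = [float(noise_sds)] * len(I_grid)
    if len(noise_sds) != len(I_grid):
        raise ValueError("need one noise SD per intensity")
    rng = np.random.default_rng(seed)
    states = light_response(p, sorted(I_grid), cix=cix)
    mu_at = {st.env.I: st.mu for st in states}
    failed = [st.env.I for st in states if st.status == "failed"]
    if failed:
        raise RuntimeError(f"model solve failed at intensities {failed}")
    obs = []
    for I, sd in zip(I_grid, noise_sds):
        y = mu_at[I] + noise_scale * rng.normal(0.0, sd)
        obs.append(GrowthObservation(I=I, x=max(y, 0.0), e=sd))
    return obs
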