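"""Parameter and environment containers for the proteome-allocation growth model.

The model coarse-grains the proteome of a phototrophic cell into five
classes -- carbon transport (T), metabolism (M), ribosomes (R),
photosynthetic units (P) and a growth-independent remainder (Q) -- and
describes light-driven growth through a small set of kinetic and
stoichiometric constants.  Three of them (``sigma``, ``tau``, ``kd``) are
the quantities estimated from light--growth data; the remainder are fixed
model constants with literature-plausible magnitudes (see
``docs/methods.md`` for the parametrization rationale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Mapping

import yaml

AVOGADRO = 6.02214076e23

PROTEIN_CLASSES = ("T", "M", "R", "P", "Q")
#: classes whose allocation the cell optimizes (Q is held at a fixed share)
GROWTH_CLASSES = ("T", "M", "R", "P")


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the coarse-grained phototrophic growth model.

    Rates are per second; ``sigma`` is an absorption cross-section in nm^2;
    light intensities are supplied separately (micromol photons m^-2 s^-1).
    Concentration-like quantities (pools, Km values, ``Dc``) share one
    normalized amino-acid-equivalent unit in which the total protein
    density ``Dc`` is 1 by default, except the external-carbon scale
    (``Km_T``, ``EnvironmentalCondition.cix``) which is tagged in mM.

    Parameters
    ----------
    sigma : float
        Effective absorption cross-section per photosynthetic unit (nm^2).
    tau : float
        Photosynthetic-unit turnover rate (s^-1).
    kd : float
        Photodamage probability per excitation (dimensionless, in [0, 1]).
    kdiff : float
        Passive inorganic-carbon diffusion rate constant (s^-1 mM^-1,
        fixed for a ~2 um spherical cell).
    kcat_T, Km_T : float
        Transporter turnover (carbon s^-1 per transporter) and
        half-saturation for external carbon (mM).
    kcat_M, Km_M : float
        Metabolic turnover (amino acids s^-1 per enzyme) and
        half-saturation for internal carbon.
    Ki_aa : float
        Product-inhibition constant of metabolism by the amino-acid pool
        (end-product feedback; throttles amino-acid synthesis when the
        pool accumulates).
    kcat_R, Km_aa, Km_e : float
        Ribosome elongation rate (aa s^-1) and half-saturations for the
        amino-acid and energy pools.
    m : float
        Maintenance energy drain (energy units per Dc per second).
    phi_Q : float
        Mass fraction of the growth-independent proteome class Q.
    Dc : float
        Cell protein density (amino-acid equivalents; normalization basis).
    n_T, n_M, n_R, n_P, n_Q : float
        Protein length per class (amino acids per molecule).
    b_c : float
        Carbon atoms consumed per amino acid synthesized.
    b_e : float
        Energy units consumed per amino acid synthesized (anabolic cost).
    b_r : float
        Energy units consumed per amino acid translated (GTP cost).
    b_t : float
        Energy units consumed per carbon imported by active transport.
    damage_target : str
        Which PSU state photodamage acts on: ``"excited"`` (default) or
        ``"ground"``.
    energy_recovery : float
        Fraction of the translation energy cost recovered when a damaged
        photosynthetic unit is degraded (default 0: no recovery).
    """

    sigma: float = 0.7
    tau: float = 75.0
    kd: float = 1.0e-6
    kdiff: float = 3.0e-7
    kcat_T: float = 20.0
    Km_T: float = 15.0
    kcat_M: float = 10.0
    Km_M: float = 10.0
    Ki_aa: float = 0.05
    kcat_R: float = 8.0
    Km_aa: float = 1.0e-3
    Km_e: float = 1.0e-3
    m: float = 1.3e-4
    phi_Q: float = 0.5
    Dc: float = 1.0
    n_T: float = 1700.0
    n_M: float = 2500.0
    n_R: float = 7360.0
    n_P: float = 11000.0
    n_Q: float = 300.0
    b_c: float = 5.0
    b_e: float = 39.0
    b_r: float = 4.0
    b_t: float = 0.5
    damage_target: str = "excited"
    energy_recovery: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau", "kdiff", "kcat_T", "Km_T", "kcat_M", "Km_M",
                     "Ki_aa", "kcat_R", "Km_aa", "Km_e", "Dc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.kd <= 1.0:
            raise ValueError("kd must lie in [0, 1]")
        if not 0.0 <= self.phi_Q < 1.0:
            raise ValueError("phi_Q must lie in [0, 1)")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        for z in PROTEIN_CLASSES:
            if self.protein_length(z) < 1:
                raise ValueError(f"n_{z} must be >= 1")
        if self.damage_target not in ("excited", "ground"):
            raise ValueError("damage_target must be 'excited' or 'ground'")
        if not 0.0 <= self.energy_recovery <= 1.0:
            raise ValueError("energy_recovery must lie in [0, 1]")

    def protein_length(self, z: str) -> float:
        """Amino acids per molecule of class ``z``."""
        return getattr(self, f"n_{z}")

    def with_theta(self, tau: float | None = None, kd: float | None = None,
                   sigma: float | None = None) -> "ModelParameters":
        """Copy with the fitted triple (tau, kd, sigma) replaced."""
        kw = {}
        if tau is not None:
            kw["tau"] = tau
        if kd is not None:
            kw["kd"] = kd
        if sigma is not None:
            kw["sigma"] = sigma
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        values = {k: v["value"] if isinstance(v, Mapping) else v
                  for k, v in doc.get("parameters", doc).items()}
        return cls.from_dict(values)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"parameters": self.to_dict()}, fh, sort_keys=False)


@dataclass(frozen=True)
class EnvironmentalCondition:
    """External condition: light intensity and inorganic carbon.

    ``I`` in micromol photons m^-2 s^-1; ``cix`` in mM (default 100,
    the carbon-saturated condition used for parameter estimation).
    """

    I: float = 0.0
    cix: float = 100.0

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValueError("light intensity I must be >= 0")
        if self.cix < 0:
            raise ValueError("external carbon cix must be >= 0")


def default_parameters() -> ModelParameters:
    """The packaged default parameter set (fitted triple included)."""
    ref = resources.files("cyanoecon.data").joinpath("params_default.yaml")
    with resources.as_file(ref) as path:
        return ModelParameters.from_yaml(path)


@dataclass(frozen=True)
class Allocation:
    """Ribosome allocation: fraction of translation capacity per class.

    ``beta_Q`` is the remainder that maintains the fixed Q share.
    """

    beta_T: float
    beta_M: float
    beta_R: float
    beta_P: float
    beta_Q: float = field(default=0.0)

    def __post_init__(self) -> None:
        vals = [self.beta_T, self.beta_M, self.beta_R, self.beta_P, self.beta_Q]
        if any(b < -1e-12 for b in vals):
            raise ValueError("allocation fractions must be >= 0")
        if math.fsum(vals) > 1.0 + 1e-9:
            raise ValueError("allocation fractions must sum to <= 1")

    def as_dict(self) -> dict:
        return {z: getattr(self, f"beta_{z}") for z in PROTEIN_CLASSES}
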