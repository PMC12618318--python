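"""Constitutive laws of the head-neck structures.

The toolkit ships the parameter sets used to drive the head-neck model:
linear elastic (skull, dura, pia, vertebrae), linear viscoelastic (scalp,
single-exponential shear relaxation), one-term polynomial hyperelastic with
optional Prony relaxation (CSF, intervertebral disks), hyper-viscoelastic
neo-Hookean brain tissue (white and gray matter with a normalized two-term
Prony series), Hill-type muscles and linear-spring ligaments, plus the
scalp erosion rule (element deletion above 60% maximum principal strain).

Moduli are stored in the unit their literature source quotes (MPa, kPa or
GPa, recorded per preset), Prony relaxation times in seconds, densities in
kg/m^3.  The scalp decay constant is quoted in the literature without a
unit; its time unit is therefore an explicit, configurable field (default
1/ms) rather than a silent guess.

Evaluators:

``relaxation_modulus(params, t)``
    G(t) = Ginf + (G0 - Ginf) e^(-beta t)          (scalp)
    G(t) = Ginf + sum_i Gi e^(-t/tau_i)            (brain, normalized)
    G(t) = sum_k Gk e^(-t/tau_k)                   (disks, as printed)
``strain_energy(params, ...)``
    W = mu/2 (I1 - 3) + K/2 (J - 1)^2              (brain)
    W = sum C_pq (J1-3)^p (J2-3)^q + K/2 (J-1)^2   (CSF / disks)
``hill_muscle_force(params, L, v, a)``
    F = Fmax fFL(L) fFV(v) a  +  passive exponential for L > Lrest,
    Fmax = sigma_max * PCSA with sigma_max = 0.3 MPa by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field as dfield

import numpy as np
import yaml

__all__ = [
    "LinearElasticParams",
    "LinearViscoelasticParams",
    "PolynomialHyperelasticParams",
    "HyperViscoelasticBrainParams",
    "HillMuscleParams",
    "LigamentSpringParams",
    "ErosionRule",
    "relaxation_modulus",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "hill_muscle_force",
    "ligament_force",
    "erosion_check",
    "material_registry",
    "save_registry",
    "load_registry",
]


@dataclass
class LinearElasticParams:
    E: float               # elastic modulus
    nu: float              # Poisson ratio
    rho: float             # density, kg/m^3
    E_unit: str = "MPa"

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")


@dataclass
class LinearViscoelasticParams:
    G0: float              # short-term shear modulus, MPa
    Ginf: float            # long-term shear modulus, MPa
    K: float               # bulk modulus, MPa
    beta: float            # decay constant, 1 / beta_time_unit
    rho: float
    beta_time_unit: str = "ms"

    def __post_init__(self):
        if not self.G0 >= self.Ginf > 0:
            raise ValueError("need G0 >= Ginf > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class PolynomialHyperelasticParams:
    """W = sum_pq C_pq (J1-3)^p (J2-3)^q + K/2 (J-1)^2.

    ``Cpq`` maps (p, q) -> coefficient in MPa.  The bulk modulus of the
    volumetric term comes from near-incompressibility: K = 2 mu (1+nu) /
    (3 (1-2 nu)) with mu = 2 (C10 + C01).
    """

    Cpq: dict
    nu: float
    rho: float
    prony: list = dfield(default_factory=list)  # [(Gk, tau_k seconds), ...]

    def __post_init__(self):
        self.Cpq = {tuple(int(x) for x in k): float(v) for k, v in dict(self.Cpq).items()}
        if not any(v != 0 for v in self.Cpq.values()):
            raise ValueError("need at least one nonzero C_pq")
        if any(tau <= 0 for _, tau in self.prony):
            raise ValueError("Prony relaxation times must be positive")

    @property
    def mu(self) -> float:
        return 2.0 * (self.Cpq.get((1, 0), 0.0) + self.Cpq.get((0, 1), 0.0))

    @property
    def K(self) -> float:
        return 2.0 * self.mu * (1.0 + self.nu) / (3.0 * (1.0 - 2.0 * self.nu))


@dataclass
class HyperViscoelasticBrainParams:
    """Neo-Hookean brain tissue with a normalized Prony relaxation series."""

    mu0: float             # instantaneous shear modulus, kPa
    muinf: float           # long-term shear modulus, kPa
    Ginf: float            # normalized long-term Prony coefficient
    prony: list            # [(Gi, tau_i seconds), ...], normalized
    K: float               # bulk modulus, GPa
    rho: float

    def __post_init__(self):
        if not self.mu0 > self.muinf > 0:
            raise ValueError("need mu0 > muinf > 0")
        total = self.Ginf + sum(g for g, _ in self.prony)
        if abs(total - 1.0) > 0.02:
            raise ValueError(f"normalized Prony coefficients sum to {total}, not ~1")


@dataclass
class HillMuscleParams:
    pcsa: float            # physiological cross-sectional area, mm^2
    volume: float          # muscle volume, mm^3
    sigma_max: float = 0.3  # maximum muscle stress, MPa (N/mm^2)
    ksh: float = 3.0       # passive exponential shape constant (assumed)
    lmax: float = 1.5      # max passive stretch ratio (assumed)
    fl_width: float = 0.5  # Gaussian force-length width
    fv_shape: float = 0.25  # Hill hyperbola shape parameter

    def __post_init__(self):
        if self.pcsa <= 0 or self.volume <= 0:
            raise ValueError("pcsa and volume must be positive")

    @property
    def lrest(self) -> float:
        """Resting length, mm: muscle volume divided by PCSA."""
        return self.volume / self.pcsa

    @property
    def vmax(self) -> float:
        """Maximum shortening velocity, mm/s: 10 resting lengths per second."""
        return 10.0 * self.lrest

    @property
    def fmax(self) -> float:
        """Maximum isometric force, N: sigma_max * PCSA."""
        return self.sigma_max * self.pcsa


@dataclass
class LigamentSpringParams:
    k: float               # stiffness, N/mm
    tension_only: bool = True

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("stiffness must be >= 0")


@dataclass
class ErosionRule:
    strain_threshold: float = 0.60
    strain_measure: str = "max-principal-Green-Lagrange"

    def __post_init__(self):
        if self.strain_threshold <= 0:
            raise ValueError("strain threshold must be positive")


# ---------------------------------------------------------------------------
# evaluators

def relaxation_modulus(params, t):
    """Shear relaxation modulus G(t); vectorized over t.

    Scalp-type parameters give MPa; brain parameters give the normalized
    (dimensionless) modulus whose t=0 value is Ginf + sum Gi; disk-type
    polynomial parameters with a Prony list evaluate sum Gk e^(-t/tau_k)
    exactly as printed.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("relaxation modulus is defined for t >= 0")
    if isinstance(params, LinearViscoelasticParams):
        out = params.Ginf + (params.G0 - params.Ginf) * np.exp(-params.beta * t)
    elif isinstance(params, HyperViscoelasticBrainParams):
        out = np.full_like(t, params.Ginf, dtype=float)
        for g, tau in params.prony:
            out = out + g * np.exp(-t / tau)
    elif isinstance(params, PolynomialHyperelasticParams):
        if not params.prony:
            raise ValueError("parameter set carries no relaxation series")
        out = np.zeros_like(t, dtype=float)
        for g, tau in params.prony:
            out = out + g * np.exp(-t / tau)
    else:
        raise TypeError(f"no relaxation law for {type(params).__name__}")
    return out if out.ndim else float(out)


def strain_energy(params, I1=None, J=1.0, J2=None):
    """Strain energy density at the given deformation invariants.

    For brain parameters pass ``I1`` (and ``J``); for polynomial materials
    ``I1`` is the first deviatoric invariant J1 and ``J2`` the second.
    Energy comes out in the unit the moduli are quoted in.
    """
    J = float(J)
    if J <= 0:
        raise ValueError("volume ratio J must be positive")
    if isinstance(params, HyperViscoelasticBrainParams):
        if I1 is None:
            raise ValueError("brain energy needs I1")
        # K is stored in GPa, mu0 in kPa: convert K to kPa for one scale
        K_kpa = params.K * 1e6
        return params.mu0 / 2.0 * (float(I1) - 3.0) + K_kpa / 2.0 * (J - 1.0) ** 2
    if isinstance(params, PolynomialHyperelasticParams):
        if I1 is None:
            raise ValueError("polynomial energy needs J1 (pass as I1)")
        J1 = float(I1)
        J2v = 3.0 if J2 is None else float(J2)
        W = 0.0
        for (p, q), c in params.Cpq.items():
            if p == 0 and q == 0:
                continue
            W += c * (J1 - 3.0) ** p * (J2v - 3.0) ** q
        return W + params.K / 2.0 * (J - 1.0) ** 2
    raise TypeError(f"no strain energy for {type(params).__name__}")


def _uniaxial_invariants(lam: float):
    """Isochoric uniaxial stretch: F = diag(lam, lam^-1/2, lam^-1/2)."""
    I1 = lam**2 + 2.0 / lam
    I2 = 2.0 * lam + lam**-2
    return I1, I2


def uniaxial_cauchy_stress(params, stretch):
    """Cauchy stress sigma = lam dW/dlam under isochoric uniaxial stretch.

    Analytic derivative via the invariant chain rule; vectorized over
    ``stretch``.  Unit matches the parameter set's modulus unit.
    """
    lam = np.asarray(stretch, dtype=float)
    if (lam <= 0).any():
        raise ValueError("stretch must be positive")
    dI1 = 2.0 * lam - 2.0 * lam**-2
    dI2 = 2.0 - 2.0 * lam**-3
    if isinstance(params, HyperViscoelasticBrainParams):
        out = lam * (params.mu0 / 2.0) * dI1
    elif isinstance(params, PolynomialHyperelasticParams):
        I1, I2 = _uniaxial_invariants(lam)
        dW = np.zeros_like(lam)
        for (p, q), c in params.Cpq.items():
            if p == 0 and q == 0:
                continue
            term = np.zeros_like(lam)
            if p > 0:
                term = term + p * (I1 - 3.0) ** (p - 1) * (I2 - 3.0) ** q * dI1
            if q > 0:
                term = term + q * (I1 - 3.0) ** p * (I2 - 3.0) ** (q - 1) * dI2
            dW = dW + c * term
        out = lam * dW
    else:
        raise TypeError(f"no hyperelastic stress for {type(params).__name__}")
    return out if out.ndim else float(out)


def force_length_gaussian(l_ratio, width=0.5):
    """Standard bell-shaped active force-length curve, peak 1 at L = Lrest."""
    return np.exp(-(((np.asarray(l_ratio, float) - 1.0) / width) ** 2))


def force_velocity_hill(v, vmax, shape=0.25):
    """Classic Hill hyperbola; 1 at v = 0, 0 at shortening velocity vmax.

    ``v`` is the lengthening velocity (negative = shortening).  Eccentric
    side saturates at 1.4 (a conventional plateau).
    """
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    short = v <= 0
    vs = np.clip(-v[short], 0.0, vmax)
    out[short] = (vmax - vs) / (vmax + vs / shape)
    # eccentric branch: mirror hyperbola approaching 1.4
    vl = v[~short]
    out[~short] = 1.4 - 0.4 * (vmax + vl) / (vmax + 7.56 * vl / shape)
    return out if out.ndim else float(out)


def hill_muscle_force(params: HillMuscleParams, L, v=0.0, activation=0.0,
                      fl=None, fv=None):
    """Total Hill-type muscle force (N) = active + passive.

    active  = Fmax * fFL(L/Lrest) * fFV(v) * activation
    passive = Fmax/(e^Ksh - 1) * [e^{(Ksh/Lmax)(L/Lrest - 1)} - 1], L > Lrest

    ``fl``/``fv`` override the default Gaussian force-length and Hill
    force-velocity shapes (their functional forms vary across the
    Hill-model literature, so they are deliberately pluggable).
    """
    a = np.asarray(activation, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("activation must lie in [0, 1]")
    L = np.asarray(L, dtype=float)
    lr = L / params.lrest
    ffl = fl(lr) if fl is not None else force_length_gaussian(lr, params.fl_width)
    ffv = fv(v) if fv is not None else force_velocity_hill(v, params.vmax, params.fv_shape)
    active = params.fmax * ffl * ffv * a
    stretch = np.maximum(lr - 1.0, 0.0)
    passive = params.fmax / (math.exp(params.ksh) - 1.0) * (
        np.exp(params.ksh / params.lmax * stretch) - 1.0
    )
    out = active + passive
    return out if out.ndim else float(out)


def ligament_force(params: LigamentSpringParams, x):
    """Linear spring force F = k x (N); tension-only by default."""
    x = np.asarray(x, dtype=float)
    f = params.k * x
    if params.tension_only:
        f = np.where(x > 0, f, 0.0)
    return f if f.ndim else float(f)


def erosion_check(strain_tensor, rule: ErosionRule | None = None):
    """Erosion decision from a Green-Lagrange strain tensor.

    Single (3, 3) tensor -> ``(eroded, max_principal_strain)``.
    Batch (n, 3, 3) field -> ``(eroded_ids, surviving_ids, strains)``.
    Non-symmetric input is symmetrized with a warning.
    """
    rule = rule or ErosionRule()
    S = np.asarray(strain_tensor, dtype=float)
    single = S.ndim == 2
    if single:
        S = S[None]
    if S.shape[1:] != (3, 3):
        raise ValueError("strain tensors must be (3, 3) or (n, 3, 3)")
    if not np.allclose(S, np.transpose(S, (0, 2, 1)), atol=1e-12):
        warnings.warn("non-symmetric strain tensor symmetrized")
        S = 0.5 * (S + np.transpose(S, (0, 2, 1)))
    strains = np.linalg.eigvalsh(S)[:, -1]
    eroded = strains > rule.strain_threshold
    if single:
        return bool(eroded[0]), float(strains[0])
    ids = np.arange(len(S))
    return ids[eroded], ids[~eroded], strains


# ---------------------------------------------------------------------------
# registry of the published parameter sets

def material_registry() -> dict:
    """Named presets for every structure of the head-neck model.

    Moduli are stored in the unit they are quoted in; see each preset's
    fields.  The brain presets carry a consistency self-check: the printed
    long-term modulus muinf must match mu0 * Ginf within 3%.
    """
    reg = {
        "scalp": LinearViscoelasticParams(G0=1.70, Ginf=0.68, K=20.0,
                                          beta=0.00003, rho=1100.0),
        "skull": LinearElasticParams(E=15.00e3, nu=0.21, rho=1800.0, E_unit="MPa"),
        "dura_mater": LinearElasticParams(E=5.00, nu=0.45, rho=1200.0, E_unit="MPa"),
        "pia_mater": LinearElasticParams(E=2.30e3, nu=0.45, rho=1000.0, E_unit="MPa"),
        "vertebrae": LinearElasticParams(E=8.00e3, nu=0.22, rho=1200.0, E_unit="MPa"),
        "csf": PolynomialHyperelasticParams(Cpq={(1, 0): 0.0112}, nu=0.499, rho=1000.0),
        "white_matter": HyperViscoelasticBrainParams(
            mu0=7.63, muinf=1.58, Ginf=0.21,
            prony=[(0.57, 0.02), (0.22, 0.31)], K=2.19, rho=1060.0),
        "gray_matter": HyperViscoelasticBrainParams(
            mu0=5.06, muinf=1.48, Ginf=0.29,
            prony=[(0.50, 0.015), (0.20, 0.30)], K=2.19, rho=1060.0),
        "disk": PolynomialHyperelasticParams(
            Cpq={(1, 0): 0.15, (0, 1): 0.03}, nu=0.499, rho=1000.0,
            prony=[(1.70, 11.76), (1.20, 1.10), (2.00, 0.13)]),
        "muscle_default": HillMuscleParams(pcsa=100.0, volume=10000.0),
        "ligament_default": LigamentSpringParams(k=1.0),
    }
    for name in ("white_matter", "gray_matter"):
        p = reg[name]
        if abs(p.mu0 * p.Ginf - p.muinf) / p.muinf > 0.03:
            raise AssertionError(
                f"{name}: mu0*Ginf = {p.mu0 * p.Ginf:.3f} inconsistent with muinf = {p.muinf}")
    return reg


def get_preset(name: str):
    reg = material_registry()
    try:
        return reg[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(reg)}") from None


_CLASSES = {cls.__name__: cls for cls in (
    LinearElasticParams, LinearViscoelasticParams, PolynomialHyperelasticParams,
    HyperViscoelasticBrainParams, HillMuscleParams, LigamentSpringParams)}


def save_registry(registry: dict, path) -> None:
    """Serialize a registry (or any name -> params mapping) to YAML."""
    doc = {}
    for name, p in registry.items():
        d = asdict(p)
        if "Cpq" in d:
            d["Cpq"] = {f"{pq[0]},{pq[1]}": v for pq, v in d["Cpq"].items()}
        if "prony" in d:
            d["prony"] = [list(x) for x in d["prony"]]
        doc[name] = {"type": type(p).__name__, "params": d}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_registry(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for name, entry in doc.items():
        cls = _CLASSES[entry["type"]]
        d = dict(entry["params"])
        if "Cpq" in d:
            d["Cpq"] = {tuple(int(x) for x in k.split(",")): v for k, v in d["Cpq"].items()}
        if "prony" in d:
            d["prony"] = [tuple(x) for x in d["prony"]]
        out[name] = cls(**d)
    return out
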