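"""Mass-action equilibrium of competitive Myc / Smad1 binding to DNA.

Species: the c-Myc-Max heterodimer ("Myc") binds high-GC genomic DNA (DNAH,
dissociation constant K1) and low-GC DNA (DNAL, K_L); two DNA-bound
heterodimers can associate into a bivalent heterotetramer on DNAH only
(K2), which is the model's source of cooperativity.  Smad1 binds both DNA
classes as a homodimer (Ktilde_H, Ktilde_L, units M^2).  At equilibrium:

    [Myc][DNAH] / [Myc.DNAH]           = K1
    [Myc.DNAH]^2 / [(Myc.DNAH)2]       = K2
    [Myc][DNAL] / [Myc.DNAL]           = K_L
    [Smad]^2 [DNAH] / [(Smad)2.DNAH]   = Ktilde_H
    [Smad]^2 [DNAL] / [(Smad)2.DNAL]   = Ktilde_L

with K_H = K1^2 K2 the overall tetramer constant, plus conservation of
total Myc, Smad, DNAH and DNAL.  Given free (m, s) = ([Myc], [Smad]) the
DNA species follow in closed form ([DNAL] linearly, [DNAH] from a
quadratic), reducing the problem to two unknowns.  The solver runs nested
bisection (Brent) on the two conservation residuals, which are monotone in
their own unknown, so the solution is unique and bracketing always
succeeds.

All internal concentrations are molar; Ktilde constants are M^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = [
    "EquilibriumParameters",
    "EquilibriumState",
    "SweepResult",
    "species_from_free",
    "solve_equilibrium",
    "sweep_myc_total",
    "sharpness",
    "robustness_scan",
    "hill_coefficient",
    "load_parameters",
    "FIG_PRESET_HALF_UM",
    "FIG_PRESET_ONE_UM",
]

_XTOL = 1e-30
_RTOL = 8.9e-16


@dataclass(frozen=True)
class EquilibriumParameters:
    """Dissociation constants and totals (molar; Ktilde in M^2)."""

    K1: float = 145e-9
    K2: float = 90e-9
    K_L: float = 500e-9
    Ktilde_H: float = 1e-14
    Ktilde_L: float = 2.5e-14
    Myc_tot: float = 1e-6
    Smad_tot: float = 1e-6
    DNAH_tot: float = 0.5e-6
    DNAL_tot: float = 0.5e-6
    tetramer_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "K_L", "Ktilde_H", "Ktilde_L",
                     "DNAH_tot", "DNAL_tot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Myc_tot < 0 or self.Smad_tot < 0:
            raise ValueError("totals must be >= 0")

    @property
    def K_H(self) -> float:
        """Overall tetramer dissociation constant K1^2 * K2 (M^3... per [Myc]^2[DNAH]^2)."""
        return self.K1**2 * self.K2


# published parameter presets for the two DNA-abundance settings
FIG_PRESET_HALF_UM = EquilibriumParameters(DNAH_tot=0.5e-6, DNAL_tot=0.5e-6)
FIG_PRESET_ONE_UM = EquilibriumParameters(DNAH_tot=1e-6, DNAL_tot=1e-6)


@dataclass
class EquilibriumState:
    """Solved species concentrations (M) and conservation residuals."""

    myc_free: float
    smad_free: float
    dnah_free: float
    dnal_free: float
    myc_dnah: float
    tetramer: float
    myc_dnal: float
    smad2_dnah: float
    smad2_dnal: float
    residuals: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def as_dict(self) -> dict[str, float]:
        return {
            "myc_free": self.myc_free,
            "smad_free": self.smad_free,
            "dnah_free": self.dnah_free,
            "dnal_free": self.dnal_free,
            "myc_dnah": self.myc_dnah,
            "tetramer": self.tetramer,
            "myc_dnal": self.myc_dnal,
            "smad2_dnah": self.smad2_dnah,
            "smad2_dnal": self.smad2_dnal,
        }


def species_from_free(m: float, s: float, params: EquilibriumParameters) -> EquilibriumState:
    """All species given free [Myc] = m and free [Smad] = s.

    [DNAL] is linear in its conservation equation; [DNAH] is the positive
    root of a quadratic (the tetramer term is quadratic in [DNAH]).  The
    discriminant is positive for any positive parameters.
    """
    if m < 0 or s < 0:
        raise ValueError("free concentrations must be non-negative")
    p = params
    dnal = p.DNAL_tot / (1.0 + m / p.K_L + s * s / p.Ktilde_L)
    b = 1.0 + m / p.K1 + s * s / p.Ktilde_H
    a = 2.0 * m * m / p.K_H if p.tetramer_enabled else 0.0
    if a > 0:
        # a h^2 + b h - DNAH_tot = 0; positive root, written to avoid cancellation
        disc = b * b + 4.0 * a * p.DNAH_tot
        dnah = 2.0 * p.DNAH_tot / (b + np.sqrt(disc))
    else:
        dnah = p.DNAH_tot / b
    myc_dnah = m * dnah / p.K1
    tetramer = (myc_dnah * myc_dnah / p.K2) if p.tetramer_enabled else 0.0
    return EquilibriumState(
        myc_free=m,
        smad_free=s,
        dnah_free=dnah,
        dnal_free=dnal,
        myc_dnah=myc_dnah,
        tetramer=tetramer,
        myc_dnal=m * dnal / p.K_L,
        smad2_dnah=s * s * dnah / p.Ktilde_H,
        smad2_dnal=s * s * dnal / p.Ktilde_L,
    )


def _myc_residual(m: float, s: float, p: EquilibriumParameters) -> float:
    st = species_from_free(m, s, p)
    return st.myc_free + st.myc_dnah + 2.0 * st.tetramer + st.myc_dnal - p.Myc_tot


def _smad_residual(s: float, p: EquilibriumParameters) -> float:
    m = _solve_myc_given_smad(s, p)
    st = species_from_free(m, s, p)
    return st.smad_free + 2.0 * st.smad2_dnah + 2.0 * st.smad2_dnal - p.Smad_tot


def _solve_myc_given_smad(s: float, p: EquilibriumParameters) -> float:
    if p.Myc_tot == 0:
        return 0.0
    # residual is strictly increasing in m; bracket [0, Myc_tot]
    lo, hi = 0.0, p.Myc_tot
    return brentq(_myc_residual, lo, hi, args=(s, p), xtol=_XTOL, rtol=_RTOL)


def solve_equilibrium(params: EquilibriumParameters) -> EquilibriumState:
    """Unique equilibrium satisfying all binding relations and conservation.

    Nested Brent bisection: the Smad conservation residual (with Myc
    re-solved at each trial Smad) changes sign on [0, Smad_tot] and is
    monotone, guaranteeing convergence; residuals are reported in the state.
    """
    p = params
    if p.Smad_tot == 0:
        s = 0.0
    else:
        s = brentq(_smad_residual, 0.0, p.Smad_tot, args=(p,), xtol=_XTOL, rtol=_RTOL)
    m = _solve_myc_given_smad(s, p)
    st = species_from_free(m, s, p)
    r_myc = (st.myc_free + st.myc_dnah + 2 * st.tetramer + st.myc_dnal - p.Myc_tot)
    r_smad = st.smad_free + 2 * st.smad2_dnah + 2 * st.smad2_dnal - p.Smad_tot
    r_dnah = st.dnah_free + st.myc_dnah + 2 * st.tetramer + st.smad2_dnah - p.DNAH_tot
    r_dnal = st.dnal_free + st.myc_dnal + st.smad2_dnal - p.DNAL_tot
    st.residuals = (
        r_myc / max(p.Myc_tot, 1e-300),
        r_smad / max(p.Smad_tot, 1e-300),
        r_dnah / p.DNAH_tot,
        r_dnal / p.DNAL_tot,
    )
    worst = max(abs(r) for r in st.residuals)
    if worst > 1e-9:
        raise RuntimeError(f"equilibrium solve did not converge; residual {worst:.3e}")
    return st


@dataclass
class SweepResult:
    """Equilibrium states along a total-Myc grid plus transition sharpness."""

    myc_tot_grid: np.ndarray
    states: list[EquilibriumState]
    sharpness_smad2_dnah: float
    sharpness_tetramer: float

    def species(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([s.as_dict() for s in self.states])
        df.insert(0, "myc_tot", self.myc_tot_grid)
        df["residual_norm"] = [max(abs(r) for r in s.residuals) for s in self.states]
        return df


def _max_abs_log_derivative(y: np.ndarray, log10_x: np.ndarray) -> float:
    if len(y) < 3:
        return float("nan")
    return float(np.max(np.abs(np.gradient(y, log10_x))))


def sweep_myc_total(
    params: EquilibriumParameters,
    grid: Sequence[float] | None = None,
    n_points: int = 200,
    myc_min: float = 1e-8,
    myc_max: float = 1e-5,
) -> SweepResult:
    """Solve the equilibrium along a log-spaced total-Myc grid.

    Sharpness of the binding transition is the maximum absolute derivative of
    the bound-species concentration with respect to log10 of total Myc
    (central finite differences on the grid).
    """
    if grid is None:
        grid = np.logspace(np.log10(myc_min), np.log10(myc_max), n_points)
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    states = [solve_equilibrium(replace(params, Myc_tot=float(g))) for g in grid]
    lg = np.log10(grid)
    smad2 = np.array([s.smad2_dnah for s in states])
    tet = np.array([s.tetramer for s in states])
    return SweepResult(
        myc_tot_grid=grid,
        states=states,
        sharpness_smad2_dnah=_max_abs_log_derivative(smad2, lg) if len(grid) > 2 else float("nan"),
        sharpness_tetramer=_max_abs_log_derivative(tet, lg) if len(grid) > 2 else float("nan"),
    )


def sharpness(params: EquilibriumParameters, **sweep_kw) -> float:
    """Max |d[(Smad)2.DNAH]/d log10 Myc_tot| over the sweep."""
    return sweep_myc_total(params, **sweep_kw).sharpness_smad2_dnah


def robustness_scan(
    params: EquilibriumParameters,
    factors: Sequence[float] = (0.1, 10.0),
    n_points: int = 60,
) -> pd.DataFrame:
    """Perturb each dissociation constant and compare cooperative vs not.

    For each K scaled by each factor (one at a time), records the transition
    sharpness with the tetramer enabled and disabled and whether the
    cooperative model remains the sharper one.
    """
    rows = []
    cases = [("base", None, 1.0)] + [
        (k, k, f) for k in ("K1", "K2", "K_L", "Ktilde_H", "Ktilde_L") for f in factors
    ]
    for label, key, factor in cases:
        p = params if key is None else replace(params, **{key: getattr(params, key) * factor})
        s_on = sharpness(replace(p, tetramer_enabled=True), n_points=n_points)
        s_off = sharpness(replace(p, tetramer_enabled=False), n_points=n_points)
        rows.append(
            {
                "parameter": label,
                "factor": factor,
                "sharpness_on": s_on,
                "sharpness_off": s_off,
                "cooperative_sharper": s_on > s_off,
            }
        )
    return pd.DataFrame(rows)


def hill_coefficient(params: EquilibriumParameters, **sweep_kw) -> float:
    """Effective Hill coefficient of tetramer (or Myc.DNAH if tetramer off)
    formation versus free Myc.

    Max slope of log(theta/(1-theta)) against log free Myc, where theta is
    the bound fraction of DNAH occupied by the species of interest.
    """
    res = sweep_myc_total(params, **sweep_kw)
    m = res.species("myc_free")
    if params.tetramer_enabled:
        occ = 2.0 * res.species("tetramer")
    else:
        occ = res.species("myc_dnah")
    theta = occ / params.DNAH_tot
    ok = (theta > 1e-12) & (theta < 1 - 1e-12) & (m > 0)
    if ok.sum() < 3:
        return float("nan")
    logit = np.log(theta[ok] / (1.0 - theta[ok]))
    return float(np.max(np.gradient(logit, np.log(m[ok]))))


_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12,
               "M2": 1.0, "uM2": 1e-12, "nM2": 1e-18}


def _parse_quantity(value) -> float:
    """Parse '145 nM' / '1e-14 M2' / bare float (already molar)."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) == 1:
        return float(parts[0])
    num, unit = parts
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown unit {unit!r}")
    return float(num) * _UNIT_SCALE[unit]


def load_parameters(path: str | Path) -> EquilibriumParameters:
    """Read a YAML parameter file with mandatory unit suffixes.

    Keys match EquilibriumParameters fields; concentration values are
    strings like '145 nM' or '0.5 uM', Ktilde values like '1e-14 M2'.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = {}
    for key, value in raw.items():
        if key == "tetramer_enabled":
            kwargs[key] = bool(value)
        else:
            kwargs[key] = _parse_quantity(value)
    return EquilibriumParameters(**kwargs)
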