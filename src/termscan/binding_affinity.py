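"""Single-site binding model and Kd estimation from fluorescence anisotropy.

The model accounts for ligand depletion: the labelled probe (CTD peptide or
RNA, concentration ``L``) is present at a finite concentration, so the free
protein concentration is not equal to the total titrated concentration
``P``.  Mass action for P + L <-> PL with dissociation constant ``kd``
gives the bound probe fraction as the root of a quadratic,

    f = ((P + L + kd) - sqrt((P + L + kd)^2 - 4 P L)) / (2 L),

which reduces to the familiar hyperbola P / (P + kd) when L << kd.
Anisotropy is assumed to mix linearly between the free and bound probe
(no fluorescence-intensity change on binding):

    r(P) = r_free + (r_bound - r_free) * f(P).

Kd estimates beyond the titrated concentration range are censored and
reported as a lower bound (e.g. "> 1000 uM") rather than a point estimate.
All concentrations are in micromolar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationCurve",
    "KdFit",
    "bound_fraction",
    "predict_anisotropy",
    "fit_kd",
    "monte_carlo_se",
]


@dataclass
class TitrationCurve:
    """Anisotropy readings against titrated protein concentration.

    protein_concs : strictly increasing, >= 0, micromolar.
    probe_conc    : fixed labelled-probe concentration, micromolar.
    anisotropy    : one reading per protein concentration.
    """

    protein_concs: np.ndarray
    anisotropy: np.ndarray
    probe_conc: float

    def __post_init__(self) -> None:
        self.protein_concs = np.asarray(self.protein_concs, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.probe_conc <= 0:
            raise ValueError("probe_conc must be positive")
        if self.protein_concs.ndim != 1 or self.protein_concs.size < 6:
            raise ValueError("need at least 6 titration points")
        if np.any(self.protein_concs < 0) or np.any(
            np.diff(self.protein_concs) <= 0
        ):
            raise ValueError("protein_concs must be non-negative and strictly increasing")
        if self.anisotropy.shape != self.protein_concs.shape:
            raise ValueError("anisotropy and protein_concs length mismatch")

    @property
    def c_max(self) -> float:
        return float(self.protein_concs[-1])


@dataclass
class KdFit:
    """Result of a nonlinear least-squares titration fit."""

    kd: float
    r_free: float
    r_bound: float
    c_max: float
    censored: bool = False
    censor_bound: Optional[float] = None
    kd_se: Optional[float] = None
    residual_sd: float = 0.0

    def __str__(self) -> str:  # Table-style report
        if self.censored:
            return f"Kd > {self.censor_bound:g} uM"
        if self.kd_se is not None:
            return f"Kd = {self.kd:.3g} +/- {self.kd_se:.2g} uM"
        return f"Kd = {self.kd:.3g} uM"


def bound_fraction(kd: float, P, L: float):
    """Fraction of probe bound under ligand depletion (exact quadratic root).

    Vectorized over the titrated protein concentration ``P``.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if L <= 0:
        raise ValueError("probe concentration must be positive")
    P = np.asarray(P, dtype=float)
    s = P + L + kd
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * L)


def predict_anisotropy(kd: float, L: float, P, r_free: float, r_bound: float):
    """Anisotropy of the probe at titrated concentration(s) ``P``."""
    return r_free + (r_bound - r_free) * bound_fraction(kd, P, L)


def _censor_threshold(c_max: float) -> float:
    """Largest power of ten not exceeding the top titrated concentration;
    censored fits are reported as '> threshold'."""
    return 10.0 ** math.floor(math.log10(c_max))


def fit_kd(curve: TitrationCurve, flat_range_factor: float = 5.0) -> KdFit:
    """Estimate (kd, r_free, r_bound) by nonlinear least squares.

    Initialization: r_free = min(r), r_bound = max(r), kd = protein
    concentration nearest the half-range anisotropy.  kd is constrained
    positive.  A fitted kd beyond the titrated range, or a curve whose
    dynamic range is below ``flat_range_factor`` times the residual noise,
    is censored and reported as a lower bound in the style '> 1000 uM'.
    """
    P = curve.protein_concs
    r = curve.anisotropy
    L = curve.probe_conc

    r_lo, r_hi = float(r.min()), float(r.max())
    half = 0.5 * (r_lo + r_hi)
    kd0 = float(P[np.argmin(np.abs(r - half))])
    kd0 = min(max(kd0, 1e-6), curve.c_max)

    def resid(theta):
        kd, rf, rb = theta
        return predict_anisotropy(kd, L, P, rf, rb) - r

    sol = least_squares(
        resid,
        x0=[kd0, r_lo, r_hi],
        bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"titration fit did not converge: {sol.message}")
    kd, rf, rb = (float(v) for v in sol.x)
    dof = max(P.size - 3, 1)
    resid_sd = float(np.sqrt(np.sum(sol.fun**2) / dof))

    flat = (r_hi - r_lo) < flat_range_factor * resid_sd
    if flat or kd > curve.c_max:
        return KdFit(
            kd=kd,
            r_free=rf,
            r_bound=rb,
            c_max=curve.c_max,
            censored=True,
            censor_bound=_censor_threshold(curve.c_max),
            residual_sd=resid_sd,
        )
    return KdFit(kd=kd, r_free=rf, r_bound=rb, c_max=curve.c_max, residual_sd=resid_sd)


def monte_carlo_se(
    curve: TitrationCurve,
    n_rep: int = 200,
    noise_sd: Optional[float] = None,
    seed: int = 0,
) -> float:
    """Standard error of kd by refitting noise-perturbed copies of the curve.

    noise_sd defaults to the residual standard deviation of the initial fit.
    """
    base = fit_kd(curve)
    if noise_sd is None:
        noise_sd = base.residual_sd
    if noise_sd == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    model = predict_anisotropy(
        base.kd, curve.probe_conc, curve.protein_concs, base.r_free, base.r_bound
    )
    kds = []
    for _ in range(n_rep):
        noisy = TitrationCurve(
            curve.protein_concs,
            model + rng.normal(0.0, noise_sd, size=model.shape),
            curve.probe_conc,
        )
        fit = fit_kd(noisy)
        if not fit.censored:
            kds.append(fit.kd)
    if len(kds) < 2:
        raise RuntimeError("too few uncensored replicate fits for an SE")
    return float(np.std(kds, ddof=1))
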