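"""Adhesion-isotherm normalization and fitting of apparent binding constants.

Surface-forces measurements give adhesion energy versus ionic strength for
one salt (or salt mixture) at a time.  This module converts ionic strength
to free-cation concentration, normalizes each curve to its salt-free value,
and fits the normalized competitive-binding isotherm

    E(I)/E(0) = (1 + (K4/K5)[T]) / (1 + K1[M] + K2[T])^2

jointly across curves.  Only the ratios K1, K2 and K4/K5 are identifiable
from normalized data; which of them a data set constrains is reported in
the fit diagnostics.  Grafting-density series are fitted with the salt-free
quadratic (optionally anchored through one measured point) or its
crowded-surface extension, from which the fraction of peptides sequestered
in intra-plane pairing/adsorption can be estimated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .equilibria import BathComposition, BindingConstants, extended_no_electrolyte

__all__ = [
    "AdhesionPoint",
    "AdhesionCurve",
    "SaltSpec",
    "FitResult",
    "cation_conc_from_ionic_strength",
    "normalize_curve",
    "predict_normalized",
    "fit_constants",
    "bootstrap_constants",
    "fit_grafting_series",
    "sequestered_fraction",
    "adhesion_energy_from_force",
]

ENERGY_CONVERSION_FACTOR = 1.5 * math.pi  # F_a/R = 1.5*pi*E_a (JKR-like contact)

# Default log10 bounds and multi-start count for constant fitting; the
# constants span decades and no starting values are known a priori.
LOG10_BOUNDS = (-6.0, 6.0)
DEFAULT_N_STARTS = 20

_FIT_PARAM_NAMES = ("k1", "k2", "k4_over_k5")


@dataclass(frozen=True)
class SaltSpec:
    """A fully dissociated salt M(X)z with monovalent anion X.

    ``ionic_strength_factor`` is I/c for cation concentration c:
    I = 1/2 (c z^2 + z c) = c (z^2 + z)/2.
    """

    name: str
    cation_valence: int
    anion_valence: int = 1

    def __post_init__(self) -> None:
        if self.cation_valence not in (1, 2, 3):
            raise ValueError(
                f"unsupported cation valence {self.cation_valence} for {self.name!r}"
            )
        if self.anion_valence != 1:
            raise ValueError("only monovalent anions are supported")

    @property
    def ionic_strength_factor(self) -> float:
        z = self.cation_valence
        return (z * z + z) / 2.0


@dataclass
class AdhesionPoint:
    """One adhesion measurement at a given total ionic strength."""

    ionic_strength: float  # mM
    adhesion_energy: float  # mJ/m^2, or dimensionless once normalized
    replicate_id: str = "r1"
    uncertainty: float | None = None  # SD, same units as adhesion_energy

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ValueError(f"ionic_strength must be >= 0, got {self.ionic_strength}")
        if self.uncertainty is not None and self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass
class AdhesionCurve:
    """Adhesion vs ionic strength for one salt/surface condition.

    ``fixed_t_conc`` holds the trivalent concentration maintained in a
    mixed-electrolyte series (0 for single-salt curves).  Points are kept
    sorted by ionic strength.
    """

    points: list[AdhesionPoint]
    salt: SaltSpec
    surface_label: str = ""
    fixed_t_conc: float = 0.0
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fixed_t_conc < 0:
            raise ValueError("fixed_t_conc must be >= 0")
        self.points = sorted(self.points, key=lambda p: p.ionic_strength)

    @property
    def ionic_strengths(self) -> np.ndarray:
        return np.array([p.ionic_strength for p in self.points])

    @property
    def adhesion_values(self) -> np.ndarray:
        return np.array([p.adhesion_energy for p in self.points])


@dataclass
class FitResult:
    """Outcome of a constant or grafting-density fit.

    ``constants`` maps parameter names to estimates (``None`` when the data
    do not constrain a parameter); ``identifiable`` flags which ones the
    data constrained.  ``covariance`` (when available) is in natural-log
    parameter space, from the Gauss-Newton approximation at the optimum.
    """

    constants: dict
    identifiable: dict
    rss: float
    n_points: int
    seed: int | None = None
    n_starts: int = 1
    success: bool = True
    messages: list = field(default_factory=list)
    covariance: np.ndarray | None = None
    bootstrap_intervals: dict | None = None
    mode: str = "constants"


def adhesion_energy_from_force(force_over_radius: float) -> float:
    """Convert SFA pull-off force F/R (mN/m) to adhesion energy E_a (mJ/m^2).

    Uses F_a/R = 1.5*pi*E_a (soft adhesive contact between crossed
    cylinders).
    """
    return force_over_radius / ENERGY_CONVERSION_FACTOR


def cation_conc_from_ionic_strength(i: float, salt: SaltSpec) -> float:
    """Cation concentration (mM) of salt MXz at total ionic strength ``i``."""
    if i < 0:
        raise ValueError(f"ionic strength must be >= 0, got {i}")
    return i / salt.ionic_strength_factor


def normalize_curve(curve: AdhesionCurve) -> AdhesionCurve:
    """Divide a curve by its mean zero-ionic-strength adhesion.

    The zero point maps to 1 (up to replicate scatter); point uncertainties
    are scaled by the same baseline.
    """
    if curve.normalized:
        raise ValueError("curve is already normalized")
    zero_vals = [p.adhesion_energy for p in curve.points if p.ionic_strength == 0.0]
    if not zero_vals:
        raise ValueError("no zero-ionic-strength point to normalize against")
    baseline = float(np.mean(zero_vals))
    if baseline == 0.0:
        raise ValueError("degenerate curve: zero-ionic-strength baseline is 0")
    new_points = [
        AdhesionPoint(
            ionic_strength=p.ionic_strength,
            adhesion_energy=p.adhesion_energy / baseline,
            replicate_id=p.replicate_id,
            uncertainty=None if p.uncertainty is None else p.uncertainty / baseline,
        )
        for p in curve.points
    ]
    return AdhesionCurve(
        points=new_points,
        salt=curve.salt,
        surface_label=curve.surface_label,
        fixed_t_conc=curve.fixed_t_conc,
        normalized=True,
        meta={**curve.meta, "normalization_baseline": baseline},
    )


def predict_normalized(bath: BathComposition, k: BindingConstants) -> float:
    """Normalized adhesion (1 + (K4/K5)[T]) / (1 + K1[M] + K2[T])^2.

    Equals 1 in the salt-free bath for any positive constants.
    """
    if k.k5 <= 0:
        raise ValueError("normalized prediction requires k5 > 0")
    r = k.k4 / k.k5  # type: ignore[operator]
    denom = 1.0 + k.k1 * bath.m_conc + k.k2 * bath.t_conc
    return (1.0 + r * bath.t_conc) / (denom * denom)


def bath_for_point(
    ionic_strength: float,
    salt: SaltSpec,
    fixed_t_conc: float = 0.0,
    divalent_as_trivalent: bool = False,
) -> BathComposition:
    """Map one measured point to the free-cation composition [M], [T].

    The ionic-strength axis is the TOTAL ionic strength.  For a mixed
    series (monovalent salt added on top of a held trivalent concentration
    t), points with I > 0 carry [T] = t and [M] = I - 6t; the I = 0 point
    is the salt-free baseline.  Divalent salts have no species of their own
    in the model; ``divalent_as_trivalent`` maps them onto the T role as an
    explicit model extension.
    """
    if ionic_strength == 0.0:
        return BathComposition(0.0, 0.0)
    z = salt.cation_valence
    if z == 1:
        if fixed_t_conc > 0.0:
            t_contrib = 6.0 * fixed_t_conc
            m = ionic_strength - t_contrib
            if m < -1e-9:
                raise ValueError(
                    f"ionic strength {ionic_strength} mM below the contribution "
                    f"{t_contrib} mM of the held trivalent salt"
                )
            return BathComposition(max(m, 0.0), fixed_t_conc)
        return BathComposition(cation_conc_from_ionic_strength(ionic_strength, salt), 0.0)
    if z == 3:
        return BathComposition(0.0, cation_conc_from_ionic_strength(ionic_strength, salt))
    if z == 2:
        if not divalent_as_trivalent:
            raise ValueError(
                "divalent salts have no dedicated species in the model; pass "
                "divalent_as_trivalent=True to fit them in the T role "
                "(model extension)"
            )
        return BathComposition(0.0, cation_conc_from_ionic_strength(ionic_strength, salt))
    raise ValueError(f"unsupported valence {z}")  # pragma: no cover


def _assemble_design(curves, divalent_as_trivalent):
    """Flatten curves into arrays of ([M], [T], y, weight)."""
    m_list, t_list, y_list, w_list = [], [], [], []
    for curve in curves:
        if not curve.normalized:
            raise ValueError(
                f"curve {curve.surface_label!r}/{curve.salt.name!r} must be "
                "normalized before fitting"
            )
        for p in curve.points:
            bath = bath_for_point(
                p.ionic_strength, curve.salt, curve.fixed_t_conc, divalent_as_trivalent
            )
            m_list.append(bath.m_conc)
            t_list.append(bath.t_conc)
            y_list.append(p.adhesion_energy)
            w_list.append(1.0 / p.uncertainty if p.uncertainty else 1.0)
    return (
        np.array(m_list),
        np.array(t_list),
        np.array(y_list),
        np.array(w_list),
    )


def _normalized_model(m, t, k1, k2, r):
    return (1.0 + r * t) / (1.0 + k1 * m + k2 * t) ** 2


def fit_constants(
    curves: list[AdhesionCurve],
    *,
    divalent_as_trivalent: bool = False,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    log10_bounds: tuple[float, float] = LOG10_BOUNDS,
) -> FitResult:
    """Jointly fit K1, K2 and K4/K5 to normalized adhesion curves.

    Weighted least squares (per-point SD weights when available) on the
    normalized isotherm, with parameters optimized in log10 space from a
    seeded Latin-hypercube multi-start.  Monovalent-only data constrain K1;
    trivalent (or mixed) data constrain K2 and K4/K5; parameters the data
    do not touch are flagged non-identifiable and reported as ``None``.
    Refitting with the same seed is bit-reproducible.
    """
    m, t, y, w = _assemble_design(curves, divalent_as_trivalent)
    n_points = y.size
    messages: list[str] = []

    active = {
        "k1": bool(np.any(m > 0)),
        "k2": bool(np.any(t > 0)),
        "k4_over_k5": bool(np.any(t > 0)),
    }
    active_names = [n for n in _FIT_PARAM_NAMES if active[n]]
    for name in _FIT_PARAM_NAMES:
        if not active[name]:
            messages.append(f"{name} not identifiable from the provided curves")
    if np.ptp(y) < 1e-12:
        messages.append(
            "non-identifiability warning: adhesion data are constant; "
            "fitted constants are not constrained"
        )

    if not active_names:
        return FitResult(
            constants={n: None for n in _FIT_PARAM_NAMES},
            identifiable=active,
            rss=float(np.sum((w * (y - 1.0)) ** 2)),
            n_points=n_points,
            seed=seed,
            n_starts=0,
            messages=messages,
        )

    def residuals(log10_params: np.ndarray) -> np.ndarray:
        full = dict.fromkeys(_FIT_PARAM_NAMES, 0.0)
        for name, value in zip(active_names, 10.0 ** log10_params):
            full[name] = value
        pred = _normalized_model(m, t, full["k1"], full["k2"], full["k4_over_k5"])
        return w * (pred - y)

    lo, hi = log10_bounds
    sampler = qmc.LatinHypercube(d=len(active_names), seed=seed)
    starts = qmc.scale(sampler.random(n=n_starts), lo, hi)

    best = None
    for x0 in starts:
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None

    constants: dict = {n: None for n in _FIT_PARAM_NAMES}
    for name, value in zip(active_names, 10.0 ** best.x):
        constants[name] = float(value)

    cov = None
    try:
        jtj = best.jac.T @ best.jac
        dof = max(n_points - len(active_names), 1)
        cov = 2.0 * best.cost / dof * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        messages.append("covariance not available (singular Jacobian)")

    return FitResult(
        constants=constants,
        identifiable=active,
        rss=float(2.0 * best.cost),
        n_points=n_points,
        seed=seed,
        n_starts=n_starts,
        success=bool(best.success),
        messages=messages,
        covariance=cov,
    )


def bootstrap_constants(
    curves: list[AdhesionCurve],
    fit: FitResult,
    *,
    n_boot: int = 500,
    seed: int = 0,
    divalent_as_trivalent: bool = False,
) -> dict:
    """Residual-bootstrap 95% intervals for the fitted constants.

    Residuals of the fit are resampled with replacement onto the fitted
    predictions and the model refitted from the original optimum; returns
    ``{name: (lo, hi)}`` percentile intervals for identifiable constants.
    """
    m, t, y, w = _assemble_design(curves, divalent_as_trivalent)
    full = {n: (fit.constants[n] or 0.0) for n in _FIT_PARAM_NAMES}
    pred = _normalized_model(m, t, full["k1"], full["k2"], full["k4_over_k5"])
    resid = y - pred
    active_names = [n for n in _FIT_PARAM_NAMES if fit.identifiable[n]]
    if not active_names:
        return {}
    x_hat = np.log10([full[n] for n in active_names])
    rng = np.random.default_rng(seed)
    lo, hi = LOG10_BOUNDS

    draws = {n: [] for n in active_names}
    for _ in range(n_boot):
        y_star = pred + rng.choice(resid, size=resid.size, replace=True)

        def residuals(log10_params: np.ndarray) -> np.ndarray:
            p = dict.fromkeys(_FIT_PARAM_NAMES, 0.0)
            for name, value in zip(active_names, 10.0 ** log10_params):
                p[name] = value
            return w * (_normalized_model(m, t, p["k1"], p["k2"], p["k4_over_k5"]) - y_star)

        sol = least_squares(residuals, x_hat, bounds=(lo, hi), method="trf")
        for name, value in zip(active_names, 10.0 ** sol.x):
            draws[name].append(value)

    return {
        name: tuple(np.percentile(draws[name], [2.5, 97.5]))
        for name in active_names
    }


def fit_grafting_series(
    densities,
    adhesions,
    mode: str = "quadratic",
    anchor_density: float | None = None,
) -> FitResult:
    """Fit adhesion vs peptide grafting density.

    ``quadratic`` fits E = C rho^2 (C plays the role of K5 in effective
    units); with ``anchor_density`` the parabola is forced through the
    origin and the mean measured point at that density.  ``extended`` fits
    the crowded-surface form E = C rho^2 / (1 + 2 K6 rho)^2, returning C
    and K6.
    """
    rho = np.asarray(densities, dtype=float)
    e = np.asarray(adhesions, dtype=float)
    if rho.shape != e.shape or rho.ndim != 1:
        raise ValueError("densities and adhesions must be 1-D arrays of equal length")
    min_points = 2 if mode == "quadratic" else 3
    if rho.size < min_points:
        raise ValueError(f"{mode} fit requires at least {min_points} points")

    if mode == "quadratic":
        if anchor_density is not None:
            at_anchor = np.isclose(rho, anchor_density, rtol=1e-9, atol=1e-9)
            if not np.any(at_anchor):
                raise ValueError(
                    f"anchor density {anchor_density} not present in the data"
                )
            c = float(np.mean(e[at_anchor]) / anchor_density**2)
        else:
            c = float(np.sum(e * rho**2) / np.sum(rho**4))
        resid = e - c * rho**2
        return FitResult(
            constants={"k5": c, "k6": None},
            identifiable={"k5": True, "k6": False},
            rss=float(np.sum(resid**2)),
            n_points=rho.size,
            mode="grafting_quadratic",
        )

    if mode == "extended":

        def residuals(log10_params: np.ndarray) -> np.ndarray:
            c, k6 = 10.0 ** log10_params
            return c * rho**2 / (1.0 + 2.0 * k6 * rho) ** 2 - e

        # grafting-density constants sit far below the bath-constant scale
        # (densities are thousands of peptides/um^2), so the bounds are wider
        lo, hi = -14.0, 8.0
        # deterministic coarse multi-start; constants span decades
        best = None
        scale = max(np.max(np.abs(e)) / max(np.max(rho) ** 2, 1e-30), 1e-12)
        for c0 in (scale, 10 * scale, 0.1 * scale):
            for k60 in (1e-6, 1.0 / max(np.max(rho), 1e-12), 1e-2):
                x0 = np.clip(np.log10([c0, k60]), lo + 1e-9, hi - 1e-9)
                sol = least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
                if best is None or sol.cost < best.cost:
                    best = sol
        assert best is not None
        c, k6 = (float(v) for v in 10.0 ** best.x)
        return FitResult(
            constants={"k5": c, "k6": k6},
            identifiable={"k5": True, "k6": True},
            rss=float(2.0 * best.cost),
            n_points=rho.size,
            success=bool(best.success),
            mode="grafting_extended",
        )

    raise ValueError(f"unknown mode {mode!r} (expected 'quadratic' or 'extended')")


def predict_grafting(fit: FitResult, density: float) -> float:
    """Evaluate a grafting-series fit at one density."""
    c = fit.constants["k5"]
    k6 = fit.constants.get("k6")
    if k6 is None:
        return c * density**2
    return c * density**2 / (1.0 + 2.0 * k6 * density) ** 2


def sequestered_fraction(
    density: float, observed: float, quadratic_fit: FitResult
) -> float:
    """Fraction of peptides unavailable for inter-surface pairing.

    Reads the shortfall of the measured adhesion below the anchored
    quadratic as adhesion proportional to the square of the available
    peptide pool: fraction = 1 - sqrt(observed / predicted).  This
    square-root availability reading is an interpretation of the deviation,
    recorded as such; values are clipped to [0, 1] with a warning when the
    observation exceeds the prediction.
    """
    predicted = predict_grafting(quadratic_fit, density)
    if predicted <= 0:
        raise ValueError("quadratic prediction must be positive")
    if observed < 0:
        raise ValueError("observed adhesion must be >= 0")
    ratio = observed / predicted
    if ratio > 1.0:
        warnings.warn(
            "observed adhesion exceeds the quadratic prediction; "
            "sequestered fraction clipped to 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - math.sqrt(ratio)
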