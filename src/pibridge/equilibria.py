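"""Competitive-binding mass-balance model of cation-modulated peptide pairing.

Surface-grafted aromatic peptides P pair across two opposing surfaces either
directly (pi-pi / native cation-pi, species P2) or through a multivalent
cation bridge (pi-cation-pi, species P2T).  Free monovalent cations M and
multivalent cations T in the bath compete for the aromatic rings:

    P + M  <-> PM          (K1, 1/mM)
    P + T  <-> PT          (K2, 1/mM)
    P + PT <-> P2T         (K3; composite K4 = K2*K3)
    P + P  <-> P2          (K5)
    P + P  <-> P2,intra    (K6, same-surface pairing extension)

The measurable adhesion tracks the inter-surface dimers P2 + P2T.  Two
solvers are provided: the closed-form expression obtained by neglecting the
dimer terms in the peptide conservation sum (the default used for fitting),
and an exact solver of the full conservation law which serves as the
internal oracle for that approximation.

Concentration conventions: bath ion concentrations are in mM; the adsorbed
peptide total ``p_total`` is an effective surface concentration in arbitrary
units, with K3-K6 carrying the matching inverse units.  Normalized
observables depend only on products such as K5*p_total^2, so the arbitrary
unit cancels in any fitted quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BindingConstants",
    "BathComposition",
    "SpeciesState",
    "OvershootResult",
    "solve_closed_form",
    "solve_exact",
    "adhesion_signal",
    "monovalent_limit",
    "trivalent_limit",
    "no_electrolyte_quadratic",
    "extended_no_electrolyte",
    "overshoot_diagnostic",
]

_K4_CONSISTENCY_RTOL = 1e-12


@dataclass(frozen=True)
class BindingConstants:
    """Apparent equilibrium constants of the competitive-binding model.

    Parameters
    ----------
    k1 : float
        P + M <-> PM affinity, 1/mM.
    k2 : float
        P + T <-> PT affinity, 1/mM.
    k3 : float, optional
        P + PT <-> P2T affinity (inverse effective surface concentration).
        May be omitted when ``k4`` is supplied directly.
    k4 : float, optional
        Composite bridging constant K4 = K2*K3.  Resolved from ``k2`` and
        ``k3`` when not given; when both ``k3`` and ``k4`` are given they
        must agree to relative tolerance 1e-12.
    k5 : float
        Direct pairing constant P + P <-> P2.
    k6 : float
        Effective intra-plane pairing constant (inverse effective surface
        concentration, as used by the crowded-surface extension).
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float | None = None
    k4: float | None = None
    k5: float = 0.0
    k6: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k5", "k6"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        for name in ("k3", "k4"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if self.k4 is None:
            resolved = self.k2 * self.k3 if self.k3 is not None else 0.0
            object.__setattr__(self, "k4", resolved)
        elif self.k3 is not None:
            expected = self.k2 * self.k3
            scale = max(abs(self.k4), abs(expected))
            if scale > 0 and abs(self.k4 - expected) > _K4_CONSISTENCY_RTOL * scale:
                raise ValueError(
                    f"inconsistent constants: k4={self.k4} but k2*k3={expected}"
                )

    @property
    def k4_over_k5(self) -> float:
        """Bridging-to-direct pairing ratio K4/K5 (1/mM); requires k5 > 0."""
        if self.k5 <= 0:
            raise ValueError("k4/k5 undefined for k5 = 0")
        return self.k4 / self.k5  # type: ignore[operator]


@dataclass(frozen=True)
class BathComposition:
    """Free-cation composition of the bath: [M] and [T] in mM."""

    m_conc: float = 0.0
    t_conc: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.m_conc) or self.m_conc < 0:
            raise ValueError(f"m_conc must be finite and >= 0, got {self.m_conc!r}")
        if not math.isfinite(self.t_conc) or self.t_conc < 0:
            raise ValueError(f"t_conc must be finite and >= 0, got {self.t_conc!r}")


@dataclass(frozen=True)
class SpeciesState:
    """Surface species concentrations satisfying the conservation law.

    All species share the effective units of ``p_total``.  ``solver_tag`` is
    ``"closed_form"`` for the dimer-neglecting approximation and ``"exact"``
    for the full mass-balance root; only the exact state satisfies the
    conservation sum p + pm + pt + 2(p2t + p2 + p2_intra) = p_total to
    machine precision.
    """

    p: float
    pm: float
    pt: float
    p2t: float
    p2: float
    p2_intra: float
    p_total: float
    solver_tag: str = "exact"

    def conservation_residual(self) -> float:
        """Signed residual of the conservation sum (exact solver: ~0)."""
        total = (
            self.p
            + self.pm
            + self.pt
            + 2.0 * (self.p2t + self.p2 + self.p2_intra)
        )
        return total - self.p_total


@dataclass(frozen=True)
class OvershootResult:
    """Whether the trivalent isotherm rises above its zero-salt value.

    ``t_peak`` is the analytic maximizer of the normalized trivalent signal,
    in mM; it is ``None`` when there is no interior maximum (no overshoot,
    or an unbounded rise when K2 = 0).
    """

    has_overshoot: bool
    t_peak: float | None


def _check_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


def solve_closed_form(
    p_total: float, bath: BathComposition, k: BindingConstants
) -> SpeciesState:
    """Closed-form species distribution (dimer terms dropped from conservation).

    Free peptide is approximated as p = p_total / (1 + K1[M] + K2[T]); all
    bound species follow from mass action.  Intra-plane pairing is not part
    of the base model (``k6`` is ignored; ``p2_intra = 0``).
    """
    _check_nonnegative("p_total", p_total)
    m, t = bath.m_conc, bath.t_conc
    a = 1.0 + k.k1 * m + k.k2 * t
    p = p_total / a
    return SpeciesState(
        p=p,
        pm=k.k1 * m * p,
        pt=k.k2 * t * p,
        p2t=k.k4 * t * p * p,  # type: ignore[operator]
        p2=k.k5 * p * p,
        p2_intra=0.0,
        p_total=p_total,
        solver_tag="closed_form",
    )


def solve_exact(
    p_total: float,
    bath: BathComposition,
    k: BindingConstants,
    include_intra: bool = False,
) -> SpeciesState:
    """Exact solution of the full conservation law.

    Substituting the mass-action laws into the conservation sum gives
    a*p + 2*b*p^2 = p_total with a = 1 + K1[M] + K2[T] and
    b = K4[T] + K5 (+ K6*K5 for the intra-plane extension); the unique
    non-negative root is taken.  When b = 0 the linear limit p = p_total/a
    is used directly.
    """
    _check_nonnegative("p_total", p_total)
    m, t = bath.m_conc, bath.t_conc
    a = 1.0 + k.k1 * m + k.k2 * t
    b = k.k4 * t + k.k5  # type: ignore[operator]
    intra_coeff = k.k6 * k.k5 if include_intra else 0.0
    b += intra_coeff
    if b == 0.0:
        p = p_total / a
    else:
        disc = a * a + 8.0 * b * p_total
        if disc < 0:  # pragma: no cover - impossible for valid inputs
            raise ArithmeticError("no non-negative root of the conservation law")
        # algebraically (-a + sqrt(disc)) / (4 b); this form avoids the
        # catastrophic cancellation of that difference when a dominates
        p = 2.0 * p_total / (a + math.sqrt(disc))
    return SpeciesState(
        p=p,
        pm=k.k1 * m * p,
        pt=k.k2 * t * p,
        p2t=k.k4 * t * p * p,  # type: ignore[operator]
        p2=k.k5 * p * p,
        p2_intra=intra_coeff * p * p,
        p_total=p_total,
        solver_tag="exact",
    )


def adhesion_signal(state: SpeciesState) -> float:
    """Inter-surface pairing concentration P2 + P2T governing adhesion.

    Intra-plane pairs do not bridge the surfaces and are excluded.
    """
    return state.p2t + state.p2


def monovalent_limit(p_total: float, m_conc: float, k: BindingConstants) -> float:
    """Adhesion signal for a pure monovalent bath: K5 p_total^2 / (K1[M]+1)^2.

    Predicts an inverse-square decay of adhesion with [M] at high
    monovalent concentration.
    """
    _check_nonnegative("p_total", p_total)
    _check_nonnegative("m_conc", m_conc)
    denom = k.k1 * m_conc + 1.0
    return k.k5 * p_total * p_total / (denom * denom)


def trivalent_limit(p_total: float, t_conc: float, k: BindingConstants) -> float:
    """Adhesion signal for a pure multivalent bath.

    (K4[T] + K5) p_total^2 / (K2[T] + 1)^2 — the form that produces the
    characteristic overshoot at low [T] when bridging outcompetes blocking.
    """
    _check_nonnegative("p_total", p_total)
    _check_nonnegative("t_conc", t_conc)
    denom = k.k2 * t_conc + 1.0
    return (k.k4 * t_conc + k.k5) * p_total * p_total / (denom * denom)  # type: ignore[operator]


def no_electrolyte_quadratic(p_total: float, k5: float) -> float:
    """Salt-free adhesion signal: K5 p_total^2 (quadratic in grafting density)."""
    _check_nonnegative("p_total", p_total)
    _check_nonnegative("k5", k5)
    return k5 * p_total * p_total


def extended_no_electrolyte(p_total: float, k5: float, k6: float) -> float:
    """Salt-free signal with intra-plane competition.

    K5 p_total^2 / (1 + 2 K6 p_total)^2: same-surface pairing sequesters
    peptides on crowded surfaces, so the quadratic growth saturates toward
    K5/(4 K6^2) at high grafting density.  Collapses to the plain quadratic
    when ``k6 = 0``.
    """
    _check_nonnegative("p_total", p_total)
    _check_nonnegative("k5", k5)
    _check_nonnegative("k6", k6)
    denom = 1.0 + 2.0 * k6 * p_total
    return k5 * p_total * p_total / (denom * denom)


def overshoot_diagnostic(k: BindingConstants) -> OvershootResult:
    """Analytic overshoot test for the trivalent isotherm.

    The normalized signal g(T) = (1 + (K4/K5) T) / (1 + K2 T)^2 rises above
    its zero-salt value iff g'(0) > 0, i.e. K4/K5 > 2 K2.  The interior
    maximizer is t_peak = (r - 2 K2)/(K2 r) with r = K4/K5; for K2 = 0 the
    rise is unbounded and ``t_peak`` is ``None``.
    """
    if k.k5 <= 0:
        raise ValueError("overshoot diagnostic requires k5 > 0 (normalization)")
    r = k.k4 / k.k5  # type: ignore[operator]
    has = r > 2.0 * k.k2
    if not has:
        return OvershootResult(has_overshoot=False, t_peak=None)
    if k.k2 == 0.0:
        return OvershootResult(has_overshoot=True, t_peak=None)
    return OvershootResult(has_overshoot=True, t_peak=(r - 2.0 * k.k2) / (k.k2 * r))
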