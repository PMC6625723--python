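"""Dominant-eigenvalue fitness and selection gradients for de-differentiation.

The dominant eigenvalue lambda of a projection matrix is the asymptotic
exponential growth rate of the population it generates, and serves as the
fitness measure.  For the lower-triangular resident matrix it is simply the
largest diagonal entry, ``lambda0 = r_{j0}(p_{j0} - q_{j0})``, attained at
the leading compartment j0.

A mutant family is affine in the de-differentiation scale,
``A(rho) = A0 + rho * B``, so to first order the mutant fitness is
``lambda(rho) ~ lambda0 + rho * dlam`` where the selection gradient
``dlam = mu^T B eta`` contracts the direction matrix with the left and
right eigenvectors of lambda0 (normalised ``mu^T eta = 1``).  A positive
gradient means the de-differentiating mutant out-grows the resident.

Three independent routes to the gradient are provided and cross-check each
other:

* ``selection_gradient_closed`` — the case-by-case closed form in terms of
  the ratios ``Gamma_{j,k,l} = 2 r_j q_j / (e_k - e_l)`` with
  ``e_i = r_i (p_i - q_i)``;
* ``selection_gradient_perturbation`` — the eigenvector contraction
  ``mu^T B eta`` evaluated numerically;
* ``selection_gradient_exact`` — the finite difference
  ``(lambda(rho) - lambda0) / rho`` on the actually perturbed matrix,
  accurate to O(rho).

The closed forms: with stepwise de-differentiation,

* j0 = 1:        dlam_S = Gamma_{1,1,2}                      (kappa-free, > 0)
* 1 < j0 < n-1:  dlam_S = Gamma_{j0-1,j0,j0-1} + Gamma_{j0,j0,j0+1} - kappa
* j0 = n-1:      dlam_S = Gamma_{n-2,n-1,n-2} - kappa

and with jumpwise de-differentiation,

* j0 < n-1:  dlam_J = prod_{i<j0} Gamma_{i,j0,i} * prod_{i>j0} Gamma_{i-1,j0,i}
             (kappa-free, > 0)
* j0 = n-1:  dlam_J = prod_{i=1}^{n-2} Gamma_{i,n-1,i} - kappa

Whenever the gradient is affine in kappa with slope -1, its root
``kappa* = `` (the Gamma sum or product) is the critical redistributing
factor above which de-differentiation is selected against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .matrices import (
    ProjectionMatrix,
    build_mutant_matrix,
    build_resident_matrix,
    dediff_direction,
)
from .params import (
    SIMPLICITY_RTOL,
    DedifferentiationSpec,
    HierarchyParams,
    Mode,
)

__all__ = [
    "SpectralSummary",
    "SelectionResult",
    "CriticalKappa",
    "DegenerateEigenvalueError",
    "dominant_spectrum",
    "leading_compartment",
    "gamma",
    "selection_gradient_closed",
    "selection_gradient_perturbation",
    "selection_gradient_exact",
    "selection_gradient_richardson",
    "critical_kappa",
    "critical_rate",
    "critical_rate_closed_form",
]

#: Absolute ceiling for the imaginary part of a "real" dominant eigenvalue,
#: relative to max(1, |lambda|).  Essential non-negativity guarantees a real
#: dominant eigenvalue; exceeding this is a numerical red flag.
IMAG_TOL = 1e-10


class DegenerateEigenvalueError(ArithmeticError):
    """The dominant eigenvalue is not simple within tolerance."""


@dataclass(frozen=True)
class SpectralSummary:
    """Dominant eigenvalue with its eigenpair and separation diagnostics."""

    lam: float                    #: dominant eigenvalue, per unit time
    mu: np.ndarray | None         #: left eigenvector (mu^T A = lam mu^T)
    eta: np.ndarray | None        #: right eigenvector (A eta = lam eta)
    j0: int | None                #: leading compartment (triangular matrices)
    gap: float                    #: distance to the nearest other eigenvalue
    simple: bool


@dataclass(frozen=True)
class SelectionResult:
    """A selection gradient with its provenance and threshold information."""

    delta_lambda: float
    method: str                   #: closed_form | perturbation_numeric | exact_difference
    mode: Mode
    j0: int | None = None
    #: (j, k, l, value) of every Gamma ratio entering the closed form.
    gamma_terms: tuple[tuple[int, int, int, float], ...] = ()
    #: Root of the gradient in kappa when it is kappa-dependent, else None.
    kappa_critical: float | None = None


@dataclass(frozen=True)
class CriticalKappa:
    """Outcome of the critical-redistributing-factor analysis.

    ``status`` is ``"root"`` (sign change at ``kappa_star`` inside [0, 1]),
    ``"always_positive"`` or ``"always_negative"``; ``gradient`` carries the
    kappa-independent gradient value when there is one.
    """

    status: str
    kappa_star: float | None = None
    gradient: float | None = None


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def dominant_spectrum(
    m: ProjectionMatrix,
    tie_rtol: float = SIMPLICITY_RTOL,
    require_simple: bool = True,
) -> SpectralSummary:
    """Dominant eigenvalue and eigenvectors of a projection matrix.

    The eigenvalue of largest real part is returned as a real number (its
    imaginary part must vanish to within ``IMAG_TOL``, which essential
    non-negativity guarantees).  Eigenvectors are normalised so that ``eta``
    has unit Euclidean norm with a positive anchor entry and
    ``mu^T eta = 1``, the convention the perturbation formula assumes.

    For lower-triangular matrices the eigenvalue is taken from the diagonal
    exactly and the leading compartment ``j0`` is reported.

    Raises :class:`DegenerateEigenvalueError` when the dominant eigenvalue
    is within tolerance of another one, unless ``require_simple=False``, in
    which case a summary with ``simple=False`` and no eigenvectors is
    returned.
    """
    a = m.entries
    n = m.n
    w, vl, vr = scipy.linalg.eig(a, left=True, right=True)
    idx = int(np.argmax(w.real))
    lam = w[idx]
    if abs(lam.imag) > IMAG_TOL * max(1.0, abs(lam.real)):
        raise ArithmeticError(
            f"dominant eigenvalue {lam} has a non-negligible imaginary part; "
            "the projection matrix violates essential non-negativity assumptions"
        )
    lam_r = float(lam.real)
    j0 = None
    if m.is_lower_triangular:
        diag = np.diag(a)
        j0 = int(np.argmax(diag[: n - 1])) + 1
        lam_r = float(np.max(diag))  # exact: eigenvalues of a triangular matrix
    others = np.delete(w, idx)
    gap = float(np.min(np.abs(others - lam))) if others.size else math.inf
    simple = gap >= tie_rtol * max(1.0, abs(lam_r))
    if not simple:
        if require_simple:
            raise DegenerateEigenvalueError(
                f"dominant eigenvalue {lam_r:.6g} is degenerate (gap {gap:.3g})"
            )
        return SpectralSummary(lam=lam_r, mu=None, eta=None, j0=j0, gap=gap, simple=False)
    eta = vr[:, idx]
    mu = vl[:, idx].conj()
    if max(abs(eta.imag).max(), abs(mu.imag).max()) > 1e-8:
        raise ArithmeticError("eigenvectors of the dominant eigenvalue are not real")
    eta = eta.real
    mu = mu.real
    anchor = (j0 - 1) if j0 is not None else int(np.argmax(np.abs(eta)))
    eta = eta / np.linalg.norm(eta)
    if eta[anchor] < 0:
        eta = -eta
    dot = float(mu @ eta)
    if abs(dot) < 1e-12:
        raise DegenerateEigenvalueError(
            "left/right eigenvectors are near-orthogonal; the dominant "
            "eigenvalue is effectively defective"
        )
    mu = mu / dot
    return SpectralSummary(lam=lam_r, mu=mu, eta=eta, j0=j0, gap=gap, simple=True)


def leading_compartment(params: HierarchyParams) -> tuple[int, float]:
    """Leading compartment ``j0`` and resident fitness ``lambda0``.

    ``j0`` is the unique argmax of the effective self-renewal rates
    ``r_i (p_i - q_i)``; a tie within tolerance or a shrinking resident
    (``lambda0 < 0``) is rejected, matching the model's standing assumptions.
    """
    e = params.effective_self_renewal
    lam0 = float(np.max(e))
    order = np.sort(e)
    if len(order) > 1 and order[-1] - order[-2] < params.tie_rtol * max(1.0, abs(lam0)):
        raise DegenerateEigenvalueError(
            f"two compartments tie for the largest effective self-renewal rate "
            f"({order[-1]:.6g} vs {order[-2]:.6g}); lambda0 is not simple"
        )
    if lam0 < 0:
        raise ValueError(
            f"resident population is shrinking (lambda0 = {lam0:.6g} < 0); "
            "the invasion analysis assumes lambda0 >= 0"
        )
    return int(np.argmax(e)) + 1, lam0


def gamma(params: HierarchyParams, j: int, k: int, l: int) -> float:
    """The ratio ``Gamma_{j,k,l} = 2 r_j q_j / (e_k - e_l)``.

    ``e_i = r_i (p_i - q_i)`` is the effective self-renewal rate.  These
    ratios are the building blocks of the closed-form selection gradients;
    every ratio appearing there has ``k = j0`` and is positive whenever
    lambda0 is simple.  Indices are 1-based compartments.
    """
    e = params.effective_self_renewal
    den = e[k - 1] - e[l - 1]
    if abs(den) < 1e-300:
        raise ZeroDivisionError(
            f"Gamma_{{{j},{k},{l}}} undefined: compartments {k} and {l} have "
            "equal effective self-renewal rates"
        )
    return 2.0 * params.r[j - 1] * params.q[j - 1] / den


# ---------------------------------------------------------------------------
# Selection gradients: closed form
# ---------------------------------------------------------------------------


def _stepwise_terms(params: HierarchyParams, j0: int, n: int):
    if j0 == 1:
        return [(1, 1, 2)]
    if j0 < n - 1:
        return [(j0 - 1, j0, j0 - 1), (j0, j0, j0 + 1)]
    return [(n - 2, n - 1, n - 2)]


def _jumpwise_terms(j0: int, n: int):
    if j0 < n - 1:
        return [(i, j0, i) for i in range(1, j0)] + [
            (i - 1, j0, i) for i in range(j0 + 1, n)
        ]
    return [(i, n - 1, i) for i in range(1, n - 1)]


def selection_gradient_closed(
    params: HierarchyParams, mode: "Mode | str", kappa: float
) -> SelectionResult:
    """Closed-form selection gradient (Gamma-ratio cases by leading compartment).

    The gradient is kappa-free when de-differentiation feeds the leading
    compartment from above (stepwise with j0 = 1, jumpwise with j0 < n-1)
    and affine in kappa with slope exactly -1 otherwise; in the latter case
    ``kappa_critical`` records the root of the gradient.
    """
    mode = Mode(mode)
    j0, _ = leading_compartment(params)
    n = params.n
    if mode is Mode.STEPWISE:
        terms = _stepwise_terms(params, j0, n)
        values = [gamma(params, *t) for t in terms]
        base = sum(values)
        kappa_dep = j0 > 1
    else:
        terms = _jumpwise_terms(j0, n)
        values = [gamma(params, *t) for t in terms]
        base = math.prod(values)
        kappa_dep = j0 == n - 1
    dlam = base - kappa if kappa_dep else base
    return SelectionResult(
        delta_lambda=float(dlam),
        method="closed_form",
        mode=mode,
        j0=j0,
        gamma_terms=tuple((j, k, l, v) for (j, k, l), v in zip(terms, values)),
        kappa_critical=float(base) if kappa_dep else None,
    )


# ---------------------------------------------------------------------------
# Selection gradients: perturbation and exact difference
# ---------------------------------------------------------------------------


def selection_gradient_perturbation(
    params: HierarchyParams, dediff: DedifferentiationSpec
) -> SelectionResult:
    """Selection gradient via the eigenvalue-perturbation contraction.

    Evaluates ``mu^T B eta`` where ``B = dA/d(rho)`` at ``rho = 0`` for the
    given mode and kappa, and mu, eta are the resident eigenvectors of
    lambda0 normalised to ``mu^T eta = 1``.  Independent of the eigenvector
    scaling convention by construction.
    """
    spec = dominant_spectrum(build_resident_matrix(params))
    b = dediff_direction(params.n, dediff.mode, dediff.kappa)
    dlam = float(spec.mu @ b @ spec.eta)
    return SelectionResult(
        delta_lambda=dlam, method="perturbation_numeric", mode=dediff.mode, j0=spec.j0
    )


def selection_gradient_exact(
    params: HierarchyParams, dediff: DedifferentiationSpec
) -> SelectionResult:
    """Finite-rho selection gradient ``(lambda(rho) - lambda0) / rho``.

    Uses the dominant eigenvalue of the actually perturbed matrix, so it
    carries an O(rho) truncation error relative to the gradient at rho = 0.
    This is the quantity the reference figures plot as exact numerical
    solutions.  Requires ``rho > 0``.
    """
    if dediff.rho <= 0:
        raise ZeroDivisionError("exact gradient requires rho > 0")
    lam0 = dominant_spectrum(build_resident_matrix(params)).lam
    lam = dominant_spectrum(build_mutant_matrix(params, dediff)).lam
    j0, _ = leading_compartment(params)
    return SelectionResult(
        delta_lambda=(lam - lam0) / dediff.rho,
        method="exact_difference",
        mode=dediff.mode,
        j0=j0,
    )


def selection_gradient_richardson(
    params: HierarchyParams, dediff: DedifferentiationSpec
) -> SelectionResult:
    """Richardson extrapolation of the exact gradient over (rho, rho/2).

    The leading truncation error of the finite-rho gradient is linear in
    rho, so ``2 g(rho/2) - g(rho)`` cancels it and converges to the closed
    form as O(rho^2).  Serves as the convergence oracle for the other
    routes.
    """
    g1 = selection_gradient_exact(params, dediff).delta_lambda
    half = DedifferentiationSpec(mode=dediff.mode, rho=dediff.rho / 2.0, kappa=dediff.kappa)
    g2 = selection_gradient_exact(params, half).delta_lambda
    return SelectionResult(
        delta_lambda=2.0 * g2 - g1,
        method="exact_difference",
        mode=dediff.mode,
        j0=leading_compartment(params)[0],
    )


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


def critical_kappa(params: HierarchyParams, mode: "Mode | str") -> CriticalKappa:
    """Critical redistributing factor ``kappa*`` where the gradient crosses zero.

    Only the kappa-dependent cases (stepwise with j0 > 1, jumpwise with
    j0 = n-1) have a threshold; there ``kappa*`` equals the Gamma sum or
    product.  If that value falls at or above 1 the gradient is positive on
    the whole admissible range, and at or below 0 it is negative throughout
    (unreachable while the Gamma ratios are positive, but guarded).
    Kappa-independent cases report ``always_positive`` with the gradient
    value.
    """
    result = selection_gradient_closed(params, mode, kappa=0.0)
    if result.kappa_critical is None:
        return CriticalKappa(status="always_positive", gradient=result.delta_lambda)
    ks = result.kappa_critical
    if ks >= 1.0:
        return CriticalKappa(status="always_positive", kappa_star=ks)
    if ks <= 0.0:
        return CriticalKappa(status="always_negative", kappa_star=ks)
    return CriticalKappa(status="root", kappa_star=ks)


def critical_rate(
    params: HierarchyParams,
    mode: "Mode | str",
    rate_index: int,
    bracket: tuple[float, float],
    kappa: float = 1.0,
    xtol: float = 1e-6,
    cross_check_rho: float | None = 0.01,
) -> float:
    """Division rate at which the closed-form gradient (at ``kappa``) crosses zero.

    Bisects ``dlam(r_{rate_index})`` over ``bracket``; the leading
    compartment must be identical at both ends and at the root, since the
    closed form switches branches with j0.  When ``cross_check_rho`` is set
    the sign change is verified on the finite-rho exact gradient as well; a
    disagreement raises a warning rather than an error (the exact gradient
    is offset by O(rho)).
    """
    mode = Mode(mode)
    key = f"r{rate_index}"

    def grad(rate: float) -> tuple[float, int]:
        res = selection_gradient_closed(params.replace(**{key: rate}), mode, kappa)
        return res.delta_lambda, res.j0

    lo, hi = bracket
    g_lo, j_lo = grad(lo)
    g_hi, j_hi = grad(hi)
    if j_lo != j_hi:
        raise ValueError(
            f"leading compartment changes across the bracket (j0={j_lo} at "
            f"{key}={lo}, j0={j_hi} at {key}={hi}); the closed form is not "
            "single-branch there"
        )
    if g_lo * g_hi > 0:
        raise ValueError(
            f"no sign change of the selection gradient over the bracket "
            f"({g_lo:.6g} at {key}={lo}, {g_hi:.6g} at {key}={hi})"
        )
    root = float(
        scipy.optimize.bisect(lambda x: grad(x)[0], lo, hi, xtol=xtol)
    )
    if grad(root)[1] != j_lo:
        raise ValueError("leading compartment changes at the root")
    if cross_check_rho is not None:
        eps = max(10.0 * xtol, 1e-4)
        signs = []
        for x in (max(lo, root - 50 * eps), min(hi, root + 50 * eps)):
            dd = DedifferentiationSpec(mode=mode, rho=cross_check_rho, kappa=kappa)
            signs.append(
                selection_gradient_exact(params.replace(**{key: x}), dd).delta_lambda
            )
        if signs[0] * signs[1] > 0 and min(abs(s) for s in signs) > 10 * cross_check_rho:
            warnings.warn(
                "finite-rho exact gradient does not change sign near the "
                f"closed-form root {root:.6g}; check rho and the bracket",
                stacklevel=2,
            )
    return root


def critical_rate_closed_form(params: HierarchyParams, mode: "Mode | str" = Mode.JUMPWISE) -> float:
    """Closed-form critical stem-cell division rate for the jumpwise threshold.

    Valid when the leading compartment is the last dividing one
    (j0 = n-1) so the jumpwise gradient at kappa = 1 is
    ``prod_{i=1}^{n-2} Gamma_{i,n-1,i} - 1``.  Only the i = 1 factor depends
    on r_1 (as ``2 r_1 q_1 / (lambda0 - r_1 (p_1 - q_1))``), so the root of
    the product is

        ``r_1* = lambda0 / (2 q_1 C + (p_1 - q_1))``

    with ``C`` the product of the remaining factors.  Matches the bisection
    root of :func:`critical_rate` with ``rate_index=1``.
    """
    if Mode(mode) is not Mode.JUMPWISE:
        raise ValueError("the closed-form rate threshold is defined for jumpwise mode")
    j0, lam0 = leading_compartment(params)
    n = params.n
    if j0 != n - 1:
        raise ValueError(
            f"threshold requires the last dividing compartment to lead (j0={j0}, n-1={n - 1})"
        )
    c = math.prod(gamma(params, i, n - 1, i) for i in range(2, n - 1))
    p1, q1 = params.p[0], params.q[0]
    return lam0 / (2.0 * q1 * c + (p1 - q1))
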