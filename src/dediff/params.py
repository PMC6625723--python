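"""Parameter containers for hierarchical-tissue models with de-differentiation.

A tissue is a chain of ``n`` compartments ordered by differentiation stage:
compartment 1 holds the stem cells, compartment ``n`` the terminally
differentiated cells, which no longer divide and are removed at rate ``d``.
A cell in dividing compartment ``i`` (1 <= i <= n-1) divides at rate ``r_i``
and produces either two daughters in its own compartment (self-renewal,
probability ``p_i``) or two daughters in compartment ``i+1``
(differentiation, probability ``q_i``); residents close the probability
budget with ``p_i + q_i = 1``.

De-differentiating mutants spend an extra probability ``delta_i`` per
division on producing two daughters in an upstream compartment, either the
adjacent one (stepwise) or the stem-cell compartment directly (jumpwise).
The per-compartment influx scale ``rho = 2 r_i delta_i`` is assumed equal
across compartments, so ``rho`` is the single knob and ``delta_i`` is always
derived as ``rho / (2 r_i)``.  The redistributing factor ``kappa`` sets how
the budget for de-differentiation is taken from the other two outcomes:
``p_i -> p_i - kappa*delta_i`` and ``q_i -> q_i - (1-kappa)*delta_i``.

This module also ships the named parameter sets used by the reference
figures and a seeded random-parameter generator for property-based testing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Mode",
    "ValidationError",
    "HierarchyParams",
    "DedifferentiationSpec",
    "AsymmetricExtension",
    "validate",
    "validate_fields",
    "random_params",
    "FigureFixture",
    "named_fixture",
    "list_fixtures",
    "SIMPLICITY_RTOL",
]

#: Relative tolerance below which two effective self-renewal rates are
#: treated as tied (degenerate dominant eigenvalue).  Scaled by
#: ``max(1, |lambda0|)``.
SIMPLICITY_RTOL = 1e-9


class Mode(str, enum.Enum):
    """De-differentiation pattern of the mutant lineage."""

    STEPWISE = "stepwise"  #: compartment i+1 -> i, one step up
    JUMPWISE = "jumpwise"  #: compartment n-1 -> 1, straight to the stem cells

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ValidationError(ValueError):
    """Raised by constructors on invalid parameter sets.

    Carries the full report of violated invariants in ``report``.
    """

    def __init__(self, report: list[str]):
        self.report = list(report)
        super().__init__("; ".join(report))


def _as_mode(mode: "Mode | str") -> Mode:
    return Mode(mode) if not isinstance(mode, Mode) else mode


# ---------------------------------------------------------------------------
# Resident tissue parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HierarchyParams:
    """Resident (non de-differentiating) tissue parameters.

    Parameters
    ----------
    n : int
        Number of compartments, at least 3 (with n=2 the only non-stem
        compartment is terminal and non-dividing, so no de-differentiation
        pattern is defined).
    r : sequence of n-1 positive floats
        Division rate of each dividing compartment, per unit time.
    p : sequence of n-1 floats in [0, 1]
        Symmetric self-renewal probability per division.
    d : float
        Removal rate of the terminal compartment, per unit time.
    q : sequence of n-1 floats, optional
        Symmetric differentiation probability; defaults to ``1 - p`` and
        must satisfy ``p_i + q_i = 1`` (resident divisions have exactly two
        outcomes).
    tie_rtol : float
        Relative tolerance used to declare the leading effective
        self-renewal rate degenerate.

    All indices in the public API are 1-based (compartment 1 = stem cells);
    internally arrays are 0-based with ``r[0]`` belonging to compartment 1.
    """

    n: int
    r: tuple[float, ...]
    p: tuple[float, ...]
    d: float
    q: tuple[float, ...] | None = None
    tie_rtol: float = SIMPLICITY_RTOL
    #: Permit p_i + q_i < 1; the remainder is the asymmetric-division share
    #: s_i = 1 - p_i - q_i (used only by the asymmetric resident variant).
    open_budget: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", tuple(float(x) for x in self.r))
        object.__setattr__(self, "p", tuple(float(x) for x in self.p))
        if self.q is None:
            object.__setattr__(self, "q", tuple(1.0 - x for x in self.p))
        else:
            object.__setattr__(self, "q", tuple(float(x) for x in self.q))
        object.__setattr__(self, "d", float(self.d))
        report = validate_fields(
            n=self.n, r=self.r, p=self.p, q=self.q, d=self.d, tie_rtol=self.tie_rtol,
            open_budget=self.open_budget,
        )
        if report:
            raise ValidationError(report)

    # -- derived quantities -------------------------------------------------

    @property
    def effective_self_renewal(self) -> np.ndarray:
        """``r_i (p_i - q_i)`` for the dividing compartments (length n-1)."""
        r = np.asarray(self.r)
        return r * (np.asarray(self.p) - np.asarray(self.q))

    @property
    def diagonal(self) -> np.ndarray:
        """Full projection-matrix diagonal, ``(-d)`` appended (length n)."""
        return np.append(self.effective_self_renewal, -self.d)

    @property
    def leading_compartment(self) -> int:
        """1-based index of the compartment with the largest effective
        self-renewal rate (the leading compartment j0)."""
        return int(np.argmax(self.effective_self_renewal)) + 1

    @property
    def lambda0(self) -> float:
        """Dominant eigenvalue of the resident matrix (max diagonal entry)."""
        return float(np.max(self.effective_self_renewal))

    def replace(self, **updates: object) -> "HierarchyParams":
        """Return a copy with named scalar parameters replaced.

        Accepts keys like ``r1``, ``p2``, ``q3`` (1-based compartment index)
        and ``d``.  Setting ``p_i`` re-closes ``q_i = 1 - p_i`` and vice
        versa, preserving the two-outcome budget.
        """
        r, p, q = list(self.r), list(self.p), list(self.q)
        d = self.d
        for key, raw in updates.items():
            value = float(raw)  # type: ignore[arg-type]
            if key == "d":
                d = value
                continue
            name, idx = key[0], int(key[1:]) - 1
            if not 0 <= idx < self.n - 1:
                raise KeyError(f"compartment index out of range in {key!r}")
            if name == "r":
                r[idx] = value
            elif name == "p":
                p[idx] = value
                q[idx] = 1.0 - value
            elif name == "q":
                q[idx] = value
                p[idx] = 1.0 - value
            else:
                raise KeyError(f"unknown parameter {key!r}")
        return HierarchyParams(n=self.n, r=tuple(r), p=tuple(p), q=tuple(q), d=d,
                               tie_rtol=self.tie_rtol)


@dataclass(frozen=True)
class DedifferentiationSpec:
    """Mutant de-differentiation pattern.

    ``rho`` is the de-differentiation influx scale (``rho = 2 r_i delta_i``,
    shared by all compartments); ``kappa`` in [0, 1] redistributes the
    probability cost between self-renewal (fraction ``kappa``) and
    differentiation (fraction ``1 - kappa``).
    """

    mode: Mode
    rho: float
    kappa: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", _as_mode(self.mode))
        object.__setattr__(self, "rho", float(self.rho))
        object.__setattr__(self, "kappa", float(self.kappa))
        report = []
        if self.rho < 0:
            report.append(f"rho must be non-negative, got {self.rho}")
        if not 0.0 <= self.kappa <= 1.0:
            report.append(f"kappa must lie in [0, 1], got {self.kappa}")
        if report:
            raise ValidationError(report)

    def delta(self, params: HierarchyParams) -> np.ndarray:
        """Per-compartment de-differentiation probability ``rho / (2 r_i)``.

        Derived on demand: ``rho`` stays the single source of truth.
        """
        return self.rho / (2.0 * np.asarray(params.r))

    def affected_compartments(self, n: int) -> range:
        """1-based dividing compartments whose division probabilities are
        redistributed by this mode (the stem compartment never
        de-differentiates)."""
        if self.mode is Mode.STEPWISE:
            return range(2, n)
        return range(n - 1, n)


@dataclass(frozen=True)
class AsymmetricExtension:
    """Asymmetric-division probabilities ``s_i`` for the resident variant.

    When active the probability budget is ``p_i + q_i + s_i = 1``: one
    daughter stays in compartment i, the other moves to i+1.  Used only to
    demonstrate that asymmetric division leaves the fitness analysis
    unchanged (it shifts the subdiagonal influx from ``2 r_i q_i`` to
    ``2 r_i q_i + r_i s_i`` without touching the diagonal).
    """

    s: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", tuple(float(x) for x in self.s))
        if any(x < 0 for x in self.s):
            raise ValidationError(
                [f"s[{i + 1}] must be non-negative" for i, x in enumerate(self.s) if x < 0]
            )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_fields(
    n: int,
    r: Sequence[float],
    p: Sequence[float],
    q: Sequence[float] | None,
    d: float,
    tie_rtol: float = SIMPLICITY_RTOL,
    open_budget: bool = False,
) -> list[str]:
    """Report every violated resident invariant on raw field values.

    Unlike the constructors this never raises, so invalid candidate sets can
    be inspected.  An empty list means the fields describe a valid tissue.
    """
    report: list[str] = []
    if n < 3:
        report.append(f"n must be at least 3, got {n}")
        return report
    if q is None:
        q = [1.0 - x for x in p]
    for name, seq in (("r", r), ("p", p), ("q", q)):
        if len(seq) != n - 1:
            report.append(f"{name} must have length n-1={n - 1}, got {len(seq)}")
    if report:
        return report
    for i in range(n - 1):
        c = i + 1
        if r[i] <= 0:
            report.append(f"r[{c}] must be positive, got {r[i]}")
        if not 0.0 <= p[i] <= 1.0:
            report.append(f"p[{c}] must lie in [0, 1], got {p[i]}")
        if not 0.0 <= q[i] <= 1.0:
            report.append(f"q[{c}] must lie in [0, 1], got {q[i]}")
        if open_budget:
            if p[i] + q[i] > 1.0 + 1e-12:
                report.append(f"p[{c}] + q[{c}] = {p[i] + q[i]:.6g} > 1")
        elif abs(p[i] + q[i] - 1.0) > 1e-12:
            report.append(
                f"p[{c}] + q[{c}] = {p[i] + q[i]:.6g} != 1 (resident divisions have"
                " exactly two outcomes)"
            )
    if d <= 0:
        report.append(f"d must be positive, got {d}")
    if report:
        return report
    diag = np.asarray(r) * (np.asarray(p) - np.asarray(q))
    lam0 = float(np.max(diag))
    if lam0 < 0:
        report.append(
            f"resident population is shrinking (max effective self-renewal {lam0:.6g} < 0)"
        )
    order = np.sort(diag)
    if len(order) > 1 and order[-1] - order[-2] < tie_rtol * max(1.0, abs(lam0)):
        report.append(
            "leading effective self-renewal rate is degenerate "
            f"(top two entries {order[-1]:.6g}, {order[-2]:.6g})"
        )
    return report


def validate(
    params: "HierarchyParams | Mapping[str, object]",
    dediff: DedifferentiationSpec | None = None,
) -> list[str]:
    """Report every violated invariant of a (tissue, de-differentiation) pair.

    ``params`` may be a constructed :class:`HierarchyParams` (already valid
    by construction) or a mapping of raw fields, which allows reporting on
    candidate sets the constructor would reject.  Returns an empty list when
    everything holds.
    """
    if isinstance(params, HierarchyParams):
        n, r, p, q, d = params.n, params.r, params.p, params.q, params.d
        report = []
    else:
        n = int(params["n"])  # type: ignore[index]
        r = list(params["r"])  # type: ignore[index]
        p = list(params["p"])  # type: ignore[index]
        q = list(params["q"]) if params.get("q") is not None else None  # type: ignore
        d = float(params["d"])  # type: ignore[index]
        report = validate_fields(n=n, r=r, p=p, q=q, d=d)
        if q is None:
            q = [1.0 - x for x in p]
    if dediff is None or report:
        return report
    # redistributed probabilities must stay valid in every affected compartment
    for c in dediff.affected_compartments(n):
        i = c - 1
        delta = dediff.rho / (2.0 * r[i])
        p_prime = p[i] - dediff.kappa * delta
        q_prime = q[i] - (1.0 - dediff.kappa) * delta
        if p_prime < 0:
            report.append(
                f"p[{c}] - kappa*delta[{c}] = {p_prime:.6g} < 0"
                " (self-renewal probability of the mutant would be negative)"
            )
        if q_prime < 0:
            report.append(
                f"q[{c}] - (1-kappa)*delta[{c}] = {q_prime:.6g} < 0"
                " (differentiation probability of the mutant would be negative)"
            )
    return report


# ---------------------------------------------------------------------------
# Random parameter generator
# ---------------------------------------------------------------------------


def random_params(
    seed: int,
    regime: str = "expanding",
    j0_target: int = 1,
    n: int = 4,
) -> HierarchyParams:
    """Draw a valid resident parameter set with a prescribed leading compartment.

    ``regime="homeostatic"`` pins the leading compartment at zero net growth
    (``p_{j0} = q_{j0} = 1/2``) with every other effective self-renewal rate
    strictly negative; ``regime="expanding"`` makes the leading entry
    strictly positive and strictly maximal by a margin of at least 1e-3.
    Deterministic for a fixed seed.
    """
    if n < 3:
        raise ValidationError([f"n must be at least 3, got {n}"])
    if not 1 <= j0_target <= n - 1:
        raise ValueError(f"j0_target must lie in [1, {n - 1}], got {j0_target}")
    if regime not in ("expanding", "homeostatic"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.1, 1.0, size=n - 1)
    p = np.empty(n - 1)
    j = j0_target - 1
    if regime == "homeostatic":
        p[j] = 0.5
        lam0 = 0.0
    else:
        p[j] = rng.uniform(0.55, 0.95)
        lam0 = r[j] * (2.0 * p[j] - 1.0)
    margin = 1e-3
    for i in range(n - 1):
        if i == j:
            continue
        if regime == "homeostatic":
            # strictly negative net growth everywhere else
            p[i] = rng.uniform(0.05, 0.45)
        else:
            hi = min(lam0 - margin, 0.9 * r[i])
            lo = -0.9 * r[i]
            target = rng.uniform(lo, min(hi, lam0 - margin))
            p[i] = 0.5 * (target / r[i] + 1.0)
    d = rng.uniform(0.01, 0.2)
    return HierarchyParams(n=n, r=tuple(r), p=tuple(p), d=d)


# ---------------------------------------------------------------------------
# Named figure fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FigureFixture:
    """A named parameter set from the reference figures.

    ``fixed`` holds the values the figure caption states verbatim; ``free``
    maps each parameter the figure varies to the range it sweeps (ranges not
    stated by the caption are package choices, see ``docs/methods.md``);
    ``unspecified`` maps parameters the caption omits entirely to the
    package's documented default.
    """

    name: str
    mode: Mode
    fixed: Mapping[str, float]
    free: Mapping[str, tuple[float, float]]
    unspecified: Mapping[str, float] = field(default_factory=dict)

    def bind(self, **values: float) -> tuple[HierarchyParams, DedifferentiationSpec]:
        """Materialise the fixture with the free parameters bound.

        Unbound free parameters take the midpoint of their range and
        caption-omitted parameters take their documented default.
        """
        resolved: dict[str, float] = dict(self.fixed)
        for key, (lo, hi) in self.free.items():
            resolved[key] = 0.5 * (lo + hi)
        resolved.update(self.unspecified)
        resolved.update({k: float(v) for k, v in values.items()})
        n = int(resolved.pop("n"))
        rho = resolved.pop("rho")
        kappa = resolved.pop("kappa")
        d = resolved.pop("d")
        r = tuple(resolved.pop(f"r{i}") for i in range(1, n))
        p = tuple(resolved.pop(f"p{i}") for i in range(1, n))
        if resolved:
            raise KeyError(f"unused fixture values: {sorted(resolved)}")
        params = HierarchyParams(n=n, r=r, p=p, d=d)
        return params, DedifferentiationSpec(mode=self.mode, rho=rho, kappa=kappa)


def _fx(name, mode, fixed, free, unspecified=()):
    return FigureFixture(
        name=name, mode=Mode(mode), fixed=dict(fixed), free=dict(free),
        unspecified=dict(unspecified),
    )


_FIG2 = {"n": 4, "kappa": 0.1, "rho": 0.001, "d": 0.05, "r1": 0.99, "r3": 0.3}
_FIG3 = {"n": 4, "rho": 0.01, "d": 0.05}
_FIG5 = {"n": 4, "kappa": 0.1, "rho": 0.01, "d": 0.05}
_FIG6 = {"n": 4, "rho": 0.01, "d": 0.05}

#: Registry of figure parameter sets.  Free-parameter ranges marked with the
#: caption's own bounds where it states them; other ranges and the defaults
#: for caption-omitted rates are package choices.
FIXTURES: dict[str, FigureFixture] = {
    f.name: f
    for f in (
        _fx("fig2a", "stepwise", {**_FIG2, "p2": 0.55, "p3": 0.6},
            {"p1": (0.55, 1.0), "r2": (0.1, 0.8)}),
        _fx("fig2b", "stepwise", {**_FIG2, "p1": 0.5, "p3": 0.0},
            {"p2": (0.0, 0.3), "r2": (0.1, 0.8)}),
        _fx("fig3a", "stepwise",
            {**_FIG3, "p1": 0.5, "p2": 0.95, "p3": 0.55, "r2": 0.44, "r3": 0.17},
            {"r1": (0.05, 0.4), "kappa": (0.0, 1.0)}),
        _fx("fig3b", "stepwise",
            {**_FIG3, "p1": 0.001, "p2": 0.5, "p3": 0.001, "r1": 0.99, "r3": 0.8},
            {"r2": (0.1, 0.9), "kappa": (0.0, 1.0)}),
        _fx("fig4", "stepwise",
            {"n": 4, "rho": 0.01, "r1": 0.0885, "r2": 0.4145, "r3": 0.5555,
             "p1": 0.4723, "p3": 0.0727, "d": 0.005},
            {"p2": (0.55, 0.95), "kappa": (0.0, 1.0)}),
        _fx("fig5a", "jumpwise",
            {**_FIG5, "p2": 0.55, "p3": 0.6, "r1": 0.2, "r3": 0.3},
            {"p1": (0.7, 1.0)}, {"r2": 0.3}),
        _fx("fig5b", "jumpwise",
            {**_FIG5, "p1": 0.55, "p3": 0.6, "r1": 0.2, "r3": 0.3},
            {"p2": (0.65, 1.0)}, {"r2": 0.3}),
        _fx("fig5c", "jumpwise",
            {**_FIG5, "p1": 0.5, "p3": 0.1, "r2": 0.4, "r3": 0.6},
            {"p2": (0.05, 0.45)}, {"r1": 0.2}),
        _fx("fig5d", "jumpwise",
            {**_FIG5, "p2": 0.5, "p3": 0.1, "r1": 0.4, "r3": 0.6},
            {"p1": (0.05, 0.45)}, {"r2": 0.3}),
        _fx("fig6a", "jumpwise",
            {**_FIG6, "p1": 0.5, "p2": 0.65, "p3": 0.85, "r2": 0.4, "r3": 0.6},
            {"r1": (0.01, 0.6), "kappa": (0.0, 1.0)}),
        _fx("fig6b", "jumpwise",
            {**_FIG6, "p1": 0.01, "p3": 0.5, "r1": 0.8, "r2": 0.7, "r3": 0.2},
            {"p2": (0.05, 0.45), "kappa": (0.0, 1.0)}),
    )
}


def named_fixture(name: str) -> FigureFixture:
    """Look up a figure parameter set by name (``fig2a`` ... ``fig6b``)."""
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(sorted(FIXTURES))}"
        ) from None


def list_fixtures() -> list[str]:
    """Names of all registered figure parameter sets."""
    return sorted(FIXTURES)
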