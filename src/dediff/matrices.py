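"""Projection matrices of the compartmental population model.

The resident matrix is lower bidiagonal: diagonal entries are the effective
self-renewal rates ``r_i (p_i - q_i)`` (and ``-d`` for the terminal
compartment), subdiagonal entries are the differentiation influx rates
``2 r_i q_i``.  The mutant matrices add the de-differentiation influx
``rho`` above the diagonal — on the whole superdiagonal for the stepwise
pattern, or as a single entry in row 1, column n-1 for the jumpwise pattern
— and subtract the redistributed probability cost ``kappa*rho`` from the
affected diagonal entries and ``(1-kappa)*rho`` from the affected
subdiagonal entries.

All matrices are essentially non-negative (off-diagonal entries >= 0), so
the dominant eigenvalue is real and the flow preserves the non-negative
orthant.  Matrices are built dense; n is small in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    AsymmetricExtension,
    DedifferentiationSpec,
    HierarchyParams,
    Mode,
    ValidationError,
    validate,
)

__all__ = [
    "ProjectionMatrix",
    "build_resident_matrix",
    "build_stepwise_matrix",
    "build_jumpwise_matrix",
    "build_asymmetric_resident_matrix",
    "build_mutant_matrix",
    "dediff_direction",
]

_TRIANGULAR_TAGS = frozenset({"resident", "resident_asym"})


@dataclass(frozen=True)
class ProjectionMatrix:
    """An n-by-n projection matrix with structural provenance.

    ``tag`` is one of ``resident``, ``stepwise``, ``jumpwise``,
    ``resident_asym``; ``params_hash`` identifies the generating parameter
    set so downstream results can be traced back.
    """

    entries: np.ndarray
    tag: str
    params_hash: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"projection matrix must be square, got shape {a.shape}")
        off = a - np.diag(np.diag(a))
        if np.any(off < 0):
            i, j = np.argwhere(off < 0)[0]
            raise ValidationError(
                [f"off-diagonal entry ({i + 1},{j + 1}) = {a[i, j]:.6g} is negative"]
            )
        a.setflags(write=False)
        object.__setattr__(self, "entries", a)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def is_lower_triangular(self) -> bool:
        return self.tag in _TRIANGULAR_TAGS


def _hash(params: HierarchyParams, *extra: object) -> str:
    return f"{hash((params.n, params.r, params.p, params.q, params.d, *extra)) & 0xFFFFFFFF:08x}"


def build_resident_matrix(params: HierarchyParams) -> ProjectionMatrix:
    """Lower-bidiagonal matrix of the resident hierarchy.

    Diagonal ``r_i (p_i - q_i)`` for i = 1..n-1 and ``-d`` at (n, n);
    subdiagonal ``2 r_i q_i`` (differentiation influx from i to i+1).
    """
    n = params.n
    a = np.zeros((n, n))
    r, p, q = map(np.asarray, (params.r, params.p, params.q))
    a[np.arange(n - 1), np.arange(n - 1)] = r * (p - q)
    a[n - 1, n - 1] = -params.d
    a[np.arange(1, n), np.arange(n - 1)] = 2.0 * r * q
    return ProjectionMatrix(a, tag="resident", params_hash=_hash(params))


def build_stepwise_matrix(
    params: HierarchyParams, dediff: DedifferentiationSpec
) -> ProjectionMatrix:
    """Mutant matrix for stepwise de-differentiation (one compartment up).

    Relative to the resident matrix: superdiagonal entries ``(i, i+1) = rho``
    for i = 1..n-2; the diagonal of compartments 2..n-1 is reduced by
    ``kappa*rho`` and their subdiagonal outflux by ``(1-kappa)*rho``.  Row 1
    (the stem compartment never de-differentiates) and the terminal removal
    rate are untouched.
    """
    if dediff.mode is not Mode.STEPWISE:
        raise ValueError(f"expected stepwise spec, got mode {dediff.mode}")
    n = params.n
    a = np.array(build_resident_matrix(params).entries)
    rho, kappa = dediff.rho, dediff.kappa
    a[np.arange(n - 2), np.arange(1, n - 1)] = rho
    a[np.arange(1, n - 1), np.arange(1, n - 1)] -= kappa * rho
    a[np.arange(2, n), np.arange(1, n - 1)] -= (1.0 - kappa) * rho
    return ProjectionMatrix(a, tag="stepwise",
                            params_hash=_hash(params, dediff.rho, dediff.kappa, "S"))


def build_jumpwise_matrix(
    params: HierarchyParams, dediff: DedifferentiationSpec
) -> ProjectionMatrix:
    """Mutant matrix for jumpwise de-differentiation (straight to the stem pool).

    Relative to the resident matrix: a single influx entry
    ``(1, n-1) = rho``; the diagonal of compartment n-1 is reduced by
    ``kappa*rho`` and its subdiagonal outflux by ``(1-kappa)*rho``.
    """
    if dediff.mode is not Mode.JUMPWISE:
        raise ValueError(f"expected jumpwise spec, got mode {dediff.mode}")
    n = params.n
    a = np.array(build_resident_matrix(params).entries)
    rho, kappa = dediff.rho, dediff.kappa
    a[0, n - 2] += rho
    a[n - 2, n - 2] -= kappa * rho
    a[n - 1, n - 2] -= (1.0 - kappa) * rho
    return ProjectionMatrix(a, tag="jumpwise",
                            params_hash=_hash(params, dediff.rho, dediff.kappa, "J"))


def build_mutant_matrix(
    params: HierarchyParams, dediff: DedifferentiationSpec
) -> ProjectionMatrix:
    """Dispatch to the stepwise or jumpwise builder by ``dediff.mode``."""
    if dediff.mode is Mode.STEPWISE:
        return build_stepwise_matrix(params, dediff)
    return build_jumpwise_matrix(params, dediff)


def build_asymmetric_resident_matrix(
    params: HierarchyParams, ext: AsymmetricExtension
) -> ProjectionMatrix:
    """Resident variant with asymmetric division (one daughter stays, one moves).

    Requires ``p_i + q_i + s_i = 1``; the caller therefore supplies ``q``
    explicitly on ``params`` (``q = 1 - p - s``).  The diagonal is unchanged
    while the subdiagonal influx becomes ``2 r_i q_i + r_i s_i`` — the
    spectrum, and hence the fitness analysis, is identical to the symmetric
    model with the same diagonal.
    """
    n = params.n
    if len(ext.s) != n - 1:
        raise ValidationError([f"s must have length n-1={n - 1}, got {len(ext.s)}"])
    bad = [
        f"p[{i + 1}] + q[{i + 1}] + s[{i + 1}] = {params.p[i] + params.q[i] + ext.s[i]:.6g} != 1"
        for i in range(n - 1)
        if abs(params.p[i] + params.q[i] + ext.s[i] - 1.0) > 1e-12
    ]
    if bad:
        raise ValidationError(bad)
    a = np.zeros((n, n))
    r, p, q, s = map(np.asarray, (params.r, params.p, params.q, ext.s))
    a[np.arange(n - 1), np.arange(n - 1)] = r * (p - q)
    a[n - 1, n - 1] = -params.d
    a[np.arange(1, n), np.arange(n - 1)] = 2.0 * r * q + r * s
    return ProjectionMatrix(a, tag="resident_asym", params_hash=_hash(params, ext.s))


def dediff_direction(n: int, mode: "Mode | str", kappa: float) -> np.ndarray:
    """The constant direction matrix ``B = dA/d(rho)`` of a mutant family.

    Both mutant matrices are affine in ``rho``:
    ``A(rho) = A_resident + rho * B`` with ``B`` depending only on the mode
    and the redistributing factor ``kappa``.  This is the matrix contracted
    with the left/right eigenvectors in the perturbation formula for the
    selection gradient.
    """
    mode = Mode(mode)
    b = np.zeros((n, n))
    if mode is Mode.STEPWISE:
        b[np.arange(n - 2), np.arange(1, n - 1)] = 1.0
        b[np.arange(1, n - 1), np.arange(1, n - 1)] = -kappa
        b[np.arange(2, n), np.arange(1, n - 1)] = -(1.0 - kappa)
    else:
        b[0, n - 2] += 1.0
        b[n - 2, n - 2] = -kappa
        b[n - 1, n - 2] += -(1.0 - kappa)
    return b
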