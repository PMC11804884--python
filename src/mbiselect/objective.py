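"""GMM quadratic form, block-diagonal weighting and the SCAD penalty.

The stacked moment vector is overdetermined (more equations than
coefficients), so estimation minimizes the generalized-method-of-moments
quadratic form ``Q(b) = g(b)' C(b)^+ g(b)``, where ``C`` is the empirical
second-moment matrix of the subject-level scores, block-diagonal across
missing patterns (subjects from different patterns are independent).  ``C``
may be singular; the Moore–Penrose pseudoinverse is used throughout.

Each pattern's score dimension is of the same order as its subject count, so
the raw empirical second moment is badly conditioned (its smallest
eigenvalues are sampling artefacts whose pseudo-inversion would dominate the
quadratic form).  By default each block is therefore estimated with
Ledoit–Wolf shrinkage toward a scaled identity, with the data-driven
intensity; ``shrinkage="none"`` gives the raw second moment.

The penalized objective adds a SCAD term per coefficient:

    S(b) = Q(b) + sum_j p_lam(|b_j|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .scores import MomentProblem

__all__ = [
    "WeightMatrix",
    "ledoit_wolf_second_moment",
    "weight_matrix",
    "gmm_quadratic",
    "scad",
    "scad_deriv",
    "objective_value",
]

PINV_RTOL = 1e-10


@dataclass
class WeightMatrix:
    """Block-diagonal GMM weight: one PSD block per missing pattern."""

    blocks: list[np.ndarray]
    pinv_tol: float = PINV_RTOL
    _solvers: list | None = field(default=None, repr=False)

    def _factorize(self) -> list:
        """Cholesky solve per block where possible, else Moore–Penrose."""
        if self._solvers is None:
            solvers = []
            for b in self.blocks:
                try:
                    cf = scipy.linalg.cho_factor(b, check_finite=False)
                    piv = np.diag(cf[0])
                    # near-zero pivots mean the factorization is numerically
                    # meaningless even though it did not raise
                    if (piv.min() / piv.max()) ** 2 <= 1e3 * self.pinv_tol:
                        raise scipy.linalg.LinAlgError("near-singular block")
                    solvers.append(
                        lambda v, cf=cf: scipy.linalg.cho_solve(
                            cf, v, check_finite=False
                        )
                    )
                except (scipy.linalg.LinAlgError, ValueError):
                    cinv = np.linalg.pinv(b, rcond=self.pinv_tol, hermitian=True)
                    solvers.append(lambda v, cinv=cinv: cinv @ v)
            self._solvers = solvers
        return self._solvers

    def pinv_blocks(self) -> list[np.ndarray]:
        """Explicit ``C^+`` per block (Moore–Penrose)."""
        return [
            np.linalg.pinv(b, rcond=self.pinv_tol, hermitian=True)
            for b in self.blocks
        ]

    def apply_pinv(self, v: np.ndarray) -> np.ndarray:
        """``C^+ v`` for a stacked vector or matrix conforming to the blocks."""
        out = np.empty_like(v, dtype=float)
        off = 0
        for b, solve in zip(self.blocks, self._factorize()):
            d = b.shape[0]
            out[off : off + d] = solve(v[off : off + d])
            off += d
        return out

    @property
    def dim(self) -> int:
        return sum(b.shape[0] for b in self.blocks)


def weight_matrix(
    problem: MomentProblem,
    beta: np.ndarray,
    shrinkage: str = "ledoit-wolf",
) -> WeightMatrix:
    """Per-pattern second-moment blocks of the subject-level stacked scores.

    ``shrinkage="none"``: the raw empirical blocks
    ``(1/n_k) sum_i g_ki g_ki'``.  ``"ledoit-wolf"`` (default): each block
    shrunk toward a scaled identity with the Ledoit–Wolf intensity.
    """
    return _weight_from_scores(problem.subject_scores(beta), shrinkage)


def ledoit_wolf_second_moment(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Ledoit–Wolf-shrunk (uncentered) second moment of the rows of ``x``.

    Returns the shrunk matrix ``(1 - s) S + s mu I`` and the data-driven
    intensity ``s``, where ``S = x'x/n`` and ``mu = tr(S)/d``.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    emp = x.T @ x / n
    mu = np.trace(emp) / d
    delta = float(np.sum((emp - mu * np.eye(d)) ** 2)) / d
    if delta == 0.0:
        return emp, 0.0
    x2 = x**2
    beta_ = (float(np.sum(x2.T @ x2)) / n - float(np.sum(emp**2))) / (d * n)
    shrink = min(max(beta_, 0.0), delta) / delta
    return (1.0 - shrink) * emp + shrink * mu * np.eye(d), shrink


def _weight_from_scores(
    scores: list[np.ndarray], shrinkage: str = "ledoit-wolf"
) -> WeightMatrix:
    if shrinkage == "none":
        blocks = [s.T @ s / s.shape[0] for s in scores]
    elif shrinkage == "ledoit-wolf":
        blocks = [ledoit_wolf_second_moment(s)[0] for s in scores]
    else:
        raise ValueError(f"unknown shrinkage {shrinkage!r}")
    return WeightMatrix(blocks=blocks)


def gmm_quadratic(g: np.ndarray, c: WeightMatrix) -> float:
    """``g' C^+ g`` with the Moore–Penrose pseudoinverse; always >= 0."""
    q = float(g @ c.apply_pinv(g))
    return max(q, 0.0)


def scad(beta_j, lam: float, a: float = 3.7):
    """SCAD penalty value at magnitude(s) ``beta_j``.

    Linear (slope ``lam``) up to ``lam``, quadratically clipped on
    ``(lam, a*lam]``, constant ``lam^2 (a+1)/2`` beyond ``a*lam``.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if a <= 2:
        raise ValueError("SCAD shape constant must exceed 2")
    b = np.abs(np.asarray(beta_j, dtype=float))
    out = np.where(
        b <= lam,
        lam * b,
        np.where(
            b <= a * lam,
            (2 * a * lam * b - b**2 - lam**2) / (2 * (a - 1)),
            lam**2 * (a + 1) / 2,
        ),
    )
    return out if out.ndim else float(out)


def scad_deriv(beta_j, lam: float, a: float = 3.7):
    """Derivative of the SCAD penalty on magnitudes: ``lam`` near zero,
    ``(a*lam - |b|)/(a-1)`` in the clipped region, 0 beyond ``a*lam``."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if a <= 2:
        raise ValueError("SCAD shape constant must exceed 2")
    b = np.abs(np.asarray(beta_j, dtype=float))
    out = np.where(
        b <= lam,
        lam,
        np.maximum(a * lam - b, 0.0) / (a - 1),
    )
    return out if out.ndim else float(out)


def objective_value(
    problem: MomentProblem,
    beta: np.ndarray,
    lam: float,
    a: float = 3.7,
) -> float:
    """Penalized objective ``S(b) = Q(b) + sum_j p_lam(|b_j|)``.

    The weight ``C(b)`` is evaluated at the same ``b`` (continuously updated
    weighting).  Every coefficient is penalized; the simulation models carry
    no intercept.
    """
    g, scores = problem.moments(beta)
    q = gmm_quadratic(g, _weight_from_scores(scores))
    return q + float(np.sum(scad(beta, lam, a)))
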