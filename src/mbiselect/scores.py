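"""Extended-score moment conditions over imputed copies.

The estimating function follows the quadratic-inference-function idea: the
inverse working correlation is replaced by the span of fixed basis matrices
``M_1..M_J`` (identity plus an off-diagonal pattern), so the correlation
nuisance parameters never need to be estimated.  For subject ``i`` in pattern
``k`` with imputed copy ``r``, the extended score stacks, over ``j = 1..J``,

    D_r' A^{-1/2} M_j A^{-1/2} (y_i - mu_i^{(r)}),

where ``mu^{(r)}`` is the conditional mean evaluated on the imputed design,
``A`` is the diagonal variance function, and ``D_r`` is the derivative of
the mean restricted to the *score columns* of copy ``r``.  For the primary
copy (all observed sources used as imputation predictors) the score columns
are all observed columns of the pattern.  For a reduced copy that imputed
from a proper subset ``S`` of the observed sources, the score columns are
the columns of ``S`` only: the least-squares imputation residual is
orthogonal to the predictor sources, so those moments are mean-zero at the
truth, whereas scores against the non-predictor observed sources would
inherit the imputation's omitted-covariate bias.  Pattern averages of these
scores, concatenated over patterns and copies, form the stacked moment
vector ``g(b)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit

from .data_model import PanelData, PatternLayout, SourcePartition
from .imputation import ImputedSet

__all__ = [
    "CorrelationBasis",
    "LinkFunctions",
    "identity_link",
    "logit_link",
    "get_link",
    "basis_matrices",
    "subject_score",
    "MomentProblem",
    "MomentVector",
    "build_problem",
    "stack_moments",
    "moment_jacobian",
]

_ETA_CLIP = 30.0


@dataclass(frozen=True)
class CorrelationBasis:
    """Basis matrices spanning the inverse working correlation."""

    structure: str
    matrices: tuple[np.ndarray, ...]

    @property
    def J(self) -> int:
        return len(self.matrices)

    @property
    def m(self) -> int:
        return self.matrices[0].shape[0]


def basis_matrices(structure: str, m: int) -> CorrelationBasis:
    """Basis for the chosen working correlation at ``m`` occasions.

    independence: ``{I}``; exchangeable: ``{I, ones off-diagonal}``;
    ar1: ``{I, first off-diagonal}``.  For ``m = 1`` every structure
    collapses to ``{[1]}``.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    eye = np.eye(m)
    if structure == "independence" or m == 1:
        if structure not in ("independence", "exchangeable", "ar1"):
            raise ValueError(f"unknown correlation structure {structure!r}")
        return CorrelationBasis(structure, (eye,))
    if structure == "exchangeable":
        m2 = np.ones((m, m)) - eye
    elif structure == "ar1":
        m2 = np.diag(np.ones(m - 1), 1) + np.diag(np.ones(m - 1), -1)
    else:
        raise ValueError(f"unknown correlation structure {structure!r}")
    return CorrelationBasis(structure, (eye, m2))


@dataclass(frozen=True)
class LinkFunctions:
    """Mean, mean-derivative and variance function of a GLM link."""

    name: str
    mean: Callable[[np.ndarray], np.ndarray]
    deriv: Callable[[np.ndarray], np.ndarray]
    variance: Callable[[np.ndarray], np.ndarray]


def identity_link() -> LinkFunctions:
    return LinkFunctions(
        name="identity",
        mean=lambda eta: eta,
        deriv=lambda eta: np.ones_like(eta),
        variance=lambda mu: np.ones_like(mu),
    )


def logit_link() -> LinkFunctions:
    def mean(eta):
        return expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    def deriv(eta):
        mu = mean(eta)
        return mu * (1.0 - mu)

    return LinkFunctions(
        name="logit",
        mean=mean,
        deriv=deriv,
        variance=lambda mu: mu * (1.0 - mu),
    )


def get_link(name: str) -> LinkFunctions:
    if name == "identity":
        return identity_link()
    if name == "logit":
        return logit_link()
    raise ValueError(f"unknown link {name!r}")


def _pattern_scores(
    y: np.ndarray,
    x_obs: np.ndarray,
    x_imp: np.ndarray,
    beta: np.ndarray,
    basis: CorrelationBasis,
    link: LinkFunctions,
) -> np.ndarray:
    """Extended scores for one (pattern, copy): returns ``n x (J*q)``.

    ``x_obs`` is ``n x m x q`` (observed columns), ``x_imp`` ``n x m x p``
    (full imputed design).
    """
    eta = x_imp @ beta
    mu = link.mean(eta)
    mud = link.deriv(eta)
    ah = 1.0 / np.sqrt(np.maximum(link.variance(mu), 1e-12))
    resid_s = ah * (y - mu)  # A^{-1/2}(y - mu), n x m
    d_obs = x_obs * mud[:, :, None]  # n x m x q
    blocks = []
    for mj in basis.matrices:
        t = ah * np.einsum("st,nt->ns", mj, resid_s)
        blocks.append(np.einsum("ntq,nt->nq", d_obs, t))
    return np.concatenate(blocks, axis=1)


def _pattern_jacobian(
    x_obs: np.ndarray,
    x_imp: np.ndarray,
    beta: np.ndarray,
    basis: CorrelationBasis,
    link: LinkFunctions,
) -> np.ndarray:
    """Average score Jacobian for one (pattern, copy): ``(J*q) x p``.

    Main (Gauss–Newton) term only: the residual derivative through the
    imputed design.  Exact for the identity link; for the logit link the
    omitted curvature terms vanish at ``beta = 0``.
    """
    n = x_obs.shape[0]
    eta = x_imp @ beta
    mu = link.mean(eta)
    mud = link.deriv(eta)
    ah = 1.0 / np.sqrt(np.maximum(link.variance(mu), 1e-12))
    d_obs = x_obs * mud[:, :, None]
    z = ah[:, :, None] * (x_imp * mud[:, :, None])  # A^{-1/2} D_imp
    blocks = []
    for mj in basis.matrices:
        wz = ah[:, :, None] * np.einsum("st,ntp->nsp", mj, z)
        blocks.append(-np.einsum("ntq,ntp->qp", d_obs, wz) / n)
    return np.concatenate(blocks, axis=0)


def subject_score(
    y_i: np.ndarray,
    x_obs: np.ndarray,
    x_imp: np.ndarray,
    beta: np.ndarray,
    basis: CorrelationBasis,
    link: LinkFunctions,
) -> np.ndarray:
    """Extended score of a single subject (one imputed copy), length ``J*q``.

    ``x_obs`` is ``m x q`` (observed columns only), ``x_imp`` is ``m x p``.
    """
    return _pattern_scores(
        np.asarray(y_i, float)[None],
        np.asarray(x_obs, float)[None],
        np.asarray(x_imp, float)[None],
        np.asarray(beta, float),
        basis,
        link,
    )[0]


@dataclass
class MomentVector:
    """Stacked moment vector with its (pattern, copy, basis) block map."""

    g: np.ndarray
    block_index: dict[tuple[int, int, int], slice]


@dataclass
class MomentProblem:
    """Preassembled per-pattern data for fast repeated moment evaluation.

    Holds, per pattern and imputed copy: the responses, the score-column
    design, the imputed design, and the block bookkeeping of the stacked
    moment vector.  The subject-level stacked scores (one row per subject,
    columns running over copies then basis matrices) feed both ``g`` and the
    GMM weight.  ``score_cols[k][r]`` lists the covariate columns the copy's
    score projects on (all observed columns for a full-predictor copy, the
    predictor-source columns for a reduced copy).
    """

    y: list[np.ndarray]
    x_score: list[list[np.ndarray]]
    x_imp: list[list[np.ndarray]]
    score_cols: list[list[np.ndarray]]
    basis: CorrelationBasis
    link: LinkFunctions
    p: int
    n_total: int
    _jac_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return len(self.y)

    @property
    def n_k(self) -> tuple[int, ...]:
        return tuple(yk.shape[0] for yk in self.y)

    @property
    def r_counts(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.x_imp)

    def block_dims(self) -> list[int]:
        """Length of each pattern's segment of the stacked moment vector."""
        j = self.basis.J
        return [
            sum(len(cols) * j for cols in self.score_cols[k])
            for k in range(self.K)
        ]

    @property
    def dim(self) -> int:
        return sum(self.block_dims())

    def block_index(self) -> dict[tuple[int, int, int], slice]:
        """Map (pattern, copy r, basis j) — all 1-based — to a slice of g."""
        out: dict[tuple[int, int, int], slice] = {}
        off = 0
        for k in range(self.K):
            for r in range(self.r_counts[k]):
                q = len(self.score_cols[k][r])
                for j in range(self.basis.J):
                    out[(k + 1, r + 1, j + 1)] = slice(off, off + q)
                    off += q
        return out

    def subject_scores(self, beta: np.ndarray) -> list[np.ndarray]:
        """Per-pattern matrices of stacked subject scores, ``n_k x dim_k``."""
        beta = np.asarray(beta, float)
        out = []
        for k in range(self.K):
            parts = [
                _pattern_scores(
                    self.y[k],
                    self.x_score[k][r],
                    self.x_imp[k][r],
                    beta,
                    self.basis,
                    self.link,
                )
                for r in range(self.r_counts[k])
            ]
            out.append(np.concatenate(parts, axis=1))
        return out

    def moments(self, beta: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Stacked moment vector and the subject scores it averages."""
        scores = self.subject_scores(beta)
        g = np.concatenate([s.mean(axis=0) for s in scores])
        return g, scores

    def jacobian(self, beta: np.ndarray) -> np.ndarray:
        """Jacobian of the stacked moment vector, ``dim x p``.

        Constant in ``beta`` for the identity link, hence cached.
        """
        if self.link.name == "identity" and self._jac_cache is not None:
            return self._jac_cache
        beta = np.asarray(beta, float)
        blocks = [
            _pattern_jacobian(
                self.x_score[k][r],
                self.x_imp[k][r],
                beta,
                self.basis,
                self.link,
            )
            for k in range(self.K)
            for r in range(self.r_counts[k])
        ]
        jac = np.vstack(blocks)
        if self.link.name == "identity":
            self._jac_cache = jac
        return jac

    def mean_copies(self, beta: np.ndarray) -> list[list[np.ndarray]]:
        """Fitted means ``mu^{(r)}`` per pattern and copy (for RSS)."""
        beta = np.asarray(beta, float)
        return [
            [self.link.mean(xr @ beta) for xr in self.x_imp[k]]
            for k in range(self.K)
        ]


def build_problem(
    imputed: ImputedSet,
    panel: PanelData,
    partition: SourcePartition,
    layout: PatternLayout,
    basis: CorrelationBasis,
    link: LinkFunctions,
) -> MomentProblem:
    """Assemble the moment problem from a panel and its imputed copies.

    Score columns per copy: the pattern's observed columns for an identity
    or full-predictor copy, the predictor-source columns for a reduced copy
    (see module docstring for why).
    """
    y, x_score, x_imp, score_cols = [], [], [], []
    for k in range(layout.K):
        idx = imputed.index[k]
        if len(idx) == 0:
            raise ValueError(f"pattern {k + 1} has no subjects")
        y.append(panel.y[idx])
        x_imp.append(list(imputed.copies[k]))
        cols_k, xs_k = [], []
        for r, combo in enumerate(imputed.combos[k]):
            if combo.is_identity or combo.predictor_sources == layout.observed[k]:
                cols = partition.columns(sorted(layout.observed[k]))
            else:
                cols = partition.columns(sorted(combo.predictor_sources))
            cols_k.append(cols)
            xs_k.append(imputed.copies[k][r][:, :, cols])
        score_cols.append(cols_k)
        x_score.append(xs_k)
    return MomentProblem(
        y=y,
        x_score=x_score,
        x_imp=x_imp,
        score_cols=score_cols,
        basis=basis,
        link=link,
        p=panel.p,
        n_total=panel.n,
    )


def stack_moments(
    imputed: ImputedSet,
    panel: PanelData,
    partition: SourcePartition,
    layout: PatternLayout,
    beta: np.ndarray,
    basis: CorrelationBasis,
    link: LinkFunctions,
) -> MomentVector:
    """Stacked moment vector ``g(beta)`` with complete block bookkeeping."""
    problem = build_problem(imputed, panel, partition, layout, basis, link)
    g, _ = problem.moments(beta)
    return MomentVector(g=g, block_index=problem.block_index())


def moment_jacobian(
    imputed: ImputedSet,
    panel: PanelData,
    partition: SourcePartition,
    layout: PatternLayout,
    beta: np.ndarray,
    basis: CorrelationBasis,
    link: LinkFunctions,
) -> np.ndarray:
    """Analytic Jacobian of ``g`` with respect to the full coefficient vector."""
    problem = build_problem(imputed, panel, partition, layout, basis, link)
    return problem.jacobian(beta)
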