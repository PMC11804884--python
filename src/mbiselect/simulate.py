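"""Synthetic multi-source longitudinal data with block-wise missingness.

Three sources, three missing patterns (the canonical layout: source 1 always
observed, source 3 missing in pattern 2, source 2 missing in pattern 3) and
three occasions per subject.  Covariates: the first column is time-fixed
standard normal; the remaining columns are time-varying, drawn per occasion
from a mean-zero multivariate normal with exchangeable correlation 0.5 and
unit variance.  Outcomes: continuous ``y = X'b + e`` with exchangeable
within-subject errors (correlation ``rho``), or correlated binary through
``logit(pi) = X'b + e`` with exchangeable errors at correlation 0.3.

Pattern assignment is covariate-driven (missing at random): with
``phi_i = 1 / (1 + exp(1 + sum of selected baseline covariates))``, patterns
are filled sequentially by weighted sampling without replacement with
probability proportional to ``phi_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_model import PanelData, SourcePartition, detect_layout

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "gen_covariates",
    "gen_outcome",
    "assign_patterns",
    "scenario",
    "SCENARIOS",
]


@dataclass
class ScenarioSpec:
    """Full description of one simulation condition."""

    n_k: tuple[int, int, int]
    p: int
    sources: SourcePartition
    beta0: np.ndarray
    rho: float
    m: int = 3
    outcome: str = "continuous"
    cov_rho: float = 0.5
    phi_cols: tuple[int, ...] = ()  # 0-based baseline covariates driving phi
    binary_error_rho: float = 0.3

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        if len(self.beta0) != self.p:
            raise ValueError("beta0 length must equal p")
        if self.m > 1 and not (-1.0 / (self.m - 1) < self.rho < 1.0):
            raise ValueError("rho outside the exchangeable-validity range")
        if self.outcome not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def n(self) -> int:
        return int(sum(self.n_k))

    @property
    def true_support(self) -> np.ndarray:
        return np.where(self.beta0 != 0)[0]


@dataclass
class SimulatedDataset:
    """A generated panel plus the ground truth needed for scoring."""

    panel: PanelData
    partition: SourcePartition
    beta0: np.ndarray
    true_support: np.ndarray
    x_full: np.ndarray  # unmasked design, truth bookkeeping only
    assignment: np.ndarray  # pattern per subject, 0-based


def _exchangeable_chol(m: int, rho: float) -> np.ndarray:
    return np.linalg.cholesky((1.0 - rho) * np.eye(m) + rho * np.ones((m, m)))


def gen_covariates(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw the ``n x m x p`` covariate array (before masking).

    Column 1 is drawn once per subject and repeated across occasions; the
    other columns are drawn independently per occasion from the exchangeable
    multivariate normal.
    """
    n, m, p = spec.n, spec.m, spec.p
    x = np.empty((n, m, p))
    x[:, :, 0] = rng.standard_normal(n)[:, None]
    chol = _exchangeable_chol(p - 1, spec.cov_rho)
    z = rng.standard_normal((n, m, p - 1))
    x[:, :, 1:] = z @ chol.T
    return x


def gen_outcome(
    x: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Responses given the design: linear-Gaussian or logistic-Bernoulli."""
    n, m = x.shape[0], x.shape[1]
    eta = x @ spec.beta0
    if spec.outcome == "continuous":
        chol = _exchangeable_chol(m, spec.rho)
        eps = rng.standard_normal((n, m)) @ chol.T
        return eta + eps
    chol = _exchangeable_chol(m, spec.binary_error_rho)
    eps = rng.standard_normal((n, m)) @ chol.T
    pi = expit(eta + eps)
    return (rng.random((n, m)) < pi).astype(float)


def assign_patterns(
    x: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sequential weighted pattern assignment without replacement.

    ``phi_i = 1/(1 + exp(1 + sum of baseline phi-columns))``; the first
    ``n_1`` subjects are drawn with probability proportional to ``phi_i``
    into pattern 1, then ``n_2`` from the remainder into pattern 2, the rest
    forming pattern 3.  Implemented by Gumbel perturbation of ``log phi``
    (exponential-race weighted sampling).
    """
    n = x.shape[0]
    if sum(spec.n_k) != n:
        raise ValueError("pattern sizes do not sum to n")
    score = 1.0 + x[:, 0, list(spec.phi_cols)].sum(axis=1)
    log_phi = -np.logaddexp(0.0, score)  # log(1/(1+exp(score)))
    gumbel = rng.gumbel(size=n)
    order = np.argsort(-(log_phi + gumbel))
    assignment = np.empty(n, dtype=int)
    start = 0
    for k, nk in enumerate(spec.n_k):
        assignment[order[start : start + nk]] = k
        start += nk
    return assignment


def _mask(x: np.ndarray, assignment: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    """Blank the unobserved source per pattern: pattern 2 loses source 3,
    pattern 3 loses source 2 (source 1 is always observed)."""
    xm = x.copy()
    src = spec.sources.blocks
    xm[np.ix_(np.where(assignment == 1)[0], range(spec.m), src[2])] = np.nan
    xm[np.ix_(np.where(assignment == 2)[0], range(spec.m), src[1])] = np.nan
    return xm


def _beta_pattern(n_sources: int, block: int, lead: tuple[float, ...]) -> np.ndarray:
    """Per-source coefficient template: leading values then zeros, repeated."""
    one = np.zeros(block)
    one[: len(lead)] = lead
    return np.tile(one, n_sources)


def _spec_s1(rho: float, n_k=(40, 100, 100)) -> ScenarioSpec:
    return ScenarioSpec(
        n_k=tuple(n_k),
        p=30,
        sources=SourcePartition.equal_blocks(3, 10),
        beta0=_beta_pattern(3, 10, (1.0, 2.0)),
        rho=rho,
        phi_cols=tuple(range(10)),
    )


def _spec_s2(rho: float, n_k=(120, 300, 300)) -> ScenarioSpec:
    return _spec_s1(rho, n_k)


def _spec_s3(rho: float, n_k=(120, 300, 300)) -> ScenarioSpec:
    beta = np.zeros(15)
    beta[[0, 5, 10]] = (1.0, -0.7, 0.5)
    return ScenarioSpec(
        n_k=tuple(n_k),
        p=15,
        sources=SourcePartition.equal_blocks(3, 5),
        beta0=beta,
        rho=rho,
        outcome="binary",
        phi_cols=tuple(range(10, 15)),
    )


SCENARIOS = {"s1": _spec_s1, "s2": _spec_s2, "s3": _spec_s3}


def scenario(
    name: str,
    rho: float = 0.3,
    seed: int | np.random.Generator = 0,
    n_k: tuple[int, int, int] | None = None,
) -> SimulatedDataset:
    """Generate one replicate of a named scenario.

    ``s1``: continuous outcome, p=30 over three sources of 10, nonzero
    coefficients (1, 2) leading each source, pattern sizes (40, 100, 100).
    ``s2``: as s1 with pattern sizes (120, 300, 300).  ``s3``: correlated
    binary outcome, p=15 over three sources of 5, nonzero coefficients
    1, -0.7, 0.5 leading each source, pattern sizes (120, 300, 300).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    spec = SCENARIOS[name](rho) if n_k is None else SCENARIOS[name](rho, tuple(n_k))
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = gen_covariates(spec, rng)
    y = gen_outcome(x, spec, rng)
    assignment = assign_patterns(x, spec, rng)
    panel = PanelData(
        y=y,
        x=_mask(x, assignment, spec),
        subject_id=np.arange(1, spec.n + 1),
    )
    detect_layout(panel, spec.sources)
    return SimulatedDataset(
        panel=panel,
        partition=spec.sources,
        beta0=spec.beta0,
        true_support=spec.true_support,
        x_full=x,
        assignment=assignment,
    )
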