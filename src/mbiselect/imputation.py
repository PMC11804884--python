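"""Multiple block-wise imputation of missing covariate sources.

Each incomplete pattern ``k`` is imputed several times.  One imputation is
defined by a *combo*: a predictor source set ``S ⊆ O(k)`` together with the
donor patterns ``D = {k' : S ∪ M(k) ⊆ O(k')}`` that observe both the
predictors and the target sources.  Training on different donor/predictor
combinations yields distinct imputed copies ``X^(r)``, whose multiplicity is
what "multiple" refers to here — the imputer itself is a deterministic
per-occasion, per-column least-squares regression, so no between-imputation
randomness is introduced.

Candidate predictor sets are pruned by a domination rule: ``S`` is dropped
when a strict superset ``S'`` has at least the same donors, since ``S'`` then
uses strictly more predictor information from exactly the same (or more)
training subjects.  For the canonical three-source layout this reproduces the
two imputation routes per incomplete pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data_model import PanelData, PatternLayout, SourcePartition

__all__ = [
    "ImputationCombo",
    "Imputer",
    "ImputedSet",
    "enumerate_combos",
    "single_imputation_combos",
    "fit_imputer",
    "impute_all",
]

logger = logging.getLogger(__name__)

_RIDGE_FALLBACK = 1e-3
_TIME_FIXED_TOL = 1e-12


@dataclass(frozen=True)
class ImputationCombo:
    """One imputation route for a pattern: predictors ``S`` and donors ``D``."""

    target_pattern: int
    predictor_sources: frozenset
    donor_patterns: frozenset
    r_index: int

    @property
    def is_identity(self) -> bool:
        return not self.donor_patterns and not self.predictor_sources


def _identity_combo(k: int) -> ImputationCombo:
    return ImputationCombo(
        target_pattern=k,
        predictor_sources=frozenset(),
        donor_patterns=frozenset(),
        r_index=1,
    )


def _donors(layout: PatternLayout, needed: frozenset) -> frozenset:
    return frozenset(
        kk for kk, o in enumerate(layout.observed) if needed <= o
    )


def enumerate_combos(layout: PatternLayout) -> dict[int, list[ImputationCombo]]:
    """All non-dominated imputation combos, keyed by target pattern.

    For a fully observed pattern the single identity combo is returned.  For
    an incomplete pattern, every nonempty ``S ⊆ O(k)`` with a nonempty donor
    set is a candidate; dominated candidates are removed and survivors are
    indexed ``r = 1..R_k``, ordered by ``|S|`` descending then lexicographic.
    """
    out: dict[int, list[ImputationCombo]] = {}
    for k in range(layout.K):
        if not layout.missing[k]:
            out[k] = [_identity_combo(k)]
            continue
        obs = sorted(layout.observed[k])
        cands: list[tuple[frozenset, frozenset]] = []
        for size in range(len(obs), 0, -1):
            for subset in combinations(obs, size):
                s = frozenset(subset)
                d = _donors(layout, s | layout.missing[k])
                if d:
                    cands.append((s, d))
        if not cands:
            raise ValueError(
                f"pattern {k + 1} unimputable: no pattern observes its missing "
                "sources together with any of its observed sources"
            )
        survivors = [
            (s, d)
            for s, d in cands
            if not any(s2 > s and d2 >= d for s2, d2 in cands)
        ]
        survivors.sort(key=lambda sd: (-len(sd[0]), tuple(sorted(sd[0]))))
        out[k] = [
            ImputationCombo(k, s, d, r + 1) for r, (s, d) in enumerate(survivors)
        ]
    return out


def single_imputation_combos(
    layout: PatternLayout,
) -> dict[int, list[ImputationCombo]]:
    """The single-imputation restriction: complete-case donors only.

    Each incomplete pattern gets exactly one combo with all its observed
    sources as predictors and the complete pattern as sole donor — the
    classical "train on complete cases" imputation.
    """
    cc = layout.complete_pattern()
    out: dict[int, list[ImputationCombo]] = {}
    for k in range(layout.K):
        if not layout.missing[k]:
            out[k] = [_identity_combo(k)]
        else:
            out[k] = [
                ImputationCombo(
                    target_pattern=k,
                    predictor_sources=frozenset(layout.observed[k]),
                    donor_patterns=frozenset({cc}),
                    r_index=1,
                )
            ]
    return out


@dataclass
class Imputer:
    """Fitted least-squares imputation models for one combo.

    ``coef[(occ, col)]`` holds ``(intercept, slope vector over predictor
    columns)`` for occasion ``occ`` (or ``occ = -1`` for a time-fixed target
    column, fitted at the first occasion and broadcast).
    """

    combo: ImputationCombo
    predictor_cols: np.ndarray
    target_cols: np.ndarray
    coef: dict[tuple[int, int], tuple[float, np.ndarray]]
    m: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Imputed values for recipients; ``x`` is ``n x m x p`` observed data."""
        n = x.shape[0]
        out = np.empty((n, self.m, len(self.target_cols)))
        for tj, col in enumerate(self.target_cols):
            if (-1, col) in self.coef:
                b0, b = self.coef[(-1, col)]
                pred = b0 + x[:, 0, self.predictor_cols] @ b
                out[:, :, tj] = pred[:, None]
            else:
                for occ in range(self.m):
                    b0, b = self.coef[(occ, col)]
                    out[:, occ, tj] = b0 + x[:, occ, self.predictor_cols] @ b
        return out


def _solve_ols(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares fit of target t on design z with intercept.

    Falls back to a lightly ridged solve when the donor rows cannot support
    an ordinary fit.
    """
    design = np.column_stack([np.ones(len(z)), z])
    if len(z) < z.shape[1] + 2:
        logger.info(
            "imputation fallback: %d donor rows for %d predictors, using ridge",
            len(z),
            z.shape[1],
        )
        gram = design.T @ design
        gram[1:, 1:] += _RIDGE_FALLBACK * np.eye(z.shape[1])
        beta = np.linalg.solve(gram, design.T @ t)
    else:
        beta, *_ = np.linalg.lstsq(design, t, rcond=None)
    return float(beta[0]), beta[1:]


def fit_imputer(
    panel: PanelData,
    partition: SourcePartition,
    layout: PatternLayout,
    combo: ImputationCombo,
) -> Imputer:
    """Train the per-occasion OLS imputer for one combo.

    Donor subjects (patterns in ``D``) observe both the predictor sources and
    the target sources; each missing covariate column is regressed, occasion
    by occasion, on all predictor-source columns at the same occasion.
    Columns that are constant across occasions among donors (time-fixed
    covariates) are fitted once at the first occasion and broadcast.
    """
    if combo.is_identity:
        raise ValueError("identity combo has nothing to fit")
    if panel.pattern_id is None:
        raise ValueError("panel has no pattern labels; run detect_layout first")
    pred_cols = partition.columns(sorted(combo.predictor_sources))
    targ_cols = partition.columns(sorted(layout.missing[combo.target_pattern]))
    donor_mask = np.isin(panel.pattern_id, list(combo.donor_patterns))
    if not donor_mask.any():
        raise ValueError(f"combo {combo} has no donor subjects")
    xd = panel.x[donor_mask]
    coef: dict[tuple[int, int], tuple[float, np.ndarray]] = {}
    for col in targ_cols:
        tvals = xd[:, :, col]
        time_fixed = np.ptp(tvals, axis=1).max() <= _TIME_FIXED_TOL
        occasions = [-1] if time_fixed else range(panel.m)
        for occ in occasions:
            j = 0 if occ == -1 else occ
            coef[(occ, col)] = _solve_ols(xd[:, j, pred_cols], tvals[:, j])
    return Imputer(
        combo=combo,
        predictor_cols=pred_cols,
        target_cols=targ_cols,
        coef=coef,
        m=panel.m,
    )


@dataclass
class ImputedSet:
    """All imputed covariate copies, grouped by pattern.

    ``copies[k][r]`` is the ``n_k x m x p`` design for pattern ``k`` under
    combo ``r`` (missing columns filled, observed columns untouched);
    ``index[k]`` maps rows back to subject positions in the source panel.
    """

    copies: dict[int, list[np.ndarray]]
    index: dict[int, np.ndarray]
    combos: dict[int, list[ImputationCombo]]

    def r_counts(self) -> tuple[int, ...]:
        return tuple(len(self.copies[k]) for k in sorted(self.copies))


def impute_all(
    panel: PanelData,
    partition: SourcePartition,
    layout: PatternLayout,
    combos: dict[int, list[ImputationCombo]],
) -> ImputedSet:
    """Execute every combo, producing the full set of imputed design copies."""
    copies: dict[int, list[np.ndarray]] = {}
    index: dict[int, np.ndarray] = {}
    for k in range(layout.K):
        idx = np.where(panel.pattern_id == k)[0]
        index[k] = idx
        copies[k] = []
        for combo in combos[k]:
            xk = panel.x[idx].copy()
            if not combo.is_identity:
                try:
                    imputer = fit_imputer(panel, partition, layout, combo)
                except Exception as exc:  # re-raise with provenance
                    raise RuntimeError(
                        f"imputation failed for pattern {k + 1}, combo "
                        f"r={combo.r_index} (S={sorted(combo.predictor_sources)}, "
                        f"D={sorted(combo.donor_patterns)}): {exc}"
                    ) from exc
                xk[:, :, imputer.target_cols] = imputer.predict(panel.x[idx])
            if np.isnan(xk).any():
                raise RuntimeError(
                    f"pattern {k + 1} combo r={combo.r_index} left NaNs behind"
                )
            copies[k].append(xk)
    return ImputedSet(copies=copies, index=index, combos=combos)
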