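"""Containers for multi-source longitudinal data with block-wise missingness.

A *source* is a group of covariate columns that are jointly observed or
jointly missing for any given subject (e.g. MRI, PET and CSF panels merged
into one design matrix).  Subjects sharing the same set of observed sources
form a *missing pattern*; with a handful of sources there are only a few
patterns, each with its observed/missing source index sets ``O(k)``/``M(k)``.

The population-level model is a marginal GLM ``E[Y_ij | X_ij] = mu(X_ij' b)``
with a known monotone link ``mu`` and balanced panels (every subject has the
same number of measurement occasions ``m``).  Missingness of covariate blocks
is assumed (completely) at random; the response is always observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SourcePartition",
    "PatternLayout",
    "PanelData",
    "ModelSpec",
    "detect_layout",
    "read_panel",
    "write_panel",
    "complete_case_missing_rate",
]


class BlockStructureError(ValueError):
    """Raised when the NA structure of a subject violates block-wise missingness."""


@dataclass(frozen=True)
class SourcePartition:
    """Disjoint partition of the covariate columns ``{0..p-1}`` into sources.

    Columns are 0-based internally; user-facing reports are 1-based, matching
    the conventional ``x1..xp`` naming.
    """

    blocks: tuple[tuple[int, ...], ...]

    def __init__(self, blocks: Sequence[Sequence[int]]):
        object.__setattr__(
            self, "blocks", tuple(tuple(int(c) for c in b) for b in blocks)
        )
        self._validate()

    def _validate(self) -> None:
        if not self.blocks:
            raise ValueError("partition needs at least one source block")
        seen: set[int] = set()
        for b in self.blocks:
            if not b:
                raise ValueError("source blocks must be nonempty")
            if seen & set(b):
                raise ValueError("source blocks must be disjoint")
            seen |= set(b)
        if seen != set(range(len(seen))):
            raise ValueError("source blocks must cover columns 0..p-1 exactly")

    @property
    def n_sources(self) -> int:
        return len(self.blocks)

    @property
    def p(self) -> int:
        return sum(len(b) for b in self.blocks)

    def columns(self, sources: Sequence[int]) -> np.ndarray:
        """Sorted covariate columns belonging to the given source indices."""
        cols: list[int] = []
        for s in sources:
            cols.extend(self.blocks[s])
        return np.array(sorted(cols), dtype=int)

    def source_of(self, column: int) -> int:
        for s, b in enumerate(self.blocks):
            if column in b:
                return s
        raise KeyError(column)

    @classmethod
    def equal_blocks(cls, n_sources: int, block_size: int) -> "SourcePartition":
        """Partition of ``n_sources * block_size`` columns into equal blocks."""
        return cls(
            [
                range(s * block_size, (s + 1) * block_size)
                for s in range(n_sources)
            ]
        )


@dataclass(frozen=True)
class PatternLayout:
    """The missing patterns of a dataset at source granularity.

    ``observed[k]`` / ``missing[k]`` are the source index sets ``O(k)`` and
    ``M(k)``; ``n_k[k]`` counts the subjects in pattern ``k``.  Patterns are
    ordered by descending ``|O(k)|`` then descending ``n_k``, so pattern 0 is
    the complete-case pattern whenever one exists.
    """

    n_sources: int
    observed: tuple[frozenset, ...]
    missing: tuple[frozenset, ...]
    n_k: tuple[int, ...]

    def __post_init__(self) -> None:
        all_sources = frozenset(range(self.n_sources))
        for o, m_ in zip(self.observed, self.missing):
            if o | m_ != all_sources or o & m_:
                raise ValueError("O(k) and M(k) must partition the sources")
            if not o:
                raise ValueError("every pattern must observe at least one source")
        if not any(not m_ for m_ in self.missing):
            warnings.warn(
                "no fully observed pattern: complete-case and single-imputation "
                "baselines are unavailable",
                stacklevel=3,
            )

    @property
    def K(self) -> int:
        return len(self.observed)

    @property
    def n(self) -> int:
        return sum(self.n_k)

    def complete_pattern(self) -> int:
        """Index of the fully observed pattern, or raise if none exists."""
        for k, m_ in enumerate(self.missing):
            if not m_:
                return k
        raise ValueError("layout has no fully observed pattern")


@dataclass
class PanelData:
    """Balanced long-format panel: responses, covariates and pattern labels.

    ``y`` is ``n x m``; ``x`` is ``n x m x p`` with ``NaN`` where a covariate
    is unobserved.  Within a subject the NaN columns are constant across
    occasions and always comprise whole source blocks.
    """

    y: np.ndarray
    x: np.ndarray
    subject_id: np.ndarray
    pattern_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y.ndim != 2 or self.x.ndim != 3:
            raise ValueError("y must be n x m and x must be n x m x p")
        if self.x.shape[:2] != self.y.shape:
            raise ValueError("x and y disagree on n or m")
        if np.isnan(self.y).any():
            raise ValueError("responses must be fully observed")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def m(self) -> int:
        return self.y.shape[1]

    @property
    def p(self) -> int:
        return self.x.shape[2]

    def subset(self, idx: np.ndarray) -> "PanelData":
        return PanelData(
            y=self.y[idx],
            x=self.x[idx],
            subject_id=self.subject_id[idx],
            pattern_id=None if self.pattern_id is None else self.pattern_id[idx],
        )


@dataclass
class ModelSpec:
    """Modelling choices: link, working correlation, penalty and tuning knobs.

    ``scad_a`` is the SCAD shape constant (must exceed 2; 3.7 is the usual
    convention).  ``zero_threshold`` is the magnitude below which a fitted
    coefficient is reported as exactly zero (selection rule).  ``ebic_gamma``
    is the extended-BIC weight on the ``log p`` model-size term.
    """

    link: str = "identity"
    correlation: str = "exchangeable"
    scad_a: float = 3.7
    zero_threshold: float = 0.01
    ebic_gamma: float = 0.5
    penalty_exclude: tuple = ()  # 0-based columns left unpenalized

    def __post_init__(self) -> None:
        self.penalty_exclude = tuple(int(j) for j in self.penalty_exclude)
        if self.link not in ("identity", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.correlation not in ("independence", "exchangeable", "ar1"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.scad_a <= 2:
            raise ValueError("SCAD shape constant must exceed 2")
        if self.zero_threshold <= 0:
            raise ValueError("zero_threshold must be positive")
        if not 0 <= self.ebic_gamma <= 1:
            raise ValueError("ebic_gamma must lie in [0, 1]")


def _subject_na_sources(
    x_i: np.ndarray, partition: SourcePartition, subject: object
) -> frozenset:
    """Missing-source set of one subject; validates block-constant NA structure."""
    na = np.isnan(x_i)  # m x p
    col_any = na.any(axis=0)
    col_all = na.all(axis=0)
    if not np.array_equal(col_any, col_all):
        bad = np.where(col_any & ~col_all)[0]
        raise BlockStructureError(
            f"subject {subject!r}: covariate column {bad[0] + 1} is missing at "
            "some occasions but not all (missing patterns must be constant "
            "across measurements)"
        )
    na_cols = set(np.where(col_all)[0])
    missing_sources = set()
    for s, block in enumerate(partition.blocks):
        inside = na_cols & set(block)
        if inside and inside != set(block):
            raise BlockStructureError(
                f"subject {subject!r}: source {s + 1} is partially missing "
                "(block-wise missingness requires whole sources)"
            )
        if inside:
            missing_sources.add(s)
    if len(missing_sources) == partition.n_sources:
        raise BlockStructureError(f"subject {subject!r} observes no source at all")
    return frozenset(missing_sources)


def detect_layout(panel: PanelData, partition: SourcePartition) -> PatternLayout:
    """Group subjects into missing patterns and label ``panel.pattern_id``.

    Patterns are sorted by descending number of observed sources, then by
    descending pattern size (ties broken by the sorted observed set), so the
    result is invariant to subject order.  Subjects whose NaN columns are not
    a union of whole source blocks raise :class:`BlockStructureError`.
    """
    if partition.p != panel.p:
        raise ValueError("partition covers a different number of covariates")
    miss = [
        _subject_na_sources(panel.x[i], partition, panel.subject_id[i])
        for i in range(panel.n)
    ]
    groups: dict[frozenset, list[int]] = {}
    for i, m_ in enumerate(miss):
        groups.setdefault(m_, []).append(i)
    all_sources = frozenset(range(partition.n_sources))
    ordered = sorted(
        groups.items(),
        key=lambda kv: (
            -(partition.n_sources - len(kv[0])),
            -len(kv[1]),
            tuple(sorted(all_sources - kv[0])),
        ),
    )
    layout = PatternLayout(
        n_sources=partition.n_sources,
        observed=tuple(all_sources - m_ for m_, _ in ordered),
        missing=tuple(m_ for m_, _ in ordered),
        n_k=tuple(len(idx) for _, idx in ordered),
    )
    pattern_id = np.empty(panel.n, dtype=int)
    for k, (_, idx) in enumerate(ordered):
        pattern_id[idx] = k
    panel.pattern_id = pattern_id
    return layout


_DEFAULT_SCHEMA = {"subject": "subject", "occasion": "occasion", "y": "y"}


def read_panel(
    path,
    schema: dict | None = None,
    na_values: Sequence[str] = ("", "NA"),
) -> PanelData:
    """Read a long-format CSV (one row per subject-occasion) into a panel.

    Expected columns: ``subject, occasion, y, x1..xp`` (renameable through
    ``schema``).  Occasions are sorted within subject; panels must be
    balanced (equal ``m``) and free of duplicate (subject, occasion) rows.
    """
    names = dict(_DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=False)
    for key in ("subject", "occasion", "y"):
        if names[key] not in df.columns:
            raise ValueError(f"missing required column {names[key]!r}")
    xcols = [c for c in df.columns if c not in names.values()]
    if not xcols:
        raise ValueError("no covariate columns found")
    if df.duplicated([names["subject"], names["occasion"]]).any():
        raise ValueError("duplicate (subject, occasion) rows")
    if df[names["y"]].isna().any():
        raise ValueError("missing responses are not supported")
    df = df.sort_values([names["occasion"]], kind="stable")
    subjects = pd.unique(df[names["subject"]])
    counts = df[names["subject"]].value_counts()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced panel: all subjects must share the same number of "
            "occasions"
        )
    m = int(counts.iloc[0])
    n, p = len(subjects), len(xcols)
    y = np.empty((n, m))
    x = np.empty((n, m, p))
    pos = {s: i for i, s in enumerate(subjects)}
    grouped = df.groupby(names["subject"], sort=False)
    for s, g in grouped:
        i = pos[s]
        y[i] = g[names["y"]].to_numpy(dtype=float)
        x[i] = g[xcols].to_numpy(dtype=float)
    return PanelData(y=y, x=x, subject_id=np.asarray(subjects))


def write_panel(panel: PanelData, path, float_format: str | None = None) -> None:
    """Write a panel back to the long CSV dialect used by :func:`read_panel`."""
    n, m, p = panel.n, panel.m, panel.p
    rows = {
        "subject": np.repeat(panel.subject_id, m),
        "occasion": np.tile(np.arange(1, m + 1), n),
        "y": panel.y.reshape(-1),
    }
    flat = panel.x.reshape(n * m, p)
    for j in range(p):
        rows[f"x{j + 1}"] = flat[:, j]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=float_format)


def complete_case_missing_rate(n_k: Sequence[int], complete: int = 0) -> float:
    """Fraction of subjects that are *not* complete cases.

    With pattern counts ``n_k`` and the complete pattern at index ``complete``,
    returns ``1 - n_complete / n`` — the headline "missing rate" of a
    block-wise missing study.
    """
    n_k = np.asarray(n_k, dtype=float)
    return float(1.0 - n_k[complete] / n_k.sum())
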