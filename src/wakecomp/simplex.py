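"""Aitchison-simplex primitives for wake-time movement compositions.

A day's waking time splits exhaustively into sedentary behavior (SB), light
physical activity (LPA) and moderate-to-vigorous physical activity (MVPA).
Those three durations carry only *relative* information: once the wake window
is fixed, increasing one behavior necessarily decreases the others.  This
module provides the compositional geometry needed to analyse such data with
ordinary linear models:

* closure of a part vector to a constant total (``kappa``, e.g. 724 min or 1),
* sequential binary partitions (SBPs) and the orthonormal isometric log-ratio
  (ilr) bases they induce,
* forward/inverse ilr maps, compositional (geometric) means, centered
  log-ratio differences between group and overall means, and
* exact minute-for-minute reallocation between two behaviors (the primitive
  underlying isotemporal substitution).

The canonical three-part basis puts SB in the first pivot coordinate::

    ilr1 = sqrt(2/3) * ln( SB / sqrt(LPA * MVPA) )
    ilr2 = sqrt(1/2) * ln( LPA / MVPA )

Rotated bases (LPA or MVPA as pivot) are generated programmatically, never
hand-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_LABELS: tuple[str, ...] = ("SB", "LPA", "MVPA")

__all__ = [
    "DEFAULT_LABELS",
    "Composition",
    "CompositionError",
    "DegenerateCompositionError",
    "InfeasibleReallocationError",
    "SequentialBinaryPartition",
    "ZeroReport",
    "IlrTransformer",
    "check_zeros",
    "close",
    "compositional_mean",
    "ilr_forward",
    "ilr_inverse",
    "logratio_diff",
    "make_default_sbp",
    "make_pivot_sbp",
    "multiplicative_replacement",
    "reallocate",
]


class CompositionError(ValueError):
    """A compositional-domain violation (negative part, label mismatch...)."""


class DegenerateCompositionError(CompositionError):
    """All parts zero: no relative information to close."""


class InfeasibleReallocationError(CompositionError):
    """A requested time reallocation would exhaust (or exceed) a part."""


@dataclass(frozen=True)
class Composition:
    """An ordered vector of nonnegative parts summing to ``kappa``.

    Parameters
    ----------
    parts
        Part values (minutes or proportions), one per behavior.
    labels
        Unique behavior names, same length as ``parts``.
    kappa
        Closure constant; ``sum(parts) == kappa`` within 1e-9 relative
        tolerance.
    """

    parts: np.ndarray
    labels: tuple[str, ...] = DEFAULT_LABELS
    kappa: float = 1.0

    def __post_init__(self) -> None:
        parts = np.asarray(self.parts, dtype=float)
        object.__setattr__(self, "parts", parts)
        object.__setattr__(self, "labels", tuple(self.labels))
        if parts.ndim != 1:
            raise CompositionError("parts must be a 1-d vector")
        if len(self.labels) != parts.size:
            raise CompositionError("labels and parts length differ")
        if len(set(self.labels)) != len(self.labels):
            raise CompositionError("labels must be unique")
        if np.any(parts < 0):
            raise CompositionError("negative part in composition")
        if self.kappa <= 0:
            raise CompositionError("kappa must be positive")
        total = parts.sum()
        if not np.isclose(total, self.kappa, rtol=1e-9, atol=0.0):
            raise CompositionError(
                f"parts sum to {total!r}, not kappa={self.kappa!r}"
            )

    @property
    def D(self) -> int:
        return self.parts.size

    def proportions(self) -> "Composition":
        """The same composition closed to 1."""
        return close(self.parts, 1.0, self.labels)

    def reclose(self, kappa: float) -> "Composition":
        return close(self.parts, kappa, self.labels)

    def part(self, label: str) -> float:
        return float(self.parts[self.labels.index(label)])

    def __iter__(self):
        return iter(self.parts)


def close(
    parts: Sequence[float] | np.ndarray,
    kappa: float = 1.0,
    labels: Sequence[str] | None = None,
) -> Composition:
    """Rescale nonnegative parts proportionally so they sum to ``kappa``.

    Raises
    ------
    DegenerateCompositionError
        If every part is zero.
    CompositionError
        If any part is negative or ``kappa <= 0``.
    """
    p = np.asarray(parts, dtype=float)
    if np.any(p < 0):
        raise CompositionError("negative part passed to close()")
    if kappa <= 0:
        raise CompositionError("kappa must be positive")
    total = p.sum()
    if total == 0:
        raise DegenerateCompositionError("all parts are zero")
    if labels is None:
        labels = DEFAULT_LABELS if p.size == 3 else tuple(f"x{i+1}" for i in range(p.size))
    return Composition(p * (kappa / total), tuple(labels), float(kappa))


@dataclass(frozen=True)
class ZeroReport:
    """Location of zero cells in a table of parts; empty iff ilr computable."""

    entries: tuple[tuple[int, str], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __bool__(self) -> bool:  # truthy when zeros exist
        return bool(self.entries)


def check_zeros(table, labels: Sequence[str] | None = None) -> ZeroReport:
    """Report every (row, part-label) cell equal to zero.

    ``table`` is any rectangular array-like (or DataFrame, whose columns
    supply the labels). Negative cells are a domain error.
    """
    if hasattr(table, "columns"):  # pandas DataFrame
        if labels is None:
            labels = tuple(map(str, table.columns))
        values = np.asarray(table, dtype=float)
    else:
        values = np.atleast_2d(np.asarray(table, dtype=float))
        if labels is None:
            labels = (
                DEFAULT_LABELS
                if values.shape[1] == 3
                else tuple(f"x{i+1}" for i in range(values.shape[1]))
            )
    if np.any(values < 0):
        raise CompositionError("negative value in parts table")
    rows, cols = np.nonzero(values == 0)
    return ZeroReport(tuple((int(r), str(labels[c])) for r, c in zip(rows, cols)))


def _contrast_from_signs(signs: np.ndarray) -> np.ndarray:
    """Orthonormal log-contrast (balance) matrix for an SBP sign matrix."""
    signs = np.asarray(signs, dtype=float)
    V = np.zeros_like(signs)
    for i, row in enumerate(signs):
        r = float(np.sum(row > 0))
        s = float(np.sum(row < 0))
        coef = np.sqrt(r * s / (r + s))
        V[i, row > 0] = coef / r
        V[i, row < 0] = -coef / s
    return V


@dataclass(frozen=True)
class SequentialBinaryPartition:
    """A recursive split of parts defining an orthonormal ilr basis.

    ``sign_matrix`` has shape (D-1, D) with entries in {+1, -1, 0}: row ``i``
    splits the parts still in play into a numerator (+1) and denominator (-1)
    group; parts already isolated are 0.  The derived ``contrast_matrix`` V
    satisfies ``V @ V.T == I`` and ``ilr(x) = V @ ln(x)``.
    """

    sign_matrix: np.ndarray
    labels: tuple[str, ...] = DEFAULT_LABELS
    contrast_matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.sign_matrix, dtype=float)
        object.__setattr__(self, "sign_matrix", S)
        object.__setattr__(self, "labels", tuple(self.labels))
        if S.ndim != 2 or S.shape[0] != S.shape[1] - 1:
            raise CompositionError("sign matrix must be (D-1) x D")
        if S.shape[1] != len(self.labels):
            raise CompositionError("labels length must equal D")
        if not np.all(np.isin(S, (-1.0, 0.0, 1.0))):
            raise CompositionError("sign matrix entries must be in {+1,-1,0}")
        isolated: set[int] = set()
        for i, row in enumerate(S):
            if not (np.any(row > 0) and np.any(row < 0)):
                raise CompositionError(f"row {i} lacks a +1 or a -1")
            if any(row[j] != 0 for j in isolated):
                raise CompositionError(
                    f"row {i} reuses a part isolated by an earlier row"
                )
            pos = np.flatnonzero(row > 0)
            neg = np.flatnonzero(row < 0)
            if pos.size == 1:
                isolated.add(int(pos[0]))
            if neg.size == 1:
                isolated.add(int(neg[0]))
        V = _contrast_from_signs(S)
        if not np.allclose(V @ V.T, np.eye(S.shape[0]), atol=1e-12):
            raise CompositionError("sign matrix is not a valid SBP (non-orthonormal)")
        object.__setattr__(self, "contrast_matrix", V)

    @property
    def D(self) -> int:
        return self.sign_matrix.shape[1]


def make_default_sbp(labels: Sequence[str] = DEFAULT_LABELS) -> SequentialBinaryPartition:
    """The canonical 3-part SBP: first label vs. the rest, then the rest split.

    Row 1 is (+1, -1, -1) and row 2 is (0, +1, -1), so with labels
    (SB, LPA, MVPA) the first coordinate is sedentary time against the
    geometric mean of the two activity intensities.
    """
    labels = tuple(labels)
    if len(labels) != 3:
        raise CompositionError("the default SBP constructor is for exactly 3 parts")
    signs = np.array([[1, -1, -1], [0, 1, -1]], dtype=float)
    return SequentialBinaryPartition(signs, labels)


def make_pivot_sbp(
    labels: Sequence[str], pivot: str
) -> SequentialBinaryPartition:
    """Rotated 3-part basis whose first coordinate isolates ``pivot``.

    The remaining two parts keep their original relative order in the second
    coordinate's (+1, -1) split.
    """
    labels = tuple(labels)
    if pivot not in labels:
        raise CompositionError(f"pivot {pivot!r} not among labels {labels}")
    order = [pivot] + [lab for lab in labels if lab != pivot]
    base = make_default_sbp(tuple(order))
    # re-express over the original column order
    perm = [order.index(lab) for lab in labels]
    signs = base.sign_matrix[:, perm]
    return SequentialBinaryPartition(signs, labels)


def _as_parts(c, labels=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(c, Composition):
        return c.parts, c.labels
    p = np.asarray(c, dtype=float)
    if labels is None:
        labels = DEFAULT_LABELS if p.shape[-1] == 3 else tuple(
            f"x{i+1}" for i in range(p.shape[-1])
        )
    return p, tuple(labels)


def ilr_forward(c, basis: SequentialBinaryPartition | None = None) -> np.ndarray:
    """Map a composition (or row-wise array of them) to ilr coordinates.

    Scale invariant: the result does not depend on the closure constant.
    Any zero or negative part is a domain error naming the offending part.
    """
    parts, labels = _as_parts(c)
    if basis is None:
        basis = make_default_sbp(labels)
    arr = np.atleast_2d(parts)
    if arr.shape[-1] != basis.D:
        raise CompositionError("composition length does not match basis")
    bad = np.nonzero(arr <= 0)
    if bad[0].size:
        lab = basis.labels[int(bad[1][0])]
        raise CompositionError(f"non-positive part {lab!r}: ilr undefined")
    z = np.log(arr) @ basis.contrast_matrix.T
    return z[0] if np.ndim(parts) == 1 else z


def ilr_inverse(
    z,
    basis: SequentialBinaryPartition | None = None,
    kappa: float = 1.0,
    labels: Sequence[str] | None = None,
):
    """Invert ilr coordinates back to a composition closed to ``kappa``.

    For 1-d input returns a :class:`Composition`; for a 2-d array of
    coordinate rows returns the closed parts as an array.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise CompositionError("non-finite ilr coordinates")
    if basis is None:
        basis = make_default_sbp(labels if labels is not None else DEFAULT_LABELS)
    arr = np.atleast_2d(z)
    if arr.shape[-1] != basis.D - 1:
        raise CompositionError("coordinate length must be D-1")
    logx = arr @ basis.contrast_matrix
    x = np.exp(logx - logx.max(axis=1, keepdims=True))  # overflow-safe
    x = x / x.sum(axis=1, keepdims=True) * kappa
    if z.ndim == 1:
        return Composition(x[0], basis.labels, float(kappa))
    return x


def compositional_mean(
    rows: Iterable[Composition] | np.ndarray,
    kappa: float = 1.0,
    labels: Sequence[str] | None = None,
) -> Composition:
    """Closed vector of per-part geometric means (the compositional center).

    Equivalent to mapping the arithmetic mean of the ilr coordinates back
    through the inverse ilr — the identity tested as a cross-oracle.
    """
    rows = list(rows) if not isinstance(rows, np.ndarray) else rows
    if len(rows) == 0:
        raise CompositionError("compositional mean of an empty collection")
    if isinstance(rows, np.ndarray):
        arr = np.atleast_2d(np.asarray(rows, dtype=float))
        labs = labels
    else:
        arr = np.vstack([_as_parts(r)[0] for r in rows])
        labs = labels if labels is not None else (
            rows[0].labels if isinstance(rows[0], Composition) else None
        )
    if np.any(arr <= 0):
        raise CompositionError("geometric mean requires strictly positive parts")
    gm = np.exp(np.mean(np.log(arr), axis=0))
    return close(gm, kappa, labs)


def logratio_diff(group_mean, overall_mean) -> np.ndarray:
    """Centered part-wise log-ratio of a group mean against the overall mean.

    Both compositions are closed to 1, the part-wise ``ln(group/overall)`` is
    taken, and the mean of the D log-ratios is subtracted (i.e. the centered
    log-ratio of the perturbation difference).  Identical means give zeros;
    the operation is antisymmetric in its arguments.
    """
    g, glabs = _as_parts(group_mean)
    o, olabs = _as_parts(overall_mean)
    if glabs != olabs:
        raise CompositionError(f"label mismatch: {glabs} vs {olabs}")
    if g.size != o.size:
        raise CompositionError("dimension mismatch")
    gp = g / g.sum()
    op = o / o.sum()
    if np.any(gp <= 0) or np.any(op <= 0):
        raise CompositionError("log-ratio difference requires positive parts")
    d = np.log(gp / op)
    return d - d.mean()


def reallocate(
    c: Composition, from_part: str, to_part: str, delta_minutes: float
) -> Composition:
    """Move ``delta_minutes`` from one behavior to another, total fixed.

    The third behavior is untouched and ``kappa`` is conserved exactly.
    Reallocating a part's entire value (or more) is infeasible because the
    resulting zero would leave the ilr undefined.
    """
    if from_part == to_part:
        raise CompositionError("from_part and to_part must differ")
    if from_part not in c.labels or to_part not in c.labels:
        raise CompositionError("unknown behavior label")
    if delta_minutes < 0:
        raise CompositionError("delta must be nonnegative")
    i, j = c.labels.index(from_part), c.labels.index(to_part)
    if delta_minutes >= c.parts[i]:
        raise InfeasibleReallocationError(
            f"moving {delta_minutes} min would exhaust {from_part} "
            f"({c.parts[i]:.4g} min available)"
        )
    parts = c.parts.copy()
    parts[i] -= delta_minutes
    parts[j] += delta_minutes
    return Composition(parts, c.labels, c.kappa)


def multiplicative_replacement(table, delta: float = 1e-5) -> np.ndarray:
    """Replace zero parts by ``delta`` of the total, shrinking the rest.

    Utility beyond the default pipeline, which treats zeros as a hard error;
    provided for exploratory reuse only.
    """
    arr = np.atleast_2d(np.asarray(table, dtype=float))
    if np.any(arr < 0):
        raise CompositionError("negative value in parts table")
    closed = arr / arr.sum(axis=1, keepdims=True)
    nz = closed == 0
    k = nz.sum(axis=1, keepdims=True)
    out = np.where(nz, delta, closed * (1 - k * delta))
    return out / out.sum(axis=1, keepdims=True)


class IlrTransformer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer wrapping the ilr forward/inverse maps.

    Parameters
    ----------
    labels : sequence of str
        Behavior names in column order.
    pivot : str or None
        Behavior isolated by the first coordinate; ``None`` means the first
        label (the canonical basis).
    kappa : float
        Closure constant used by :meth:`inverse_transform`.
    """

    def __init__(self, labels: Sequence[str] = DEFAULT_LABELS, pivot: str | None = None,
                 kappa: float = 1.0):
        self.labels = labels
        self.pivot = pivot
        self.kappa = kappa

    def fit(self, X, y=None):
        labels = tuple(self.labels)
        pivot = self.pivot if self.pivot is not None else labels[0]
        self.basis_ = make_pivot_sbp(labels, pivot)
        self.n_features_in_ = len(labels)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "basis_"):
            self.fit(X)
        arr = np.asarray(X, dtype=float)
        return ilr_forward(arr, self.basis_)

    def inverse_transform(self, Z) -> np.ndarray:
        if not hasattr(self, "basis_"):
            self.fit(Z)
        return np.atleast_2d(ilr_inverse(np.asarray(Z, float), self.basis_, self.kappa))
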