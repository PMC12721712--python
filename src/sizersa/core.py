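"""Core containers and transforms for representational dissimilarity matrices (RDMs).

An RDM is a symmetric ``n x n`` matrix of pairwise dissimilarities between
experimental conditions (here: object images).  Everything downstream —
decoding RDM stacks, hypothesis RDMs, model RDMs, and the RSA statistics —
is built on the containers defined here.

Pair order convention
---------------------
All vectorizations of the strict upper triangle use row-major order over
``(i, j)`` with ``i < j`` and 0-based condition indices, i.e.
``(0,1), (0,2), ..., (0,n-1), (1,2), ...``.  The order is fixed so that
bootstrap resampling indices computed on one vector apply to every other
vector in the same analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: tolerance used when checking matrix symmetry
SYMMETRY_TOL = 1e-10

#: legal dissimilarity kinds
KINDS = ("decoding_accuracy", "abs_difference", "one_minus_pearson")

#: feature columns of a condition table, in canonical order
FEATURE_NAMES = ("real_world_size", "retinal_size", "real_world_depth")


class RDMError(ValueError):
    """Raised when an RDM (or RDM input) violates its invariants."""


# ---------------------------------------------------------------------------
# condition tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ConditionSet:
    """An ordered set of condition identifiers with per-condition features.

    Parameters
    ----------
    ids
        Unique condition identifiers (length ``n >= 2``); order is the
        canonical row/column order of every RDM built from this set.
    features
        DataFrame indexed by ``ids`` with real-valued columns.  The columns
        ``real_world_size`` (behavioral rating units) and ``retinal_size``
        (pixels, strictly positive) are required; ``real_world_depth`` is
        optional and, when absent, derived as size / retinal size.
    """

    ids: tuple[str, ...]
    features: pd.DataFrame

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        if len(ids) < 2:
            raise RDMError(f"need at least 2 conditions, got {len(ids)}")
        if len(set(ids)) != len(ids):
            raise RDMError("condition ids must be unique")
        feats = self.features.copy()
        feats.index = pd.Index(ids, name="id")
        for col in ("real_world_size", "retinal_size"):
            if col not in feats.columns:
                raise RDMError(f"missing required feature column {col!r}")
        feats = feats.astype(float)
        if not np.all(np.isfinite(feats.to_numpy())):
            raise RDMError("feature values must be finite")
        if np.any(feats["retinal_size"].to_numpy() <= 0):
            raise RDMError("retinal_size must be strictly positive")
        object.__setattr__(self, "features", feats)

    def __len__(self) -> int:
        return len(self.ids)

    def column(self, name: str) -> np.ndarray:
        if name not in self.features.columns:
            raise RDMError(
                f"no feature column {name!r}; have {list(self.features.columns)}"
            )
        return self.features[name].to_numpy(dtype=float)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "ConditionSet":
        """Read a delimited table with header columns ``id, real_world_size, retinal_size``."""
        df = pd.read_csv(path)
        if "id" not in df.columns:
            raise RDMError("condition table must have an 'id' column")
        ids = tuple(str(i) for i in df["id"])
        return cls(ids=ids, features=df.drop(columns=["id"]))

    def to_csv(self, path) -> None:
        out = self.features.reset_index()
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RDM containers
# ---------------------------------------------------------------------------


def pair_index(n: int) -> np.ndarray:
    """Return the ``(m, 2)`` array of 0-based index pairs in canonical order.

    ``m = n (n - 1) / 2``; rows are ``(i, j)`` with ``i < j``, row-major.
    """
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


@dataclasses.dataclass
class RDM:
    """A symmetric condition-by-condition dissimilarity matrix.

    Invariants (checked on construction): square matching ``ids``; symmetric
    within :data:`SYMMETRY_TOL`; zero diagonal; for ``decoding_accuracy``
    kind, off-diagonal values in ``[0, 1]``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        n = len(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise RDMError(f"values shape {v.shape} does not match {n} ids")
        if self.kind not in KINDS:
            raise RDMError(f"unknown dissimilarity kind {self.kind!r}")
        if not np.all(np.isfinite(v)):
            raise RDMError("RDM values must be finite")
        asym = np.max(np.abs(v - v.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise RDMError(
                f"matrix not symmetric: max |M - M.T| = {asym:.3e} > {SYMMETRY_TOL}"
            )
        v = 0.5 * (v + v.T)  # remove sub-tolerance asymmetry
        if np.any(np.diag(v) != 0.0):
            raise RDMError("RDM diagonal must be exactly zero")
        if self.kind == "decoding_accuracy":
            off = v[~np.eye(n, dtype=bool)]
            if off.size and (off.min() < 0.0 or off.max() > 1.0):
                raise RDMError("decoding-accuracy dissimilarities must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_accuracy_matrix(
        cls, ids: Sequence[str], values: np.ndarray, symmetrize: bool = True
    ) -> "RDM":
        """Build a decoding RDM, optionally averaging ``M`` and ``M.T``.

        Symmetrization is permitted only here: pairwise decoding estimates
        one accuracy per unordered pair, but an estimator that fills both
        ordered cells may carry fold noise; the average is the natural
        statistic.
        """
        v = np.asarray(values, dtype=float)
        if symmetrize:
            v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        return cls(ids=tuple(ids), values=v, kind="decoding_accuracy")

    # -- I/O ---------------------------------------------------------------

    def to_npz(self, path) -> None:
        np.savez(
            path,
            values=self.values,
            ids=np.asarray(self.ids, dtype="U"),
            kind=np.asarray(self.kind),
        )

    @classmethod
    def from_npz(cls, path) -> "RDM":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                ids=tuple(z["ids"].tolist()),
                values=z["values"],
                kind=str(z["kind"]),
            )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view: one row per unordered pair (condition_a, condition_b, value)."""
        idx = pair_index(self.n)
        ids = np.asarray(self.ids)
        return pd.DataFrame(
            {
                "condition_a": ids[idx[:, 0]],
                "condition_b": ids[idx[:, 1]],
                "value": self.values[idx[:, 0], idx[:, 1]],
            }
        )


@dataclasses.dataclass
class RDMVector:
    """The strict upper triangle of an RDM in canonical pair order."""

    values: np.ndarray
    ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        m = n * (n - 1) // 2
        if self.values.shape != (m,):
            raise RDMError(
                f"vector length {self.values.shape} does not match n={n} (expect {m})"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def pairs(self) -> np.ndarray:
        """``(m, 2)`` array mapping vector position to condition index pair."""
        return pair_index(len(self.ids))


def vectorize_upper(rdm: RDM) -> RDMVector:
    """Extract the strictly-above-diagonal cells in canonical pair order.

    For ``n = 200`` conditions this yields the 19,900 unique pairwise cells.
    """
    iu = np.triu_indices(rdm.n, k=1)
    return RDMVector(values=rdm.values[iu].copy(), ids=rdm.ids, kind=rdm.kind)


def unvectorize(vec: RDMVector) -> RDM:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric matrix exactly."""
    n = len(vec.ids)
    m = np.zeros((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    m[iu] = vec.values
    m = m + m.T
    return RDM(ids=vec.ids, values=m, kind=vec.kind)


# ---------------------------------------------------------------------------
# RDM constructions
# ---------------------------------------------------------------------------


def rdm_from_feature_column(conditions: ConditionSet, column: str) -> RDM:
    """Absolute-difference RDM of a per-condition scalar feature.

    ``values[i, j] = |x_i - x_j|``, the construction used for all three
    hypothesis RDMs (size ratings, retinal size, depth index).
    """
    x = conditions.column(column)
    if not np.all(np.isfinite(x)):
        raise RDMError(f"non-finite values in column {column!r}")
    v = np.abs(x[:, None] - x[None, :])
    return RDM(ids=conditions.ids, values=v, kind="abs_difference")


def rdm_from_feature_vectors(ids: Sequence[str], feature_matrix: np.ndarray) -> RDM:
    """Correlation-distance RDM: ``1 - Pearson(row_i, row_j)``, range [0, 2].

    This is the construction used for model feature spaces (network layer
    activations, word embeddings): each row is one condition's feature vector.
    """
    ids = tuple(str(i) for i in ids)
    x = np.asarray(feature_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(ids):
        raise RDMError(
            f"feature matrix shape {x.shape} does not match {len(ids)} ids"
        )
    if x.shape[1] < 2:
        raise RDMError("feature vectors need at least 2 dimensions")
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ids[i] for i in bad[:5]]
        raise RDMError(f"zero-variance feature row(s): {names}")
    c = np.corrcoef(x)
    v = 1.0 - np.clip(c, -1.0, 1.0)
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    return RDM(ids=ids, values=v, kind="one_minus_pearson")


def rank_transform(v: RDMVector | np.ndarray) -> RDMVector | np.ndarray:
    """Average-rank transform (the Spearman tie convention).

    Shared primitive for every Spearman computation in the package; accepts
    either a bare array or an :class:`RDMVector` and returns the same type.
    """
    if isinstance(v, RDMVector):
        vals = np.asarray(v.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise RDMError("cannot rank non-finite values")
        return RDMVector(values=rankdata(vals), ids=v.ids, kind=v.kind)
    vals = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise RDMError("cannot rank non-finite values")
    return rankdata(vals)


def percentile_equalize(rdm: RDM) -> RDM:
    """Histogram-equalize an RDM into percentile units (visualization only).

    Off-diagonal cells are replaced by their percentile rank among all
    off-diagonal cells (average ranks, scaled to (0, 100]).  Never used in
    inference — ranks, not percentiles, feed the statistics.  The output is
    a generic dissimilarity (kind ``abs_difference``): percentile units are
    no longer accuracies or correlation distances.
    """
    vec = vectorize_upper(rdm)
    m = len(vec)
    pct = rankdata(vec.values) / m * 100.0
    out = RDMVector(values=pct, ids=rdm.ids, kind="abs_difference")
    return unvectorize(out)


# ---------------------------------------------------------------------------
# stacks of time-resolved (and multi-subject) RDMs
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RDMStack:
    """Per-subject, per-timepoint RDMs sharing one condition set.

    ``values`` has shape ``(n_subjects, n_timepoints, n, n)``; ``time_axis``
    maps timepoint index to milliseconds relative to stimulus onset and must
    be strictly increasing.
    """

    values: np.ndarray
    ids: tuple[str, ...]
    time_axis: np.ndarray
    kind: str
    subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        n = len(self.ids)
        if self.values.ndim != 4 or self.values.shape[2:] != (n, n):
            raise RDMError(
                f"stack shape {self.values.shape} does not match n={n} conditions"
            )
        s, t = self.values.shape[:2]
        if self.time_axis.shape != (t,):
            raise RDMError("time axis length does not match number of timepoints")
        if t > 1 and not np.all(np.diff(self.time_axis) > 0):
            raise RDMError("time axis must be strictly increasing")
        if self.kind not in KINDS:
            raise RDMError(f"unknown dissimilarity kind {self.kind!r}")
        if not self.subjects:
            self.subjects = tuple(f"sub{i:02d}" for i in range(s))
        self.subjects = tuple(str(x) for x in self.subjects)
        if len(self.subjects) != s:
            raise RDMError("subjects length does not match stack")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def rdm(self, subject: int, timepoint: int) -> RDM:
        return RDM(
            ids=self.ids, values=self.values[subject, timepoint].copy(), kind=self.kind
        )

    def vectors(self, subject: int) -> np.ndarray:
        """``(n_timepoints, m)`` matrix of upper-triangle vectors for one subject."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[subject][:, iu[0], iu[1]]

    @classmethod
    def from_subject_stacks(cls, stacks: Sequence["RDMStack"]) -> "RDMStack":
        """Concatenate single-subject stacks that share ids, kind, and time axis."""
        first = stacks[0]
        for s in stacks[1:]:
            if s.ids != first.ids or s.kind != first.kind:
                raise RDMError("stacks do not share ids/kind")
            if not np.array_equal(s.time_axis, first.time_axis):
                raise RDMError("stacks do not share a time axis")
        vals = np.concatenate([s.values for s in stacks], axis=0)
        subjects = tuple(x for s in stacks for x in s.subjects)
        return cls(
            values=vals,
            ids=first.ids,
            time_axis=first.time_axis,
            kind=first.kind,
            subjects=subjects,
        )

    # -- I/O ---------------------------------------------------------------

    def to_npz(self, path) -> None:
        np.savez(
            path,
            values=self.values,
            ids=np.asarray(self.ids, dtype="U"),
            time_axis=self.time_axis,
            kind=np.asarray(self.kind),
            subjects=np.asarray(self.subjects, dtype="U"),
        )

    @classmethod
    def from_npz(cls, path) -> "RDMStack":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                values=z["values"],
                ids=tuple(z["ids"].tolist()),
                time_axis=z["time_axis"],
                kind=str(z["kind"]),
                subjects=tuple(z["subjects"].tolist()),
            )
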