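"""Time-resolved pairwise decoding: labeled trials -> decoding-accuracy RDMs.

For every unordered pair of conditions and every timepoint, a linear SVM is
trained and tested on the channel vector at that timepoint under repeated
stratified k-fold cross-validation (default five-times fivefold).  The mean
held-out accuracy is the pairwise dissimilarity; chance is 0.5, and values
near 1 indicate well-separated neural patterns.

Choices the underlying recording-analysis convention leaves open are fixed
here and exposed in :class:`DecodingConfig`: regularization ``C = 1``,
features z-scored with training-fold statistics only (no leakage), and
pseudo-trial averaging off by default.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._svm import pair_accuracy_timecourse
from .core import RDM, RDMError, RDMStack


class DecodingError(ValueError):
    """Raised for invalid decoding inputs (e.g. too few trials)."""


@dataclasses.dataclass
class TrialArray:
    """Labeled multichannel epochs: ``data`` is trials x channels x timepoints."""

    data: np.ndarray
    labels: np.ndarray
    time_axis: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels).astype(str)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.data.ndim != 3:
            raise DecodingError("trial data must be trials x channels x timepoints")
        if self.labels.shape != (self.data.shape[0],):
            raise DecodingError("one label per trial required")
        if self.time_axis.shape != (self.data.shape[2],):
            raise DecodingError("time axis length must match timepoints")
        if self.data.shape[2] > 1 and not np.all(np.diff(self.time_axis) > 0):
            raise DecodingError("time axis must be strictly increasing")

    @property
    def condition_ids(self) -> tuple[str, ...]:
        """Unique condition labels in first-appearance order."""
        _, idx = np.unique(self.labels, return_index=True)
        return tuple(self.labels[np.sort(idx)])

    def to_npz(self, path) -> None:
        np.savez(
            path,
            data=self.data,
            labels=np.asarray(self.labels, dtype="U"),
            time_axis=self.time_axis,
        )

    @classmethod
    def from_npz(cls, path) -> "TrialArray":
        with np.load(path, allow_pickle=False) as z:
            return cls(data=z["data"], labels=z["labels"], time_axis=z["time_axis"])


@dataclasses.dataclass(frozen=True)
class DecodingConfig:
    n_folds: int = 5
    n_repeats: int = 5
    C: float = 1.0
    pseudo_average_k: int = 1  # 1 = off
    seed: int = 0
    max_epochs: int = 200
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise DecodingError("need at least 2 folds")
        if self.n_repeats < 1:
            raise DecodingError("need at least 1 repeat")
        if self.pseudo_average_k < 1:
            raise DecodingError("pseudo_average_k must be >= 1")


def _canonical_condition_trials(trials: TrialArray, cond: str) -> np.ndarray:
    """Trials of one condition in a canonical, data-derived order.

    Sorting by the raw sample values makes fold assignment a function of the
    trial *contents*, so decoding results are invariant to any permutation
    of trial order in the input array.
    """
    idx = np.flatnonzero(trials.labels == cond)
    if idx.size == 0:
        raise DecodingError(f"condition {cond!r} not present")
    flat = trials.data[idx].reshape(idx.size, -1)
    order = np.lexsort(flat.T[::-1])
    return idx[order]


def _pseudo_average(x: np.ndarray, k: int) -> np.ndarray:
    """Average disjoint groups of k trials (drop the ragged remainder)."""
    n = (x.shape[0] // k) * k
    return x[:n].reshape(n // k, k, *x.shape[1:]).mean(axis=1)


def _fold_assignments(
    n1: int, n2: int, config: DecodingConfig
) -> np.ndarray:
    """Stratified fold ids of shape (n_repeats, n1 + n2).

    Repeats differ only in the seeded shuffle (seed + r) applied within each
    condition before chunking into balanced folds.
    """
    out = np.empty((config.n_repeats, n1 + n2), dtype=np.int64)
    for r in range(config.n_repeats):
        rng = np.random.default_rng(config.seed + r)
        for offset, n in ((0, n1), (n1, n2)):
            perm = rng.permutation(n)
            folds = (np.arange(n) * config.n_folds) // n
            out[r, offset + perm] = folds
    return out


def decode_pair_timecourse(
    trials: TrialArray, pair: tuple[str, str], config: DecodingConfig
) -> np.ndarray:
    """Cross-validated decoding accuracy per timepoint for one condition pair."""
    a, b = pair
    idx_a = _canonical_condition_trials(trials, a)
    idx_b = _canonical_condition_trials(trials, b)
    xa = trials.data[idx_a]
    xb = trials.data[idx_b]
    if config.pseudo_average_k > 1:
        xa = _pseudo_average(xa, config.pseudo_average_k)
        xb = _pseudo_average(xb, config.pseudo_average_k)
    need = 2 * config.n_folds
    for name, x in ((a, xa), (b, xb)):
        if x.shape[0] < need:
            raise DecodingError(
                f"condition {name!r} has {x.shape[0]} (pseudo-)trials; "
                f"need at least {need} for {config.n_folds}-fold CV"
            )
    x = np.ascontiguousarray(np.concatenate([xa, xb], axis=0), dtype=np.float64)
    y = np.concatenate([np.ones(xa.shape[0]), -np.ones(xb.shape[0])])
    fold_assign = _fold_assignments(xa.shape[0], xb.shape[0], config)
    return pair_accuracy_timecourse(
        x, y, fold_assign, config.n_folds, config.C, config.max_epochs, config.tol
    )


def neural_rdm_stack(
    trials: TrialArray,
    config: DecodingConfig,
    conditions: Sequence[str] | None = None,
    subject: str = "sub00",
) -> RDMStack:
    """Decode all ``n (n - 1) / 2`` pairs and assemble one RDM per timepoint.

    Deterministic given the config seed; each pair is decoded independently,
    so results do not depend on the order pairs are processed in.
    """
    ids = tuple(conditions) if conditions is not None else trials.condition_ids
    if len(ids) < 2:
        raise DecodingError("need at least 2 conditions to decode")
    n = len(ids)
    nt = trials.data.shape[2]
    values = np.zeros((1, nt, n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                acc = decode_pair_timecourse(trials, (ids[i], ids[j]), config)
            except DecodingError as err:
                raise DecodingError(f"pair ({ids[i]}, {ids[j]}): {err}") from err
            values[0, :, i, j] = acc
            values[0, :, j, i] = acc
    return RDMStack(
        values=values,
        ids=ids,
        time_axis=trials.time_axis,
        kind="decoding_accuracy",
        subjects=(subject,),
    )
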