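"""RSA statistics: (partial) Spearman timecourses and resampling inference.

Implements the full statistical toolkit for comparing RDMs:

* full and partial Spearman correlations between RDM vectors (partial =
  Pearson on rank-transformed vectors after least-squares residualization
  on the rank-transformed controls);
* subject-level RSA timecourses against a target RDM with optional controls;
* one-sample cluster-based permutation tests over timecourses (sign-flip
  null, max-cluster-statistic correction);
* bootstrap peak-latency estimation by resampling RDM cells with
  replacement;
* paired t-tests on per-subject bootstrap-mean latencies;
* a shuffle-null bootstrap test for model RDM x hypothesis RDM partial
  correlations;
* variance partitioning (commonality analysis) of a neural RDM vector over
  up to four regressor RDMs;
* leave-one-subject-out noise ceilings.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .core import RDM, RDMError, RDMStack, RDMVector, vectorize_upper
from .hypotheses import FEATURES, HypothesisRDMs


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------


def _as_values(v) -> np.ndarray:
    if isinstance(v, RDMVector):
        return np.asarray(v.values, dtype=float)
    return np.asarray(v, dtype=float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("zero-variance vector in correlation; returning NaN")
        return float("nan")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def spearman_rsa(x, y) -> float:
    """Spearman rank correlation between two RDM vectors (average-rank ties)."""
    xv = _as_values(x)
    yv = _as_values(y)
    if xv.shape != yv.shape or xv.size < 3:
        raise RDMError("vectors must share a length of at least 3")
    return _pearson(rankdata(xv), rankdata(yv))


def _check_collinear(ranked_controls: Sequence[np.ndarray], names: Sequence[str]):
    """Raise naming an offending pair if the ranked controls are collinear."""
    k = len(ranked_controls)
    for i in range(k):
        if np.std(ranked_controls[i]) == 0:
            raise RDMError(f"control {names[i]!r} is constant")
    for i, j in itertools.combinations(range(k), 2):
        r = _pearson(ranked_controls[i], ranked_controls[j])
        if abs(r) > 1.0 - 1e-12:
            raise RDMError(
                f"collinear controls: {names[i]!r} and {names[j]!r} (|r| = {abs(r):.12f})"
            )


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_spearman_rsa(x, y, controls: Sequence = ()) -> float:
    """Partial Spearman correlation of x and y given control vectors.

    All vectors are rank-transformed; x and y are residualized on the
    ranked controls (plus intercept) by least squares and the residuals are
    Pearson-correlated.  With no controls this reduces exactly to
    :func:`spearman_rsa`.
    """
    if len(controls) == 0:
        return spearman_rsa(x, y)
    xv = _as_values(x)
    yv = _as_values(y)
    cvs = [_as_values(c) for c in controls]
    names = [
        getattr(c, "name", None) or f"control[{i}]" for i, c in enumerate(controls)
    ]
    m = xv.size
    for v in [yv, *cvs]:
        if v.shape != xv.shape:
            raise RDMError("all vectors must share the same length")
    if m <= len(cvs) + 2:
        raise RDMError(f"need length > n_controls + 2, got {m}")
    rx = rankdata(xv)
    ry = rankdata(yv)
    rcs = [rankdata(c) for c in cvs]
    _check_collinear(rcs, names)
    design = np.column_stack([np.ones(m), *rcs])
    ex = _residualize(rx, design)
    ey = _residualize(ry, design)
    # a vector fully explained by the controls has (numerically) zero
    # residual; the partial correlation is 0 by definition, not noise
    if np.linalg.norm(ex) < 1e-8 * np.linalg.norm(rx - rx.mean()) or np.linalg.norm(
        ey
    ) < 1e-8 * np.linalg.norm(ry - ry.mean()):
        return 0.0
    return _pearson(ex, ey)


# ---------------------------------------------------------------------------
# timecourses
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RSATimecourse:
    """Per-subject (partial) correlation values over time.

    ``values`` is subjects x timepoints; ``target`` names the compared RDM
    and ``controls`` the partialled RDMs (empty for full Spearman).
    """

    values: np.ndarray
    time_axis: np.ndarray
    target: str
    controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.shape[1] != self.time_axis.size:
            raise RDMError("values/time axis mismatch")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise RDMError("correlation values outside [-1, 1]")
        if self.target in self.controls:
            raise RDMError("controls must not include the target")

    @property
    def group_mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


def _check_shared_ids(neural: RDMStack, rdms: Sequence[RDM]) -> None:
    for r in rdms:
        if r.ids != neural.ids:
            missing = set(neural.ids) - set(r.ids)
            extra = set(r.ids) - set(neural.ids)
            raise RDMError(
                f"condition id mismatch; missing from RDM: {sorted(missing)[:5]}, "
                f"unexpected: {sorted(extra)[:5]}"
            )


def rsa_timecourse(
    neural: RDMStack,
    target: RDM,
    controls: Sequence[RDM] = (),
    target_name: str | None = None,
    control_names: Sequence[str] | None = None,
) -> RSATimecourse:
    """(Partial) Spearman RSA of each subject's neural RDMs against a target."""
    _check_shared_ids(neural, [target, *controls])
    tv = vectorize_upper(target).values
    cvs = [vectorize_upper(c).values for c in controls]
    for c in cvs:
        if np.array_equal(c, tv):
            raise RDMError("a control RDM duplicates the target RDM")
    s, t = neural.n_subjects, neural.n_timepoints
    values = np.empty((s, t))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for si in range(s):
            vecs = neural.vectors(si)
            for ti in range(t):
                values[si, ti] = partial_spearman_rsa(vecs[ti], tv, cvs)
    return RSATimecourse(
        values=values,
        time_axis=neural.time_axis,
        target=target_name or "target",
        controls=tuple(control_names or (f"control[{i}]" for i in range(len(cvs)))),
    )


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    stat: float  # sum of t-values in the cluster
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclasses.dataclass
class ClusterTestResult:
    clusters: tuple[Cluster, ...]
    n_permutations: int
    cluster_forming_p: float
    tail: str
    time_axis: np.ndarray
    mask: np.ndarray  # boolean, timepoints inside significant clusters

    @property
    def significant_clusters(self) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.significant)

    def significant_window(self) -> tuple[float, float] | None:
        """(start_ms, end_ms) spanning the union of significant clusters."""
        sig = self.significant_clusters
        if not sig:
            return None
        return (min(c.start_ms for c in sig), max(c.end_ms for c in sig))


def _tvalues(values: np.ndarray) -> np.ndarray:
    """One-sample t against zero per timepoint; zero-variance -> -inf (excluded)."""
    s = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(s))
    t[~np.isfinite(t)] = -np.inf
    return t


def _clusters_from_t(t: np.ndarray, thresh: float) -> list[tuple[int, int, float]]:
    """Contiguous supra-threshold runs as (start, end inclusive, sum of t)."""
    above = t > thresh
    out = []
    i = 0
    n = t.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            out.append((i, j, float(t[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def cluster_permutation_test(
    tc: RSATimecourse,
    n_permutations: int = 1000,
    cluster_forming_p: float = 0.05,
    tail: str = "greater",
    seed: int = 0,
) -> ClusterTestResult:
    """One-sample cluster-based permutation test over a timecourse.

    Per timepoint, a one-sample t-test against zero (one-tailed) defines
    supra-threshold clusters (t above the ``cluster_forming_p`` critical
    value, df = n_subjects - 1); each cluster's statistic is the sum of its
    t-values.  The null is built by randomly sign-flipping each subject's
    whole timecourse and recording the maximum cluster statistic; cluster
    p-values use the (1 + count) / (1 + N) estimator.
    """
    if tail != "greater":
        raise NotImplementedError("only the one-tailed 'greater' test is provided")
    values = np.asarray(tc.values, dtype=float)
    s, nt = values.shape
    if s < 2 or nt < 2:
        raise RDMError("need at least 2 subjects and 2 timepoints")
    if np.any(values.std(axis=0, ddof=1) == 0):
        warnings.warn("zero across-subject variance at some timepoints; excluded")
    thresh = float(stats.t.ppf(1.0 - cluster_forming_p, df=s - 1))
    t_obs = _tvalues(values)
    obs = _clusters_from_t(t_obs, thresh)

    rng = np.random.default_rng(seed)
    sq_sum = np.sum(values**2, axis=0)  # invariant under sign flips
    null = np.zeros(n_permutations)
    for p in range(n_permutations):
        signs = rng.choice(np.array([-1.0, 1.0]), size=s)
        mean = (signs @ values) / s
        var = (sq_sum - s * mean**2) / (s - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = mean / np.sqrt(var / s)
        t_p[~np.isfinite(t_p)] = -np.inf
        runs = _clusters_from_t(t_p, thresh)
        null[p] = max((r[2] for r in runs), default=0.0)

    clusters = []
    mask = np.zeros(nt, dtype=bool)
    for start, end, stat in obs:
        pval = (1.0 + np.sum(null >= stat)) / (1.0 + n_permutations)
        c = Cluster(
            start_ms=float(tc.time_axis[start]),
            end_ms=float(tc.time_axis[end]),
            stat=stat,
            p_value=float(pval),
        )
        clusters.append(c)
        if c.significant:
            mask[start : end + 1] = True
    return ClusterTestResult(
        clusters=tuple(clusters),
        n_permutations=n_permutations,
        cluster_forming_p=cluster_forming_p,
        tail=tail,
        time_axis=tc.time_axis,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# bootstrap peak latency
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PeakLatencyResult:
    """Bootstrap peak-latency distributions per subject, plus group summary."""

    latencies: np.ndarray  # (n_subjects, n_bootstrap) ms
    subject_means: np.ndarray  # (n_subjects,) bootstrap-mean latency per subject
    group_mean: float
    group_sem: float
    n_bootstrap: int
    search_window_ms: tuple[float, float]
    target: str = "target"


def _window_mask(time_axis: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi < lo:
        raise RDMError("empty peak-search window")
    mask = (time_axis >= lo) & (time_axis <= hi)
    if not mask.any():
        raise RDMError(
            f"window {window} contains no samples of the time axis "
            f"[{time_axis[0]}, {time_axis[-1]}]"
        )
    return mask


def _orthonormal_design(columns: list[np.ndarray]) -> np.ndarray:
    m = columns[0].size
    d = np.column_stack([np.ones(m), *columns])
    q, _ = np.linalg.qr(d)
    return q


def bootstrap_peak_latency(
    neural: RDMStack,
    target: RDM,
    controls: Sequence[RDM] = (),
    window: tuple[float, float] = (0.0, 300.0),
    n_bootstrap: int = 1000,
    seed: int = 0,
    target_name: str = "target",
) -> PeakLatencyResult:
    """Peak latency of the (partial) RSA timecourse, bootstrapped over RDM cells.

    Per subject and bootstrap sample, the upper-triangle cells are resampled
    with replacement — the *same* resample indices applied to the neural,
    target, and control vectors — the partial-correlation timecourse is
    recomputed on the resampled (re-ranked) vectors, and the argmax latency
    within the search window is recorded.  The subject's latency estimate is
    the bootstrap mean; ties at the maximum resolve to the earliest sample.
    """
    if n_bootstrap < 1:
        raise RDMError("n_bootstrap must be >= 1")
    _check_shared_ids(neural, [target, *controls])
    mask = _window_mask(neural.time_axis, window)
    t_window = neural.time_axis[mask]
    tv = vectorize_upper(target).values
    cvs = [vectorize_upper(c).values for c in controls]
    m = tv.size
    s = neural.n_subjects
    lat = np.empty((s, n_bootstrap))
    rng = np.random.default_rng(seed)
    for si in range(s):
        vecs = neural.vectors(si)[mask]  # (Tw, m)
        for b in range(n_bootstrap):
            idx = rng.integers(0, m, size=m)
            rt = rankdata(tv[idx])
            rn = rankdata(vecs[:, idx], axis=1)
            if cvs:
                q = _orthonormal_design([rankdata(c[idx]) for c in cvs])
                rt = rt - q @ (q.T @ rt)
                rn = rn - (rn @ q) @ q.T
            else:
                rt = rt - rt.mean()
                rn = rn - rn.mean(axis=1, keepdims=True)
            denom = np.linalg.norm(rn, axis=1) * np.linalg.norm(rt)
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = (rn @ rt) / denom
            rho[~np.isfinite(rho)] = -np.inf
            lat[si, b] = t_window[int(np.argmax(rho))]
    subject_means = lat.mean(axis=1)
    return PeakLatencyResult(
        latencies=lat,
        subject_means=subject_means,
        group_mean=float(subject_means.mean()),
        group_sem=float(subject_means.std(ddof=1) / np.sqrt(s)) if s > 1 else 0.0,
        n_bootstrap=n_bootstrap,
        search_window_ms=(float(window[0]), float(window[1])),
        target=target_name,
    )


def paired_latency_test(
    a: PeakLatencyResult, b: PeakLatencyResult
) -> tuple[float, int, float]:
    """Two-tailed paired t-test on per-subject bootstrap-mean latencies.

    Returns ``(t, df, p)``.  Degenerate case: identical nonzero shifts with
    zero variance of differences yield an infinite t, reported as p -> 0
    with a warning.
    """
    x = np.asarray(a.subject_means, dtype=float)
    y = np.asarray(b.subject_means, dtype=float)
    if x.shape != y.shape:
        raise RDMError("latency results must cover the same subjects in order")
    n = x.size
    diff = x - y
    df = n - 1
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, df, 1.0
        warnings.warn("zero variance of latency differences; p reported as 0")
        return float(np.inf * np.sign(diff.mean())), df, 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------------
# model RDM x hypothesis RDMs shuffle-null test
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BootstrapNullResult:
    """Observed partial correlations vs. cell-shuffle null, per hypothesis."""

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    critical: dict[str, float]  # one-sided 95th percentile of the null
    significant: dict[str, bool]
    n_shuffles: int


def model_hyp_partial_test(
    model_rdm: RDM,
    hyps: HypothesisRDMs,
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapNullResult:
    """Partial correlation of a model RDM with each hypothesis RDM + shuffle null.

    Observed statistic per hypothesis: partial Spearman of the model RDM
    vector with that hypothesis vector, controlling the other two.  The null
    shuffles the order of the model RDM's upper-triangle cells ``n_shuffles``
    times and recomputes all three partials each time; a hypothesis is
    flagged significant iff the observed value exceeds the null's one-sided
    ``1 - alpha`` percentile.
    """
    if n_shuffles < 100:
        raise RDMError("n_shuffles must be >= 100")
    if model_rdm.ids != hyps.real_world_size.ids:
        raise RDMError("model RDM and hypothesis RDMs must share condition ids")
    mv = vectorize_upper(model_rdm).values
    hvecs = hyps.vectors()
    m = mv.size
    rm = rankdata(mv)
    rh = {f: rankdata(v) for f, v in hvecs.items()}

    rng = np.random.default_rng(seed)
    perms = np.empty((n_shuffles, m), dtype=np.int64)
    for i in range(n_shuffles):
        perms[i] = rng.permutation(m)
    shuffled = rm[perms]  # ranks of a shuffled vector are the shuffled ranks

    observed: dict[str, float] = {}
    null: dict[str, np.ndarray] = {}
    critical: dict[str, float] = {}
    significant: dict[str, bool] = {}
    for f in FEATURES:
        others = [rh[g] for g in FEATURES if g != f]
        _check_collinear(others, [g for g in FEATURES if g != f])
        q = _orthonormal_design(others)
        ht = rh[f] - q @ (q.T @ rh[f])
        hn = ht / np.linalg.norm(ht)
        mt = rm - q @ (q.T @ rm)
        mt_norm = np.linalg.norm(mt)
        if mt_norm < 1e-8 * np.linalg.norm(rm - rm.mean()):
            observed[f] = 0.0  # model fully explained by the controls
        else:
            observed[f] = float(np.clip((mt / mt_norm) @ hn, -1, 1))
        sres = shuffled - (shuffled @ q) @ q.T
        norms = np.linalg.norm(sres, axis=1)
        null_f = (sres @ hn) / norms
        null[f] = null_f
        critical[f] = float(np.percentile(null_f, 100 * (1 - alpha)))
        significant[f] = observed[f] > critical[f]
    return BootstrapNullResult(
        observed=observed,
        null=null,
        critical=critical,
        significant=significant,
        n_shuffles=n_shuffles,
    )


# ---------------------------------------------------------------------------
# variance partitioning (commonality analysis)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class VariancePartition:
    """Commonality decomposition of a full-model R² over regressor subsets.

    ``components`` maps a frozenset of regressor names to the variance
    component uniquely shared by exactly that subset; components sum to the
    full-model R².  Negative shared components can occur (suppression) and
    are reported as-is.
    """

    regressors: tuple[str, ...]
    components: dict[frozenset, float]
    r2_full: float

    def unique(self, name: str) -> float:
        return self.components[frozenset([name])]

    def shared(self, *names: str) -> float:
        return self.components[frozenset(names)]


def _subset_r2(y: np.ndarray, cols: Mapping[str, np.ndarray]) -> dict[frozenset, float]:
    names = list(cols)
    m = y.size
    yc = y - y.mean()
    sst = float(yc @ yc)
    out: dict[frozenset, float] = {frozenset(): 0.0}
    for k in range(1, len(names) + 1):
        for sub in itertools.combinations(names, k):
            d = np.column_stack([np.ones(m), *(cols[s] for s in sub)])
            resid = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
            out[frozenset(sub)] = 1.0 - float(resid @ resid) / sst
    return out


def variance_partitioning(
    neural_vec, regressors: Mapping[str, np.ndarray | RDMVector]
) -> VariancePartition:
    """Commonality analysis of a neural RDM vector over 2–4 regressor vectors.

    All vectors are rank-transformed; R² of every nonempty regressor subset
    is computed by least squares, and unique/shared components follow by
    inclusion–exclusion: ``C(S) = (-1)^(|S|+1) * sum_{T ⊆ S} (-1)^|T|
    R²(all \\ T)``.
    """
    names = tuple(regressors)
    if not 2 <= len(names) <= 4:
        raise RDMError("need between 2 and 4 regressors")
    y = rankdata(_as_values(neural_vec))
    cols = {k: rankdata(_as_values(v)) for k, v in regressors.items()}
    for v in cols.values():
        if v.shape != y.shape:
            raise RDMError("all vectors must share the same length")
    _check_collinear(list(cols.values()), list(names))
    r2 = _subset_r2(y, cols)
    full = frozenset(names)
    components: dict[frozenset, float] = {}
    for k in range(1, len(names) + 1):
        for sub in itertools.combinations(names, k):
            s = frozenset(sub)
            total = 0.0
            for kk in range(0, len(sub) + 1):
                for t in itertools.combinations(sub, kk):
                    total += (-1.0) ** kk * r2[full - frozenset(t)]
            components[s] = (-1.0) ** (len(sub) + 1) * total
    return VariancePartition(
        regressors=names, components=components, r2_full=r2[full]
    )


# ---------------------------------------------------------------------------
# noise ceiling
# ---------------------------------------------------------------------------


def noise_ceiling(neural: RDMStack) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper noise-ceiling timecourses from subject RDM agreement.

    Upper bound: mean over subjects of Spearman(subject vector, all-subject
    mean vector).  Lower bound: same with the subject left out of the mean.
    Requires at least 3 subjects.
    """
    s = neural.n_subjects
    if s < 3:
        raise RDMError("noise ceiling needs at least 3 subjects")
    nt = neural.n_timepoints
    vecs = np.stack([neural.vectors(si) for si in range(s)])  # (S, T, m)
    upper = np.empty(nt)
    lower = np.empty(nt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ti in range(nt):
            v = vecs[:, ti, :]
            mean_all = v.mean(axis=0)
            ups, los = [], []
            for si in range(s):
                ups.append(spearman_rsa(v[si], mean_all))
                loo = (mean_all * s - v[si]) / (s - 1)
                los.append(spearman_rsa(v[si], loo))
            upper[ti] = np.nanmean(ups)
            lower[ti] = np.nanmean(los)
    return lower, upper
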