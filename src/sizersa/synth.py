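"""Synthetic multichannel datasets with known, time-localized feature geometry.

The generator emulates the statistical shape of a rapid-visual-presentation
recording: per-condition feature values (size rating, retinal size, derived
depth), multichannel trial epochs in which each feature's pairwise geometry
is injected into channel space inside a Gaussian temporal window, and model
feature matrices ("early layer" / "late layer" recipes) whose correlation
RDMs realize chosen feature geometries.

Signal model
------------
For condition ``c`` the noiseless signal is

    s_c(ch, t) = sum_f  a_f * g_f(t) * u_f[ch] * z_f(c)

with ``g_f`` a unit-peak Gaussian bump (center, width in ms), ``u_f`` a
fixed random unit channel vector, and ``z_f(c)`` the standardized latent
feature value.  Each trial adds i.i.d. Gaussian noise.  Because a feature
occupies a *single* direction scaled by its value, the noiseless pattern
distance between two conditions inside one window is proportional to
``|z_f(c_i) - z_f(c_j)|`` — exactly the geometry of an absolute-difference
hypothesis RDM, so injected geometry is recoverable by the decoding + RSA
pipeline.

Defaults mirror the recording the package is designed around: 17 posterior
channels, 80 trials per condition, a −100..300 ms epoch sampled at 100 Hz
(40 samples), and feature windows centered at 87 ms (depth), 138 ms
(retinal size), and 206 ms (real-world size).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ConditionSet, RDMError
from .hypotheses import FEATURES

#: default injected windows: (center_ms, width_ms = gaussian SD, amplitude)
DEFAULT_WINDOWS = {
    "real_world_depth": (87.0, 20.0, 1.5),
    "retinal_size": (138.0, 20.0, 1.5),
    "real_world_size": (206.0, 20.0, 1.5),
}


@dataclasses.dataclass(frozen=True)
class FeatureWindow:
    center_ms: float
    width_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("feature window width must be positive")
        if self.amplitude < 0:
            raise ValueError("feature window amplitude must be non-negative")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    ``noise_sd`` is the per-channel, per-sample trial noise SD in the same
    (arbitrary) units as the injected amplitudes; the default amplitude 1.5
    against noise SD 1.0 yields pairwise decoding peaking well above chance
    but far from saturation, comparable to a strong posterior-channel
    visual effect.
    """

    n_conditions: int = 20
    n_trials_per_condition: int = 80
    n_channels: int = 17
    time_window_ms: tuple[float, float] = (-100.0, 300.0)
    sample_rate_hz: float = 100.0
    feature_windows: Mapping[str, FeatureWindow] = dataclasses.field(
        default_factory=lambda: {
            name: FeatureWindow(*params) for name, params in DEFAULT_WINDOWS.items()
        }
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 4:
            raise ValueError("need at least 4 conditions")
        if self.n_trials_per_condition < 10 or self.n_trials_per_condition % 2:
            raise ValueError("trials per condition must be even and >= 10")
        if self.n_channels < 1:
            raise ValueError("need at least 1 channel")
        t0, t1 = self.time_window_ms
        if t1 <= t0:
            raise ValueError("empty time window")
        object.__setattr__(
            self,
            "feature_windows",
            {
                str(k): (v if isinstance(v, FeatureWindow) else FeatureWindow(*v))
                for k, v in self.feature_windows.items()
            },
        )
        unknown = set(self.feature_windows) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown feature(s) in windows: {sorted(unknown)}")

    @property
    def n_timepoints(self) -> int:
        t0, t1 = self.time_window_ms
        return int(round((t1 - t0) / 1000.0 * self.sample_rate_hz))

    @property
    def time_axis(self) -> np.ndarray:
        """Sample k -> t0 + k / rate; onset (0 ms) falls on a sample for defaults."""
        t0 = self.time_window_ms[0]
        step = 1000.0 / self.sample_rate_hz
        return t0 + step * np.arange(self.n_timepoints)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feature_windows"] = {
            k: [w.center_ms, w.width_ms, w.amplitude]
            for k, w in self.feature_windows.items()
        }
        d["time_window_ms"] = list(self.time_window_ms)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "feature_windows" in d:
            d["feature_windows"] = {
                k: FeatureWindow(*v) for k, v in dict(d["feature_windows"]).items()
            }
        if "time_window_ms" in d:
            d["time_window_ms"] = tuple(d["time_window_ms"])
        return cls(**d)


@dataclasses.dataclass
class GroundTruth:
    """Everything needed to recompute the noiseless signal bit-exactly."""

    z: pd.DataFrame  # standardized latent feature values, one column per feature
    channel_vectors: dict[str, np.ndarray]  # unit vectors u_f
    temporal_gains: dict[str, np.ndarray]  # a_f * g_f(t) per timepoint
    config: SimulationConfig

    def noiseless_patterns(self) -> np.ndarray:
        """``(n_conditions, n_channels, n_timepoints)`` noiseless signal."""
        cfg = self.config
        out = np.zeros((len(self.z), cfg.n_channels, cfg.n_timepoints))
        for name in self.channel_vectors:
            zf = self.z[name].to_numpy()
            out += (
                zf[:, None, None]
                * self.channel_vectors[name][None, :, None]
                * self.temporal_gains[name][None, None, :]
            )
        return out


@dataclasses.dataclass
class SyntheticDataset:
    conditions: ConditionSet
    trials: "TrialArray"
    ground_truth: GroundTruth


def sample_latent_features(n: int, seed: int) -> ConditionSet:
    """Draw a condition table with realistic size/retinal/depth structure.

    Size ratings are log-uniform on [100, 423] (the span of actual mean
    ratings on the 0–519 behavioral scale); retinal sizes are log-uniform on
    [50, 600] pixels, independent of size, roughly the object-diagonal range
    available in a 500x500 image; depth is exactly size / retinal.  The
    resulting three columns are mutually correlated (size and depth
    positively), reproducing the qualitative intercorrelation structure the
    partial-correlation machinery exists to untangle.
    """
    if n < 4:
        raise ValueError("need at least 4 conditions")
    rng = np.random.default_rng(seed)
    size = np.exp(rng.uniform(np.log(100.0), np.log(423.0), size=n))
    retinal = np.exp(rng.uniform(np.log(50.0), np.log(600.0), size=n))
    ids = tuple(f"obj{i:03d}" for i in range(n))
    feats = pd.DataFrame(
        {
            "real_world_size": size,
            "retinal_size": retinal,
            "real_world_depth": size / retinal,
        },
        index=pd.Index(ids, name="id"),
    )
    return ConditionSet(ids=ids, features=feats)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise RDMError("cannot standardize a constant feature")
    return (x - x.mean()) / sd


def standardized_latents(conditions: ConditionSet) -> pd.DataFrame:
    """Z-scored latent feature values in canonical feature order."""
    from .hypotheses import depth_index

    size = conditions.column("real_world_size")
    retinal = conditions.column("retinal_size")
    cols = {
        "real_world_size": _standardize(size),
        "retinal_size": _standardize(retinal),
        "real_world_depth": _standardize(depth_index(size, retinal)),
    }
    return pd.DataFrame(cols, index=pd.Index(conditions.ids, name="id"))


def simulate_trials(
    conditions: ConditionSet, config: SimulationConfig
) -> SyntheticDataset:
    """Generate one pseudo-subject's trial array under the signal model.

    Deterministic given ``config.seed``: the same seed and config reproduce
    the dataset bit-exactly.  Multi-subject datasets are built from
    independent seeds sharing the same :class:`ConditionSet` (see
    :func:`simulate_subjects`).
    """
    from .decoding import TrialArray

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    z = standardized_latents(conditions)
    time_axis = cfg.time_axis

    channel_vectors: dict[str, np.ndarray] = {}
    temporal_gains: dict[str, np.ndarray] = {}
    # iterate in canonical feature order for seed-stable draws
    for name in FEATURES:
        if name not in cfg.feature_windows:
            continue
        w = cfg.feature_windows[name]
        u = rng.normal(size=cfg.n_channels)
        u /= np.linalg.norm(u)
        channel_vectors[name] = u
        g = np.exp(-0.5 * ((time_axis - w.center_ms) / w.width_ms) ** 2)
        temporal_gains[name] = w.amplitude * g

    truth = GroundTruth(
        z=z, channel_vectors=channel_vectors, temporal_gains=temporal_gains, config=cfg
    )
    patterns = truth.noiseless_patterns()

    n_trials = len(conditions) * cfg.n_trials_per_condition
    labels = np.repeat(np.asarray(conditions.ids), cfg.n_trials_per_condition)
    noise = rng.normal(
        scale=cfg.noise_sd, size=(n_trials, cfg.n_channels, cfg.n_timepoints)
    )
    data = np.repeat(patterns, cfg.n_trials_per_condition, axis=0) + noise

    trials = TrialArray(data=data, labels=labels, time_axis=time_axis)
    return SyntheticDataset(conditions=conditions, trials=trials, ground_truth=truth)


def simulate_subjects(
    conditions: ConditionSet, config: SimulationConfig, n_subjects: int, seed: int
) -> list[SyntheticDataset]:
    """Independent pseudo-subjects sharing one condition set.

    Subject ``s`` uses seed ``seed + s``; channel directions and noise are
    therefore independent across subjects while the latent condition
    features (hence the true RDM geometry) are shared.
    """
    out = []
    for s in range(n_subjects):
        cfg = dataclasses.replace(config, seed=seed + s)
        out.append(simulate_trials(conditions, cfg))
    return out


# ---------------------------------------------------------------------------
# synthetic model feature matrices
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ModelRecipe:
    """Recipe for a synthetic model feature matrix.

    ``weights`` maps feature name -> non-negative weight; ``noise_sd`` is
    i.i.d. Gaussian noise added to every entry of the feature matrix (on
    the scale of the signal entries, which are O(1)); ``dims_per_feature``
    sets the embedding width per weighted feature (total dimensionality
    comparable to a pooled network layer or word-embedding space).
    """

    weights: Mapping[str, float]
    noise_sd: float = 0.3
    dims_per_feature: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", dict(self.weights))
        unknown = set(self.weights) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown feature(s) in recipe: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("recipe weights must be non-negative")
        if self.dims_per_feature < 3:
            raise ValueError("need at least 3 dims per feature block")


def early_layer_recipe(noise_sd: float = 0.3) -> ModelRecipe:
    """Early-layer-like geometry: retinal size + depth encoded, size absent."""
    return ModelRecipe(
        weights={"retinal_size": 1.0, "real_world_depth": 1.0}, noise_sd=noise_sd
    )


def late_layer_recipe(noise_sd: float = 0.3) -> ModelRecipe:
    """Late-layer-like geometry: dominated by real-world size."""
    return ModelRecipe(weights={"real_world_size": 1.0}, noise_sd=noise_sd)


def noise_recipe(noise_sd: float = 1.0) -> ModelRecipe:
    """Pure-noise features: no hypothesis geometry encoded."""
    return ModelRecipe(weights={}, noise_sd=noise_sd)


def simulate_model_features(
    conditions: ConditionSet, recipe: ModelRecipe, seed: int
) -> np.ndarray:
    """Feature matrix whose correlation RDM realizes the recipe's geometry.

    The 1 − Pearson dissimilarity between zero-mean, unit-norm rows equals
    ``1 - <x_i, x_j>``, so any admissible cell structure can be realized
    exactly by choosing the Gram matrix of the rows.  The noiseless target
    cells here are a *linear* combination of the weighted features'
    rank-transformed absolute-difference vectors, scaled to the largest
    magnitude that keeps the Gram matrix positive definite.  Consequences:

    * a single-feature recipe at zero noise yields an RDM exactly
      rank-equivalent (Spearman 1) to that feature's hypothesis RDM;
    * a multi-feature recipe's noiseless RDM lies exactly in the linear
      span of the encoded features' rank vectors, so partial correlations
      with *non*-encoded features vanish — the encoding carries a feature
      estimate's geometry, not an exact latent value that would implicitly
      pin down algebraically related features.

    The embedding is drawn in ``dims_per_feature * n_weighted`` dimensions
    (random rotation, seeded), scaled so signal entries are O(1), with
    i.i.d. Gaussian noise of ``recipe.noise_sd`` added per entry.
    """
    rng = np.random.default_rng(seed)
    z = standardized_latents(conditions)
    n = len(conditions)
    n_blocks = sum(1 for w in recipe.weights.values() if w > 0)
    d = max(recipe.dims_per_feature * max(n_blocks, 1), n + 2)

    # weighted sum of rank-standardized |delta feature| cell scores
    from scipy.stats import rankdata

    iu = np.triu_indices(n, k=1)
    s = np.zeros(len(iu[0]))
    for name in FEATURES:  # canonical order
        w = float(recipe.weights.get(name, 0.0))
        if w == 0.0:
            continue
        zf = z[name].to_numpy()
        cells = np.abs(zf[iu[0]] - zf[iu[1]])
        r = rankdata(cells)
        s += w * (r - r.mean()) / r.std()

    gram = np.eye(n)
    if np.any(s != 0.0):
        smat = np.zeros((n, n))
        smat[iu] = s
        smat = smat + smat.T
        lam = np.linalg.eigvalsh(-smat)
        scale = 0.95 / max(-lam[0], 1e-12)  # keep eigmin(G) >= 0.05
        gram = np.eye(n) - scale * smat
    elif recipe.noise_sd <= 0:
        raise ValueError("recipe with no weights requires noise_sd > 0")

    evals, evecs = np.linalg.eigh(gram)
    y = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))  # (n, n), rows' Gram = gram

    # orthonormal basis of the zero-mean subspace of R^d (rows get exact zero mean)
    basis = rng.normal(size=(d, n))
    basis -= basis.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(basis)
    x = np.sqrt(d) * (y @ q.T)  # entries O(1)
    if recipe.noise_sd > 0:
        x = x + rng.normal(scale=recipe.noise_sd, size=(n, d))
    return x


# ---------------------------------------------------------------------------
# on-disk artifacts
# ---------------------------------------------------------------------------


def save_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "config": truth.config.to_dict(),
        "z": {k: truth.z[k].tolist() for k in truth.z.columns},
        "ids": list(truth.z.index),
        "channel_vectors": {k: v.tolist() for k, v in truth.channel_vectors.items()},
        "temporal_gains": {k: v.tolist() for k, v in truth.temporal_gains.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
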