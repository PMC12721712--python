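"""Hypothesis RDMs for object real-world size, retinal size, and inferred depth.

Three feature models of the same stimulus set:

* **real-world size** — behavioral size ratings of the object concept
  (published rating scale runs 0–519 and already spans a logarithmic size
  range, so ratings are used as-is, without a log transform; downstream
  statistics are rank-based anyway);
* **retinal size** — diagonal of the object's bounding region in pixels, a
  property of the displayed image;
* **real-world depth** — inferred egocentric distance.  Under perspective
  projection at a fixed viewing distance, depth is proportional to
  real-world size divided by retinal size; the constant viewing distance is
  absorbed into the proportionality.

Each feature yields an absolute-difference RDM; the trio is summarized
together with its Spearman intercorrelation matrix because the three
features are intrinsically correlated — which is exactly why the RSA stage
uses partial correlations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import (
    RDM,
    ConditionSet,
    RDMError,
    rdm_from_feature_column,
    vectorize_upper,
)

#: canonical feature order used everywhere in this module
FEATURES = ("real_world_size", "retinal_size", "real_world_depth")


def depth_index(size_rating, retinal_px):
    """Depth proxy: size rating divided by retinal size (both positive).

    Note the caveat inherited from the construction: only the *ranks* of
    pairwise depth differences feed the statistics downstream, but
    ``|delta(s / r)|`` is not scale-free in general, so the index is a proxy
    for perceived egocentric distance, not a calibrated measurement.
    """
    size_rating = np.asarray(size_rating, dtype=float)
    retinal_px = np.asarray(retinal_px, dtype=float)
    if np.any(retinal_px <= 0):
        raise RDMError("retinal size must be strictly positive")
    out = size_rating / retinal_px
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class HypothesisRDMs:
    """The three hypothesis RDMs plus their Spearman intercorrelations."""

    real_world_size: RDM
    retinal_size: RDM
    real_world_depth: RDM
    intercorrelations: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.real_world_size.ids
        if self.retinal_size.ids != ids or self.real_world_depth.ids != ids:
            raise RDMError("hypothesis RDMs must share condition ids")
        m = self.intercorrelations.to_numpy(dtype=float)
        if m.shape != (3, 3) or np.max(np.abs(m - m.T)) > 1e-12:
            raise RDMError("intercorrelation matrix must be symmetric 3x3")
        if not np.allclose(np.diag(m), 1.0):
            raise RDMError("intercorrelation diagonal must be 1")

    def __getitem__(self, feature: str) -> RDM:
        if feature not in FEATURES:
            raise KeyError(feature)
        return getattr(self, feature)

    def vectors(self) -> dict[str, np.ndarray]:
        """Upper-triangle vectors per feature, canonical pair order."""
        return {f: vectorize_upper(self[f]).values for f in FEATURES}


def build_hypothesis_rdms(conditions: ConditionSet) -> HypothesisRDMs:
    """Build all three absolute-difference hypothesis RDMs from a condition table.

    The depth column is always recomputed from the size and retinal columns
    via :func:`depth_index` (a stored depth column is ignored), keeping the
    trio internally consistent.
    """
    size = conditions.column("real_world_size")
    retinal = conditions.column("retinal_size")
    depth = depth_index(size, retinal)

    feats = conditions.features.copy()
    feats["real_world_depth"] = depth
    cset = ConditionSet(ids=conditions.ids, features=feats)

    rdms = {f: rdm_from_feature_column(cset, f) for f in FEATURES}
    vecs = {f: vectorize_upper(rdms[f]).values for f in FEATURES}

    inter = np.eye(3)
    for i, fi in enumerate(FEATURES):
        for j in range(i + 1, 3):
            rho = spearmanr(vecs[fi], vecs[FEATURES[j]]).statistic
            inter[i, j] = inter[j, i] = rho
    table = pd.DataFrame(inter, index=list(FEATURES), columns=list(FEATURES))
    return HypothesisRDMs(
        real_world_size=rdms["real_world_size"],
        retinal_size=rdms["retinal_size"],
        real_world_depth=rdms["real_world_depth"],
        intercorrelations=table,
    )
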