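"""End-to-end orchestration: simulate -> decode -> RDMs -> RSA -> report.

Runs the whole analysis on synthetic (or user-supplied) data, writing every
intermediate artifact plus a manifest of seeds, settings, and content
hashes.  Array artifacts are NPZ containers with embedded ids/time axes;
small tables are mirrored as CSV; results and the manifest are JSON.

Determinism contract: every random stage consumes a named seed derived from
the global seed, so a rerun with the same config reproduces the manifest's
content hashes exactly.  (Hashes cover array/table *contents*; zip container
bytes may embed timestamps.)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    RDM,
    ConditionSet,
    RDMError,
    RDMStack,
    rdm_from_feature_vectors,
    vectorize_upper,
)
from .decoding import DecodingConfig, TrialArray, neural_rdm_stack
from .hypotheses import FEATURES, HypothesisRDMs, build_hypothesis_rdms
from .inference import (
    bootstrap_peak_latency,
    cluster_permutation_test,
    model_hyp_partial_test,
    noise_ceiling,
    paired_latency_test,
    rsa_timecourse,
    variance_partitioning,
)
from .synth import (
    ModelRecipe,
    SimulationConfig,
    early_layer_recipe,
    late_layer_recipe,
    sample_latent_features,
    save_ground_truth,
    simulate_model_features,
    simulate_subjects,
)

#: word-embedding-like space: real-world size encoded amid a large amount of
#: unrelated semantic variance
SEMANTIC_RECIPE = ModelRecipe(weights={"real_world_size": 1.0}, noise_sd=1.5)

# offsets applied to the global seed, one per random stage
SEED_OFFSETS = {
    "conditions": 11,
    "trials": 101,
    "decode": 211,
    "bootstrap": 307,
    "cluster": 401,
    "model_features": 503,
    "model_test": 601,
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end run (demo scale by default)."""

    seed: int
    n_subjects: int = 3
    simulation: SimulationConfig = dataclasses.field(
        default_factory=lambda: SimulationConfig()
    )
    decoding: DecodingConfig = dataclasses.field(default_factory=DecodingConfig)
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    n_shuffles: int = 1000
    cluster_forming_p: float = 0.05
    peak_window_ms: tuple[float, float] | None = None  # None -> post-onset epoch

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("pipeline config must set a seed")
        sim = SimulationConfig.from_dict(raw.pop("simulation", {}))
        dec = DecodingConfig(**raw.pop("decoding", {}))
        if "peak_window_ms" in raw and raw["peak_window_ms"] is not None:
            raw["peak_window_ms"] = tuple(raw["peak_window_ms"])
        return cls(simulation=sim, decoding=dec, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        if self.peak_window_ms is not None:
            d["peak_window_ms"] = list(self.peak_window_ms)
        return d


def _json_default(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _content_hash(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
        h.update(str(obj.shape).encode())
    elif isinstance(obj, pd.DataFrame):
        h.update(obj.to_csv().encode())
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()


def read_feature_matrix(
    path, conditions: ConditionSet | None = None
) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a per-condition feature matrix from CSV (id column) or NPZ.

    Rows are re-aligned to the ConditionSet id order when one is given;
    duplicate or missing ids raise.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            ids = tuple(str(i) for i in z["ids"].tolist())
            matrix = np.asarray(z["matrix"], dtype=float)
    else:
        df = pd.read_csv(path)
        if "id" not in df.columns:
            raise RDMError("feature table must have an 'id' column")
        ids = tuple(str(i) for i in df["id"])
        matrix = df.drop(columns=["id"]).to_numpy(dtype=float)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise RDMError(f"duplicate feature-matrix ids: {dupes[:5]}")
    if matrix.shape[0] != len(ids):
        raise RDMError("ragged feature matrix: rows do not match ids")
    if conditions is not None:
        missing = [i for i in conditions.ids if i not in set(ids)]
        if missing:
            raise RDMError(f"feature matrix missing ids: {missing[:5]}")
        order = [ids.index(i) for i in conditions.ids]
        return conditions.ids, matrix[order]
    return ids, matrix


def write_feature_matrix(path, ids: Sequence[str], matrix: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, ids=np.asarray(list(ids), dtype="U"), matrix=matrix)
    else:
        df = pd.DataFrame(matrix)
        df.insert(0, "id", list(ids))
        df.to_csv(path, index=False)


def _timecourse_frame(tc) -> pd.DataFrame:
    df = pd.DataFrame(
        tc.values.T, columns=[f"sub{si:02d}" for si in range(tc.values.shape[0])]
    )
    df.insert(0, "time_ms", tc.time_axis)
    return df


def run_end_to_end(config: PipelineConfig, outdir) -> dict:
    """Execute every stage on synthetic data and write the report bundle.

    Returns the results dictionary (also written to ``results.json``).
    Inference stages are skipped with an explicit notice when their
    resampling count is set to 0.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {k: seed + v for k, v in SEED_OFFSETS.items()},
        "artifacts": {},
        "notices": [],
    }
    results: dict = {"seed": seed}

    def record(name: str, obj, path: Path | None = None) -> None:
        manifest["artifacts"][name] = {
            "sha256": _content_hash(obj),
            "path": str(path.name) if path is not None else None,
        }

    # --- stage 1: conditions ------------------------------------------------
    conditions = sample_latent_features(
        config.simulation.n_conditions, seed + SEED_OFFSETS["conditions"]
    )
    cpath = outdir / "conditions.csv"
    conditions.to_csv(cpath)
    record("conditions", conditions.features, cpath)

    # --- stage 2: trials ----------------------------------------------------
    datasets = simulate_subjects(
        conditions, config.simulation, config.n_subjects, seed + SEED_OFFSETS["trials"]
    )
    for s, ds in enumerate(datasets):
        tpath = outdir / f"trials_sub{s:02d}.npz"
        ds.trials.to_npz(tpath)
        record(f"trials_sub{s:02d}", ds.trials.data, tpath)
    save_ground_truth(datasets[0].ground_truth, outdir / "ground_truth_sub00.json")

    # --- stage 3: decoding --------------------------------------------------
    dec_cfg = dataclasses.replace(config.decoding, seed=seed + SEED_OFFSETS["decode"])
    stacks = [
        neural_rdm_stack(
            ds.trials, dec_cfg, conditions=conditions.ids, subject=f"sub{s:02d}"
        )
        for s, ds in enumerate(datasets)
    ]
    neural = RDMStack.from_subject_stacks(stacks)
    npath = outdir / "neural_rdms.npz"
    neural.to_npz(npath)
    record("neural_rdms", neural.values, npath)

    # --- stage 4: hypothesis RDMs ------------------------------------------
    hyps = build_hypothesis_rdms(conditions)
    for f in FEATURES:
        hpath = outdir / f"hyp_rdm_{f}.npz"
        hyps[f].to_npz(hpath)
        record(f"hyp_rdm_{f}", hyps[f].values, hpath)
    hyps.intercorrelations.to_csv(outdir / "intercorrelations.csv")
    results["hyp_intercorrelations"] = hyps.intercorrelations.round(6).to_dict()

    # --- stage 5: EEG x HYP partial RSA + inference -------------------------
    window = config.peak_window_ms or (0.0, float(neural.time_axis[-1]))
    results["timecourses"] = {}
    results["clusters"] = {}
    results["peak_latency_ms"] = {}
    latencies = {}
    for f in FEATURES:
        others = [g for g in FEATURES if g != f]
        tc = rsa_timecourse(
            neural,
            hyps[f],
            [hyps[g] for g in others],
            target_name=f,
            control_names=others,
        )
        _timecourse_frame(tc).to_csv(outdir / f"timecourse_{f}.csv", index=False)
        record(f"timecourse_{f}", tc.values)
        results["timecourses"][f] = {
            "group_mean_peak": float(np.max(tc.group_mean)),
            "group_mean_peak_ms": float(tc.time_axis[int(np.argmax(tc.group_mean))]),
        }
        if config.n_permutations > 0:
            ct = cluster_permutation_test(
                tc,
                n_permutations=config.n_permutations,
                cluster_forming_p=config.cluster_forming_p,
                seed=seed + SEED_OFFSETS["cluster"],
            )
            results["clusters"][f] = [
                dataclasses.asdict(c) for c in ct.clusters
            ]
        else:
            manifest["notices"].append(
                f"cluster permutation test skipped for {f} (n_permutations=0)"
            )
        if config.n_bootstrap > 0:
            pl = bootstrap_peak_latency(
                neural,
                hyps[f],
                [hyps[g] for g in others],
                window=window,
                n_bootstrap=config.n_bootstrap,
                seed=seed + SEED_OFFSETS["bootstrap"],
                target_name=f,
            )
            latencies[f] = pl
            results["peak_latency_ms"][f] = {
                "group_mean": pl.group_mean,
                "group_sem": pl.group_sem,
                "subject_means": pl.subject_means.tolist(),
            }
        else:
            manifest["notices"].append(
                f"bootstrap peak latency skipped for {f} (n_bootstrap=0)"
            )

    if latencies:
        results["latency_order"] = sorted(
            FEATURES, key=lambda f: latencies[f].group_mean
        )
        results["paired_latency_tests"] = {}
        for i, fa in enumerate(FEATURES):
            for fb in FEATURES[i + 1 :]:
                t, df, p = paired_latency_test(latencies[fa], latencies[fb])
                results["paired_latency_tests"][f"{fa}_vs_{fb}"] = {
                    "t": t,
                    "df": df,
                    "p": p,
                }

    # --- stage 6: model feature spaces --------------------------------------
    results["model_tests"] = {}
    model_rdms = {}
    for name, recipe in (
        ("early_layer", early_layer_recipe()),
        ("late_layer", late_layer_recipe()),
    ):
        x = simulate_model_features(
            conditions, recipe, seed + SEED_OFFSETS["model_features"]
        )
        write_feature_matrix(outdir / f"model_features_{name}.npz", conditions.ids, x)
        rdm = rdm_from_feature_vectors(conditions.ids, x)
        model_rdms[name] = rdm
        rdm.to_npz(outdir / f"model_rdm_{name}.npz")
        record(f"model_rdm_{name}", rdm.values)
        if config.n_shuffles > 0:
            bt = model_hyp_partial_test(
                rdm, hyps, n_shuffles=config.n_shuffles,
                seed=seed + SEED_OFFSETS["model_test"],
            )
            results["model_tests"][name] = {
                "observed": bt.observed,
                "critical": bt.critical,
                "significant": bt.significant,
            }
        else:
            manifest["notices"].append(
                f"model-vs-hypothesis shuffle test skipped for {name} (n_shuffles=0)"
            )

    # --- stage 7: variance partitioning at the size peak --------------------
    peak_ti = int(
        np.argmin(
            np.abs(
                neural.time_axis
                - results["timecourses"]["real_world_size"]["group_mean_peak_ms"]
            )
        )
    )
    group_vec = np.mean(
        [neural.vectors(si)[peak_ti] for si in range(neural.n_subjects)], axis=0
    )
    semantic_rdm = rdm_from_feature_vectors(
        conditions.ids,
        simulate_model_features(
            conditions, SEMANTIC_RECIPE, seed + SEED_OFFSETS["model_features"] + 1
        ),
    )
    semantic_rdm.to_npz(outdir / "model_rdm_semantic.npz")
    regressors = {f: vectorize_upper(hyps[f]).values for f in FEATURES}
    regressors["semantic"] = vectorize_upper(semantic_rdm).values
    vp = variance_partitioning(group_vec, regressors)
    results["variance_partition"] = {
        "r2_full": vp.r2_full,
        "components": {
            "+".join(sorted(k)): v for k, v in vp.components.items()
        },
        "at_time_ms": float(neural.time_axis[peak_ti]),
    }

    # --- stage 8: noise ceiling --------------------------------------------
    if neural.n_subjects >= 3:
        lower, upper = noise_ceiling(neural)
        nc = pd.DataFrame(
            {"time_ms": neural.time_axis, "lower": lower, "upper": upper}
        )
        nc.to_csv(outdir / "noise_ceiling.csv", index=False)
        results["noise_ceiling_max_upper"] = float(np.max(upper))

    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=_json_default)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(outdir / "report.md", "w") as fh:
        fh.write(render_report(results))
    return results


def render_report(results: Mapping) -> str:
    """Human-readable markdown summary of an end-to-end results dictionary."""
    lines = ["# RSA pipeline report", ""]
    if "latency_order" in results:
        order = " < ".join(results["latency_order"])
        lines += [f"Recovered peak-latency order: **{order}**", ""]
    if results.get("peak_latency_ms"):
        lines += ["## Bootstrap peak latencies (ms)", ""]
        for f, d in results["peak_latency_ms"].items():
            lines.append(
                f"- {f}: {d['group_mean']:.1f} ± {d['group_sem']:.1f} (group mean ± SEM)"
            )
        lines.append("")
    if results.get("clusters"):
        lines += ["## Significant clusters (p < 0.05)", ""]
        for f, cs in results["clusters"].items():
            sig = [c for c in cs if c["p_value"] < 0.05]
            if sig:
                spans = ", ".join(
                    f"{c['start_ms']:.0f}-{c['end_ms']:.0f} ms (p={c['p_value']:.3f})"
                    for c in sig
                )
            else:
                spans = "none"
            lines.append(f"- {f}: {spans}")
        lines.append("")
    if results.get("model_tests"):
        lines += ["## Model RDM x hypothesis RDM partial correlations", ""]
        for name, d in results["model_tests"].items():
            flags = ", ".join(
                f"{f}: r={d['observed'][f]:.3f}{'*' if d['significant'][f] else ''}"
                for f in d["observed"]
            )
            lines.append(f"- {name}: {flags}")
        lines += ["", "(* = exceeds the 95th percentile of the shuffle null)", ""]
    if "variance_partition" in results:
        vp = results["variance_partition"]
        lines += [
            "## Variance partitioning",
            "",
            f"Full-model R² = {vp['r2_full']:.4f} at {vp['at_time_ms']:.0f} ms",
            "",
        ]
    return "\n".join(lines)
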