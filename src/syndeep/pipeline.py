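"""End-to-end pipeline: simulate -> label -> featurize -> train ->
evaluate / ablate / compare, with a manifest that records the seed
derivation and content hashes of every artifact so any output can be
reproduced from its recorded inputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (METRIC_NAMES, ablation_report, ablation_table,
                         cross_validate, mcnemar, stratified_kfold)
from .featnet import FeatureSchema, build_design_matrix
from .labels import EXCLUDED, aggregate_replicates, balance_classes, write_labels
from .models import MODEL_KINDS, ModelSpec
from .synth import (SynthConfig, center_signal, generate_universe, plant_labels,
                    random_signal)
from .universe import save_universe

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "label", "featurize", "train", "evaluate", "ablate", "compare")


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the single pipeline seed (recorded in
    the manifest; the derivation is the seed sequence of (root, stage index))."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([root_seed, idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-serializable."""

    out_dir: str
    synth: SynthConfig = field(default_factory=SynthConfig)
    signal_scale: float = 1.0
    signal_intercept: float = 0.0
    models: tuple[str, ...] = MODEL_KINDS
    group: int = 6
    groups: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    k: int = 10
    seed: int = 0
    mlp_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "out_dir" not in raw:
            raise ValueError("config error: missing required field 'out_dir'")
        if "synth" in raw and isinstance(raw["synth"], dict):
            raw["synth"] = SynthConfig(**raw["synth"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config error: unknown fields {sorted(unknown)}")
        for key in ("models", "groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _spec_for(kind: str, config: RunConfig, seed: int) -> ModelSpec:
    overrides = config.mlp_overrides if kind in ("syndeep_mlp", "snn") else {}
    return ModelSpec(kind, dict(overrides), seed=seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest.

    A stage failure aborts with the failing stage named; artifacts written
    before the failure are listed in the exception's manifest fragment.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "artifacts": {},
    }

    def register(name, path):
        manifest["artifacts"][name] = {"path": path, "sha256": _sha256(path)}

    stage = "simulate"
    try:
        synth_cfg = dataclasses.replace(config.synth,
                                        seed=stage_seed(config.seed, "simulate"))
        universe = generate_universe(synth_cfg)
        schema = FeatureSchema.from_universe(universe)
        signal = random_signal(schema, seed=synth_cfg.seed,
                               scale=config.signal_scale,
                               intercept=config.signal_intercept)
        signal = center_signal(universe, signal, synth_cfg)
        records = plant_labels(universe, signal, synth_cfg)
        udir = os.path.join(config.out_dir, "universe")
        save_universe(universe, udir)
        combos = os.path.join(config.out_dir, "combos.tsv")
        pd.DataFrame(
            [(r.drug_i, r.drug_j, r.cell_line, r.combo_score) for r in records],
            columns=["drug_i", "drug_j", "cell_line", "comboscore"],
        ).to_csv(combos, sep="\t", index=False)
        register("combos", combos)

        stage = "label"
        labeled = aggregate_replicates(records, drug_order=universe.drugs)
        labeled = [r for r in labeled if r.label != EXCLUDED]
        balanced = balance_classes(labeled, seed=stage_seed(config.seed, "label"))
        labels_path = os.path.join(config.out_dir, "labels.tsv")
        write_labels(balanced, labels_path)
        register("labels", labels_path)

        stage = "featurize"
        X, y = build_design_matrix(universe, balanced, config.group, schema=schema)
        feats_path = os.path.join(config.out_dir, f"features_group{config.group}.npz")
        np.savez_compressed(feats_path, X=X, y=y)
        register("features", feats_path)

        stage = "evaluate"
        eval_seed = stage_seed(config.seed, "evaluate")
        fold_assignment = stratified_kfold(y, k=config.k, seed=eval_seed)

        stage = "compare"
        per_model = {}
        pooled = {}
        for kind in config.models:
            spec = _spec_for(kind, config, eval_seed)
            cv = cross_validate(spec, balanced, universe, config.group,
                                k=config.k, seed=eval_seed, schema=schema,
                                fold_assignment=fold_assignment)
            per_model[kind] = cv.mean.as_dict()
            pooled[kind] = cv.pooled_predictions
        metrics_path = os.path.join(config.out_dir, "metrics.tsv")
        pd.DataFrame.from_dict(per_model, orient="index",
                               columns=list(METRIC_NAMES)).to_csv(metrics_path, sep="\t")
        register("metrics", metrics_path)

        labels_vec = np.asarray([r.label for r in balanced])
        rows = []
        for a in config.models:
            for b in config.models:
                if a == b:
                    continue
                res = mcnemar(pooled[a], pooled[b], labels_vec)
                rows.append((a, b, res.b, res.c, res.statistic, res.p_value,
                             res.applicable))
        mcn_path = os.path.join(config.out_dir, "mcnemar.tsv")
        pd.DataFrame(rows, columns=["model_a", "model_b", "B", "C",
                                    "statistic", "p_value", "applicable"]
                     ).to_csv(mcn_path, sep="\t", index=False)
        register("mcnemar", mcn_path)

        stage = "ablate"
        syndeep = _spec_for("syndeep_mlp", config, eval_seed)
        report = ablation_report(balanced, universe, syndeep, seed=eval_seed,
                                 k=config.k, groups=config.groups, schema=schema)
        abl_path = os.path.join(config.out_dir, "ablation.tsv")
        ablation_table(report).to_csv(abl_path, sep="\t")
        register("ablation", abl_path)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc} "
            f"(partial artifacts: {sorted(manifest['artifacts'])})"
        ) from exc

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
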