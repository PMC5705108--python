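"""Declarative pipeline: simulate -> preprocess -> contrast -> statistics.

A run configuration is a YAML/dict tree::

    seed: 1
    out_dir: results/run1
    stages:
      - {stage: simulate, name: dsA, params: {n_regions: 20, ...}}
      - {stage: compare, name: AvsB, a: dsA, b: dsB, n_perm: 1000}
      ...

Each stage draws its own seed from the global seed by stable hashing of
the stage name, so adding or reordering stages never shifts another
stage's randomness. ``run`` executes the stages in order and writes a
manifest enumerating every artifact with its producing stage, parameters
and seed; rerunning the same config reproduces the outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Sequence

import yaml

from . import classify as _classify
from . import consistency as _consistency
from . import preprocess as _preprocess
from . import reproducibility as _repro
from .connectivity import collection_fc, write_fc_wide
from .contrast import welch_contrast
from .io import read_scan_collection, write_scan_collection
from .records import ScanRecord
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage_name: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage_name}".encode()) & 0x7FFFFFFF


def _require(stage: dict, *keys: str) -> list:
    missing = [k for k in keys if k not in stage]
    if missing:
        raise StageError(f"stage {stage.get('stage')!r} missing key(s) {missing}")
    return [stage[k] for k in keys]


class PipelineRun:
    def __init__(self, config: dict):
        self.config = config
        self.seed = int(config.get("seed", 0))
        self.out_dir = Path(config.get("out_dir", "pipeline_out"))
        self.collections: dict[str, list[ScanRecord]] = {}
        self.manifest: dict = {"seed": self.seed, "stages": []}

    def _get_collection(self, name: str) -> list[ScanRecord]:
        if name not in self.collections:
            raise StageError(f"stage references unknown collection {name!r}")
        return self.collections[name]

    def execute(self) -> dict:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        for stage in self.config.get("stages", []):
            kind = stage.get("stage")
            name = stage.get("name", kind)
            seed = stage_seed(self.seed, str(name))
            handler = getattr(self, f"_stage_{kind}", None)
            if handler is None:
                raise StageError(f"unknown stage kind {kind!r}")
            try:
                outputs = handler(stage, name, seed)
            except StageError:
                raise
            except Exception as err:
                raise StageError(f"stage {name!r} ({kind}) failed: {err}") from err
            self.manifest["stages"].append(
                {"stage": kind, "name": name, "seed": seed, "params": stage, "outputs": outputs}
            )
        manifest_path = self.out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=1, default=str))
        return self.manifest

    # ---- stage handlers ------------------------------------------------

    def _stage_load(self, stage: dict, name: str, seed: int) -> list[str]:
        (path,) = _require(stage, "path")
        self.collections[name] = read_scan_collection(path)
        return []

    def _stage_simulate(self, stage: dict, name: str, seed: int) -> list[str]:
        params = dict(stage.get("params", {}))
        params.setdefault("dataset_id", name)
        params.setdefault("seed", seed)
        if "effect_pairs" in params:
            params["effect_pairs"] = tuple(
                (tuple(e["pairs"]), float(e["delta_z"])) for e in params["effect_pairs"]
            )
        scans, truth = simulate_cohort(SimConfig(**params))
        self.collections[name] = scans
        out = self.out_dir / name
        write_scan_collection(scans, out)
        truth.to_json(out / "ground_truth.json")
        return [str(out)]

    def _stage_preprocess(self, stage: dict, name: str, seed: int) -> list[str]:
        source, op = _require(stage, "collection", "op")
        scans = self._get_collection(source)
        if op == "gsr":
            func = _preprocess.global_signal_regress
        elif op == "bandpass":
            low, high = stage.get("low_hz", 0.01), stage.get("high_hz", 0.1)
            func = lambda ts: _preprocess.ideal_bandpass(ts, low, high)  # noqa: E731
        elif op == "decimate":
            func = _preprocess.decimate_double_tr
        else:
            raise StageError(f"unknown preprocess op {op!r}")
        self.collections[name] = [s.map_timeseries(func) for s in scans]
        return []

    def _stage_fc(self, stage: dict, name: str, seed: int) -> list[str]:
        (source,) = _require(stage, "collection")
        out = self.out_dir / f"{name}_fc.tsv"
        write_fc_wide(self._get_collection(source), out)
        return [str(out)]

    def _stage_contrast(self, stage: dict, name: str, seed: int) -> list[str]:
        (source,) = _require(stage, "collection")
        res = welch_contrast(self._get_collection(source))
        out = self.out_dir / f"{name}_contrast.tsv"
        res.write(out)
        return [str(out)]

    def _stage_compare(self, stage: dict, name: str, seed: int) -> list[str]:
        a, b = _require(stage, "a", "b")
        res = _repro.permutation_p(
            self._get_collection(a),
            self._get_collection(b),
            n_perm=int(stage.get("n_perm", 1000)),
            seed=seed,
            perm_unit=stage.get("perm_unit", "subject"),
        )
        out = self.out_dir / f"{name}_compare.json"
        out.write_text(
            json.dumps(
                {
                    "r": res.r_value,
                    "p_perm": res.p_perm,
                    "p_perm_corrected": res.p_perm_corrected,
                    "n_permutations": res.n_permutations,
                    "dataset_pair": list(res.dataset_pair),
                },
                indent=1,
            )
        )
        null_out = self.out_dir / f"{name}_null.tsv"
        import numpy as np

        np.savetxt(null_out, res.null_sample, fmt="%.10g", header="r_perm", comments="")
        scatter_out = self.out_dir / f"{name}_scatter.tsv"
        _repro.scatter_frame(res).to_csv(scatter_out, sep="\t", index=False)
        return [str(out), str(null_out), str(scatter_out)]

    def _stage_splits(self, stage: dict, name: str, seed: int) -> list[str]:
        (source,) = _require(stage, "collection")
        batch = _repro.split_batch(
            self._get_collection(source),
            mode=stage.get("mode", "split_subjects"),
            n_splits=int(stage.get("n_splits", 200)),
            n_perm=int(stage.get("n_perm", 1000)),
            seed=seed,
        )
        out = self.out_dir / f"{name}_splits.json"
        summary = batch.summary()
        summary["r_values"] = batch.r_values.tolist()
        summary["p_values"] = batch.p_values.tolist()
        out.write_text(json.dumps(summary, indent=1))
        return [str(out)]

    def _stage_minmaxp(self, stage: dict, name: str, seed: int) -> list[str]:
        (sources,) = _require(stage, "collections")
        res = _consistency.consistency_permutation_test(
            [self._get_collection(s) for s in sources],
            direction=stage.get("direction", "plus"),
            n_perm=int(stage.get("n_perm", 1000)),
            seed=seed,
        )
        table_out = self.out_dir / f"{name}_table.tsv"
        res.ranked_pairs.to_csv(table_out, sep="\t", index=False)
        out = self.out_dir / f"{name}_minmaxp.json"
        out.write_text(
            json.dumps(
                {
                    "direction": res.direction,
                    "min_max_p": res.min_max_p,
                    "p_of_min_max_p": res.p_of_min_max_p,
                    "n_permutations": res.n_permutations,
                },
                indent=1,
            )
        )
        return [str(table_out), str(out)]

    def _stage_classify(self, stage: dict, name: str, seed: int) -> list[str]:
        train, test = _require(stage, "train", "test")
        res = _classify.evaluate(
            self._get_collection(train),
            self._get_collection(test),
            classifier=stage.get("classifier", "linear_svm"),
            n_features=int(stage.get("n_features", 100)),
        )
        out = self.out_dir / f"{name}_eval.json"
        out.write_text(
            json.dumps(
                {
                    "train_id": res.train_id,
                    "test_id": res.test_id,
                    "classifier": res.classifier,
                    "n_features": res.n_features,
                    "acc_nc": res.acc_nc,
                    "acc_pd": res.acc_pd,
                    "a_acc": res.a_acc,
                },
                indent=1,
            )
        )
        return [str(out)]

    def _stage_classify_splits(self, stage: dict, name: str, seed: int) -> list[str]:
        (source,) = _require(stage, "collection")
        batch = _classify.split_half_batch(
            self._get_collection(source),
            classifier=stage.get("classifier", "linear_svm"),
            n_features=int(stage.get("n_features", 100)),
            n_repeats=int(stage.get("n_repeats", 500)),
            seed=seed,
        )
        out = self.out_dir / f"{name}_splithalf.json"
        out.write_text(
            json.dumps(
                {
                    "mean_a_acc": batch.mean,
                    "sd_a_acc": batch.sd,
                    "n_repeats": batch.n_repeats,
                    "classifier": batch.classifier,
                    "n_features": batch.n_features,
                    "a_acc_values": batch.a_acc_values.tolist(),
                },
                indent=1,
            )
        )
        return [str(out)]


def run(config: dict | str | Path) -> dict:
    """Execute a run configuration (dict, YAML text, or YAML file path)."""
    if isinstance(config, (str, Path)) and Path(config).exists():
        config = yaml.safe_load(Path(config).read_text())
    elif isinstance(config, str):
        config = yaml.safe_load(config)
    return PipelineRun(dict(config)).execute()
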