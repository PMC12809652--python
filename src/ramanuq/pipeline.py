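"""End-to-end pipeline stages with a content-addressed manifest.

Stages: simulate -> preprocess -> train -> calibrate -> evaluate (-> ablate,
report). Each stage reads the previous stage's artifacts from the run
directory, writes its own, and appends a manifest entry recording the config
hash, the derived stage seed and the SHA-256 of every input and output, so
an unchanged config + seed reproduces identical artifact hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig, stage_seed
from .conformal import ConformalAdjustment, calibrate, default_z
from .evaluate import ablate_conformalization, coverage_curve, render_coverage_table
from .preprocess import preprocess_dataset, read_dataset_matrix, write_dataset_matrix
from .synthetic import generate_dataset, read_dataset, write_dataset
from .uq import load_model, train as train_uq

logger = logging.getLogger(__name__)

__all__ = ["DataError", "STAGES", "run_stage", "run_demo"]

STAGES = ("simulate", "preprocess", "train", "calibrate", "evaluate", "ablate", "report")


class DataError(RuntimeError):
    """Missing or inconsistent upstream artifacts."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _record(out_dir: Path, stage: str, config: RunConfig, inputs: list[Path],
            outputs: list[Path]) -> None:
    manifest_path = out_dir / "manifest.json"
    entries = json.loads(manifest_path.read_text()) if manifest_path.exists() else []
    cfg_hash = hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()
    entries.append(
        {
            "stage": stage,
            "config_hash": cfg_hash,
            "seed": stage_seed(config.seed, stage),
            "inputs": {str(p.relative_to(out_dir)): _sha256(p) for p in inputs},
            "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
        }
    )
    manifest_path.write_text(json.dumps(entries, indent=2))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DataError(
            f"stage '{needed_by}' requires artifact {path} from upstream stage "
            f"'{stage}' — run it first"
        )
    return path


def _splits(n: int, config: RunConfig, seed: int) -> dict[str, list[int]]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(config.test_fraction * n))
    n_cal = config.cv.calibration_size
    if n_test + n_cal >= n:
        raise DataError(
            f"cannot split {n} samples into test={n_test} + calibration={n_cal} + training"
        )
    return {
        "test": sorted(int(i) for i in order[:n_test]),
        "calibration": sorted(int(i) for i in order[n_test : n_test + n_cal]),
        "train": sorted(int(i) for i in order[n_test + n_cal :]),
    }


def run_stage(stage: str, config: RunConfig) -> list[Path]:
    """Run one named pipeline stage; returns the paths it wrote."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, stage)
    logger.info("stage %s (seed %d) -> %s", stage, seed, out_dir)

    if stage == "simulate":
        syn = config.synthetic.model_copy(update={"seed": seed})
        samples = generate_dataset(syn)
        sim_dir = out_dir / "simulate"
        write_dataset(samples, sim_dir, syn)
        outputs = sorted(sim_dir.glob("*"))
        _record(out_dir, stage, config, [], outputs)
        return outputs

    if stage == "preprocess":
        sim_dir = _require(out_dir / "simulate" / "manifest.json", "simulate", stage).parent
        samples = read_dataset(sim_dir)
        X, y = preprocess_dataset(samples, config.preprocess)
        pre_dir = out_dir / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        matrix = write_dataset_matrix(X, y, pre_dir / "matrix.csv",
                                      grid=config.preprocess.target_grid())
        _record(out_dir, stage, config, [sim_dir / "manifest.json"], [matrix])
        return [matrix]

    matrix_path = out_dir / "preprocess" / "matrix.csv"

    if stage == "train":
        _require(matrix_path, "preprocess", stage)
        X, y = read_dataset_matrix(matrix_path)
        splits = _splits(y.size, config, seed)
        splits_path = out_dir / "train" / "splits.json"
        splits_path.parent.mkdir(exist_ok=True)
        splits_path.write_text(json.dumps(splits, indent=2))
        backbone = config.backbone.model_copy(update={"input_channels": X.shape[1]})
        outputs = [splits_path]
        tr = splits["train"]
        for method in config.methods:
            tcfg = config.training.model_copy(update={"seed": stage_seed(seed, method)})
            model = train_uq(method, (X[tr], y[tr]), tcfg, backbone)
            outputs.append(model.save(out_dir / "train" / method) / "config.json")
        _record(out_dir, stage, config, [matrix_path], outputs)
        return outputs

    if stage == "calibrate":
        _require(matrix_path, "preprocess", stage)
        splits_path = _require(out_dir / "train" / "splits.json", "train", stage)
        X, y = read_dataset_matrix(matrix_path)
        splits = json.loads(splits_path.read_text())
        cal = splits["calibration"]
        z = config.conformal.z or default_z(config.conformal.alpha)
        outputs = []
        for method in config.methods:
            model_dir = _require(out_dir / "train" / method / "config.json", "train", stage).parent
            model = load_model(model_dir)
            adj = calibrate(model, X[cal], y[cal], alpha=config.conformal.alpha, z=z)
            path = out_dir / "calibrate" / f"{method}.json"
            path.parent.mkdir(exist_ok=True)
            adj.to_json(path, model_ref=str(model_dir))
            outputs.append(path)
        _record(out_dir, stage, config, [matrix_path, splits_path], outputs)
        return outputs

    if stage in ("evaluate", "ablate"):
        _require(matrix_path, "preprocess", stage)
        splits_path = _require(out_dir / "train" / "splits.json", "train", stage)
        X, y = read_dataset_matrix(matrix_path)
        splits = json.loads(splits_path.read_text())
        te, cal = splits["test"], splits["calibration"]
        outputs = []
        if stage == "evaluate":
            from .evaluate import DEFAULT_LEVELS

            levels = tuple(config.levels) if config.levels else DEFAULT_LEVELS
            for method in config.methods:
                model = load_model(
                    _require(out_dir / "train" / method / "config.json", "train", stage).parent
                )
                if config.no_conformal:
                    adj = None
                else:
                    adj_path = _require(
                        out_dir / "calibrate" / f"{method}.json", "calibrate", stage
                    )
                    adj = ConformalAdjustment.from_json(adj_path)
                mu, sig = model.predict(X[te])
                report = coverage_curve(y[te], mu, sig, adj, levels)
                path = out_dir / "evaluate" / f"{method}.json"
                path.parent.mkdir(exist_ok=True)
                report.to_json(path)
                outputs.append(path)
        else:
            models = {
                m: load_model(
                    _require(out_dir / "train" / m / "config.json", "train", stage).parent
                )
                for m in config.methods
            }
            tables = ablate_conformalization(
                models, X[cal], y[cal], X[te], y[te], alpha=config.conformal.alpha
            )
            path = out_dir / "ablate" / "coverage_tables.json"
            path.parent.mkdir(exist_ok=True)
            path.write_text(
                json.dumps({k: tables[k].to_dict() for k in ("after", "before", "delta")},
                           indent=2)
            )
            text = out_dir / "ablate" / "coverage_tables.txt"
            text.write_text(render_coverage_table(tables))
            outputs = [path, text]
        _record(out_dir, stage, config, [matrix_path, splits_path], outputs)
        return outputs

    # report: human-readable roll-up of whatever evaluate/ablate produced
    eval_dir = out_dir / "evaluate"
    ablate_txt = out_dir / "ablate" / "coverage_tables.txt"
    if not eval_dir.exists() and not ablate_txt.exists():
        raise DataError("stage 'report' needs 'evaluate' or 'ablate' artifacts")
    lines = []
    for path in sorted(eval_dir.glob("*.json")) if eval_dir.exists() else []:
        rep = json.loads(path.read_text())
        lines.append(
            f"{path.stem}: coverage(90%)={rep['coverage_by_level'].get('0.9'):.3f} "
            f"calib-RMSE={rep['calibration_rmse']:.3f} "
            f"sharpness={rep['sharpness']:.3f} R2={rep['accuracy']['r2']:.3f}"
        )
    if ablate_txt.exists():
        lines.append("")
        lines.append(ablate_txt.read_text())
    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    _record(out_dir, "report", config, [], [report_path])
    return [report_path]


def run_demo(config: RunConfig) -> Path:
    """Tiny end-to-end run: simulate through report with the given config."""
    for stage in ("simulate", "preprocess", "train", "calibrate", "evaluate", "report"):
        run_stage(stage, config)
    return Path(config.output_dir) / "report.txt"
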