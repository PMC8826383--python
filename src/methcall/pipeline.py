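"""Pipeline orchestration: simulate -> extract -> train -> call-reads ->
call-positions -> evaluate, with per-stage manifests and resume.

Each stage writes its outputs plus a ``<stage>.manifest.json`` recording the
config hash, the stage seed, and SHA-256 hashes of its inputs and outputs.
Re-running a stage whose manifest matches the current inputs is a no-op;
deleting an intermediate output re-runs only from the producing stage on.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .caller import (
    BetaMixtureParams,
    DegenerateFitError,
    call_positions,
    estimate_mixture_params,
    group_reads_by_position,
)
from .config import RunConfig, stage_seed
from .features import build_windows
from .metrics import ConfusionCounts, compute_metrics, roc_auc
from .nn.model import (
    ModelSpec,
    ReadClassifier,
    TrainingConfig,
    call_reads,
    train_model,
    windows_to_tensors,
)
from .simulate import SimulationConfig, preset_config, simulate_read, split_dataset

log = logging.getLogger("methcall")

STAGE_ORDER = ["simulate", "extract", "train", "call-reads", "call-positions", "evaluate"]


class MissingArtifactError(FileNotFoundError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_tree(path: Path) -> str:
    if path.is_dir():
        h = hashlib.sha256()
        for p in sorted(path.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(_sha256(p).encode())
        return h.hexdigest()
    return _sha256(path)


class Stage:
    name: str
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()

    def run(self, run_dir: Path, cfg: RunConfig) -> None:
        raise NotImplementedError


def _require(run_dir: Path, relpath: str, producer: str | None) -> Path:
    path = run_dir / relpath
    if not path.exists():
        origin = f" (produced by stage {producer!r})" if producer else ""
        raise MissingArtifactError(f"missing input {relpath}{origin}")
    return path


def _sim_config(cfg: RunConfig, seed: int) -> SimulationConfig:
    return preset_config(
        cfg.preset,
        l=cfg.l,
        n_reads=cfg.n_reads,
        coverage=cfg.coverage,
        methylation_proportion=cfg.methylation_proportion,
        signal_shift=cfg.signal_shift,
        motif=cfg.motif,
        target_offset=cfg.target_offset,
        seed=seed,
    )


class SimulateStage(Stage):
    name = "simulate"
    outputs = ("events.tsv", "errors.tsv", "truth_reads.tsv")

    def run(self, run_dir: Path, cfg: RunConfig) -> None:
        seed = stage_seed(cfg.seed, self.name)
        sim = _sim_config(cfg, seed)
        rng = np.random.default_rng(seed)
        from .simulate import _pore_model  # frozen pore table for the whole run

        pore = _pore_model(rng, sim)
        n_sites = max(1, sim.n_reads // sim.coverage)
        spacing = sim.l + 2 * sim.read_pad + 10
        all_events, all_errors, labels = [], [], []
        for i in range(sim.n_reads):
            label = i % 2  # 50/50 class balance
            events, records = simulate_read(
                sim, label, rng, pore=pore, read_id=f"r{i:06d}",
                start=(i % n_sites) * spacing,
            )
            all_events.append(events)
            all_errors.extend(records)
            labels.append((f"r{i:06d}", label))
        io.write_events(run_dir / "events.tsv", all_events)
        io.write_errors(run_dir / "errors.tsv", all_errors)
        with open(run_dir / "truth_reads.tsv", "w") as fh:
            fh.write("read_id\tlabel\n")
            for rid, lab in labels:
                fh.write(f"{rid}\t{lab}\n")
        log.info("simulate: %d reads, %d error records", len(all_events), len(all_errors))


class ExtractStage(Stage):
    name = "extract"
    inputs = ("events.tsv", "errors.tsv")
    outputs = ("features.tsv",)

    def run(self, run_dir: Path, cfg: RunConfig) -> None:
        events = io.read_events(_require(run_dir, "events.tsv", "simulate"))
        errors = io.read_errors(_require(run_dir, "errors.tsv", "simulate"))
        truth_path = run_dir / "truth_reads.tsv"
        labels = {}
        if truth_path.exists():
            df = pd.read_csv(truth_path, sep="\t")
            labels = dict(zip(df["read_id"].astype(str), df["label"].astype(int)))
        by_read: dict[str, list] = {}
        for rec in errors:
            by_read.setdefault(rec.read_id, []).append(rec)
        windows = []
        for read in events:
            windows.extend(
                build_windows(
                    read, by_read.get(read.read_id, []), motif=cfg.motif,
                    target_offset=cfg.target_offset, l=cfg.l,
                    label=labels.get(read.read_id),
                )
            )
        io.write_features(run_dir / "features.tsv", windows)
        log.info("extract: %d reads in, %d windows out", len(events), len(windows))


class TrainStage(Stage):
    name = "train"
    inputs = ("features.tsv",)
    outputs = ("model", "history.json")

    def run(self, run_dir: Path, cfg: RunConfig) -> None:
        windows = io.read_features(_require(run_dir, "features.tsv", "extract"))
        labeled = [w for w in windows if w.label is not None]
        if not labeled:
            raise MissingArtifactError("no labeled windows to train on")
        seed = stage_seed(cfg.seed, self.name)
        train, val, _test = split_dataset(labeled, seed=seed)
        model = ReadClassifier(ModelSpec(mode=cfg.mode), l=cfg.l, seed=seed)
        tcfg = TrainingConfig(
            learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
            max_epochs=cfg.epochs, patience=cfg.patience, seed=seed,
        )
        Xs, Xe, y = windows_to_tensors(train)
        vXs, vXe, vy = windows_to_tensors(val)
        use_seq = cfg.mode in ("joint", "sequence_only")
        use_err = cfg.mode in ("joint", "error_only")
        history = train_model(
            model,
            (Xs if use_seq else None, Xe if use_err else None, y),
            (vXs if use_seq else None, vXe if use_err else None, vy),
            tcfg,
        )
        model.save(run_dir / "model", feature_schema=io.feature_columns())
        (run_dir / "history.json").write_text(json.dumps(history, indent=2))
        log.info("train: %d train / %d val windows, %d epochs",
                 len(train), len(val), len(history["train_loss"]))


class CallReadsStage(Stage):
    name = "call-reads"
    inputs = ("model", "features.tsv")
    outputs = ("read_predictions.tsv",)

    def run(self, run_dir: Path, cfg: RunConfig) -> None:
        model, schema = ReadClassifier.load(_require(run_dir, "model", "train"))
        windows = io.read_features(_require(run_dir, "features.tsv", "extract"))
        have = set(windows[0].features) if windows else set()
        missing = [c for c in schema if c not in have]
        if missing:
            raise ValueError(f"feature table lacks columns the model expects: {missing}")
        preds = call_reads(model, windows)
        io.write_read_predictions(run_dir / "read_predictions.tsv", preds)
        log.info("call-reads: %d windows in, %d predictions out", len(windows), len(preds))


class CallPositionsStage(Stage):
    name = "call-positions"
    inputs = ("read_predictions.tsv",)
    outputs = ("position_calls.tsv",)

    def run(self, run_dir: Path, cfg: RunConfig) -> None:
        preds = io.read_read_predictions(_require(run_dir, "read_predictions.tsv", "call-reads"))
        params = None
        if cfg.method == "bayes":
            labeled = preds[preds["label"] >= 0] if "label" in preds else preds.iloc[0:0]
            params = BetaMixtureParams(2, 8, 8, 2, gamma=cfg.gamma, epsilon=cfg.epsilon)
            if len(labeled) >= 10 and labeled["label"].nunique() == 2:
                try:
                    params = estimate_mixture_params(
                        labeled["score"].to_numpy(), labeled["label"].to_numpy(),
                        gamma=cfg.gamma, epsilon=cfg.epsilon,
                    )
                except DegenerateFitError:
                    log.warning("calibration fit degenerate; using default components")
        evidences, dropped = group_reads_by_position(preds, min_coverage=cfg.min_coverage)
        calls = call_positions(
            evidences, method=cfg.method, params=params, t=cfg.threshold,
            prior_meth=cfg.prior_meth,
        )
        io.write_position_calls(run_dir / "position_calls.tsv", calls)
        log.info("call-positions: %d positions, %d reads dropped", len(calls), dropped)


class EvaluateStage(Stage):
    name = "evaluate"
    inputs = ("read_predictions.tsv",)
    outputs = ("metrics.json",)

    def run(self, run_dir: Path, cfg: RunConfig) -> None:
        preds = io.read_read_predictions(_require(run_dir, "read_predictions.tsv", "call-reads"))
        labeled = preds[preds["label"] >= 0]
        result: dict = {"n_reads": int(len(preds)), "n_labeled": int(len(labeled))}
        if len(labeled):
            counts = ConfusionCounts.from_calls(
                labeled["label"].to_numpy(), labeled["call"].to_numpy()
            )
            result["read_level"] = compute_metrics(counts).to_dict()
            result["read_level"]["auc"] = roc_auc(
                labeled["score"].to_numpy(), labeled["label"].to_numpy()
            )
        (run_dir / "metrics.json").write_text(json.dumps(result, indent=2))
        log.info("evaluate: metrics for %d labeled reads", len(labeled))


STAGES: dict[str, Stage] = {
    s.name: s for s in (
        SimulateStage(), ExtractStage(), TrainStage(), CallReadsStage(),
        CallPositionsStage(), EvaluateStage(),
    )
}


def _manifest_path(run_dir: Path, stage: str) -> Path:
    return run_dir / f"{stage}.manifest.json"


def _current_hashes(run_dir: Path, names: tuple[str, ...]) -> dict[str, str]:
    out = {}
    for name in names:
        p = run_dir / name
        if p.exists():
            out[name] = _hash_tree(p)
    return out


def run_pipeline(stages: list[str], cfg: RunConfig, out_dir: str | Path) -> Path:
    """Run the requested stages in canonical order inside ``out_dir``.

    A stage is skipped when its manifest exists, its config hash matches and
    all recorded input/output hashes still match on disk.
    """
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.dump(run_dir / "config.yaml")
    for name in STAGE_ORDER:
        if name not in stages:
            continue
        stage = STAGES[name]
        manifest_file = _manifest_path(run_dir, name)
        in_hashes = _current_hashes(run_dir, stage.inputs)
        if manifest_file.exists():
            manifest = json.loads(manifest_file.read_text())
            if (
                manifest.get("config_hash") == cfg.hash()
                and manifest.get("inputs") == in_hashes
                and manifest.get("outputs") == _current_hashes(run_dir, stage.outputs)
            ):
                log.info("%s: up to date, skipping", name)
                continue
        stage.run(run_dir, cfg)
        manifest = {
            "stage": name,
            "version": __version__,
            "seed": stage_seed(cfg.seed, name),
            "config_hash": cfg.hash(),
            "inputs": in_hashes,
            "outputs": _current_hashes(run_dir, stage.outputs),
        }
        manifest_file.write_text(json.dumps(manifest, indent=2))
    return run_dir
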