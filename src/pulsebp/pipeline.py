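"""Configured end-to-end runs with manifests, plus cycle/table serialization.

A run executes simulate -> preprocess -> features -> train -> evaluate in
order inside an output directory, echoes the effective configuration, and
writes a manifest with SHA-256 checksums of every artifact so reruns can be
compared file-by-file.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, replace

import numpy as np

from .evaluate import evaluate
from .features import extract_features
from .net import ABPNet, TrainConfig, predict, resample_cycles, save_model, train
from .preprocess import CardiacCycle, QualityRules, preprocess_record
from .signal_io import write_record
from .synth import SimConfig, simulate_record, truth_to_frame

__all__ = ["run_pipeline", "save_cycles", "load_cycles", "PipelineError"]

_STAGES = ("simulate", "preprocess", "features", "train", "evaluate")


class PipelineError(RuntimeError):
    """A stage failed or the configuration is invalid."""


# ---------------------------------------------------------------------------
# cycle serialization: one array container per record
# ---------------------------------------------------------------------------

def save_cycles(path: str, cycles: list[CardiacCycle]) -> None:
    """Store cycles as concatenated arrays plus per-cycle offsets (.npz)."""
    ppg = np.concatenate([c.ppg_segment for c in cycles]) if cycles else np.empty(0)
    abp = np.concatenate([c.abp_segment for c in cycles]) if cycles else np.empty(0)
    lengths = np.array([len(c.ppg_segment) for c in cycles], dtype=int)
    np.savez(
        path,
        ppg=ppg,
        abp=abp,
        lengths=lengths,
        r_peak=np.array([c.r_peak_index for c in cycles], dtype=int),
        sbp=np.array([c.sbp for c in cycles]),
        dbp=np.array([c.dbp for c in cycles]),
        fs=np.array([cycles[0].sampling_rate if cycles else 0.0]),
        flags=np.array([",".join(sorted(c.quality_flags)) for c in cycles], dtype="U"),
    )


def load_cycles(path: str) -> list[CardiacCycle]:
    data = np.load(path, allow_pickle=False)
    offsets = np.concatenate([[0], np.cumsum(data["lengths"])])
    fs = float(data["fs"][0])
    cycles = []
    for i, n in enumerate(data["lengths"]):
        lo, hi = offsets[i], offsets[i + 1]
        flags = set(str(data["flags"][i]).split(",")) - {""}
        cycles.append(
            CardiacCycle(
                r_peak_index=int(data["r_peak"][i]),
                ppg_segment=data["ppg"][lo:hi],
                abp_segment=data["abp"][lo:hi],
                sbp=float(data["sbp"][i]),
                dbp=float(data["dbp"][i]),
                sampling_rate=fs,
                quality_flags=flags,
            )
        )
    return cycles


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _merge_dataclass(cls, overrides: dict, **extra):
    try:
        return replace(cls(), **{**overrides, **extra})
    except TypeError as exc:
        raise PipelineError(f"invalid {cls.__name__} key: {exc}") from exc


def run_pipeline(config: dict | None, out_dir: str, seed: int = 0) -> dict:
    """Execute the full pipeline into ``out_dir`` and return the manifest.

    ``config`` maps stage names (``simulate``, ``preprocess``, ``features``,
    ``train``, ``evaluate``) to parameter overrides for that stage; unknown
    stage names or parameters are rejected before anything runs.  All
    randomness derives from ``seed``.  Rerunning with the same configuration
    and seed reproduces identical checksums.
    """
    config = dict(config or {})
    unknown = set(config) - set(_STAGES)
    if unknown:
        raise PipelineError(f"unknown pipeline stage(s): {sorted(unknown)}")
    for stage, val in config.items():
        if not isinstance(val, dict):
            raise PipelineError(f"stage {stage!r} must map to a parameter table")

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1)) for s in _STAGES}
    manifest = {"seed": int(seed), "stage_seeds": stage_seeds, "files": {}, "stages": {}}

    def emit(name: str, path: str):
        manifest["files"][name] = _sha256(path)

    # -- simulate ------------------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = _merge_dataclass(SimConfig, config.get(stage, {}), seed=stage_seeds[stage])
        record, truth = simulate_record(sim_cfg)
        rec_path = os.path.join(out_dir, "record.csv")
        write_record(record, rec_path, format="csv")
        truth_to_frame(truth).to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
        manifest["stages"][stage] = asdict(sim_cfg)
        emit("record.csv", rec_path)
        emit("ground_truth.csv", os.path.join(out_dir, "ground_truth.csv"))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # -- preprocess ----------------------------------------------------------
    stage = "preprocess"
    try:
        rules = _merge_dataclass(QualityRules, config.get(stage, {}))
        cycles, summary = preprocess_record(record, rules)
        cyc_path = os.path.join(out_dir, "cycles.npz")
        save_cycles(cyc_path, cycles)
        manifest["stages"][stage] = {**asdict(rules), **summary}
        emit("cycles.npz", cyc_path)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # -- features ------------------------------------------------------------
    stage = "features"
    try:
        fcfg = dict(config.get(stage, {}))
        feats = extract_features(cycles, **fcfg)
        feat_path = os.path.join(out_dir, "features.csv")
        feats.to_csv(feat_path, index=False)
        manifest["stages"][stage] = {"n_features": int(len(feats)), **fcfg}
        emit("features.csv", feat_path)
    except TypeError as exc:
        raise PipelineError(f"stage {stage!r} failed: invalid parameter ({exc})") from exc
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # -- train ---------------------------------------------------------------
    stage = "train"
    try:
        tcfg = _merge_dataclass(TrainConfig, config.get(stage, {}), seed=stage_seeds[stage])
        used = [cycles[int(i)] for i in feats["beat"]]
        ppg = resample_cycles(used)
        ptt = feats[["ptt_p", "ptt_d"]].to_numpy()
        y = feats[["sbp", "dbp"]].to_numpy()
        n = len(used)
        split = int(0.8 * n)
        model = ABPNet(seed=stage_seeds[stage])
        history = train(model, ppg[:split], ptt[:split], y[:split], tcfg)
        model_path = os.path.join(out_dir, "model.npz")
        save_model(model, model_path)
        manifest["stages"][stage] = {
            **asdict(tcfg),
            "final_train_mse": history["train_mse"][-1],
            "final_val_mse": history["val_mse"][-1],
        }
        emit("model.npz", model_path)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # -- evaluate ------------------------------------------------------------
    stage = "evaluate"
    try:
        pred = predict(model, ppg[split:], ptt[split:])
        report = {
            "sbp": asdict(evaluate(pred[:, 0], y[split:, 0])),
            "dbp": asdict(evaluate(pred[:, 1], y[split:, 1])),
            "n_test": int(n - split),
        }
        rep_path = os.path.join(out_dir, "report.json")
        with open(rep_path, "w") as fh:
            json.dump(report, fh, indent=1)
        manifest["stages"][stage] = report
        emit("report.json", rep_path)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
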