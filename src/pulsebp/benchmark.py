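"""End-to-end synthetic benchmark: simulate, preprocess, extract, fit, score.

One call runs the whole pipeline on a generated record under the default
study conditions — 125 Hz, SBP in [100, 160] mmHg, DBP in [60, 100] mmHg,
transit-time law PTT = 350 ms − 1.2 ms/mmHg · MAP, additive noise at 5% of
the pulse amplitude — trains ABP-net alongside the classical baselines on a
chronological train split, and scores every method on the held-out tail of
the record.
"""

from __future__ import annotations

import numpy as np

from .evaluate import EvalReport, evaluate, fit_linear_regression, fit_random_forest
from .features import extract_features
from .net import ABPNet, TrainConfig, predict, resample_cycles, train
from .preprocess import preprocess_record
from .synth import SimConfig, simulate_record

__all__ = ["run_benchmark", "BENCHMARK_METHODS"]

BENCHMARK_METHODS = ("abp_net", "linreg_ptt", "linreg_ppg", "rf_ptt", "rf_ppg")


def run_benchmark(
    seed: int = 0,
    n_train_beats: int = 2000,
    n_test_beats: int = 400,
    methods=BENCHMARK_METHODS,
    train_config: TrainConfig | None = None,
    input_len: int = 128,
):
    """Run the default synthetic benchmark once.

    Parameters
    ----------
    seed
        Root seed; the generator, network initialization, batching order and
        forests all derive from it.
    n_train_beats, n_test_beats
        Nominal sizes of the chronological train/test split (the actual
        counts differ slightly because beats vary in length and a few
        cycles fail quality control).
    methods
        Subset of :data:`BENCHMARK_METHODS` to fit.
    train_config
        ABP-net training settings (defaults to :class:`TrainConfig` with
        the derived seed).

    Returns
    -------
    results : dict mapping method -> {"sbp": EvalReport, "dbp": EvalReport}
    info : dict with the realized problem sizes.
    """
    n_total = n_train_beats + n_test_beats
    cfg = SimConfig(
        duration=(n_total + 40) * 60.0 / 75.0,  # margin for HR variability and QC
        seed=int(seed) % 2**31,
    )
    record, _ = simulate_record(cfg)
    cycles, _ = preprocess_record(record)
    feats = extract_features(cycles)
    used = [cycles[int(i)] for i in feats["beat"]]

    ppg = resample_cycles(used, input_len=input_len)
    ptt = feats[["ptt_p", "ptt_d"]].to_numpy()
    y = feats[["sbp", "dbp"]].to_numpy()

    # chronological split: train on the first part of the session, test on
    # the held-out tail
    t_split = record.duration * n_train_beats / (n_total + 40)
    is_train = feats["r_peak_index"].to_numpy() < t_split * record.sampling_rate
    tr, te = np.flatnonzero(is_train), np.flatnonzero(~is_train)
    if te.size > n_test_beats:
        te = te[:n_test_beats]

    results: dict[str, dict[str, EvalReport]] = {}

    def score(pred):
        return {
            "sbp": evaluate(pred[:, 0], y[te, 0]),
            "dbp": evaluate(pred[:, 1], y[te, 1]),
        }

    if "abp_net" in methods:
        tc = train_config or TrainConfig(seed=int(seed) % 2**31)
        model = ABPNet(input_len=input_len, seed=int(seed) % 2**31)
        history = train(model, ppg[tr], ptt[tr], y[tr], tc)
        results["abp_net"] = score(predict(model, ppg[te], ptt[te]))
        results["abp_net"]["history"] = history
    if "linreg_ptt" in methods:
        reg = fit_linear_regression(ptt[tr], y[tr])
        results["linreg_ptt"] = score(reg.predict(ptt[te]))
    if "linreg_ppg" in methods:
        reg = fit_linear_regression(ppg[tr], y[tr])
        results["linreg_ppg"] = score(reg.predict(ppg[te]))
    if "rf_ptt" in methods:
        rf = fit_random_forest(ptt[tr], y[tr], seed=int(seed) % 2**31)
        results["rf_ptt"] = score(rf.predict(ptt[te]))
    if "rf_ppg" in methods:
        rf = fit_random_forest(ppg[tr], y[tr], seed=int(seed) % 2**31)
        results["rf_ppg"] = score(rf.predict(ppg[te]))

    info = {"n_train": int(tr.size), "n_test": int(te.size), "n_cycles": len(cycles)}
    return results, info
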