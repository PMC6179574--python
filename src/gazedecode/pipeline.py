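"""End-to-end pipeline: generate -> preprocess -> decode -> cluster stats.

``run_full`` sequences the three decoding analyses on a simulated cohort:

1. within-task gaze-position classification (2 features, shrinkage 0.01),
2. within-task MEG classification (sensors as features, shrinkage 0.05),
3. localizer-trained continuous orientation decoding of the task (rho),

each cross-validated / generalized over time, reduced to condition-wise time
courses over the canonical training windows (0.5-1.5 s for the task-trained
classifier, 0.09-0.12 s for the localizer-trained decoder), and tested at
the group level with sign-flip cluster permutation statistics.  All outputs
are written as TSV/JSON twins of the figure-like quantities plus a
machine-readable ``summary.json``; identical configuration and seed give a
byte-identical bundle.

One master seed spawns per-stage child seeds (generator, fold assignment,
permutations) through ``numpy.random.SeedSequence`` so stages are decoupled
but jointly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_stats as cs
from .classifier import (TemporalGeneralizationMatrix, crossval_posterior_tensor,
                         target_posterior)
from .encoding import EncodingBasis, localizer_decoded_orientations, rho_map
from .preprocess import baseline_correct, smooth_moving_average
from .simulate import (GeneratorConfig, generate_localizer_data,
                       generate_task_data)

__all__ = ["PipelineConfig", "run_full"]

log = logging.getLogger("gazedecode.pipeline")

CONDITIONS = ("VWM", "MR60", "MR120", "MR180")


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    baseline_window: tuple = (-0.2, 0.0)
    smoothing_window_s: float = 0.1
    shrinkage_meg: float = 0.05
    shrinkage_gaze: float = 0.01
    n_channels: int = 24
    kappa: float = 5.0
    n_folds: int = 8
    n_perm: int = 10000
    train_window_task: tuple = (0.5, 1.5)
    train_window_localizer: tuple = (0.09, 0.12)
    #: evaluation window for "delay-period decoding" flags: starts after the
    #: transient response (plus smoothing margin) and ends at probe onset
    delay_eval_start_s: float = 1.0
    tg_decim: int = 1
    localizer_train_decim: int = 1
    out_dir: str = "gazedecode_output"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("baseline_window", "train_window_task",
                  "train_window_localizer"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if not isinstance(gen, GeneratorConfig):
            gen = GeneratorConfig(**gen)
        for k in ("baseline_window", "train_window_task",
                  "train_window_localizer"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(generator=gen, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)          # bundle identity, not content
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _stage(name, cfg_hash):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            if exc[0] is None:
                log.info("stage=%s config=%s wall_s=%.2f", name, cfg_hash,
                         time.perf_counter() - self.t0)
            else:
                log.error("stage=%s config=%s failed: %s", name, cfg_hash,
                          exc[1])
    return _Timer()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path):
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_json_default)
        f.write("\n")


def _tg_tsv(tg: TemporalGeneralizationMatrix, path):
    df = pd.DataFrame(tg.values, index=tg.train_times, columns=tg.test_times)
    df.index.name = "train_time_s"
    df.to_csv(path, sep="\t")


def _profiles_tsv(test_times, profiles: dict, path):
    df = pd.DataFrame({"test_time_s": test_times})
    for cond, vals in profiles.items():
        df[cond] = vals
    df.to_csv(path, sep="\t", index=False)


def _clusters_tsv(result: cs.ClusterTestResult, path):
    rows = [{"sign": c.sign, "mass": c.mass, "p_value": c.p_value,
             "n_points": int(c.mask.sum())} for c in result.clusters]
    pd.DataFrame(rows, columns=["sign", "mass", "p_value", "n_points"]).to_csv(
        path, sep="\t", index=False)


def _delay_coverage(result: cs.ClusterTestResult, times, window) -> float:
    """Fraction of samples in ``window`` covered by significant positive clusters."""
    in_win = (times >= window[0]) & (times <= window[1])
    if not in_win.any():
        return 0.0
    covered = np.zeros(len(times), dtype=bool)
    for c in result.significant(sign=+1):
        covered |= c.mask
    return float(covered[in_win].mean())


def run_full(config: PipelineConfig) -> dict:
    """Run the full simulated study and write the report bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    cfg_hash = config.config_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)

    master = np.random.SeedSequence(config.seed)
    gen_ss, fold_ss, perm_ss = master.spawn(3)
    gen_cfg = replace(config.generator, seed=_child_seed(gen_ss))
    fold_seed = _child_seed(fold_ss)
    perm_seed = _child_seed(perm_ss)
    basis = EncodingBasis(n_channels=config.n_channels, kappa=config.kappa)
    probe_onset = gen_cfg.probe_onset_s
    delay_window = (config.delay_eval_start_s, probe_onset)

    # per-analysis, per-condition stacks of condition profiles across subjects
    gaze_profiles = {c: [] for c in CONDITIONS}
    meg_profiles = {c: [] for c in CONDITIONS}
    loc_profiles = {c: [] for c in CONDITIONS}
    meg_plus60_profiles = []       # MR60 trials, target = stimulus +/- 60
    gaze_scatter_rows = []
    mean_tgs = {"gaze": [], "meg": [], "localizer": []}
    test_times_task = None
    test_times_loc = None

    for subject in range(gen_cfg.n_subjects):
        with _stage(f"generate_subject_{subject}", cfg_hash):
            meg, gaze, _gt = generate_task_data(gen_cfg, subject=subject)
            loc_meg, _loc_gaze, _ = generate_localizer_data(
                gen_cfg, subject=subject)
        with _stage(f"preprocess_subject_{subject}", cfg_hash):
            meg = smooth_moving_average(
                baseline_correct(meg, config.baseline_window, "stimulus"),
                config.smoothing_window_s)
            gaze = smooth_moving_average(
                baseline_correct(gaze, config.baseline_window, "cue"),
                config.smoothing_window_s)
            loc_meg = smooth_moving_average(
                baseline_correct(loc_meg, config.baseline_window, "stimulus"),
                config.smoothing_window_s)

        trials = meg.trials
        stim = trials["stimulus_orientation_deg"].to_numpy()
        cond = trials["condition_label"].to_numpy()
        sign = np.where(trials["direction"].to_numpy() == "CW", 1.0, -1.0)
        plus60 = (stim + sign * 60.0) % 180.0

        for name, epochs, lam in (("gaze", gaze, config.shrinkage_gaze),
                                  ("meg", meg, config.shrinkage_meg)):
            with _stage(f"decode_{name}_subject_{subject}", cfg_hash):
                times, classes, tensor = crossval_posterior_tensor(
                    epochs, stim, n_folds=config.n_folds, shrinkage=lam,
                    seed=fold_seed + subject, decim=config.tg_decim)
            test_times_task = times
            own = target_posterior(tensor, classes, stim)   # (n, Tt, Tt)
            store = gaze_profiles if name == "gaze" else meg_profiles
            tg_all = TemporalGeneralizationMatrix(
                times, times, own.mean(axis=0),
                measure="mean_target_posterior", chance=1.0 / len(classes))
            mean_tgs[name].append(tg_all.values)
            for c in CONDITIONS:
                tg_c = TemporalGeneralizationMatrix(
                    times, times, own[cond == c].mean(axis=0),
                    measure="mean_target_posterior",
                    chance=1.0 / len(classes))
                store[c].append(
                    tg_c.train_window_mean(config.train_window_task))
            if name == "meg":
                p60 = target_posterior(tensor, classes, plus60)
                tg60 = TemporalGeneralizationMatrix(
                    times, times, p60[cond == "MR60"].mean(axis=0),
                    chance=1.0 / len(classes))
                meg_plus60_profiles.append(
                    tg60.train_window_mean(config.train_window_task))

        with _stage(f"decode_localizer_subject_{subject}", cfg_hash):
            tr_times, te_times, theta = localizer_decoded_orientations(
                loc_meg, meg, basis=basis, shrinkage=config.shrinkage_meg,
                train_decim=config.localizer_train_decim,
                test_decim=config.tg_decim)
        test_times_loc = te_times
        win = config.train_window_localizer
        row_mask = (tr_times >= win[0]) & (tr_times <= win[1])
        if not row_mask.any():
            raise ValueError("localizer training window selects no rows")
        full_map = rho_map(theta, stim)
        mean_tgs["localizer"].append(full_map)
        for c in CONDITIONS:
            cmap = rho_map(theta[cond == c], stim[cond == c])
            loc_profiles[c].append(cmap[row_mask].mean(axis=0))

        # gaze scatter: mean position 0.5-1.5 s post-stimulus per orientation
        scatter_mask = gaze.time_mask(0.5, 1.5)
        for ori in np.unique(stim):
            sel = gaze.data[stim == ori][:, :, scatter_mask]
            mean_xy = sel.mean(axis=(0, 2))
            gaze_scatter_rows.append({
                "subject": subject, "stimulus_orientation_deg": float(ori),
                "gaze_x_deg": float(mean_xy[0]),
                "gaze_y_deg": float(mean_xy[1]),
            })

    with _stage("cluster_stats", cfg_hash):
        results = {}
        for name, store, times, chance in (
                ("gaze", gaze_profiles, test_times_task, 1.0 / 3.0),
                ("meg", meg_profiles, test_times_task, 1.0 / 3.0),
                ("localizer", loc_profiles, test_times_loc, 0.0)):
            maps = np.stack(store["VWM"])
            results[name] = cs.cluster_permutation_test(
                maps, chance=chance, n_perm=config.n_perm, seed=perm_seed)

    # ---- report bundle ---------------------------------------------------
    summary = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_subjects": gen_cfg.n_subjects,
        "chance_task": 1.0 / 3.0,
        "analyses": {},
        "condition_means_delay": {},
    }
    late = {
        "gaze": (test_times_task >= delay_window[0])
        & (test_times_task <= delay_window[1]),
        "meg": (test_times_task >= delay_window[0])
        & (test_times_task <= delay_window[1]),
        "localizer": (test_times_loc >= delay_window[0])
        & (test_times_loc <= delay_window[1]),
    }
    for name, store, times in (("gaze", gaze_profiles, test_times_task),
                               ("meg", meg_profiles, test_times_task),
                               ("localizer", loc_profiles, test_times_loc)):
        res = results[name]
        coverage = _delay_coverage(res, times, delay_window)
        best_p = min((c.p_value for c in res.clusters if c.sign == +1),
                     default=1.0)
        summary["analyses"][name] = {
            "min_positive_cluster_p": best_p,
            "delay_coverage_by_significant_clusters": coverage,
            "delay_decoding_significant": coverage > 0.5,
        }
        summary["condition_means_delay"][name] = {
            c: float(np.stack(store[c]).mean(axis=0)[late[name]].mean())
            for c in CONDITIONS
        }
        _profiles_tsv(times,
                      {c: np.stack(store[c]).mean(axis=0) for c in CONDITIONS},
                      out / f"profiles_{name}.tsv")
        _clusters_tsv(res, out / f"clusters_{name}.tsv")
    summary["meg_mr60_plus60_late_delay"] = float(
        np.stack(meg_plus60_profiles).mean(axis=0)[late["meg"]].mean())
    summary["headline"] = {
        "within_task_delay_decoding_significant":
            summary["analyses"]["meg"]["delay_decoding_significant"],
        "localizer_trained_delay_decoding_significant":
            summary["analyses"]["localizer"]["delay_decoding_significant"],
    }

    for name in ("gaze", "meg"):
        _tg_tsv(TemporalGeneralizationMatrix(
            test_times_task, test_times_task,
            np.mean(mean_tgs[name], axis=0), chance=1.0 / 3.0),
            out / f"tg_{name}_groupmean.tsv")
    _tg_tsv(TemporalGeneralizationMatrix(
        tr_times, test_times_loc, np.mean(mean_tgs["localizer"], axis=0),
        measure="rho", chance=0.0), out / "tg_localizer_groupmean.tsv")
    pd.DataFrame(gaze_scatter_rows).to_csv(out / "gaze_scatter.tsv",
                                           sep="\t", index=False)
    _write_json(summary, out / "summary.json")
    return summary
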