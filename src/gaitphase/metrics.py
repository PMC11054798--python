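"""Spatial and temporal error metrics, cross-validation, and model comparison.

The *spatial* error of a prediction is the wraparound-safe signed phase
difference between the predicted and target encodings,

    dphi = (1/2pi) * atan2(yh2*y1 - yh1*y2, yh1*y1 + yh2*y2),

i.e. the angle of the predicted vector relative to the target vector in
units of a full cycle (predicted minus target, in (-0.5, 0.5]); sRMSE and
sMAE are its RMS and mean absolute value in percent of a cycle. The
*temporal* error matches each estimated heel strike to the closest actual
one and normalizes the offset by the duration of the previous actual
stride (tMAE, percent).

Cross-validation holds out one subject (or one walking condition from the
training data) per fold. Model comparisons use a Friedman test across
models followed by pairwise two-tailed Wilcoxon signed-rank tests with
Bonferroni correction; condition-out comparisons use two-sample
Kolmogorov-Smirnov tests, likewise corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import SegmentCalibration, extract_feature_channels
from .labeling import GaitEvents, PhaseSeries
from .models import Network, NetworkSpec, build_network, predict_phase
from .training import Standardizer, TrainConfig, train_network
from .windowing import WindowConfig, WindowSet, antialias_filter_bank, assemble_windows

__all__ = [
    "FoldResult",
    "MetricsReport",
    "SubjectData",
    "phase_error",
    "spatial_metrics",
    "estimated_heel_strikes",
    "temporal_mae",
    "prepare_subject",
    "cross_validate",
    "compare_models",
]


def phase_error(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Signed wraparound-safe phase difference (predicted minus target).

    ``y`` and ``y_hat`` are (..., 2) sinusoidal encodings; neither may be
    the zero vector. The result is in cycles, in (-0.5, 0.5], and is
    invariant to positive rescaling of either vector.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if np.any(np.all(y == 0.0, axis=-1)) or np.any(np.all(y_hat == 0.0, axis=-1)):
        raise ValueError("phase error undefined for zero vectors")
    y1, y2 = y[..., 0], y[..., 1]
    h1, h2 = y_hat[..., 0], y_hat[..., 1]
    return np.arctan2(h2 * y1 - h1 * y2, h1 * y1 + h2 * y2) / (2.0 * np.pi)


def spatial_metrics(dphi: np.ndarray) -> tuple[float, float]:
    """(sRMSE %, sMAE %) of a sample of phase errors in cycles."""
    d = np.asarray(dphi, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("no valid phase-error samples")
    return (100.0 * float(np.sqrt(np.mean(d**2))),
            100.0 * float(np.mean(np.abs(d))))


def estimated_heel_strikes(
    phi_hat: np.ndarray,
    time: np.ndarray,
    *,
    wrap_drop: float = 0.5,
    refine: bool = True,
    min_separation_s: float = 0.2,
) -> np.ndarray:
    """Heel-strike times from the sawtooth wrap of a decoded phase series.

    An event is recorded wherever the phase drops by more than ``wrap_drop``
    between consecutive samples (the 1 -> 0 wrap). With ``refine`` the time
    is interpolated to where the unwrapped phase crosses the integer;
    otherwise the first sample after the wrap is used. Events closer
    together than ``min_separation_s`` — below the physiological floor on
    stride rate, so necessarily estimator jitter around a single wrap —
    are merged, keeping the earliest.
    """
    phi = np.asarray(phi_hat, dtype=float).ravel()
    t = np.asarray(time, dtype=float).ravel()
    if phi.size < 2:
        return np.empty(0)
    drops = np.where(np.diff(phi) < -wrap_drop)[0]
    if refine:
        out = []
        for i in drops:
            # unwrapped phase goes phi[i] -> phi[i+1] + 1; crosses 1 between
            rise = phi[i + 1] + 1.0 - phi[i]
            frac = (1.0 - phi[i]) / rise if rise > 0 else 0.0
            out.append(t[i] + frac * (t[i + 1] - t[i]))
        events = np.asarray(out)
    else:
        events = t[drops + 1]
    if min_separation_s > 0 and events.size > 1:
        kept = [events[0]]
        for e in events[1:]:
            if e - kept[-1] >= min_separation_s:
                kept.append(e)
        events = np.asarray(kept)
    return events


def temporal_mae(
    estimated: np.ndarray,
    actual: np.ndarray,
) -> tuple[float, int]:
    """Temporal mean absolute error (%) and the number of matched steps.

    Each estimated heel strike is matched to the closest actual one; the
    timing offset is normalized by the duration of the stride preceding the
    matched actual event. Actual events without a preceding stride are
    skipped. Spurious estimated events each count as one matched step.
    """
    est = np.sort(np.asarray(estimated, dtype=float).ravel())
    act = np.sort(np.asarray(actual, dtype=float).ravel())
    if est.size < 1 or act.size < 2:
        raise ValueError("need >=1 estimated and >=2 actual heel strikes")
    errors = []
    for t_hat in est:
        k = int(np.argmin(np.abs(act - t_hat)))
        if k == 0:
            continue  # no preceding stride to normalize by
        stride = act[k] - act[k - 1]
        errors.append(abs(act[k] - t_hat) / stride)
    if not errors:
        raise ValueError("no matchable heel strikes")
    return 100.0 * float(np.mean(errors)), len(errors)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Windowed data and ground truth for one subject's session."""

    subject_id: str
    windows: WindowSet
    events: dict[str, GaitEvents]
    labels: PhaseSeries
    condition_of_window: np.ndarray  # (n_windows,) condition index
    condition_names: list[str]


def prepare_subject(
    session,
    calibs: dict[str, SegmentCalibration],
    *,
    stride_step: int = 1,
    window_cfg: WindowConfig = WindowConfig(),
    include_shank_pitch: bool = True,
) -> SubjectData:
    """Run the feature/filter/window pipeline on one session."""
    feats = extract_feature_channels(session, calibs,
                                     include_shank_pitch=include_shank_pitch)
    lp_short, lp_long = antialias_filter_bank(feats.data, window_cfg,
                                              time=feats.time)
    ws = assemble_windows(lp_short, lp_long, session.truth_phase,
                          stride_step=stride_step, cfg=window_cfg)
    cond = session.condition_index()
    ref_idx = np.round(ws.t_ref * session.fs).astype(int)
    return SubjectData(
        subject_id=session.subject_id,
        windows=ws,
        events=session.truth_events,
        labels=session.truth_phase,
        condition_of_window=cond[ref_idx],
        condition_names=[c.name for c in session.schedule],
    )


@dataclass
class FoldResult:
    fold: int
    test_subject: str
    held_out_condition: str | None
    srmse: float
    smae: float
    tmae: float
    n_samples: int
    n_steps: int


@dataclass
class MetricsReport:
    """Per-fold metrics with mean +/- SD aggregation."""

    architecture: str
    mode: str
    folds: list[FoldResult]
    per_condition: dict[str, dict[str, float]] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def _agg(self, attr: str) -> tuple[float, float]:
        v = np.array([getattr(f, attr) for f in self.folds])
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    @property
    def srmse_mean_sd(self):
        return self._agg("srmse")

    @property
    def smae_mean_sd(self):
        return self._agg("smae")

    @property
    def tmae_mean_sd(self):
        return self._agg("tmae")

    def fold_vector(self, attr: str = "srmse") -> np.ndarray:
        return np.array([getattr(f, attr) for f in self.folds])

    def summary(self) -> dict:
        s, ssd = self.srmse_mean_sd
        m, msd = self.smae_mean_sd
        t, tsd = self.tmae_mean_sd
        return {
            "architecture": self.architecture,
            "mode": self.mode,
            "n_folds": len(self.folds),
            "srmse_pct": {"mean": s, "sd": ssd},
            "smae_pct": {"mean": m, "sd": msd},
            "tmae_pct": {"mean": t, "sd": tsd},
        }


def _evaluate_fold(
    net: Network,
    std: Standardizer,
    test: SubjectData,
    fs: float = 100.0,
) -> tuple[float, float, float, int, int]:
    """Spatial and temporal errors of a trained network on one subject."""
    ws = test.windows
    pred = []
    for i in range(0, len(ws), 1024):
        sl = slice(i, i + 1024)
        pred.append(predict_phase(
            net,
            std.apply(ws.long[sl]),
            None if net.head_short is None else std.apply(ws.short[sl]),
        ))
    raw = np.concatenate([p["raw"] for p in pred])
    valid = ws.target_valid

    dphi = np.concatenate([
        phase_error(ws.target[valid, 0:2], raw[valid, 0:2]),
        phase_error(ws.target[valid, 2:4], raw[valid, 2:4]),
    ])
    srmse, smae = spatial_metrics(dphi)

    tmaes, steps = [], 0
    for leg, sl in (("r", slice(0, 2)), ("l", slice(2, 4))):
        phi_hat = np.concatenate([p[f"phi_{leg}"] for p in pred])
        est = estimated_heel_strikes(phi_hat, ws.t_ref)
        # restrict to intervals where the gait phase is defined (walking)
        leg_valid = getattr(test.labels, f"valid_{leg}")
        idx = np.clip(np.round(est * fs).astype(int), 0, leg_valid.size - 1)
        est = est[leg_valid[idx]]
        actual = test.events[leg].times
        if est.size and actual.size >= 2:
            t, n = temporal_mae(est, actual)
            tmaes.append(t)
            steps += n
    if not tmaes:
        raise ValueError("no heel strikes could be matched on the test subject")
    return srmse, smae, float(np.mean(tmaes)), int(valid.sum()), steps


def cross_validate(
    dataset: list[SubjectData],
    architecture: str = "dual_head_4",
    mode: str = "subject_out",
    *,
    train_cfg: TrainConfig = TrainConfig(),
    net_spec: NetworkSpec | None = None,
    conditions: list[str] | None = None,
    eval_subjects: list[SubjectData] | None = None,
) -> MetricsReport:
    """One-subject-out (or one-condition-out) cross-validation.

    ``subject_out``: for each subject s, test on s, validate on the next
    subject round-robin, train on the rest. ``condition_out``: for each
    held-out condition, run the subject-out folds with that condition's
    windows removed from the training (and validation) sets; the test
    subject keeps all conditions. ``eval_subjects`` optionally supplies a
    differently windowed copy of the same subjects (e.g. a denser
    prediction stride) for test-time evaluation.
    """
    n = len(dataset)
    if n < 3:
        raise ValueError("cross-validation needs at least 3 subjects")
    if eval_subjects is None:
        eval_subjects = dataset
    if [s.subject_id for s in eval_subjects] != [s.subject_id for s in dataset]:
        raise ValueError("eval_subjects must mirror the dataset's subjects")
    if mode not in ("subject_out", "condition_out"):
        raise ValueError("mode must be 'subject_out' or 'condition_out'")
    if net_spec is None:
        net_spec = NetworkSpec(
            architecture=architecture,
            n_channels=dataset[0].windows.long.shape[-1],
        )

    def run_folds(exclude_condition: str | None, fold_offset: int = 0):
        results = []
        for s in range(n):
            test = eval_subjects[s]
            val_i = (s + 1) % n
            train_ids = [i for i in range(n) if i not in (s, val_i)]

            def select(sd: SubjectData) -> WindowSet:
                ws = sd.windows
                if exclude_condition is None:
                    return ws
                names = np.array(sd.condition_names)[sd.condition_of_window]
                keep = names != exclude_condition
                return WindowSet(ws.short[keep], ws.long[keep], ws.t_ref[keep],
                                 ws.target[keep], ws.target_valid[keep])

            train_ws = WindowSet.concatenate([select(dataset[i]) for i in train_ids])
            val_ws = select(dataset[val_i])
            net = build_network(net_spec, seed=train_cfg.seed + fold_offset + s)
            net, _, std = train_network(net, train_ws, val_ws, train_cfg)
            srmse, smae, tmae, n_samp, n_steps = _evaluate_fold(net, std, test)
            results.append(FoldResult(
                fold=fold_offset + s, test_subject=test.subject_id,
                held_out_condition=exclude_condition,
                srmse=srmse, smae=smae, tmae=tmae,
                n_samples=n_samp, n_steps=n_steps,
            ))
        return results

    if mode == "subject_out":
        folds = run_folds(None)
    else:
        if conditions is None:
            conditions = sorted(set(dataset[0].condition_names))
        folds = []
        for ci, cond in enumerate(conditions):
            folds.extend(run_folds(cond, fold_offset=ci * n))

    report = MetricsReport(architecture=net_spec.architecture, mode=mode,
                           folds=folds)
    if mode == "condition_out":
        for cond in {f.held_out_condition for f in folds}:
            sel = [f for f in folds if f.held_out_condition == cond]
            report.per_condition[cond] = {
                "srmse_mean": float(np.mean([f.srmse for f in sel])),
                "tmae_mean": float(np.mean([f.tmae for f in sel])),
            }
    return report


def compare_models(
    errors: dict[str, np.ndarray],
    *,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> dict:
    """Statistical comparison of per-fold error vectors across models.

    ``wilcoxon``: a Friedman test across all models; if significant at
    ``alpha``, pairwise two-tailed Wilcoxon signed-rank tests at the
    Bonferroni-corrected threshold ``alpha / n_pairs`` (paired folds).
    ``ks``: pairwise two-sample Kolmogorov-Smirnov tests with the same
    correction (condition-out comparisons).
    """
    names = list(errors)
    vecs = [np.asarray(errors[k], dtype=float) for k in names]
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    lengths = {v.size for v in vecs}
    if len(lengths) != 1:
        raise ValueError("error vectors must have equal fold counts")

    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    corrected_alpha = alpha / len(pairs)
    out: dict = {"alpha": alpha, "corrected_alpha": corrected_alpha,
                 "pairwise": {}}

    if test == "wilcoxon":
        if all(np.allclose(v, vecs[0]) for v in vecs[1:]):
            f_stat, f_p = np.nan, 1.0  # identical models: nothing to rank
        elif len(names) >= 3:
            f_stat, f_p = stats.friedmanchisquare(*vecs)
        else:
            f_stat, f_p = np.nan, 0.0  # two models: go straight to pairwise
        out["friedman"] = {"statistic": float(f_stat), "p": float(f_p),
                           "significant": bool(f_p < alpha)}
        run_pairwise = out["friedman"]["significant"]
        for a, b in pairs:
            va, vb = errors[a], errors[b]
            if np.allclose(va, vb):
                res = {"statistic": np.nan, "p": 1.0}
            else:
                w = stats.wilcoxon(va, vb, alternative="two-sided",
                                   mode="exact" if len(va) <= 25 else "auto")
                res = {"statistic": float(w.statistic), "p": float(w.pvalue)}
            res["significant"] = bool(run_pairwise and res["p"] < corrected_alpha)
            out["pairwise"][f"{a} vs {b}"] = res
    elif test == "ks":
        for a, b in pairs:
            k = stats.ks_2samp(errors[a], errors[b])
            out["pairwise"][f"{a} vs {b}"] = {
                "statistic": float(k.statistic), "p": float(k.pvalue),
                "significant": bool(k.pvalue < corrected_alpha),
            }
    else:
        raise ValueError("test must be 'wilcoxon' or 'ks'")
    return out
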