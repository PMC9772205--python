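"""Experimental protocols and report statistics.

Two protocols are implemented, both repeated over independent random
splits (30 by default):

* ``entire`` — an 8:2 train/test split of the whole cohort, stratified
  on activity status (for patients with a defined CAS) to keep both
  classes present at small n;
* ``consistent_subset`` — the test set is a fixed-size random draw
  (100 by default) from the patients on whom all three raters agreed
  on every sign, everyone else training.

Per-sign sensitivity/specificity/AUC are computed at the patient level
(after the at-least-one-eye OR), active-TAO sensitivity/specificity on
the CAS >= 3 rule, and predicted-vs-reference CAS pairs are pooled over
repeats into an 8x8 confusion matrix with exact and within-1 agreement.
Per-repeat metrics are summarized as mean with a Student-t 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    SignConsensusClassifier,
    default_consensus_assignment,
    extract_features,
)
from .roi import CropGeometry, DEFAULT_GEOMETRY, crop_rois, roi_for_sign
from .scoring import PatientSigns, combine_eyes, compute_cas
from .signs import EYES, IMAGE_SIGNS, SignKind
from .synthetic import SyntheticCohort
from .utils import substream_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and report containers


@dataclass(frozen=True)
class ExperimentConfig:
    n_repeats: int = 30
    test_fraction: float = 0.2
    protocol: str = "entire"  # or "consistent_subset"
    consistent_test_size: int = 100
    stratify: bool = True
    per_eye_metrics: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.protocol not in ("entire", "consistent_subset"):
            raise ValueError(f"unknown protocol {self.protocol!r}")


@dataclass(frozen=True)
class MetricWithCI:
    mean: float
    ci_low: float
    ci_high: float
    values: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "values": list(self.values),
        }


@dataclass
class CasConfusion:
    """8x8 predicted-vs-reference CAS cross-tabulation."""

    matrix: np.ndarray  # rows = reference CAS 0..7, cols = predicted CAS 0..7

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.shape != (8, 8):
            raise ValueError(f"confusion matrix must be 8x8, got {m.shape}")
        if (m < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        self.matrix = m

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(range(8), name="reference_cas"),
            columns=[f"pred_{j}" for j in range(8)],
        )

    @classmethod
    def from_csv(cls, path) -> "CasConfusion":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy())


@dataclass
class EvaluationReport:
    config: ExperimentConfig
    per_sign: dict[SignKind, dict[str, MetricWithCI]]
    active: dict[str, MetricWithCI]
    confusion: CasConfusion
    exact_agreement: MetricWithCI | None
    within1_agreement: MetricWithCI | None
    pooled_exact_pct: float | None
    pooled_within1_pct: float | None
    completed_repeats: int
    cas_undefined_reason: str | None = None
    errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_repeats": self.config.n_repeats,
                "test_fraction": self.config.test_fraction,
                "protocol": self.config.protocol,
                "consistent_test_size": self.config.consistent_test_size,
                "stratify": self.config.stratify,
                "seed": self.config.seed,
            },
            "per_sign": {
                s.value: {k: v.as_dict() for k, v in d.items()}
                for s, d in self.per_sign.items()
            },
            "active_tao": {k: v.as_dict() for k, v in self.active.items()},
            "cas_confusion": self.confusion.matrix.tolist(),
            "cas_confusion_total": self.confusion.total,
            "exact_agreement": self.exact_agreement.as_dict() if self.exact_agreement else None,
            "within1_agreement": (
                self.within1_agreement.as_dict() if self.within1_agreement else None
            ),
            "pooled_exact_pct": self.pooled_exact_pct,
            "pooled_within1_pct": self.pooled_within1_pct,
            "completed_repeats": self.completed_repeats,
            "cas_undefined_reason": self.cas_undefined_reason,
            "errors": list(self.errors),
        }


# ---------------------------------------------------------------------------
# splits


def _allocate(sizes: Sequence[int], n_test: int) -> list[int]:
    """Largest-remainder proportional allocation of test slots to strata."""
    total = sum(sizes)
    quotas = [n_test * s / total for s in sizes]
    alloc = [int(np.floor(q)) for q in quotas]
    remainders = sorted(
        range(len(sizes)), key=lambda i: (quotas[i] - alloc[i], sizes[i]), reverse=True
    )
    short = n_test - sum(alloc)
    for i in remainders[:short]:
        alloc[i] += 1
    return [min(a, s) for a, s in zip(alloc, sizes)]


def split_entire(
    patient_ids: Sequence[str],
    active_status: Mapping[str, bool | None],
    repeat_index: int,
    seed: int,
    test_fraction: float = 0.2,
    stratify: bool = True,
) -> tuple[list[str], list[str]]:
    """One 8:2 random split; a fresh draw for every repeat index."""
    ids = list(patient_ids)
    if not ids:
        raise ValueError("dataset is empty")
    n_test = int(round(test_fraction * len(ids)))
    rng = np.random.default_rng(substream_seed(seed, "split-entire", repeat_index))
    if stratify:
        strata: dict[object, list[str]] = {}
        for pid in ids:
            strata.setdefault(active_status.get(pid), []).append(pid)
        keys = sorted(strata, key=str)
        alloc = _allocate([len(strata[k]) for k in keys], n_test)
        test: list[str] = []
        for k, take in zip(keys, alloc):
            group = strata[k]
            order = rng.permutation(len(group))
            test.extend(group[i] for i in order[:take])
        test_set = set(test)
        train = [pid for pid in ids if pid not in test_set]
    else:
        order = rng.permutation(len(ids))
        test = [ids[i] for i in order[:n_test]]
        test_set = set(test)
        train = [pid for pid in ids if pid not in test_set]
    defined = [active_status.get(pid) for pid in train if active_status.get(pid) is not None]
    has_both_overall = {True, False} <= {v for v in active_status.values() if v is not None}
    if has_both_overall and len(set(defined)) < 2:
        raise ValueError("training split lost one activity class; dataset too small")
    return train, sorted(test)


def split_consistent(
    patient_ids: Sequence[str],
    consistent: Mapping[str, bool],
    repeat_index: int,
    seed: int,
    test_size: int = 100,
) -> tuple[list[str], list[str]]:
    """Test = fixed-size random draw from rater-consistent patients."""
    pool = [pid for pid in patient_ids if consistent.get(pid)]
    if len(pool) < test_size:
        raise ValueError(
            f"only {len(pool)} rater-consistent patients available, "
            f"need {test_size} for the test set"
        )
    rng = np.random.default_rng(substream_seed(seed, "split-consistent", repeat_index))
    order = rng.permutation(len(pool))
    test = sorted(pool[i] for i in order[:test_size])
    test_set = set(test)
    train = [pid for pid in patient_ids if pid not in test_set]
    return train, test


# ---------------------------------------------------------------------------
# metrics


def binary_metrics(
    refs: Sequence[bool], preds: Sequence[bool], scores: Sequence[float]
) -> tuple[float, float, float]:
    """Sensitivity, specificity, and rank-form (Mann-Whitney) AUC.

    Tied scores contribute 1/2 to the AUC.
    """
    r = np.asarray(refs, dtype=bool)
    p = np.asarray(preds, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if not (len(r) == len(p) == len(s)):
        raise ValueError("refs, preds and scores must be aligned")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos, n_neg = int(r.sum()), int((~r).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: reference labels contain a single class")
    sens = float((p & r).sum() / n_pos)
    spec = float((~p & ~r).sum() / n_neg)
    ranks = stats.rankdata(s)  # average ranks: ties count 1/2
    auc = float((ranks[r].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
    return sens, spec, auc


def aggregate_ci(values: Sequence[float], confidence: float = 0.95) -> MetricWithCI:
    """Mean with a Student-t confidence interval over repeat values."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 values to form a confidence interval")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if np.ptp(vals) == 0.0:
        mean = float(vals[0])
        half = 0.0
    else:
        half = float(stats.t.ppf(0.5 + confidence / 2.0, len(vals) - 1) * sd / np.sqrt(len(vals)))
    return MetricWithCI(mean, mean - half, mean + half, tuple(float(v) for v in vals))


def pool_confusion(pairs: Sequence[tuple[int, int]]) -> CasConfusion:
    """Accumulate (reference CAS, predicted CAS) pairs over all repeats."""
    m = np.zeros((8, 8), dtype=np.int64)
    for ref, pred in pairs:
        if not (0 <= ref <= 7 and 0 <= pred <= 7):
            raise ValueError(f"CAS values must be in 0..7, got ({ref}, {pred})")
        m[ref, pred] += 1
    return CasConfusion(m)


def agreement_stats(cm: CasConfusion) -> tuple[float, float]:
    """Percent exact agreement and percent within one CAS point."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    idx = np.arange(8)
    band = np.abs(idx[:, None] - idx[None, :]) <= 1
    exact = 100.0 * float(np.trace(cm.matrix)) / total
    within1 = 100.0 * float(cm.matrix[band].sum()) / total
    return exact, within1


# ---------------------------------------------------------------------------
# the full experiment


def cohort_features(
    cohort: SyntheticCohort, geometry: CropGeometry = DEFAULT_GEOMETRY
) -> dict[tuple[str, str], dict]:
    """Crop every face once; features keyed by (patient_id, eye) then ROI."""
    feats: dict[tuple[str, str], dict] = {}
    for pid in cohort.patient_ids:
        crops = crop_rois(cohort.images[pid], cohort.landmarks[pid], geometry, patient_id=pid)
        for c in crops:
            feats.setdefault((pid, c.eye), {})[c.roi] = extract_features(c)
    return feats


def _reference_cas(record) -> object:
    patient_signs = combine_eyes(record.consensus["left"], record.consensus["right"])
    return compute_cas(
        PatientSigns(patient_signs, record.pain_spont, record.pain_gaze)
    )


def reference_activity(cohort: SyntheticCohort) -> dict[str, bool | None]:
    """Active/inactive per patient from the consensus CAS; None if undefined."""
    return {p.patient_id: _reference_cas(p).active for p in cohort.patients}


def _fit_sign_models(
    cohort: SyntheticCohort,
    feats: dict,
    train_ids: Sequence[str],
    assignment: Mapping[SignKind, str],
    C_grid: tuple[float, ...],
    n_components_grid: tuple[int, ...],
    seed: int,
) -> dict[SignKind, SignConsensusClassifier]:
    models = {}
    for sign in IMAGE_SIGNS:
        roi = roi_for_sign(sign)
        X, R, y = [], [], []
        for pid in train_ids:
            rec = cohort.record(pid)
            for eye in EYES:
                X.append(feats[(pid, eye)][roi])
                R.append([rec.rater_labels[r][eye][sign] for r in range(3)])
                y.append(rec.consensus[eye][sign])
        model = SignConsensusClassifier(
            sign=sign,
            consensus=assignment[sign],
            C_grid=C_grid,
            n_components_grid=n_components_grid,
            random_state=substream_seed(seed, "fit", sign.value),
        )
        model.fit(np.asarray(X), np.asarray(y), rater_labels=np.asarray(R))
        models[sign] = model
    return models


def _predict_patients(
    cohort: SyntheticCohort,
    feats: dict,
    models: Mapping[SignKind, SignConsensusClassifier],
    test_ids: Sequence[str],
) -> pd.DataFrame:
    rows = []
    for pid in test_ids:
        rec = cohort.record(pid)
        row: dict[str, object] = {"patient_id": pid}
        pred_eye: dict[str, dict[SignKind, bool]] = {e: {} for e in EYES}
        for sign, model in models.items():
            roi = roi_for_sign(sign)
            scores = {}
            for eye in EYES:
                x = feats[(pid, eye)][roi]
                label, score = model.predict_with_score(x)
                pred_eye[eye][sign] = bool(label[0])
                scores[eye] = float(score[0])
            row[f"pred_{sign.value}"] = pred_eye["left"][sign] or pred_eye["right"][sign]
            row[f"score_{sign.value}"] = max(scores.values())
            ref_eye = {e: rec.consensus[e][sign] for e in EYES}
            row[f"ref_{sign.value}"] = ref_eye["left"] or ref_eye["right"]
        pred_cas = compute_cas(
            PatientSigns(
                combine_eyes(pred_eye["left"], pred_eye["right"]),
                rec.pain_spont,
                rec.pain_gaze,
            )
        )
        ref_cas = _reference_cas(rec)
        row.update(
            pred_cas=pred_cas.cas,
            pred_active=pred_cas.active,
            ref_cas=ref_cas.cas,
            ref_active=ref_cas.active,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(
    cohort: SyntheticCohort,
    cfg: ExperimentConfig,
    *,
    assignment: Mapping[SignKind, str] | None = None,
    C_grid: tuple[float, ...] | None = None,
    n_components_grid: tuple[int, ...] | None = None,
    geometry: CropGeometry = DEFAULT_GEOMETRY,
    features: dict | None = None,
) -> EvaluationReport:
    """Run the repeated-split protocol end to end and assemble the report."""
    from .models import DEFAULT_C_GRID, DEFAULT_COMPONENTS_GRID

    assignment = dict(assignment or default_consensus_assignment())
    C_grid = tuple(C_grid or DEFAULT_C_GRID)
    n_components_grid = tuple(n_components_grid or DEFAULT_COMPONENTS_GRID)
    feats = features if features is not None else cohort_features(cohort, geometry)
    activity = reference_activity(cohort)
    consistent = {p.patient_id: p.is_consistent for p in cohort.patients}
    ids = cohort.patient_ids
    if cfg.protocol == "consistent_subset":
        n_pool = sum(consistent.values())
        if n_pool < cfg.consistent_test_size:
            raise ValueError(
                f"only {n_pool} rater-consistent patients available, "
                f"need {cfg.consistent_test_size} for the test set"
            )

    per_sign_vals: dict[SignKind, dict[str, list[float]]] = {
        s: {"sensitivity": [], "specificity": [], "auc": []} for s in IMAGE_SIGNS
    }
    active_vals: dict[str, list[float]] = {"sensitivity": [], "specificity": []}
    exact_vals: list[float] = []
    within1_vals: list[float] = []
    cas_pairs: list[tuple[int, int]] = []
    errors: list[str] = []
    completed = 0

    for rep in range(cfg.n_repeats):
        try:
            if cfg.protocol == "entire":
                train_ids, test_ids = split_entire(
                    ids, activity, rep, cfg.seed, cfg.test_fraction, cfg.stratify
                )
            else:
                train_ids, test_ids = split_consistent(
                    ids, consistent, rep, cfg.seed, cfg.consistent_test_size
                )
            models = _fit_sign_models(
                cohort, feats, train_ids, assignment, C_grid, n_components_grid,
                substream_seed(cfg.seed, "repeat", rep),
            )
            preds = _predict_patients(cohort, feats, models, test_ids)
            for sign in IMAGE_SIGNS:
                try:
                    sens, spec, auc = binary_metrics(
                        preds[f"ref_{sign.value}"],
                        preds[f"pred_{sign.value}"],
                        preds[f"score_{sign.value}"],
                    )
                except ValueError as exc:
                    logger.warning("repeat %d sign %s: %s", rep, sign.value, exc)
                    continue
                per_sign_vals[sign]["sensitivity"].append(sens)
                per_sign_vals[sign]["specificity"].append(spec)
                per_sign_vals[sign]["auc"].append(auc)
            defined = preds[preds["ref_cas"].notna() & preds["pred_cas"].notna()]
            if len(defined):
                ref_act = defined["ref_active"].astype(bool)
                pred_act = defined["pred_active"].astype(bool)
                if ref_act.nunique() == 2:
                    active_vals["sensitivity"].append(
                        float((pred_act & ref_act).sum() / ref_act.sum())
                    )
                    active_vals["specificity"].append(
                        float((~pred_act & ~ref_act).sum() / (~ref_act).sum())
                    )
                pairs = list(
                    zip(defined["ref_cas"].astype(int), defined["pred_cas"].astype(int))
                )
                cas_pairs.extend(pairs)
                rep_cm = pool_confusion(pairs)
                e, w = agreement_stats(rep_cm)
                exact_vals.append(e)
                within1_vals.append(w)
            completed += 1
        except Exception as exc:  # noqa: BLE001 - a repeat must not kill the run
            logger.error("repeat %d failed: %s", rep, exc)
            errors.append(f"repeat {rep}: {exc}")

    def _agg(vals: list[float]) -> MetricWithCI | None:
        if len(vals) >= 2:
            return aggregate_ci(vals)
        if len(vals) == 1:
            return MetricWithCI(vals[0], vals[0], vals[0], (vals[0],))
        return None

    confusion = pool_confusion(cas_pairs)
    pooled_exact = pooled_within1 = None
    if confusion.total > 0:
        pooled_exact, pooled_within1 = agreement_stats(confusion)
    report = EvaluationReport(
        config=cfg,
        per_sign={
            s: {k: m for k, v in d.items() if (m := _agg(v)) is not None}
            for s, d in per_sign_vals.items()
        },
        active={k: m for k, v in active_vals.items() if (m := _agg(v)) is not None},
        confusion=confusion,
        exact_agreement=_agg(exact_vals),
        within1_agreement=_agg(within1_vals),
        pooled_exact_pct=pooled_exact,
        pooled_within1_pct=pooled_within1,
        completed_repeats=completed,
        cas_undefined_reason=(
            "missing_pain" if confusion.total == 0 and completed > 0 else None
        ),
        errors=errors,
    )
    return report
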