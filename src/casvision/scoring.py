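"""Clinical activity score (CAS) arithmetic.

Per-eye sign predictions are reduced to patient-level signs (a patient
shows a sign if at least one eye shows it), summed with the two pain
symptoms into the 0--7 CAS, and thresholded into the active /
inactive phases.  Missing pain records make the CAS undefined rather
than being imputed; a bounds mode reports the attainable CAS range
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from .signs import IMAGE_SIGNS, PAIN_SYMPTOMS, SignKind

#: Tri-state pain answer: True/False, or None when the record is missing.
PainValue = bool | None

ACTIVITY_THRESHOLD = 3
HIGH_ACTIVITY_THRESHOLD = 5


@dataclass(frozen=True)
class PatientSigns:
    """Patient-level CAS inputs: five image signs plus two pain answers."""

    signs: Mapping[SignKind, bool]
    pain_spont: PainValue
    pain_gaze: PainValue

    def __post_init__(self) -> None:
        missing = [s for s in IMAGE_SIGNS if s not in self.signs]
        if missing:
            raise ValueError(f"image signs missing from PatientSigns: {missing}")


@dataclass(frozen=True)
class CasResult:
    """CAS total and activity class; undefined when a pain record is missing."""

    cas: int | None
    active: bool | None
    highly_active: bool | None
    reason: str | None = None
    #: attainable CAS range when pains are missing (bounds mode only)
    cas_min: int | None = None
    cas_max: int | None = None

    @property
    def defined(self) -> bool:
        return self.cas is not None


def combine_eyes(
    left: Mapping[SignKind, bool], right: Mapping[SignKind, bool]
) -> dict[SignKind, bool]:
    """Per-sign OR over the two eyes: a sign is present if either eye shows it."""
    for name, eye in (("left", left), ("right", right)):
        missing = [s for s in IMAGE_SIGNS if s not in eye]
        if missing:
            raise ValueError(f"{name} eye vector missing signs: {missing}")
    return {s: bool(left[s]) or bool(right[s]) for s in IMAGE_SIGNS}


def classify_activity(cas: int) -> Literal["active", "inactive"]:
    """Active phase iff CAS >= 3."""
    if not 0 <= int(cas) <= 7:
        raise ValueError(f"cas must be in 0..7, got {cas}")
    return "active" if cas >= ACTIVITY_THRESHOLD else "inactive"


def compute_cas(s: PatientSigns, *, bounds: bool = False) -> CasResult:
    """Sum the seven items into the CAS and classify activity.

    If either pain answer is missing the CAS is undefined and the result
    carries a machine-readable ``reason``.  With ``bounds=True`` the
    attainable range (missing pains counted as all-no / all-yes) is
    reported alongside.
    """
    n_signs = sum(bool(s.signs[k]) for k in IMAGE_SIGNS)
    pains = (s.pain_spont, s.pain_gaze)
    if any(p is None for p in pains):
        known = sum(bool(p) for p in pains if p is not None)
        n_missing = sum(p is None for p in pains)
        return CasResult(
            cas=None,
            active=None,
            highly_active=None,
            reason="missing_pain",
            cas_min=n_signs + known if bounds else None,
            cas_max=n_signs + known + n_missing if bounds else None,
        )
    cas = n_signs + sum(bool(p) for p in pains)
    return CasResult(
        cas=cas,
        active=cas >= ACTIVITY_THRESHOLD,
        highly_active=cas >= HIGH_ACTIVITY_THRESHOLD,
        cas_min=cas if bounds else None,
        cas_max=cas if bounds else None,
    )


def _parse_tristate(value: object) -> PainValue:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in {"1", "true", "yes", "y"}:
            return True
        if lowered in {"0", "false", "no", "n"}:
            return False
        raise ValueError(f"unrecognized pain value {value!r}")
    return bool(value)


def score_table(per_eye: pd.DataFrame, *, bounds: bool = False) -> pd.DataFrame:
    """Score a table of per-eye predicted signs plus pain answers.

    Expects one row per patient with columns ``patient_id``,
    ``{sign}_{eye}`` for the five image signs and both eyes, and
    ``pain_spont`` / ``pain_gaze`` (blank = missing).  Returns one row
    per patient with patient-level signs, ``cas``, ``active``,
    ``highly_active`` and ``reason`` columns.
    """
    rows = []
    for _, row in per_eye.iterrows():
        eyes = {
            eye: {s: bool(row[f"{s.value}_{eye}"]) for s in IMAGE_SIGNS}
            for eye in ("left", "right")
        }
        patient = combine_eyes(eyes["left"], eyes["right"])
        signs = PatientSigns(
            signs=patient,
            pain_spont=_parse_tristate(row["pain_spont"]),
            pain_gaze=_parse_tristate(row["pain_gaze"]),
        )
        res = compute_cas(signs, bounds=bounds)
        out = {"patient_id": row["patient_id"]}
        out.update({s.value: patient[s] for s in IMAGE_SIGNS})
        out.update(
            cas=res.cas,
            active=res.active,
            highly_active=res.highly_active,
            reason=res.reason or "",
        )
        if bounds:
            out.update(cas_min=res.cas_min, cas_max=res.cas_max)
        rows.append(out)
    columns = (
        ["patient_id"]
        + [s.value for s in IMAGE_SIGNS]
        + ["cas", "active", "highly_active", "reason"]
        + (["cas_min", "cas_max"] if bounds else [])
    )
    return pd.DataFrame(rows, columns=columns)
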