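"""Synthetic periorbital cohort generator.

Renders schematic periorbital images carrying controllable, localized
inflammatory-sign perturbations, together with exact facial landmarks,
simulated expert raters and a discussion-consensus process, and the two
orbital-pain symptoms.  The generator emulates the statistical structure
of a TAO photo-scoring cohort — per-sign prevalences, three imperfect
raters, a ~10% fraction of patients with no pain record — so the whole
classification pipeline can be exercised end to end without clinical
photographs.

Rendering is deliberately flat-shaded (skin field, elliptical sclera,
iris disk, eyelid band, medial caruncle blob): the goal is an
ROI-localized, linearly separable class signal, not photorealism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .roi import EyeLandmarks, LandmarkSet
from .signs import EYES, IMAGE_SIGNS, SignKind
from .utils import substream_rng, substream_seed

# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RaterProfile:
    """Sensitivity / specificity of one simulated rater.

    Either scalar (applied to every sign) or a per-sign mapping.
    """

    sensitivity: float | Mapping[SignKind, float] = 0.8
    specificity: float | Mapping[SignKind, float] = 0.9

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            val = getattr(self, name)
            vals = val.values() if isinstance(val, Mapping) else [val]
            for v in vals:
                if not 0.0 < v <= 1.0:
                    raise ValueError(f"{name} must be in (0, 1], got {v}")

    def sens(self, sign: SignKind) -> float:
        s = self.sensitivity
        return float(s[sign]) if isinstance(s, Mapping) else float(s)

    def spec(self, sign: SignKind) -> float:
        s = self.specificity
        return float(s[sign]) if isinstance(s, Mapping) else float(s)


DEFAULT_RATERS: tuple[RaterProfile, ...] = (
    RaterProfile(0.75, 0.88),
    RaterProfile(0.80, 0.90),
    RaterProfile(0.85, 0.92),
)

#: Default patient-level sign prevalences, matching a 1,020-patient
#: TAO cohort (yes-counts 342, 428, 849, 123, 107 of 1020).
DEFAULT_PREVALENCE: dict[SignKind, float] = {
    SignKind.EYELID_REDNESS: 342 / 1020,
    SignKind.CONJUNCTIVAL_REDNESS: 428 / 1020,
    SignKind.EYELID_SWELLING: 849 / 1020,
    SignKind.CARUNCLE_INFLAMMATION: 123 / 1020,
    SignKind.CONJUNCTIVAL_EDEMA: 107 / 1020,
}

#: Pain-symptom prevalences among patients with a pain record
#: (109/918 spontaneous retrobulbar pain, 78/918 pain on gaze).
DEFAULT_PAIN_PREVALENCE: dict[SignKind, float] = {
    SignKind.SPONTANEOUS_PAIN: 109 / 918,
    SignKind.GAZE_PAIN: 78 / 918,
}


@dataclass(frozen=True)
class PhenotypeSpec:
    """Latent ground truth for one rendered face."""

    #: per-eye sign intensity in [0, 1]; 0 = absent
    intensities: Mapping[str, Mapping[SignKind, float]] = field(
        default_factory=lambda: {e: {} for e in EYES}
    )
    aperture_width: float = 64.0
    aperture_height: float = 28.0
    inter_eye_distance: float = 150.0
    skin_color: tuple[float, float, float] = (0.80, 0.62, 0.52)
    sclera_color: tuple[float, float, float] = (0.97, 0.96, 0.93)
    pain_spont: bool = False
    pain_gaze: bool = False
    #: (height, width); None = smallest canvas that fits the geometry
    canvas: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("aperture_width", "aperture_height", "inter_eye_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        clipped = {
            eye: {s: float(np.clip(v, 0.0, 1.0)) for s, v in self.intensities.get(eye, {}).items()}
            for eye in EYES
        }
        object.__setattr__(self, "intensities", clipped)

    def intensity(self, sign: SignKind, eye: str) -> float:
        return float(self.intensities[eye].get(sign, 0.0))


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic cohort."""

    n_patients: int = 1020
    prevalence: Mapping[SignKind, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    pain_prevalence: Mapping[SignKind, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIN_PREVALENCE)
    )
    missing_pain_fraction: float = 102 / 1020
    raters: Sequence[RaterProfile] = DEFAULT_RATERS
    consensus_flip_prob: float = 0.1
    #: probability a positive sign affects both eyes (else one random eye)
    bilateral_prob: float = 0.5
    #: sampled rendering intensity for a present sign
    intensity_range: tuple[float, float] = (0.4, 1.0)
    aperture_width: float = 64.0
    aperture_height: float = 28.0
    inter_eye_distance: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        probs = {
            "prevalence": self.prevalence.values(),
            "pain_prevalence": self.pain_prevalence.values(),
            "missing_pain_fraction": [self.missing_pain_fraction],
            "bilateral_prob": [self.bilateral_prob],
        }
        for name, vals in probs.items():
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} entries must be in [0, 1], got {v}")
        if not 0.0 <= self.consensus_flip_prob < 0.5:
            raise ValueError("consensus_flip_prob must be in [0, 0.5)")
        if len(self.raters) != 3:
            raise ValueError(f"exactly 3 rater profiles required, got {len(self.raters)}")


# ---------------------------------------------------------------------------
# face rendering

# additive RGB perturbation per unit intensity, per sign
_SIGN_TINT: dict[SignKind, np.ndarray] = {
    SignKind.EYELID_REDNESS: np.array([0.35, -0.12, -0.12]),
    SignKind.EYELID_SWELLING: np.array([0.10, 0.07, -0.20]),
    SignKind.CONJUNCTIVAL_REDNESS: np.array([0.40, -0.25, -0.25]),
    # stays in gamut on the near-white sclera; clipped channels carry no signal
    SignKind.CONJUNCTIVAL_EDEMA: np.array([-0.15, -0.06, 0.06]),
    SignKind.CARUNCLE_INFLAMMATION: np.array([0.45, -0.15, -0.15]),
}


def _eye_centers(spec: PhenotypeSpec, canvas: tuple[int, int]) -> dict[str, tuple[float, float]]:
    h, w = canvas
    cx = (w - 1) / 2.0
    cy = np.ceil(0.80 * spec.aperture_width + spec.aperture_height / 2.0) + 2.0
    half = spec.inter_eye_distance / 2.0
    # anatomical left eye sits on the image's right half (frontal photo)
    return {"left": (cx + half, cy), "right": (cx - half, cy)}


def _default_canvas(spec: PhenotypeSpec) -> tuple[int, int]:
    aw, ah = spec.aperture_width, spec.aperture_height
    width = int(np.ceil(spec.inter_eye_distance + aw + 2 * 0.45 * aw)) + 4
    height = int(np.ceil(ah + 0.80 * aw + 0.55 * aw)) + 6
    return height, width


def _check_canvas(spec: PhenotypeSpec, canvas: tuple[int, int]) -> None:
    h, w = canvas
    need_h, need_w = _default_canvas(spec)
    if w < need_w:
        raise ValueError(
            f"canvas width {w} too small for inter_eye_distance={spec.inter_eye_distance} "
            f"and aperture_width={spec.aperture_width} (need >= {need_w})"
        )
    if h < need_h:
        raise ValueError(
            f"canvas height {h} too small for aperture_width={spec.aperture_width} "
            f"and aperture_height={spec.aperture_height} (need >= {need_h})"
        )


def _landmarks(spec: PhenotypeSpec, canvas: tuple[int, int]) -> LandmarkSet:
    aw, ah = spec.aperture_width, spec.aperture_height
    centers = _eye_centers(spec, canvas)
    eyes = {}
    for eye, (cx, cy) in centers.items():
        # medial = toward the nose (image centre); left eye is on image right
        medial_dx = -aw / 2 if eye == "left" else aw / 2
        eyes[eye] = EyeLandmarks(
            medial_canthus=(cx + medial_dx, cy),
            lateral_canthus=(cx - medial_dx, cy),
            upper_lid_apex=(cx, cy - ah / 2),
            lower_lid_apex=(cx, cy + ah / 2),
            brow_mid=(cx, cy - ah / 2 - 0.45 * aw),
        )
    return LandmarkSet(left=eyes["left"], right=eyes["right"])


def generate_face(
    spec: PhenotypeSpec,
) -> tuple[np.ndarray, LandmarkSet, dict[str, dict[SignKind, bool]]]:
    """Render one schematic periorbital image.

    Returns the float RGB raster in [0, 1], the exact landmark set, and
    the per-eye boolean sign truths (intensity > 0).  Bitwise
    deterministic for a given spec (the seed drives skin-tone jitter and
    pixel noise).  Each sign with positive intensity perturbs only
    pixels inside the region-of-interest that sign is read from.
    """
    canvas = spec.canvas or _default_canvas(spec)
    _check_canvas(spec, canvas)
    h, w = canvas
    aw, ah = spec.aperture_width, spec.aperture_height
    rng = np.random.default_rng(substream_seed(spec.seed, "render"))

    jitter = rng.uniform(-0.04, 0.04, size=3)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.clip(np.asarray(spec.skin_color) + jitter, 0.0, 1.0)

    ys, xs = np.mgrid[0:h, 0:w]
    landmarks = _landmarks(spec, canvas)
    centers = _eye_centers(spec, canvas)

    for eye in EYES:
        cx, cy = centers[eye]
        lateral_sign = +1.0 if eye == "left" else -1.0  # toward the temple, in x

        # palpebral aperture: sclera ellipse, iris, pupil
        ell = ((xs - cx) / (aw / 2)) ** 2 + ((ys - cy) / (ah / 2)) ** 2 <= 1.0
        img[ell] = spec.sclera_color
        iris = (xs - cx) ** 2 + (ys - cy) ** 2 <= (0.42 * ah) ** 2
        img[iris & ell] = (0.35, 0.25, 0.15)
        pupil = (xs - cx) ** 2 + (ys - cy) ** 2 <= (0.18 * ah) ** 2
        img[pupil & ell] = (0.05, 0.05, 0.05)

        # resting anatomy: faint eyelid crease and caruncle blob
        band = (
            (ys >= cy - ah / 2 - 0.28 * aw)
            & (ys <= cy - ah / 2 - 0.10 * aw)
            & (np.abs(xs - cx) <= aw / 2 + 0.15 * aw)
        )
        img[band] = np.clip(img[band] - 0.03, 0.0, 1.0)
        mx, my = landmarks.eye(eye).medial_canthus
        car_cx = mx + lateral_sign * 0.06 * aw
        caruncle = (xs - car_cx) ** 2 + (ys - my) ** 2 <= (0.055 * aw) ** 2
        img[caruncle] = (0.78, 0.50, 0.45)

        # sign perturbations (additive, intensity-scaled, ROI-localized)
        lateral_x = cx + lateral_sign * aw / 2  # lateral canthus x
        for sign in IMAGE_SIGNS:
            val = spec.intensity(sign, eye)
            if val <= 0.0:
                continue
            tint = _SIGN_TINT[sign]
            if sign in (SignKind.EYELID_REDNESS, SignKind.EYELID_SWELLING):
                mask = band
                if sign is SignKind.EYELID_SWELLING:
                    # smooth bump: strongest mid-band, fading laterally
                    profile = np.clip(1.0 - ((xs - cx) / (0.65 * aw)) ** 2, 0.0, 1.0)
                    add = val * tint[None, None, :] * profile[..., None]
                    img[mask] = np.clip(img[mask] + add[mask], 0.0, 1.0)
                    continue
            elif sign is SignKind.CONJUNCTIVAL_REDNESS:
                mask = ell & (lateral_sign * (xs - cx) >= 0.45 * ah)
            elif sign is SignKind.CONJUNCTIVAL_EDEMA:
                outer = ((xs - cx) / (aw / 2 + 0.06 * aw)) ** 2 + (
                    (ys - cy) / (ah / 2 + 0.08 * aw)
                ) ** 2 <= 1.0
                mask = outer & (lateral_sign * (xs - cx) >= 0.45 * ah)
            elif sign is SignKind.CARUNCLE_INFLAMMATION:
                mask = (xs - car_cx) ** 2 + (ys - my) ** 2 <= (0.10 * aw) ** 2
            img[mask] = np.clip(img[mask] + val * tint, 0.0, 1.0)

    img += rng.normal(0.0, 0.015, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    truths = {
        eye: {s: spec.intensity(s, eye) > 0.0 for s in IMAGE_SIGNS} for eye in EYES
    }
    return img, landmarks, truths


# ---------------------------------------------------------------------------
# raters


def simulate_raters(
    truths: Mapping[str, Mapping[SignKind, bool]],
    profiles: Sequence[RaterProfile],
    flip_prob: float,
    seed: int,
) -> tuple[list[dict[str, dict[SignKind, bool]]], dict[str, dict[SignKind, bool]]]:
    """Pass per-eye sign truths through three noisy raters and a consensus.

    Each rater reads each sign/eye independently through their
    sensitivity/specificity channel.  When all three agree, the
    consensus is their shared reading; otherwise the simulated
    discussion recovers the latent truth except with probability
    ``flip_prob``.
    """
    if len(profiles) != 3:
        raise ValueError(f"exactly 3 rater profiles required, got {len(profiles)}")
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    rater_labels: list[dict[str, dict[SignKind, bool]]] = [
        {e: {} for e in EYES} for _ in profiles
    ]
    consensus: dict[str, dict[SignKind, bool]] = {e: {} for e in EYES}
    for sign in IMAGE_SIGNS:
        for eye in EYES:
            truth = bool(truths[eye][sign])
            votes = []
            for r, prof in enumerate(profiles):
                p_yes = prof.sens(sign) if truth else 1.0 - prof.spec(sign)
                lab = bool(rng.random() < p_yes)
                rater_labels[r][eye][sign] = lab
                votes.append(lab)
            if votes[0] == votes[1] == votes[2]:
                consensus[eye][sign] = votes[0]
            else:
                flip = bool(rng.random() < flip_prob)
                consensus[eye][sign] = (not truth) if flip else truth
    return rater_labels, consensus


# ---------------------------------------------------------------------------
# cohort


@dataclass
class PatientRecord:
    """Labels and latent truths for one synthetic patient."""

    patient_id: str
    truth: dict[str, dict[SignKind, bool]]
    rater_labels: list[dict[str, dict[SignKind, bool]]]
    consensus: dict[str, dict[SignKind, bool]]
    pain_spont: bool | None
    pain_gaze: bool | None

    @property
    def is_consistent(self) -> bool:
        """True if all three raters agreed on every sign for both eyes."""
        return all(
            self.rater_labels[0][e][s] == self.rater_labels[1][e][s] == self.rater_labels[2][e][s]
            for e in EYES
            for s in IMAGE_SIGNS
        )


class SyntheticCohort:
    """In-memory synthetic dataset: images, landmarks and labels."""

    def __init__(
        self,
        spec: CohortSpec,
        patients: list[PatientRecord],
        images: dict[str, np.ndarray],
        landmarks: dict[str, LandmarkSet],
    ) -> None:
        self.spec = spec
        self.patients = patients
        self.images = images
        self.landmarks = landmarks

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def record(self, patient_id: str) -> PatientRecord:
        return self._by_id[patient_id]

    @property
    def _by_id(self) -> dict[str, PatientRecord]:
        cache = getattr(self, "_by_id_cache", None)
        if cache is None or len(cache) != len(self.patients):
            cache = {p.patient_id: p for p in self.patients}
            self._by_id_cache = cache
        return cache

    def labels_frame(self) -> pd.DataFrame:
        """Flat label table: one row per patient, blank = missing pain."""
        rows = []
        for p in self.patients:
            row: dict[str, object] = {"patient_id": p.patient_id}
            for r in range(3):
                for s in IMAGE_SIGNS:
                    for e in EYES:
                        row[f"rater{r + 1}_{s.value}_{e}"] = int(p.rater_labels[r][e][s])
            for s in IMAGE_SIGNS:
                for e in EYES:
                    row[f"consensus_{s.value}_{e}"] = int(p.consensus[e][s])
            for s in IMAGE_SIGNS:
                for e in EYES:
                    row[f"truth_{s.value}_{e}"] = int(p.truth[e][s])
            row["pain_spont"] = "" if p.pain_spont is None else int(p.pain_spont)
            row["pain_gaze"] = "" if p.pain_gaze is None else int(p.pain_gaze)
            rows.append(row)
        cols = ["patient_id"]
        cols += [
            f"rater{r + 1}_{s.value}_{e}" for r in range(3) for s in IMAGE_SIGNS for e in EYES
        ]
        cols += [f"consensus_{s.value}_{e}" for s in IMAGE_SIGNS for e in EYES]
        cols += [f"truth_{s.value}_{e}" for s in IMAGE_SIGNS for e in EYES]
        cols += ["pain_spont", "pain_gaze"]
        return pd.DataFrame(rows, columns=cols)

    # -- disk round trip ----------------------------------------------------

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for pid, img in self.images.items():
            arr = np.clip(img * 255.0 + 0.5, 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(path / f"{pid}.png")
            self.landmarks[pid].write_sidecar(path / f"{pid}.json", image_name=f"{pid}.png")
        self.labels_frame().to_csv(path / "labels.csv", index=False)
        manifest = dataclasses.asdict(self.spec)
        manifest["prevalence"] = {s.value: float(v) for s, v in self.spec.prevalence.items()}
        manifest["pain_prevalence"] = {
            s.value: float(v) for s, v in self.spec.pain_prevalence.items()
        }
        manifest["raters"] = [
            {"sensitivity": r.sensitivity, "specificity": r.specificity}
            for r in self.spec.raters
        ]
        with open(path / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)


def _parse_pain(value: object) -> bool | None:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return bool(int(value))


def load_cohort(path: str | Path) -> SyntheticCohort:
    """Reload a cohort previously written with :meth:`SyntheticCohort.write_dir`."""
    path = Path(path)
    labels = pd.read_csv(path / "labels.csv", dtype={"patient_id": str})
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    spec = CohortSpec(
        n_patients=manifest["n_patients"],
        prevalence={SignKind(k): v for k, v in manifest["prevalence"].items()},
        pain_prevalence={SignKind(k): v for k, v in manifest["pain_prevalence"].items()},
        missing_pain_fraction=manifest["missing_pain_fraction"],
        raters=tuple(
            RaterProfile(r["sensitivity"], r["specificity"]) for r in manifest["raters"]
        ),
        consensus_flip_prob=manifest["consensus_flip_prob"],
        bilateral_prob=manifest["bilateral_prob"],
        intensity_range=tuple(manifest["intensity_range"]),
        aperture_width=manifest["aperture_width"],
        aperture_height=manifest["aperture_height"],
        inter_eye_distance=manifest["inter_eye_distance"],
        seed=manifest["seed"],
    )
    patients: list[PatientRecord] = []
    images: dict[str, np.ndarray] = {}
    landmarks: dict[str, LandmarkSet] = {}
    for _, row in labels.iterrows():
        pid = row["patient_id"]
        rater_labels = [
            {e: {s: bool(row[f"rater{r + 1}_{s.value}_{e}"]) for s in IMAGE_SIGNS} for e in EYES}
            for r in range(3)
        ]
        consensus = {
            e: {s: bool(row[f"consensus_{s.value}_{e}"]) for s in IMAGE_SIGNS} for e in EYES
        }
        truth = {
            e: {s: bool(row[f"truth_{s.value}_{e}"]) for s in IMAGE_SIGNS} for e in EYES
        }
        patients.append(
            PatientRecord(
                patient_id=pid,
                truth=truth,
                rater_labels=rater_labels,
                consensus=consensus,
                pain_spont=_parse_pain(row["pain_spont"]),
                pain_gaze=_parse_pain(row["pain_gaze"]),
            )
        )
        img_path = path / f"{pid}.png"
        if img_path.exists():
            images[pid] = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
            from .roi import SidecarBackend

            landmarks[pid] = SidecarBackend().detect(img_path)
    return SyntheticCohort(spec, patients, images, landmarks)


def generate_cohort(spec: CohortSpec, *, render: bool = True) -> SyntheticCohort:
    """Draw a full synthetic cohort from its statistical description.

    ``render=False`` skips image synthesis (labels and landmarks only),
    which is convenient for purely statistical checks on large n.
    Deterministic for a given spec seed, and label draws do not depend
    on whether images are rendered.
    """
    rng = substream_rng(spec.seed, "cohort-labels")
    patients: list[PatientRecord] = []
    images: dict[str, np.ndarray] = {}
    landmarks: dict[str, LandmarkSet] = {}
    digits = max(4, len(str(max(spec.n_patients - 1, 0))))
    for i in range(spec.n_patients):
        pid = f"p{i:0{digits}d}"
        intensities: dict[str, dict[SignKind, float]] = {e: {} for e in EYES}
        for sign in IMAGE_SIGNS:
            if rng.random() >= spec.prevalence.get(sign, 0.0):
                continue
            if rng.random() < spec.bilateral_prob:
                affected = list(EYES)
            else:
                affected = [EYES[int(rng.integers(0, 2))]]
            for eye in affected:
                lo, hi = spec.intensity_range
                intensities[eye][sign] = float(rng.uniform(lo, hi))
        pain_spont: bool | None = bool(
            rng.random() < spec.pain_prevalence.get(SignKind.SPONTANEOUS_PAIN, 0.0)
        )
        pain_gaze: bool | None = bool(
            rng.random() < spec.pain_prevalence.get(SignKind.GAZE_PAIN, 0.0)
        )
        if rng.random() < spec.missing_pain_fraction:
            pain_spont = pain_gaze = None

        pheno = PhenotypeSpec(
            intensities=intensities,
            aperture_width=spec.aperture_width,
            aperture_height=spec.aperture_height,
            inter_eye_distance=spec.inter_eye_distance,
            pain_spont=bool(pain_spont),
            pain_gaze=bool(pain_gaze),
            seed=substream_seed(spec.seed, "face", i),
        )
        if render:
            img, lset, truths = generate_face(pheno)
            images[pid] = img
            landmarks[pid] = lset
        else:
            lset = _landmarks(pheno, _default_canvas(pheno))
            landmarks[pid] = lset
            truths = {
                e: {s: pheno.intensity(s, e) > 0 for s in IMAGE_SIGNS} for e in EYES
            }
        rater_labels, consensus = simulate_raters(
            truths,
            spec.raters,
            spec.consensus_flip_prob,
            substream_seed(spec.seed, "raters", i),
        )
        patients.append(
            PatientRecord(
                patient_id=pid,
                truth={e: dict(truths[e]) for e in EYES},
                rater_labels=rater_labels,
                consensus=consensus,
                pain_spont=pain_spont,
                pain_gaze=pain_gaze,
            )
        )
    return SyntheticCohort(spec, patients, images, landmarks)
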