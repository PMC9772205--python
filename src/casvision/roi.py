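"""Periorbital region-of-interest cropping.

Three regions are cropped per eye from a frontal facial image, guided by
five named landmarks per eye: the orbital region (eyelid redness and
swelling), the lateral conjunctiva (conjunctival redness and edema), and
the medial conjunctiva with the caruncle (caruncle/plica inflammation).
Crop geometry is expressed in units of the palpebral fissure width W
(medial-to-lateral canthal distance), so rectangles scale linearly with
eye size and translate with the face.

Coordinates are 0-based pixels, x rightward, y downward; rectangles are
half-open ``[x0, x1) x [y0, y1)``.  Laterality is anatomical: in a
frontal photograph the patient's left eye appears on the image's right
half, and is always taken from the landmark labels, never inferred from
position.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
from PIL import Image
from skimage.transform import resize

from .signs import EYES, SignKind

POINT_NAMES = ("medial_canthus", "lateral_canthus", "upper_lid_apex", "lower_lid_apex", "brow_mid")

Point = tuple[float, float]


@dataclass(frozen=True)
class EyeLandmarks:
    medial_canthus: Point
    lateral_canthus: Point
    upper_lid_apex: Point
    lower_lid_apex: Point
    brow_mid: Point

    def palpebral_width(self) -> float:
        m, l = np.asarray(self.medial_canthus), np.asarray(self.lateral_canthus)
        return float(np.linalg.norm(l - m))

    def points(self) -> dict[str, Point]:
        return {name: getattr(self, name) for name in POINT_NAMES}


@dataclass(frozen=True)
class LandmarkSet:
    """Named periorbital landmarks for both eyes (anatomical frame)."""

    left: EyeLandmarks
    right: EyeLandmarks

    def eye(self, side: str) -> EyeLandmarks:
        if side not in EYES:
            raise ValueError(f"unknown eye side {side!r}")
        return getattr(self, side)

    def validate(self, image_shape: tuple[int, int]) -> None:
        """Check all points lie inside the image and eyes are non-degenerate."""
        h, w = image_shape[:2]
        for side in EYES:
            eye = self.eye(side)
            for name, (x, y) in eye.points().items():
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(
                        f"landmark {side}.{name} = ({x}, {y}) outside image bounds {w}x{h}"
                    )
            if abs(eye.lateral_canthus[0] - eye.medial_canthus[0]) <= 0:
                raise ValueError(f"{side} eye: canthi are not horizontally distinct")
            if not eye.upper_lid_apex[1] < eye.lower_lid_apex[1]:
                raise ValueError(f"{side} eye: upper_lid_apex must lie above lower_lid_apex")

    # -- sidecar JSON -------------------------------------------------------

    def to_sidecar_dict(self, image_name: str = "") -> dict:
        return {
            "image": image_name,
            "eyes": {
                side: {name: [float(c) for c in pt] for name, pt in self.eye(side).points().items()}
                for side in EYES
            },
        }

    def write_sidecar(self, path: str | Path, image_name: str = "") -> None:
        with open(path, "w") as fh:
            json.dump(self.to_sidecar_dict(image_name), fh, indent=1, sort_keys=True)

    @classmethod
    def from_sidecar_dict(cls, payload: dict) -> "LandmarkSet":
        if "eyes" not in payload:
            raise ValueError("landmark sidecar missing 'eyes' section")
        eyes = {}
        for side in EYES:
            if side not in payload["eyes"]:
                raise ValueError(f"landmark sidecar missing eye {side!r}")
            entry = payload["eyes"][side]
            missing = [n for n in POINT_NAMES if n not in entry]
            if missing:
                raise ValueError(f"landmark sidecar missing points for {side} eye: {missing}")
            eyes[side] = EyeLandmarks(**{n: tuple(map(float, entry[n])) for n in POINT_NAMES})
        return cls(left=eyes["left"], right=eyes["right"])


class LandmarkBackend(Protocol):
    """Anything that can produce landmarks for an image path."""

    def detect(self, image_path: str | Path) -> LandmarkSet: ...


class SidecarBackend:
    """Default backend: reads the JSON sidecar written alongside the image."""

    def __init__(self, sidecar_path: str | Path | None = None) -> None:
        self.sidecar_path = sidecar_path

    def detect(self, image_path: str | Path) -> LandmarkSet:
        sidecar = Path(self.sidecar_path) if self.sidecar_path else Path(image_path).with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"landmark sidecar not found: {sidecar}")
        with open(sidecar) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"invalid landmark sidecar {sidecar}: {exc}") from exc
        return LandmarkSet.from_sidecar_dict(payload)


def load_landmarks(
    image_path: str | Path,
    sidecar_path: str | Path | None = None,
    backend: LandmarkBackend | None = None,
) -> LandmarkSet:
    """Load and validate landmarks for an image.

    The default backend reads a JSON sidecar; any detector satisfying
    the :class:`LandmarkBackend` protocol may be substituted.
    """
    backend = backend or SidecarBackend(sidecar_path)
    lset = backend.detect(image_path)
    with Image.open(image_path) as im:
        w, h = im.size
    lset.validate((h, w))
    return lset


# ---------------------------------------------------------------------------
# ROI kinds and crop geometry


class RoiKind(str, enum.Enum):
    ORBITAL = "orbital"
    LATERAL_CONJUNCTIVA = "lateral_conjunctiva"
    MEDIAL_CONJUNCTIVA_CARUNCLE = "medial_conjunctiva_caruncle"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SIGN_TO_ROI = {
    SignKind.EYELID_REDNESS: RoiKind.ORBITAL,
    SignKind.EYELID_SWELLING: RoiKind.ORBITAL,
    SignKind.CONJUNCTIVAL_REDNESS: RoiKind.LATERAL_CONJUNCTIVA,
    SignKind.CONJUNCTIVAL_EDEMA: RoiKind.LATERAL_CONJUNCTIVA,
    SignKind.CARUNCLE_INFLAMMATION: RoiKind.MEDIAL_CONJUNCTIVA_CARUNCLE,
}


def roi_for_sign(sign: SignKind) -> RoiKind:
    """Which cropped region a given inflammatory sign is read from."""
    try:
        return _SIGN_TO_ROI[sign]
    except KeyError:
        raise ValueError(
            f"{sign} is a pain symptom taken from patient records, not an image sign"
        ) from None


@dataclass(frozen=True)
class CropGeometry:
    """Crop rectangles in palpebral-width units W.

    The orbital box spans the eye landmarks expanded laterally by
    ``orbital_lateral``*W on each side, ``orbital_above``*W above the
    upper lid apex and ``orbital_below``*W below the lower lid apex.
    The conjunctival boxes are squares of side ``conj_size``*W centred
    ``conj_inset``*W inward from the respective canthus along the
    canthal axis.
    """

    orbital_lateral: float = 0.30
    orbital_above: float = 0.70
    orbital_below: float = 0.45
    conj_inset: float = 0.25
    conj_size: float = 0.60
    output_size: int = 64


DEFAULT_GEOMETRY = CropGeometry()


@dataclass(frozen=True)
class CroppedImage:
    """A fixed-size RGB crop tagged with its provenance."""

    pixels: np.ndarray  # (output_size, output_size, 3), values in [0, 1]
    roi: RoiKind
    eye: str
    patient_id: str
    rect: tuple[int, int, int, int]  # (x0, y0, x1, y1) in source coords


def _eye_rects(
    eye: EyeLandmarks, geometry: CropGeometry
) -> dict[RoiKind, tuple[float, float, float, float]]:
    W = eye.palpebral_width()
    if W <= 2.0:
        raise ValueError(f"degenerate palpebral width {W:.2f} px (must exceed 2 px)")
    med = np.asarray(eye.medial_canthus, dtype=float)
    lat = np.asarray(eye.lateral_canthus, dtype=float)
    pts = np.asarray([eye.medial_canthus, eye.lateral_canthus,
                      eye.upper_lid_apex, eye.lower_lid_apex], dtype=float)
    x0 = pts[:, 0].min() - geometry.orbital_lateral * W
    x1 = pts[:, 0].max() + geometry.orbital_lateral * W
    y0 = eye.upper_lid_apex[1] - geometry.orbital_above * W
    y1 = eye.lower_lid_apex[1] + geometry.orbital_below * W
    rects = {RoiKind.ORBITAL: (x0, y0, x1, y1)}

    axis = (med - lat) / W  # unit vector lateral -> medial
    half = geometry.conj_size * W / 2.0
    for roi, origin, direction in (
        (RoiKind.LATERAL_CONJUNCTIVA, lat, axis),
        (RoiKind.MEDIAL_CONJUNCTIVA_CARUNCLE, med, -axis),
    ):
        c = origin + geometry.conj_inset * W * direction
        rects[roi] = (c[0] - half, c[1] - half, c[0] + half, c[1] + half)
    return rects


def crop_rois(
    image: np.ndarray,
    landmarks: LandmarkSet,
    geometry: CropGeometry = DEFAULT_GEOMETRY,
    patient_id: str = "",
) -> list[CroppedImage]:
    """Produce the six standard crops (3 ROI kinds x 2 eyes).

    Rectangles are pure functions of the eye's landmarks, snapped to
    integer pixels, clipped to the image, and resized to the fixed
    output size with bilinear interpolation.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB image (h, w, 3), got shape {img.shape}")
    h, w = img.shape[:2]
    landmarks.validate((h, w))
    out = []
    size = geometry.output_size
    for side in EYES:
        for roi, (x0, y0, x1, y1) in _eye_rects(landmarks.eye(side), geometry).items():
            ix0 = max(int(np.floor(x0)), 0)
            iy0 = max(int(np.floor(y0)), 0)
            ix1 = min(int(np.floor(x1)), w)
            iy1 = min(int(np.floor(y1)), h)
            if ix1 - ix0 < 2 or iy1 - iy0 < 2:
                raise ValueError(
                    f"crop {roi.value}/{side} collapsed after clipping "
                    f"(rect {(ix0, iy0, ix1, iy1)})"
                )
            patch = img[iy0:iy1, ix0:ix1]
            pixels = resize(
                patch, (size, size), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            )
            out.append(
                CroppedImage(
                    pixels=np.clip(pixels, 0.0, 1.0),
                    roi=roi,
                    eye=side,
                    patient_id=patient_id,
                    rect=(ix0, iy0, ix1, iy1),
                )
            )
    return out


def crop_rects(
    landmarks: LandmarkSet, geometry: CropGeometry = DEFAULT_GEOMETRY
) -> dict[tuple[str, RoiKind], tuple[float, float, float, float]]:
    """Un-snapped crop rectangles per (eye, ROI), for geometry checks."""
    return {
        (side, roi): rect
        for side in EYES
        for roi, rect in _eye_rects(landmarks.eye(side), geometry).items()
    }
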