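"""The seven clinical-activity-score (CAS) items.

The CAS for thyroid-associated orbitopathy (TAO) counts seven binary
items: five inflammatory signs read from the periorbital appearance and
two orbital-pain symptoms taken from the patient's history.  The five
image signs are what the classifiers predict; the two pain items enter
only at scoring time.
"""

from __future__ import annotations

import enum


class SignKind(str, enum.Enum):
    """One CAS item."""

    EYELID_REDNESS = "eyelid_redness"
    CONJUNCTIVAL_REDNESS = "conjunctival_redness"
    EYELID_SWELLING = "eyelid_swelling"
    CARUNCLE_INFLAMMATION = "caruncle_inflammation"
    CONJUNCTIVAL_EDEMA = "conjunctival_edema"
    SPONTANEOUS_PAIN = "spontaneous_pain"
    GAZE_PAIN = "gaze_pain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_image_sign(self) -> bool:
        return self in IMAGE_SIGNS


#: The five signs detectable in a periorbital image, in canonical order.
IMAGE_SIGNS: tuple[SignKind, ...] = (
    SignKind.EYELID_REDNESS,
    SignKind.CONJUNCTIVAL_REDNESS,
    SignKind.EYELID_SWELLING,
    SignKind.CARUNCLE_INFLAMMATION,
    SignKind.CONJUNCTIVAL_EDEMA,
)

#: The two orbital-pain symptoms, answered from records rather than images.
PAIN_SYMPTOMS: tuple[SignKind, ...] = (
    SignKind.SPONTANEOUS_PAIN,
    SignKind.GAZE_PAIN,
)

#: Eye laterality labels, in the patient's anatomical frame.
EYES: tuple[str, str] = ("left", "right")
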