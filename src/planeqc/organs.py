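"""The eight pelvic-floor organs visible in a correct midsagittal plane.

A correctly captured midsagittal transperineal view shows, from cranioventral
(image left) to dorsocaudal (image right): the pubic symphysis, urethra,
urinary bladder, vagina, uterus, anus, rectum and levator ani muscle.  The
enum order below is the canonical order used everywhere in this package
(label vectors, feature tables, verdicts).
"""

from __future__ import annotations

import enum


class OrganId(enum.Enum):
    pubis = "pubis"
    urethra = "urethra"
    urinary_bladder = "urinary_bladder"
    vagina = "vagina"
    uterus = "uterus"
    anus = "anus"
    rectum = "rectum"
    levator_ani = "levator_ani"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical organ order (tuple of OrganId, length 8).
ORGANS: tuple[OrganId, ...] = tuple(OrganId)

#: Canonical organ names in order.
ORGAN_NAMES: tuple[str, ...] = tuple(o.value for o in ORGANS)


def organ_from_name(name: str) -> OrganId:
    """Look up an organ by its canonical name, with a helpful error."""
    try:
        return OrganId(name)
    except ValueError:
        raise ValueError(
            f"unknown organ name {name!r}; expected one of {list(ORGAN_NAMES)}"
        ) from None
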