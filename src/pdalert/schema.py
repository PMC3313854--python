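"""UPDRS motor-item attribute schema.

The assessor works on a motor subset of the Unified Parkinson's Disease
Rating Scale (UPDRS): 13 items from parts III-IV, each scored 0-4 by a
clinician.  Because parkinsonism is asymmetric, most of the limb items are
scored separately per side (or per limb for rest tremor), which expands the
13 items into 21 condition attributes.  Attribute names are short symbols
like ``d13`` (axial item 13) or ``d23RH`` (item 23, right hand); delta
attributes reuse the same names.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ValidationError

#: Motor items the assessor accepts (falling, freezing, tremor, rapid
#: alternating movement, gait, posture, bradykinesia, dyskinesia, off-time).
ALLOWED_ITEMS = frozenset({13, 14, 20, 21, 23, 24, 25, 26, 28, 29, 31, 32, 39})

#: Laterality flag -> attribute-name suffixes, in expansion order.
LATERALITY_SUFFIXES = {
    "none": ("",),
    "hands": ("RH", "LH"),
    "legs": ("RF", "LF"),
    "limbs": ("RH", "LH", "RF", "LF"),
}


@dataclass(frozen=True)
class ItemSpec:
    """One UPDRS item together with how it is lateralized."""

    number: int
    laterality: str = "none"

    def __post_init__(self) -> None:
        if self.number not in ALLOWED_ITEMS:
            raise ValidationError(
                f"UPDRS item {self.number} is not in the supported motor-item set "
                f"{sorted(ALLOWED_ITEMS)}"
            )
        if self.laterality not in LATERALITY_SUFFIXES:
            raise ValidationError(
                f"unknown laterality {self.laterality!r}; expected one of "
                f"{sorted(LATERALITY_SUFFIXES)}"
            )

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(
            f"d{self.number}{suffix}" for suffix in LATERALITY_SUFFIXES[self.laterality]
        )


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered set of lateralized UPDRS attributes.

    The default schema expands the 13 supported items to exactly 21
    attributes: seven axial/global items kept whole, rest tremor (item 20)
    split into four limbs, the four hand items split left/right, and leg
    agility (item 26) split left/right.
    """

    items: tuple[ItemSpec, ...]
    attribute_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        names: list[str] = []
        for item in self.items:
            names.extend(item.attribute_names)
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate attribute names in schema: {names}")
        object.__setattr__(self, "attribute_names", tuple(names))

    def __len__(self) -> int:
        return len(self.attribute_names)

    def __contains__(self, name: str) -> bool:
        return name in self.attribute_names

    def validate_attrs(self, attrs) -> tuple[str, ...]:
        """Check that ``attrs`` is a nonempty subset of the schema; return it as a tuple."""
        attrs = tuple(attrs)
        if not attrs:
            raise ValidationError("attribute subset must be nonempty")
        unknown = [a for a in attrs if a not in self.attribute_names]
        if unknown:
            raise ValidationError(f"unknown attributes: {unknown}")
        return attrs

    def display_name(self, attribute: str) -> str:
        """Clinician-facing delta symbol, e.g. ``d23RH`` -> ``ΔUPDRS23RH``."""
        if attribute not in self:
            raise ValidationError(f"unknown attribute: {attribute}")
        return "ΔUPDRS" + attribute[1:]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "items": [
                {"item": i.number, "laterality": i.laterality} for i in self.items
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AttributeSchema":
        try:
            items = tuple(
                ItemSpec(int(entry["item"]), str(entry.get("laterality", "none")))
                for entry in data["items"]
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed schema config: {exc}") from exc
        return cls(items)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AttributeSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_schema() -> AttributeSchema:
    """The 21-attribute motor schema used throughout the package."""
    return AttributeSchema(
        items=(
            ItemSpec(13),            # falling
            ItemSpec(14),            # freezing of gait
            ItemSpec(20, "limbs"),   # rest tremor, four limbs
            ItemSpec(21, "hands"),   # action tremor of hands
            ItemSpec(23, "hands"),   # finger taps
            ItemSpec(24, "hands"),   # hand movements
            ItemSpec(25, "hands"),   # rapid alternating movements
            ItemSpec(26, "legs"),    # leg agility
            ItemSpec(28),            # posture
            ItemSpec(29),            # gait
            ItemSpec(31),            # body bradykinesia
            ItemSpec(32),            # dyskinesia duration
            ItemSpec(39),            # proportion of waking day in "off" state
        )
    )
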