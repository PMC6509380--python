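"""Barcode/backbone study conditions.

A condition records which DNA barcode regions (rbcL, matK, ITS, ITS2) were
concatenated into the supermatrix a set of trees was inferred from, and
whether tree inference was constrained by a family-level backbone.  The seven
supermatrices of the study design are every combination of

    {rbcL+matK}  ∪  {each plastid × each ITS variant}
                 ∪  {both plastids × each ITS variant},

i.e. R+M, R+I, R+I2, M+I, M+I2, R+M+I, R+M+I2; crossed with the backbone
flag they give the fourteen tree sets of the full design.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = ["Condition", "enumerate_supermatrices", "enumerate_conditions"]

#: canonical term order used in model labels (matches "~B + M + R + I" style)
TERM_ORDER = ("backbone", "matK", "rbcL", "ITS", "ITS2")
TERM_LETTER = {"backbone": "B", "matK": "M", "rbcL": "R", "ITS": "I", "ITS2": "I2"}
LETTER_TERM = {v: k for k, v in TERM_LETTER.items()}

#: barcode display order used in condition labels
_BARCODE_ORDER = ("rbcL", "matK", "ITS", "ITS2")
_BARCODE_LETTER = {"rbcL": "R", "matK": "M", "ITS": "I", "ITS2": "I2"}


@dataclass(frozen=True)
class Condition:
    """Barcode composition of a supermatrix plus the backbone flag."""

    has_rbcL: bool = False
    has_matK: bool = False
    has_ITS: bool = False
    has_ITS2: bool = False
    has_backbone: bool = False

    def __post_init__(self):
        if self.has_ITS and self.has_ITS2:
            raise ValueError("ITS and ITS2 are mutually exclusive")

    @property
    def barcodes(self) -> tuple:
        return tuple(
            b for b in _BARCODE_ORDER if getattr(self, f"has_{b}")
        )

    @property
    def indicators(self) -> dict:
        """0/1 fixed-effect indicators keyed by term name."""
        return {
            "rbcL": int(self.has_rbcL),
            "matK": int(self.has_matK),
            "ITS": int(self.has_ITS),
            "ITS2": int(self.has_ITS2),
            "backbone": int(self.has_backbone),
        }

    @property
    def label(self) -> str:
        parts = [_BARCODE_LETTER[b] for b in self.barcodes]
        if self.has_backbone:
            parts.append("B")
        return "+".join(parts) if parts else "none"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        flags = dict.fromkeys(
            ("has_rbcL", "has_matK", "has_ITS", "has_ITS2", "has_backbone"), False
        )
        if label and label != "none":
            rev = {"R": "has_rbcL", "M": "has_matK", "I": "has_ITS",
                   "I2": "has_ITS2", "B": "has_backbone"}
            for tok in label.split("+"):
                tok = tok.strip()
                if tok not in rev:
                    raise ValueError(f"unknown condition token: {tok!r}")
                flags[rev[tok]] = True
        return cls(**flags)

    def __str__(self):
        return self.label


def enumerate_supermatrices() -> list:
    """The seven barcode supermatrices of the study design (no backbone)."""
    out = [Condition(has_rbcL=True, has_matK=True)]
    for plastid in ("rbcL", "matK"):
        for its in ("ITS", "ITS2"):
            out.append(Condition(**{f"has_{plastid}": True, f"has_{its}": True}))
    for its in ("ITS", "ITS2"):
        out.append(
            Condition(has_rbcL=True, has_matK=True, **{f"has_{its}": True})
        )
    return out


def enumerate_conditions() -> list:
    """All fourteen tree-set conditions: 7 supermatrices × backbone yes/no."""
    out = []
    for sm, bb in product(enumerate_supermatrices(), (False, True)):
        out.append(
            Condition(
                has_rbcL=sm.has_rbcL, has_matK=sm.has_matK,
                has_ITS=sm.has_ITS, has_ITS2=sm.has_ITS2, has_backbone=bb,
            )
        )
    return out
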