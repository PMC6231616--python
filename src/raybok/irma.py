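"""IRMA mono-hierarchical multi-axial codes.

An IRMA code annotates a radiograph with four independent axes packed into a
13-character alphanumeric string, canonically written ``TTTT-DDD-AAA-BBB``:

* **T** (technical, 4 chars) — imaging modality and technique,
* **D** (directional, 3 chars) — body orientation,
* **A** (anatomical, 3 chars) — body region examined,
* **B** (biological, 3 chars) — organ system examined.

Each axis is mono-hierarchical: characters further right refine the meaning of
the characters to their left.  This module parses and validates codes,
projects them onto the five classification schemes used for evaluation (one
per axis plus the full joined code), enumerates class universes from a label
table, and optionally decodes axis values through a user-supplied dictionary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IrmaCode",
    "LabelTable",
    "SCHEMES",
    "UNKNOWN_CODE_MARKER",
    "parse_irma_code",
    "format_irma_code",
    "project_to_scheme",
    "enumerate_classes",
    "decode_axis_label",
    "load_axis_dictionary",
]

#: The five classification schemes: one per axis plus the full joined code.
SCHEMES = ("T", "D", "A", "B", "IRMA")

#: Marker returned when an axis value is absent from a decoding dictionary.
UNKNOWN_CODE_MARKER = "<unknown code>"

_AXIS_LENGTHS = {"T": 4, "D": 3, "A": 3, "B": 3}
_VALID_CHAR = re.compile(r"[0-9a-z]")


class IrmaCodeError(ValueError):
    """Raised for malformed IRMA code strings."""


@dataclass(frozen=True)
class IrmaCode:
    """A parsed 13-character IRMA code split into its four axes."""

    technical: str
    directional: str
    anatomical: str
    biological: str

    def __post_init__(self) -> None:
        for axis, value in zip("TDAB", self._axes()):
            expected = _AXIS_LENGTHS[axis]
            if len(value) != expected:
                raise IrmaCodeError(
                    f"{axis} axis must have {expected} characters, got {value!r}"
                )
            for pos, ch in enumerate(value):
                if not _VALID_CHAR.fullmatch(ch):
                    raise IrmaCodeError(
                        f"illegal character {ch!r} at position {pos} of {axis} axis"
                    )

    def _axes(self) -> tuple[str, str, str, str]:
        return (self.technical, self.directional, self.anatomical, self.biological)

    def axis(self, scheme: str) -> str:
        """Return the axis value for a single-axis scheme."""
        return {
            "T": self.technical,
            "D": self.directional,
            "A": self.anatomical,
            "B": self.biological,
        }[scheme]

    def __str__(self) -> str:
        return "-".join(self._axes())


def parse_irma_code(text: str) -> IrmaCode:
    """Parse a hyphenated (16 chars) or raw (13 chars) IRMA code string.

    Accepts ``TTTT-DDD-AAA-BBB`` or the bare 13-character concatenation; the
    canonical output form is always hyphenated.

    Raises
    ------
    IrmaCodeError
        On wrong length, misplaced hyphens, or illegal characters, naming the
        offending position.
    """
    if not isinstance(text, str):
        raise IrmaCodeError(f"expected a string, got {type(text).__name__}")
    if len(text) == 16:
        for pos in (4, 8, 12):
            if text[pos] != "-":
                raise IrmaCodeError(
                    f"expected hyphen at position {pos} of {text!r}, got {text[pos]!r}"
                )
        raw = text[:4] + text[5:8] + text[9:12] + text[13:16]
        if "-" in raw:
            pos = text.index("-", 0)
            raise IrmaCodeError(f"misplaced hyphen in {text!r}")
    elif len(text) == 13:
        raw = text
    else:
        raise IrmaCodeError(
            f"IRMA code must have 13 characters (or 16 with hyphens), "
            f"got {len(text)} in {text!r}"
        )
    for pos, ch in enumerate(raw):
        if not _VALID_CHAR.fullmatch(ch):
            raise IrmaCodeError(f"illegal character {ch!r} at position {pos} of {text!r}")
    return IrmaCode(raw[:4], raw[4:7], raw[7:10], raw[10:13])


def format_irma_code(code: IrmaCode) -> str:
    """Canonical hyphenated text form ``TTTT-DDD-AAA-BBB``."""
    return str(code)


def project_to_scheme(code: IrmaCode, scheme: str) -> str:
    """Project a code onto one classification scheme.

    ``T`` yields the 4-character technical label, ``D``/``A``/``B`` the
    3-character axis labels, and ``IRMA`` the full 16-character canonical
    string.
    """
    _check_scheme(scheme)
    if scheme == "IRMA":
        return str(code)
    return code.axis(scheme)


@dataclass
class LabelTable:
    """Rows of (image filename, IRMA code), optionally with a train/test flag.

    Serialized as CSV with header ``image_id,irma_code`` (plus ``split`` when
    present); codes are stored hyphenated.
    """

    image_ids: list[str]
    codes: list[IrmaCode]
    splits: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.image_ids) != len(self.codes):
            raise ValueError("image_ids and codes must have the same length")
        if self.splits is not None and len(self.splits) != len(self.codes):
            raise ValueError("splits must match the number of rows")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("image_id values must be unique")

    def __len__(self) -> int:
        return len(self.image_ids)

    def __iter__(self):
        return iter(zip(self.image_ids, self.codes))

    def labels(self, scheme: str) -> list[str]:
        return [project_to_scheme(c, scheme) for c in self.codes]

    def subset(self, split: str) -> "LabelTable":
        """Rows whose split flag equals ``split`` (e.g. 'train' or 'test')."""
        if self.splits is None:
            raise ValueError("table carries no split column")
        keep = [i for i, s in enumerate(self.splits) if s == split]
        return LabelTable(
            [self.image_ids[i] for i in keep],
            [self.codes[i] for i in keep],
            [self.splits[i] for i in keep],
        )

    def to_csv(self, path: str | Path) -> None:
        data = {"image_id": self.image_ids, "irma_code": [str(c) for c in self.codes]}
        if self.splits is not None:
            data["split"] = self.splits
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelTable":
        df = pd.read_csv(path, dtype=str)
        for col in ("image_id", "irma_code"):
            if col not in df.columns:
                raise ValueError(f"label CSV is missing required column {col!r}")
        codes = [parse_irma_code(c) for c in df["irma_code"]]
        splits = list(df["split"]) if "split" in df.columns else None
        return cls(list(df["image_id"]), codes, splits)


def enumerate_classes(table: LabelTable, scheme: str) -> list[str]:
    """Sorted distinct class labels of ``table`` under ``scheme``.

    The class universe is derived from data, never hard-coded; an empty table
    is an error because it defines no universe.
    """
    _check_scheme(scheme)
    if len(table) == 0:
        raise ValueError("cannot enumerate classes of an empty label table")
    return sorted({project_to_scheme(c, scheme) for c in table.codes})


def load_axis_dictionary(path: str | Path) -> dict[str, str]:
    """Load a TSV dictionary mapping axis value -> human-readable text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"axis dictionary not found: {path}")
    out: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        key, _, text = line.partition("\t")
        out[key.strip()] = text.strip()
    return out


def decode_axis_label(
    axis_value: str,
    axis: str,
    dictionary: Mapping[str, str] | str | Path,
) -> str:
    """Translate an axis value to human-readable text via a lookup table.

    The full IRMA terminology is not bundled; the dictionary is a
    user-supplied TSV (``axis_value<TAB>description``) or an in-memory
    mapping.  Missing values yield :data:`UNKNOWN_CODE_MARKER`.
    """
    _check_scheme(axis)
    if axis == "IRMA":
        raise ValueError("decode_axis_label works on single axes, not the full code")
    if not isinstance(dictionary, Mapping):
        dictionary = load_axis_dictionary(dictionary)
    return dictionary.get(axis_value, UNKNOWN_CODE_MARKER)


def _check_scheme(scheme: str) -> None:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
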