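"""ID-table cleaning and fixed-width character-positional encoding.

An identifier string is turned into a fixed-width integer vector: feature
``posj`` is the integer code of the identifier's j-th character, and
positions past the identifier's end carry the reserved pad code 0.  The code
map is fixed and case-sensitive (identifier case is meaningful), and is
stored alongside trained models so prediction always reuses the training map.
"""

from __future__ import annotations

import json
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CharEncoding",
    "EncodedMatrix",
    "default_char_encoding",
    "clean_table",
    "pad_length",
    "split_and_pad",
    "encode",
    "encode_table",
    "decode",
    "read_id_table",
    "write_id_table",
]

#: Pad symbol used in character matrices (never a valid identifier character).
PAD = ""


class EncodingError(ValueError):
    """A character outside the encoding's inventory was met in strict mode."""


@dataclass(frozen=True)
class CharEncoding:
    """Injective character -> positive-integer code map with pad code 0."""

    code_map: dict[str, int]
    pad_code: int = 0

    def __post_init__(self) -> None:
        codes = list(self.code_map.values())
        if len(set(codes)) != len(codes):
            raise ValueError("code map is not injective")
        if self.pad_code in codes:
            raise ValueError("pad code collides with a character code")
        if any(c <= self.pad_code for c in codes):
            raise ValueError("character codes must exceed the pad code")

    @property
    def inverse(self) -> dict[int, str]:
        return {v: k for k, v in self.code_map.items()}

    @property
    def max_code(self) -> int:
        return max(self.code_map.values())

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"pad_code": self.pad_code, "code_map": self.code_map}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CharEncoding":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(code_map=dict(payload["code_map"]), pad_code=int(payload["pad_code"]))


def default_char_encoding() -> CharEncoding:
    """Canonical map: digits 1-10, 'A'-'Z' 11-36, 'a'-'z' 37-62, ``._-:/()`` 63-69."""
    chars = string.digits + string.ascii_uppercase + string.ascii_lowercase + "._-:/()"
    return CharEncoding(code_map={ch: i + 1 for i, ch in enumerate(chars)})


@dataclass
class EncodedMatrix:
    """n x L integer feature matrix plus optional labels.

    Row order always mirrors the source table.  ``feature_names`` label the
    character positions (``pos1`` ... ``posL``).
    """

    X: np.ndarray
    y: np.ndarray | None
    encoding: CharEncoding
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int16)
        if not self.feature_names:
            self.feature_names = [f"pos{j + 1}" for j in range(self.X.shape[1])]
        if self.y is not None:
            self.y = np.asarray(self.y)
            if len(self.y) != len(self.X):
                raise ValueError("labels and matrix length differ")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "EncodedMatrix":
        y = None if self.y is None else self.y[idx]
        return EncodedMatrix(self.X[idx], y, self.encoding, list(self.feature_names))


# ---------------------------------------------------------------------------


def clean_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Drop empty/missing ids and exact duplicate (id, class) rows.

    Idempotent; preserves row order. Requires ``id`` and ``class`` columns.
    """
    missing = {"id", "class"} - set(raw.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    df = raw[["id", "class"]].copy()
    df["id"] = df["id"].astype("string").str.strip()
    ok = df["id"].notna() & (df["id"] != "")
    df = df[ok]
    df = df.drop_duplicates(subset=["id", "class"], keep="first")
    df["id"] = df["id"].astype(str)
    return df.reset_index(drop=True)


def pad_length(table: pd.DataFrame) -> int:
    """Length of the longest identifier in the table."""
    if len(table) == 0:
        raise ValueError("empty table has no pad length")
    return int(table["id"].astype(str).str.len().max())


def split_and_pad(table: pd.DataFrame, L: int) -> np.ndarray:
    """n x L character matrix: row i holds id i's characters, left-aligned,
    right-padded with the pad symbol."""
    ids = table["id"].astype(str).tolist()
    longest = max((len(s) for s in ids), default=0)
    if L < longest:
        raise ValueError(f"pad length {L} smaller than longest id ({longest})")
    mat = np.full((len(ids), L), PAD, dtype=object)
    for i, s in enumerate(ids):
        mat[i, : len(s)] = list(s)
    return mat


def encode(
    char_matrix: np.ndarray,
    encoding: CharEncoding,
    y=None,
    on_unknown: str = "error",
) -> EncodedMatrix:
    """Map a character matrix to integer codes (pad symbol -> pad code).

    ``on_unknown='error'`` (training) reports the offending character and
    row; ``on_unknown='pad'`` (prediction) maps unknown characters to the pad
    code with a warning.
    """
    if on_unknown not in {"error", "pad"}:
        raise ValueError("on_unknown must be 'error' or 'pad'")
    n, L = char_matrix.shape
    X = np.zeros((n, L), dtype=np.int16)
    code_map = encoding.code_map
    unknown: set[str] = set()
    for i in range(n):
        row = char_matrix[i]
        for j in range(L):
            ch = row[j]
            if ch == PAD:
                continue
            code = code_map.get(ch)
            if code is None:
                if on_unknown == "error":
                    raise EncodingError(f"unknown character {ch!r} in row {i}")
                unknown.add(ch)
            else:
                X[i, j] = code
    if unknown:
        warnings.warn(
            f"{len(unknown)} unknown character(s) mapped to pad code: {sorted(unknown)}",
            stacklevel=2,
        )
    yy = None if y is None else np.asarray(y)
    return EncodedMatrix(X, yy, encoding)


def encode_table(
    table: pd.DataFrame,
    encoding: CharEncoding | None = None,
    L: int | None = None,
    on_unknown: str = "error",
) -> EncodedMatrix:
    """Clean-table -> EncodedMatrix convenience (split, pad, encode).

    At prediction time ids longer than the training pad length ``L`` are
    truncated to ``L`` with a warning.
    """
    encoding = encoding or default_char_encoding()
    if L is None:
        L = pad_length(table)
    else:
        too_long = table["id"].astype(str).str.len() > L
        if too_long.any():
            warnings.warn(
                f"{int(too_long.sum())} id(s) longer than pad length {L}; truncated",
                stacklevel=2,
            )
            table = table.copy()
            table["id"] = table["id"].astype(str).str.slice(0, L)
    chars = split_and_pad(table, L)
    y = table["class"].to_numpy() if "class" in table.columns else None
    return encode(chars, encoding, y=y, on_unknown=on_unknown)


def decode(X: np.ndarray, encoding: CharEncoding) -> list[str]:
    """Inverse of :func:`encode` for valid rows (codes -> id strings)."""
    inv = encoding.inverse
    out = []
    for row in np.asarray(X):
        out.append("".join(inv.get(int(c), "") for c in row if int(c) != encoding.pad_code))
    return out


def read_id_table(path) -> pd.DataFrame:
    """Read a TSV ID table (columns ``id``, optionally ``class``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError("id column missing")
    return df


def write_id_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
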