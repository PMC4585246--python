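"""Character-coordinate geometry of fixed-width-font sentences.

Sentences are displayed in a fixed-width font, so the horizontal gaze
position maps affinely onto a continuous character coordinate: coordinate
0 is the left edge of the first letter and one unit is one letter cell
(default 14 px).  Inter-word spaces are counted in the coordinate system
— a spatial eye-voice span therefore measures display-line distance
including spaces — but the space cells are owned by no word.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "WordToken",
    "SentenceLayout",
    "build_layout",
    "gaze_to_char",
    "char_to_word",
    "locate_char",
]


@dataclass(frozen=True)
class WordToken:
    """One word of a displayed sentence with its character span.

    ``char_start``/``char_end`` are 0-based, half-open character indices
    into the sentence string; ``char_end - char_start`` is the word
    length in letters.
    """

    index: int
    text: str
    char_start: int
    char_end: int
    frequency_per_million: float = float("nan")
    predictability: float = float("nan")

    @property
    def length_letters(self) -> int:
        return self.char_end - self.char_start

    def __post_init__(self) -> None:
        if self.char_end <= self.char_start:
            raise ValueError("empty word token span")
        if len(self.text) != self.char_end - self.char_start:
            raise ValueError(
                f"token text {self.text!r} does not match span "
                f"[{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class SentenceLayout:
    """Geometry of one displayed sentence.

    ``origin_px`` is the pixel x of character coordinate 0 and
    ``px_per_char`` the width of one letter cell in pixels.
    """

    sentence_text: str
    tokens: tuple[WordToken, ...]
    origin_px: float
    px_per_char: float = 14.0

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("layout needs at least one token")
        if self.px_per_char <= 0:
            raise ValueError("px_per_char must be positive")

    @property
    def n_words(self) -> int:
        return len(self.tokens)

    @property
    def n_chars(self) -> int:
        return len(self.sentence_text)

    def char_to_px(self, char_coord: float) -> float:
        """Inverse of :func:`gaze_to_char`."""
        return self.origin_px + char_coord * self.px_per_char


def build_layout(
    sentence_text: str,
    word_properties: pd.DataFrame | None = None,
    origin_px: float = 0.0,
    px_per_char: float = 14.0,
) -> SentenceLayout:
    """Tokenize a single-space-separated sentence into a layout.

    ``word_properties`` (optional) is a table with one row per word in
    sentence order; columns ``frequency_per_million`` and
    ``predictability`` are attached to the tokens when present.

    Raises ``ValueError`` if the sentence is empty or the property table
    row count does not match the word count.
    """
    if not sentence_text or not sentence_text.strip():
        raise ValueError("empty sentence")
    words = sentence_text.split(" ")
    if any(w == "" for w in words):
        raise ValueError("sentence must be single-space separated")
    if word_properties is not None and len(word_properties) != len(words):
        raise ValueError(
            f"word count mismatch: sentence has {len(words)} words but the "
            f"property table has {len(word_properties)} rows"
        )
    tokens = []
    pos = 0
    for i, w in enumerate(words):
        freq, pred = float("nan"), float("nan")
        if word_properties is not None:
            row = word_properties.iloc[i]
            freq = float(row.get("frequency_per_million", float("nan")))
            pred = float(row.get("predictability", float("nan")))
        tokens.append(
            WordToken(
                index=i,
                text=w,
                char_start=pos,
                char_end=pos + len(w),
                frequency_per_million=freq,
                predictability=pred,
            )
        )
        pos += len(w) + 1  # the separating space is owned by no word
    return SentenceLayout(
        sentence_text=sentence_text,
        tokens=tuple(tokens),
        origin_px=float(origin_px),
        px_per_char=float(px_per_char),
    )


def gaze_to_char(layout: SentenceLayout, x_px: float) -> float:
    """Map a pixel x-position to a continuous character coordinate.

    Pure affine map ``(x - origin) / px_per_char``; the result may be
    negative or beyond the sentence end (callers clamp via
    :func:`locate_char`).
    """
    return (x_px - layout.origin_px) / layout.px_per_char


def locate_char(layout: SentenceLayout, char_coord: float) -> tuple[int, bool]:
    """Resolve a character coordinate to ``(word_index, in_bounds)``.

    The integer character cell ``floor(char_coord)`` decides: a cell
    inside a token's span belongs to that token; a cell on a separating
    space or outside the sentence goes to the nearest token by letter
    distance, ties to the following token.  Off-sentence coordinates
    resolve to the first/last token with ``in_bounds=False``.
    """
    import math

    cell = math.floor(char_coord)
    in_bounds = 0 <= char_coord < layout.n_chars
    if cell < 0:
        return 0, in_bounds
    if cell >= layout.n_chars:
        return layout.n_words - 1, in_bounds
    best, best_dist = 0, float("inf")
    for tok in layout.tokens:
        if tok.char_start <= cell < tok.char_end:
            return tok.index, in_bounds
        # distance from the cell to the token's nearest owned cell
        dist = max(tok.char_start - cell, cell - (tok.char_end - 1))
        if dist < best_dist or dist == best_dist:  # ties go forward
            best, best_dist = tok.index, dist
    return best, in_bounds


def char_to_word(layout: SentenceLayout, char_coord: float) -> int:
    """Word index for a character coordinate (see :func:`locate_char`)."""
    return locate_char(layout, char_coord)[0]
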