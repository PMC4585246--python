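"""Continuous voice position from word articulation intervals.

The voice position at time ``t`` is expressed in the sentence's
character coordinates.  Within an articulated word the position is
linearly interpolated — the per-letter duration is the word's
articulated duration divided by its number of letters — so over a
word's interval the voice advances by exactly its letter count.  During
inter-word pauses the position holds at the completed word's end
(nothing is being articulated; spaces are never articulated, so the
voice jumps over the space cell at the next word's onset).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .io_formats import WordInterval
from .text_layout import SentenceLayout

__all__ = ["VoiceTimeline", "voice_char_at", "articulation_onset"]


@dataclass
class VoiceTimeline:
    """Tracker-clock articulation intervals bound to a sentence layout."""

    intervals: list[WordInterval]
    layout: SentenceLayout

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.word_index)
        for a, b in zip(ivs, ivs[1:]):
            if b.t_on_ms < a.t_off_ms - 1e-9:
                raise ValueError("overlapping articulation intervals")
            if b.word_index == a.word_index:
                raise ValueError(f"duplicate interval for word {a.word_index}")
        for iv in ivs:
            if iv.clock != "tracker":
                raise ValueError("VoiceTimeline expects tracker-clock intervals")
            if not 0 <= iv.word_index < self.layout.n_words:
                raise ValueError(f"interval for unknown word {iv.word_index}")
        self.intervals = ivs
        self._onsets = [iv.t_on_ms for iv in ivs]

    @property
    def articulation_start_ms(self) -> float | None:
        return self.intervals[0].t_on_ms if self.intervals else None

    @property
    def articulation_end_ms(self) -> float | None:
        return self.intervals[-1].t_off_ms if self.intervals else None

    def by_word(self, word_index: int) -> WordInterval | None:
        for iv in self.intervals:
            if iv.word_index == word_index:
                return iv
        return None


def voice_char_at(vt: VoiceTimeline, t_ms: float) -> float | None:
    """Character coordinate of the voice at tracker time ``t_ms``.

    Returns ``None`` before articulation starts; holds at the last
    completed word's end during pauses and after articulation ends.
    """
    if not vt.intervals or t_ms < vt.intervals[0].t_on_ms:
        return None
    # last interval with onset <= t
    k = bisect.bisect_right(vt._onsets, t_ms) - 1
    iv = vt.intervals[k]
    tok = vt.layout.tokens[iv.word_index]
    if t_ms >= iv.t_off_ms:  # pause after word k, or past the end
        return float(tok.char_end)
    frac = (t_ms - iv.t_on_ms) / (iv.t_off_ms - iv.t_on_ms)
    return tok.char_start + tok.length_letters * frac


def articulation_onset(vt: VoiceTimeline, word_index: int) -> float | None:
    """Tracker time at which the word's articulation began, or ``None``
    if the word was never articulated."""
    iv = vt.by_word(word_index)
    return None if iv is None else iv.t_on_ms
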