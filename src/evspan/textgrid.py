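"""Minimal Praat TextGrid text-format reader and writer.

Supports interval tiers in both the long ("verbose") and short text
encodings.  Point (TextTier) tiers are parsed and ignored.  Labels
round-trip exactly, including embedded spaces and Praat's doubled-quote
escape; boundary times round-trip to full float precision (written with
``repr``), comfortably inside 1 µs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = ["Interval", "IntervalTier", "TextGrid", "read_textgrid", "write_textgrid"]


@dataclass(frozen=True)
class Interval:
    xmin: float
    xmax: float
    label: str


@dataclass
class IntervalTier:
    name: str
    xmin: float
    xmax: float
    intervals: list[Interval] = field(default_factory=list)


@dataclass
class TextGrid:
    xmin: float
    xmax: float
    tiers: list[IntervalTier] = field(default_factory=list)

    def tier(self, name: str) -> IntervalTier:
        for t in self.tiers:
            if t.name == name:
                return t
        raise KeyError(f"no interval tier named {name!r}; "
                       f"available: {[t.name for t in self.tiers]}")


def _unquote(s: str) -> str:
    return s[1:-1].replace('""', '"')


def _quote(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def _tokenize(text: str) -> list[str]:
    """Split a short-format body into number and quoted-string tokens."""
    tokens = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == '"':
            j = i + 1
            while j < n:
                if text[j] == '"':
                    if j + 1 < n and text[j + 1] == '"':
                        j += 2
                        continue
                    break
                j += 1
            tokens.append(text[i : j + 1])
            i = j + 1
        else:
            j = i
            while j < n and not text[j].isspace():
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def _parse_short(body: str) -> TextGrid:
    toks = _tokenize(body)
    pos = 0

    def nxt() -> str:
        nonlocal pos
        t = toks[pos]
        pos += 1
        return t

    xmin, xmax = float(nxt()), float(nxt())
    exists = nxt()  # <exists> flag
    if exists not in ("<exists>", "1"):
        return TextGrid(xmin, xmax, [])
    ntiers = int(nxt())
    grid = TextGrid(xmin, xmax, [])
    for _ in range(ntiers):
        klass = _unquote(nxt())
        name = _unquote(nxt())
        t_xmin, t_xmax = float(nxt()), float(nxt())
        size = int(nxt())
        if klass == "IntervalTier":
            tier = IntervalTier(name, t_xmin, t_xmax)
            for _ in range(size):
                a, b = float(nxt()), float(nxt())
                tier.intervals.append(Interval(a, b, _unquote(nxt())))
            grid.tiers.append(tier)
        else:  # TextTier: number + label per point, skipped
            for _ in range(size):
                nxt()
                nxt()
    return grid


_LONG_NUM = re.compile(r"^\s*(xmin|xmax|number)\s*=\s*(\S+)")
_LONG_STR = re.compile(r'^\s*(class|name|text|mark)\s*=\s*(".*")\s*$', re.DOTALL)
_LONG_ITEM = re.compile(r"^\s*(item|intervals|points)\s*\[\s*\d*\s*\]\s*:")
_LONG_SIZE = re.compile(r"^\s*(?:intervals|points):\s*size\s*=\s*(\d+)")


def _parse_long(body: str) -> TextGrid:
    lines = body.splitlines()
    grid: TextGrid | None = None
    g_xmin = g_xmax = 0.0
    tier: IntervalTier | None = None
    tier_class = ""
    # parser state: scope is "grid", "tier" or "interval"
    scope = "grid"
    cur: dict[str, float | str] = {}
    pending_tier: dict[str, float | str] = {}

    def flush_interval() -> None:
        nonlocal cur
        if scope == "interval" and tier is not None and "text" in cur:
            tier.intervals.append(
                Interval(float(cur["xmin"]), float(cur["xmax"]), str(cur["text"]))
            )
        cur = {}

    tiers: list[IntervalTier] = []
    for line in lines:
        s = line.strip()
        if not s:
            continue
        m = _LONG_ITEM.match(s)
        if m:
            kind = m.group(1)
            if kind == "item" and "[" in s and s.strip() != "item []:":
                flush_interval()
                tier = None
                tier_class = ""
                pending_tier = {}
                scope = "tier"
            elif kind in ("intervals", "points"):
                flush_interval()
                scope = "interval"
            continue
        m = _LONG_STR.match(s)
        if m:
            key, val = m.group(1), _unquote(m.group(2).strip())
            if scope == "tier":
                if key == "class":
                    tier_class = val
                elif key == "name":
                    pending_tier["name"] = val
            elif scope == "interval" and key == "text":
                cur["text"] = val
            continue
        m = _LONG_NUM.match(s)
        if m:
            key, val = m.group(1), float(m.group(2))
            if scope == "grid":
                if key == "xmin":
                    g_xmin = val
                elif key == "xmax":
                    g_xmax = val
            elif scope == "tier":
                pending_tier[key] = val
                if key == "xmax" and tier_class == "IntervalTier":
                    tier = IntervalTier(
                        str(pending_tier.get("name", "")),
                        float(pending_tier.get("xmin", 0.0)),
                        val,
                    )
                    tiers.append(tier)
            elif scope == "interval":
                cur[key] = val
            continue
        if _LONG_SIZE.match(s):
            continue
    flush_interval()
    return TextGrid(g_xmin, g_xmax, tiers)


def read_textgrid(source: str | TextIO) -> TextGrid:
    """Parse a TextGrid from a path, text content, or open text stream."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "ooTextFile" not in text:
            with open(text, encoding="utf-8") as fh:
                text = fh.read()
    if "ooTextFile" not in text or "TextGrid" not in text:
        raise ValueError("not a Praat TextGrid text file")
    # strip the two header lines
    body = re.sub(
        r'^\s*File type\s*=\s*"ooTextFile"\s*Object class\s*=\s*"TextGrid"\s*',
        "",
        text,
        flags=re.DOTALL,
    )
    if re.search(r"^\s*xmin\s*=", body, flags=re.MULTILINE):
        return _parse_long(body)
    return _parse_short(body)


def _fmt(x: float) -> str:
    return repr(float(x))


def write_textgrid(grid: TextGrid, stream: TextIO, fmt: str = "long") -> None:
    """Serialize a TextGrid in the long or short text encoding."""
    w = stream.write
    w('File type = "ooTextFile"\n')
    w('Object class = "TextGrid"\n\n')
    if fmt == "short":
        w(f"{_fmt(grid.xmin)}\n{_fmt(grid.xmax)}\n<exists>\n{len(grid.tiers)}\n")
        for t in grid.tiers:
            w('"IntervalTier"\n')
            w(f"{_quote(t.name)}\n{_fmt(t.xmin)}\n{_fmt(t.xmax)}\n")
            w(f"{len(t.intervals)}\n")
            for iv in t.intervals:
                w(f"{_fmt(iv.xmin)}\n{_fmt(iv.xmax)}\n{_quote(iv.label)}\n")
        return
    if fmt != "long":
        raise ValueError(f"unknown TextGrid format {fmt!r}")
    w(f"xmin = {_fmt(grid.xmin)}\n")
    w(f"xmax = {_fmt(grid.xmax)}\n")
    w("tiers? <exists>\n")
    w(f"size = {len(grid.tiers)}\n")
    w("item []:\n")
    for k, t in enumerate(grid.tiers, start=1):
        w(f"    item [{k}]:\n")
        w('        class = "IntervalTier"\n')
        w(f"        name = {_quote(t.name)}\n")
        w(f"        xmin = {_fmt(t.xmin)}\n")
        w(f"        xmax = {_fmt(t.xmax)}\n")
        w(f"        intervals: size = {len(t.intervals)}\n")
        for j, iv in enumerate(t.intervals, start=1):
            w(f"        intervals [{j}]:\n")
            w(f"            xmin = {_fmt(iv.xmin)}\n")
            w(f"            xmax = {_fmt(iv.xmax)}\n")
            w(f"            text = {_quote(iv.label)}\n")


def fill_gaps(
    intervals: Iterable[tuple[float, float, str]], xmin: float, xmax: float
) -> list[Interval]:
    """Tile [xmin, xmax] with the given labelled intervals plus empty fillers,
    as Praat interval tiers require."""
    out: list[Interval] = []
    t = xmin
    for a, b, lab in intervals:
        if a < t - 1e-12:
            raise ValueError("overlapping intervals")
        if a > t:
            out.append(Interval(t, a, ""))
        out.append(Interval(a, b, lab))
        t = b
    if xmax > t:
        out.append(Interval(t, xmax, ""))
    return out
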