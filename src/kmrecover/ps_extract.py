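"""Extract line segments and dots from PostScript text.

PostScript pages are described in printer points (72 per inch).  A published
step curve is a sequence of stroked line segments; a censored observation is
sometimes encoded as a zero-length segment ("an invisible dot").  This module
tokenizes the page description and interprets the small operator subset that
path construction uses — ``moveto``/``lineto`` and relatives, the graphics
state operators (``gsave``/``grestore``), and the coordinate-system operators
(``translate``, ``scale``, ``rotate``, ``concat``) — emitting every stroked
segment in device coordinates.

Everything else in the file (fonts, shading, clipping, procedure machinery) is
irrelevant to the curve and is skipped; a count of skipped operators is logged
so the user can judge how exotic the file is.  Binary input (e.g. a PDF passed
by mistake) is rejected: the workflow expects the figure exported as
PostScript *text* by a PDF viewer.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import PostScriptError

logger = logging.getLogger(__name__)

DEFAULT_SNAP_TOL = 1e-6  # points; segments at or below this length are dots
DEFAULT_MAX_BYTES = 100_000_000

#: affine matrix (a, b, c, d, e, f): x' = a x + c y + e ; y' = b x + d y + f
Matrix = tuple[float, float, float, float, float, float]
IDENTITY: Matrix = (1.0, 0.0, 0.0, 1.0, 0.0, 0.0)


@dataclass(frozen=True)
class StrokeAttrs:
    """Graphics attributes at stroke time, used downstream to group paths."""

    linewidth: float = 1.0
    color: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PathSegment:
    """One stroked line segment (or zero-length dot) in device space."""

    x0: float
    y0: float
    x1: float
    y1: float
    path_id: int
    is_dot: bool
    stroke_attrs: StrokeAttrs = StrokeAttrs()

    @property
    def length(self) -> float:
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)


@dataclass
class Token:
    kind: str  # "number" | "name" | "literal" | "proc"
    value: object
    offset: int

    def __repr__(self) -> str:  # compact, for parse-error messages
        return f"{self.value!r}@{self.offset}"


_NUMBER_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?$")


def _check_text(data: bytes) -> None:
    """Reject binary input, naming the first offending byte offset."""
    allowed_ctrl = {9, 10, 12, 13}
    for i, b in enumerate(data):
        if b < 32 and b not in allowed_ctrl:
            raise PostScriptError("not a PostScript text file", offset=i)


def tokenize_postscript(text: str | bytes, max_bytes: int = DEFAULT_MAX_BYTES) -> list[Token]:
    """Lex PostScript text into numbers, names and opaque procedure blocks.

    Comments (``%`` to end of line), string literals ``(...)`` (with nesting
    and backslash escapes) and hex strings ``<...>`` are skipped.  Procedure
    bodies ``{ ... }`` are retained as single opaque tokens.
    """
    if isinstance(text, bytes):
        data = text
    else:
        data = text.encode("latin-1", errors="replace")
    if len(data) > max_bytes:
        raise PostScriptError(f"input exceeds configured size limit ({max_bytes} bytes)")
    _check_text(data)
    s = data.decode("latin-1")

    tokens: list[Token] = []
    i, n = 0, len(s)
    delim = "()<>[]{}/%"
    while i < n:
        ch = s[i]
        if ch in " \t\r\n\f":
            i += 1
            continue
        if ch == "%":
            j = i
            while j < n and s[j] not in "\r\n":
                j += 1
            i = j
            continue
        if ch == "(":
            depth, j = 1, i + 1
            while j < n and depth:
                if s[j] == "\\":
                    j += 2
                    continue
                if s[j] == "(":
                    depth += 1
                elif s[j] == ")":
                    depth -= 1
                j += 1
            i = j
            continue
        if ch == "<":
            j = s.find(">", i + 1)
            i = n if j < 0 else j + 1
            continue
        if ch == "{":
            depth, j = 1, i + 1
            while j < n and depth:
                if s[j] == "{":
                    depth += 1
                elif s[j] == "}":
                    depth -= 1
                j += 1
            tokens.append(Token("proc", s[i:j], i))
            i = j
            continue
        if ch in "[]":
            tokens.append(Token("name", ch, i))
            i += 1
            continue
        if ch == "/":
            j = i + 1
            while j < n and s[j] not in " \t\r\n\f" + delim:
                j += 1
            tokens.append(Token("literal", s[i + 1 : j], i))
            i = j
            continue
        # regular token: number or executable name
        j = i
        while j < n and s[j] not in " \t\r\n\f" + delim:
            j += 1
        word = s[i:j]
        if _NUMBER_RE.match(word):
            tokens.append(Token("number", float(word), i))
        else:
            tokens.append(Token("name", word, i))
        i = j
    return tokens


def _mat_mul(m: Matrix, n: Matrix) -> Matrix:
    """Matrix for: apply m, then n."""
    ma, mb, mc, md, me, mf = m
    na, nb, nc, nd, ne, nf = n
    return (
        ma * na + mb * nc,
        ma * nb + mb * nd,
        mc * na + md * nc,
        mc * nb + md * nd,
        me * na + mf * nc + ne,
        me * nb + mf * nd + nf,
    )


def _apply(m: Matrix, x: float, y: float) -> tuple[float, float]:
    a, b, c, d, e, f = m
    return (a * x + c * y + e, b * x + d * y + f)


def _apply_delta(m: Matrix, dx: float, dy: float) -> tuple[float, float]:
    a, b, c, d, _, _ = m
    return (a * dx + c * dy, b * dx + d * dy)


@dataclass
class GraphicsState:
    ctm: Matrix = IDENTITY
    attrs: StrokeAttrs = StrokeAttrs()


@dataclass
class _Interp:
    """Mutable interpreter state for :func:`extract_paths`."""

    state: GraphicsState = field(default_factory=GraphicsState)
    saved: list[GraphicsState] = field(default_factory=list)
    stack: list[float] = field(default_factory=list)
    # current path, already in device space
    subpaths: list[list[tuple[float, float]]] = field(default_factory=list)
    current: tuple[float, float] | None = None
    start: tuple[float, float] | None = None
    path_id: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    def pop(self, k: int, op: str, idx: int) -> list[float]:
        if len(self.stack) < k:
            raise PostScriptError(f"operand stack underflow for '{op}'", token_index=idx)
        vals = self.stack[-k:]
        del self.stack[-k:]
        return vals


def extract_paths(
    tokens: Sequence[Token],
    snap_tol: float = DEFAULT_SNAP_TOL,
) -> list[PathSegment]:
    """Interpret path-construction operators and return stroked segments.

    Coordinates are emitted CTM-transformed (device points).  Unstroked path
    content (``fill``, paths abandoned by ``newpath``) is discarded.  Each
    ``stroke`` increments the path id.  Unknown operators are counted and
    skipped, never fatal; ``curveto`` is flattened to its chord with a
    warning, since a genuine step curve contains no curves.
    """
    it = _Interp()
    segments: list[PathSegment] = []
    curve_warned = False

    def begin_subpath(pt: tuple[float, float]) -> None:
        it.subpaths.append([pt])
        it.current = pt
        it.start = pt

    def line_to(pt: tuple[float, float]) -> None:
        if it.current is None or not it.subpaths:
            begin_subpath(pt)
            return
        it.subpaths[-1].append(pt)
        it.current = pt

    for idx, tok in enumerate(tokens):
        if tok.kind == "number":
            it.stack.append(float(tok.value))
            continue
        if tok.kind in ("literal", "proc"):
            continue
        op = tok.value

        if op == "moveto":
            y, x = reversed(it.pop(2, op, idx))
            begin_subpath(_apply(it.state.ctm, x, y))
        elif op == "rmoveto":
            dy, dx = reversed(it.pop(2, op, idx))
            if it.current is None:
                raise PostScriptError("rmoveto with no current point", token_index=idx)
            ddx, ddy = _apply_delta(it.state.ctm, dx, dy)
            begin_subpath((it.current[0] + ddx, it.current[1] + ddy))
        elif op == "lineto":
            y, x = reversed(it.pop(2, op, idx))
            line_to(_apply(it.state.ctm, x, y))
        elif op == "rlineto":
            dy, dx = reversed(it.pop(2, op, idx))
            if it.current is None:
                raise PostScriptError("rlineto with no current point", token_index=idx)
            ddx, ddy = _apply_delta(it.state.ctm, dx, dy)
            line_to((it.current[0] + ddx, it.current[1] + ddy))
        elif op in ("curveto", "rcurveto"):
            vals = it.pop(6, op, idx)
            if not curve_warned:
                logger.warning(
                    "curveto encountered; flattened to its chord — step curves "
                    "should contain no curves, inspect the source figure"
                )
                curve_warned = True
            x3, y3 = vals[4], vals[5]
            if op == "curveto":
                line_to(_apply(it.state.ctm, x3, y3))
            else:
                if it.current is None:
                    raise PostScriptError("rcurveto with no current point", token_index=idx)
                ddx, ddy = _apply_delta(it.state.ctm, x3, y3)
                line_to((it.current[0] + ddx, it.current[1] + ddy))
        elif op == "closepath":
            if it.start is not None and it.current is not None and it.current != it.start:
                line_to(it.start)
        elif op == "newpath":
            it.subpaths.clear()
            it.current = it.start = None
        elif op == "stroke":
            emitted = False
            for sub in it.subpaths:
                pts = sub
                if len(pts) == 1:
                    # bare moveto paints nothing; ignore
                    continue
                for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
                    seg_len = math.hypot(x1 - x0, y1 - y0)
                    segments.append(
                        PathSegment(
                            x0, y0, x1, y1,
                            path_id=it.path_id,
                            is_dot=seg_len <= snap_tol,
                            stroke_attrs=it.state.attrs,
                        )
                    )
                    emitted = True
            if emitted:
                it.path_id += 1
            it.subpaths.clear()
            it.current = it.start = None
        elif op in ("fill", "eofill", "clip", "eoclip"):
            it.subpaths.clear()
            it.current = it.start = None
        elif op == "gsave":
            it.saved.append(GraphicsState(it.state.ctm, it.state.attrs))
        elif op == "grestore":
            if not it.saved:
                raise PostScriptError("grestore with empty graphics-state stack", token_index=idx)
            it.state = it.saved.pop()
        elif op == "translate":
            ty, tx = reversed(it.pop(2, op, idx))
            it.state.ctm = _mat_mul((1, 0, 0, 1, tx, ty), it.state.ctm)
        elif op == "scale":
            sy, sx = reversed(it.pop(2, op, idx))
            it.state.ctm = _mat_mul((sx, 0, 0, sy, 0, 0), it.state.ctm)
        elif op == "rotate":
            (ang,) = it.pop(1, op, idx)
            r = math.radians(ang)
            it.state.ctm = _mat_mul(
                (math.cos(r), math.sin(r), -math.sin(r), math.cos(r), 0, 0), it.state.ctm
            )
        elif op == "concat":
            f_, e_, d_, c_, b_, a_ = reversed(it.pop(6, op, idx))
            it.state.ctm = _mat_mul((a_, b_, c_, d_, e_, f_), it.state.ctm)
        elif op == "setlinewidth":
            (w,) = it.pop(1, op, idx)
            it.state.attrs = StrokeAttrs(w, it.state.attrs.color)
        elif op == "setgray":
            (g,) = it.pop(1, op, idx)
            it.state.attrs = StrokeAttrs(it.state.attrs.linewidth, (g, g, g))
        elif op == "setrgbcolor":
            b_, g_, r_ = reversed(it.pop(3, op, idx))
            it.state.attrs = StrokeAttrs(it.state.attrs.linewidth, (r_, g_, b_))
        elif op == "def":
            if len(it.stack) >= 1:
                it.stack.pop()
        elif op in ("showpage", "[", "]"):
            pass
        else:
            it.skipped[op] = it.skipped.get(op, 0) + 1

    if it.skipped:
        total = sum(it.skipped.values())
        logger.info(
            "skipped %d occurrence(s) of %d unknown operator(s): %s",
            total, len(it.skipped), ", ".join(sorted(it.skipped)),
        )
    return segments


def extract_segments(
    text: str | bytes,
    snap_tol: float = DEFAULT_SNAP_TOL,
    max_bytes: int = DEFAULT_MAX_BYTES,
) -> list[PathSegment]:
    """Convenience: tokenize then extract in one call."""
    return extract_paths(tokenize_postscript(text, max_bytes=max_bytes), snap_tol=snap_tol)


def segments_to_table(segments: Iterable[PathSegment]) -> pd.DataFrame:
    """Flatten segments into a record table (one row per segment)."""
    rows = [
        {
            "path_id": s.path_id,
            "x0": s.x0,
            "y0": s.y0,
            "x1": s.x1,
            "y1": s.y1,
            "is_dot": s.is_dot,
            "length": s.length,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=["path_id", "x0", "y0", "x1", "y1", "is_dot", "length"])
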