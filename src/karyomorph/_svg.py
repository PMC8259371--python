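"""Minimal deterministic SVG assembly (no external dependency).

Elements are emitted in insertion order and all coordinates are formatted
with fixed precision, so identical input always yields byte-identical files
— a requirement for snapshot testing of rendered figures.
"""

from __future__ import annotations


def _fmt(value: float) -> str:
    return f"{value:.3f}".rstrip("0").rstrip(".")


class SvgCanvas:
    def __init__(self, width: float, height: float) -> None:
        self.width = width
        self.height = height
        self._elements: list[str] = []

    def rect(self, x: float, y: float, w: float, h: float, *, fill: str = "black",
             stroke: str = "none") -> None:
        self._elements.append(
            f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" height="{_fmt(h)}" '
            f'fill="{fill}" stroke="{stroke}"/>'
        )

    def line(self, x1: float, y1: float, x2: float, y2: float, *, stroke: str = "black",
             width: float = 1.0) -> None:
        self._elements.append(
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="{stroke}" stroke-width="{_fmt(width)}"/>'
        )

    def circle(self, cx: float, cy: float, r: float, *, fill: str = "black") -> None:
        self._elements.append(
            f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" fill="{fill}"/>'
        )

    def text(self, x: float, y: float, content: str, *, size: float = 10.0,
             anchor: str = "middle") -> None:
        self._elements.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(size)}" '
            f'text-anchor="{anchor}" font-family="sans-serif">{content}</text>'
        )

    def to_string(self) -> str:
        header = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(self.width)}" '
            f'height="{_fmt(self.height)}" viewBox="0 0 {_fmt(self.width)} {_fmt(self.height)}">'
        )
        return "\n".join([header, *self._elements, "</svg>"]) + "\n"
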