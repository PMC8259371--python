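"""Mean haploid idiogram construction and deterministic SVG rendering.

Chromosomes are drawn left-to-right by decreasing total length, short arm
up and long arm down, with a gap marking the centromere.  When a cohort of
karyotypes is rendered together the same µm-to-pixel scale is used for all
panels so lengths stay comparable across accessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._svg import SvgCanvas
from .errors import KaryomorphError
from .karyomorphometry import MeanKaryotype


@dataclass(frozen=True)
class ChromosomeBar:
    position: int  # 1-based, ordered by decreasing length
    short_arm: float  # µm
    long_arm: float  # µm
    levan_class: str


@dataclass(frozen=True)
class IdiogramSpec:
    accession_id: str
    bars: tuple[ChromosomeBar, ...]
    scale: float  # drawing units per µm

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise KaryomorphError("scale must be positive")
        totals = [b.short_arm + b.long_arm for b in self.bars]
        if any(a < b - 1e-9 for a, b in zip(totals, totals[1:])):
            raise KaryomorphError("idiogram bars not ordered by decreasing length")


def build_idiogram(
    karyotype: MeanKaryotype, *, scale: float | None = None, units_per_um: float = 20.0
) -> IdiogramSpec:
    """One drawing record per haploid chromosome, ordered by decreasing length."""
    bars = tuple(
        ChromosomeBar(position=k + 1, short_arm=c.p, long_arm=c.q, levan_class=c.levan_class)
        for k, c in enumerate(karyotype.chromosomes)
    )
    return IdiogramSpec(karyotype.accession_id, bars, scale if scale is not None else units_per_um)


def build_cohort_idiograms(
    karyotypes: Sequence[MeanKaryotype], *, units_per_um: float = 20.0
) -> list[IdiogramSpec]:
    """Idiogram specs for a cohort sharing one common µm-to-unit scale."""
    return [build_idiogram(k, scale=units_per_um) for k in karyotypes]


_BAR_WIDTH = 14.0
_GAP = 4.0  # centromere gap, drawing units
_STEP = 34.0  # horizontal pitch between chromosomes
_MARGIN = 30.0


def render_idiogram(spec: IdiogramSpec) -> str:
    """Deterministic SVG for one idiogram; element order is stable so the
    same spec always yields byte-identical output."""
    max_short = max((b.short_arm for b in spec.bars), default=0.0) * spec.scale
    max_long = max((b.long_arm for b in spec.bars), default=0.0) * spec.scale
    width = 2 * _MARGIN + max(len(spec.bars), 1) * _STEP
    height = 2 * _MARGIN + max_short + max_long + _GAP + 20.0
    baseline = _MARGIN + max_short  # y of the centromere line (top of gap)

    canvas = SvgCanvas(width, height)
    for k, bar in enumerate(spec.bars):
        x = _MARGIN + k * _STEP
        short_px = bar.short_arm * spec.scale
        long_px = bar.long_arm * spec.scale
        canvas.rect(x, baseline - short_px, _BAR_WIDTH, short_px, fill="#555555")
        canvas.rect(x, baseline + _GAP, _BAR_WIDTH, long_px, fill="#999999")
        canvas.text(x + _BAR_WIDTH / 2, baseline + _GAP + long_px + 14.0,
                    str(bar.position), size=9.0)
    if spec.bars:
        canvas.text(width / 2, _MARGIN / 2, spec.accession_id, size=11.0)
    return canvas.to_string()


def render_cohort(specs: Sequence[IdiogramSpec]) -> str:
    """Multi-panel SVG: one idiogram panel per accession, stacked vertically."""
    panels = [render_idiogram(s) for s in specs]
    if not panels:
        return SvgCanvas(100.0, 40.0).to_string()
    # naive vertical stack: re-render panels into one canvas via nesting
    bodies = []
    y = 0.0
    total_w = 0.0
    for panel in panels:
        lines = panel.strip().splitlines()
        header = lines[1]
        w = float(header.split('width="')[1].split('"')[0])
        h = float(header.split('height="')[1].split('"')[0])
        inner = "\n".join(lines[2:-1])
        bodies.append(f'<g transform="translate(0 {y:.3f})">\n{inner}\n</g>')
        y += h
        total_w = max(total_w, w)
    header = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{total_w:.3f}" '
        f'height="{y:.3f}" viewBox="0 0 {total_w:.3f} {y:.3f}">'
    )
    return "\n".join([header, *bodies, "</svg>"]) + "\n"
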