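"""Haploid idiogram construction and SVG rendering.

An idiogram is the schematic of the haploid complement: one glyph per
chromosome pair, ordered left-to-right by decreasing total length, each glyph
split at the centromere with the short arm drawn above. Rendering is a pure
function of (layout, style) so identical inputs give byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ValidationError
from .karyotype import ChromosomeMetrics


@dataclass(frozen=True)
class IdiogramSlot:
    pair_id: int
    long_arm: float
    short_arm: float
    total_len: float
    morph_class: str | None
    slot: int
    #: centromere offset from the chromosome top, as fraction of its length
    centromere_offset: float


@dataclass(frozen=True)
class IdiogramLayout:
    slots: tuple[IdiogramSlot, ...]
    #: unit used for glyph heights: µm, or 1.0 == largest chromosome if normalized
    max_total_len: float


@dataclass(frozen=True)
class IdiogramStyle:
    glyph_width: float = 18.0
    slot_spacing: float = 30.0
    height_scale: float = 40.0  # px per unit total length
    margin: float = 20.0
    centromere_radius: float = 3.0
    label_font_size: float = 8.0
    class_colors: dict[str, str] = field(
        default_factory=lambda: {
            "m": "#4878a8",
            "sm": "#6aa84f",
            "st": "#e69138",
            "t": "#cc4125",
            None: "#999999",
        }
    )
    diploid: bool = False  # draw each pair twice

    def with_overrides(self, **kwargs) -> "IdiogramStyle":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def build_idiogram(
    metrics: list[ChromosomeMetrics], *, normalize: bool = False
) -> IdiogramLayout:
    """Order chromosome pairs into idiogram slots.

    Sorted by total length descending; ties broken by higher centromeric
    index (more metacentric first), then by pair id. With ``normalize`` the
    lengths are rescaled so the largest chromosome has unit height.
    """
    if not metrics:
        raise ValidationError("cannot build an idiogram from zero chromosomes")
    ordered = sorted(
        metrics, key=lambda m: (-m.total_len, -m.centromeric_index, m.pair_id)
    )
    scale = 1.0 / ordered[0].total_len if normalize else 1.0
    slots = tuple(
        IdiogramSlot(
            pair_id=m.pair_id,
            long_arm=m.long_arm * scale,
            short_arm=m.short_arm * scale,
            total_len=m.total_len * scale,
            morph_class=m.morph_class,
            slot=i,
            centromere_offset=m.short_arm / m.total_len,
        )
        for i, m in enumerate(ordered)
    )
    return IdiogramLayout(slots=slots, max_total_len=slots[0].total_len)


def _fmt(x: float) -> str:
    return f"{x:.3f}".rstrip("0").rstrip(".")


def render_idiogram(layout: IdiogramLayout, style: IdiogramStyle | None = None) -> str:
    """Render a layout to an SVG document string.

    One ``<g class="chromosome">`` group per glyph: short-arm block above,
    long-arm block below, a circular centromere mark between them and the
    morphology class annotated underneath. Deterministic: the output is a
    pure string function of layout and style.
    """
    style = style or IdiogramStyle()
    for s in layout.slots:
        if s.long_arm <= 0 or s.short_arm <= 0:
            raise ValidationError(f"pair {s.pair_id}: zero-length arm cannot be drawn")

    copies = 2 if style.diploid else 1
    n = len(layout.slots) * copies
    width = 2 * style.margin + n * style.slot_spacing
    max_h = layout.max_total_len * style.height_scale
    height = 2 * style.margin + max_h + 2 * style.label_font_size

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
    ]
    col = 0
    for s in layout.slots:
        for _ in range(copies):
            x = style.margin + col * style.slot_spacing
            col += 1
            top = style.margin + (layout.max_total_len - s.total_len) * style.height_scale
            h_short = s.short_arm * style.height_scale
            h_long = s.long_arm * style.height_scale
            color = style.class_colors.get(s.morph_class, "#999999")
            cy = top + h_short
            parts.append(
                f'<g class="chromosome" data-pair="{s.pair_id}" '
                f'data-class="{s.morph_class or "?"}">'
            )
            parts.append(
                f'<rect x="{_fmt(x)}" y="{_fmt(top)}" width="{_fmt(style.glyph_width)}" '
                f'height="{_fmt(h_short)}" rx="2" fill="{color}"/>'
            )
            parts.append(
                f'<rect x="{_fmt(x)}" y="{_fmt(cy)}" width="{_fmt(style.glyph_width)}" '
                f'height="{_fmt(h_long)}" rx="2" fill="{color}"/>'
            )
            parts.append(
                f'<circle class="centromere" cx="{_fmt(x + style.glyph_width / 2)}" '
                f'cy="{_fmt(cy)}" r="{_fmt(style.centromere_radius)}" '
                'fill="#ffffff" stroke="#000000"/>'
            )
            label_y = style.margin + max_h + style.label_font_size
            parts.append(
                f'<text x="{_fmt(x + style.glyph_width / 2)}" y="{_fmt(label_y)}" '
                f'font-size="{_fmt(style.label_font_size)}" text-anchor="middle">'
                f'{s.pair_id}</text>'
            )
            parts.append(
                f'<text x="{_fmt(x + style.glyph_width / 2)}" '
                f'y="{_fmt(label_y + style.label_font_size)}" '
                f'font-size="{_fmt(style.label_font_size)}" text-anchor="middle">'
                f'{s.morph_class or "?"}</text>'
            )
            parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
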