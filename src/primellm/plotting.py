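"""Radar-polygon figures (SVG) for domain-accuracy profiles."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError
from .metric import DomainProfile, polygon_vertices


def render_radar(
    profiles: DomainProfile | Sequence[DomainProfile],
    path: str | Path,
    labels: Sequence[str] | None = None,
    title: str | None = None,
) -> Path:
    """Draw one or more domain profiles as closed radar polygons.

    All profiles must share a domain order; the unit reference polygon (a
    model at 100% in every domain) is drawn as a dashed outline.  The first
    vertex sits at the top, subsequent vertices proceed clockwise.
    """
    if isinstance(profiles, DomainProfile):
        profiles = [profiles]
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles to plot")
    order = profiles[0].domain_order
    for p in profiles:
        if p.domain_order != order:
            raise ValidationError(
                f"profiles disagree on domain order: {p.domain_order} vs {order}"
            )
    if labels is not None and len(labels) != len(profiles):
        raise ValidationError("labels must match the number of profiles")

    k = profiles[0].k
    fig, ax = plt.subplots(figsize=(5, 5))
    ref = polygon_vertices([1.0] * k)
    ref_closed = np.vstack([ref, ref[:1]])
    ax.plot(ref_closed[:, 0], ref_closed[:, 1], "k--", lw=0.8, label="reference (100%)")
    for r in (0.25, 0.5, 0.75):
        grid = polygon_vertices([r] * k)
        grid = np.vstack([grid, grid[:1]])
        ax.plot(grid[:, 0], grid[:, 1], color="0.85", lw=0.5, zorder=0)

    for i, prof in enumerate(profiles):
        verts = polygon_vertices(prof.radii)
        closed = np.vstack([verts, verts[:1]])
        lab = labels[i] if labels is not None else None
        line, = ax.plot(closed[:, 0], closed[:, 1], lw=1.5, label=lab)
        ax.fill(closed[:, 0], closed[:, 1], alpha=0.10, color=line.get_color())

    for (x, y), name in zip(ref * 1.12, order):
        ax.text(x, y, name, ha="center", va="center", fontsize=10)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    if labels is not None or True:
        ax.legend(loc="lower right", fontsize=7, frameon=False)
    path = Path(path)
    # fixed hashsalt + stripped date keep the SVG byte-stable across reruns
    with matplotlib.rc_context({"svg.hashsalt": "primellm"}):
        fig.savefig(path, format="svg", bbox_inches="tight", metadata={"Date": None})
    plt.close(fig)
    return path
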