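"""Minimal figure helpers (occupancy heatmap, per-stage site map)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dynamics import OccupancyMatrix
from .footprints import SiteSet


def occupancy_heatmap(matrix: OccupancyMatrix, path: str) -> None:
    """Sites × stages presence heatmap (occupied red, unoccupied blue)."""
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix.stages),
                                    1 + 0.25 * max(len(matrix.reference_sites), 4)))
    ax.imshow(matrix.presence, aspect="auto", cmap="coolwarm", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.stages)), matrix.stages, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.reference_sites)),
                  [f"{s.start}-{s.end}" for s in matrix.reference_sites], fontsize=7)
    ax.set_xlabel("developmental stage")
    ax.set_ylabel("reference site (mtDNA position)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def site_map(per_stage: list[SiteSet], stages: list[str], path: str) -> None:
    """Horizontal bars of called sites per stage along the genome."""
    L = per_stage[0].genome.length
    fig, ax = plt.subplots(figsize=(9, 1 + 0.4 * len(stages)))
    for y, (stage, ss) in enumerate(zip(stages, per_stage)):
        for s in ss:
            if s.end > s.start:
                ax.barh(y, s.end - s.start, left=s.start, height=0.6, color="C0")
            else:
                ax.barh(y, L - s.start, left=s.start, height=0.6, color="C0")
                ax.barh(y, s.end, left=0, height=0.6, color="C0")
    ax.set_yticks(range(len(stages)), stages)
    ax.set_xlim(0, L)
    ax.set_xlabel("mtDNA position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
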