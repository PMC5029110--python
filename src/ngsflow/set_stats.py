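"""n-way Venn intersects and differential-expression table filtering.

:func:`overlapper` computes *disjoint occupancy regions*: every element of
the union is assigned to exactly one region, keyed by the full subset of
input sets containing it.  Region counts therefore always sum to the size of
the union.  Full-region mode supports 2-20 sets (2^n - 1 regions).

:func:`filter_degs` consumes differential-expression result tables (one
logFC and one FDR column per comparison, e.g. ``A-B_logFC`` / ``A-B_FDR``)
and enumerates up- and down-regulated genes per comparison.  Sign
convention: logFC of comparison ``A-B`` is positive when abundance is higher
in ``A`` (the first-named factor).  FDR values are consumed, never computed
here; multiple-testing correction belongs to the upstream DE tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["VennResult", "DegFilterResult", "overlapper", "venn_counts_plot",
           "filter_degs"]

RegionKey = tuple[str, ...]


@dataclass
class VennResult:
    """Disjoint Venn regions of 2..20 named sets."""

    set_names: list[str]
    regions: dict[RegionKey, list]   # only non-empty regions stored
    counts: dict[RegionKey, int]

    def count(self, key: Iterable[str]) -> int:
        """Region size for any subset of set names (0 if empty/absent)."""
        canon = tuple(sorted(set(key)))
        unknown = set(canon) - set(self.set_names)
        if unknown:
            raise KeyError(f"unknown set name(s): {sorted(unknown)}")
        return self.counts.get(canon, 0)

    def all_counts(self) -> dict[RegionKey, int]:
        """Counts for every possible region, zeros included."""
        from itertools import combinations
        out: dict[RegionKey, int] = {}
        for r in range(1, len(self.set_names) + 1):
            for combo in combinations(sorted(self.set_names), r):
                out[combo] = self.counts.get(combo, 0)
        return out


def overlapper(sets: dict[str, Iterable]) -> VennResult:
    """Compute the disjoint Venn regions of 2-20 named sets.

    Duplicate identifiers within a set are collapsed.  Region keys are
    canonical sorted tuples of set names.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    if len(sets) > 20:
        raise ValueError(
            "more than 20 sets: full-region mode is exponential; compute "
            "pairwise intersects instead")
    names = list(sets)
    materialized = {name: set(v) for name, v in sets.items()}
    regions: dict[RegionKey, list] = {}
    union = set().union(*materialized.values())
    for element in union:
        key = tuple(sorted(n for n in names if element in materialized[n]))
        regions.setdefault(key, []).append(element)
    for members in regions.values():
        members.sort(key=repr)
    counts = {k: len(v) for k, v in regions.items()}
    return VennResult(set_names=names, regions=regions, counts=counts)


# ---------------------------------------------------------------------------
# Venn diagram (2-5 sets)

# Shape layouts per n: (cx, cy, width, height, angle_deg) per set.
_SHAPES: dict[int, list[tuple[float, float, float, float, float]]] = {
    2: [(0.40, 0.50, 0.56, 0.56, 0), (0.60, 0.50, 0.56, 0.56, 0)],
    3: [(0.42, 0.56, 0.58, 0.58, 0), (0.58, 0.56, 0.58, 0.58, 0),
        (0.50, 0.42, 0.58, 0.58, 0)],
    4: [(0.350, 0.400, 0.72, 0.45, 140), (0.450, 0.500, 0.72, 0.45, 140),
        (0.544, 0.500, 0.72, 0.45, 40), (0.644, 0.400, 0.72, 0.45, 40)],
    5: [(0.428, 0.449, 0.87, 0.50, 155), (0.469, 0.543, 0.87, 0.50, 82),
        (0.558, 0.523, 0.87, 0.50, 10), (0.578, 0.432, 0.87, 0.50, 118),
        (0.489, 0.383, 0.87, 0.50, 46)],
}


def _in_ellipse(x, y, cx, cy, w, h, angle_deg):
    t = math.radians(angle_deg)
    dx, dy = x - cx, y - cy
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / (w / 2)) ** 2 + (v / (h / 2)) ** 2 <= 1.0


def _region_label_positions(n: int, grid: int = 400) -> dict[RegionKey, tuple[float, float]]:
    """Numerically locate a label point inside every occupancy region.

    The diagram area is rasterized; each grid point's membership bitmask
    assigns it to one region, and the label goes to the region point nearest
    the region centroid.
    """
    shapes = _SHAPES[n]
    xs = np.linspace(0, 1, grid)
    ys = np.linspace(0, 1, grid)
    X, Y = np.meshgrid(xs, ys)
    masks = []
    for cx, cy, w, h, ang in shapes:
        t = math.radians(ang)
        dx, dy = X - cx, Y - cy
        u = dx * math.cos(t) + dy * math.sin(t)
        v = -dx * math.sin(t) + dy * math.cos(t)
        masks.append((u / (w / 2)) ** 2 + (v / (h / 2)) ** 2 <= 1.0)
    code = np.zeros_like(X, dtype=np.int64)
    for i, m in enumerate(masks):
        code += m.astype(np.int64) << i
    positions: dict[int, tuple[float, float]] = {}
    for bits in range(1, 2 ** n):
        sel = code == bits
        if not sel.any():
            raise RuntimeError(f"degenerate layout: region {bits:b} empty")
        px, py = X[sel], Y[sel]
        cx, cy = px.mean(), py.mean()
        j = int(np.argmin((px - cx) ** 2 + (py - cy) ** 2))
        positions[bits] = (float(px[j]), float(py[j]))
    return {
        tuple(i for i in range(n) if bits >> i & 1): positions[bits]  # type: ignore
        for bits in positions
    }


def venn_counts_plot(result: VennResult, out: str | Path) -> Path:
    """Draw a 2-5-way Venn diagram with one numeric label per region.

    Labels equal the region counts of ``result`` exactly (zeros included).
    For more than 5 sets, render the count table instead
    (``VennResult.all_counts``).
    """
    n = len(result.set_names)
    if not 2 <= n <= 5:
        raise ValueError(
            f"Venn diagrams support 2-5 sets, got {n}; use the region count "
            f"table (VennResult.all_counts) instead")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    out = Path(out)
    sorted_names = sorted(result.set_names)
    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("tab10")
    for i, (cx, cy, w, h, ang) in enumerate(_SHAPES[n]):
        ax.add_patch(Ellipse((cx, cy), w, h, angle=ang, fill=True,
                             alpha=0.25, facecolor=cmap(i),
                             edgecolor=cmap(i), lw=1.5))
        ax.annotate(result.set_names[i],
                    xy=(cx, cy), xytext=(cx, cy + h / 2 + 0.03 + 0.03 * i),
                    ha="center", fontsize=10, color=cmap(i))
    label_pos = _region_label_positions(n)
    for idx_key, (x, y) in label_pos.items():
        # idx_key holds indices into result.set_names (layout order)
        names_key = tuple(sorted(result.set_names[i] for i in idx_key))
        ax.text(x, y, str(result.counts.get(names_key, 0)),
                ha="center", va="center", fontsize=9)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out


# ---------------------------------------------------------------------------
# DEG filtering


@dataclass
class DegFilterResult:
    """Up/down-regulated gene lists per comparison plus a summary table."""

    up: dict[str, list[str]]
    down: dict[str, list[str]]
    summary: pd.DataFrame        # comparison, n_up, n_down, n_total
    lfc_min: float
    fdr_max: float


def _comparison_columns(columns: Sequence[str]) -> dict[str, tuple[str, str]]:
    lfc = {c[: -len("_logFC")]: c for c in columns if c.endswith("_logFC")}
    fdr = {c[: -len("_FDR")]: c for c in columns if c.endswith("_FDR")}
    comps = {}
    for name in lfc:
        if name not in fdr:
            raise ValueError(f"comparison {name}: logFC column without FDR column")
        comps[name] = (lfc[name], fdr[name])
    for name in fdr:
        if name not in lfc:
            raise ValueError(f"comparison {name}: FDR column without logFC column")
    if not comps:
        raise ValueError("no <comparison>_logFC/_FDR column pairs found")
    return comps


def filter_degs(
    deg_table: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> DegFilterResult:
    """Enumerate up-/down-regulated genes per comparison.

    A gene is *up* in comparison ``c`` iff ``logFC_c >= lfc_min`` and
    ``FDR_c <= fdr_max``; *down* iff ``logFC_c <= -lfc_min`` and
    ``FDR_c <= fdr_max``.  Missing values never pass.  Gene identifiers are
    taken from the table index.
    """
    if lfc_min < 0:
        raise ValueError("lfc_min must be non-negative")
    if not 0 < fdr_max <= 1:
        raise ValueError("fdr_max must be in (0, 1]")
    comps = _comparison_columns(deg_table.columns)
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    rows = []
    for name, (lfc_col, fdr_col) in comps.items():
        lfc = pd.to_numeric(deg_table[lfc_col], errors="coerce")
        fdr = pd.to_numeric(deg_table[fdr_col], errors="coerce")
        sig = fdr.notna() & (fdr <= fdr_max) & lfc.notna()
        up_mask = sig & (lfc >= lfc_min)
        # "& ~up_mask" only matters at lfc_min == 0, where logFC == 0 would
        # otherwise land in both lists; up wins to keep them disjoint
        down_mask = sig & (lfc <= -lfc_min) & ~up_mask
        up[name] = deg_table.index[up_mask].tolist()
        down[name] = deg_table.index[down_mask].tolist()
        rows.append((name, len(up[name]), len(down[name]),
                     len(up[name]) + len(down[name])))
    summary = pd.DataFrame(
        rows, columns=["comparison", "n_up", "n_down", "n_total"])
    return DegFilterResult(up=up, down=down, summary=summary,
                           lfc_min=lfc_min, fdr_max=fdr_max)
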