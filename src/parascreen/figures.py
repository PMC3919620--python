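"""Figure-data builders and rendering.

The signature visualization is the 2D stacked bar: sequences are binned by
abundance into approximately log-uniform bins (0.3, 1], (0.1, 0.3],
(0.03, 0.1], ... and each bin becomes a segment of height
h = S_bin / S_all (fraction of all reads) and width w = log10(U_bin)
(log unique sequences).  Singletons (count 1) form their own bottom
segment regardless of abundance.  All builders here are pure functions of
their inputs; rendering is a side effect layered on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PeptideMultiset

__all__ = [
    "Segment",
    "StackedBarLayout",
    "default_bin_edges",
    "stacked_bar_layout",
    "scatter_grid",
    "figure_data",
    "venn_regions",
    "render_stacked_bar",
]


@dataclass
class Segment:
    lower: float  # abundance interval (lower, upper]
    upper: float
    S: int  # total reads in bin
    U: int  # unique sequences in bin
    h: float  # S / S_all
    w: float  # log10(U)


@dataclass
class StackedBarLayout:
    segments: list[Segment]
    singleton_S: int
    singleton_U: int
    S_all: int

    @property
    def singleton_h(self) -> float:
        return self.singleton_S / self.S_all

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lower": s.lower,
                "upper": s.upper,
                "S": s.S,
                "U": s.U,
                "h": s.h,
                "w": s.w,
            }
            for s in self.segments
        ]
        rows.append(
            {
                "lower": 0.0,
                "upper": float("nan"),
                "S": self.singleton_S,
                "U": self.singleton_U,
                "h": self.singleton_h,
                "w": math.log10(self.singleton_U) if self.singleton_U else float("nan"),
            }
        )
        return pd.DataFrame(rows)


def default_bin_edges(min_abundance: float) -> list[float]:
    """Descending edges 1, 0.3, 0.1, 0.03, 0.01, ... extended per decade
    until strictly below ``min_abundance`` (so the lowest sequence falls
    inside a half-open (lower, upper] bin).

    Edges are built from exact powers of ten rather than repeated
    multiplication, which would drift (0.3 * 1/3 != 0.1 in floats).
    """
    edges = [1.0]
    decade = 0
    while edges[-1] >= min_abundance:
        decade += 1
        edges.append(3.0 / 10.0 ** decade)  # division lands on the 0.3/0.03/... literals
        if edges[-1] < min_abundance:
            break
        edges.append(1.0 / 10.0 ** decade)
    return edges


def stacked_bar_layout(
    ms: PeptideMultiset, edges: list[float] | None = None
) -> StackedBarLayout:
    """Bin a multiset into stacked-bar segments.

    Sequence i with abundance N_i goes to bin (N_1, N_2] iff
    N_1 < N_i <= N_2; sequences with count 1 go to the singleton segment
    regardless of abundance.  Empty bins are omitted, so every emitted
    segment has U >= 1.
    """
    if len(ms) == 0:
        raise ValueError("empty multiset")
    s_all = ms.n_reads
    non_single = {p: c for p, c in ms.counts.items() if c > 1}
    singleton_u = len(ms) - len(non_single)
    singleton_s = sum(c for c in ms.counts.values() if c == 1)

    if edges is None:
        min_ab = min(non_single.values()) / s_all if non_single else 1.0
        edges = default_bin_edges(min_ab)
    else:
        if list(edges) != sorted(edges, reverse=True) or edges[0] != 1:
            raise ValueError("edges must be strictly descending and start at 1")
        edges = list(edges)

    seg_s = [0] * (len(edges) - 1)
    seg_u = [0] * (len(edges) - 1)
    for pep, cnt in non_single.items():
        ab = cnt / s_all
        for b in range(len(edges) - 1):
            if edges[b + 1] < ab <= edges[b]:
                seg_s[b] += cnt
                seg_u[b] += 1
                break
        else:
            raise ValueError(f"abundance {ab} below the lowest bin edge")

    segments = [
        Segment(edges[b + 1], edges[b], seg_s[b], seg_u[b], seg_s[b] / s_all,
                math.log10(seg_u[b]))
        for b in range(len(edges) - 1)
        if seg_u[b] > 0
    ]
    return StackedBarLayout(segments, singleton_s, singleton_u, s_all)


def scatter_grid(A: PeptideMultiset, B: PeptideMultiset):
    """Abundance-vs-abundance scatter with log-decade grid cells.

    Sequences absent from one multiset sit on an off-axis band at half the
    minimum observable abundance of that axis (a rendering convention; the
    ``common`` / ``only_A`` / ``only_B`` class labels carry the analysis
    meaning).  Returns ``(points, cells)``; cell counts conserve
    |A ∪ B|.
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both multisets must be nonempty")
    ta, tb = A.n_reads, B.n_reads
    off_a, off_b = 0.5 / ta, 0.5 / tb
    rows = []
    for pep in sorted(set(A.counts) | set(B.counts)):
        ca, cb = A.counts.get(pep, 0), B.counts.get(pep, 0)
        x = ca / ta if ca else off_a
        y = cb / tb if cb else off_b
        cls = "common" if ca and cb else ("only_A" if ca else "only_B")
        rows.append(
            {
                "peptide": pep,
                "x": x,
                "y": y,
                "class": cls,
                "cell_x": math.floor(math.log10(x)),
                "cell_y": math.floor(math.log10(y)),
            }
        )
    points = pd.DataFrame(rows).set_index("peptide")
    cells = (
        points.groupby(["cell_x", "cell_y"]).size().rename("count").reset_index()
    )
    return points, cells


def venn_regions(sets: dict[str, set]) -> dict[str, int]:
    """Cardinalities of all nonempty-membership regions of up to 4 sets.

    Region keys name the member sets joined by ``&`` (e.g. ``"P10&P1R"``
    is the count of elements in exactly those two sets and no other).
    """
    names = list(sets)
    if not 1 <= len(names) <= 4:
        raise ValueError("venn supports 1-4 sets")
    regions: dict[str, int] = {}
    for mask in range(1, 2 ** len(names)):
        inside = [n for i, n in enumerate(names) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set.intersection(*(set(sets[n]) for n in inside))
        for n in outside:
            region -= set(sets[n])
        regions["&".join(inside)] = len(region)
    return regions


def figure_data(kind: str, **inputs) -> pd.DataFrame | dict:
    """Deterministic reshaping of analysis outputs into plot-ready tables.

    ``ratio``: ratio table -> (x = naive_count, y = normalized_ratio,
    class = P1R flag when present).  ``volcano``: volcano table ->
    (x = f, y = -log10 p, class = PBR).  ``qq``: GOF statistics + df ->
    sorted (x = chi-square quantile, y = statistic).  ``venn``: named sets
    -> region cardinalities.
    """
    if kind == "ratio":
        t = inputs["table"]
        out = pd.DataFrame(
            {"x": t["naive_count"], "y": t["normalized_ratio"]}, index=t.index
        )
        out["class"] = t["P1R"] if "P1R" in t else False
        return out
    if kind == "volcano":
        t = inputs["table"]
        return pd.DataFrame(
            {"x": t["f"], "y": -np.log10(t["p"]), "class": t["PBR"]}, index=t.index
        )
    if kind == "qq":
        from scipy import stats as sps

        x = np.sort(np.asarray(inputs["gof_stats"], dtype=float))
        df = inputs.get("df", 4)
        probs = (np.arange(1, x.size + 1) - 0.5) / x.size
        return pd.DataFrame({"x": sps.chi2.ppf(probs, df), "y": x})
    if kind == "venn":
        return venn_regions(inputs["sets"])
    raise ValueError(f"unknown figure kind {kind!r}")


def render_stacked_bar(
    layout: StackedBarLayout,
    ax=None,
    w_min: float = 0.3,
    highlight: set | None = None,
    colors=None,
):
    """Draw a stacked-bar layout; returns the matplotlib Axes.

    Segment width is max(w, w_min) so single-sequence segments (w = 0)
    stay visible; the raw w is preserved in the layout itself.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 6))
    frame = layout.to_frame()
    cmap = colors or plt.get_cmap("viridis")
    y0 = 0.0
    n = len(frame)
    for i, row in frame.iterrows():
        width = max(row["w"], w_min) if np.isfinite(row["w"]) else w_min
        color = "0.6" if i == n - 1 else cmap(i / max(n - 1, 1))
        ax.bar(0.0, row["h"], width=width, bottom=y0, color=color,
               edgecolor="black", linewidth=0.5)
        y0 += row["h"]
    ax.set_ylabel("fraction of reads")
    ax.set_xlabel("log10 unique sequences (segment width)")
    ax.set_xticks([])
    return ax
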