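"""Figure rendering: relationship maps and burden histograms.

The relationship map places the 20 domains on a circle (motor and
sensorimotor instruments along the upper semicircle, neuropsychological
subtests along the lower), annotates each node with its impaired-child
count (red), draws an edge for every domain pair with at least the
threshold number of co-occurring children — line thickness linear in the
count, with a minimum visible width — and prints the total number of
impaired test pairs bottom left.

SVG output is written with the date metadata stripped so that identical
inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "comorbmap"  # reproducible SVG ids
import matplotlib.pyplot as plt  # noqa: E402

from .maps import BurdenProfile, CooccurrenceGraph, edges_at_threshold, \
    total_impaired_pairs  # noqa: E402

_MIN_WIDTH_PT = 0.5
_WIDTH_PER_CHILD_PT = 0.35


def _save(fig, out_path: str | Path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    kwargs = {}
    if out_path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}
    elif out_path.suffix.lower() == ".pdf":
        kwargs["metadata"] = {"CreationDate": None}
    fig.savefig(out_path, **kwargs)
    plt.close(fig)


def render_relationship_map(graph: CooccurrenceGraph, threshold: int,
                            out_path: str | Path, *,
                            label_edges: bool | None = None) -> Path:
    """Render one group's relationship map at a pair-count threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    pos = graph.registry.layout_positions()
    edges = edges_at_threshold(graph, threshold)
    if label_edges is None:
        label_edges = threshold > 1  # the k=1 map is too dense to label

    fig, ax = plt.subplots(figsize=(7.5, 7.5))
    for d1, d2, count in edges:
        (x1, y1), (x2, y2) = pos[d1], pos[d2]
        ax.plot([x1, x2], [y1, y2], color="0.35", zorder=1,
                linewidth=_MIN_WIDTH_PT + _WIDTH_PER_CHILD_PT * count)
        if label_edges:
            ax.text((x1 + x2) / 2, (y1 + y2) / 2, str(count), fontsize=7,
                    color="black", ha="center", va="bottom", zorder=3)
    for abbr, (x, y) in pos.items():
        ax.scatter([x], [y], s=120, color="#1f77b4", zorder=2)
        lx, ly = x * 1.22, y * 1.22
        ax.text(lx, ly, abbr, ha="center", va="center", fontsize=9,
                fontweight="bold")
        cx, cy = x * 1.10, y * 1.10
        ax.text(cx, cy, str(graph.node_counts[abbr]), ha="center",
                va="center", fontsize=8, color="red")
    total = total_impaired_pairs(graph, threshold)
    ax.text(-1.28, -1.28, str(total), fontsize=13, fontweight="bold")
    ax.set_title(f"{graph.group} (n={graph.n_children}), "
                 f"co-occurrence threshold ≥ {threshold}")
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)
    ax.set_aspect("equal")
    ax.axis("off")
    _save(fig, out_path)
    return Path(out_path)


def render_burden_histogram(profile: BurdenProfile, out_path: str | Path,
                            groups=("EPT", "TERM")) -> Path:
    """Bar-chart profile: children per impairment-burden value, by group."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    max_burden = max(profile.per_child.values(), default=0)
    xs = list(range(max_burden + 1))
    width = 0.4
    for offset, (group, color) in enumerate(zip(groups, ("#d62728", "#1f77b4"))):
        hist = profile.histogram(group)
        ax.bar([x + (offset - 0.5) * width for x in xs],
               [hist.get(x, 0) for x in xs], width=width, color=color,
               label=group)
    ax.set_xlabel("number of impaired test domains")
    ax.set_ylabel("number of children")
    ax.set_xticks(xs)
    ax.legend()
    _save(fig, out_path)
    return Path(out_path)
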