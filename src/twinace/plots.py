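"""Stacked-bar rendering of ACE variance decompositions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .liability import VarianceComponents

__all__ = ["render_variance_figure"]

_COLORS = {"a2": "#4C72B0", "c2": "#DD8452", "e2": "#55A868"}
_NAMES = {"a2": "A (additive genetic)", "c2": "C (shared environment)",
          "e2": "E (non-shared environment)"}


def render_variance_figure(
    components: dict[str, VarianceComponents],
    path: str | Path,
) -> Path:
    """One stacked bar per model: A, C and E proportions summing to 1.

    Each segment is annotated with its proportion; CIs, when present on the
    components, are appended to the annotation.
    """
    labels = list(components)
    fig, ax = plt.subplots(figsize=(1.8 + 1.4 * len(labels), 4.2))
    for x, label in enumerate(labels):
        comp = components[label]
        bottom = 0.0
        for key in ("a2", "c2", "e2"):
            value = getattr(comp, key)
            ax.bar(x, value, bottom=bottom, width=0.6, color=_COLORS[key],
                   label=_NAMES[key] if x == 0 else None)
            if value > 0.015:
                text = f"{value:.2f}"
                ci = comp.ci.get(key)
                if ci:
                    text += f"\n[{ci[0]:.2f}, {ci[1]:.2f}]"
                ax.text(x, bottom + value / 2, text, ha="center", va="center", fontsize=8)
            bottom += value
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels)
    ax.set_ylim(0, 1.0)
    ax.set_ylabel("Proportion of liability variance")
    ax.legend(loc="upper left", bbox_to_anchor=(1.01, 1.0), fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
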