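"""Rendering: per-pair alignment display, F1 accuracy grids, phonemegram.

Every plot has a data-only twin (a DataFrame builder) so results can be
exported and asserted on as numbers; the matplotlib functions are thin
layers over those tables. Figures use the Agg-friendly object API and are
returned for the caller to save or show.
"""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .align import Alignment
from .costs import OP_DEL, OP_INS, OP_MATCH
from .features import FeatureTable, default_feature_table
from .phonemes import is_vowel
from .scoring import tally

_OP_GLYPH = {OP_MATCH: "M", "substitution": "S", OP_DEL: "D", OP_INS: "I"}

#: phonemegram bar colours by frequency band
BAND_COLORS = {
    "low": "black",
    "mid_vowel": "darkblue",
    "mid_consonant": "lightblue",
    "high": "white",
}


def render_alignment(alignment: Alignment, gap: str = "-") -> str:
    """Three-row fixed-width text display plus per-phoneme F1 scores.

    Row 1: stimulus (gaps for insertions); row 2: response (gaps for
    deletions); row 3: operation glyphs M/S/D/I.
    """
    stim_row, resp_row, op_row = [], [], []
    for col in alignment.columns:
        s = col.stimulus if col.stimulus is not None else gap
        r = col.response if col.response is not None else gap
        g = _OP_GLYPH[col.op]
        width = max(len(s), len(r))
        stim_row.append(s.ljust(width))
        resp_row.append(r.ljust(width))
        op_row.append(g.ljust(width))
    lines = [" ".join(stim_row).rstrip(),
             " ".join(resp_row).rstrip(),
             " ".join(op_row).rstrip(),
             f"MED: {alignment.total_cost:g}"]
    scores = []
    for p, t in sorted(tally(alignment).items()):
        f1 = t.f1
        shown = "n/a" if f1 is None else f"{100 * f1:.0f}%"
        scores.append(f"{p}: {shown}")
    if scores:
        lines.append("F1: " + ", ".join(scores))
    return "\n".join(lines)


def f1_grid_data(
    f1_by_phoneme: Mapping[str, float],
    features: FeatureTable | None = None,
) -> pd.DataFrame:
    """Grid coordinates for the three accuracy panels.

    Vowels plot at (vowel place, vowel height); consonants, split into
    voiced and unvoiced panels, at (place, manner). Columns: phoneme,
    panel, x, y, f1_percent.
    """
    features = features or default_feature_table()
    rows = []
    for p, f1 in sorted(f1_by_phoneme.items()):
        if is_vowel(p):
            panel = "vowels"
            x = features.value(p, "vowel_place")
            y = features.value(p, "vowel_height")
        else:
            voiced = features.value(p, "voicing") == 1
            panel = "voiced_consonants" if voiced else "unvoiced_consonants"
            x = features.value(p, "place")
            y = features.value(p, "manner")
        rows.append({"phoneme": p, "panel": panel, "x": x, "y": y,
                     "f1_percent": float(f1)})
    return pd.DataFrame(rows)


def render_f1_grids(
    f1_by_phoneme: Mapping[str, float],
    features: FeatureTable | None = None,
):
    """Three colour-coded accuracy panels (vowels, voiced, unvoiced).

    Phonemes sharing a cell (e.g. L/R/Y) are offset deterministically in
    label order so all stay visible. Returns (figure, grid DataFrame).
    """
    data = f1_grid_data(f1_by_phoneme, features)
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    panels = [
        ("vowels", "Vowels", "place (0=front, 2=back)",
         "height (0=low, 2=high)"),
        ("voiced_consonants", "Voiced consonants", "place (0=front, 2=back)",
         "manner (0=stop .. 4=affricate)"),
        ("unvoiced_consonants", "Unvoiced consonants",
         "place (0=front, 2=back)", "manner (0=stop .. 4=affricate)"),
    ]
    for ax, (panel, title, xlabel, ylabel) in zip(axes, panels):
        sub = data[data["panel"] == panel].sort_values("phoneme")
        # deterministic offsets for co-located phonemes
        offsets: dict[tuple[int, int], int] = {}
        xs, ys = [], []
        for _, row in sub.iterrows():
            k = (row["x"], row["y"])
            rank = offsets.get(k, 0)
            offsets[k] = rank + 1
            xs.append(row["x"] + 0.18 * rank)
            ys.append(row["y"])
        if len(sub):
            sc = ax.scatter(xs, ys, c=sub["f1_percent"], cmap="viridis",
                            vmin=0, vmax=100, s=180, edgecolors="grey")
            fig.colorbar(sc, ax=ax, label="F1 (%)")
            for x, y, (_, row) in zip(xs, ys, sub.iterrows()):
                ax.annotate(row["phoneme"], (x, y), textcoords="offset points",
                            xytext=(0, 10), ha="center", fontsize=8)
        ax.set_title(title)
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.set_xlim(-0.5, 2.9)
    fig.tight_layout()
    return fig, data


def render_phonemegram(pg: pd.DataFrame):
    """Bar chart of relative IT by feature, coloured by frequency band.

    ``pg`` is the DataFrame from :func:`phonalign.infotransfer.phonemegram`.
    Undefined features (NaN relative IT, Hstim = 0) are drawn hatched at
    zero height and annotated. Returns the figure.
    """
    fig, ax = plt.subplots(figsize=(8, 4))
    xs = np.arange(len(pg))
    for i, (_, row) in enumerate(pg.iterrows()):
        value = row["relative_percent"]
        color = BAND_COLORS[row["band"]]
        if np.isnan(value):
            ax.bar(i, 100, color="none", edgecolor="grey", hatch="//")
            ax.annotate("undef.", (i, 50), ha="center", fontsize=8,
                        rotation=90)
        else:
            ax.bar(i, value, color=color, edgecolor="black")
    ax.set_xticks(xs)
    ax.set_xticklabels(pg["feature"], rotation=45, ha="right")
    ax.set_ylabel("relative information transfer (%)")
    ax.set_ylim(0, 105)
    ax.set_title("Phonemegram (bands: black=low, dark/light blue=mid, "
                 "white=high frequency)")
    fig.tight_layout()
    return fig
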