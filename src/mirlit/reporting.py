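"""Report figures and their companion data tables.

Each renderer writes an image (PNG by default, SVG/PDF on request) *and*
the exact table it plotted, as CSV.  Downstream checks — and anyone
auditing a figure — read the companion table; the image is presentation
only.  All renderers are deterministic: the same bundle and style settings
reproduce the same table byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from mirlit.dictionaries import CATEGORIES
from mirlit.engine import CooccurrenceMatrix, Ranking, TrendSeries, top_k
from mirlit.mirna import family_index


@dataclass
class ReportArtifact:
    kind: str               # trend_lines | top_bar | breadth_chart | donut_per_corpus | heatmap
    image_path: str
    table_path: str
    table: pd.DataFrame


def _save(fig, table: pd.DataFrame, outdir: str, stem: str, kind: str,
          image_format: str = "png") -> ReportArtifact:
    os.makedirs(outdir, exist_ok=True)
    image_path = os.path.join(outdir, f"{stem}.{image_format}")
    table_path = os.path.join(outdir, f"{stem}.csv")
    fig.savefig(image_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    table.to_csv(table_path, index=False)
    return ReportArtifact(kind=kind, image_path=image_path, table_path=table_path, table=table)


def render_trends(series: list[TrendSeries], outdir: str, stem: str = "trends",
                  image_format: str = "png") -> ReportArtifact:
    """Publication-count lines per corpus over the union of years.

    Years missing from a corpus are plotted (and tabulated) as zero, so
    every line spans the same x axis.
    """
    if not series:
        raise ValueError("render_trends requires at least one series")
    observed = {y for s in series for y in s.year_counts}
    all_years = list(range(min(observed), max(observed) + 1)) if observed else []
    rows = []
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for s in series:
        counts = [s.year_counts.get(y, 0) for y in all_years]
        ax.plot(all_years, counts, marker="o", markersize=3, label=s.label)
        rows.extend((s.label, y, c) for y, c in zip(all_years, counts))
    ax.set_xlabel("publication year")
    ax.set_ylabel("articles")
    ax.set_title("miRNA publications per year")
    ax.legend(fontsize=7, ncol=2)
    table = pd.DataFrame(rows, columns=["label", "year", "count"])
    return _save(fig, table, outdir, stem, "trend_lines", image_format)


def render_top_bar(aggregate: dict[str, int], outdir: str, n: int = 25,
                   stem: str = "top_families", image_format: str = "png") -> ReportArtifact:
    """Bar chart of the n most-published families across all corpora."""
    ranking = top_k(aggregate, k=max(n, 1), label="aggregate") if aggregate else None
    entries = ranking.entries if ranking else []
    table = pd.DataFrame(entries, columns=["family", "count"])
    fig, ax = plt.subplots(figsize=(8, 4.5))
    if entries:
        families = [f for f, _ in entries]
        counts = [c for _, c in entries]
        ax.bar(range(len(families)), counts, color="#40617f")
        ax.set_xticks(range(len(families)))
        ax.set_xticklabels(families, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("articles (summed over corpora)")
    ax.set_title(f"top {n} most-published miRNA families")
    return _save(fig, table, outdir, stem, "top_bar", image_format)


def render_breadth(breadth_map: dict[str, int], outdir: str, stem: str = "breadth",
                   image_format: str = "png") -> ReportArtifact:
    """Chart of how many corpora rank each family in their top-k."""
    items = sorted(breadth_map.items(), key=lambda it: (-it[1], family_index(it[0])))
    table = pd.DataFrame(items, columns=["family", "n_corpora_top_k"])
    fig, ax = plt.subplots(figsize=(8, 4.5))
    if items:
        families = [f for f, _ in items]
        values = [v for _, v in items]
        ax.bar(range(len(families)), values, color="#7f4060")
        ax.set_xticks(range(len(families)))
        ax.set_xticklabels(families, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("corpora with family in top-k")
    ax.set_title("breadth of top-k membership across corpora")
    return _save(fig, table, outdir, stem, "breadth_chart", image_format)


def render_donuts(rankings: list[Ranking], outdir: str, stem: str = "top_donuts",
                  image_format: str = "png") -> ReportArtifact:
    """One donut per corpus; wedge fraction = count / sum of top-k counts."""
    n = max(len(rankings), 1)
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.1 * ncols, 3.1 * nrows))
    axes = np.atleast_1d(axes).ravel()
    rows = []
    for ax in axes[len(rankings):]:
        ax.axis("off")
    for ax, ranking in zip(axes, rankings):
        total = sum(c for _, c in ranking.entries)
        if total:
            ax.pie(
                [c for _, c in ranking.entries],
                labels=[f for f, _ in ranking.entries],
                wedgeprops={"width": 0.45},
                textprops={"fontsize": 6},
                startangle=90, counterclock=False,
            )
            rows.extend(
                (ranking.corpus_label, f, c, c / total) for f, c in ranking.entries
            )
        ax.set_title(ranking.corpus_label, fontsize=8)
    table = pd.DataFrame(rows, columns=["label", "family", "count", "fraction"])
    return _save(fig, table, outdir, stem, "donut_per_corpus", image_format)


def render_heatmaps(matrices: list[CooccurrenceMatrix], outdir: str,
                    stem: str = "cooccurrence_heatmaps",
                    image_format: str = "png") -> ReportArtifact:
    """Annotated co-occurrence heatmaps, one panel per corpus.

    Rows are the corpus's top-k families; columns are grouped by category
    (cell types, then cytokines, then processes) in dictionary order.  The
    color scale is anchored at 0 and normalized per panel.
    """
    n = max(len(matrices), 1)
    fig, axes = plt.subplots(n, 1, figsize=(14, 2.2 * n + 1))
    axes = np.atleast_1d(axes).ravel()
    rows = []
    for ax in axes[len(matrices):]:
        ax.axis("off")
    for ax, matrix in zip(axes, matrices):
        cols = sorted(
            matrix.col_terms,
            key=lambda ct: (CATEGORIES.index(ct[0]), matrix.col_terms.index(ct)),
        )
        data = np.array(
            [[matrix.counts.loc[f, col] for col in cols] for f in matrix.row_families],
            dtype=int,
        ) if matrix.row_families else np.zeros((0, len(cols)), dtype=int)
        vmax = data.max() if data.size else 1
        ax.imshow(data, cmap="YlOrRd", vmin=0, vmax=max(vmax, 1), aspect="auto")
        ax.set_yticks(range(len(matrix.row_families)))
        ax.set_yticklabels(matrix.row_families, fontsize=6)
        ax.set_xticks(range(len(cols)))
        ax.set_xticklabels([t for _, t in cols], rotation=80, ha="right", fontsize=5)
        for i, f in enumerate(matrix.row_families):
            for j, col in enumerate(cols):
                ax.text(j, i, str(data[i, j]), ha="center", va="center", fontsize=4)
                rows.append((matrix.corpus_label, f, col[0], col[1], int(data[i, j])))
        ax.set_title(matrix.corpus_label, fontsize=8)
    table = pd.DataFrame(rows, columns=["label", "family", "category", "term", "count"])
    return _save(fig, table, outdir, stem, "heatmap", image_format)


def render_all(bundle, outdir: str, image_format: str = "png") -> list[ReportArtifact]:
    """Render the full figure set for a pipeline result bundle."""
    artifacts = [
        render_trends([bundle.trends[l] for l in bundle.corpus_labels], outdir,
                      image_format=image_format),
        render_top_bar(bundle.aggregate, outdir, image_format=image_format),
        render_breadth(bundle.breadth_map, outdir, image_format=image_format),
        render_donuts([bundle.rankings[l] for l in bundle.corpus_labels], outdir,
                      image_format=image_format),
        render_heatmaps([bundle.matrices[l] for l in bundle.corpus_labels], outdir,
                        image_format=image_format),
    ]
    return artifacts
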