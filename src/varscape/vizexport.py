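"""The six figure types and file export.

Figure builders are pure functions from data to a matplotlib ``Figure``;
rendering is deterministic (fixed SVG hash salt, no timestamps) so
identical inputs give byte-identical SVG exports.  Color semantics follow
the field's conventions throughout: pathogenic/likely-pathogenic red,
benign/likely-benign blue, population exomes green, genomes blue.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.figure import Figure
from scipy.stats import gaussian_kde

from .datasources import ClinVarRecord, PopulationCount, ScoreMeta
from .genemodel import ExonLayout, TranscriptModel
from .groupstats import GROUP_NAMES, GroupedScores, PairwiseTest
from .scoremodel import ScoreProfile

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "varscape"

COLOR_PLP = "#c0392b"       # pathogenic / likely pathogenic
COLOR_BLB = "#2e86c1"       # benign / likely benign
COLOR_EXOMES = "#1e8449"
COLOR_GENOMES = "#2e86c1"
COLOR_SIMULATED = "#7f8c8d"

MAX_SCORE_PANELS = 3


class PlotCapacityError(ValueError):
    """More score profiles requested than one figure can hold."""


@dataclass(frozen=True)
class ProteinFeature:
    """One annotated protein feature (domain/region/motif) in AA coordinates."""

    feature_type: str
    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad feature interval {self.start}-{self.end}")


@dataclass(frozen=True)
class SelectedVariant:
    """A variant picked for labelling in the transcript/protein plots."""

    gpos: int
    aa_pos: int | None
    label: str
    source: str = "clinvar"      # "clinvar" (red) | "simulated" (gray)


@dataclass
class PlotBundle:
    """The named figure panel set a full run produces."""

    utp: Figure | None = None
    protein: Figure | None = None
    clinvar_density: Figure | None = None
    af_hist: Figure | None = None
    score_model: Figure | None = None
    violins: Figure | None = None

    def as_dict(self) -> dict[str, Figure]:
        return {
            name: fig for name, fig in vars(self).items() if fig is not None
        }


def read_protein_features(tsv_path) -> list[ProteinFeature]:
    """Read a UniProt-like feature TSV: feature_type, label, start, end."""
    feats = []
    with open(tsv_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            feats.append(ProteinFeature(
                feature_type=row["feature_type"], label=row["label"],
                start=int(row["start"]), end=int(row["end"])))
    return feats


def _new_fig(width=8.0, height=3.0) -> tuple[Figure, plt.Axes]:
    fig = Figure(figsize=(width, height))
    ax = fig.add_subplot(111)
    return fig, ax


def build_utp(
    t: TranscriptModel,
    layout: ExonLayout,
    lollipops: list[ClinVarRecord] | None = None,
    selected: list[SelectedVariant] | None = None,
) -> Figure:
    """Unspliced transcript plot: scaled exons, compressed introns, lollipops.

    Exon 1 is leftmost regardless of strand.  Pathogenic/likely-pathogenic
    records are drawn as lollipops (intronic ones land inside the
    compressed intron segments); selected variants get text labels, red
    for ClinVar and gray for simulated ones.
    """
    fig, ax = _new_fig(9, 2.6)
    for seg in layout.segments:
        if seg.kind == "exon":
            ax.add_patch(plt.Rectangle(
                (seg.x0, -0.12), seg.x1 - seg.x0, 0.24,
                facecolor="#34495e", edgecolor="none", zorder=3))
        else:
            ax.plot([seg.x0, seg.x1], [0, 0], color="#95a5a6",
                    lw=1.0, zorder=1)

    span = t.span
    n_drawn = 0
    for rec in lollipops or []:
        if rec.chrom != span.chrom or not span.contains(rec.gpos):
            logger.warning("variant %s:%d outside gene span, skipped",
                           rec.chrom, rec.gpos)
            continue
        x = layout.to_plot(rec.gpos)
        ax.plot([x, x], [0.12, 0.55], color=COLOR_PLP, lw=0.8, zorder=2)
        ax.plot([x], [0.55], "o", color=COLOR_PLP, ms=4, zorder=4)
        n_drawn += 1

    for i, sel in enumerate(selected or []):
        if not span.contains(sel.gpos):
            logger.warning("selected variant at %d outside span, skipped",
                           sel.gpos)
            continue
        color = COLOR_PLP if sel.source == "clinvar" else COLOR_SIMULATED
        x = layout.to_plot(sel.gpos)
        y = 0.75 + 0.12 * (i % 3)
        ax.plot([x, x], [0.12, y], color=color, lw=0.8)
        ax.annotate(sel.label, (x, y), ha="center", va="bottom",
                    fontsize=7, color=color)

    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.4, 1.35)
    ax.set_yticks([])
    ax.set_xlabel(f"{t.gene_symbol} ({t.transcript_id}), transcription order")
    ax.set_title("Unspliced transcript")
    fig._varscape_n_lollipops = n_drawn
    return fig


def build_protein_plot(
    features: list[ProteinFeature],
    length: int,
    selected: list[SelectedVariant] | None = None,
) -> Figure:
    """Linear protein backbone with feature boxes and labelled variants.

    Overlapping features stack into separate lanes so nothing occludes.
    Features reaching past the protein end are clipped with a warning.
    """
    fig, ax = _new_fig(9, 2.8)
    ax.add_patch(plt.Rectangle((1, -0.06), length - 1, 0.12,
                               facecolor="#bdc3c7", edgecolor="none"))

    # greedy lane assignment for overlapping features
    lanes: list[int] = []       # rightmost end per lane
    drawn = []
    for f in sorted(features, key=lambda f: (f.start, f.end)):
        start, end = f.start, f.end
        if end > length:
            logger.warning("feature %s clipped to protein length %d",
                           f.label, length)
            end = length
            if start > length:
                continue
        lane = next((i for i, right in enumerate(lanes) if start > right), None)
        if lane is None:
            lanes.append(end)
            lane = len(lanes) - 1
        else:
            lanes[lane] = end
        y = 0.25 + 0.3 * lane
        ax.add_patch(plt.Rectangle((start, y), end - start + 1, 0.22,
                                   facecolor="#8e44ad", alpha=0.6,
                                   edgecolor="none"))
        ax.annotate(f.label, ((start + end) / 2, y + 0.11), ha="center",
                    va="center", fontsize=7, color="white")
        drawn.append((f, lane))

    marker_positions = []
    for i, sel in enumerate(selected or []):
        if sel.aa_pos is None:
            continue
        color = COLOR_PLP if sel.source == "clinvar" else COLOR_SIMULATED
        ax.plot([sel.aa_pos], [-0.2], marker="v", color=color, ms=6)
        ax.annotate(sel.label, (sel.aa_pos, -0.3 - 0.12 * (i % 3)),
                    ha="center", va="top", fontsize=7, color=color)
        marker_positions.append(sel.aa_pos)

    ax.set_xlim(0, length + 1)
    ax.set_ylim(-0.9, 0.4 + 0.3 * max(1, len(lanes)))
    ax.set_yticks([])
    ax.set_xlabel("amino-acid position")
    ax.set_title("Protein")
    fig._varscape_marker_positions = marker_positions
    fig._varscape_n_lanes = len(lanes)
    return fig


def _kde_curve(positions: np.ndarray, grid: np.ndarray):
    kde = gaussian_kde(positions, bw_method="silverman")
    return kde(grid)


def build_clinvar_density(
    plp_positions: list[int],
    blb_positions: list[int],
    protein_length: int,
) -> Figure:
    """Kernel densities of P/LP (red) and B/LB (blue) variant positions.

    Each curve is normalized independently (shape comparison); per-variant
    rug lines sit underneath.  A group with fewer than two distinct
    positions draws rug only.
    """
    fig, ax = _new_fig(9, 2.8)
    grid = np.linspace(1, protein_length, 512)
    modes = {}
    for positions, color, name in (
        (plp_positions, COLOR_PLP, "P/LP"),
        (blb_positions, COLOR_BLB, "B/LB"),
    ):
        arr = np.asarray(positions, dtype=float)
        if len(arr) >= 2 and len(np.unique(arr)) >= 2:
            dens = _kde_curve(arr, grid)
            ax.plot(grid, dens, color=color, label=name)
            ax.fill_between(grid, dens, color=color, alpha=0.15)
            modes[name] = float(grid[int(np.argmax(dens))])
        elif len(arr):
            logger.warning("%s: <2 distinct positions, rug only", name)
        rug_y = -0.06 if name == "P/LP" else -0.12
        for p in arr:
            ax.plot([p, p], [rug_y, rug_y + 0.05],
                    transform=ax.get_xaxis_transform(),
                    color=color, lw=0.6, clip_on=False)
    ax.set_xlim(1, protein_length)
    ax.set_ylim(bottom=0)
    ax.set_xlabel("amino-acid position")
    ax.set_ylabel("density")
    ax.set_title("ClinVar variant density")
    if modes:
        ax.legend(frameon=False, fontsize=8)
    fig._varscape_density_modes = modes
    return fig


def build_af_hist(
    exomes: list[PopulationCount],
    genomes: list[PopulationCount],
    aa_pos_of: dict[tuple, int] | None = None,
) -> Figure:
    """Two log-scale allele-frequency bar panels (exomes green, genomes blue).

    One bar per variant at its protein (or genomic) position; the log axis
    bottom clips at half the smallest observed allele frequency so no bar
    vanishes.
    """
    fig = Figure(figsize=(9, 3.6))
    axes = fig.subplots(2, 1, sharex=True)
    all_af = [p.af for p in exomes + genomes]
    floor = min(all_af) * 0.5 if all_af else 1e-6
    for ax, records, color, name in (
        (axes[0], exomes, COLOR_EXOMES, "exomes"),
        (axes[1], genomes, COLOR_GENOMES, "genomes"),
    ):
        xs, hts = [], []
        for p in records:
            pos = (aa_pos_of or {}).get(p.key, p.gpos)
            xs.append(pos)
            hts.append(p.af)
        if xs:
            ax.bar(xs, hts, bottom=0, width=1.2, color=color)
        ax.set_yscale("log")
        ax.set_ylim(floor, 1.0)
        ax.set_ylabel(f"AF ({name})")
        ax._varscape_n_bars = len(xs)
    axes[1].set_xlabel("position")
    axes[0].set_title("Population allele frequencies")
    return fig


def _strip_cmap(meta: ScoreMeta | None):
    # damaging end of the scale renders hot (red)
    if meta is not None and meta.orientation == "lower_damaging":
        return plt.get_cmap("RdYlBu")
    return plt.get_cmap("RdYlBu_r")


def build_score_model(
    profiles: list[ScoreProfile],
    registry: dict[str, ScoreMeta] | None = None,
) -> Figure:
    """Smoothed score curve + 95% ribbon with the aligned heat-strip below.

    Up to three scores stack as panels sharing the position axis; a fourth
    raises :class:`PlotCapacityError`.  The registry cutoff is drawn as a
    dashed reference line and orients the heat-strip color map (damaging
    end hot).
    """
    if len(profiles) > MAX_SCORE_PANELS:
        raise PlotCapacityError(
            f"at most {MAX_SCORE_PANELS} score profiles per figure "
            f"(got {len(profiles)})")
    if not profiles:
        raise ValueError("no profiles given")
    registry = registry or {}
    n = len(profiles)
    fig = Figure(figsize=(9, 2.8 * n))
    gs = fig.add_gridspec(2 * n, 1, height_ratios=[6, 1] * n, hspace=0.45)
    length = profiles[0].protein_length
    for i, prof in enumerate(profiles):
        meta = registry.get(prof.score_name)
        ax = fig.add_subplot(gs[2 * i])
        ax.fill_between(prof.grid, prof.ci_low, prof.ci_high,
                        color="#85c1e9", alpha=0.5, lw=0)
        ax.plot(prof.grid, prof.fit, color="#1a5276", lw=1.4)
        if meta is not None:
            ax.axhline(meta.damaging_cutoff, color="#922b21", ls="--", lw=0.8)
        ax.set_xlim(0.5, length + 0.5)
        ax.set_ylabel(prof.score_name, fontsize=8)
        ax.set_title(f"{prof.score_name} ({prof.smoother_used})", fontsize=9)

        axs = fig.add_subplot(gs[2 * i + 1], sharex=ax)
        strip = prof.heat_strip.reshape(1, -1)
        axs.imshow(
            np.ma.masked_invalid(strip), aspect="auto",
            extent=(0.5, length + 0.5, 0, 1),
            cmap=_strip_cmap(meta), interpolation="nearest")
        axs.set_yticks([])
        if i == n - 1:
            axs.set_xlabel("amino-acid position")
    return fig


def build_violins(
    tests: list[PairwiseTest],
    gs: GroupedScores,
) -> Figure:
    """Violin per group with quartile lines and starred significance brackets."""
    fig, ax = _new_fig(8, 4)
    present = [g for g in GROUP_NAMES if len(gs.groups[g]) >= 2]
    if not present:
        raise ValueError("no group with >= 2 values")
    data = [np.asarray(gs.groups[g], float) for g in present]
    positions = np.arange(1, len(present) + 1)
    parts = ax.violinplot(data, positions=positions, showextrema=False)
    for body in parts["bodies"]:
        body.set_facecolor("#5dade2")
        body.set_alpha(0.6)
    quartiles = {}
    for pos, g, vals in zip(positions, present, data):
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        quartiles[g] = (q1, q2, q3)
        ax.hlines([q1, q3], pos - 0.15, pos + 0.15, color="#1b4f72", lw=0.9)
        ax.hlines([q2], pos - 0.22, pos + 0.22, color="#1b4f72", lw=1.6)

    top = max(v.max() for v in data)
    span = max(top - min(v.min() for v in data), 1e-9)
    h = top + 0.06 * span
    idx = {g: p for g, p in zip(present, positions)}
    for t in tests:
        if not t.stars or t.group_a not in idx or t.group_b not in idx:
            continue
        xa, xb = idx[t.group_a], idx[t.group_b]
        ax.plot([xa, xa, xb, xb], [h, h + 0.02 * span, h + 0.02 * span, h],
                color="black", lw=0.8)
        ax.annotate(t.stars, ((xa + xb) / 2, h + 0.02 * span),
                    ha="center", va="bottom", fontsize=9)
        h += 0.09 * span
    ax.set_xticks(positions)
    ax.set_xticklabels(present, fontsize=8)
    ax.set_ylabel(gs.score_name)
    ax.set_title("Score distribution by variant group")
    fig._varscape_quartiles = quartiles
    return fig


def export_plot(fig: Figure, path, format: str | None = None,
                width: float | None = None, height: float | None = None):
    """Write a figure as SVG or PNG with an optional size in inches."""
    path = str(path)
    if format is None:
        format = path.rsplit(".", 1)[-1].lower()
    if format not in ("svg", "png"):
        raise ValueError(f"unsupported plot format {format!r} (svg|png)")
    if width or height:
        w, h = fig.get_size_inches()
        fig.set_size_inches(width or w, height or h)
    metadata = {"Date": None} if format == "svg" else None
    fig.savefig(path, format=format, metadata=metadata)
    return path


def export_table(
    rows,
    path,
    format: str | None = None,
    registry: dict[str, ScoreMeta] | None = None,
) -> str:
    """Write a table as CSV or XLSX, round-trip safe.

    ``rows`` is a DataFrame or list of dicts.  When a registry is given,
    every column matching a registered score name gains a companion
    ``<score>_class`` column tagging each value damaging/tolerated by the
    score's cutoff and orientation.
    """
    path = str(path)
    if format is None:
        format = path.rsplit(".", 1)[-1].lower()
    if format not in ("csv", "xlsx"):
        raise ValueError(f"unsupported table format {format!r} (csv|xlsx)")
    df = rows.copy() if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    if registry:
        for col in [c for c in df.columns if c in registry]:
            meta = registry[col]
            df[f"{col}_class"] = [
                ("" if pd.isna(v) else
                 "damaging" if meta.is_damaging(v) else "tolerated")
                for v in df[col]
            ]
    if format == "csv":
        df.to_csv(path, index=False)
    else:
        df.to_excel(path, index=False)
    return path
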