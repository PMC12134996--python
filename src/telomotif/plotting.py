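"""Occupancy plot rendering.

Each motif class gets a three-part panel: positional occupancy in the
first n bp (x = distance from the read start), positional occupancy in
the last n bp (x = distance from the read end), and a bar pair with the
middle-occupancy fractions.  The forward (G-rich, conventional telomere)
orientation is drawn in blue, the reverse complement in red.  Output is
SVG with a fixed hash salt and no timestamp, so identical profiles render
to identical bytes.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .motifs import reverse_complement, rotations
from .occupancy import OccupancyProfile

__all__ = [
    "profile_figure",
    "render_occupancy_grid",
    "render_single_motif",
    "panel_series",
]

_FWD_COLOR = "tab:blue"
_REV_COLOR = "tab:red"
_SVG_OPTS = {"metadata": {"Date": None}, "format": "svg"}


def panel_series(profile: OccupancyProfile) -> dict[str, np.ndarray]:
    """The exact series a panel plots (no resampling), for assertions."""
    return {
        "five_prime_fwd": profile.five_prime_fwd,
        "five_prime_rev": profile.five_prime_rev,
        "three_prime_fwd": profile.three_prime_fwd,
        "three_prime_rev": profile.three_prime_rev,
        "middle": np.array([profile.middle_fwd_frac, profile.middle_rev_frac]),
    }


def _draw_panel(
    axes,
    profile: OccupancyProfile,
    title: str,
    fwd_label: str,
    rev_label: str,
    fwd_series: tuple[np.ndarray, np.ndarray],
    rev_series: tuple[np.ndarray, np.ndarray],
    three_prime_axis: str = "from_end",
) -> None:
    ax5, ax3, axm = axes
    x = np.arange(1, profile.n + 1)
    ax5.plot(x, fwd_series[0], color=_FWD_COLOR, lw=0.8, label=fwd_label)
    ax5.plot(x, rev_series[0], color=_REV_COLOR, lw=0.8, label=rev_label)
    ax5.set_xlabel("distance from 5' end (bp)")
    ax5.set_ylabel("reads")
    ax5.set_title(title, fontsize=8)
    ax3.plot(x, fwd_series[1], color=_FWD_COLOR, lw=0.8)
    ax3.plot(x, rev_series[1], color=_REV_COLOR, lw=0.8)
    ax3.set_xlabel("distance from 3' end (bp)")
    if three_prime_axis == "mirrored":
        ax3.invert_xaxis()
    axm.bar([0, 1], [profile.middle_fwd_frac, profile.middle_rev_frac],
            color=[_FWD_COLOR, _REV_COLOR])
    axm.set_xticks([0, 1])
    axm.set_xticklabels(["fwd", "rev"], fontsize=6)
    axm.set_ylim(0, 1)
    axm.set_title("middle frac", fontsize=6)


def profile_figure(
    profile: OccupancyProfile,
    title: Optional[str] = None,
    three_prime_axis: str = "from_end",
) -> plt.Figure:
    """One-panel figure for a profile; plotted lines carry the raw arrays."""
    fig = plt.figure(figsize=(7, 2.4))
    gs = fig.add_gridspec(1, 3, width_ratios=[2, 2, 1], wspace=0.4)
    axes = [fig.add_subplot(gs[0, i]) for i in range(3)]
    motif = profile.motif_class.display_motif
    _draw_panel(
        axes,
        profile,
        title or f"{motif} (period {profile.motif_class.period})",
        fwd_label=motif,
        rev_label=reverse_complement(motif),
        fwd_series=(profile.five_prime_fwd, profile.three_prime_fwd),
        rev_series=(profile.five_prime_rev, profile.three_prime_rev),
        three_prime_axis=three_prime_axis,
    )
    axes[0].legend(fontsize=6)
    return fig


def _save(fig: plt.Figure, path: Path) -> None:
    with plt.rc_context({"svg.hashsalt": "telomotif"}):
        fig.savefig(path, **_SVG_OPTS)
    plt.close(fig)


def render_occupancy_grid(
    profiles: Sequence[OccupancyProfile],
    mode: str = "occupancy",
    out_dir: str | Path = ".",
    ranks: Optional[Sequence[int]] = None,
    three_prime_axis: str = "from_end",
) -> list[Path]:
    """Render profiles in occupancy mode (one ranked file per class) or
    exhaustive mode (one grid: periods in columns, occupancy in rows).

    Files are named ``rank{R}_{canonical_key}.svg``; profiles must share
    the same plotting window n.
    """
    if not profiles:
        warnings.warn("no profiles to render")
        return []
    if len({p.n for p in profiles}) > 1:
        raise ValueError("profiles must share the same plotting window n")
    if ranks is None:
        ranks = list(range(1, len(profiles) + 1))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if mode == "occupancy":
        for rank, profile in zip(ranks, profiles):
            fig = profile_figure(profile, three_prime_axis=three_prime_axis)
            path = out_dir / f"rank{rank}_{profile.motif_class.canonical_key}.svg"
            _save(fig, path)
            written.append(path)
        return written
    if mode != "exhaustive":
        raise ValueError(f"unknown mode {mode!r}")
    periods = sorted({p.motif_class.period for p in profiles})
    columns: dict[int, list[tuple[int, OccupancyProfile]]] = {p: [] for p in periods}
    for rank, profile in zip(ranks, profiles):
        columns[profile.motif_class.period].append((rank, profile))
    for col in columns.values():
        col.sort(key=lambda rp: rp[0])  # occupancy order = rank order
    nrows = max(len(col) for col in columns.values())
    ncols = len(periods)
    fig = plt.figure(figsize=(7 * ncols, 2.4 * nrows))
    gs = fig.add_gridspec(nrows, 3 * ncols, wspace=0.6, hspace=0.8)
    for j, period in enumerate(periods):
        for i, (rank, profile) in enumerate(columns[period]):
            axes = [fig.add_subplot(gs[i, 3 * j + k]) for k in range(3)]
            motif = profile.motif_class.display_motif
            _draw_panel(
                axes,
                profile,
                f"rank {rank}: {motif} (period {period})",
                fwd_label=motif,
                rev_label=reverse_complement(motif),
                fwd_series=(profile.five_prime_fwd, profile.three_prime_fwd),
                rev_series=(profile.five_prime_rev, profile.three_prime_rev),
                three_prime_axis=three_prime_axis,
            )
    path = out_dir / "exhaustive_grid.svg"
    _save(fig, path)
    return [path]


def render_single_motif(
    profile: OccupancyProfile,
    motif_as_typed: str,
    out_path: str | Path,
    three_prime_axis: str = "from_end",
) -> Path:
    """Render one panel titled with the user's exact motif spelling.

    If the user typed the reverse-complement orientation of the class's
    display motif, the blue curve follows *their* spelling (so the colors
    swap relative to the discovered-class convention).
    """
    if set(motif_as_typed) - set("ACGT"):
        raise ValueError(
            f"motif {motif_as_typed!r} contains characters outside ACGT"
        )
    display = profile.motif_class.display_motif
    fwd_rots = set(rotations(display))
    rev_rots = set(rotations(reverse_complement(display)))
    if motif_as_typed in fwd_rots:
        fwd_series = (profile.five_prime_fwd, profile.three_prime_fwd)
        rev_series = (profile.five_prime_rev, profile.three_prime_rev)
    elif motif_as_typed in rev_rots:
        fwd_series = (profile.five_prime_rev, profile.three_prime_rev)
        rev_series = (profile.five_prime_fwd, profile.three_prime_fwd)
    else:
        raise ValueError(
            f"motif {motif_as_typed} does not belong to class "
            f"{profile.motif_class.canonical_key}"
        )
    fig = plt.figure(figsize=(7, 2.4))
    gs = fig.add_gridspec(1, 3, width_ratios=[2, 2, 1], wspace=0.4)
    axes = [fig.add_subplot(gs[0, i]) for i in range(3)]
    _draw_panel(
        axes,
        profile,
        motif_as_typed,
        fwd_label=motif_as_typed,
        rev_label=reverse_complement(motif_as_typed),
        fwd_series=fwd_series,
        rev_series=rev_series,
        three_prime_axis=three_prime_axis,
    )
    axes[0].legend(fontsize=6)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    _save(fig, out_path)
    return out_path
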