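"""Presentational rendering of traces: cross-section profiles at selected
generations plus the odor/extent time series.  Purely cosmetic — nothing
downstream depends on these figures."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .errors import ValidationError  # noqa: E402
from .state import SimulationTrace  # noqa: E402


def plot_profiles(trace: SimulationTrace, generations: Sequence[int],
                  path: str | Path) -> Path:
    """Plot thickness and quorum profiles at the requested generations,
    plus the colony-extent and odor time series, into one image file.

    Raises :class:`ValidationError` listing the available generations if
    a requested one is absent (e.g. thinned away)."""
    generations = list(generations)
    if not generations:
        raise ValidationError("generations: empty list, nothing to plot")
    available = [s.generation for s in trace.snapshots]
    missing = [g for g in generations if g not in available]
    if missing:
        raise ValidationError(
            f"generations {missing} not recorded in trace; available: "
            f"{available[0]}..{available[-1]} "
            f"({len(available)} snapshots)")

    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=False)
    ax_thick, ax_quorum, ax_series = axes
    for gen in generations:
        snap = trace.snapshot_at(gen)
        ax_thick.plot(snap.thickness, label=f"gen {gen}")
        ax_quorum.plot(snap.quorum, label=f"gen {gen}")
    ax_thick.set_ylabel("thickness (bacteria)")
    ax_thick.set_title("colony cross-section")
    ax_thick.legend(fontsize="small")
    ax_quorum.set_ylabel("quorum (a.u.)")
    ax_quorum.set_xlabel("site")

    gens = [s.generation for s in trace.snapshots]
    ax_series.plot(gens, trace.extent_series, label="extent (sites)")
    ax_series.set_ylabel("extent")
    ax2 = ax_series.twinx()
    ax2.plot(gens, trace.odor_series, color="tab:red", label="odor")
    ax2.set_ylabel("odor (a.u.)")
    ax_series.set_xlabel("generation")
    ax_series.set_title("colony size and odor level")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
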