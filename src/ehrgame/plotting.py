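"""Optional trajectory plots (requires matplotlib, installed via the
``plot`` extra)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .dynamics import Trajectory

__all__ = ["plot_trajectory", "plot_scenarios"]


def plot_trajectory(traj: Trajectory, path: str | Path, title: str = "") -> None:
    """Line chart of x, y, z against time, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, label in (("x", "government pushes (x)"),
                        ("y", "hospital active (y)"),
                        ("z", "patient supervises (z)")):
        ax.plot(traj.times, traj.coordinate(name), label=label)
    ax.set_xlabel("time (years)")
    ax.set_ylabel("strategy fraction")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scenarios(trajectories: Mapping[str, Trajectory], out_dir: str | Path) -> None:
    """One plot per labelled trajectory, ``scenario_<label>.png`` each."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label, traj in trajectories.items():
        plot_trajectory(traj, out_dir / f"scenario_{label}.png",
                        title=f"scenario {label}")
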