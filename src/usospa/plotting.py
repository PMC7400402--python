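"""Optional matplotlib rendering for trajectories and sweeps.

Import is deferred so the package works without matplotlib; every
quantitative output lives in CSV/JSON, never in an image.
"""

from __future__ import annotations

from pathlib import Path

from .integrate import Trajectory


def plot_trajectory(traj: Trajectory, path: str | Path, title: str = "") -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name in ("S", "O", "P", "U"):
        ax.plot(traj.times, traj.compartment(name), label=name)
    ax.set_xlabel("t (model time)")
    ax.set_ylabel("population fraction")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_figure(figure_id: str, result, out_dir: str | Path) -> Path:
    """Render whatever :func:`usospa.reproduce_figure` returned."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{figure_id}.png"

    if isinstance(result, Trajectory):
        return plot_trajectory(result, path, title=figure_id)

    items = result if isinstance(result, list) else [result]
    fig, axes = plt.subplots(1, len(items), figsize=(6 * len(items), 4.5),
                             squeeze=False)
    for ax, item in zip(axes[0], items):
        if not hasattr(item, "trajectories"):  # comparison record etc.
            continue
        comp = item.spec.compartment
        for value, traj in zip(item.spec.grid, item.trajectories):
            ax.plot(traj.times, traj.compartment(comp),
                    label=f"{item.spec.quantity}={value:g}")
        ax.set_xlabel("t (model time)")
        ax.set_ylabel(f"{comp} fraction")
        ax.legend(fontsize=8)
    fig.suptitle(figure_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
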