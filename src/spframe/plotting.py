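"""RMSe-versus-height plots, one figure per scenario pair."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_rmse_table"]

_TARGET_ORDER = ["center", "right", "left", "anterior", "posterior", "anterolateral"]


def plot_rmse_table(table, out_dir, prefix="rmse"):
    """One RMSe-vs-z figure per scenario in the table.

    Returns the list of written file paths (PNG).
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for scenario_id, sub in table.groupby("scenario_id"):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        targets = [t for t in _TARGET_ORDER if t in set(sub["target"])]
        targets += sorted(set(sub["target"]) - set(targets))
        for target in targets:
            cell = sub[sub["target"] == target].sort_values("z_mm")
            ax.plot(cell["z_mm"], cell["rmse_mm"], label=target, lw=1.2)
        mode = sub["mode"].iloc[0]
        theta = sub["theta_deg"].iloc[0]
        ax.set_xlabel("height z (mm)")
        ax.set_ylabel("RMSe (mm)")
        ax.set_title(f"{scenario_id}: {mode}, tilt {theta:g}\N{DEGREE SIGN}")
        ax.legend(fontsize=8)
        ax.grid(alpha=0.3)
        path = out_dir / f"{prefix}_{scenario_id}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
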