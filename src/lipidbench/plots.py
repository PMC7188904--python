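"""QC plots for CE model fits (requires the ``plot`` extra / matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import stats

from .ce import CEProfile, FitResult


def qc_plot(profile: CEProfile, fit: FitResult, path: str | Path) -> Path:
    """Three-panel fit QC: data + fitted curve, residuals vs CE, residual QQ."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = profile.x, profile.y
    grid = np.linspace(x.min(), x.max(), 400)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.4))

    ax = axes[0]
    ax.plot(x, y, ".", ms=3, alpha=0.4, label="observed")
    ax.plot(grid, fit.predict(grid), "-", lw=2, label="fit")
    ax.axvline(fit.params.mode, ls="--", c="grey", lw=1)
    ax.set_xlabel("collision energy")
    ax.set_ylabel("scan-relative intensity")
    ax.set_title(f"{fit.lipid} / {fit.fragment}")
    ax.legend(frameon=False)

    ax = axes[1]
    ax.plot(x, fit.residuals, ".", ms=3, alpha=0.5)
    ax.axhline(0, c="k", lw=0.8)
    ax.set_xlabel("collision energy")
    ax.set_ylabel("residual")
    ax.set_title(f"MSE={fit.mse:.2e}  SW p={fit.shapiro_wilk_p:.3f}")

    ax = axes[2]
    std = fit.residuals.std(ddof=1)
    z = (fit.residuals - fit.residuals.mean()) / std if std > 0 else fit.residuals
    stats.probplot(z, dist="norm", plot=ax)
    ax.set_title("standardized residual QQ")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
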