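"""Diagnostic figures: Bland–Altman, HR correlation, alignment check."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .validation import AgreementReport

__all__ = ["bland_altman_plot", "hr_correlation_plot"]


def bland_altman_plot(
    means: np.ndarray,
    diffs: np.ndarray,
    report: AgreementReport,
    path: str | Path,
    title: str = "RR′ agreement",
) -> Path:
    """Scatter of paired differences with mean and ±1.96·SD limits."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=6, alpha=0.3, color="tab:blue", edgecolors="none")
    ax.axhline(report.mean_diff_ms, color="k", lw=1, label=f"mean {report.mean_diff_ms:.2f} ms")
    for y in (report.loa_low_ms, report.loa_high_ms):
        ax.axhline(y, color="tab:red", lw=1, ls="--")
    ax.set_xlabel("mean RR′ of the two devices (ms)")
    ax.set_ylabel("device − criterion RR′ (ms)")
    ax.set_title(title)
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def hr_correlation_plot(
    hr_criterion: np.ndarray,
    hr_device: np.ndarray,
    path: str | Path,
    title: str = "instantaneous HR",
) -> Path:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(hr_criterion, hr_device, s=6, alpha=0.3, color="tab:blue", edgecolors="none")
    lims = [
        min(np.min(hr_criterion), np.min(hr_device)) - 5,
        max(np.max(hr_criterion), np.max(hr_device)) + 5,
    ]
    ax.plot(lims, lims, color="k", lw=1)
    ax.set_xlim(lims), ax.set_ylim(lims)
    ax.set_xlabel("criterion HR (bpm)")
    ax.set_ylabel("device HR (bpm)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
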