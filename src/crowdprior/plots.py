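"""Headless figure generation for sweep summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_SPEC_ORDER = ("interest", "education", "both")


def _by_spec(frame: pd.DataFrame):
    for spec in _SPEC_ORDER:
        sub = frame[frame["spec"] == spec].sort_values("sigma")
        if not sub.empty:
            yield spec, sub


def accuracy_vs_effort(frame: pd.DataFrame, path: str | Path) -> None:
    """Mean accuracy (Bayesian solid, majority dotted) and win-rate vs nu_bar."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for spec, sub in _by_spec(frame):
        ax1.plot(sub["nu_bar"], sub["chi_bar"], "-o", ms=3, label=f"Bayes ({spec})")
        ax1.plot(sub["nu_bar"], sub["chi_mv_bar"], ":", label=f"majority ({spec})")
        ax2.plot(sub["nu_bar"], sub["pi_pct"], "-o", ms=3, label=spec)
    ax1.set_xlabel(r"mean volunteers used $\bar\nu$")
    ax1.set_ylabel(r"mean accuracy $\bar\chi$")
    ax2.set_xlabel(r"mean volunteers used $\bar\nu$")
    ax2.set_ylabel(r"win-rate $\pi$ (%)")
    ax2.axhline(50, color="gray", lw=0.5)
    for ax in (ax1, ax2):
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def accuracy_effort_vs_sigma(frame: pd.DataFrame, path: str | Path) -> None:
    """chi_bar and nu_bar as functions of the threshold sigma."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for spec, sub in _by_spec(frame):
        ax1.plot(sub["sigma"], sub["chi_bar"], "-o", ms=3, label=spec)
        ax2.plot(sub["sigma"], sub["nu_bar"], "-o", ms=3, label=spec)
    ax1.set_xlabel(r"$\sigma$")
    ax1.set_ylabel(r"$\bar\chi$")
    ax2.set_xlabel(r"$\sigma$")
    ax2.set_ylabel(r"$\bar\nu$")
    for ax in (ax1, ax2):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_and_auc(frame: pd.DataFrame, path: str | Path) -> None:
    """Pooled one-point ROC trajectory over sigma, and AUC vs sigma."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for spec, sub in _by_spec(frame):
        ax1.plot(sub["fpr"], sub["tpr"], "-o", ms=3, label=spec)
        ax2.plot(sub["sigma"], sub["auc"], "-o", ms=3, label=spec)
    ax1.plot([0, 1], [0, 1], color="gray", lw=0.5)
    ax1.set_xlabel("FPR")
    ax1.set_ylabel("TPR")
    ax2.set_xlabel(r"$\sigma$")
    ax2.set_ylabel("AUC")
    for ax in (ax1, ax2):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
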