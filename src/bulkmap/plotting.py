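"""Manhattan-style plots of windowed SNP indices and the ΔSNP index."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def manhattan(flagged: pd.DataFrame, path, pools=("brown", "yellow")) -> None:
    """Three stacked panels per genome: each pool's windowed SNP index and
    the ΔSNP index with its confidence band and significant windows."""
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    x = flagged["start"].to_numpy() / 1e6
    for ax, pool in zip(axes[:2], pools):
        ax.plot(x, flagged[f"{pool}_index"], ".", ms=1.5, color="0.4")
        ax.set_ylabel(f"{pool}\nSNP index")
        ax.set_ylim(-0.05, 1.05)
    ax = axes[2]
    ax.plot(x, flagged["delta"], ".", ms=1.5, color="0.4")
    if "lower" in flagged:
        ax.plot(x, flagged["lower"], color="tab:blue", lw=0.8)
        ax.plot(x, flagged["upper"], color="tab:blue", lw=0.8)
    sig = flagged[flagged["significant"]] if "significant" in flagged else flagged.iloc[:0]
    if len(sig):
        ax.plot(sig["start"] / 1e6, sig["delta"], ".", ms=2, color="tab:red")
    ax.set_ylabel("ΔSNP index")
    ax.set_xlabel("position (Mb)")
    ax.set_ylim(-1.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
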