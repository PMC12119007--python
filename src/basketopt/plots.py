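"""Optional plotting views over emitted study tables.

The CSV tables are the contract; these helpers only visualize them.
matplotlib is imported lazily so the core package has no hard plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_toer_curves(table: str | Path, out: str | Path) -> None:
    """Type-I error of the inactive basket vs the partner basket's rate,
    one line per (eps, tau) combination."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(table)
    fig, ax = plt.subplots(figsize=(6, 4))
    for (eps, tau), grp in df.groupby(["epsilon", "tau"]):
        ax.plot(grp["p2"], grp["toer_basket1"],
                label=f"eps={eps:g}, tau={tau:g}")
    ax.set_xlabel("true response rate of basket 2")
    ax.set_ylabel("TOER of basket 1")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_convergence(table: str | Path, out: str | Path) -> None:
    """Best-so-far utility value against evaluation index for one optimizer
    trajectory CSV (columns: eval, lambda, epsilon, tau, value)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(table)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["eval"], df["value"].cummax())
    ax.set_xlabel("function evaluation")
    ax.set_ylabel("best utility value so far")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
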