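"""Optional plotting helpers: ranked-interval and bias dot plots."""

from __future__ import annotations

import numpy as np


def caterpillar(risk_frame, ax=None, label="RR"):
    """Ranked per-region estimates with 95% credible intervals.

    ``risk_frame`` is an RR/RER summary frame (columns region_id, mean, lo,
    hi). Regions are sorted by posterior mean; the horizontal line marks 1
    (risk fully explained / at the state average).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    df = risk_frame.sort_values("mean").reset_index(drop=True)
    x = np.arange(len(df))
    ax.vlines(x, df["lo"], df["hi"], color="0.6", lw=1)
    ax.plot(x, df["mean"], "o", ms=3, color="C0")
    ax.axhline(1.0, color="C3", lw=0.8, ls="--")
    ax.set_xlabel("regions (ranked)")
    ax.set_ylabel(label)
    return ax


def bias_dotplot(records, covariate, ax=None):
    """Per-cell bias with interval bars for one covariate, by method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    sub = records[records["covariate"] == covariate]
    for k, (method, mrec) in enumerate(sub.groupby("method")):
        x = np.arange(len(mrec)) + 0.2 * k
        ax.plot(x, mrec["bias"], "o", ms=3, label=method)
    ax.axhline(0.0, color="0.3", lw=0.8)
    ax.set_ylabel(f"bias ({covariate})")
    ax.set_xlabel("imputed cells")
    ax.legend()
    return ax
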