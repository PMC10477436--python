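"""Basic diagnostic plots (PSD overlays, canonical scatter).

matplotlib is imported lazily so the core pipeline has no hard plotting
dependency; install the ``plot`` extra to use this module.
"""

from __future__ import annotations


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_mean_psd(psd, title: str = "", max_freq: float | None = None):
    """Mean PSD with its confidence band."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    f = psd.freqs
    sel = slice(None) if max_freq is None else f <= max_freq
    ax.plot(f[sel], psd.mean_power[sel], color="k", lw=1)
    ax.fill_between(f[sel], psd.ci_low[sel], psd.ci_high[sel], color="0.8")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (AU$^2$/Hz)")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_canonical_scatter(model, title: str = ""):
    """Scores on the first two (or three) canonical variables, one colour per class."""
    plt = _plt()
    k = model.k
    fig = plt.figure(figsize=(5, 4.5))
    if k >= 3:
        ax = fig.add_subplot(projection="3d")
    else:
        ax = fig.add_subplot()
    for cls in model.class_labels:
        pts = model.scores[model.labels == cls]
        if k >= 3:
            ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=2, alpha=0.4, label=cls)
        elif k == 2:
            ax.scatter(pts[:, 0], pts[:, 1], s=2, alpha=0.4, label=cls)
        else:
            ax.scatter(pts[:, 0], pts[:, 0] * 0, s=2, alpha=0.4, label=cls)
    ax.set_xlabel("CAN1")
    ax.set_ylabel("CAN2" if k >= 2 else "")
    ax.set_title(title)
    ax.legend(fontsize=7, markerscale=3)
    fig.tight_layout()
    return fig
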