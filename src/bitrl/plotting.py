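"""Figures: binned choice trajectories by group and recovery scatter plots."""

from __future__ import annotations

import numpy as np

from .behavior import bin_trajectory

__all__ = ["plot_bin_trajectories", "plot_recovery"]


def plot_bin_trajectories(cohort, bin_width: int = 5, ax=None):
    """Mean chosen inflation % per bin, one line per sensation-seeking
    group, with SD error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    by_group: dict = {}
    for subj, sess in zip(cohort.subjects, cohort.sessions):
        label = subj.group_label or "all"
        by_group.setdefault(label, []).append(
            bin_trajectory(sess, bin_width=bin_width).table["mean"].to_numpy()
        )
    for label, curves in sorted(by_group.items()):
        arr = np.stack(curves)
        bins = np.arange(1, arr.shape[1] + 1)
        ax.errorbar(
            bins,
            arr.mean(axis=0),
            yerr=arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else None,
            marker="o",
            capsize=2,
            label=label,
        )
    ax.set_xlabel(f"bin ({bin_width} trials)")
    ax.set_ylabel("mean chosen inflation (%)")
    ax.legend(title="SS group")
    return ax


def plot_recovery(cohort, fit, axes=None):
    """True generative parameters vs posterior means, one panel per
    parameter, with the identity line."""
    import matplotlib.pyplot as plt

    truths = cohort.true_params_frame()
    names = fit.param_names
    if axes is None:
        _, axes = plt.subplots(
            1, len(names), figsize=(3.2 * len(names), 3.2)
        )
    for ax, name in zip(np.atleast_1d(axes), names):
        true = truths[name].to_numpy()
        est = fit.param_draws(name).mean(axis=0)
        ax.scatter(true, est, s=18, alpha=0.7)
        lims = [min(true.min(), est.min()), max(true.max(), est.max())]
        ax.plot(lims, lims, ls="--", c="gray", lw=1)
        ax.set_title(name)
        ax.set_xlabel("true")
    np.atleast_1d(axes)[0].set_ylabel("posterior mean")
    return axes
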