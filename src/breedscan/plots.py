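"""QQ and Manhattan plots for scan results."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .assoc import AssocResult, PermutationEnvelope


def qq_plot(result: AssocResult, envelope: PermutationEnvelope | None = None,
            path=None, title: str = ""):
    """Observed vs expected -log10 p, with the permutation envelope band
    drawn per order statistic when supplied."""
    p = np.sort(result.table["p"].to_numpy())
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(expected, observed, ".", ms=3, color="#1f3b73")
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], lw=1, color="grey")
    if envelope is not None:
        if len(envelope.upper) == n:
            # envelope rank 0 is the most extreme order statistic; flip to
            # match the ascending expected axis
            ax.plot(expected, envelope.upper[::-1], "--", lw=1, color="grey")
            ax.plot(expected, envelope.lower[::-1], "--", lw=1, color="grey")
        ax.axhline(envelope.threshold, lw=1, color="#b3332a")
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def manhattan_plot(result: AssocResult, threshold: float | None = None,
                   suggestive_p: float = 0.0005, path=None, title: str = ""):
    """Per-SNP -log10 p along the genome, chromosomes alternating shade."""
    table = result.table.sort_values(["chrom", "bp"], kind="stable")
    fig, ax = plt.subplots(figsize=(8, 3.5))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(table.groupby("chrom", sort=False)):
        x = sub["bp"].to_numpy() + offset
        ax.plot(x, -np.log10(sub["p"]), ".", ms=3,
                color="#1f3b73" if i % 2 == 0 else "#7b9acc")
        ticks.append(offset + sub["bp"].to_numpy().mean())
        labels.append(str(chrom))
        offset += sub["bp"].max() + 1
    ax.axhline(-np.log10(suggestive_p), lw=1, ls=":", color="grey")
    if threshold is not None:
        ax.axhline(threshold, lw=1, ls="--", color="#b3332a")
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels)
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
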