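"""Optional figure exports: enrichment dot plot and cluster profile lines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def enrichment_dotplot(enrichment_tsv: Path | str, out_png: Path | str) -> str | None:
    """Dot plot of pathway enrichment: colour = adjusted p, size = row
    percentage (overlap / pathway size)."""
    df = pd.read_csv(enrichment_tsv, sep="\t")
    if df.empty:
        return None
    df["row"] = df["pathway_name"] + " (" + df["K"].astype(str) + ")"
    clusters = sorted(df["cluster"].unique())
    rows = sorted(df["row"].unique())
    fig, ax = plt.subplots(figsize=(2 + 1.2 * len(clusters), 1 + 0.4 * len(rows)))
    x = df["cluster"].map({c: i for i, c in enumerate(clusters)})
    y = df["row"].map({r: i for i, r in enumerate(rows)})
    sc = ax.scatter(x, y, s=df["row_pct"] * 6, c=-np.log10(df["padj"]),
                    cmap="coolwarm", edgecolor="k", linewidth=0.4)
    ax.set_xticks(range(len(clusters)), [f"cluster {c}" for c in clusters])
    ax.set_yticks(range(len(rows)), rows)
    fig.colorbar(sc, ax=ax, label="-log10 adjusted p")
    ax.set_title("Pathway enrichment of anti-correlated targets")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return str(out_png)


def profile_plot(profiles_tsv: Path | str, out_png: Path | str) -> str:
    """Line plot of per-cluster mean expression profiles."""
    df = pd.read_csv(profiles_tsv, sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    for cluster, row in df.iterrows():
        ax.plot(range(len(row)), row.values, marker="o", label=f"cluster {cluster}")
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=30)
    ax.set_ylabel("standardised expression")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return str(out_png)
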