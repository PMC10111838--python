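"""Optional matplotlib rendering; imported lazily by the CLI."""

from __future__ import annotations


def render_heatmap(matrix, ids, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix, cmap="viridis")
    if len(ids) <= 40:
        ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(ids)), ids, fontsize=6)
    fig.colorbar(im, ax=ax, label="kinship")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
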