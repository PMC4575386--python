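#!/usr/bin/env python
"""Stage 3: toxin fingerprint factor map.

Takes the relative-change matrix written by stage 2 (peaks x treatments,
ratios vs the pooled control), log-transforms it, and projects the
treatment variables onto the first two principal components. Each
treatment becomes an arrow in the (PC1, PC2) plane; distinct toxins
pointing into distinct half-planes is the quantitative form of "the
fingerprints are toxin-specific".

Writes PCA tables under results/ and, if matplotlib is available, a
variables-factor-map SVG.
"""

import itertools
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from toxprint.fingerprint import fingerprint_pca, half_plane_separable

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix_path = RESULTS / "profile_run" / "change_matrix.csv"
    if not matrix_path.exists():
        print("run analysis/02_simulate_and_profile.py first", file=sys.stderr)
        return 1
    matrix = pd.read_csv(matrix_path, index_col=0)
    result = fingerprint_pca(matrix, log_ratio=True)

    evf = result.explained_variance_fraction
    print(f"PC1 explains {evf[0]:.0%} of the variance, PC2 {evf[1]:.0%}")
    load = result.loadings[["PC1", "PC2"]]
    load.to_csv(RESULTS / "pca_loadings.csv")
    pd.Series(evf, index=result.loadings.columns, name="explained_variance_fraction").to_csv(
        RESULTS / "pca_variance.csv"
    )

    groups: dict = {}
    for name in load.index:
        if name == "control":
            continue
        groups.setdefault(name.split(":")[0], []).append(load.loc[name].to_numpy())
    for a, b in itertools.combinations(sorted(groups), 2):
        sep = half_plane_separable(np.array(groups[a]), np.array(groups[b]))
        print(f"  {a} vs {b}: {'separable' if sep else 'NOT separable'} in the PC plane")

    try:
        import matplotlib

        matplotlib.use("svg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        colors = {"copper_sulfate": "tab:blue", "acridine": "tab:orange", "bnf": "tab:green", "control": "gray"}
        for name in load.index:
            x, y = load.loc[name]
            toxin = name.split(":")[0]
            ax.annotate(
                "", xy=(x, y), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color=colors.get(toxin, "black")),
            )
            ax.text(x, y, name, fontsize=7, color=colors.get(toxin, "black"))
        lim = float(np.abs(load.to_numpy()).max()) * 1.2
        ax.set(
            xlim=(-lim, lim), ylim=(-lim, lim),
            xlabel=f"PC1 ({evf[0]:.0%})", ylabel=f"PC2 ({evf[1]:.0%})",
            title="Treatment variables factor map",
        )
        ax.axhline(0, lw=0.5, color="k")
        ax.axvline(0, lw=0.5, color="k")
        fig.tight_layout()
        fig.savefig(RESULTS / "pca_factor_map.svg")
        print(f"factor map -> {RESULTS/'pca_factor_map.svg'}")
    except ImportError:
        print("matplotlib not available; skipped the factor-map figure")
    return 0


if __name__ == "__main__":
    sys.exit(main())
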