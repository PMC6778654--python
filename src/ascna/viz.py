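"""Diagnostic beta-vs-logR lattice and the ploidy/admixture check plot."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .clonality import expected_signal
from .ploidy_admixture import AdmixtureEstimate, PloidyEstimate, shift_from_ploidy

__all__ = ["expected_lattice", "check_ploidy_and_admixture"]


def expected_lattice(G: float, shift: float = 0.0,
                     max_cn: int = 6) -> pd.DataFrame:
    """Expected (beta, logR) of every clonal integer state up to ``max_cn``.

    One row per allele-specific state 0 <= cnB <= cnA <= max_cn,
    computed from the forward cell-mixture model at clonality 1. The
    clonal homozygous deletion (0, 0) sits at logR -inf when G = 0 and
    is flagged unplottable.
    """
    rows = []
    for a in range(max_cn + 1):
        for b in range(a + 1):
            beta_exp, logr_exp = expected_signal(a, b, 1.0, G, shift)
            rows.append((a, b, beta_exp, logr_exp, f"({a},{b})",
                         bool(np.isfinite(logr_exp))))
    return pd.DataFrame(rows, columns=["cnA", "cnB", "beta_exp", "logR_exp",
                                       "label", "plottable"])


def check_ploidy_and_admixture(beta_table: pd.DataFrame,
                               ploidy: PloidyEstimate | float,
                               admixture: AdmixtureEstimate | float,
                               out_image: str | None = None,
                               out_table: str | None = None,
                               max_cn: int = 6):
    """Beta-vs-logR scatter with the expected integer-state lattice.

    Observed segments are drawn as gray dots and the lattice of
    expected positions (given the ploidy and admixture estimates) as
    light-red circles with state labels; the title carries both
    estimates so conflicting interpretations can be compared at a
    glance. The lattice is also written as TSV (``out_table``) — the
    same object that is plotted, so the two cannot drift apart.

    Returns ``(figure, lattice)``.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from . import tables_io

    if isinstance(ploidy, PloidyEstimate):
        shift, pl = ploidy.shift, ploidy.ploidy
    else:
        pl = float(ploidy)
        shift = shift_from_ploidy(pl)
    g = admixture.adm if isinstance(admixture, AdmixtureEstimate) else float(admixture)
    lattice = expected_lattice(g, shift, max_cn)

    fig, ax = plt.subplots(figsize=(7, 5))
    obs = beta_table.loc[beta_table["beta"].notna() & beta_table["logR"].notna()]
    if obs.empty:
        warnings.warn("no segment with a defined beta; plotting the expected "
                      "lattice only", stacklevel=2)
    else:
        ax.scatter(obs["logR"], obs["beta"], s=14, c="0.45", alpha=0.7,
                   label="segments", zorder=2)
    plottable = lattice.loc[lattice["plottable"]]
    ax.scatter(plottable["logR_exp"], plottable["beta_exp"], s=180,
               facecolors="none", edgecolors="lightcoral", linewidths=1.6,
               label="expected states", zorder=3)
    for row in plottable.itertuples(index=False):
        ax.annotate(row.label, (row.logR_exp, row.beta_exp), fontsize=7,
                    ha="center", va="center", color="firebrick")
    ax.set_xlabel("logR")
    ax.set_ylabel("beta")
    ax.set_ylim(-0.02, 1.05)
    ax.set_title(f"ploidy {pl:.2f}, DNA admixture {g:.2f}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if out_table is not None:
        tables_io.write_table(lattice, out_table)
    if out_image is not None:
        fig.savefig(out_image, dpi=150)
    return fig, lattice
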