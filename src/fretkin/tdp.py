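"""Transition density plots (TDPs) from idealized FRET paths.

A TDP is a 2-D histogram of (FRET before transition, FRET after
transition) accumulated over Viterbi-idealized trajectories: the initial
FRET value on the x-axis, the final value on the y-axis.  A reversible
system produces a TDP symmetric under transposition; the symmetry score
quantifies how much transition mass has a matching reverse transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .hmm import IdealizedPath

__all__ = [
    "TdpMatrix",
    "extract_transitions",
    "build_tdp",
    "tdp_symmetry_score",
    "plot_tdp",
]


@dataclass
class TdpMatrix:
    bin_edges: np.ndarray          # shared by both axes
    counts: np.ndarray             # raw 2-D histogram, initial axis first
    density: np.ndarray            # kernel-smoothed counts
    n_transitions: int
    smoothing_bandwidth: float


def extract_transitions(paths: list[IdealizedPath]) -> np.ndarray:
    """(initial_fret, final_fret) pairs, one per state change in each path.

    Coordinates are the fitted state means; self-persistence contributes
    nothing.  Returns an (n, 2) array (possibly empty).
    """
    if not paths:
        raise ValueError("need at least one path")
    pairs = []
    for p in paths:
        states = np.asarray(p.state_index)
        change = np.flatnonzero(np.diff(states) != 0)
        if change.size:
            pairs.append(
                np.column_stack([p.state_fret[change], p.state_fret[change + 1]])
            )
    if not pairs:
        return np.empty((0, 2))
    return np.vstack(pairs)


def build_tdp(
    pairs: np.ndarray,
    bins: int = 50,
    bandwidth: float = 0.02,
    fret_range: tuple[float, float] = (0.0, 1.0),
) -> TdpMatrix:
    """Histogram transition pairs over [0,1]^2 and smooth with a Gaussian kernel.

    Smoothing uses reflected boundaries so the total mass is conserved
    exactly; raw counts are kept alongside the smoothed density.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("no transition pairs")
    counts, xedges, _ = np.histogram2d(
        pairs[:, 0], pairs[:, 1], bins=bins, range=[fret_range, fret_range]
    )
    bin_width = (fret_range[1] - fret_range[0]) / bins
    sigma = bandwidth / bin_width
    density = gaussian_filter(counts, sigma=sigma, mode="reflect") if sigma > 0 else counts.copy()
    return TdpMatrix(
        bin_edges=xedges,
        counts=counts,
        density=density,
        n_transitions=int(pairs.shape[0]),
        smoothing_bandwidth=bandwidth,
    )


def tdp_symmetry_score(tdp: TdpMatrix) -> float:
    """Fraction of transition mass with a matching reverse transition.

    score = 1 - (unmatched mass)/(2 * total mass), where the unmatched
    mass is half the entrywise L1 norm of D - D^T on the raw counts.
    A perfectly reversible TDP scores 1.0; a TDP whose mass sits entirely
    in one off-diagonal cell (no reverse partner) scores 0.5.
    """
    if tdp.n_transitions < 1:
        raise ValueError("TDP has no transitions")
    d = tdp.counts
    unmatched = 0.5 * np.abs(d - d.T).sum()
    return float(1.0 - unmatched / (2.0 * d.sum()))


def save_tdp(tdp: TdpMatrix, prefix: str | Path) -> None:
    """Write the matrix as TSV plus a JSON metadata sidecar."""
    import json

    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".counts.tsv"), tdp.counts, delimiter="\t", fmt="%.1f")
    np.savetxt(prefix.with_suffix(".density.tsv"), tdp.density, delimiter="\t", fmt="%.6f")
    prefix.with_suffix(".meta.json").write_text(json.dumps({
        "bin_edges": tdp.bin_edges.tolist(),
        "n_transitions": tdp.n_transitions,
        "smoothing_bandwidth": tdp.smoothing_bandwidth,
    }, indent=1))


def plot_tdp(tdp: TdpMatrix, path: str | Path | None = None, ax=None):
    """Render the TDP heat map (initial FRET on x, final on y, viridis)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4))
    lo, hi = tdp.bin_edges[0], tdp.bin_edges[-1]
    im = ax.imshow(
        tdp.density.T, origin="lower", extent=(lo, hi, lo, hi),
        cmap="viridis", aspect="equal",
    )
    ax.set_xlabel("initial FRET")
    ax.set_ylabel("final FRET")
    ax.figure.colorbar(im, ax=ax, label="transition density")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
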