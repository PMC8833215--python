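"""Selection-vs-library enrichment statistics for RNA-fold selections.

After an in vitro selection, each RNA fold's read frequency in the bound
(selected) pool is compared with its frequency in the sequenced starting
library as a pooled population comparison: the two-proportion z statistic

    p_hat = (x_sel + x_lib) / (n_sel + n_lib)
    Z_obs = (x_sel/n_sel - x_lib/n_lib)
            / sqrt(p_hat (1 - p_hat) (1/n_sel + 1/n_lib))

Folds with Z_obs above a fixed cutoff (default 4, empirically anchored to
measured affinities) are called "privileged" for that compound.  Sequence
preference across the six variable positions is summarized as a position
profile with per-position information content in bits, and profiles of two
compounds (e.g. a diastereomer pair) are compared position-wise by
Jensen-Shannon divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rna import RNA_ALPHABET

DEFAULT_Z_CUTOFF = 4.0

COUNT_COLUMNS = ["motif", "compound", "dose", "x_sel", "n_sel", "x_lib", "n_lib"]


def z_obs(x_sel, n_sel, x_lib, n_lib, pooled: bool = True):
    """Two-proportion z statistic of selected vs starting-library counts.

    Vectorized over array-like inputs.  The pooled-variance form is the
    default; ``pooled=False`` uses the unpooled standard error for
    sensitivity analysis.  Degenerate tables (pooled proportion 0 or 1)
    return 0.
    """
    x_sel = np.asarray(x_sel, dtype=float)
    n_sel = np.asarray(n_sel, dtype=float)
    x_lib = np.asarray(x_lib, dtype=float)
    n_lib = np.asarray(n_lib, dtype=float)
    if np.any(n_sel <= 0) or np.any(n_lib <= 0):
        raise ValueError("pool totals must be positive")
    if np.any(x_sel < 0) or np.any(x_lib < 0) or np.any(x_sel > n_sel) or np.any(x_lib > n_lib):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p_sel = x_sel / n_sel
    p_lib = x_lib / n_lib
    if pooled:
        p_hat = (x_sel + x_lib) / (n_sel + n_lib)
        var = p_hat * (1.0 - p_hat) * (1.0 / n_sel + 1.0 / n_lib)
    else:
        var = p_sel * (1.0 - p_sel) / n_sel + p_lib * (1.0 - p_lib) / n_lib
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p_sel - p_lib) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return z if z.ndim else float(z)


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a selection-count table's schema and invariants."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table lacks columns {missing}")
    bad = (
        (counts["x_sel"] < 0)
        | (counts["x_lib"] < 0)
        | (counts["x_sel"] > counts["n_sel"])
        | (counts["x_lib"] > counts["n_lib"])
    )
    if bad.any():
        raise ValueError("counts must satisfy 0 <= x <= n")
    return counts


def call_privileged(
    counts: pd.DataFrame,
    cutoff: float = DEFAULT_Z_CUTOFF,
    pooled: bool = True,
) -> pd.DataFrame:
    """Score every (motif, compound, dose) row and flag privileged folds.

    Returns the table with ``p_sel``, ``p_lib``, ``z_obs`` and
    ``privileged`` (z_obs > cutoff) columns appended, sorted by compound,
    dose, then descending z_obs.
    """
    counts = validate_counts(counts).copy()
    counts["p_sel"] = counts["x_sel"] / counts["n_sel"]
    counts["p_lib"] = counts["x_lib"] / counts["n_lib"]
    counts["z_obs"] = z_obs(
        counts["x_sel"], counts["n_sel"], counts["x_lib"], counts["n_lib"], pooled=pooled
    )
    counts["privileged"] = counts["z_obs"] > cutoff
    return counts.sort_values(
        ["compound", "dose", "z_obs"], ascending=[True, True, False]
    ).reset_index(drop=True)


def privileged_sets(
    results: pd.DataFrame, dose_policy: str = "union"
) -> dict[str, set[str]]:
    """Per-compound privileged motif sets.

    ``dose_policy`` is "union" (privileged at any dose, the default) or
    "max_dose" (only the highest — most stringent — dose counts).
    """
    if dose_policy not in {"union", "max_dose"}:
        raise ValueError(f"unknown dose_policy {dose_policy!r}")
    out: dict[str, set[str]] = {}
    for compound, grp in results.groupby("compound"):
        if dose_policy == "max_dose":
            grp = grp[grp["dose"] == grp["dose"].max()]
        out[str(compound)] = set(grp.loc[grp["privileged"], "motif"])
    return out


def compound_fold_summary(sets: Mapping[str, set[str]]) -> dict:
    """Descriptive summary of privileged folds across compounds.

    Reports per-compound counts, their mean / sd / range, the size of the
    union over compounds, and how many motifs each compound binds uniquely
    (privileged for exactly one compound).  sd is 0 by convention for a
    single compound.
    """
    if not sets:
        raise ValueError("at least one compound required")
    counts = {c: len(s) for c, s in sets.items()}
    values = np.array(list(counts.values()), dtype=float)
    union: set[str] = set().union(*sets.values()) if sets else set()
    motif_owners: dict[str, int] = {}
    for s in sets.values():
        for m in s:
            motif_owners[m] = motif_owners.get(m, 0) + 1
    unique_counts = {
        c: sum(1 for m in s if motif_owners[m] == 1) for c, s in sets.items()
    }
    return {
        "per_compound": counts,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "range": (int(values.min()), int(values.max())),
        "union_size": len(union),
        "unique_counts": unique_counts,
    }


@dataclass(frozen=True)
class PositionProfile:
    """Per-position nucleotide frequencies and information content.

    ``freq`` is positions x 4 (A, C, G, U), each row summing to 1;
    ``bits`` is the per-position information content 2 - H (optionally
    small-sample corrected); ``n_eff`` the (weighted) motif count.
    """

    freq: np.ndarray
    n_eff: float
    bits: np.ndarray

    def __post_init__(self) -> None:
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError("freq must be positions x 4")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must sum to 1")


def position_profile(
    motifs: Sequence[str],
    weights: Sequence[float] | None = None,
    small_sample_correction: bool = False,
) -> PositionProfile:
    """Build a sequence-preference profile from 6-mer motif windows.

    Motifs are the concatenated 3x3 windows (top 3-mer + bottom 3-mer, or
    any fixed-length RNA strings); optional weights (e.g. Z_obs scores)
    bias the frequencies toward the strongest binders.  Information content
    per position is 2 - H bits; the optional small-sample correction
    subtracts e_n = 3 / (2 ln2 n), floored at zero.
    """
    if not motifs:
        raise ValueError("no motifs supplied")
    length = len(motifs[0])
    for m in motifs:
        if len(m) != length or any(c not in RNA_ALPHABET for c in m):
            raise ValueError(f"motif {m!r} is not RNA of length {length}")
    if weights is None:
        w = np.ones(len(motifs))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(motifs),) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    counts = np.zeros((length, 4))
    index = {b: i for i, b in enumerate(RNA_ALPHABET)}
    for m, wi in zip(motifs, w):
        for pos, base in enumerate(m):
            counts[pos, index[base]] += wi
    freq = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    bits = 2.0 - entropy
    if small_sample_correction:
        e_n = 3.0 / (2.0 * np.log(2) * w.sum())
        bits = np.maximum(bits - e_n, 0.0)
    return PositionProfile(freq=freq, n_eff=float(w.sum()), bits=bits)


def diff_profile(a: PositionProfile, b: PositionProfile) -> np.ndarray:
    """Per-position Jensen-Shannon divergence (base 2) between two profiles.

    0 iff the position's frequency columns coincide; 1 bit for disjoint
    point masses; symmetric in its arguments.
    """
    if a.freq.shape != b.freq.shape:
        raise ValueError("profile dimensions differ")

    def _kl(p: np.ndarray, q: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * (np.log2(p) - np.log2(q)), 0.0)
        return terms.sum(axis=1)

    mid = 0.5 * (a.freq + b.freq)
    return 0.5 * _kl(a.freq, mid) + 0.5 * _kl(b.freq, mid)


def plot_logo(profile: PositionProfile, path: str | Path, title: str = "") -> None:
    """Render the profile as a simple stacked-letter information logo (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
    n_pos = profile.freq.shape[0]
    fig, ax = plt.subplots(figsize=(max(4, n_pos), 3))
    for pos in range(n_pos):
        heights = profile.freq[pos] * profile.bits[pos]
        order = np.argsort(heights)
        y = 0.0
        for bi in order:
            h = heights[bi]
            if h <= 0:
                continue
            base = RNA_ALPHABET[bi]
            ax.text(
                pos + 0.5,
                y + h / 2,
                base,
                ha="center",
                va="center",
                fontsize=10 + 20 * h,
                color=colors[base],
                family="monospace",
            )
            y += h
    ax.set_xlim(0, n_pos)
    ax.set_ylim(0, 2)
    ax.set_xticks(np.arange(n_pos) + 0.5, [str(i + 1) for i in range(n_pos)])
    ax.set_ylabel("bits")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --- TSV I/O --------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    return validate_counts(pd.read_csv(path, sep="\t", comment="#"))


def write_results(results: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        results.to_csv(fh, sep="\t", index=False)
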