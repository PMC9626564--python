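"""Systematic-bias quantification: length-binned variability and 3'-end bias.

Ligation-based library preparations load molecules via their ends, so the
identity of the 3' terminal base(s) left by a blunt cutter modulates read
frequency (A-ending fragments ligate worst).  These functions quantify that
effect, and the overall frequency variability, in expected-length bins.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

#: Default end-bias length bins: 401-1000 bp, then 1000-wide to 10,000 bp.
DEFAULT_END_BIAS_EDGES: list[tuple[int, int]] = [(401, 1000)] + [
    (lo + 1, lo + 1000) for lo in range(1000, 10000, 1000)
]


def cv_by_length(table: pd.DataFrame, bin_width: int = 500) -> pd.DataFrame:
    """Coefficient of variation of ``freq_pct`` in fixed-width length bins.

    CV = sample standard deviation / mean within each bin of expected
    fragment length; bins with fewer than two members are omitted (the CV is
    undefined there).
    """
    df = table[["fragment_id", "length", "freq_pct"]].copy()
    df["bin_lo"] = (df["length"] // bin_width) * bin_width
    rows = []
    for bin_lo, grp in df.groupby("bin_lo"):
        if len(grp) < 2:
            continue
        mean = grp["freq_pct"].mean()
        sd = grp["freq_pct"].std(ddof=1)
        rows.append(
            {
                "bin_lo": int(bin_lo),
                "bin_hi": int(bin_lo) + bin_width,
                "n": int(len(grp)),
                "mean_freq_pct": mean,
                "cv": sd / mean if mean > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n", "mean_freq_pct", "cv"])


def _end_column(mode: str) -> str:
    if mode == "single":
        return "end_bases_3p"
    if mode == "dinuc":
        return "end_dinucs_3p"
    raise ValueError("mode must be 'single' or 'dinuc'")


def all_end_classes(mode: str = "single") -> list[str]:
    """Enumerate the unordered 3'-end classes: 10 single-base pairs."""
    if mode == "single":
        alphabet = list("ACGT")
    else:
        alphabet = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
    sep = "" if mode == "single" else "/"
    return sorted(
        sep.join(sorted((a, b)))
        for a, b in itertools.combinations_with_replacement(alphabet, 2)
    )


def end_bias_table(
    table: pd.DataFrame,
    bin_edges: list[tuple[int, int]] | None = None,
    mode: str = "single",
    min_fragments: int = 5,
    value: str = "count",
) -> pd.DataFrame:
    """Mean read count and CV per (3'-end class x length bin) cell.

    Cells with ``n_fragments <= min_fragments`` are suppressed — too few
    fragments for a stable mean.  ``value="freq"`` switches the response
    from raw counts to normalized frequency (class ordering is invariant to
    uniform library rescaling either way).  Per-bin class rankings by mean
    are attached in the ``rank`` column (1 = lowest mean).
    """
    edges = bin_edges if bin_edges is not None else DEFAULT_END_BIAS_EDGES
    col = _end_column(mode)
    if col not in table.columns:
        raise ValueError(f"count table lacks the {col!r} end-class column")
    resp = "count" if value == "count" else "freq_pct"
    rows = []
    for lo, hi in edges:
        in_bin = table[(table["length"] >= lo) & (table["length"] <= hi)]
        for end_class, grp in in_bin.groupby(col):
            if len(grp) <= min_fragments:
                continue
            mean = grp[resp].mean()
            sd = grp[resp].std(ddof=1)
            rows.append(
                {
                    "end_class": end_class,
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "n_fragments": int(len(grp)),
                    "mean_count": mean,
                    "cv": sd / mean if mean > 0 else np.nan,
                }
            )
    cells = pd.DataFrame(
        rows, columns=["end_class", "bin_lo", "bin_hi", "n_fragments", "mean_count", "cv"]
    )
    if len(cells):
        cells["rank"] = cells.groupby("bin_lo")["mean_count"].rank(method="min").astype(int)
    else:
        cells["rank"] = pd.Series(dtype=int)
    return cells


def end_bias_summary(cells: pd.DataFrame) -> dict:
    """Aggregate end-bias cells into class-level means and pairwise ratios.

    Each class's summary mean is its length-bin-weighted mean count
    (weights = fragments per cell), so bins with more fragments dominate.
    Pairwise ratios between every two observed classes are reported; a class
    missing from the cells yields a null ratio.
    """
    if not len(cells):
        return {"class_means": {}, "pairwise_ratios": {}}
    means = {}
    for end_class, grp in cells.groupby("end_class"):
        w = grp["n_fragments"].to_numpy(dtype=float)
        means[end_class] = float(np.average(grp["mean_count"], weights=w))
    classes = sorted(means)
    ratios: dict[str, float | None] = {}
    for a in classes:
        for b in classes:
            if a == b:
                continue
            ratios[f"{a}:{b}"] = means[a] / means[b] if means[b] > 0 else None
    return {"class_means": means, "pairwise_ratios": ratios}
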