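"""Replication-driven copy-number gradients from two-condition count ratios.

A rapidly growing bacterium carries more copies of origin-proximal sequence
than of terminus-proximal sequence, so the ratio of within-sample-normalized
read frequencies between exponential- and stationary-phase DNA rises near
the replication origin and dips near the terminus.  These functions compute
per-fragment ratios across genomic position, smooth them (fixed genomic
bins or a weighted rolling window of adjacent fragments), locate the
extrema, and test origin-vs-terminus differences by permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _circular_distance(a: np.ndarray | float, b: float, glen: float) -> np.ndarray | float:
    d = np.abs(np.asarray(a, dtype=float) - b) % glen
    return np.minimum(d, glen - d)


def per_fragment_ratio(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    fragments: pd.DataFrame,
    digest_label: str = "",
) -> pd.DataFrame:
    """Ratio of normalized frequencies (condition A / condition B) per fragment.

    Both tables must be normalized within-sample (``freq_pct``), which makes
    the ratio invariant to either library's sequencing depth.  Fragments
    with zero frequency in either condition are excluded; their number is
    recorded in ``.attrs["n_excluded"]``.  The genomic midpoint is
    ``(start + length/2) mod genome_length``.
    """
    ids_a, ids_b = set(table_a["fragment_id"]), set(table_b["fragment_id"])
    inv_ids = set(fragments["fragment_id"])
    if not (inv_ids <= ids_a and inv_ids <= ids_b):
        raise ValueError("count tables do not cover the fragment inventory")
    need = ["fragment_id", "start", "length", "genome_length"]
    merged = (
        fragments[need]
        .merge(table_a[["fragment_id", "freq_pct"]], on="fragment_id")
        .merge(table_b[["fragment_id", "freq_pct"]], on="fragment_id", suffixes=("_a", "_b"))
    )
    defined = (merged["freq_pct_a"] > 0) & (merged["freq_pct_b"] > 0)
    out = merged[defined].copy()
    out["ratio"] = out["freq_pct_a"] / out["freq_pct_b"]
    out["midpoint"] = (out["start"] + out["length"] / 2.0) % out["genome_length"]
    out["digest"] = digest_label
    out = out[["fragment_id", "digest", "midpoint", "length", "ratio"]].reset_index(drop=True)
    out.attrs["n_excluded"] = int((~defined).sum())
    return out


def rolling_bin_average(
    ratios: pd.DataFrame,
    genome_length: int,
    bin_width: int = 100_000,
) -> pd.DataFrame:
    """Unweighted mean ratio in fixed genomic bins, pooled across digests.

    Bins tile the circular genome; a fragment belongs to the bin containing
    its midpoint.  Empty bins are kept with a null mean so the track always
    tiles the genome.  The bin's representative position is the midpoint of
    the member fragment with the extreme-defining ratio consumers may need;
    both the bin start and the argmax member midpoint are emitted.
    """
    n_bins = int(np.ceil(genome_length / bin_width))
    idx = (ratios["midpoint"] // bin_width).astype(int) % n_bins
    rows = []
    for b in range(n_bins):
        grp = ratios[idx == b]
        rows.append(
            {
                "bin_start": b * bin_width,
                "bin_width": bin_width,
                "n_fragments": int(len(grp)),
                "mean_ratio": float(grp["ratio"].mean()) if len(grp) else np.nan,
                "argmax_midpoint": float(grp.loc[grp["ratio"].idxmax(), "midpoint"])
                if len(grp)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def weighted_rolling_average(
    ratios: pd.DataFrame,
    window_k: int = 50,
) -> pd.DataFrame:
    """Length-weighted rolling mean over ``window_k`` genomically adjacent fragments.

    Fragments are ordered by midpoint with circular adjacency; each output
    point is the fragment-length-weighted mean ratio of the window centered
    (by count) on that fragment, anchored at the center fragment's midpoint.
    ``window_k=1`` is the identity.
    """
    n = len(ratios)
    if window_k > n:
        raise ValueError(f"window of {window_k} fragments exceeds the {n} available")
    if window_k < 1:
        raise ValueError("window_k must be >= 1")
    srt = ratios.sort_values("midpoint").reset_index(drop=True)
    r = srt["ratio"].to_numpy(dtype=float)
    w = srt["length"].to_numpy(dtype=float)
    half = window_k // 2
    offsets = np.arange(-half, -half + window_k)
    smoothed = np.empty(n)
    for i in range(n):
        idx = (i + offsets) % n
        smoothed[i] = np.average(r[idx], weights=w[idx])
    return pd.DataFrame(
        {
            "midpoint": srt["midpoint"],
            "smoothed_ratio": smoothed,
            "window_k": window_k,
        }
    )


def extremum_report(track: pd.DataFrame) -> dict:
    """Locate the track's extreme mean ratios and their max/min quotient.

    Positions are reported both as the bin start and as the midpoint of the
    strongest member fragment within the extreme bin (when available).
    """
    col = "mean_ratio" if "mean_ratio" in track.columns else "smoothed_ratio"
    pos_col = "bin_start" if "bin_start" in track.columns else "midpoint"
    defined = track.dropna(subset=[col])
    if not len(defined):
        raise ValueError("track has no defined bins")
    imax = defined[col].idxmax()
    imin = defined[col].idxmin()
    report = {
        "max_position": float(defined.loc[imax, pos_col]),
        "max_ratio": float(defined.loc[imax, col]),
        "min_position": float(defined.loc[imin, pos_col]),
        "min_ratio": float(defined.loc[imin, col]),
    }
    report["max_min_ratio"] = report["max_ratio"] / report["min_ratio"]
    if "argmax_midpoint" in defined.columns:
        report["max_fragment_midpoint"] = float(defined.loc[imax, "argmax_midpoint"])
        report["min_fragment_midpoint"] = float(defined.loc[imin, "argmax_midpoint"])
    return report


def _region_members(
    ratios: pd.DataFrame,
    center: float,
    glen: float,
    mode: str,
    extent: float,
) -> pd.Index:
    d = _circular_distance(ratios["midpoint"].to_numpy(), center, glen)
    if mode == "fixed_distance":
        return ratios.index[d <= extent]
    if mode == "fixed_count":
        k = int(extent)
        return ratios.index[np.argsort(d, kind="stable")[:k]]
    raise ValueError("mode must be 'fixed_distance' or 'fixed_count'")


def region_significance(
    ratios: pd.DataFrame,
    genome_length: int,
    center_a: float,
    center_b: float,
    mode: str = "fixed_distance",
    extent: float = 200_000,
    n_perm: int = 10_000,
    seed: int | None = None,
    statistic: str = "permutation",
) -> dict:
    """Test whether two genomic regions differ in mean ratio.

    Regions are windows around two positions (typically the replication
    origin and terminus), either all fragments within ``extent`` bp
    (``fixed_distance``) or the ``extent`` nearest fragments
    (``fixed_count``).  The default test permutes region labels over member
    fragments and reports a two-sided p-value for the difference in means
    (add-one estimator, floor 1/(n_perm+1)); a Mann-Whitney U alternative is
    available.  Overlapping regions are refused.
    """
    idx_a = _region_members(ratios, center_a, genome_length, mode, extent)
    idx_b = _region_members(ratios, center_b, genome_length, mode, extent)
    if len(set(idx_a) & set(idx_b)):
        raise ValueError("regions overlap; choose narrower windows")
    va = ratios.loc[idx_a, "ratio"].to_numpy(dtype=float)
    vb = ratios.loc[idx_b, "ratio"].to_numpy(dtype=float)
    if not len(va) or not len(vb):
        raise ValueError("a region contains no fragments")
    observed = va.mean() - vb.mean()
    result = {
        "statistic": observed,
        "n_a": int(len(va)),
        "n_b": int(len(vb)),
        "mode": mode,
        "seed": seed,
    }
    if statistic == "mannwhitney":
        stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        result.update({"test": "mannwhitney", "u": float(stat), "p": float(p)})
        return result
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([va, vb])
    n_a = len(va)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    diffs = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
    exceed = int(np.sum(np.abs(diffs) >= abs(observed)))
    result.update({"test": "permutation", "n_perm": n_perm, "p": (exceed + 1) / (n_perm + 1)})
    return result
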