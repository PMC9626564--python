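"""Per-fragment read counting, filtering and normalization.

Reads are aligned (upstream, e.g. with pbmm2 or minimap2) against a
reference in which every restriction fragment is one entry, so read->fragment
assignment is simply the alignment's reference name.  A read producing any
supplementary alignment is the signature of an incompletely digested,
chimeric molecule and is removed entirely; secondary and unmapped records
are never counted; each surviving read contributes exactly one primary
record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

COUNT_COLUMNS = [
    "fragment_id", "length", "count", "freq_pct", "rpm", "rpkm",
    "mean_obs_len", "median_obs_len", "mean_aligned_len",
]


class MalformedInputError(ValueError):
    """An alignment file violates the one-primary-per-read contract."""


@dataclass
class AlignedRead:
    """One SAM record reduced to what counting needs."""

    read_id: str
    fragment_id: str | None
    read_length: int
    alignment_type: str  # primary | secondary | supplementary | unmapped
    ref_start: int = -1
    ref_end: int = -1

    @property
    def aligned_span(self) -> int:
        return max(self.ref_end - self.ref_start, 0)


def _classify(rec: pysam.AlignedSegment) -> str:
    if rec.is_unmapped:
        return "unmapped"
    if rec.is_supplementary:
        return "supplementary"
    if rec.is_secondary:
        return "secondary"
    return "primary"


def load_alignments(
    path: str | Path,
    inventory: pd.DataFrame | None = None,
) -> list[AlignedRead]:
    """Stream a SAM/BAM file into :class:`AlignedRead` records.

    Read length is the query sequence length (full molecule for
    ligation-style long reads), inferred from the CIGAR when the record
    stores no sequence.  Records aligned to a reference missing from the
    fragment inventory are bucketed as ``unassigned`` with a warning.
    """
    known = set(inventory["fragment_id"]) if inventory is not None else None
    reads: list[AlignedRead] = []
    n_unassigned = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            atype = _classify(rec)
            fragment_id = rec.reference_name if not rec.is_unmapped else None
            if fragment_id is not None and known is not None and fragment_id not in known:
                n_unassigned += 1
                fragment_id = "unassigned"
            length = rec.query_length or rec.infer_read_length() or 0
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    fragment_id=fragment_id,
                    read_length=length,
                    alignment_type=atype,
                    ref_start=rec.reference_start if not rec.is_unmapped else -1,
                    ref_end=rec.reference_end if not rec.is_unmapped else -1,
                )
            )
    if n_unassigned:
        warnings.warn(
            f"{path}: {n_unassigned} records aligned to references absent from the "
            "fragment inventory; bucketed as 'unassigned'",
            stacklevel=2,
        )
    return reads


def filter_reads(reads: list[AlignedRead]) -> list[AlignedRead]:
    """Drop chimera-signature reads; keep one primary record per survivor.

    Any read id with >= 1 supplementary alignment (incomplete digestion) is
    removed with all its records.  The operation is a projection: applying
    it twice equals applying it once.
    """
    by_read: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_read.setdefault(r.read_id, []).append(r)
    kept: list[AlignedRead] = []
    for read_id, group in by_read.items():
        if any(r.alignment_type == "supplementary" for r in group):
            continue
        primaries = [r for r in group if r.alignment_type == "primary"]
        if len(primaries) > 1:
            raise MalformedInputError(f"read {read_id!r} has {len(primaries)} primary alignments")
        if primaries and primaries[0].fragment_id not in (None, "unassigned"):
            kept.append(primaries[0])
    return kept


def count_and_normalize(
    reads: list[AlignedRead],
    fragments: pd.DataFrame,
) -> pd.DataFrame:
    """Build the per-fragment count table with percent / RPM / RPKM columns.

    Every inventory fragment is retained, zero-count fragments included: the
    full inventory is the denominator for summaries.  ``freq_pct`` sums to
    100 and ``rpm`` to 1e6 over the library; ``rpkm = rpm / (L/1000)``.
    Observed-length statistics are over the counted reads of each fragment
    (NaN where a fragment got no reads).
    """
    if not len(reads):
        raise ValueError("zero counted reads: normalization undefined")
    obs = pd.DataFrame(
        {
            "fragment_id": [r.fragment_id for r in reads],
            "obs_len": [r.read_length for r in reads],
            "aligned_len": [r.aligned_span for r in reads],
        }
    )
    per_frag = obs.groupby("fragment_id").agg(
        count=("obs_len", "size"),
        mean_obs_len=("obs_len", "mean"),
        median_obs_len=("obs_len", "median"),
        mean_aligned_len=("aligned_len", "mean"),
    )
    table = fragments[["fragment_id", "length"]].merge(
        per_frag, on="fragment_id", how="left"
    )
    extra = [c for c in ("end_bases_3p", "end_dinucs_3p", "copy_count", "start", "end",
                         "genome_id", "genome_length") if c in fragments.columns]
    if extra:
        table = table.merge(fragments[["fragment_id", *extra]], on="fragment_id", how="left")
    table["count"] = table["count"].fillna(0).astype(int)
    total = table["count"].sum()
    if total == 0:
        raise ValueError("zero counted reads: normalization undefined")
    table["freq_pct"] = 100.0 * table["count"] / total
    table["rpm"] = 1e6 * table["count"] / total
    table["rpkm"] = table["rpm"] / (table["length"] / 1000.0)
    return table


def length_concordance(table: pd.DataFrame, shear_threshold: float = 0.9) -> pd.DataFrame:
    """Expected vs observed fragment length, flagging shear suspects.

    A fragment whose median observed read length falls below
    ``shear_threshold * L`` is flagged: random shearing truncates long
    molecules while the predicted length keeps growing.
    """
    out = table[["fragment_id", "length", "mean_obs_len", "median_obs_len"]].copy()
    out["shear_suspect"] = out["median_obs_len"] < shear_threshold * out["length"]
    out.loc[out["median_obs_len"].isna(), "shear_suspect"] = False
    return out


def coverage_profile(
    reads: list[AlignedRead],
    fragments: pd.DataFrame,
    n_bins: int = 100,
    normalize: str = "source",
) -> pd.DataFrame:
    """Binned positional coverage per fragment, on a normalized [0, 1) axis.

    Depth is accumulated in ``n_bins`` equal-width bins over [0, L) per
    fragment, then divided by the maximum depth over all fragments of the
    declared DNA source (``normalize="source"``) or by each fragment's own
    maximum (``normalize="fragment"``).  Zero-coverage fragments yield
    all-zero profiles.
    """
    if normalize not in ("source", "fragment"):
        raise ValueError("normalize must be 'source' or 'fragment'")
    lengths = dict(zip(fragments["fragment_id"], fragments["length"]))
    depth = {fid: np.zeros(n_bins) for fid in lengths}
    for r in reads:
        if r.fragment_id not in depth or r.ref_start < 0:
            continue
        L = lengths[r.fragment_id]
        lo = int(np.floor(r.ref_start / L * n_bins))
        hi = int(np.ceil(r.ref_end / L * n_bins))
        depth[r.fragment_id][lo : min(hi, n_bins)] += 1.0
    source_max = max((d.max() for d in depth.values()), default=0.0)
    rows = []
    for fid, d in depth.items():
        denom = d.max() if normalize == "fragment" else source_max
        norm = d / denom if denom > 0 else d
        for b in range(n_bins):
            rows.append(
                {"fragment_id": fid, "bin": b, "x_norm": (b + 0.5) / n_bins,
                 "depth": d[b], "depth_norm": norm[b]}
            )
    return pd.DataFrame(rows)


def threshold_summary(
    table: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.001, 0.01, 0.1),
    top_k: int = 20,
) -> dict:
    """Library summary: fragments above frequency thresholds and top-20 sizes.

    Counts fragments with ``freq_pct`` strictly greater than each threshold
    (in percent).  The ``top_k`` most frequent fragments (frequency ties
    broken toward longer expected length) are summarized by their median and
    (min, max) expected length.
    """
    n_above = {t: int((table["freq_pct"] > t).sum()) for t in thresholds}
    ranked = table.sort_values(["freq_pct", "length"], ascending=[False, False])
    truncated = len(table) < top_k
    top = ranked.head(top_k)
    return {
        "n_fragments": int(len(table)),
        "n_above": n_above,
        "max_pct": float(table["freq_pct"].max()),
        "top_k": int(len(top)),
        "top_k_truncated": truncated,
        "top_k_median_length": float(top["length"].median()),
        "top_k_length_range": (int(top["length"].min()), int(top["length"].max())),
    }


def count_ratio(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    bin_width: int | None = None,
) -> pd.DataFrame:
    """Per-fragment ratio of normalized frequencies between two libraries.

    Within-library normalization makes the ratio invariant to scaling either
    library's raw counts.  Fragments with zero frequency in the denominator
    library carry a NaN ratio and are excluded from any binned aggregation.
    With ``bin_width`` set, mean ratios per expected-length bin are attached
    as a second frame.
    """
    shared = set(table_a["fragment_id"]) & set(table_b["fragment_id"])
    if not shared:
        raise ValueError("count tables share no fragments")
    merged = table_a[["fragment_id", "length", "freq_pct"]].merge(
        table_b[["fragment_id", "freq_pct"]],
        on="fragment_id",
        suffixes=("_a", "_b"),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["ratio"] = np.where(
            merged["freq_pct_b"] > 0, merged["freq_pct_a"] / merged["freq_pct_b"], np.nan
        )
    merged.attrs["n_undefined"] = int(merged["ratio"].isna().sum())
    if bin_width is not None:
        defined = merged.dropna(subset=["ratio"])
        bins = (defined["length"] // bin_width).astype(int)
        binned = (
            defined.groupby(bins)["ratio"].agg(mean_ratio="mean", n="size").reset_index()
        )
        binned["bin_lo"] = binned["length"] * bin_width
        binned["bin_hi"] = binned["bin_lo"] + bin_width
        merged.attrs["binned"] = binned[["bin_lo", "bin_hi", "mean_ratio", "n"]]
    return merged
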