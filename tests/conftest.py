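"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fragcal import (
    BiasModel,
    GenomeSequence,
    collapse_unique,
    digest,
    get_enzyme,
    simulate_genome,
    simulate_library,
)
from fragcal.digest import FragmentReference, inventory_frame
from fragcal.enzymes import IUPAC_CODES, RecognitionSite, reverse_complement

FLAT_ENDS = {b: 1.0 for b in "ACGT"}

_BASE_TO_IDX = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


def brute_force_cut_sites(genome: GenomeSequence, enzyme: RecognitionSite) -> list[int]:
    """Independent cut-site scan: test every window against the IUPAC pattern.

    Vectorized sliding-window membership test over an integer-encoded
    genome, run separately for the pattern and its reverse complement; no
    regular expressions involved.  Genome N never matches.
    """
    seq = genome.sequence
    glen, plen = len(seq), len(enzyme.pattern)
    if plen > glen:
        return []
    s = seq + (seq[: plen - 1] if genome.is_circular else "")
    idx = _BASE_TO_IDX[np.frombuffer(s.encode(), dtype=np.uint8)]
    n_win = len(s) - plen + 1
    cuts: set[int] = set()
    variants = {(enzyme.pattern, enzyme.cut_offset),
                (reverse_complement(enzyme.pattern), plen - enzyme.cut_offset)}
    for pattern, offset in variants:
        allowed = np.zeros((plen, 5), dtype=bool)
        for j, code in enumerate(pattern):
            for b in IUPAC_CODES[code]:
                allowed[j, _BASE_TO_IDX[ord(b)]] = True
        match = np.ones(n_win, dtype=bool)
        for j in range(plen):
            match &= allowed[j, idx[j : j + n_win]]
        for i in np.nonzero(match)[0]:
            cuts.add((int(i) + offset) % glen if genome.is_circular else int(i) + offset)
    return sorted(cuts)


def make_fragment(
    fid: str,
    length: int,
    start: int = 0,
    genome_length: int = 1_000_000,
    left_dinuc_3p: str | None = None,
    right_dinuc_3p: str | None = None,
    seed: int = 0,
) -> FragmentReference:
    """Construct a standalone fragment, optionally with prescribed 3' ends.

    ``left_dinuc_3p`` is the bottom-strand 3'-terminal 2-mer (5'->3'), i.e.
    the reverse complement of the fragment's first two bases.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    if left_dinuc_3p is not None:
        seq[:2] = list(reverse_complement(left_dinuc_3p))
    if right_dinuc_3p is not None:
        seq[-2:] = list(right_dinuc_3p)
    return FragmentReference(
        fragment_id=fid,
        genome_id="synthetic",
        start=start,
        end=start + length,
        length=length,
        sequence="".join(seq),
        genome_length=genome_length,
    )


def truth_count_table(library, fragments) -> pd.DataFrame:
    """Count table built from the simulator's truth (molecule counts)."""
    inv = inventory_frame(fragments)
    t = library.truth.rename(columns={"n_molecules": "count"})[["fragment_id", "count"]]
    tab = inv.merge(t, on="fragment_id")
    total = tab["count"].sum()
    tab["freq_pct"] = 100.0 * tab["count"] / total
    tab["rpm"] = 1e6 * tab["count"] / total
    tab["rpkm"] = tab["rpm"] / (tab["length"] / 1000.0)
    return tab


@pytest.fixture(scope="session")
def xmn_digest():
    """A 1 Mb random circular genome digested with XmnI (collapsed)."""
    genome = simulate_genome(1_000_000, seed=3)
    fragments = collapse_unique(digest(genome, get_enzyme("XmnI")))
    return genome, fragments


@pytest.fixture(scope="session")
def flat_library(xmn_digest):
    """Unbiased ligation library on the XmnI digest: the null fixture."""
    _, fragments = xmn_digest
    bias = BiasModel(length_efficiency="flat", end_efficiency_3p=dict(FLAT_ENDS))
    return simulate_library(fragments, bias, 100_000, seed=9), fragments
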