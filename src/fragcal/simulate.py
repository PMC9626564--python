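"""Truth-annotated synthetic genomes, digests and biased read libraries.

The simulator embodies the bias mechanisms that shape long-read counts of
restriction-fragment standards, so every analysis module is testable
against known ground truth without any sequencing data:

* a unimodal length-efficiency curve (SPRI size selection plus polymerase
  residence), peaking near 4 kb for a short-fragment prep and near 10 kb
  for a long-fragment prep;
* per-3'-base ligation-efficiency multipliers (A-ending fragments ligate
  worst), composed multiplicatively over a fragment's two blunt ends;
* Poisson random shearing whose break count grows with molecule length,
  producing truncated reads and mid-fragment coverage dips;
* incomplete digestion, emitting chimeric molecules that span two
  genomically adjacent fragments and show up as supplementary alignments;
* a replication copy-number gradient between an origin and a terminus;
* a transposase ("rapid") mode whose reads start at random internal
  positions, making counts proportional to length and destroying length
  information.

All randomness flows from one integer seed; regenerating with the same seed
reproduces every file bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from fragcal.digest import FragmentReference, GenomeSequence

#: Ligation-efficiency multiplier per 3' terminal base (A < T < G < C).
DEFAULT_END_EFFICIENCY = {"A": 0.41, "T": 0.8, "G": 0.9, "C": 1.0}

LENGTH_PRESETS = {"flat": None, "short_prep": 4_000.0, "long_prep": 10_000.0}


def _lognormal_efficiency(L: np.ndarray, peak: float, width: float = 0.75,
                          floor: float = 0.05) -> np.ndarray:
    """Unimodal curve in L, maximum 1 + floor at ``peak``, never below ``floor``."""
    return floor + np.exp(-((np.log(L / peak)) ** 2) / (2.0 * width**2))


@dataclass
class BiasModel:
    """Declared bias mechanisms for one simulated library.

    ``length_efficiency`` is a preset name (``"flat"``, ``"short_prep"``,
    ``"long_prep"``) or a callable L -> efficiency.  ``copy_number_profile``
    is ``None`` (uniform) or a dict with ``origin``, ``terminus`` (bp) and
    ``fold`` (copy number at the origin relative to the terminus); copy
    number interpolates linearly with circular distance along each arc.
    """

    length_efficiency: str | object = "flat"
    end_efficiency_3p: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_END_EFFICIENCY)
    )
    shear_rate: float = 0.0  # per-base break probability per molecule
    incomplete_digest_rate: float = 0.0
    mode: str = "ligation"  # ligation | transposase
    copy_number_profile: dict | None = None

    def __post_init__(self) -> None:
        if isinstance(self.length_efficiency, str) and self.length_efficiency not in LENGTH_PRESETS:
            raise ValueError(f"unknown length-efficiency preset {self.length_efficiency!r}")
        if any(v <= 0 for v in self.end_efficiency_3p.values()):
            raise ValueError("end efficiencies must be positive")
        for rate in (self.shear_rate, self.incomplete_digest_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mode not in ("ligation", "transposase"):
            raise ValueError("mode must be 'ligation' or 'transposase'")

    def length_eff(self, L: np.ndarray) -> np.ndarray:
        L = np.asarray(L, dtype=float)
        if callable(self.length_efficiency):
            return np.asarray(self.length_efficiency(L), dtype=float)
        peak = LENGTH_PRESETS[self.length_efficiency]
        if peak is None:
            return np.ones_like(L)
        return _lognormal_efficiency(L, peak)

    def end_eff(self, end_bases: tuple[str, str]) -> float:
        return self.end_efficiency_3p[end_bases[0]] * self.end_efficiency_3p[end_bases[1]]

    def copy_number(self, midpoint: np.ndarray, genome_length: int) -> np.ndarray:
        """Copy number at genomic positions under the replication gradient."""
        m = np.asarray(midpoint, dtype=float)
        if self.copy_number_profile is None:
            return np.ones_like(m)
        o = float(self.copy_number_profile["origin"])
        t = float(self.copy_number_profile["terminus"])
        fold = float(self.copy_number_profile["fold"])
        G = float(genome_length)
        arc_ot = (t - o) % G  # origin -> terminus, clockwise
        pos_cw = (m - o) % G
        on_cw = pos_cw <= arc_ot
        frac = np.where(
            on_cw,
            np.divide(pos_cw, arc_ot, out=np.zeros_like(m), where=arc_ot > 0),
            np.divide((o - m) % G, G - arc_ot, out=np.zeros_like(m), where=G - arc_ot > 0),
        )
        return fold * (1.0 - frac) + frac

    def abundance_weights(self, fragments: list[FragmentReference]) -> np.ndarray:
        """Relative molecular abundance per fragment (copy number x duplicates)."""
        mid = np.array([f.midpoint for f in fragments])
        glen = fragments[0].genome_length
        return self.copy_number(mid, glen) * np.array(
            [f.copy_count for f in fragments], dtype=float
        )

    def sampling_weights(self, fragments: list[FragmentReference]) -> np.ndarray:
        """Truth: relative probability an emitted read comes from each fragment.

        Exact for unsheared libraries (abundance x length efficiency x end
        efficiencies, or abundance x L in transposase mode); with shearing it
        is the no-break approximation of the piece-level retention model.
        """
        L = np.array([f.length for f in fragments], dtype=float)
        w = self.abundance_weights(fragments)
        if self.mode == "transposase":
            # every internal position is an insertion opportunity
            w = w * L
        else:
            w = w * self.length_eff(L)
            w = w * np.array([self.end_eff(f.end_bases_3p) for f in fragments])
        return w

    def to_dict(self) -> dict:
        return {
            "length_efficiency": self.length_efficiency
            if isinstance(self.length_efficiency, str)
            else "custom",
            "end_efficiency_3p": self.end_efficiency_3p,
            "shear_rate": self.shear_rate,
            "incomplete_digest_rate": self.incomplete_digest_rate,
            "mode": self.mode,
            "copy_number_profile": self.copy_number_profile,
        }


@dataclass
class SimulatedRead:
    read_id: str
    fragment_id: str
    start: int
    end: int
    is_chimeric: bool = False
    chimera_partner: str | None = None
    partner_length: int = 0


@dataclass
class SimulatedLibrary:
    """Reads plus the truth table they were drawn from."""

    reads: list[SimulatedRead]
    truth: pd.DataFrame  # fragment_id, length, weight, n_molecules, n_chimeric
    bias: BiasModel
    seed: int
    fragments: list[FragmentReference]

    def to_sam(self, path: str | Path) -> None:
        """Write a minimal valid SAM: primaries, plus the supplementary
        records betraying chimeric (incompletely digested) molecules."""
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": f.fragment_id, "LN": int(f.length)} for f in self.fragments
            ],
        }
        lengths = {f.fragment_id: f.length for f in self.fragments}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            hdr = out.header
            for read in self.reads:
                rec = pysam.AlignedSegment(hdr)
                rec.query_name = read.read_id
                rec.reference_id = hdr.get_tid(read.fragment_id)
                rec.reference_start = read.start
                rec.mapping_quality = 60
                rec.cigarstring = f"{read.end - read.start}M"
                rec.flag = 0
                out.write(rec)
                if read.is_chimeric:
                    sup = pysam.AlignedSegment(hdr)
                    sup.query_name = read.read_id
                    sup.reference_id = hdr.get_tid(read.chimera_partner)
                    sup.reference_start = 0
                    sup.mapping_quality = 60
                    sup.cigarstring = f"{read.partner_length}M"
                    sup.flag = 0x800
                    out.write(sup)

    def truth_counts(self) -> pd.DataFrame:
        return self.truth.copy()

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_genome(
    length: int, gc: float = 0.5, topology: str = "circular", seed: int = 0
) -> GenomeSequence:
    """Random i.i.d. genome at a requested GC content, deterministic under seed."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    if length < 100:
        raise ValueError("genome length must be >= 100")
    rng = np.random.default_rng(seed)
    at, cg = (1.0 - gc) / 2.0, gc / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, cg, cg, at])
    return GenomeSequence(id=f"sim{seed}", sequence="".join(bases), topology=topology)


def simulate_library(
    fragments: list[FragmentReference],
    bias: BiasModel,
    n_reads: int,
    seed: int = 0,
) -> SimulatedLibrary:
    """Draw ``n_reads`` molecules from a digest under a declared bias model.

    Molecules are attributed to fragments by molecular abundance (copy
    number x duplicate copies).  In ligation mode each molecule may shear
    into Poisson-distributed pieces that tile its interval exactly; each
    piece then survives library preparation with probability proportional to
    the length-efficiency curve evaluated at the *piece* length times the
    fragment's end-efficiency product (library preparation sees the sheared
    piece, not the original molecule).  Without shearing this reduces
    exactly to per-fragment sampling weights abundance x length_eff(L) x
    end efficiencies, and every sampled molecule yields one read;
    with shearing fewer than ``n_reads`` reads may be emitted.
    Transposase-mode reads run from a uniform internal start to a uniform
    end beyond it, and their count is proportional to fragment length.
    With probability ``incomplete_digest_rate`` a molecule is a chimera
    extending into the genomically adjacent fragment, emitted as a primary
    plus a supplementary alignment.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not fragments:
        raise ValueError("no fragments to sample from")
    rng = np.random.default_rng(seed)
    weights = bias.sampling_weights(fragments)
    probs = weights / weights.sum()

    sheared_mode = bias.mode == "ligation" and bias.shear_rate > 0
    if sheared_mode:
        # piece-level retention model: molecules by abundance, pieces kept
        # with probability scaled so the best piece class is always kept
        ab = bias.abundance_weights(fragments)
        molecule_counts = rng.multinomial(n_reads, ab / ab.sum())
        L_grid = np.array([f.length for f in fragments], dtype=float)
        eff_norm = float(np.max(bias.length_eff(np.linspace(1, L_grid.max(), 512))))
        end_norm = max(bias.end_efficiency_3p.values()) ** 2
    else:
        molecule_counts = rng.multinomial(n_reads, probs)

    # genomic successor of each fragment (digest order, circular wrap)
    successor = {i: (i + 1) % len(fragments) for i in range(len(fragments))}

    reads: list[SimulatedRead] = []
    n_chimeric = np.zeros(len(fragments), dtype=int)
    serial = 0
    for i, frag in enumerate(fragments):
        n_mol = int(molecule_counts[i])
        if n_mol == 0:
            continue
        chim = (
            rng.random(n_mol) < bias.incomplete_digest_rate
            if bias.incomplete_digest_rate > 0
            else np.zeros(n_mol, dtype=bool)
        )
        end_keep = bias.end_eff(frag.end_bases_3p) / end_norm if sheared_mode else 1.0
        for is_chim in chim:
            serial += 1
            rid = f"read{serial:08d}"
            if is_chim:
                j = successor[i]
                n_chimeric[i] += 1
                reads.append(
                    SimulatedRead(
                        read_id=rid,
                        fragment_id=frag.fragment_id,
                        start=0,
                        end=frag.length,
                        is_chimeric=True,
                        chimera_partner=fragments[j].fragment_id,
                        partner_length=fragments[j].length,
                    )
                )
                continue
            if bias.mode == "transposase":
                start = int(rng.integers(0, frag.length))
                end = int(rng.integers(start + 1, frag.length + 1))
                reads.append(SimulatedRead(rid, frag.fragment_id, start, end))
                continue
            # ligation mode: whole molecule, then Poisson shearing
            n_breaks = (
                int(rng.poisson(bias.shear_rate * frag.length))
                if sheared_mode and frag.length > 1
                else 0
            )
            if n_breaks == 0:
                if not sheared_mode or rng.random() < (
                    float(bias.length_eff(np.array([frag.length]))[0]) / eff_norm * end_keep
                ):
                    reads.append(SimulatedRead(rid, frag.fragment_id, 0, frag.length))
                continue
            breaks = np.sort(rng.integers(1, frag.length, size=n_breaks))
            bounds = np.concatenate([[0], np.unique(breaks), [frag.length]])
            piece_len = np.diff(bounds).astype(float)
            keep = rng.random(len(piece_len)) < bias.length_eff(piece_len) / eff_norm * end_keep
            for piece_idx in np.nonzero(keep)[0]:
                reads.append(
                    SimulatedRead(
                        read_id=f"{rid}.{piece_idx}",
                        fragment_id=frag.fragment_id,
                        start=int(bounds[piece_idx]),
                        end=int(bounds[piece_idx + 1]),
                    )
                )
    truth = pd.DataFrame(
        {
            "fragment_id": [f.fragment_id for f in fragments],
            "length": [f.length for f in fragments],
            "weight": weights,
            "sampling_prob": probs,
            "n_molecules": molecule_counts,
            "n_chimeric": n_chimeric,
        }
    )
    return SimulatedLibrary(reads=reads, truth=truth, bias=bias, seed=seed, fragments=fragments)
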