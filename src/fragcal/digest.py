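"""In-silico restriction digestion of circular and linear genomes.

Coordinates are 0-based, half-open, on the top strand.  A cut coordinate is
the genome position immediately before which the blunt cut falls.  For a
circular genome the fragment spanning the sequence origin is represented
with ``end > genome_length`` and interpreted modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from fragcal.enzymes import RecognitionSite, reverse_complement

VALID_TOPOLOGIES = ("circular", "linear")


@dataclass
class GenomeSequence:
    """A reference sequence plus its topology (circular chromosome or linear phage)."""

    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-ACGTN characters {sorted(bad)}")
        if self.topology not in VALID_TOPOLOGIES:
            raise ValueError(f"{self.id}: topology must be one of {VALID_TOPOLOGIES}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


def read_genome_fasta(path: str | Path, topology: str = "linear") -> list[GenomeSequence]:
    """Load every record of a FASTA file as a :class:`GenomeSequence`."""
    genomes = [
        GenomeSequence(id=rec.id, sequence=str(rec.seq), topology=topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not genomes:
        raise ValueError(f"{path}: no FASTA records found")
    return genomes


@dataclass
class FragmentReference:
    """One predicted restriction fragment of a digested genome.

    ``start``/``end`` are 0-based half-open top-strand coordinates; for the
    wrap fragment of a circular genome ``end`` exceeds the genome length.
    ``end_bases_3p`` is the unordered pair of single 3' terminal bases, one
    per double-stranded end: on the left end the 3' base sits on the bottom
    strand (complement of the fragment's first base), on the right end it is
    the top strand's last base.  ``end_dinucs_3p`` is the analogous pair of
    3'-terminal 2-mers, each written 5'->3'.
    """

    fragment_id: str
    genome_id: str
    start: int
    end: int
    length: int
    sequence: str
    genome_length: int
    end_bases_3p: tuple[str, str] = field(default=("", ""))
    end_dinucs_3p: tuple[str, str] | None = None
    copy_count: int = 1

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError(f"{self.fragment_id}: length {self.length} != sequence length")
        if self.length < 1:
            raise ValueError(f"{self.fragment_id}: empty fragment")
        if not self.end_bases_3p[0]:
            bases, dinucs = _terminal_classes_of(self.sequence)
            self.end_bases_3p = bases
            self.end_dinucs_3p = dinucs

    @property
    def midpoint(self) -> float:
        """Fragment midpoint on the genome, modulo genome length."""
        return (self.start + self.length / 2.0) % self.genome_length


def _unordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _terminal_classes_of(seq: str) -> tuple[tuple[str, str], tuple[str, str] | None]:
    left_base = reverse_complement(seq[0])
    right_base = seq[-1]
    bases = _unordered(left_base, right_base)
    if len(seq) < 2:
        return bases, None
    dinucs = _unordered(reverse_complement(seq[:2]), seq[-2:])
    return bases, dinucs


def terminal_classes(
    fragment: FragmentReference,
) -> tuple[tuple[str, str], tuple[str, str]]:
    """Unordered 3'-terminal base pair and dinucleotide pair of a blunt fragment.

    Ten distinct single-base classes exist (unordered pairs over {A,C,G,T}).
    Raises for fragments shorter than 2 bp, where the dinucleotide class is
    undefined.
    """
    if fragment.length < 2:
        raise ValueError(
            f"{fragment.fragment_id}: dinucleotide end class undefined for length-1 fragment"
        )
    bases, dinucs = _terminal_classes_of(fragment.sequence)
    assert dinucs is not None
    return bases, dinucs


def find_cut_sites(genome: GenomeSequence, enzyme: RecognitionSite) -> list[int]:
    """Distinct blunt-cut coordinates of an enzyme on a genome, sorted ascending.

    Both strands are scanned (for the palindromic-degenerate built-ins one
    strand suffices, and the double-strand scan agrees); coordinates implied
    by overlapping windows are de-duplicated.  On circular genomes windows
    spanning the sequence origin are considered and coordinates reduced
    modulo the genome length.
    """
    seq = genome.sequence
    plen = len(enzyme)
    glen = len(seq)
    if plen > glen:
        return []
    search_space = seq + (seq[: plen - 1] if genome.is_circular else "")

    cuts: set[int] = set()
    for m in enzyme.regex().finditer(search_space):
        cuts.add((m.start() + enzyme.cut_offset) % glen if genome.is_circular
                 else m.start() + enzyme.cut_offset)
    rc_pattern = reverse_complement(enzyme.pattern)
    if rc_pattern != enzyme.pattern:
        # a bottom-strand site appears as the reverse-complement pattern on
        # the top strand; its blunt cut sits plen - cut_offset into the window
        rc_enzyme = replace(enzyme, pattern=rc_pattern, cut_offset=len(enzyme) - enzyme.cut_offset)
        for m in rc_enzyme.regex().finditer(search_space):
            cuts.add((m.start() + rc_enzyme.cut_offset) % glen if genome.is_circular
                     else m.start() + rc_enzyme.cut_offset)
    return sorted(cuts)


def _fragment_seq(seq: str, start: int, end: int) -> str:
    """Slice with circular wrap when end exceeds the sequence length."""
    if end <= len(seq):
        return seq[start:end]
    return seq[start:] + seq[: end - len(seq)]


def digest(genome: GenomeSequence, enzyme: RecognitionSite) -> list[FragmentReference]:
    """Cut a genome with an enzyme and inventory the resulting fragments.

    A circular genome with n >= 1 cuts yields exactly n fragments (the last
    wraps past the origin); a linear genome with n cuts yields n + 1.  With
    no cuts the whole genome is returned as a single fragment.  Fragment
    sequences concatenate, in genome order with wrap, back to the genome.
    """
    cuts = find_cut_sites(genome, enzyme)
    glen = len(genome)
    intervals: list[tuple[int, int]]
    if not cuts:
        intervals = [(0, glen)]
    elif genome.is_circular:
        intervals = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
        intervals.append((cuts[-1], cuts[0] + glen))
    else:
        bounds = [0] + cuts + [glen]
        intervals = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        intervals = [(s, e) for s, e in intervals if e > s]  # cut at 0 or glen

    fragments = []
    for start, end in intervals:
        seq = _fragment_seq(genome.sequence, start, end)
        fragments.append(
            FragmentReference(
                fragment_id=f"{genome.id}:{start}-{end}",
                genome_id=genome.id,
                start=start,
                end=end,
                length=end - start,
                sequence=seq,
                genome_length=glen,
            )
        )
    return fragments


def collapse_unique(fragments: list[FragmentReference]) -> list[FragmentReference]:
    """Collapse fragments with identical canonical sequence into one entry.

    Ribosomal-repeat regions of a bacterial genome yield identical fragments
    that are indistinguishable to an aligner; they are merged into a single
    representative whose ``copy_count`` is the group size.  Canonical form is
    the lexicographic minimum of the sequence and its reverse complement, so
    a fragment equal to another's reverse complement collapses too.
    """
    groups: dict[str, list[FragmentReference]] = {}
    order: list[str] = []
    for frag in fragments:
        canon = min(frag.sequence, str(Seq(frag.sequence).reverse_complement()))
        if canon not in groups:
            order.append(canon)
            groups[canon] = []
        groups[canon].append(frag)
    collapsed = []
    for canon in order:
        group = groups[canon]
        rep = replace(group[0], copy_count=sum(f.copy_count for f in group))
        collapsed.append(rep)
    return collapsed


# ---------------------------------------------------------------------------
# artifact io


def _header_of(frag: FragmentReference) -> str:
    return (
        f"{frag.genome_id}:{frag.start}-{frag.end}"
        f"|len={frag.length}|copies={frag.copy_count}"
    )


def write_fragment_fasta(fragments: list[FragmentReference], path: str | Path) -> None:
    """Emit one FASTA record per fragment; headers round-trip all metadata."""
    if not fragments:
        raise ValueError("no fragments to write")
    try:
        with open(path, "w") as fh:
            for frag in fragments:
                fh.write(f">{_header_of(frag)}\n")
                for i in range(0, frag.length, 70):
                    fh.write(frag.sequence[i : i + 70] + "\n")
    except OSError as exc:
        raise OSError(f"cannot write fragment FASTA {path}: {exc}") from exc


def read_fragment_fasta(path: str | Path, genome_length: int | None = None) -> list[FragmentReference]:
    """Parse a fragment FASTA written by :func:`write_fragment_fasta`."""
    fragments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.description
        locus, len_part, copies_part = name.split("|")
        genome_id, span = locus.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        fragments.append(
            FragmentReference(
                fragment_id=locus,
                genome_id=genome_id,
                start=start,
                end=end,
                length=int(len_part.split("=")[1]),
                sequence=str(rec.seq),
                genome_length=genome_length if genome_length is not None else end,
                copy_count=int(copies_part.split("=")[1]),
            )
        )
    if not fragments:
        raise ValueError(f"{path}: no fragment records")
    return fragments


def write_inventory(fragments: list[FragmentReference], path: str | Path) -> None:
    """Write the fragment inventory TSV consumed by the counting module."""
    inventory_frame(fragments).to_csv(path, sep="\t", index=False)


def inventory_frame(fragments: list[FragmentReference]) -> pd.DataFrame:
    rows = []
    for f in fragments:
        rows.append(
            {
                "fragment_id": f.fragment_id,
                "genome_id": f.genome_id,
                "start": f.start,
                "end": f.end,
                "length": f.length,
                "genome_length": f.genome_length,
                "end_bases_3p": "".join(f.end_bases_3p),
                "end_dinucs_3p": "/".join(f.end_dinucs_3p) if f.end_dinucs_3p else "",
                "copy_count": f.copy_count,
            }
        )
    return pd.DataFrame(rows)


def read_inventory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"end_bases_3p": str, "end_dinucs_3p": str})
    required = {"fragment_id", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: inventory missing columns {sorted(missing)}")
    return df
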