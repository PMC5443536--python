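"""Chromosome model and chi-motif scanning.

AddAB-family helicase-nucleases degrade DNA bidirectionally from a
double-strand break (DSB) until they recognise a chi motif in the correct
orientation, which attenuates further processing.  This module locates chi
motifs (default 5'-GCGGTGGT-3') on both strands of a circular bacterial
chromosome, classifies them by replichore, and derives, for a given DSB
position, the ordered distances of chi sites able to attenuate the machine
travelling along each arm.

Coordinates are 0-based, half-open, in base pairs throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

CHI_MOTIF = "GCGGTGGT"

_VALID = set("ACGT")


def _check_dna(s: str, what: str) -> None:
    for i, c in enumerate(s):
        if c not in _VALID:
            raise ValueError(
                f"{what} contains non-ACGT character {c!r} at position {i} "
                "(ambiguity codes are not supported)"
            )


def reverse_complement(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass
class MotifHits:
    """Start coordinates of a motif on each strand of the reference."""

    forward_positions: np.ndarray
    reverse_positions: np.ndarray
    motif: str

    def __post_init__(self) -> None:
        self.forward_positions = np.asarray(self.forward_positions, dtype=np.int64)
        self.reverse_positions = np.asarray(self.reverse_positions, dtype=np.int64)
        for arr in (self.forward_positions, self.reverse_positions):
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError("hit positions must be strictly increasing")


@dataclass
class GenomeModel:
    """A (circular) chromosome with a DSB site and per-strand chi coordinates.

    ``chi_forward`` holds start coordinates of motif occurrences on the
    reference strand, ``chi_reverse`` those of the motif's reverse
    complement.  ``sequence`` is optional: chi positions may be supplied
    directly (the usual case for synthetic layouts).
    """

    length: int
    dsb_position: int
    ori_position: int = 0
    ter_position: int | None = None
    circular: bool = True
    chi_forward: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    chi_reverse: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    sequence: str | None = None
    motif: str = CHI_MOTIF

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if self.ter_position is None:
            self.ter_position = (self.ori_position + self.length // 2) % self.length
        if self.ori_position == self.ter_position:
            raise ValueError("ori_position and ter_position must differ")
        self.chi_forward = np.sort(np.asarray(self.chi_forward, dtype=np.int64))
        self.chi_reverse = np.sort(np.asarray(self.chi_reverse, dtype=np.int64))
        for name in ("dsb_position", "ori_position", "ter_position"):
            v = getattr(self, name)
            if not (0 <= v < self.length):
                raise ValueError(f"{name}={v} outside [0, {self.length})")
        for name in ("chi_forward", "chi_reverse"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() >= self.length):
                raise ValueError(f"{name} coordinates outside [0, {self.length})")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with genome length")

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        dsb_position: int,
        ori_position: int = 0,
        ter_position: int | None = None,
        circular: bool = True,
        motif: str = CHI_MOTIF,
    ) -> "GenomeModel":
        hits = scan_motif(sequence, motif, circular=circular)
        return cls(
            length=len(sequence),
            dsb_position=dsb_position,
            ori_position=ori_position,
            ter_position=ter_position,
            circular=circular,
            chi_forward=hits.forward_positions,
            chi_reverse=hits.reverse_positions,
            sequence=sequence,
            motif=motif,
        )

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "GenomeModel":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected a single-record FASTA, found {len(records)} records in {path}"
            )
        return cls.from_sequence(str(records[0].seq).upper(), **kwargs)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["chi_forward"] = [int(x) for x in self.chi_forward]
        d["chi_reverse"] = [int(x) for x in self.chi_reverse]
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenomeModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def scan_motif(sequence: str, motif: str, circular: bool = False) -> MotifHits:
    """Find all occurrences of ``motif`` on both strands of ``sequence``.

    Overlapping occurrences are all reported.  For a circular sequence,
    matches spanning the coordinate origin are reported once at their
    start modulo the sequence length.
    """
    sequence = sequence.upper()
    motif = motif.upper()
    _check_dna(sequence, "sequence")
    _check_dna(motif, "motif")
    n, m = len(sequence), len(motif)
    if m > n:
        raise ValueError("motif longer than sequence")
    search = sequence + (sequence[: m - 1] if circular and m > 1 else "")
    rc = reverse_complement(motif)

    def _find(pat: str) -> np.ndarray:
        out = []
        i = search.find(pat)
        while i != -1:
            out.append(i % n)
            i = search.find(pat, i + 1)
        return np.array(sorted(set(out)), dtype=np.int64)

    return MotifHits(_find(motif), _find(rc), motif)


def classify_replichore(
    hits: MotifHits,
    ori: int,
    ter: int,
    length: int,
    leading_is_forward_on_right: bool = True,
) -> "pd.DataFrame":
    """Label each hit leading/lagging by replichore arc and strand.

    The right replichore is the ori->ter arc in increasing-coordinate
    direction (mod length); the left replichore is the complement.  With
    the default convention a forward-strand motif on the right replichore
    is *leading* and on the left replichore *lagging* (reverse-strand
    motifs the other way round); ``leading_is_forward_on_right=False``
    flips every label.  Swapping ori and ter swaps the arcs and therefore
    also flips every label.
    """
    import pandas as pd

    if ori == ter:
        raise ValueError("ori and ter must differ")
    rows = []
    for strand, positions in (("+", hits.forward_positions), ("-", hits.reverse_positions)):
        for p in positions:
            on_right = (p - ori) % length < (ter - ori) % length
            leading = (strand == "+") == on_right
            if not leading_is_forward_on_right:
                leading = not leading
            rows.append(
                {
                    "position": int(p),
                    "strand": strand,
                    "replichore": "right" if on_right else "left",
                    "label": "leading" if leading else "lagging",
                }
            )
    return pd.DataFrame(rows, columns=["position", "strand", "replichore", "label"])


def directional_chi(
    genome: GenomeModel,
    dsb: int | None = None,
    convention: str = "A",
) -> tuple[np.ndarray, np.ndarray]:
    """Distances (bp, ascending) of attenuating chi sites along each arm.

    A machine leaving the DSB toward decreasing coordinates ("left") is
    attenuated by chi sites carried on one reference strand, the machine
    moving toward increasing coordinates ("right") by the other.  Which
    strand feeds which machine is not something the reference assembly
    dictates, so it is exposed as a convention: under ``"A"``
    forward-strand motifs face the left-moving machine and reverse-strand
    motifs the right-moving machine; ``"B"`` is the flipped assignment.
    On a circular genome each list runs the whole way round (distances in
    (0, length]), so the two lists partition all sites for one convention
    and each site appears exactly once per convention.
    """
    if dsb is None:
        dsb = genome.dsb_position
    if not (0 <= dsb < genome.length):
        raise ValueError(f"dsb={dsb} outside [0, {genome.length})")
    if convention not in ("A", "B"):
        raise ValueError("convention must be 'A' or 'B'")
    fwd, rev = genome.chi_forward, genome.chi_reverse
    left_src, right_src = (fwd, rev) if convention == "A" else (rev, fwd)
    L = genome.length
    left = np.sort((dsb - left_src) % L)
    right = np.sort((right_src - dsb) % L)
    # distance 0 means a chi at the break itself: recognised immediately
    if not genome.circular:
        left = left[left <= dsb]
        right = right[right <= L - 1 - dsb]
    return left.astype(np.float64), right.astype(np.float64)


def hits_to_bed(hits: MotifHits, path: str | Path, chrom: str = "chr") -> None:
    """Write hits as BED6 (name="chi", score=0, strand +/-)."""
    m = len(hits.motif)
    with open(path, "w") as fh:
        for strand, positions in (("+", hits.forward_positions), ("-", hits.reverse_positions)):
            for p in positions:
                fh.write(f"{chrom}\t{p}\t{p + m}\tchi\t0\t{strand}\n")


def hits_to_tsv(
    hits: MotifHits, ori: int, ter: int, length: int, path: str | Path
) -> None:
    df = classify_replichore(hits, ori, ter, length)
    df.to_csv(path, sep="\t", index=False)
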