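"""Circular genome coordinate frame, reference geometry, and region sets.

Human mtDNA is a ~16.6 kb circular duplex with two replication origins:
OriH, where heavy(H)-strand synthesis initiates, and OriL, where
light(L)-strand synthesis initiates once the fork has exposed it.
Everything downstream of this module (exposure models, occupancy, read
mapping) works in a single 0-based circular coordinate frame defined here.

Conventions
-----------
* Coordinates are 0-based with half-open intervals; all arithmetic is
  modulo the genome length.
* ``sequence``, when present, is the H-strand read 5'->3' in ascending
  coordinates.
* The H-strand replication fork moves in *descending* coordinates from
  ``ori_h``; L-strand synthesis moves in ascending coordinates from
  ``ori_l``. This is the orientation under which the gene just downstream
  of the control region (CYTB) is displaced first and the gene just
  upstream of OriL (COX1) is covered first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircularGenome",
    "Region",
    "RegionSet",
    "DEFAULT_REGIONS",
    "RCRS_LENGTH",
    "RCRS_ORI_H",
    "RCRS_ORI_L",
    "rcrs_geometry",
]

#: Length of the standard human mtDNA reference frame (rCRS), nucleotides.
RCRS_LENGTH = 16569
#: Heavy-strand origin position in the rCRS frame (within the D-loop).
RCRS_ORI_H = 191
#: Light-strand origin position in the rCRS frame.
RCRS_ORI_L = 5735


@dataclass(frozen=True)
class CircularGenome:
    """A circular reference genome with its two replication origins.

    Parameters
    ----------
    length
        Genome size in nucleotides (> 1).
    ori_h, ori_l
        0-based positions of the heavy- and light-strand origins. They
        must be distinct; a genome without two separate origins has no
        strand-displacement geometry.
    sequence
        Optional H-strand nucleotide sequence (5'->3' in ascending
        coordinates), length must equal ``length``.
    name
        Free-text identifier carried through outputs.
    """

    length: int
    ori_h: int
    ori_l: int
    sequence: str | None = None
    name: str = "mtDNA"

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError(f"genome length must be >= 2, got {self.length}")
        for label, pos in (("ori_h", self.ori_h), ("ori_l", self.ori_l)):
            if not 0 <= pos < self.length:
                raise ValueError(f"{label}={pos} outside [0, {self.length})")
        if self.ori_h == self.ori_l:
            raise ValueError("ori_h and ori_l must be distinct positions")
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.length:
                raise ValueError(
                    f"sequence length {len(seq)} != genome length {self.length}"
                )
            object.__setattr__(self, "sequence", seq)

    # -- coordinate arithmetic -------------------------------------------------

    def fork_distance(self, x):
        """Path distance travelled by the H-strand fork from ``ori_h`` to ``x``.

        The fork moves in descending coordinates, so this is
        ``(ori_h - x) mod length``. Accepts scalars or numpy arrays.
        """
        return (self.ori_h - np.asarray(x)) % self.length

    def lagging_distance(self, x):
        """Path distance from ``ori_l`` to ``x`` along the L-synthesis direction.

        L-strand synthesis moves in ascending coordinates:
        ``(x - ori_l) mod length``.
        """
        return (np.asarray(x) - self.ori_l) % self.length

    @property
    def ori_separation(self) -> int:
        """Fork-path distance from OriH to OriL.

        Equal to the lagging-path distance from OriL back to OriH, because
        the two paths run in opposite directions around the same circle.
        """
        return (self.ori_h - self.ori_l) % self.length

    def fraction_synthesized_at_oril(self) -> float:
        """Fraction of the H-strand synthesized when the fork reaches OriL."""
        return self.ori_separation / self.length

    def fetch(self, start: int, length: int) -> str:
        """Return ``length`` nt of H-strand sequence starting at ``start``, circularly."""
        if self.sequence is None:
            raise ValueError("genome has no sequence")
        if length < 0 or length > self.length:
            raise ValueError(f"fetch length {length} outside [0, {self.length}]")
        start %= self.length
        end = start + length
        if end <= self.length:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - self.length]


def rcrs_geometry(sequence: str | None = None, name: str = "rCRS-geometry") -> CircularGenome:
    """The standard human mtDNA geometry (16,569 nt; OriH 191, OriL 5,735)."""
    return CircularGenome(
        length=RCRS_LENGTH, ori_h=RCRS_ORI_H, ori_l=RCRS_ORI_L,
        sequence=sequence, name=name,
    )


@dataclass(frozen=True)
class Region:
    """A named, strand-agnostic genomic interval (0-based, half-open)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.name!r}: empty interval [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError(f"region {self.name!r}: negative start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionSet:
    """An ordered collection of uniquely named regions used for binning."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("RegionSet must contain at least one region")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def validate_against(self, genome: CircularGenome) -> None:
        for r in self.regions:
            if r.end > genome.length:
                raise ValueError(
                    f"region {r.name!r} [{r.start}, {r.end}) exceeds genome length {genome.length}"
                )


# Eight evenly spread gene bins in the rCRS frame used for occupancy binning
# and model comparison. The control region (around OriH) is deliberately not
# represented: mtSSB binds both strands there for reasons unrelated to the
# replication-mode question.
DEFAULT_REGIONS = RegionSet((
    Region("RNR2", 1671, 3229),
    Region("ND1", 3307, 4262),
    Region("ND2", 4470, 5511),
    Region("COX1", 5904, 7445),
    Region("COX3", 9207, 9990),
    Region("ND4", 10760, 12137),
    Region("ND5", 12337, 14148),
    Region("CYTB", 14747, 15887),
))
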