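"""Strand-specific read processing and tagged-qPCR quantification.

Reads are assigned to the heavy or light strand by *perfect-match* search
against the circular reference — the filter actually applied to the
ChIP-seq data being emulated ("reads without a perfect match to the mtDNA"
were excluded). A read whose sequence occurs verbatim in the H-strand
(extended circularly) is an H-strand fragment, i.e. a fragment of the
strand mtSSB binds; a read matching the reverse complement is an L-strand
fragment. Multi-hit and dual-strand reads are discarded as ambiguous.

The qPCR model follows the tagged-primer strand-specific protocol: a
standard curve of input dilutions is fitted by least squares on
log2(quantity) vs Cq, IP and IgG-control quantities are interpolated, and
the reported signal is ``IP/input - IgG/input``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CircularGenome

__all__ = [
    "ReadSet",
    "AlignmentSet",
    "map_reads",
    "StrandFractions",
    "strand_fractions",
    "coverage_track",
    "QpcrMeasurement",
    "QpcrResult",
    "quantify_qpcr",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadSet:
    """Short reads with optional generator truth labels.

    ``truth``, when present, is a DataFrame indexed like ``ids`` with
    columns ``position``, ``strand`` and ``is_background``.
    """

    ids: list[str]
    sequences: list[str]
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        valid = frozenset("ACGTN")
        seqs = []
        for s in self.sequences:
            u = s if s.isupper() else s.upper()
            if not u or not valid.issuperset(u):
                raise ValueError("read sequences must be nonempty ACGT(N)")
            seqs.append(u)
        self.sequences = seqs

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class AlignmentSet:
    """Per-read placements plus summary counts.

    ``table`` columns: ``read_id``, ``position`` (H-strand coordinate of
    the footprint start; -1 if unplaced), ``strand`` ('H', 'L' or ''),
    ``length``, ``mapped``, ``ambiguous``.
    """

    table: pd.DataFrame
    n_total: int
    n_mapped: int
    n_h: int
    n_l: int
    n_ambiguous: int

    def __post_init__(self) -> None:
        if self.n_h + self.n_l != self.n_mapped or self.n_mapped > self.n_total:
            raise ValueError("inconsistent alignment counts")


def _window_index(genome: CircularGenome, k: int) -> dict:
    """Map every circular k-mer window of the H-strand to its start, or to
    None when the window occurs at more than one position."""
    doubled = genome.sequence + genome.sequence[: k - 1]
    index: dict[str, int | None] = {}
    for i in range(genome.length):
        w = doubled[i:i + k]
        index[w] = None if w in index else i
    return index


def map_reads(reads: ReadSet, genome: CircularGenome) -> AlignmentSet:
    """Place reads on the circular genome by exact string match.

    A read maps to strand H if its sequence occurs exactly once in the
    circularly extended H-strand, to strand L if its reverse complement
    does. Reads hitting both strands or multiple positions are discarded
    as ambiguous; reads containing N, or matching nowhere, are unmapped.
    The reported position is always the H-strand coordinate of the
    footprint start.
    """
    if genome.sequence is None:
        raise ValueError("genome sequence required for mapping")
    lengths = {len(s) for s in reads.sequences}
    if any(k > genome.length for k in lengths):
        raise ValueError("read length exceeds genome length")
    indices = {k: _window_index(genome, k) for k in lengths}

    rows = []
    n_h = n_l = n_amb = 0
    for rid, seq in zip(reads.ids, reads.sequences):
        pos, strand, mapped, amb = -1, "", False, False
        if "N" not in seq:
            idx = indices[len(seq)]
            hit_h = idx.get(seq, -1)
            hit_l = idx.get(revcomp(seq), -1)
            amb_h = seq in idx and hit_h is None
            amb_l = revcomp(seq) in idx and hit_l is None
            has_h = amb_h or hit_h >= 0
            has_l = amb_l or hit_l >= 0
            if has_h and has_l or amb_h or amb_l:
                amb = True
                n_amb += 1
            elif has_h:
                pos, strand, mapped = hit_h, "H", True
                n_h += 1
            elif has_l:
                pos, strand, mapped = hit_l, "L", True
                n_l += 1
        rows.append((rid, pos, strand, len(seq), mapped, amb))
    table = pd.DataFrame(
        rows, columns=["read_id", "position", "strand", "length", "mapped", "ambiguous"]
    )
    return AlignmentSet(
        table=table,
        n_total=len(reads),
        n_mapped=n_h + n_l,
        n_h=n_h,
        n_l=n_l,
        n_ambiguous=n_amb,
    )


@dataclass(frozen=True)
class StrandFractions:
    """Mapping-rate summary; per-strand fractions are None when nothing mapped."""

    frac_mapped: float
    frac_h_of_mapped: float | None
    frac_l_of_mapped: float | None

    @property
    def defined(self) -> bool:
        return self.frac_h_of_mapped is not None


def strand_fractions(alignments: AlignmentSet) -> StrandFractions:
    """Mapped fraction and H/L split of the mapped reads.

    With zero mapped reads the per-strand fractions are undefined and
    reported as flagged ``None`` rather than raising.
    """
    if alignments.n_total <= 0:
        raise ValueError("no reads")
    frac_mapped = alignments.n_mapped / alignments.n_total
    if alignments.n_mapped == 0:
        return StrandFractions(frac_mapped, None, None)
    return StrandFractions(
        frac_mapped,
        alignments.n_h / alignments.n_mapped,
        alignments.n_l / alignments.n_mapped,
    )


def coverage_track(
    alignments: AlignmentSet, genome: CircularGenome, read_length: int | None = None
):
    """Per-strand, per-position read coverage with circular footprints.

    Returns ``(cov_h, cov_l)`` integer arrays; the coverage mass on each
    strand equals the number of mapped reads times the read length.
    """
    L = genome.length
    cov = {"H": np.zeros(L, dtype=int), "L": np.zeros(L, dtype=int)}
    mapped = alignments.table[alignments.table["mapped"]]
    for strand in ("H", "L"):
        sub = mapped[mapped["strand"] == strand]
        if sub.empty:
            continue
        pos = sub["position"].to_numpy()
        lens = (
            np.full(len(sub), read_length, dtype=int)
            if read_length is not None
            else sub["length"].to_numpy()
        )
        for k in np.unique(lens):
            starts = pos[lens == k]
            span = (starts[:, None] + np.arange(int(k))[None, :]) % L
            np.add.at(cov[strand], span.ravel(), 1)
    return cov["H"], cov["L"]


@dataclass
class QpcrMeasurement:
    """Strand-specific tagged qPCR readout for one region/strand.

    ``standard_cqs`` are the Cq values of input-dilution standards with
    known relative quantities ``standard_quantities`` (1 = undiluted
    input).
    """

    region: str
    strand: str
    ip_cq: float
    igg_cq: float
    standard_cqs: tuple[float, ...]
    standard_quantities: tuple[float, ...]
    input_quantity: float = 1.0

    def __post_init__(self) -> None:
        if len(self.standard_cqs) != len(self.standard_quantities):
            raise ValueError("standards must pair quantities with Cq values")
        if len(self.standard_cqs) < 2:
            raise ValueError("need at least 2 standard points")
        if any(q <= 0 for q in self.standard_quantities):
            raise ValueError("standard quantities must be positive")
        for cq in (self.ip_cq, self.igg_cq, *self.standard_cqs):
            if not np.isfinite(cq) or cq <= 0:
                raise ValueError("Cq values must be finite and positive")
        if self.input_quantity <= 0:
            raise ValueError("input_quantity must be positive")


@dataclass(frozen=True)
class QpcrResult:
    signal: float
    ip_over_input: float
    igg_over_input: float
    slope: float
    intercept: float
    flagged_nonmonotone: bool


def fit_log_quantity_curve(cqs, quantities):
    """OLS fit of log2(quantity) = slope * Cq + intercept.

    Returns ``(slope, intercept, flagged)``; ``flagged`` marks a
    non-monotone curve (quantity not decreasing with Cq).
    """
    cqs = np.asarray(cqs, dtype=float)
    logq = np.log2(np.asarray(quantities, dtype=float))
    if np.ptp(cqs) == 0:
        raise ValueError("standard Cq values are identical; cannot fit")
    slope, intercept = np.polyfit(cqs, logq, 1)
    return float(slope), float(intercept), bool(slope >= 0)


def quantify_qpcr(measurement: QpcrMeasurement) -> QpcrResult:
    """IgG-corrected, input-normalized strand-specific ChIP signal.

    Fits the input-dilution standard curve, interpolates the IP and IgG
    quantities, and returns ``IP/input - IgG/input``.
    """
    m = measurement
    slope, intercept, flagged = fit_log_quantity_curve(
        m.standard_cqs, m.standard_quantities
    )
    q_ip = 2.0 ** (slope * m.ip_cq + intercept)
    q_igg = 2.0 ** (slope * m.igg_cq + intercept)
    ip_ratio = q_ip / m.input_quantity
    igg_ratio = q_igg / m.input_quantity
    return QpcrResult(
        signal=ip_ratio - igg_ratio,
        ip_over_input=ip_ratio,
        igg_over_input=igg_ratio,
        slope=slope,
        intercept=intercept,
        flagged_nonmonotone=flagged,
    )
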