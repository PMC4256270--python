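"""Synthetic-data generators emulating the ChIP, western and qPCR experiments.

Everything the pipeline consumes can be generated here at desk scale with
known truth: a random circular genome with the standard mtDNA geometry,
a population-averaged occupancy profile obtained by sampling asynchronous
replication phases, strand-specific ChIP-style reads with a labeled
nuclear-background fraction, quantitative-western band-intensity tables
with a linear standard curve, and qPCR Cq tables.

All generators are pure functions of ``(spec, seed)``: the same spec and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import CircularGenome, RCRS_LENGTH, RCRS_ORI_H, RCRS_ORI_L
from .occupancy import DEFAULT_NONSPECIFIC_FRACTION, OccupancyProfile
from .replication import Mode, ReplicationConfig, exposure
from .strandseq import ReadSet, revcomp

__all__ = [
    "SimulationSpec",
    "random_genome",
    "simulate_population_occupancy",
    "sample_chip_reads",
    "simulate_western",
    "simulate_qpcr",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic experiment.

    Defaults emulate the profiled system at desk scale: the standard
    16,569 nt mtDNA geometry, strand-displacement replication with the
    L-strand polymerase twice as fast as the fork, a 20% replicating
    fraction of molecules, 50,000 reads of 36 nt of which 20% are
    nuclear background, a 15% nonspecific within-genome pulldown floor,
    and western/qPCR noise levels typical of those assays.
    """

    genome_length: int = RCRS_LENGTH
    ori_h: int = RCRS_ORI_H
    ori_l: int = RCRS_ORI_L
    gt_bias: float = 0.0
    mode: Mode = Mode.SDM
    v_h: float = 1.0
    v_l: float = 2.0
    okazaki_length: int = 100
    oril_delay: float = 0.0
    n_molecules: int = 20000
    replicating_fraction: float = 0.2
    n_reads: int = 50000
    read_length: int = 36
    background_fraction: float = 0.2
    nonspecific_fraction: float = DEFAULT_NONSPECIFIC_FRACTION
    true_molecules_per_cell: float = 1.08e7
    n_replicates: int = 3
    intensity_cv: float = 0.02
    qpcr_efficiency: float = 1.0
    cq_noise_sd: float = 0.0
    seed: int = 20141204

    def __post_init__(self) -> None:
        for name in ("replicating_fraction", "background_fraction", "nonspecific_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.gt_bias < 0.5:
            raise ValueError("gt_bias must be in [0, 0.5)")
        if min(self.n_molecules, self.n_reads, self.read_length, self.n_replicates) < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 < self.qpcr_efficiency <= 1.0:
            raise ValueError("qpcr_efficiency must be in (0, 1]")
        object.__setattr__(self, "mode", Mode(self.mode))

    @property
    def replication_config(self) -> ReplicationConfig:
        return ReplicationConfig(
            mode=self.mode, v_h=self.v_h, v_l=self.v_l,
            okazaki_length=self.okazaki_length, oril_delay=self.oril_delay,
        )

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=seed)


def _rng(spec_or_seed, stream: int) -> np.random.Generator:
    """Independent, reproducible stream derived from the spec seed."""
    seed = spec_or_seed.seed if isinstance(spec_or_seed, SimulationSpec) else spec_or_seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def random_genome(spec: SimulationSpec, name: str = "synthetic-mtDNA") -> CircularGenome:
    """A random circular genome with the spec's geometry.

    Base composition is uniform by default; ``gt_bias`` shifts the
    H-strand toward G and T, mimicking the heavy strand's base-composition
    bias. The bias affects only sequence realism, never occupancy.
    """
    rng = _rng(spec, 0)
    p_gt = 0.25 + spec.gt_bias / 2.0
    p_ac = 0.25 - spec.gt_bias / 2.0
    probs = {"A": p_ac, "C": p_ac, "G": p_gt, "T": p_gt}
    seq = "".join(rng.choice(_BASES, size=spec.genome_length,
                             p=[probs[b] for b in "ACGT"]))
    return CircularGenome(
        length=spec.genome_length, ori_h=spec.ori_h, ori_l=spec.ori_l,
        sequence=seq, name=name,
    )


def simulate_population_occupancy(
    spec: SimulationSpec, genome: CircularGenome | None = None
) -> OccupancyProfile:
    """Population-average occupancy over asynchronous replicating molecules.

    Draws one replication phase per molecule, uniform over the cycle for
    the replicating fraction; a position contributes occupancy when its
    exposure window contains the sampled phase. Converges to
    ``replicating_fraction * t_ss / cycle_time`` (the analytic expectation)
    as the number of molecules grows.
    """
    if genome is None:
        genome = random_genome(spec)
    prof = exposure(genome, spec.replication_config)
    rng = _rng(spec, 1)
    n_rep = int(round(spec.replicating_fraction * spec.n_molecules))
    if n_rep == 0 or spec.n_molecules == 0:
        z = np.zeros(genome.length)
        return OccupancyProfile(genome, z, z.copy())
    phases = np.sort(rng.uniform(0.0, prof.cycle_time, size=n_rep))
    occ = {}
    for strand, start, t_ss in (
        ("H", prof.start_h, prof.t_ss_h),
        ("L", prof.start_l, prof.t_ss_l),
    ):
        lo = np.searchsorted(phases, start, side="left")
        hi = np.searchsorted(phases, start + t_ss, side="left")
        occ[strand] = (hi - lo) / spec.n_molecules
    return OccupancyProfile(genome, occ["H"], occ["L"])


def _random_reads(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n == 0:
        return []
    chars = rng.choice(_BASES, size=(n, length))
    return ["".join(row) for row in chars]


def sample_chip_reads(occupancy: OccupancyProfile, spec: SimulationSpec) -> ReadSet:
    """Strand-specific ChIP-style reads from an occupancy profile.

    ``background_fraction`` of the reads are random-sequence nuclear
    background, rejection-checked to be unmappable against the genome so
    the mapped fraction has a clean binomial truth. Within-genome reads
    split into a uniform nonspecific-pulldown floor
    (``nonspecific_fraction``, both strands) and specific reads whose
    start positions are drawn proportional to occupancy. H-strand reads
    carry the H-strand sequence; L-strand reads its reverse complement.
    Truth labels (position, strand, background flag) ride along.
    """
    genome = occupancy.genome
    if genome.sequence is None:
        raise ValueError("genome sequence required to emit reads")
    rng = _rng(spec, 2)
    n_bg = int(round(spec.background_fraction * spec.n_reads))
    n_mito = spec.n_reads - n_bg
    n_nonspec = int(round(spec.nonspecific_fraction * n_mito))
    n_specific = n_mito - n_nonspec

    total = occupancy.total
    if total <= 0:
        # No specific signal anywhere (e.g. RITOLS): the nonspecific floor
        # absorbs every within-genome read.
        if n_mito > 0 and spec.nonspecific_fraction == 0 and spec.background_fraction < 1:
            raise ValueError(
                "all-zero occupancy cannot source specific reads; "
                "use background_fraction=1 or a nonzero nonspecific_fraction"
            )
        n_nonspec, n_specific = n_mito, 0

    L = genome.length
    starts = np.empty(n_mito, dtype=int)
    strands = np.empty(n_mito, dtype="U1")
    if n_specific > 0:
        weights = np.concatenate([occupancy.occ_h, occupancy.occ_l]) / total
        draw = rng.choice(2 * L, size=n_specific, p=weights)
        starts[:n_specific] = draw % L
        strands[:n_specific] = np.where(draw < L, "H", "L")
    if n_nonspec > 0:
        starts[n_specific:] = rng.integers(0, L, size=n_nonspec)
        strands[n_specific:] = np.where(rng.random(n_nonspec) < 0.5, "H", "L")

    src = genome.sequence + genome.sequence[: spec.read_length]
    pos_list = starts.tolist()
    strand_list = strands.tolist()
    ids = [f"mito_{i}" for i in range(n_mito)]
    seqs = [
        src[p:p + spec.read_length] if s == "H" else revcomp(src[p:p + spec.read_length])
        for p, s in zip(pos_list, strand_list)
    ]
    truth_rows = [
        (rid, p, s, False) for rid, p, s in zip(ids, pos_list, strand_list)
    ]

    # Background reads: random sequence, re-drawn until unmappable. The
    # window set makes the check O(1) per candidate.
    k = spec.read_length
    windows = frozenset(src[i:i + k] for i in range(L)) if n_bg else frozenset()
    n_accepted = 0
    while n_accepted < n_bg:
        for cand in _random_reads(rng, n_bg - n_accepted, k):
            if cand in windows or revcomp(cand) in windows:
                continue
            rid = f"bg_{n_accepted}"
            ids.append(rid)
            seqs.append(cand)
            truth_rows.append((rid, -1, "", True))
            n_accepted += 1

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "position", "strand", "is_background"]
    )
    return ReadSet(ids=ids, sequences=seqs, truth=truth)


def simulate_western(spec: SimulationSpec) -> pd.DataFrame:
    """Quantitative-western band table: known-amount standards plus cell lanes.

    Intensities respond linearly to loaded amount (arbitrary units per ng)
    and are multiplied by lognormal noise of coefficient of variation
    ``intensity_cv``. Sample lanes load a fixed number of cell equivalents
    whose protein content follows ``true_molecules_per_cell``.

    Columns: ``lane_type`` (standard/sample), ``amount_ng`` (NaN for
    samples), ``n_cells`` (NaN for standards), ``replicate``,
    ``intensity``.
    """
    if spec.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng(spec, 3)
    slope = 1000.0  # arbitrary intensity units per ng
    standard_amounts = np.array([0.05, 0.1, 0.2, 0.4, 0.8])  # ng
    n_cells_per_lane = 1000.0
    monomer_g = 16.0 * 1000.0 / 6.02214076e23
    sample_ng = spec.true_molecules_per_cell * n_cells_per_lane * monomer_g * 1e9

    sigma = np.sqrt(np.log1p(spec.intensity_cv ** 2))

    def noisy(mean_intensity, size):
        if sigma == 0:
            return np.full(size, mean_intensity)
        return mean_intensity * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=size)

    rows = []
    for amount in standard_amounts:
        for i, inten in enumerate(noisy(slope * amount, spec.n_replicates)):
            rows.append(("standard", amount, np.nan, i, float(inten)))
    for i, inten in enumerate(noisy(slope * sample_ng, spec.n_replicates)):
        rows.append(("sample", np.nan, n_cells_per_lane, i, float(inten)))
    return pd.DataFrame(
        rows, columns=["lane_type", "amount_ng", "n_cells", "replicate", "intensity"]
    )


def simulate_qpcr(spec: SimulationSpec, true_quantities: pd.DataFrame) -> pd.DataFrame:
    """Cq table for strand-specific tagged qPCR.

    ``true_quantities`` has columns ``region``, ``strand``,
    ``ip_quantity``, ``igg_quantity`` (relative to input = 1). Emits input
    dilution standards (1, 1/4, 1/16, 1/64) plus IP and IgG rows per
    region/strand, with
    ``Cq = cq_ref - log(q / q_ref) / log(1 + efficiency)`` and Gaussian
    noise of sd ``cq_noise_sd``.
    """
    required = {"region", "strand", "ip_quantity", "igg_quantity"}
    if not required.issubset(true_quantities.columns):
        raise ValueError(f"true_quantities needs columns {sorted(required)}")
    rng = _rng(spec, 4)
    cq_ref, q_ref = 20.0, 1.0
    log_base = np.log(1.0 + spec.qpcr_efficiency)

    def cq_of(q):
        if q <= 0:
            raise ValueError("quantities must be positive")
        cq = cq_ref - np.log(q / q_ref) / log_base
        if spec.cq_noise_sd > 0:
            cq += rng.normal(0.0, spec.cq_noise_sd)
        return float(cq)

    dilutions = [1.0, 0.25, 0.0625, 0.015625]
    rows = []
    for rec in true_quantities.itertuples(index=False):
        for q in dilutions:
            rows.append((rec.region, rec.strand, "standard", q, cq_of(q)))
        rows.append((rec.region, rec.strand, "IP", np.nan, cq_of(rec.ip_quantity)))
        rows.append((rec.region, rec.strand, "IgG", np.nan, cq_of(rec.igg_quantity)))
    return pd.DataFrame(rows, columns=["region", "strand", "role", "quantity", "cq"])
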