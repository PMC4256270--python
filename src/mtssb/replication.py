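"""Single-stranded exposure models for mitochondrial DNA replication.

Three replication modes are modeled, each predicting how long every
parental-strand position stays single-stranded during one replication
cycle — the quantity that determines where the single-stranded DNA
binding protein (mtSSB) can load:

``SDM`` (strand-displacement mode)
    H-strand synthesis starts at OriH and continuously displaces the
    parental H-strand while moving in descending coordinates. When the
    fork reaches OriL (about two-thirds of the genome later), the exposed
    OriL folds into a stem-loop and L-strand synthesis initiates, moving
    in ascending coordinates over the displaced strand. The parental
    H-strand is therefore single-stranded from fork passage until the
    L-strand polymerase covers it; the parental L-strand is never
    displaced.

``SC`` (strand-coupled mode)
    A conventional fork: the parental H-strand is the lagging-strand
    template, exposed only for the lifetime of one Okazaki fragment; the
    parental L-strand is the leading-strand template, exposed only on the
    per-nucleotide timescale of fork passage. Both exposures are small
    and position-independent.

``RITOLS``
    Same fork geometry as SDM, but the displaced strand is covered by RNA
    rather than mtSSB, so the *mtSSB-available* single-stranded time is
    zero everywhere.

The module also carries three smaller models from the same study: the
rolling-circle lagging-strand product-length simulator, the poly-dT
primer-initiation propensity, and the OriL stem-loop accessibility fold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genome import CircularGenome

__all__ = [
    "Mode",
    "ReplicationConfig",
    "ExposureProfile",
    "sdm_exposure",
    "sc_exposure",
    "ritols_exposure",
    "exposure",
    "RollingCircleTemplate",
    "rolling_circle_products",
    "initiation_propensity",
    "OriLStructure",
    "oril_fold",
]


class Mode(str, Enum):
    """Replication mode. Enumeration order is the deterministic tie-break order."""

    SDM = "SDM"
    SC = "SC"
    RITOLS = "RITOLS"


#: Canonical ordering used to break ties in model comparison.
MODE_ORDER = {Mode.SDM: 0, Mode.SC: 1, Mode.RITOLS: 2}


@dataclass(frozen=True)
class ReplicationConfig:
    """Parameters of one replication mode.

    Parameters
    ----------
    mode
        Which replication mode the config describes.
    v_h
        H-strand fork speed, nt per time unit. The absolute scale is
        arbitrary (only ratios of times matter downstream); 1.0 makes one
        time unit = one nucleotide of fork travel.
    v_l
        L-strand synthesis speed. Default 2.0: L-strand synthesis does not
        need the (relatively slow) replicative helicase, since its template
        is already single-stranded, so it is taken to be faster than the
        fork. The ratio is a tunable.
    okazaki_length
        Okazaki fragment length in nt (SC mode only).
    oril_delay
        Time between fork passage of OriL and the first L-strand
        nucleotide (origin folding + priming). Default 0 = instantaneous
        activation.
    control_region
        Optional (start, end) interval exempted from modeling; carried as
        metadata (binning excludes the control region by construction).
    """

    mode: Mode
    v_h: float = 1.0
    v_l: float = 2.0
    okazaki_length: int = 100
    oril_delay: float = 0.0
    control_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if self.v_h <= 0 or self.v_l <= 0:
            raise ValueError("fork speeds must be positive")
        if self.okazaki_length < 1:
            raise ValueError("okazaki_length must be >= 1")
        if self.oril_delay < 0:
            raise ValueError("oril_delay must be >= 0")


@dataclass
class ExposureProfile:
    """Per-position single-stranded exposure times under one mode.

    ``t_ss_h[x]`` / ``t_ss_l[x]`` are the times the parental H/L strand at
    position ``x`` spends single-stranded (and mtSSB-available) during one
    replication cycle. ``start_h`` / ``start_l`` are the times at which each
    exposure window opens, so that a molecule at replication phase ``tau``
    has position ``x`` single-stranded iff
    ``start[x] <= tau < start[x] + t_ss[x]``.
    """

    genome: CircularGenome
    t_ss_h: np.ndarray
    t_ss_l: np.ndarray
    cycle_time: float
    start_h: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    start_l: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    mode: Mode | None = None

    def __post_init__(self) -> None:
        L = self.genome.length
        self.t_ss_h = np.asarray(self.t_ss_h, dtype=float)
        self.t_ss_l = np.asarray(self.t_ss_l, dtype=float)
        if self.t_ss_h.shape != (L,) or self.t_ss_l.shape != (L,):
            raise ValueError("exposure vectors must have genome length")
        if self.start_h is None:
            self.start_h = np.zeros(L)
        if self.start_l is None:
            self.start_l = np.zeros(L)
        self.start_h = np.asarray(self.start_h, dtype=float)
        self.start_l = np.asarray(self.start_l, dtype=float)
        if self.cycle_time <= 0:
            raise ValueError("cycle_time must be positive")
        for v in (self.t_ss_h, self.t_ss_l):
            if (v < -1e-9).any():
                raise ValueError("exposure times must be nonnegative")
            if (v > self.cycle_time + 1e-9).any():
                raise ValueError("exposure times cannot exceed cycle_time")


def _sdm_geometry(genome: CircularGenome, config: ReplicationConfig):
    """Shared SDM/RITOLS fork geometry: displacement and coverage times.

    Displacement: position ``x`` at fork-path distance ``d`` is displaced at
    ``t1 = d / v_h``. OriL activates at ``t_act = D_OL / v_h + oril_delay``.
    L-strand synthesis then proceeds along the lagging path (distance ``e``
    from OriL). For ``e <= D_OL`` the path runs over positions displaced
    before activation, so arrival is the unconstrained ``t_act + e / v_l``.
    At ``e = D_OL`` the polymerase crosses OriH into the segment the fork
    reaches last (and displaces in reverse order along the lagging path).
    The first lattice site past OriH (``e = D_OL + 1``, fork distance
    ``L - 1``) is displaced only as the fork completes the circle, so a
    polymerase arriving earlier blocks there and the delay propagates over
    the rest of the path — and because displacement times fall while
    arrival times rise along the path, this is the only site where a block
    can occur. Coverage on that segment is
    ``max(t_act + e/v_l, (L-1)/v_h + (e - D_OL - 1)/v_l)``. Both candidates
    have the same slope in ``e``, so the profile stays piecewise linear
    with breakpoints only at the two origins.
    """
    L = genome.length
    x = np.arange(L)
    d = genome.fork_distance(x).astype(float)
    e = genome.lagging_distance(x).astype(float)
    d_ol = float(genome.ori_separation)

    t_disp = d / config.v_h
    t_act = d_ol / config.v_h + config.oril_delay
    unconstrained = t_act + e / config.v_l
    blocked = (L - 1) / config.v_h + (e - d_ol - 1) / config.v_l
    t_cov = np.where(e <= d_ol, unconstrained, np.maximum(unconstrained, blocked))
    return t_disp, t_cov


def sdm_exposure(genome: CircularGenome, config: ReplicationConfig) -> ExposureProfile:
    """Exposure profile under the strand-displacement mode.

    The parental H-strand at ``x`` is exposed from fork passage until the
    L-strand polymerase covers it; the parental L-strand is never displaced
    (``t_ss_l`` identically zero).
    """
    if config.mode is not Mode.SDM:
        raise ValueError(f"sdm_exposure requires an SDM config, got {config.mode}")
    t_disp, t_cov = _sdm_geometry(genome, config)
    t_ss_h = t_cov - t_disp
    zeros = np.zeros(genome.length)
    cycle = max(genome.length / config.v_h, float(t_cov.max()))
    return ExposureProfile(genome, t_ss_h, zeros, cycle,
                           start_h=t_disp, start_l=zeros, mode=Mode.SDM)


def sc_exposure(genome: CircularGenome, config: ReplicationConfig) -> ExposureProfile:
    """Exposure profile under the strand-coupled mode.

    The parental H-strand (lagging-strand template) at offset ``o`` within
    its Okazaki fragment of length ``k`` is exposed for ``(k - 1 - o)/v_l``
    (fragments tiled from the fork, the fragment's fork-proximal end
    covered last); the position-averaged exposure is ``(k-1)/(2 v_l)``.
    The parental L-strand (leading-strand template) is exposed only for the
    per-nucleotide fork-passage time ``1/v_h``. Both profiles are flat up
    to fragment-phase periodicity.
    """
    if config.mode is not Mode.SC:
        raise ValueError(f"sc_exposure requires an SC config, got {config.mode}")
    L = genome.length
    d = genome.fork_distance(np.arange(L)).astype(float)
    k = config.okazaki_length
    offset = d.astype(int) % k
    t_ss_h = (k - 1 - offset) / config.v_l
    t_ss_l = np.full(L, 1.0 / config.v_h)
    start = d / config.v_h
    cycle = max(
        L / config.v_h,
        float((start + t_ss_h).max()),
        float((start + t_ss_l).max()),
    )
    return ExposureProfile(genome, t_ss_h, t_ss_l, cycle,
                           start_h=start, start_l=start, mode=Mode.SC)


def ritols_exposure(genome: CircularGenome, config: ReplicationConfig) -> ExposureProfile:
    """mtSSB-available exposure under RITOLS: zero on both strands.

    The fork geometry is the same as SDM, but RNA covers the displaced
    strand, leaving no single-stranded DNA for mtSSB to bind. The cycle
    time is that of the SDM geometry.
    """
    if config.mode is not Mode.RITOLS:
        raise ValueError(f"ritols_exposure requires a RITOLS config, got {config.mode}")
    _, t_cov = _sdm_geometry(genome, config)
    zeros = np.zeros(genome.length)
    cycle = max(genome.length / config.v_h, float(t_cov.max()))
    return ExposureProfile(genome, zeros.copy(), zeros.copy(), cycle,
                           start_h=zeros.copy(), start_l=zeros.copy(), mode=Mode.RITOLS)


_DISPATCH = {Mode.SDM: sdm_exposure, Mode.SC: sc_exposure, Mode.RITOLS: ritols_exposure}


def exposure(genome: CircularGenome, config: ReplicationConfig) -> ExposureProfile:
    """Compute the exposure profile for ``config.mode``."""
    return _DISPATCH[Mode(config.mode)](genome, config)


# ---------------------------------------------------------------------------
# Rolling-circle lagging-strand products
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RollingCircleTemplate:
    """Geometry of the in vitro rolling-circle replication template.

    ``oril_offset`` is the distance from the OriL priming site to the fork
    start measured along the lagging-synthesis direction, and
    ``t_stretch_positions`` lists candidate poly-dT priming sites (same
    coordinate frame) that can fire when mtSSB coverage is incomplete.
    Defaults reproduce the published template: a 3,900 nt circle whose
    OriL-primed first-round product is about 2,100 nt.
    """

    circle_length: int = 3900
    oril_offset: int = 2100
    t_stretch_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.oril_offset <= self.circle_length:
            raise ValueError("oril_offset must lie in (0, circle_length]")
        for p in self.t_stretch_positions:
            if not 0 < p <= self.circle_length:
                raise ValueError(f"priming site {p} outside (0, circle_length]")
        object.__setattr__(
            self, "t_stretch_positions", tuple(self.t_stretch_positions)
        )


def rolling_circle_products(
    template: RollingCircleTemplate,
    mtssb_saturation: float,
    n_rounds: int,
    seed: int | np.random.Generator | None = 20141204,
) -> Counter:
    """Lagging-strand product lengths from rolling-circle replication.

    At full mtSSB saturation, primer synthesis is restricted to OriL: the
    first round yields a product of ``oril_offset`` nt and every later
    round spans the full circle (``circle_length`` nt). Below saturation,
    each non-OriL poly-dT site independently primes with probability
    ``1 - mtssb_saturation`` per round, fragmenting the products into the
    gaps between consecutive active priming sites.

    Returns a multiset of product lengths as ``collections.Counter``.
    """
    if not 0.0 <= mtssb_saturation <= 1.0:
        raise ValueError("mtssb_saturation must be in [0, 1]")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if mtssb_saturation < 1.0 and not template.t_stretch_positions:
        raise ValueError(
            "sub-saturating mtSSB requires candidate t_stretch_positions"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_fire = 1.0 - mtssb_saturation

    products: Counter = Counter()
    for rnd in range(n_rounds):
        active = {template.oril_offset}
        for site in template.t_stretch_positions:
            if site == template.oril_offset:
                continue
            if p_fire >= 1.0 or (p_fire > 0.0 and rng.random() < p_fire):
                active.add(site)
        sites = sorted(active)
        if rnd == 0:
            # First round: each primer extends back to the previous priming
            # site (or to the fork start for the most fork-proximal one).
            lengths = [sites[0]] + [b - a for a, b in zip(sites, sites[1:])]
        else:
            # Steady state: circular gaps between consecutive priming sites.
            lengths = [b - a for a, b in zip(sites, sites[1:])]
            lengths.append(template.circle_length - sites[-1] + sites[0])
        products.update(lengths)
    return products


# ---------------------------------------------------------------------------
# Primer-initiation propensity
# ---------------------------------------------------------------------------


def initiation_propensity(
    t_run_length: int, local_occupancy: float, n_sat: int = 6
) -> float:
    """Relative rate of POLRMT primer initiation at a poly-dT run.

    The mitochondrial RNA polymerase can prime from a template containing
    one or more dT; deleting the poly-dT run abolishes priming, and runs
    longer than ``n_sat`` (default 6, the longest run probed) saturate.
    Local mtSSB occupancy masks the template:

    ``rate = min(n, n_sat)/n_sat * (1 - local_occupancy)``.
    """
    if t_run_length < 0:
        raise ValueError("t_run_length must be >= 0")
    if not 0.0 <= local_occupancy <= 1.0:
        raise ValueError("local_occupancy must be in [0, 1]")
    if n_sat < 1:
        raise ValueError("n_sat must be >= 1")
    g = min(t_run_length, n_sat) / n_sat
    return g * (1.0 - local_occupancy)


# ---------------------------------------------------------------------------
# OriL stem-loop fold
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OriLStructure:
    """Result of the OriL hairpin scan.

    ``mtssb_accessible`` is True when the strongest stem is shorter than
    the discriminating threshold: a stable stem-loop excludes the
    tetramer, keeping the loop's poly-dT run available to the primase.
    """

    stem_length: int
    loop_sequence: str
    loop_t_run: int
    mtssb_accessible: bool
    position: int | None = None

    def __post_init__(self) -> None:
        if self.stem_length < 0:
            raise ValueError("stem_length must be >= 0")
        if self.loop_t_run > len(self.loop_sequence):
            raise ValueError("loop_t_run cannot exceed loop length")


def _longest_t_run(seq: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == "T" else 0
        best = max(best, run)
    return best


def oril_fold(
    sequence: str,
    min_stem: int = 5,
    loop_range: tuple[int, int] = (3, 14),
) -> OriLStructure:
    """Find the strongest hairpin (perfect inverted repeat) in an oligo.

    Scans for the longest perfectly Watson-Crick-complementary inverted
    repeat whose loop size lies within ``loop_range`` (inclusive); ties are
    broken by 5'-most position, then by smallest loop. No wobble pairs and
    no energy model: the biological question only needs a stem/no-stem
    discriminator, ``mtssb_accessible = stem_length < min_stem``.
    """
    seq = sequence.upper()
    if not seq or any(c not in "ACGT" for c in seq):
        raise ValueError("sequence must be nonempty and contain only A, C, G, T")
    lo, hi = loop_range
    if lo < 1 or hi < lo:
        raise ValueError("loop_range must satisfy 1 <= lo <= hi")
    if min_stem < 1:
        raise ValueError("min_stem must be >= 1")
    n = len(seq)
    if n < 2 * min_stem + lo:
        raise ValueError(
            f"sequence of length {n} too short for a stem of {min_stem} with loop >= {lo}"
        )

    max_stem = (n - lo) // 2
    for stem in range(max_stem, 0, -1):
        for i in range(0, n - 2 * stem - lo + 1):
            for loop in range(lo, hi + 1):
                j = i + stem + loop
                if j + stem > n:
                    break
                if seq[i:i + stem] == _revcomp(seq[j:j + stem]):
                    loop_seq = seq[i + stem:j]
                    return OriLStructure(
                        stem_length=stem,
                        loop_sequence=loop_seq,
                        loop_t_run=_longest_t_run(loop_seq),
                        mtssb_accessible=stem < min_stem,
                        position=i,
                    )
    return OriLStructure(
        stem_length=0,
        loop_sequence="",
        loop_t_run=0,
        mtssb_accessible=True,
        position=None,
    )
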