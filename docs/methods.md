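# Methods

## Coordinate frame and geometry

All positions are 0-based on a circle of length `L`, intervals half-open,
arithmetic modulo `L`. The `sequence` of a `CircularGenome` is the H-strand
read 5'→3' in ascending coordinates. The H-strand replication fork moves in
*descending* coordinates from `ori_h`; L-strand synthesis moves in
ascending coordinates from `ori_l`. This orientation is not arbitrary: it
is the only one under which the gene immediately downstream of the control
region (CYTB) is displaced first and the gene just ahead of OriL (COX1) is
covered first, i.e. the one that produces the observed H-strand occupancy
gradient. The default geometry is the standard human reference frame
(`L = 16,569`, `ori_h = 191`, `ori_l = 5,735`), under which the fork
reaches OriL after `D_OL/L = 11,025/16,569 = 66.5%` of H-strand synthesis —
the "two-thirds" geometry. A genome must have two distinct origins;
`ori_h == ori_l` is rejected rather than treated as origin-less.

## Strand-displacement exposure (SDM)

Let `d(x) = (ori_h − x) mod L` be fork-path distance, `e(x) = (x − ori_l)
mod L` lagging-path distance, and `D_OL = (ori_h − ori_l) mod L` (the two
are complementary: `d + e ≡ D_OL mod L`). With fork speed `v_h`, L-strand
speed `v_l`, and activation `t_act = D_OL/v_h + delay`:

* displacement: `t_disp(x) = d(x)/v_h`;
* coverage on the pre-OriH segment (`e ≤ D_OL`, template displaced before
  activation): `t_cov = t_act + e/v_l`;
* coverage beyond OriH (`e > D_OL`): `t_cov = max(t_act + e/v_l,
  (L−1)/v_h + (e − D_OL − 1)/v_l)`.

The second candidate is the *stall rule*. The lagging-path positions past
OriH are displaced by the fork in reverse path order, so the first lattice
site past OriH (fork distance `L−1`) is displaced last, as the fork
completes the circle. A continuous L-strand cannot skip ahead of its own
5'→3' growth, so an L-polymerase arriving there earlier blocks, and the
delay propagates over the rest of the path. Because arrival times rise and
displacement times fall along the path, that first site is the only
possible blocking point, which keeps the closed form a maximum of two
lines with the same slope — piecewise linear with breakpoints only at the
two origins. Exposure is `t_ss = t_cov − t_disp ≥ 0`; the parental
L-strand is never displaced (`t_ss_l ≡ 0`).

A deliberately naive discrete-time simulator (`mtssb.stepper`) advances
the fork and the L-polymerase on a time grid with the blocking rule
enforced mechanically, and serves as the independent cross-check: the
closed form agrees within one time step on random genomes
(property-tested, and re-measured by the acceptance script). One
consequence of blocking worth noting: the post-OriL peak height *relative*
to the pre-OriL maximum decreases with `v_l/v_h` only until the block
dominates, after which it is exactly `(e − D_OL − 1)/D_OL`, independent of
`v_l`.

`ExposureProfile` also carries the window-start times, so that a molecule
at replication phase `τ` has position `x` single-stranded iff
`start[x] ≤ τ < start[x] + t_ss[x]` — this is what the population
simulator samples.

## Strand-coupled and RITOLS exposure

Under SC, the parental H-strand is the lagging-strand template of a
conventional fork: within an Okazaki fragment of length `k` (tiled from
the fork), the position at offset `o` is exposed for `(k − 1 − o)/v_l`
(the fragment's last-synthesized nucleotide is covered immediately), so
the fragment-averaged exposure is `(k−1)/(2 v_l)` and the binned profile
is flat up to fragment phase. The parental L-strand (leading template) is
exposed only for the per-nucleotide fork-passage time `1/v_h`. The two
strands therefore carry small but *unequal* flat exposures; this residual
asymmetry is what keeps the SC prediction distinguishable from the
RITOLS one after normalization. Under RITOLS the fork geometry is SDM's,
but RNA occupies the displaced strand, so the mtSSB-available exposure is
identically zero on both strands.

## Occupancy model and its assumptions

Expected occupancy is linear in exposure:
`occ(x) = replicating_fraction · t_ss(x)/cycle_time`, the probability that
a uniformly phased replicating molecule has `x` single-stranded. No
binding kinetics or saturation are modeled — the analysis argues orderings
and gradients, not absolute affinities. The total expected number of bound
tetramers `Σocc/footprint` (footprint 59 nt) is capped at the available
tetramer count by uniform rescaling, preserving profile shape. The
replicating fraction of molecules is not constrained by any measurement we
model, so it is an explicit free parameter (default 0.2 in the synthetic
spec, a plausible value for cycling cultured cells); it cancels in all
normalized comparisons.

OriH initiation is treated as a single site; distributed initiation across
the D-loop would smear the profile near the control region, which is
excluded from comparison anyway (see binning). This is a known limitation,
as is the instantaneous OriL activation default (`oril_delay = 0`; primer
synthesis and polymerase hand-off take finite time and the delay is
exposed as a parameter, not modeled kinetically).

## Binning and model comparison

Profiles are averaged over eight gene bins (RNR2, ND1, ND2, COX1, COX3,
ND4, ND5, CYTB in standard reference coordinates) on each strand — 16
values, region-major, H before L. The control region is deliberately not a
bin: mtSSB binds both strands there for reasons outside the replication
models (7S DNA/D-loop turnover), so it carries no discriminating signal.

Observed and predicted bin vectors are normalized to unit sum *jointly*
over strands, making strand asymmetry part of the fit (this is what
separates the H-only SDM gradient from symmetric alternatives). Candidate
modes are ranked by residual sum of squares; Pearson r is reported but not
used for selection, because the RITOLS prediction is constant and
correlation against a constant vector is undefined (reported as 0 by
convention). Ties break by fixed mode order SDM < SC < RITOLS, independent
of candidate order.

Predictions mix the mode-specific normalized profile with a uniform
nonspecific-pulldown floor on both strands, weight
`nonspecific_fraction = 0.15` by default; the RITOLS prediction is the
floor alone ("background-only"). The same floor parameter drives the read
generator, for two reasons: real ChIP data shows background-level signal
on the unbound strand rather than zero (with the SDM profile, a 0.15 floor
leaves ≈7.5% of mapped reads on the L-strand, matching the observed
background level), and a strictly zero RITOLS prediction could never win
an RSS comparison against any prediction positively correlated with noisy
data — the floor is what makes the background-only model falsifiable and
recoverable.

## Read mapping

Mapping is literal perfect-match search, the filter the emulated
experiment applied: a read maps to strand H if its sequence occurs exactly
in the H-strand extended circularly by read-length − 1 nt, to strand L if
its reverse complement does. Multi-position or dual-strand hits are
discarded as ambiguous (counted separately — the conservative choice for
multi-mappers), reads containing N are unmapped, and no mismatches,
qualities or indels are considered. Implementation is a hash of all
circular read-length windows, checked against a brute-force doubled-string
scan by property test. Positions always refer to the H-strand footprint
start, and "H-strand read" means a fragment *of* the H-strand — the strand
mtSSB binds. Default read length is 36 nt; fragment-length distributions
are not modeled.

## Stoichiometry

The calibration line `intensity = a·amount + b` is ordinary least squares
through known amounts of recombinant protein, not forced through the
origin. Band intensities are interpolated (extrapolation beyond the
standards is flagged with a warning, not fatal), converted to molecules
via Avogadro's number and the 16 kDa monomer mass (taken as given, not
computed from sequence), and divided by cells loaded. The mtSSB:mtDNA
ratio propagates uncertainty to first order assuming independence:
`sd = mean·√((sd₁/m₁)² + (sd₂/m₂)²)` — with the measured per-cell values
(1.08 ± 0.45)e7 and (5.07 ± 0.06)e3 this gives 2.13e3 ± 0.89e3, matching
the published ratio within rounding of its printed inputs, which is the
evidence this propagation is the right reading. Tetramers per genome are
`floor(ratio/4)`; coat capacity is tetramers × 59 nt.

qPCR quantification fits `log2(quantity)` vs Cq by least squares on input
dilutions (slope free, so the fitted efficiency need not be 100% even
though the simulator's default is), interpolates IP and IgG, and reports
`IP/input − IgG/input`. A non-decreasing curve (slope ≥ 0) is flagged.

## Synthetic data: what it does and does not emulate

Generators are pure functions of `(spec, seed)` (independent numpy
`SeedSequence` streams per generator; identical spec + seed gives
byte-identical FASTQ). The population simulator draws one uniform
replication phase per replicating molecule and counts window membership —
it converges to the analytic expectation and is tested against it. Read
start positions are drawn proportional to occupancy; the nuclear
background is *not* aligned but represented as random-sequence reads
rejection-checked to be unmappable, so the mapped fraction has an exact
binomial truth. Base composition is uniform by default, with an optional
G+T bias for H-strand realism (affects sequence only, never occupancy).

Not modeled: sequencing errors, PCR duplicates, fragment-size
distributions, mappability structure of a real nuclear genome, chimeric
reads, and any saturation of occupancy with exposure. Passing tests
therefore demonstrate correctness of the analysis chain under its own
assumptions — that the mode-selection statistic recovers the generating
mode at realistic depth and background — not robustness to artifacts real
libraries contain.

## Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| `v_h` | 1.0 | nt/time | sets the time unit (fork travel) |
| `v_l` | 2.0 | nt/time | L-synthesis needs no helicase on an ssDNA template; faster than the (slow) fork. The ratio is tunable; 2 reproduces the secondary ND2 peak qualitatively |
| `okazaki_length` | 100 | nt | SC mode fragment length |
| `oril_delay` | 0 | time | instantaneous origin activation |
| `footprint` | 59 | nt/tetramer | measured tetramer binding-site size |
| `monomer mass` | 16 | kDa | mtSSB subunit mass |
| `replicating_fraction` | 0.2 | — | free parameter (see above) |
| `n_reads` / `read_length` | 50,000 / 36 | — | desk-scale depth at which mode recovery is reliable |
| `background_fraction` | 0.2 | — | mapped-fraction truth for the synthetic mixture |
| `nonspecific_fraction` | 0.15 | — | background-level signal on the unbound strand (≈7.5% L-strand reads under SDM) |
| `min_stem` / `loop_range` | 5 / (3, 14) | bp / nt | stem/no-stem discriminator for OriL folds |
| `n_sat` | 6 | dT | longest poly-dT run probed; propensity saturates there |
| `seed` | 20141204 | — | reproducible documentation |

## Numerical choices

The hairpin scan uses perfect Watson–Crick complementarity only (no
wobble, no energy model): the biological question needs a stem/no-stem
discriminator, and ties are broken by longer stem, then 5'-most position,
then smallest loop. The rolling-circle simulator fires each non-OriL
poly-dT site independently with probability `1 − saturation` per round;
first-round products run from each primer back to the previous priming
site (or the fork start), later rounds are circular gaps. Degenerate
inputs fail fast with `ValueError`; zero mapped reads yield flagged-null
strand fractions rather than exceptions, and the CLI reports them with
exit code 0 (an empty result is a result). Problem sizes in the test and
acceptance runs (genomes ≤ 2 kb for stepper comparisons, 100 runs per mode
at 50,000 reads) were chosen as the smallest at which the statistical
checks are stable.
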