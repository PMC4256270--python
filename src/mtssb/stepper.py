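"""Brute-force discrete-time reference simulator for SDM exposure.

This is a deliberately simple, mechanism-level simulation of one
strand-displacement replication cycle, used as an independent cross-check
of the closed-form profile in :mod:`mtssb.replication`. It advances two
machines on a time grid:

* the H-strand fork, which displaces parental H-strand positions in
  descending coordinate order at speed ``v_h``;
* the L-strand polymerase, which starts at OriL once the fork has passed
  it (plus ``oril_delay``) and covers the displaced strand in ascending
  coordinate order at speed ``v_l`` — but can never advance past a
  position whose parental H-strand is still in the duplex ahead of the
  fork (the stall rule).

Positions are tracked as continuous path lengths; crossing times of
integer positions are linearly interpolated within a step, so the only
discretization error (at most one time step) occurs in the step where a
stall releases.
"""

from __future__ import annotations

import numpy as np

from .genome import CircularGenome
from .replication import Mode, ReplicationConfig

__all__ = ["stepped_sdm_exposure"]


def stepped_sdm_exposure(
    genome: CircularGenome, config: ReplicationConfig, dt: float = 0.25
):
    """Simulate SDM exposure on a time grid.

    Returns ``(t_ss_h, t_disp, t_cov)`` arrays of genome length: the
    single-stranded time of each parental H-strand position and the
    underlying displacement/coverage crossing times.
    """
    if Mode(config.mode) is not Mode.SDM:
        raise ValueError("stepper models SDM only")
    if dt <= 0:
        raise ValueError("dt must be positive")
    L = genome.length
    d_ol = genome.ori_separation
    v_h, v_l = config.v_h, config.v_l
    t_act = d_ol / v_h + config.oril_delay

    # Displacement time of lagging-path coordinate e (position ori_l + e):
    # the fork reaches it at path distance D_OL - e (before OriL) or
    # D_OL + L - e (after wrapping past OriH).
    e_grid = np.arange(L)
    d_of_e = np.where(e_grid <= d_ol, d_ol - e_grid, d_ol + L - e_grid).astype(float)
    t_disp_e = d_of_e / v_h

    t_cov_e = np.full(L, np.nan)
    covered = 0.0  # continuous L-path length covered so far
    next_idx = 0  # first integer e not yet recorded
    t = 0.0
    # Safely past any possible completion time.
    t_max = t_act + L / v_l + L / v_h + 10 * dt
    while next_idx < L and t < t_max:
        t_next = t + dt
        if t_next > t_act:
            adv_start = max(t, t_act)
            new_covered = covered + v_l * (t_next - adv_start)
            # Stall rule: cannot pass an undisplaced position. Walk the
            # integer positions we are about to cross and clamp at the
            # first one the fork has not yet displaced.
            limit = new_covered
            e = next_idx
            while e < limit and e < L:
                if t_disp_e[e] > t_next:
                    limit = float(e)
                    break
                e += 1
            new_covered = min(new_covered, limit)
            # Record crossing times for newly covered integer positions.
            while next_idx < new_covered and next_idx < L:
                t_cov_e[next_idx] = adv_start + (next_idx - covered) / v_l
                next_idx += 1
            covered = new_covered
        t = t_next

    if np.isnan(t_cov_e).any():
        raise RuntimeError("stepper failed to complete the cycle")

    # Map back from lagging-path coordinates to genome coordinates.
    x = (genome.ori_l + e_grid) % L
    t_cov = np.empty(L)
    t_disp = np.empty(L)
    t_cov[x] = t_cov_e
    t_disp[x] = t_disp_e
    return t_cov - t_disp, t_disp, t_cov
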