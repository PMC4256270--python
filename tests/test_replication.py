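"""Exposure models, rolling-circle products, initiation propensity, OriL fold."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtssb.genome import CircularGenome, DEFAULT_REGIONS, rcrs_geometry
from mtssb.occupancy import bin_profile, exposure_to_occupancy
from mtssb.replication import (
    Mode,
    OriLStructure,
    ReplicationConfig,
    RollingCircleTemplate,
    initiation_propensity,
    oril_fold,
    ritols_exposure,
    rolling_circle_products,
    sc_exposure,
    sdm_exposure,
)
from mtssb.stepper import stepped_sdm_exposure


def sdm(v_h=1.0, v_l=2.0, delay=0.0):
    return ReplicationConfig(mode=Mode.SDM, v_h=v_h, v_l=v_l, oril_delay=delay)


class TestSdmExposure:
    def test_first_l_covered_position_has_zero_exposure(self, toy_genome):
        # OriL itself is displaced and immediately covered: no exposure.
        prof = sdm_exposure(toy_genome, sdm(v_h=1, v_l=1))
        assert prof.t_ss_h[toy_genome.ori_l] == pytest.approx(0.0)

    def test_infinite_lagging_speed(self, toy_genome):
        # With instant L-synthesis, OriH stays exposed exactly until OriL
        # activates; positions displaced after activation wait only for the
        # fork to release the blocked polymerase.
        g = toy_genome
        prof = sdm_exposure(g, sdm(v_h=1, v_l=1e12))
        assert prof.t_ss_h[g.ori_h] == pytest.approx(50.0, abs=1e-6)
        d = g.fork_distance(np.arange(g.length))
        post = d > g.ori_separation
        # Sequential synthesis blocks at the first site past OriH until the
        # fork displaces it at (L-1)/v_h; stepper-verified below.
        np.testing.assert_allclose(
            prof.t_ss_h[post], (g.length - 1) - d[post], atol=1e-6
        )
        t_ss_stepped, _, _ = stepped_sdm_exposure(g, sdm(v_h=1, v_l=1e12), dt=0.25)
        np.testing.assert_allclose(prof.t_ss_h, t_ss_stepped, atol=0.5)

    def test_closed_form_matches_stepper_reference(self):
        # Independent discrete-time simulation, 1 kb genome, OriL two-thirds
        # around, sampled positions agree within one time step.
        g = CircularGenome(length=1000, ori_h=0, ori_l=(0 - 667) % 1000)
        cfg = sdm(v_h=1, v_l=2)
        dt = 0.25
        closed = sdm_exposure(g, cfg).t_ss_h
        stepped, _, _ = stepped_sdm_exposure(g, cfg, dt=dt)
        sampled = np.linspace(0, 999, 20, dtype=int)
        assert np.abs(closed[sampled] - stepped[sampled]).max() <= dt + 1e-9

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.data())
    def test_closed_form_matches_stepper_random_genomes(self, data):
        L = data.draw(st.integers(10, 500))
        ori_h = data.draw(st.integers(0, L - 1))
        ori_l = (ori_h + data.draw(st.integers(1, L - 1))) % L
        v_h = data.draw(st.floats(0.5, 3.0))
        v_l = data.draw(st.floats(0.5, 4.0))
        delay = data.draw(st.floats(0.0, 5.0))
        g = CircularGenome(length=L, ori_h=ori_h, ori_l=ori_l)
        cfg = sdm(v_h=v_h, v_l=v_l, delay=delay)
        dt = 0.1
        closed = sdm_exposure(g, cfg).t_ss_h
        stepped, _, _ = stepped_sdm_exposure(g, cfg, dt=dt)
        assert np.abs(closed - stepped).max() <= dt + 1e-9

    def test_parental_l_strand_never_exposed(self, rcrs_genome):
        prof = sdm_exposure(rcrs_genome, sdm())
        assert not prof.t_ss_l.any()
        assert (prof.t_ss_h >= 0).all()
        assert (prof.t_ss_h <= prof.cycle_time + 1e-9).all()

    def test_piecewise_linear_with_breakpoints_only_at_origins(self, rcrs_genome):
        g = rcrs_genome
        prof = sdm_exposure(g, sdm())
        e = g.lagging_distance(np.arange(g.length))
        order = np.argsort(e)
        t = prof.t_ss_h[order]
        curvature = np.abs(np.diff(t, 2))
        kinks = set(np.nonzero(curvature > 1e-9)[0] + 1)
        boundary = {int(np.where(e[order] == g.ori_separation)[0][0])}
        assert kinks <= {b + d for b in boundary for d in (-1, 0, 1)}

    def test_maximum_exposure_adjacent_to_ori_h(self, rcrs_genome):
        # The D-loop-proximal side (CYTB direction) is displaced first and
        # covered last, for any v_l >= v_h.
        g = rcrs_genome
        for v_l in (1.0, 2.0, 4.0):
            t = sdm_exposure(g, sdm(v_l=v_l)).t_ss_h
            assert t.argmax() == g.ori_h
            # strictly decreasing walking away from OriH against fork travel
            seg = t[[g.ori_h, g.ori_h - 1, g.ori_h - 2, g.ori_h - 50]]
            assert np.all(np.diff(seg) < 0)

    def test_post_oril_peak_shrinks_as_lagging_speed_grows(self, rcrs_genome):
        g = rcrs_genome
        nd2 = next(r for r in DEFAULT_REGIONS if r.name == "ND2")
        rel = []
        for v_l in (1.0, 1.5, 2.0, 4.0):
            t = sdm_exposure(g, sdm(v_l=v_l)).t_ss_h
            rel.append(t[nd2.start:nd2.end].mean() / t.max())
        # Weakly decreasing: once the polymerase block at OriH dominates the
        # coverage time, the relative peak height plateaus.
        assert np.all(np.diff(rel) <= 1e-12)
        assert rel[-1] < rel[0]

    def test_gene_bin_ordering_matches_observed_gradient(self, rcrs_genome):
        # CYTB max / COX1 min among coding bins, with the secondary peak just
        # after OriL: ND2 > ND1 > RNR2.
        for v_l in (1.5, 2.0, 4.0):
            prof = sdm_exposure(rcrs_genome, sdm(v_l=v_l))
            occ = exposure_to_occupancy(prof, n_tetramers=np.inf)
            bins = bin_profile(occ, DEFAULT_REGIONS)
            h = bins[bins.strand == "H"].set_index("region")["mean_occupancy"]
            coding = h.drop("RNR2")
            assert coding.idxmax() == "CYTB"
            assert coding.idxmin() == "COX1"
            assert h["ND2"] > h["ND1"] > h["RNR2"]

    def test_rejects_wrong_mode_and_degenerate_genome(self, toy_genome):
        with pytest.raises(ValueError):
            sdm_exposure(toy_genome, ReplicationConfig(mode=Mode.SC))
        with pytest.raises(ValueError):
            CircularGenome(length=1, ori_h=0, ori_l=0)


class TestScExposure:
    def test_single_nucleotide_fragments_leave_no_exposure(self, toy_genome):
        cfg = ReplicationConfig(mode=Mode.SC, okazaki_length=1)
        prof = sc_exposure(toy_genome, cfg)
        np.testing.assert_allclose(prof.t_ss_h, 0.0)

    def test_fragment_mean_exposure_matches_direct_summation(self, rcrs_genome):
        k, v_l = 100, 1.0
        cfg = ReplicationConfig(mode=Mode.SC, okazaki_length=k, v_l=v_l)
        prof = sc_exposure(rcrs_genome, cfg)
        # Oracle: average the per-offset exposure of one fragment directly.
        oracle = sum((k - 1 - o) / v_l for o in range(k)) / k
        assert oracle == pytest.approx(49.5)
        one_fragment = prof.t_ss_h[1000:1000 + k]
        assert one_fragment.mean() == pytest.approx(oracle, rel=1e-3)

    def test_bin_averaged_profile_is_flat(self, rcrs_genome):
        cfg = ReplicationConfig(mode=Mode.SC, okazaki_length=100)
        prof = sc_exposure(rcrs_genome, cfg)
        L = rcrs_genome.length
        edges = np.linspace(0, L, 9, dtype=int)
        means = np.array([
            prof.t_ss_h[a:b].mean() for a, b in zip(edges, edges[1:])
        ])
        assert means.std() / means.mean() < 0.02

    def test_leading_strand_exposure_is_fork_passage_time(self, toy_genome):
        cfg = ReplicationConfig(mode=Mode.SC, v_h=2.0)
        prof = sc_exposure(toy_genome, cfg)
        np.testing.assert_allclose(prof.t_ss_l, 0.5)

    def test_rejects_wrong_mode(self, toy_genome):
        with pytest.raises(ValueError):
            sc_exposure(toy_genome, sdm())


class TestRitolsExposure:
    def test_no_mtssb_available_exposure_anywhere(self, rcrs_genome):
        cfg = ReplicationConfig(mode=Mode.RITOLS)
        prof = ritols_exposure(rcrs_genome, cfg)
        assert not prof.t_ss_h.any() and not prof.t_ss_l.any()
        assert prof.cycle_time > 0

    def test_rejects_wrong_mode(self, toy_genome):
        with pytest.raises(ValueError):
            ritols_exposure(toy_genome, sdm())


class TestRollingCircle:
    def test_saturating_mtssb_restricts_products_to_oril(self):
        tpl = RollingCircleTemplate(t_stretch_positions=(500, 1200, 3000))
        products = rolling_circle_products(tpl, mtssb_saturation=1.0, n_rounds=5)
        assert products == {2100: 1, 3900: 4}

    def test_single_round_yields_oril_offset(self):
        tpl = RollingCircleTemplate()
        assert rolling_circle_products(tpl, 1.0, n_rounds=1) == {2100: 1}

    def test_two_distinct_lengths_at_saturation(self):
        tpl = RollingCircleTemplate(circle_length=500, oril_offset=123)
        products = rolling_circle_products(tpl, 1.0, n_rounds=4)
        assert set(products) == {123, 500}

    def test_unsaturated_products_are_priming_site_gaps(self):
        sites = (500, 1200, 3000)
        tpl = RollingCircleTemplate(t_stretch_positions=sites)
        products = rolling_circle_products(tpl, mtssb_saturation=0.0, n_rounds=2)
        # Brute-force oracle: every site fires; first round gaps from the
        # fork start, steady state circular gaps.
        active = sorted(set(sites) | {2100})
        first = [active[0]] + [b - a for a, b in zip(active, active[1:])]
        steady = [b - a for a, b in zip(active, active[1:])]
        steady.append(3900 - active[-1] + active[0])
        expected: dict[int, int] = {}
        for length in first + steady:
            expected[length] = expected.get(length, 0) + 1
        assert dict(products) == expected

    def test_subsaturating_without_sites_rejected(self):
        with pytest.raises(ValueError):
            rolling_circle_products(RollingCircleTemplate(), 0.5, 2)

    def test_seed_determinism(self):
        tpl = RollingCircleTemplate(t_stretch_positions=(700, 2900))
        a = rolling_circle_products(tpl, 0.5, 10, seed=3)
        b = rolling_circle_products(tpl, 0.5, 10, seed=3)
        assert a == b


class TestInitiationPropensity:
    def test_no_poly_dt_run_means_no_priming(self):
        assert initiation_propensity(0, 0.0) == 0.0

    def test_full_occupancy_masks_any_run(self):
        assert initiation_propensity(10, 1.0) == 0.0

    @pytest.mark.parametrize("occ", [0.0, 0.3, 0.9])
    def test_rate_nondecreasing_in_run_length(self, occ):
        rates = [initiation_propensity(n, occ) for n in range(12)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[1] > 0 or occ == 1.0

    def test_saturates_at_six_dt(self):
        assert initiation_propensity(6, 0.0) == initiation_propensity(9, 0.0) == 1.0

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            initiation_propensity(-1, 0.0)
        with pytest.raises(ValueError):
            initiation_propensity(3, 1.5)


def brute_force_hairpin(seq: str, loop_range):
    """Exhaustive inverted-repeat enumeration (test oracle)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = lambda s: "".join(comp[c] for c in reversed(s))
    best = (0, None, "")
    n = len(seq)
    for stem in range(1, n // 2 + 1):
        for i in range(n):
            for loop in range(loop_range[0], loop_range[1] + 1):
                j = i + stem + loop
                if j + stem > n:
                    break
                if seq[i:i + stem] == rc(seq[j:j + stem]) and stem > best[0]:
                    best = (stem, i, seq[i + stem:j])
    return best


class TestOriLFold:
    def test_unstructured_oligo_is_accessible(self):
        res = oril_fold("A" * 60)
        assert res.stem_length == 0
        assert res.mtssb_accessible

    def test_constructed_hairpin_matches_exhaustive_enumeration(self):
        flank5, flank3 = "ACACACACAC", "ACACACACAC"
        seq = flank5 + "GGGGCC" + "TTTTTTT" + "GGCCCC" + flank3
        res = oril_fold(seq)
        assert (res.stem_length, res.loop_t_run) == (6, 7)
        assert res.loop_sequence == "TTTTTTT"
        oracle_stem, _, oracle_loop = brute_force_hairpin(seq, (3, 14))
        assert res.stem_length == oracle_stem
        assert res.loop_sequence == oracle_loop

    def test_stem_extension_excludes_mtssb(self):
        # Qualitative contract: a no-stem derivative stays accessible, a
        # 6 bp stem extension is not, with the threshold between the two.
        loop = "CTTTTTTAG"
        wt_stem5, wt_stem3 = "GGAGCC", "GGCTCC"
        plus6_5, plus6_3 = "TACGTA" + wt_stem5, wt_stem3 + "TACGTA"
        flank = "ACACACAC"
        no_stem = oril_fold(flank + "CAACCA" + loop + "CAACCA" + flank, min_stem=8)
        plus6 = oril_fold(flank + plus6_5 + loop + plus6_3 + flank, min_stem=8)
        assert no_stem.mtssb_accessible
        assert not plus6.mtssb_accessible
        assert plus6.stem_length >= 12

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            oril_fold("ACGTACGTNNACGTACGTACGT")

    def test_loop_t_run_invariant(self):
        with pytest.raises(ValueError):
            OriLStructure(stem_length=2, loop_sequence="AT", loop_t_run=5,
                          mtssb_accessible=True)
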