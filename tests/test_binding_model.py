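import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfantenna.binding_model import (
    EnergyModelParams,
    PWMMatrix,
    batch_kd,
    electrostatic_energy,
    landscape,
    occupancy,
    pwm_site_energy,
    segment_kd_profile,
    specific_energy,
)
from tfantenna.sequence_io import SequenceError, SequenceRecord, reverse_complement

dna = st.text(alphabet="ACGT", min_size=6, max_size=120)


class TestElectrostatics:
    def test_central_six_contacts_at_zero_ionic(self, params):
        assert electrostatic_energy(params, True) == pytest.approx(6 * -8.18)

    def test_end_site_loses_one_contact(self, params):
        assert electrostatic_energy(params, False) == pytest.approx(5 * -8.18)

    def test_screened_out_at_high_ionic_strength(self, params):
        strong = params.with_(ionic_strength=1e4)
        assert electrostatic_energy(strong, True) == pytest.approx(0.0, abs=1e-30)

    def test_extended_contact_mode(self):
        p = EnergyModelParams(elec_contacts="extended")
        assert electrostatic_energy(p, True) == pytest.approx(8 * -8.18)
        assert electrostatic_energy(p, False) == pytest.approx(7 * -8.18)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            EnergyModelParams(ionic_strength=-0.1)


class TestSpecificEnergy:
    @pytest.mark.parametrize(
        "hexamer,n_core,n_deg,coop",
        [
            ("TAATTA", 4, 2, 2.0),  # full consensus
            ("TGACAT", 1, 3, 0.0),  # degenerate site
            ("GCGCGC", 0, 0, 0.0),  # no A/T, no consensus match
            ("TAATTG", 4, 1, 0.5),  # first five consensus bases only
            ("GAATTA", 4, 1, 0.5),  # last five consensus bases only
        ],
    )
    def test_decomposition(self, params, hexamer, n_core, n_deg, coop):
        dg, core, deg, cp = specific_energy(hexamer, params)
        assert (core, deg, cp) == (n_core, n_deg, coop)

    def test_consensus_numeric_value(self, params):
        dg, *_ = specific_energy("TAATTA", params)
        assert dg == pytest.approx(4 * -3.53 + 2 * -1.75 + 2 * -3.91)

    def test_wrong_length_rejected(self, params):
        with pytest.raises(SequenceError):
            specific_energy("TAATT", params)


class TestPWMEnergy:
    def test_uniform_pwm_scores_zero(self, params):
        pwm = PWMMatrix.uniform()
        for hexamer in ("TAATTA", "GGGGGG", "ACGTAC"):
            assert pwm_site_energy(hexamer, pwm, params) == pytest.approx(0.0)

    def test_single_enriched_position(self, params):
        probs = np.full((6, 4), 0.25)
        probs[0] = [0.5, 1 / 6, 1 / 6, 1 / 6]
        pwm = PWMMatrix(probs, pseudo_count=0.0)
        rt = params.rt
        assert pwm_site_energy("AAAAAA", pwm, params) == pytest.approx(
            -rt * math.log(2.0)
        )
        assert -rt * math.log(2.0) == pytest.approx(-1.711, abs=2e-3)

    def test_matrix_from_file(self, tmp_path, params):
        path = tmp_path / "pwm.tab"
        path.write_text(
            "A\t1 1 1 1 1 1\nC\t1 1 1 1 1 1\nG\t1 1 1 1 1 1\nT\t1 1 1 1 1 1\n"
        )
        pwm = PWMMatrix.from_file(path)
        assert pwm_site_energy("ACGTAC", pwm, params) == pytest.approx(0.0, abs=1e-9)


class TestLandscape:
    def test_site_count(self, params):
        rec = SequenceRecord("r", "A" * 75)
        assert landscape(rec, params).n_sites == 2 * (75 - 5)

    def test_too_short_rejected(self, params):
        with pytest.raises(SequenceError):
            landscape(SequenceRecord("s", "ACGTA"), params)

    def test_zeroed_energies_closed_form(self, zeroed_params):
        # with all dG = 0 every weight is 1, so K_D = 1 / (n_sites * w0)
        rec = SequenceRecord("z", "ACGTAC")  # N=6 -> 2 sites
        scape = landscape(rec, zeroed_params)
        assert scape.kd == pytest.approx(1.0 / (2 * 5e-4))
        assert scape.kd == pytest.approx(1000.0)

    @given(dna)
    @settings(deadline=None, max_examples=30)
    def test_reverse_complement_invariance(self, seq):
        params = EnergyModelParams()
        fwd = landscape(SequenceRecord("f", seq), params)
        rev = landscape(SequenceRecord("r", reverse_complement(seq)), params)
        assert fwd.kd == pytest.approx(rev.kd, rel=1e-12)
        assert sorted(s.dg_binding for s in fwd.sites) == pytest.approx(
            sorted(s.dg_binding for s in rev.sites)
        )

    def test_palindromic_consensus_strand_symmetry(self, params):
        # a central full-consensus window has equal energies on both strands
        seq = "G" * 30 + "TAATTA" + "G" * 30
        scape = landscape(SequenceRecord("p", seq), params)
        hits = [s for s in scape.sites if s.hexamer == "TAATTA"]
        assert len(hits) == 2
        assert {h.strand for h in hits} == {"+", "-"}
        assert hits[0].dg_binding == pytest.approx(hits[1].dg_binding)

    def test_appending_bases_never_raises_kd(self, params):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 40))
        kd_prev = landscape(SequenceRecord("a", seq), params).kd
        for extra in ("A", "TAATTA", "GGGG"):
            seq = seq + extra
            kd_next = landscape(SequenceRecord("a", seq), params).kd
            assert kd_next <= kd_prev * (1 + 1e-12)
            kd_prev = kd_next

    def test_w0_scale_covariance(self, params):
        rec = SequenceRecord("w", "ACGTACGTACGTACGT")
        kd1 = landscape(rec, params).kd
        kd2 = landscape(rec, params.with_(w0=params.w0 * 10)).kd
        assert kd2 == pytest.approx(kd1 / 10, rel=1e-12)

    def test_toward_consensus_never_raises_site_energy(self, params):
        # replace base 3 of a degenerate site with its consensus base
        before, *_ = specific_energy("TACTTA", params)
        after, *_ = specific_energy("TAATTA", params)
        assert after <= before


def brute_force_landscape(seq: str, params: EnergyModelParams):
    """Naive per-window re-computation: no vectorization, no caching."""
    n = len(seq)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rc = "".join(comp[b] for b in reversed(seq))
    energies = []
    cons = params.consensus
    for strand_seq in (seq, rc):
        for i in range(n - 5):
            hexamer = strand_seq[i : i + 6]
            x1 = i + 1  # 1-based first base on this strand
            central = params.end_margin < x1 < n - params.end_margin
            n_contacts = params.n_elec_central - (0 if central else 1)
            e = n_contacts * params.dg_elec0 * math.exp(
                -math.sqrt(params.ionic_strength)
            )
            for k in range(6):
                b = hexamer[k]
                if 1 <= k <= 4 and b == cons[k]:
                    e += params.dg_consensus_core
                elif b in "AT":
                    e += params.dg_degenerate_at
            d15 = hexamer[:5] == cons[:5]
            d26 = hexamer[1:] == cons[1:]
            d16 = hexamer == cons
            e += (int(d16) + (int(d15) + int(d26)) / 2) * params.dg_cp
            energies.append(e)
    s = sum(math.exp(-e / (params.rt)) for e in energies)
    return sorted(energies), 1.0 / (params.w0 * s)


def test_brute_force_oracle_small(params):
    rng = np.random.default_rng(11)
    for _ in range(10):
        n = int(rng.integers(6, 200))
        seq = "".join(rng.choice(list("ACGT"), n))
        scape = landscape(SequenceRecord("b", seq), params)
        oracle_energies, oracle_kd = brute_force_landscape(seq, params)
        assert sorted(s.dg_binding for s in scape.sites) == pytest.approx(
            oracle_energies
        )
        assert scape.kd == pytest.approx(oracle_kd, rel=1e-12)


class TestOccupancy:
    def test_half_bound_at_kd(self, params):
        scape = landscape(SequenceRecord("o", "ACGT" * 10), params)
        occ = occupancy(scape, scape.kd)
        assert occ.p_bound == pytest.approx(0.5, rel=1e-12)
        assert occ.p_free == pytest.approx(0.5, rel=1e-12)

    def test_normalization(self, params):
        rng = np.random.default_rng(3)
        for conc in (1e-12, 1e-9, 1e-3):
            seq = "".join(rng.choice(list("ACGT"), 80))
            occ = occupancy(landscape(SequenceRecord("n", seq), params), conc)
            assert occ.p_free + occ.p_site.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dilute_limit_all_free(self, params):
        scape = landscape(SequenceRecord("d", "GCGCGCGCGC"), params)
        occ = occupancy(scape, 1e-30)
        assert occ.p_free == pytest.approx(1.0)

    def test_nonpositive_concentration_rejected(self, params):
        scape = landscape(SequenceRecord("e", "ACGTACGT"), params)
        with pytest.raises(ValueError):
            occupancy(scape, 0.0)


class TestSegmentProfile:
    def test_two_segments(self, params):
        rec = SequenceRecord("s", "ACGT" * 38)  # 152 bp -> 75 + 75 + 2(skipped)
        table = segment_kd_profile(rec, params, window=75)
        assert len(table) == 2
        assert not table["partial"].any()

    def test_single_segment_equals_landscape(self, params):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 75))
        rec = SequenceRecord("one", seq)
        table = segment_kd_profile(rec, params, window=75)
        assert len(table) == 1
        assert table["kd_M"].iloc[0] == pytest.approx(landscape(rec, params).kd)

    def test_implanted_consensus_lowers_segment_kd(self, params):
        base = "GCGT" * 38  # slightly A/T-poor background, 152 bp
        with_site = base[:30] + "TAATTA" + base[36:]
        t0 = segment_kd_profile(SequenceRecord("a", base), params, window=75)
        t1 = segment_kd_profile(SequenceRecord("b", with_site), params, window=75)
        assert t1["kd_M"].iloc[0] < t0["kd_M"].iloc[0]

    def test_window_too_small_rejected(self, params):
        with pytest.raises(ValueError):
            segment_kd_profile(SequenceRecord("x", "ACGTACGT"), params, window=5)


class TestBatchKd:
    def test_single_record_matches_landscape(self, params):
        rec = SequenceRecord("r1", "ACGTACGTAAGG")
        table, hist = batch_kd([rec], params)
        assert table["kd_M"].iloc[0] == pytest.approx(landscape(rec, params).kd)
        assert hist is not None

    def test_empty_batch(self, params):
        table, hist = batch_kd([], params)
        assert table.empty
        assert hist is None

    def test_synthetic_fragments_all_finite_unimodalish(self, params):
        from tfantenna.synthetic_data import implant_sites, random_sequence

        records = []
        for i in range(100):
            rec = random_sequence(150, 0.57, seed=1000 + i, seq_id=f"f{i}")
            records.append(implant_sites(rec, [(72, "TAATTA")]))
        table, hist = batch_kd(records, params)
        assert np.isfinite(table["kd_M"]).all()
        counts, edges = hist
        assert counts.sum() == 100
        # unimodal up to small fluctuations: the max bin dominates
        assert counts.max() >= 0.2 * counts.sum()
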