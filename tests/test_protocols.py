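import numpy as np
import pytest

from qmrisim import (
    ProtocolParams,
    load_preset,
    make_irse,
    make_multiecho_tse,
    make_protocol,
    make_t1_protocol,
    make_tse,
    random_slice_order,
    timing_report,
    tse_pe_order,
)
from qmrisim.events import InfeasibleTimingError
from qmrisim.protocols import ConfigurationError

RASTER = 1e-6


class TestTimingAgainstNominal:
    """Measured intervals must reproduce the protocol's printed values."""

    def test_irse_sim_preset(self):
        rep = timing_report(make_protocol(load_preset("irse_sim")))
        assert rep.measured_TI == pytest.approx(0.200, abs=RASTER)
        assert rep.measured_TE == pytest.approx(0.010, abs=RASTER)
        assert rep.measured_TR == pytest.approx(4.5, abs=RASTER)

    def test_tse_sim_preset(self):
        rep = timing_report(make_protocol(load_preset("tse_sim")))
        assert rep.measured_TR == pytest.approx(4.5, abs=RASTER)
        assert rep.measured_TE == pytest.approx(0.010, abs=RASTER)

    def test_irse_acr_preset(self):
        rep = timing_report(make_protocol(load_preset("irse_acr", scale=8)))
        assert rep.measured_TI == pytest.approx(0.150, abs=RASTER)
        assert rep.measured_TE == pytest.approx(0.012, abs=RASTER)
        assert rep.measured_TR == pytest.approx(2.0, abs=RASTER)
        assert rep.n_slices_seen == 11

    def test_tse_acr_preset(self):
        rep = timing_report(make_protocol(load_preset("tse_acr", scale=8)))
        assert rep.measured_TE == pytest.approx(0.050, abs=RASTER)
        assert rep.measured_TR == pytest.approx(3.0, abs=RASTER)
        assert rep.echoes_per_excitation == 4
        assert rep.echo_spacing == pytest.approx(0.025, abs=RASTER)

    def test_total_duration_is_sum_of_blocks(self):
        seq = make_protocol(load_preset("irse_sim"))
        total = sum(round(b.duration * 1e6) for b in seq.blocks) * 1e-6
        assert seq.duration == pytest.approx(total, abs=0)


class TestIrse:
    def test_ti_greater_than_tr_infeasible(self):
        p = ProtocolParams(kind="irse", matrix_n=16, tr=0.5, te=0.01, ti=0.6)
        with pytest.raises(InfeasibleTimingError):
            make_irse(p)

    def test_distinct_slice_frequencies(self):
        p = load_preset("irse_acr", scale=8)
        seq = make_irse(p)
        freqs = {
            b.rf.freq_offset
            for b in seq.blocks
            if b.rf is not None and b.rf.use == "excitation"
        }
        assert len(freqs) == 11


class TestTse:
    def test_excitations_and_echo_counts(self):
        p = ProtocolParams(kind="tse", matrix_n=32, tr=3.0, te=0.05, etl=4)
        seq = make_tse(p)
        excs = sum(
            1 for b in seq.blocks if b.rf is not None and b.rf.use == "excitation"
        )
        adcs = [b.adc for b in seq.blocks if b.adc is not None]
        assert excs == 32 // 4
        assert len(adcs) == 32
        assert max(a.echo_index for a in adcs) == 4

    def test_pe_coverage_across_train(self):
        p = ProtocolParams(kind="tse", matrix_n=32, tr=3.0, te=0.05, etl=4)
        seq = make_tse(p)
        lines = sorted(b.adc.pe_line for b in seq.blocks if b.adc is not None)
        assert lines == list(range(32))

    def test_matrix_not_divisible_by_etl(self):
        p = ProtocolParams(kind="tse", matrix_n=30, tr=3.0, te=0.05, etl=4)
        with pytest.raises(ConfigurationError):
            make_tse(p)

    def test_etl1_matches_irse_timing_without_inversion(self):
        se = ProtocolParams(
            kind="tse", matrix_n=16, tr=2.0, te=0.012, etl=1, center_echo=1
        )
        ir = ProtocolParams(kind="irse", matrix_n=16, tr=2.0, te=0.012, ti=0.15)
        rep_se = timing_report(make_tse(se))
        rep_ir = timing_report(make_irse(ir))
        assert rep_se.measured_TE == pytest.approx(rep_ir.measured_TE, abs=RASTER)
        assert rep_se.measured_TR == pytest.approx(rep_ir.measured_TR, abs=RASTER)
        assert rep_se.measured_TI is None


class TestMultiEchoTse:
    def test_full_preset_echo_structure(self):
        seq = make_protocol(load_preset("tse_t2map", scale=4))
        rep = timing_report(seq)
        assert rep.echoes_per_excitation == 23
        assert rep.echo_spacing == pytest.approx(0.007, abs=RASTER)
        assert rep.echo_times[-1] == pytest.approx(0.161, abs=RASTER)
        adcs = [b.adc for b in seq.blocks if b.adc is not None]
        assert len(adcs) == 32 * 23  # one line per excitation, all echoes

    def test_same_line_for_all_echoes_of_one_excitation(self):
        seq = make_protocol(load_preset("tse_t2map", scale=4))
        per_exc = {}
        exc = -1
        for b in seq.blocks:
            if b.rf is not None and b.rf.use == "excitation":
                exc += 1
            if b.adc is not None:
                per_exc.setdefault(exc, set()).add(b.adc.pe_line)
        assert all(len(v) == 1 for v in per_exc.values())

    def test_non_arithmetic_te_list_rejected(self):
        with pytest.raises(ConfigurationError):
            ProtocolParams(
                kind="multiecho_tse",
                matrix_n=16,
                tr=4.5,
                te_list=[0.007, 0.014, 0.030],
            )

    def test_single_te_degenerates_to_spin_echo(self):
        p = ProtocolParams(
            kind="multiecho_tse", matrix_n=16, tr=3.0, te_list=[0.012]
        )
        rep = timing_report(make_multiecho_tse(p))
        assert rep.echoes_per_excitation == 1
        assert rep.measured_TE == pytest.approx(0.012, abs=RASTER)


class TestT1Protocol:
    def test_measured_ti_follows_footnote_list(self):
        p = load_preset("irse_t1map", scale=4)
        seqs = make_t1_protocol(p)
        tis = [timing_report(s).measured_TI for s in seqs]
        assert np.allclose(tis, p.ti_list, atol=RASTER)
        assert np.all(np.diff(tis) > 0)

    def test_single_ti(self):
        p = ProtocolParams(
            kind="irse_t1map", matrix_n=16, tr=2.0, te=0.01, ti_list=[0.05]
        )
        assert len(make_t1_protocol(p)) == 1

    def test_infeasible_ti_names_offender(self):
        p = ProtocolParams(
            kind="irse_t1map", matrix_n=16, tr=1.0, te=0.01, ti_list=[0.05, 2.0]
        )
        with pytest.raises(InfeasibleTimingError, match="2000"):
            make_t1_protocol(p)


class TestSliceOrder:
    def test_identity_for_single_slice(self):
        assert random_slice_order(1, 0).permutation.tolist() == [0]

    def test_deterministic_given_seed(self):
        a = random_slice_order(11, 42)
        b = random_slice_order(11, 42)
        assert a.permutation.tolist() == b.permutation.tolist()

    def test_first_position_uniform(self):
        # each slice should appear first with frequency 1/11 within 3 sigma
        n, draws = 11, 10_000
        firsts = np.array(
            [random_slice_order(n, seed).permutation[0] for seed in range(draws)]
        )
        counts = np.bincount(firsts, minlength=n)
        p = 1.0 / n
        sigma = np.sqrt(draws * p * (1 - p))
        assert np.all(np.abs(counts - draws * p) < 3.5 * sigma)


class TestPeOrder:
    def test_center_band_at_center_echo(self):
        pe = tse_pe_order(8, 4, 2)
        # 0-based center line 4 lives in band {4,5} -> echo 2 (row index 1)
        assert set(pe.table[1]) == {4, 5}

    def test_flattened_table_is_permutation(self):
        pe = tse_pe_order(256, 4, 2)
        assert sorted(pe.table.ravel().tolist()) == list(range(256))

    def test_etl1_single_band(self):
        pe = tse_pe_order(16, 1, 1)
        assert pe.table.shape == (1, 16)
        assert pe.table[0].tolist() == list(range(16))

    def test_invalid_center_echo(self):
        with pytest.raises(ConfigurationError):
            tse_pe_order(16, 4, 5)
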