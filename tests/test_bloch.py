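import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmrisim import (
    Magnetization,
    ProtocolParams,
    apply_rf,
    free_precess,
    make_irse,
    make_tse,
    reconstruct,
    simulate,
    steady_state_prep,
)
from qmrisim.events import SequenceError
from qmrisim.phantoms import Phantom, make_grid_phantom
from qmrisim.sequence import Sequence


def exact_irse_echo(t1, t2, tr, ti, te, pd=1.0):
    """Closed-form steady-state IR spin-echo amplitude for the simulated
    timeline (180 inversion - TI - 90 - TE/2 - 180 - echo, ideal spoiling
    before each excitation; the refocusing pulse inverts the recovering
    longitudinal magnetization)."""
    mss = 1 + np.exp(-(tr - ti) / t1) - 2 * np.exp(-(tr - ti - te / 2) / t1)
    mexc = 1 - (1 + mss) * np.exp(-ti / t1)
    return pd * abs(mexc) * np.exp(-te / t2)


class TestRotations:
    def test_inversion(self):
        m = apply_rf(Magnetization(0, 1.0), np.pi, 0.3)
        assert m.mz == pytest.approx(-1.0, abs=1e-12)
        assert abs(m.mxy) == pytest.approx(0.0, abs=1e-12)

    def test_excitation_convention(self):
        # rotation about +x maps +z to -y: mxy = -i
        m = apply_rf(Magnetization(0, 1.0), np.pi / 2, 0.0)
        assert m.mxy == pytest.approx(-1j, abs=1e-12)
        assert m.mz == pytest.approx(0.0, abs=1e-12)

    def test_zero_flip_identity(self):
        m0 = Magnetization(0.3 - 0.2j, 0.5)
        m = apply_rf(m0, 0.0, 1.0)
        assert m.mxy == pytest.approx(m0.mxy)
        assert m.mz == pytest.approx(m0.mz)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mx=st.floats(-1, 1),
        my=st.floats(-1, 1),
        mz=st.floats(-1, 1),
        flip=st.floats(0, 2 * np.pi),
        phase=st.floats(0, 2 * np.pi),
    )
    def test_rotation_preserves_norm(self, mx, my, mz, flip, phase):
        m = Magnetization(mx + 1j * my, mz)
        out = apply_rf(m, flip, phase)
        n_in = abs(m.mxy) ** 2 + m.mz**2
        n_out = abs(out.mxy) ** 2 + out.mz**2
        assert n_out == pytest.approx(n_in, abs=1e-12)


class TestFreePrecession:
    def test_long_dt_reaches_equilibrium(self):
        m = free_precess(Magnetization(1.0, -1.0), 1e3, 0.5, 0.1)
        assert m.mz == pytest.approx(1.0)
        assert abs(m.mxy) == pytest.approx(0.0)

    def test_t2_halving_time(self):
        m = free_precess(Magnetization(1.0, 0.0), 0.1 * np.log(2), 1.0, 0.1)
        assert abs(m.mxy) == pytest.approx(0.5, rel=1e-12)

    def test_inversion_recovery_closed_form(self):
        # mz' = 1 - 2 exp(-0.15/0.5) = -0.48164
        m = free_precess(Magnetization(0.0, -1.0), 0.15, 0.5, 0.1)
        assert m.mz == pytest.approx(1 - 2 * np.exp(-0.3), abs=1e-12)
        assert m.mz == pytest.approx(-0.48164, abs=5e-6)

    def test_relaxation_contractive(self):
        m = Magnetization(0.8j, 0.2)
        for dt in (1e-3, 1e-2, 0.1):
            out = free_precess(m, dt, 0.7, 0.05, dphi=0.4)
            assert abs(out.mxy) < abs(m.mxy)
            assert m.mz < out.mz <= 1.0
            m = out


class TestSimulateOracles:
    def test_irse_steady_state_closed_form(self, single_voxel_phantom):
        tr, te = 4.5, 0.010
        for t1, ti in [(0.2, 0.05), (0.9, 0.4), (2.0, 3.0)]:
            p = ProtocolParams(
                kind="irse", matrix_n=4, n_slices=1, tr=tr, te=te, ti=ti
            )
            seq = steady_state_prep(make_irse(p), 10)
            raw = simulate(seq, single_voxel_phantom(t1=t1, t2=0.1))
            idx = np.where(raw.meta["pe_line"] == 2)[0][0]
            sim = abs(raw.samples[2, 0, idx])
            assert sim == pytest.approx(
                exact_irse_echo(t1, 0.1, tr, ti, te), abs=1e-9
            )

    def test_null_point(self, single_voxel_phantom):
        t1 = 0.5
        p = ProtocolParams(
            kind="irse", matrix_n=4, n_slices=1, tr=10 * t1, te=0.01,
            ti=round(t1 * np.log(2), 6),
        )
        seq = steady_state_prep(make_irse(p), 5)
        raw = simulate(seq, single_voxel_phantom(t1=t1, t2=0.1))
        assert np.max(np.abs(raw.samples)) <= 1e-3

    def test_linearity_over_isochromats(self, se_params):
        p = se_params(n=8)
        pd = np.zeros((8, 8))
        pd[2, 3] = 1.0
        pd[5, 6] = 0.7
        mk = lambda m: Phantom(
            pd_map=m, t1_map=np.where(m > 0, 0.5, 0), t2_map=np.where(m > 0, 0.3, 0), fov=0.25
        )
        both = simulate(make_tse(p), mk(pd))
        a = np.zeros_like(pd); a[2, 3] = 1.0
        b = np.zeros_like(pd); b[5, 6] = 0.7
        ra = simulate(make_tse(p), mk(a))
        rb = simulate(make_tse(p), mk(b))
        assert np.allclose(both.samples, ra.samples + rb.samples, atol=1e-12)

    def test_encoding_oracle_against_direct_dft(self, se_params):
        """Simulated k-space of a long-TR short-TE spin echo equals the
        centered DFT of the PD map (half-voxel convention) within 1%."""
        n = 16
        ph = make_grid_phantom(n, n, t1=0.5, t2=0.4)
        raw = simulate(make_tse(se_params(n=n)), ph)
        # brute-force DFT oracle with the package's coordinate convention
        grid = np.zeros((n, n), dtype=complex)
        xx, yy = ph.coordinates()
        for p_line in range(n):
            ky = (p_line - n // 2) / ph.fov
            for j in range(n):
                kx = (j - n // 2) / ph.fov
                grid[p_line, j] = np.sum(
                    ph.pd_map * np.exp(-2j * np.pi * (kx * xx + ky * yy))
                )
        sim_grid = np.zeros_like(grid)
        for i in range(raw.n_readouts):
            sim_grid[raw.meta["pe_line"][i], :] = raw.samples[:, 0, i]
        scale = np.vdot(sim_grid, grid) / np.vdot(sim_grid, sim_grid)
        err = np.linalg.norm(scale * sim_grid - grid) / np.linalg.norm(grid)
        assert err < 0.01

    def test_sequence_without_adc_rejected(self, single_voxel_phantom):
        from qmrisim.events import delay_block

        seq = Sequence(blocks=[delay_block(1e-3)])
        with pytest.raises(SequenceError):
            simulate(seq, single_voxel_phantom())

    def test_empty_phantom_warns(self, se_params):
        ph = Phantom(
            pd_map=np.zeros((16, 16)),
            t1_map=np.zeros((16, 16)),
            t2_map=np.zeros((16, 16)),
            fov=0.25,
        )
        with pytest.warns(UserWarning):
            raw = simulate(make_tse(se_params(n=16)), ph)
        assert np.all(raw.samples == 0)


class TestSteadyStatePrep:
    def test_zero_dummies_unchanged(self, se_params):
        seq = make_tse(se_params())
        assert steady_state_prep(seq, 0) is seq

    def test_duration_grows_by_n_tr(self, se_params):
        seq = make_tse(se_params(tr=2.0))
        prepped = steady_state_prep(seq, 3)
        assert prepped.duration == pytest.approx(seq.duration + 3 * 2.0, abs=1e-6)

    def test_dummies_converge_irse_signal(self, single_voxel_phantom):
        # with TR >= 5 T1, two dummies change nothing measurable
        p = ProtocolParams(kind="irse", matrix_n=4, n_slices=1, tr=4.5, te=0.01, ti=0.2)
        seq = make_irse(p)
        ph = single_voxel_phantom(t1=0.5, t2=0.1)
        r0 = simulate(seq, ph)
        r2 = simulate(steady_state_prep(seq, 2), ph)
        # skip the very first readout (pre-steady-state in r0)
        a = np.abs(r0.samples[:, :, 1:])
        b = np.abs(r2.samples[:, :, 1:])
        assert np.max(np.abs(a - b)) <= 1e-4 * np.max(b)
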