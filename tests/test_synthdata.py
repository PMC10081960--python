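"""Phantom, coil, fingerprint and forward-sampling checks."""

import numpy as np
import pytest

import spiralmrf as smrf
from spiralmrf.synthdata import (
    default_acquisition,
    forward_sample,
    frame_image,
    make_phantom,
    simulate_fingerprint,
    undersample,
)
from spiralmrf.trajectory import make_schedule, make_spiral


class TestFingerprint:
    def test_t2prep_decay_closed_form(self):
        # one segment boundary with TE_p = 50 ms: Mz multiplied by exp(-50/T2)
        t2 = 100.0
        acq = default_acquisition(
            T=2, n_segments=2, t2prep_te_ms=(50.0,), inversion=False,
            segment_delay_ms=0.0, flip_lo_deg=30.0, flip_hi_deg=30.0,
        )
        s = simulate_fingerprint(1e12, t2, acq)  # T1 huge: no recovery
        alpha = np.deg2rad(30.0)
        e_te = np.exp(-acq.te_ms / t2)
        expected0 = np.sin(alpha) * e_te
        expected1 = np.cos(alpha) * np.exp(-50.0 / t2) * np.sin(alpha) * e_te
        assert s[0] == pytest.approx(expected0, rel=1e-12)
        assert s[1] == pytest.approx(expected1, rel=1e-12)

    def test_pure_inversion_recovery(self):
        # alpha = 0: no emission, Mz relaxes as 1 - 2 exp(-n TR / T1)
        acq = default_acquisition(
            T=8, n_segments=1, t2prep_te_ms=(), inversion=True,
            segment_delay_ms=0.0, flip_lo_deg=0.0, flip_hi_deg=0.0,
        )
        t1 = 800.0
        s = simulate_fingerprint(t1, 70.0, acq)
        assert np.all(s == 0)

    def test_three_tr_hand_unrolled(self):
        acq = default_acquisition(
            T=3, n_segments=1, t2prep_te_ms=(), inversion=True,
            segment_delay_ms=0.0, flip_lo_deg=10.0, flip_hi_deg=10.0,
            tr_ms=9.2, te_ms=1.3,
        )
        t1, t2 = 800.0, 70.0
        s = simulate_fingerprint(t1, t2, acq)
        # independent scalar recursion
        a = np.deg2rad(10.0)
        ete, etr = np.exp(-1.3 / t2), np.exp(-9.2 / t1)
        mz = -1.0
        expected = []
        for _ in range(3):
            expected.append(mz * np.sin(a) * ete)
            mz = mz * np.cos(a)
            mz = 1.0 + (mz - 1.0) * etr
        assert np.max(np.abs(s - np.array(expected))) < 1e-12

    def test_tissue_time_courses_distinguishable(self):
        acq = default_acquisition()
        wm = simulate_fingerprint(800.0, 70.0, acq)
        gm = simulate_fingerprint(1300.0, 90.0, acq)
        ip = abs(np.vdot(wm, gm)) / (np.linalg.norm(wm) * np.linalg.norm(gm))
        assert ip < 1.0 - 1e-4

    def test_rejects_nonpositive_relaxation(self):
        acq = default_acquisition()
        with pytest.raises(ValueError):
            simulate_fingerprint(-1.0, 70.0, acq)
        with pytest.raises(ValueError):
            simulate_fingerprint(800.0, 0.0, acq)


class TestMakePhantom:
    def test_deterministic_given_seed(self):
        p1, c1 = make_phantom(32, 8, 4, seed=5)
        p2, c2 = make_phantom(32, 8, 4, seed=5)
        assert np.array_equal(p1.label_map, p2.label_map)
        assert np.array_equal(c1.maps, c2.maps)

    def test_all_labels_present(self):
        phantom, _ = make_phantom(32, 12, 2, seed=0)
        counts = np.bincount(phantom.label_map.ravel(), minlength=4)
        assert np.all(counts > 0), counts

    def test_coil_coverage_inside_object(self):
        phantom, coils = make_phantom(32, 12, 4, seed=1)
        sos = coils.sos()
        assert sos[phantom.mask].min() >= 1e-6

    def test_relaxation_ordering_enforced(self):
        with pytest.raises(ValueError):
            make_phantom(16, 4, 2, seed=0, tissues={1: (70.0, 800.0, 1.0)})


class TestForwardSample:
    def test_dc_sample_equals_image_sum(self, tiny_sim):
        """The k=(0,0), central-kz sample is the spatial sum of the
        coil-weighted frame image."""
        phantom, coils, acq = tiny_sim["phantom"], tiny_sim["coils"], tiny_sim["acq"]
        P = phantom.label_map.shape[2]
        # single-point trajectory at the origin
        traj = smrf.SpiralTrajectory(
            coords=np.zeros((2, 2)), n_interleaves_full=1, k_max=0.5, turns=1.0
        )
        sched = make_schedule(P, 1, 0, T=1)
        ks = forward_sample(phantom, coils, traj, sched, _first_frame(acq), noise_sigma=0.0)
        img = frame_image(phantom, _first_frame(acq), frame=0)
        for c in range(coils.n_coils):
            expected = np.sum(img * coils.maps[c])
            got = ks.data[0, P // 2, 0, c]
            assert abs(got - expected) / abs(expected) < 1e-6

    def test_linearity_in_proton_density(self, tiny_cfg):
        phantom, coils = make_phantom(16, 6, 2, seed=3)
        doubled = smrf.DigitalPhantom(
            label_map=phantom.label_map,
            t1_ms=phantom.t1_ms,
            t2_ms=phantom.t2_ms,
            pd=phantom.pd * 2.0,
            coverage=phantom.coverage,
            pd_texture=phantom.pd_texture,
        )
        traj = make_spiral(Q=64, n_interleaves_full=4, k_max=0.5, turns=2.0)
        sched = make_schedule(6, 1, 0, T=2)
        acq = default_acquisition(T=2, n_segments=1, t2prep_te_ms=())
        a = forward_sample(phantom, coils, traj, sched, acq, noise_sigma=0.0, dtype=np.complex128)
        b = forward_sample(doubled, coils, traj, sched, acq, noise_sigma=0.0, dtype=np.complex128)
        nz = np.abs(a.data) > 0
        rel = np.abs(b.data[nz] - 2.0 * a.data[nz]) / np.abs(2.0 * a.data[nz])
        assert rel.max() < 1e-12

    def test_matches_brute_force_dft(self):
        """Fast path equals the direct triple-sum discrete Fourier oracle."""
        M, P, Q, C = 12, 4, 20, 2
        phantom, coils = make_phantom(M, P, C, seed=2)
        traj = make_spiral(Q=Q, n_interleaves_full=4, k_max=0.5, turns=2.0)
        sched = make_schedule(P, 1, 0, T=2)
        acq = default_acquisition(T=2, n_segments=1, t2prep_te_ms=())
        ks = forward_sample(phantom, coils, traj, sched, acq, noise_sigma=0.0, dtype=np.complex128)

        x = np.arange(M) - M // 2
        z = np.arange(P) - P // 2
        for t in (0, 1):
            img = frame_image(phantom, acq, frame=t)
            angle = sched.frame_angles[t]
            rot = np.array(
                [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
            )
            coords = traj.coords @ rot.T
            for p in range(P):
                kz = p - P // 2
                for q in range(0, Q, 7):
                    for c in range(C):
                        vol = img * coils.maps[c]
                        phase = (
                            coords[q, 0] * x[:, None, None]
                            + coords[q, 1] * x[None, :, None]
                            + kz * z[None, None, :] / P
                        )
                        expected = np.sum(vol * np.exp(-2j * np.pi * phase))
                        got = ks.data[t, p, q, c]
                        assert abs(got - expected) <= 1e-5 * max(abs(expected), 1e-3)

    def test_energy_invariant_under_rotation_for_circular_phantom(self):
        phantom, coils = make_phantom(
            64, 4, 1, seed=0, circular=True, uniform_coil=True, texture=0.0
        )
        traj = make_spiral(Q=256, n_interleaves_full=8, k_max=0.5, turns=4.0)
        acq = default_acquisition(T=2, n_segments=1, t2prep_te_ms=())
        sched0 = make_schedule(4, 1, 0, T=2, golden_angle=0.0)
        sched1 = make_schedule(4, 1, 0, T=2, golden_angle=0.0, angle0=1.234)
        a = forward_sample(phantom, coils, traj, sched0, acq, noise_sigma=0.0, dtype=np.complex128)
        b = forward_sample(phantom, coils, traj, sched1, acq, noise_sigma=0.0, dtype=np.complex128)
        ea = np.sum(np.abs(a.data) ** 2)
        eb = np.sum(np.abs(b.data) ** 2)
        assert abs(ea - eb) / ea < 1e-3


class TestUndersample:
    def test_r1_is_identity(self, tiny_sim):
        ks = tiny_sim["ks"]
        out = undersample(ks, make_schedule(ks.data.shape[1], 1, 0, T=ks.data.shape[0]))
        assert np.array_equal(out.data, ks.data)
        assert out.acquired_mask.all()

    def test_nonzero_partition_count_matches_schedule(self, tiny_sim):
        ks = tiny_sim["ks"]
        P, T = ks.data.shape[1], ks.data.shape[0]
        sched = make_schedule(P, 2, 4, T=T)
        out = undersample(ks, sched)
        nonzero = np.where(np.any(out.data != 0, axis=(0, 2, 3)))[0]
        assert set(nonzero.tolist()) <= set(sched.acquired_indices.tolist())
        assert out.acquired_mask.sum() == sched.acquired_indices.size

    def test_acquired_partitions_bit_identical(self, tiny_sim, tiny_undersampled):
        ks, und = tiny_sim["ks"], tiny_undersampled
        acq_idx = und.schedule.acquired_indices
        assert np.array_equal(und.data[:, acq_idx], ks.data[:, acq_idx])

    def test_partition_mismatch_rejected(self, tiny_sim):
        ks = tiny_sim["ks"]
        bad = make_schedule(ks.data.shape[1] + 1, 2, 2, T=ks.data.shape[0])
        with pytest.raises(ValueError):
            undersample(ks, bad)


def _first_frame(acq):
    """A single-TR schedule matching acq's timing (helper for DC tests)."""
    return default_acquisition(
        T=1,
        n_segments=1,
        tr_ms=acq.tr_ms,
        te_ms=acq.te_ms,
        t2prep_te_ms=(),
        inversion=acq.inversion,
        segment_delay_ms=0.0,
    )
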