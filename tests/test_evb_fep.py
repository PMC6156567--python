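"""FEP and umbrella-sampling estimators against exactly solvable models."""

import numpy as np
import pytest

from kemplab.constants import KB_KCAL
from kemplab.evb.fep import MappingFrame, fep_free_energy, umbrella_profile
from kemplab.evb.surrogate import HarmonicToggleSurrogate, TwoParabolaSurrogate


def constant_offset_frames(c, n=500, seed=0, n_lam=11):
    """eps2 = eps1 + c: any sampling gives dG(lambda=1) = c exactly."""
    rng = np.random.default_rng(seed)
    frames = []
    for lam in np.linspace(0, 1, n_lam):
        e1 = rng.normal(0, 3, n)
        frames.append(MappingFrame(lam=float(lam), eps1=e1, eps2_raw=e1 + c,
                                   alpha_map=0.0))
    return frames


class TestFEP:
    def test_constant_perturbation_exact(self):
        res = fep_free_energy(constant_offset_frames(4.2), 300.0)
        assert res.dG[-1] == pytest.approx(4.2, abs=1e-10)

    def test_harmonic_toggle_closed_form(self):
        """k -> 4k at 300 K: dG = (1/2) kT ln 4 ~ 0.413 kcal/mol."""
        ht = HarmonicToggleSurrogate(k1=1.0, k2=4.0)
        frames = ht.sample_frames(seed=3)
        res = fep_free_energy(frames, 300.0)
        exact = ht.exact_dG(300.0)
        assert exact == pytest.approx(0.5 * KB_KCAL * 300 * np.log(4.0))
        assert res.dG[-1] == pytest.approx(exact, rel=0.01)

    def test_forward_backward_consistency(self):
        ht = HarmonicToggleSurrogate(k1=1.0, k2=2.0)
        frames = ht.sample_frames(seed=4)
        fwd = fep_free_energy(frames, 300.0).dG[-1]
        rev_frames = []
        for f in reversed(frames):
            rev_frames.append(MappingFrame(lam=1.0 - f.lam, eps1=f.eps2_raw,
                                           eps2_raw=f.eps1, alpha_map=0.0))
        bwd = fep_free_energy(rev_frames, 300.0).dG[-1]
        assert bwd == pytest.approx(-fwd, abs=0.01)

    def test_bidirectional_close_to_forward(self):
        ht = HarmonicToggleSurrogate()
        frames = ht.sample_frames(seed=5)
        f = fep_free_energy(frames, 300.0).dG[-1]
        b = fep_free_energy(frames, 300.0, bidirectional=True).dG[-1]
        assert b == pytest.approx(ht.exact_dG(300.0), rel=0.01)
        assert abs(f - b) < 0.02

    def test_window_merging_additivity(self):
        """Dropping every other window changes cumulative dG only within
        estimator noise (free energy is a state function)."""
        tp = TwoParabolaSurrogate(k=0.5, d=6.0)
        frames = tp.sample_frames(lambdas=np.linspace(0, 1, 41),
                                  n_samples=20000, seed=6)
        full = fep_free_energy(frames, 300.0).dG[-1]
        merged = fep_free_energy(frames[::2], 300.0).dG[-1]
        assert merged == pytest.approx(full, abs=0.1)

    def test_single_frame_refused(self):
        with pytest.raises(ValueError, match="two mapping frames"):
            fep_free_energy(constant_offset_frames(1.0)[:1], 300.0)


class TestUmbrellaProfile:
    def test_marcus_symmetric(self):
        """dG_act = lambda_r / 4 for symmetric uncoupled parabolas."""
        tp = TwoParabolaSurrogate(k=0.5, d=8.0, dg0=0.0)
        frames = tp.sample_frames(seed=7, n_samples=20000)
        prof = umbrella_profile(frames, 300.0, bin_width=0.25, min_count=20,
                                H12=0.0)
        assert prof.barrier == pytest.approx(tp.reorganization_energy / 4.0,
                                             abs=0.1)
        assert prof.reaction_dG == pytest.approx(0.0, abs=0.1)

    def test_marcus_asymmetric(self):
        """dG_act = (lambda_r + dG0)^2 / (4 lambda_r)."""
        tp = TwoParabolaSurrogate(k=0.5, d=8.0, dg0=-6.0)
        frames = tp.sample_frames(seed=8, n_samples=20000)
        prof = umbrella_profile(frames, 300.0, bin_width=0.25, min_count=20,
                                H12=0.0)
        lr = tp.reorganization_energy
        assert prof.barrier == pytest.approx((lr - 6.0) ** 2 / (4 * lr), abs=0.1)
        assert prof.reaction_dG == pytest.approx(-6.0, abs=0.1)

    def test_coupling_lowers_barrier_by_H12(self):
        """The coupled barrier drops by ~H12 at the symmetric crossing (the
        exact lowering is H12 - H12^2/lambda_r: the coupling also depresses
        the reactant well by H12^2/lambda_r)."""
        tp = TwoParabolaSurrogate(k=0.5, d=8.0, dg0=0.0)
        frames = tp.sample_frames(seed=9, n_samples=20000)
        b0 = umbrella_profile(frames, 300.0, bin_width=0.25, min_count=20,
                              H12=0.0).barrier
        b3 = umbrella_profile(frames, 300.0, bin_width=0.25, min_count=20,
                              H12=3.0).barrier
        lr = tp.reorganization_energy
        assert b0 - b3 == pytest.approx(3.0 - 9.0 / lr, abs=0.15)
        assert b0 - b3 == pytest.approx(3.0, abs=0.3)

    def test_matches_direct_boltzmann_integration(self):
        """Estimator equals grid integration of the same 1D model within
        0.1 kcal/mol (independent oracle)."""
        for h12, dg0 in ((0.0, 0.0), (2.0, 0.0), (1.0, -4.0)):
            tp = TwoParabolaSurrogate(k=0.5, d=8.0, dg0=dg0)
            frames = tp.sample_frames(seed=10, n_samples=20000)
            prof = umbrella_profile(frames, 300.0, bin_width=0.5,
                                    min_count=20, H12=h12)
            _, _, b_oracle, g_oracle = tp.exact_profile(H12=h12, bin_width=0.5)
            assert prof.barrier == pytest.approx(b_oracle, abs=0.1)
            assert prof.reaction_dG == pytest.approx(g_oracle, abs=0.1)

    def test_basin_span_precondition(self):
        """Frames that never cross X = 0 are refused."""
        rng = np.random.default_rng(11)
        frames = [MappingFrame(lam=l, eps1=rng.normal(0, 1, 100),
                               eps2_raw=rng.normal(50, 1, 100), alpha_map=0.0)
                  for l in (0.0, 0.5, 1.0)]
        with pytest.raises(ValueError, match="never changes sign"):
            umbrella_profile(frames, 300.0)

    def test_reference_is_reactant_minimum(self):
        tp = TwoParabolaSurrogate(k=0.5, d=8.0)
        frames = tp.sample_frames(seed=12, n_samples=5000)
        prof = umbrella_profile(frames, 300.0, bin_width=0.5, min_count=10)
        assert prof.dg.min() == pytest.approx(0.0, abs=1e-9)
        assert prof.barrier >= 0.0
        assert np.all(prof.counts >= 10)
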