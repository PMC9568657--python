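"""eLORETA inverse, lambda cross-validation, orientation, ROI extraction."""

import numpy as np
import pytest

from hypercoh.io import LeadField, ROISet
from hypercoh.preprocess import EpochSet
from hypercoh.source import (
    DEFAULT_EXCLUDED_CHANNELS,
    apply_inverse,
    build_eloreta,
    crossvalidate_lambda,
    drop_unmodeled_channels,
    forward_project,
    orient_pca,
    roi_epochs,
)
from hypercoh.synth import default_montage

FS = 250.0


def _epochset_from_scalp(lf, scalp, labels=None):
    """Wrap (n_trials, n_ch, n_time) scalp data as an EpochSet."""
    n, c, t = scalp.shape
    return EpochSet(
        epochs=scalp,
        time_axis=np.arange(t) / FS,
        labels=labels or ["fair/agent"] * n,
        keep_mask=np.ones(n, bool),
        channel_names=list(lf.channel_names),
        fs=FS,
    )


class TestBuildEloreta:
    def test_weights_are_data_independent_and_deterministic(self, toy_leadfield):
        a = build_eloreta(toy_leadfield, 0.0)
        b = build_eloreta(toy_leadfield, 0.0)
        np.testing.assert_array_equal(a.T, b.T)
        assert a.iterations >= 1 and a.final_delta < 1e-6

    def test_exact_localization_every_dipole(self, toy_leadfield):
        """Defining property: noiseless lambda=0 source power peaks at the
        true dipole for every dipole (brute-force sweep)."""
        rng = np.random.default_rng(1)
        im = build_eloreta(toy_leadfield, 0.0)
        n_dip = toy_leadfield.n_dipoles
        errors = 0
        for v in range(n_dip):
            mom = np.zeros((n_dip, 3))
            mom[v] = rng.standard_normal(3)
            x = forward_project(toy_leadfield, mom)
            s = (im.T @ x).reshape(n_dip, 3)
            if np.argmax((s**2).sum(axis=1)) != v:
                errors += 1
        assert errors == 0

    def test_regularization_shrinks_solution_monotonically(self, toy_leadfield, rng):
        x = rng.standard_normal(toy_leadfield.n_channels)
        norms = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            im = build_eloreta(toy_leadfield, lam)
            norms.append(np.linalg.norm(im.T @ x))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_negative_lambda_rejected(self, toy_leadfield):
        with pytest.raises(ValueError):
            build_eloreta(toy_leadfield, -1.0)


class TestCrossvalidateLambda:
    def _leadfield(self, rng, n_ch=12, n_dip=8):
        return LeadField(
            matrix=rng.standard_normal((n_ch, 3 * n_dip)),
            dipole_positions=rng.uniform(-50, 50, (n_dip, 3)),
            channel_names=[f"c{i}" for i in range(n_ch)],
        )

    def test_noiseless_data_selects_smallest_lambda(self, rng):
        lf = self._leadfield(rng)
        mom = rng.standard_normal((lf.n_dipoles, 3, 40))
        scalp = forward_project(lf, mom)
        # noiseless: the winner sits at or near the grid minimum, never at
        # the heavy-regularization end
        grid = [1e-6, 1e-2, 1.0]
        assert crossvalidate_lambda(scalp, lf, grid) <= grid[1]

    def test_heavy_noise_selects_larger_lambda(self, rng):
        lf = self._leadfield(rng)
        mom = rng.standard_normal((lf.n_dipoles, 3, 40))
        clean = forward_project(lf, mom)
        noisy = clean + 20.0 * clean.std() * rng.standard_normal(clean.shape)
        grid = [1e-6, 1e-2, 1.0, 100.0]
        lam_clean = crossvalidate_lambda(clean, lf, grid)
        lam_noisy = crossvalidate_lambda(noisy, lf, grid)
        assert lam_noisy > lam_clean

    def test_single_element_grid_returned(self, rng):
        lf = self._leadfield(rng)
        assert crossvalidate_lambda(np.zeros((12, 10)), lf, [0.7]) == 0.7

    def test_empty_grid_rejected(self, rng):
        lf = self._leadfield(rng)
        with pytest.raises(ValueError, match="empty"):
            crossvalidate_lambda(np.zeros((12, 10)), lf, [])


class TestApplyInverse:
    def test_forward_inverse_roundtrip_at_true_dipole(self, toy_leadfield, rng):
        im = build_eloreta(toy_leadfield, 0.0)
        n_dip = toy_leadfield.n_dipoles
        mom = np.zeros((n_dip, 3, 60))
        mom[5, 2] = np.sin(np.linspace(0, 6 * np.pi, 60))
        scalp = forward_project(toy_leadfield, mom)[None, :, :]
        se = apply_inverse(im, _epochset_from_scalp(toy_leadfield, scalp))
        rec = se.moments[0, 5, 2]
        r = np.corrcoef(rec, mom[5, 2])[0, 1]
        assert r > 0.99

    def test_zero_input_zero_output(self, toy_leadfield):
        im = build_eloreta(toy_leadfield, 0.0)
        se = apply_inverse(
            im,
            _epochset_from_scalp(
                toy_leadfield, np.zeros((2, toy_leadfield.n_channels, 10))
            ),
        )
        np.testing.assert_array_equal(se.moments, 0.0)

    def test_channel_order_alignment_by_name(self, toy_leadfield, rng):
        im = build_eloreta(toy_leadfield, 0.0)
        scalp = rng.standard_normal((1, toy_leadfield.n_channels, 20))
        es = _epochset_from_scalp(toy_leadfield, scalp)
        perm = rng.permutation(toy_leadfield.n_channels)
        es_perm = EpochSet(
            epochs=scalp[:, perm, :],
            time_axis=es.time_axis,
            labels=list(es.labels),
            keep_mask=es.keep_mask.copy(),
            channel_names=[toy_leadfield.channel_names[i] for i in perm],
            fs=FS,
        )
        np.testing.assert_allclose(
            apply_inverse(im, es).moments, apply_inverse(im, es_perm).moments,
            atol=1e-12,
        )

    def test_missing_channels_rejected(self, toy_leadfield, rng):
        im = build_eloreta(toy_leadfield, 0.0)
        es = _epochset_from_scalp(
            toy_leadfield, rng.standard_normal((1, toy_leadfield.n_channels, 20))
        )
        es2 = es.pick_channels(es.channel_names[:-2])
        with pytest.raises(ValueError, match="lacks"):
            apply_inverse(im, es2)


class TestOrientPCA:
    def _se_along(self, direction, toy_leadfield, n_time=100, seed=0):
        rng = np.random.default_rng(seed)
        n_dip = toy_leadfield.n_dipoles
        base = rng.standard_normal((2, n_dip, 1, n_time))
        moments = base * np.asarray(direction)[None, None, :, None]
        from hypercoh.source import SourceEpochs

        return SourceEpochs(
            moments=moments,
            time_axis=np.arange(n_time) / FS,
            dipole_positions=toy_leadfield.dipole_positions,
            labels=["fair/agent"] * 2,
            keep_mask=np.ones(2, bool),
            fs=FS,
        )

    def test_axis_aligned_activity(self, toy_leadfield):
        se = orient_pca(self._se_along([0, 0, 1], toy_leadfield))
        np.testing.assert_allclose(np.abs(se.versors[:, 2]), 1.0, atol=1e-9)
        np.testing.assert_allclose(se.scalar, se.moments[:, :, 2, :], atol=1e-9)

    def test_sign_convention_for_negative_axis(self, toy_leadfield):
        se = orient_pca(self._se_along([0, 0, -1], toy_leadfield))
        # versor's largest component made positive -> scalar = -(z-series)
        np.testing.assert_allclose(se.versors[:, 2], 1.0, atol=1e-9)
        np.testing.assert_allclose(se.scalar, -se.moments[:, :, 2, :] * -1, atol=1e-9)

    def test_scalar_variance_equals_leading_eigenvalue(self, toy_leadfield, rng):
        from hypercoh.source import SourceEpochs

        n_dip = toy_leadfield.n_dipoles
        moments = rng.standard_normal((3, n_dip, 3, 80))
        moments[:, :, 0, :] *= 3.0  # dominant x-axis
        se = orient_pca(
            SourceEpochs(
                moments=moments,
                time_axis=np.arange(80) / FS,
                dipole_positions=toy_leadfield.dipole_positions,
                labels=["fair/agent"] * 3,
                keep_mask=np.ones(3, bool),
                fs=FS,
            )
        )
        for v in range(n_dip):
            pooled = np.concatenate([se.scalar[k, v] for k in range(3)])
            var = pooled.var(ddof=1)
            X = np.concatenate([se.moments[k, v] for k in range(3)], axis=1)
            Xc = X - X.mean(axis=1, keepdims=True)
            lam1 = np.linalg.eigvalsh(Xc @ Xc.T / (Xc.shape[1] - 1))[-1]
            assert var == pytest.approx(lam1, abs=1e-9 * max(1, lam1))

    def test_isotropic_noise_flagged_low_dominance(self, toy_leadfield, rng):
        from hypercoh.source import SourceEpochs

        moments = rng.standard_normal((4, toy_leadfield.n_dipoles, 3, 200))
        se = SourceEpochs(
            moments=moments,
            time_axis=np.arange(200) / FS,
            dipole_positions=toy_leadfield.dipole_positions,
            labels=["fair/agent"] * 4,
            keep_mask=np.ones(4, bool),
            fs=FS,
        )
        with pytest.warns(UserWarning, match="low orientation dominance"):
            orient_pca(se)


class TestROIExtraction:
    def _oriented(self, toy_leadfield, rng):
        from hypercoh.source import SourceEpochs

        moments = rng.standard_normal((2, toy_leadfield.n_dipoles, 3, 50))
        moments[:, :, 0, :] *= 4.0
        return orient_pca(
            SourceEpochs(
                moments=moments,
                time_axis=np.arange(50) / FS,
                dipole_positions=toy_leadfield.dipole_positions,
                labels=["fair/agent"] * 2,
                keep_mask=np.ones(2, bool),
                fs=FS,
            )
        )

    def test_centroid_exactly_at_dipole(self, toy_leadfield, rng):
        se = self._oriented(toy_leadfield, rng)
        rois = ROISet(names=["A"], centroids=se.dipole_positions[7][None, :])
        es = roi_epochs(se, rois)
        assert rois.assigned_dipole_index[0] == 7
        np.testing.assert_array_equal(es.epochs[:, 0, :], se.scalar[:, 7, :])

    def test_equidistant_tie_takes_lowest_index(self, toy_leadfield, rng):
        se = self._oriented(toy_leadfield, rng)
        se.dipole_positions[3] = [10.0, 0, 0]
        se.dipole_positions[9] = [-10.0, 0, 0]
        rois = ROISet(names=["mid"], centroids=np.zeros((1, 3)))
        # exactly halfway between dipoles 3 and 9 (others are random, far)
        se.dipole_positions[[i for i in range(len(se.dipole_positions)) if i not in (3, 9)]] += 500
        roi_epochs(se, rois)
        assert rois.assigned_dipole_index[0] == 3

    def test_eleven_rois_in_eleven_series_out(self, toy_leadfield, rng):
        se = self._oriented(toy_leadfield, rng)
        rois = ROISet(
            names=[f"R{i}" for i in range(11)],
            centroids=rng.uniform(-70, 70, (11, 3)),
        )
        es = roi_epochs(se, rois)
        assert es.n_channels == 11
        assert es.channel_names == rois.names

    def test_empty_roi_set_rejected(self, toy_leadfield, rng):
        se = self._oriented(toy_leadfield, rng)
        with pytest.raises(ValueError, match="empty"):
            roi_epochs(se, ROISet(names=[], centroids=np.zeros((0, 3))))


class TestDropUnmodeledChannels:
    def _es(self, names):
        n = len(names)
        return EpochSet(
            epochs=np.zeros((2, n, 10)),
            time_axis=np.arange(10) / FS,
            labels=["fair/agent"] * 2,
            keep_mask=np.ones(2, bool),
            channel_names=list(names),
            fs=FS,
        )

    def test_head_model_exclusion_61_to_53(self):
        eeg, _ = default_montage()
        out = drop_unmodeled_channels(self._es(eeg))
        assert out.n_channels == 53
        assert not set(DEFAULT_EXCLUDED_CHANNELS) & set(out.channel_names)

    def test_empty_exclusion_is_identity(self):
        es = self._es(["Pz", "Cz"])
        out = drop_unmodeled_channels(es, ())
        assert out.channel_names == es.channel_names

    def test_absent_name_warned_and_skipped(self):
        es = self._es(["Pz", "Cz"])
        with pytest.warns(UserWarning, match="absent"):
            out = drop_unmodeled_channels(es, ("TP9",))
        assert out.channel_names == ["Pz", "Cz"]

    def test_removing_everything_rejected(self):
        es = self._es(["Pz"])
        with pytest.raises(ValueError, match="every channel"):
            drop_unmodeled_channels(es, ("Pz",))


def test_source_level_coherence_localizes_to_planted_roi(rng):
    """A dyad-coupled source planted at one ROI's dipole yields higher
    source-level dyadic coherence there than at a distant ROI."""
    from hypercoh.coherence import collapse_band, dyad_trial_coherence

    n_ch, n_dip, n_trials, n_time = 16, 12, 12, 300
    lf = LeadField(
        matrix=rng.standard_normal((n_ch, 3 * n_dip)),
        dipole_positions=rng.uniform(-70, 70, (n_dip, 3)),
        channel_names=[f"c{i}" for i in range(n_ch)],
    )
    t = np.arange(n_time) / FS
    active, distant = 4, 9
    scalp = {"r": np.zeros((n_trials, n_ch, n_time)),
             "o": np.zeros((n_trials, n_ch, n_time))}
    env = np.exp(-((t - 0.6) ** 2) / (2 * 0.12**2))
    for k in range(n_trials):
        phi = rng.uniform(0, 2 * np.pi)  # shared per-trial phase (coupled)
        burst = 5.0 * env * np.cos(2 * np.pi * 5 * (t - 0.6) + phi)
        for role in ("r", "o"):
            mom = np.zeros((n_dip, 3, n_time))
            mom[active, 1] = burst  # coupled source at the planted site
            # independent theta-band activity of similar power at the
            # distant site: uncoupled between the two subjects
            drift = np.cumsum(rng.standard_normal(n_time)) * 12.0 / np.sqrt(FS)
            mom[distant, 1] = 5.0 * env * np.cos(
                2 * np.pi * 5 * (t - 0.6) + rng.uniform(0, 2 * np.pi) + drift
            )
            proj = forward_project(lf, mom)
            scalp[role][k] = proj + 0.05 * np.abs(proj).max() * rng.standard_normal(
                (n_ch, n_time)
            )

    im = build_eloreta(lf, 0.0)
    rois = ROISet(
        names=["planted", "distant"],
        centroids=np.vstack(
            [lf.dipole_positions[active], lf.dipole_positions[distant]]
        ),
    )
    series = {}
    for role in ("r", "o"):
        es = _epochset_from_scalp(lf, scalp[role])
        se = orient_pca(apply_inverse(im, es))
        series[role] = roi_epochs(se, rois)
    locus = slice(140, 160)
    coh = {}
    for roi in rois.names:
        m = dyad_trial_coherence(series["r"], series["o"], roi, None)
        coh[roi] = np.nanmean(collapse_band(m).values[locus])
    assert coh["planted"] > coh["distant"] + 0.1
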