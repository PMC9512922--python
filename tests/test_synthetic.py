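"""Generator contracts: degenerate closed forms, Monte-Carlo oracles,
reproducibility."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from dormaflux import synthetic
from dormaflux.synthetic import (
    CohortParams,
    MetabolomicsDesign,
    PhaseProfile,
    SessionParams,
    generate_expression,
    generate_imaging_session,
    generate_metabolomics,
    generate_volume_cohort,
)


class TestImagingSession:
    def test_noiseless_flat_profile_is_exact_forward_model(
        self, flat_profile, noiseless_params
    ):
        session, truth = generate_imaging_session(flat_profile, noiseless_params, seed=0)
        G, A, D = 1.0, noiseless_params.autofluorescence, noiseless_params.dark_offset
        B = truth.beam_profile
        expected = G * B * (flat_profile.mean_signal + A) + D
        np.testing.assert_allclose(session.probe_frame, expected, rtol=1e-12)
        np.testing.assert_allclose(session.dark_frame, D)
        assert np.all(truth.true_signal_field == flat_profile.mean_signal)

    def test_day_gain_scales_dark_subtracted_probe_frame(
        self, flat_profile, noiseless_params
    ):
        s1, _ = generate_imaging_session(flat_profile, noiseless_params, seed=3)
        s2, _ = generate_imaging_session(
            flat_profile, replace(noiseless_params, day_gain=2.5), seed=3
        )
        d = noiseless_params.dark_offset
        np.testing.assert_allclose(
            s2.probe_frame - d, 2.5 * (s1.probe_frame - d), rtol=1e-12
        )

    def test_field_mean_matches_profile_at_512(self):
        profile = synthetic.PHASE_PROFILES[("fast", "TMRE", "regression")]
        _, truth = generate_imaging_session(
            profile, SessionParams(shape=(512, 512)), seed=7
        )
        assert truth.true_signal_field.mean() == pytest.approx(
            profile.mean_signal, rel=0.02
        )

    def test_coverage_fraction_realized(self):
        profile = PhaseProfile(
            phase="dormancy", probe="TMRE", mean_signal=2000.0,
            coverage_fraction=0.6, signal_floor=0.2,
        )
        _, truth = generate_imaging_session(profile, SessionParams(shape=(256, 256)), seed=1)
        floor = profile.signal_floor * profile.mean_signal
        strong = truth.true_signal_field > floor + 1e-9
        assert strong.mean() == pytest.approx(0.6, abs=0.01)

    def test_same_seed_bit_reproducible(self, default_session):
        profile = synthetic.PHASE_PROFILES[("fast", "TMRE", "regression")]
        again, truth = generate_imaging_session(
            profile, SessionParams(shape=(256, 256)), seed=7
        )
        np.testing.assert_array_equal(default_session[0].probe_frame, again.probe_frame)
        np.testing.assert_array_equal(
            default_session[1].true_signal_field, truth.true_signal_field
        )

    def test_gain_does_not_touch_truth_field(self, flat_profile, noiseless_params):
        _, t1 = generate_imaging_session(flat_profile, noiseless_params, seed=5)
        _, t2 = generate_imaging_session(
            flat_profile, replace(noiseless_params, day_gain=3.0), seed=5
        )
        np.testing.assert_array_equal(t1.true_signal_field, t2.true_signal_field)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(day_gain=0.0),
            dict(day_gain=-1.0),
            dict(shape=(32, 32)),
            dict(dark_offset=-5.0),
        ],
    )
    def test_invalid_session_params_rejected(self, bad):
        with pytest.raises(ValueError):
            SessionParams(**bad)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(coverage_fraction=0.0),
            dict(coverage_fraction=1.2),
            dict(mean_signal=-1.0),
            dict(phase="growth"),
        ],
    )
    def test_invalid_profile_rejected(self, bad):
        kwargs = dict(phase="primary", probe="NBDG", mean_signal=100.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            PhaseProfile(**kwargs)


class TestVolumeCohort:
    def test_noiseless_decay_reaches_residual_at_nadir(self):
        # half-life chosen so the nadir lands exactly on the day-7 measurement
        params = CohortParams(
            n_mice=2,
            regression_halflife=7.0 / np.log2(5.0),
            residual_fraction=0.2,
            measurement_noise_cv=0.0,
        )
        traj = generate_volume_cohort(params, seed=0)[0]
        norm = traj.normalized_volumes
        i7 = np.flatnonzero(traj.days == 7.0)[0]
        assert norm[i7] == pytest.approx(0.200, abs=1e-9)

    def test_zero_spread_recurrence_is_exactly_median(self):
        params = replace(synthetic.FAST_LINE, recurrence_spread=0.0, n_mice=5)
        cohort = generate_volume_cohort(params, seed=2)
        for t in cohort:
            assert t.true_recurrence_day == pytest.approx(55.0)

    def test_latent_recurrence_median_converges(self):
        params = replace(synthetic.FAST_LINE, n_mice=500)
        cohort = generate_volume_cohort(params, seed=11)
        sample_median = np.median([t.true_recurrence_day for t in cohort])
        assert sample_median == pytest.approx(55.0, rel=0.05)

    def test_volume_formula_roundtrip_from_axes(self):
        traj = generate_volume_cohort(replace(synthetic.FAST_LINE, n_mice=2), seed=4)[0]
        np.testing.assert_allclose(
            traj.volumes, traj.lengths * traj.widths**2 / 2.0, rtol=1e-12
        )
        assert np.all(traj.lengths >= traj.widths)

    def test_three_per_week_grid(self):
        traj = generate_volume_cohort(replace(synthetic.FAST_LINE, n_mice=2), seed=0)[0]
        offsets = sorted({d % 7 for d in traj.days})
        assert offsets == [0.0, 2.0, 4.0]

    def test_recurrence_before_nadir_rejected(self):
        with pytest.raises(ValueError, match="nadir|unidentifiable"):
            CohortParams(regression_halflife=30.0, median_recurrence_day=55.0)

    def test_reproducible(self):
        a = generate_volume_cohort(synthetic.FAST_LINE, seed=9)
        b = generate_volume_cohort(synthetic.FAST_LINE, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.volumes, tb.volumes)


class TestMetabolomics:
    def test_no_effects_no_noise_equal_group_means(self):
        design = MetabolomicsDesign(
            planted_effects=(), within_group_cv=1e-9, missing_rate=0.0
        )
        table = generate_metabolomics(design, seed=0)
        g = table.group
        means_t = table.abundances[g == "etomoxir"].mean()
        means_c = table.abundances[g == "control"].mean()
        pd.testing.assert_series_equal(means_t, means_c, rtol=1e-6)

    def test_planted_effect_exact_without_noise(self):
        design = MetabolomicsDesign(
            planted_effects=(("C16", -2.5),), within_group_cv=1e-12, missing_rate=0.0
        )
        table = generate_metabolomics(design, seed=1)
        g = table.group
        fc = np.log2(
            table.abundances.loc[g == "etomoxir", "C16"].mean()
            / table.abundances.loc[g == "control", "C16"].mean()
        )
        assert fc == pytest.approx(-2.5, abs=1e-6)

    def test_missing_fraction_matches_rate(self):
        design = MetabolomicsDesign(
            n_per_group=20,
            metabolite_classes={"acylcarnitine": 45, "amino acid": 15,
                                "organic acid": 9, "generic": 150},
            planted_effects=(),
            missing_rate=0.05,
        )
        table = generate_metabolomics(design, seed=3)
        frac = table.abundances.isna().to_numpy().mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_unknown_planted_metabolite_rejected(self):
        with pytest.raises(ValueError, match="not in the class map"):
            MetabolomicsDesign(planted_effects=(("NotAMetabolite", -2.0),))

    def test_truth_table_records_planted_effects(self):
        table = generate_metabolomics(seed=0)
        truth = table.truth.set_index("metabolite")["log2_effect"]
        assert truth["C16"] == -2.8
        assert (truth != 0).sum() == 10


class TestExpression:
    def test_zero_effect_member_nonmember_same_distribution(self):
        matrix, groups, members = generate_expression(
            n_genes=400, geneset_size=40, effect=0.0, seed=0
        )
        a = groups[groups == "primary"].index
        b = groups[groups == "regression"].index
        fc = np.log2(matrix[a].mean(axis=1) / matrix[b].mean(axis=1))
        is_member = matrix.index.isin(members)
        # same law: rank-sum z-score should be modest
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(fc[is_member], fc[~is_member]).pvalue
        assert p > 0.01

    def test_large_effect_separates_all_members(self):
        matrix, groups, members = generate_expression(
            n_genes=300, geneset_size=20, effect=6.0, within_group_cv=0.05, seed=1
        )
        a = groups[groups == "primary"].index
        b = groups[groups == "regression"].index
        fc = np.log2(matrix[a].mean(axis=1) / matrix[b].mean(axis=1))
        worst_member = fc[matrix.index.isin(members)].min()
        best_other = fc[~matrix.index.isin(members)].max()
        assert worst_member > best_other

    def test_members_rank_ahead_on_average(self):
        matrix, groups, members = generate_expression(
            n_genes=2000, geneset_size=50, effect=1.0, seed=5
        )
        a = groups[groups == "primary"].index
        b = groups[groups == "regression"].index
        fc = np.log2(matrix[a].mean(axis=1) / matrix[b].mean(axis=1))
        ranks = fc.rank(ascending=False)
        assert ranks[matrix.index.isin(members)].mean() < ranks.mean() / 2

    def test_geneset_size_validation(self):
        with pytest.raises(ValueError):
            generate_expression(n_genes=100, geneset_size=0)
        with pytest.raises(ValueError):
            generate_expression(n_genes=100, geneset_size=100)
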