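"""Rating summaries, repeated-measures ANOVA, Bonferroni pairwise tests."""

import numpy as np
import pandas as pd
import pytest

from fattaste import RatingEffects, bonferroni_pairwise, cell_summary, rm_anova, simulate_ratings


def toy_2x2(arr):
    """Long-format records from a [subject, fat, modality] score array."""
    rows = [
        {"participant_id": f"s{s}", "fat_level": a, "modality": f"m{b}", "score": arr[s, a, b]}
        for s in range(arr.shape[0])
        for a in range(arr.shape[1])
        for b in range(arr.shape[2])
    ]
    return pd.DataFrame(rows)


# printed toy dataset: 3 subjects x 2 fat levels x 2 modality conditions
TOY = np.array(
    [
        [[12.0, 18.0], [25.0, 30.0]],
        [[10.0, 15.0], [22.0, 31.0]],
        [[14.0, 20.0], [28.0, 33.0]],
    ]
)


def anova_oracle(arr):
    """Independent sums-of-squares decomposition of a two-way within design."""
    ns, na, nb = arr.shape
    grand = arr.mean()
    A, B, S = arr.mean(axis=(0, 2)), arr.mean(axis=(0, 1)), arr.mean(axis=(1, 2))
    AS, BS, AB = arr.mean(axis=2), arr.mean(axis=1), arr.mean(axis=0)
    SS_A = ns * nb * ((A - grand) ** 2).sum()
    SS_B = ns * na * ((B - grand) ** 2).sum()
    SS_AB = ns * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
    SS_AS = nb * ((AS - A[None, :] - S[:, None] + grand) ** 2).sum()
    SS_BS = na * ((BS - B[None, :] - S[:, None] + grand) ** 2).sum()
    resid = (
        arr
        - AS[:, :, None]
        - BS[:, None, :]
        - AB[None, :, :]
        + A[None, :, None]
        + B[None, None, :]
        + S[:, None, None]
        - grand
    )
    SS_ABS = (resid ** 2).sum()
    F_A = (SS_A / (na - 1)) / (SS_AS / ((na - 1) * (ns - 1)))
    F_B = (SS_B / (nb - 1)) / (SS_BS / ((nb - 1) * (ns - 1)))
    F_AB = (SS_AB / ((na - 1) * (nb - 1))) / (SS_ABS / ((na - 1) * (nb - 1) * (ns - 1)))
    SS_S = na * nb * ((S - grand) ** 2).sum()
    parts = (SS_A, SS_B, SS_AB, SS_S, SS_AS, SS_BS, SS_ABS)
    return (F_A, F_B, F_AB), parts


class TestCellSummary:
    def test_mean_and_sem(self):
        df = toy_2x2(TOY)
        out = cell_summary(df)
        cell = out[(out["modality"] == "m0") & (out["fat_level"] == 0)].iloc[0]
        assert cell["n"] == 3
        assert cell["mean"] == pytest.approx(12.0)
        assert cell["sem"] == pytest.approx(np.std([12, 10, 14], ddof=1) / np.sqrt(3))

    def test_single_observation_cell_flagged(self):
        df = pd.DataFrame(
            [{"participant_id": "s0", "modality": "taste", "fat_level": 0, "score": 30.0}]
        )
        out = cell_summary(df)
        assert not out["sem_defined"].iloc[0]
        assert np.isnan(out["sem"].iloc[0])

    def test_constant_scores_have_zero_sem(self):
        df = pd.DataFrame(
            [
                {"participant_id": f"s{i}", "modality": "taste", "fat_level": 0, "score": 40.0}
                for i in range(5)
            ]
        )
        assert cell_summary(df)["sem"].iloc[0] == 0.0

    def test_out_of_scale_scores_rejected(self):
        df = toy_2x2(TOY).assign(score=150.0)
        with pytest.raises(ValueError):
            cell_summary(df)

    def test_generator_means_recovered_within_2_sem(self, rng):
        effects = RatingEffects(b0=40.0, noise_sd=6.0, subject_sd=0.0)
        records, _ = simulate_ratings(80, modalities=("taste", "overall"), effects=effects, rng=rng)
        out = cell_summary(records)
        ok = 0
        for _, row in out.iterrows():
            truth = (
                effects.b0
                + effects.b_fat * np.log1p(row["fat_level"])
                + effects.modality_offsets[row["modality"]]
            )
            ok += abs(row["mean"] - truth) <= 2 * row["sem"]
        assert ok / len(out) >= 0.80  # ~95% expected, allow sampling slack


class TestRmAnova:
    def test_matches_hand_computed_oracle(self):
        (F_A, F_B, F_AB), _ = anova_oracle(TOY)
        # frozen oracle values for the printed toy data
        assert (F_A, F_B) == pytest.approx((914.2857142857142, 144.0))
        assert F_AB == pytest.approx(0.16)
        res = {r.effect: r for r in rm_anova(toy_2x2(TOY), within=["fat_level", "modality"])}
        assert res["fat_level"].F == pytest.approx(F_A, rel=1e-9)
        assert res["modality"].F == pytest.approx(F_B, rel=1e-9)
        assert res["fat_level * modality"].F == pytest.approx(F_AB, rel=1e-9)

    def test_total_ss_partitions(self, rng):
        arr = rng.normal(50, 10, size=(8, 3, 2))
        _, parts = anova_oracle(arr)
        assert sum(parts) == pytest.approx(((arr - arr.mean()) ** 2).sum(), rel=1e-8)

    def test_gg_epsilon_is_one_for_two_levels(self):
        res = rm_anova(toy_2x2(TOY), within="fat_level")
        assert res[0].epsilon == pytest.approx(1.0)
        assert res[0].df_num == pytest.approx(1.0)

    def test_zero_mean_effect_gives_zero_F(self):
        # per-subject modality differences of (+3, 0, -3) average out to a
        # zero modality main effect while keeping a nonzero error term
        arr = TOY.copy()
        arr[:, :, 1] = arr[:, :, 0] + np.array([3.0, 0.0, -3.0])[:, None]
        res = {r.effect: r for r in rm_anova(toy_2x2(arr), within=["fat_level", "modality"])}
        assert res["modality"].F == pytest.approx(0.0, abs=1e-12)

    def test_incomplete_participants_dropped_with_warning(self):
        df = toy_2x2(TOY)
        df = df.drop(df[(df.participant_id == "s2") & (df.fat_level == 1)].index)
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova(df, within=["fat_level", "modality"])
        assert res  # fitted on the two complete subjects

    def test_mixed_design_reports_between_effect(self, rng):
        effects = RatingEffects(b0=40.0, subject_sd=5.0, noise_sd=6.0)
        records, _ = simulate_ratings(20, modalities=("taste",), effects=effects, rng=rng)
        ids = sorted(records["participant_id"].unique())
        records["group"] = np.where(records["participant_id"].isin(ids[:10]), "high", "low")
        res = {r.effect: r for r in rm_anova(records, within="fat_level", between="group")}
        assert {"group", "fat_level", "Interaction"} <= set(res)
        assert res["group"].epsilon is None
        assert res["fat_level"].epsilon is not None

    def test_epsilon_within_theoretical_bounds(self, rng):
        effects = RatingEffects(b0=40.0)
        records, _ = simulate_ratings(15, modalities=("taste",), effects=effects, rng=rng)
        res = rm_anova(records, within="fat_level")
        k = records["fat_level"].nunique()
        assert 1 / (k - 1) - 1e-9 <= res[0].epsilon <= 1 + 1e-9


class TestBonferroni:
    def test_identical_levels_give_p_one(self):
        df = pd.DataFrame(
            [
                {"participant_id": f"s{i}", "modality": "taste", "fat_level": f, "score": 30.0 + i}
                for i in range(4)
                for f in (0, 10)
            ]
        )
        out = bonferroni_pairwise(df)
        assert out["p_bonf"].iloc[0] == 1.0

    def test_pair_count_is_k_choose_2(self, rng):
        effects = RatingEffects(b0=40.0)
        records, _ = simulate_ratings(6, modalities=("taste",), effects=effects, rng=rng)
        out = bonferroni_pairwise(records, modality="taste")
        k = records["fat_level"].nunique()
        assert len(out) == k * (k - 1) // 2

    def test_adjustment_caps_at_one_and_is_idempotent(self, rng):
        effects = RatingEffects(b0=40.0, b_fat=0.0)
        records, _ = simulate_ratings(10, modalities=("taste",), effects=effects, rng=rng)
        out = bonferroni_pairwise(records)
        assert (out["p_bonf"] <= 1.0).all()
        m = len(out)
        assert np.allclose(out["p_bonf"], np.minimum(out["p_unc"] * m, 1.0))

    def test_shifted_level_detected_against_paired_t_oracle(self, rng):
        n = 12
        base = rng.normal(40, 3, size=n)
        rows = []
        for f, shift in ((0, 0.0), (10, 0.0), (20, 15.0)):
            for i in range(n):
                rows.append(
                    {
                        "participant_id": f"s{i}",
                        "modality": "taste",
                        "fat_level": f,
                        "score": base[i] + shift + rng.normal(0, 1.5),
                    }
                )
        df = pd.DataFrame(rows)
        out = bonferroni_pairwise(df)
        sig = out[out["p_bonf"] < 0.05]
        assert set(map(tuple, sig[["level_a", "level_b"]].values)) == {(0, 20), (10, 20)}
        # oracle: direct paired t on one flagged pair, times m
        from scipy.stats import ttest_rel

        wide = df.pivot_table(index="participant_id", columns="fat_level", values="score")
        t, p = ttest_rel(wide[0], wide[20])
        row = out[(out.level_a == 0) & (out.level_b == 20)].iloc[0]
        assert row["p_bonf"] == pytest.approx(min(p * 3, 1.0), rel=1e-9)

    def test_single_level_gives_empty_table(self):
        df = pd.DataFrame(
            [{"participant_id": "s0", "modality": "taste", "fat_level": 0, "score": 10.0}]
        )
        assert bonferroni_pairwise(df).empty
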