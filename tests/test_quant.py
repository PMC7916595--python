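"""Quantification contracts, with a brute-force oracle for profile building."""

import numpy as np
import pandas as pd
import pytest

from complexome.quant import (
    ABSENT_IN_PERTURBED,
    MigrationProfile,
    average_and_normalize,
    build_raw_profile,
    condition_profiles,
    map_channels_to_conditions,
    protein_ratio,
    select_representative_peptide,
    split_channels,
)
from complexome.scenario import simulate_evidence
from conftest import evidence_frame, make_noise_free_scenario

CONDS = ("wt", "ko")
SWAP = {("exp1", 1): "wt", ("exp1", 2): "ko"}


class TestSplitAndMap:
    def test_partition_conserves_rows(self):
        ev = evidence_frame(
            [("exp1", 1, s, "P1", "AK", "light", 1.0) for s in (1, 2, 3)]
            + [("exp1", 1, s, "P1", "AK", "heavy", 2.0) for s in (1, 2)]
        )
        light, heavy = split_channels(ev)
        assert (len(light), len(heavy)) == (3, 2)
        merged = pd.concat([light, heavy]).sort_index()
        assert merged.equals(ev)

    def test_all_heavy_warns(self, caplog):
        ev = evidence_frame([("exp1", 1, 1, "P1", "AK", "heavy", 1.0)])
        with caplog.at_level("WARNING"):
            light, heavy = split_channels(ev)
        assert light.empty and len(heavy) == 1
        assert any("empty" in r.message for r in caplog.records)

    def test_swap_map_assigns_conditions(self):
        ev = evidence_frame(
            [
                ("exp1", 1, 1, "P1", "AK", "heavy", 1.0),
                ("exp1", 1, 1, "P1", "AK", "light", 1.0),
                ("exp1", 2, 1, "P1", "AK", "heavy", 1.0),
                ("exp1", 2, 1, "P1", "AK", "light", 1.0),
            ]
        )
        mapped = map_channels_to_conditions(ev, SWAP, CONDS)
        assert list(mapped["condition"]) == ["wt", "ko", "ko", "wt"]

    def test_unmapped_replicate_errors(self):
        ev = evidence_frame([("exp1", 3, 1, "P1", "AK", "heavy", 1.0)])
        with pytest.raises(KeyError, match="3"):
            map_channels_to_conditions(ev, SWAP, CONDS)


class TestRepresentativePeptide:
    def test_both_channel_requirement_beats_frequency(self):
        """A (5 cells, both channels) wins over B (7 cells, light only)."""
        rows = [
            ("exp1", 1, 1, "P1", "AAAK", "light", 10.0),
            ("exp1", 1, 2, "P1", "AAAK", "light", 10.0),
            ("exp1", 1, 1, "P1", "AAAK", "heavy", 10.0),
            ("exp1", 2, 1, "P1", "AAAK", "light", 10.0),
            ("exp1", 2, 1, "P1", "AAAK", "heavy", 10.0),
        ] + [("exp1", 1, s, "P1", "CCCK", "light", 50.0) for s in range(1, 8)]
        pep, diag = select_representative_peptide(evidence_frame(rows))
        assert pep == "AAAK"
        assert diag["n_cells"] == 5
        assert not diag["single_channel_representative"]

    def test_tie_broken_by_summed_intensity(self):
        rows = []
        for s in range(1, 5):
            for chan in ("light", "heavy"):
                rows.append(("exp1", 1, s, "P1", "AAAK", chan, 900 / 8))
                rows.append(("exp1", 1, s, "P1", "BBBK", chan, 1000 / 8))
        pep, _ = select_representative_peptide(evidence_frame(rows))
        assert pep == "BBBK"

    def test_equal_count_and_sum_breaks_lexicographically(self):
        rows = [
            ("exp1", 1, 1, "P1", "ZK", "light", 5.0),
            ("exp1", 1, 1, "P1", "ZK", "heavy", 5.0),
            ("exp1", 1, 1, "P1", "AK", "light", 5.0),
            ("exp1", 1, 1, "P1", "AK", "heavy", 5.0),
        ]
        pep, _ = select_representative_peptide(evidence_frame(rows))
        assert pep == "AK"

    def test_single_channel_fallback_flag(self):
        rows = [
            ("exp1", 1, s, "P1", "AAAK", "light", 1.0) for s in (1, 2, 3)
        ] + [("exp1", 1, 1, "P1", "BBBK", "light", 1.0)]
        pep, diag = select_representative_peptide(evidence_frame(rows))
        assert pep == "AAAK"
        assert diag["single_channel_representative"]

    def test_no_rows_errors(self):
        with pytest.raises(ValueError):
            select_representative_peptide(evidence_frame([]))


class TestProfiles:
    def test_raw_profile_places_and_sums_intensities(self):
        ev = map_channels_to_conditions(
            evidence_frame(
                [
                    ("exp1", 1, 10, "P1", "AK", "heavy", 200.0),
                    ("exp1", 1, 11, "P1", "AK", "heavy", 600.0),
                    ("exp1", 1, 11, "P1", "AK", "heavy", 50.0),  # re-measurement
                    ("exp1", 1, 12, "P1", "OTHERK", "heavy", 99.0),
                ]
            ),
            SWAP,
            CONDS,
        )
        prof = build_raw_profile("P1", "wt", "AK", ev, replicate=1, n_slices=16)
        expected = np.zeros(16)
        expected[9], expected[10] = 200.0, 650.0
        np.testing.assert_array_equal(prof.values, expected)

    def test_absent_condition_gives_zero_vector(self):
        ev = map_channels_to_conditions(
            evidence_frame([("exp1", 1, 1, "P1", "AK", "heavy", 1.0)]), SWAP, CONDS
        )
        prof = build_raw_profile("P1", "ko", "AK", ev, replicate=1, n_slices=4)
        assert not prof.values.any()

    @pytest.mark.parametrize(
        "reps, expected",
        [
            ([[2, 4, 0], [4, 8, 0]], [0.5, 1.0, 0.0]),
            ([[0, 5]], [0.0, 1.0]),
        ],
    )
    def test_average_then_normalize(self, reps, expected):
        profs = [MigrationProfile("P1", "wt", r) for r in reps]
        out = average_and_normalize(profs)
        np.testing.assert_allclose(out.values, expected)
        assert out.normalized

    def test_all_zero_replicates_flagged_undetected(self):
        out = average_and_normalize(
            [MigrationProfile("P1", "wt", [0, 0]), MigrationProfile("P1", "wt", [0, 0])]
        )
        assert "undetected" in out.flags
        assert not out.values.any()

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_and_normalize(
                [MigrationProfile("P1", "wt", [0, 1]), MigrationProfile("P1", "wt", [0, 1, 2])]
            )

    def test_every_detected_profile_has_max_exactly_one(self, default_run):
        for prof in default_run["profiles"].values():
            if "undetected" not in prof.flags:
                assert prof.values.max() == 1.0


class TestProteinRatio:
    def _mapped(self, rows):
        return map_channels_to_conditions(evidence_frame(rows), SWAP, CONDS)

    def test_five_to_one(self):
        rows = []
        for rep, chan_wt, chan_ko in ((1, "heavy", "light"), (2, "light", "heavy")):
            for s, wt_i, ko_i in ((1, 60.0, 12.0), (2, 40.0, 8.0)):
                rows.append(("exp1", rep, s, "P1", "AK", chan_wt, wt_i))
                rows.append(("exp1", rep, s, "P1", "AK", chan_ko, ko_i))
        r = protein_ratio("P1", self._mapped(rows), CONDS)
        assert r.per_replicate_ratios == [pytest.approx(5.0), pytest.approx(5.0)]
        assert r.ratio == pytest.approx(5.0)

    def test_equal_sums_give_unity(self):
        rows = [
            ("exp1", 1, 1, "P1", "AK", "heavy", 7.0),
            ("exp1", 1, 1, "P1", "AK", "light", 7.0),
            ("exp1", 2, 1, "P1", "AK", "heavy", 3.0),
            ("exp1", 2, 1, "P1", "AK", "light", 3.0),
        ]
        assert protein_ratio("P1", self._mapped(rows), CONDS).ratio == pytest.approx(1.0)

    def test_geometric_mean_across_replicates(self):
        rows = [
            ("exp1", 1, 1, "P1", "AK", "heavy", 8.0),   # wt
            ("exp1", 1, 1, "P1", "AK", "light", 2.0),   # ko -> ratio 4
            ("exp1", 2, 1, "P1", "AK", "light", 9.0),   # wt
            ("exp1", 2, 1, "P1", "AK", "heavy", 9.0),   # ko -> ratio 1
        ]
        assert protein_ratio("P1", self._mapped(rows), CONDS).ratio == pytest.approx(2.0)

    def test_absent_in_perturbed_flag(self):
        rows = [
            ("exp1", 1, 1, "P1", "AK", "heavy", 5.0),
            ("exp1", 2, 1, "P1", "AK", "light", 5.0),
        ]
        r = protein_ratio("P1", self._mapped(rows), CONDS)
        assert r.ratio is None
        assert r.flag == ABSENT_IN_PERTURBED

    def test_missing_protein_errors(self):
        rows = [("exp1", 1, 1, "P1", "AK", "heavy", 5.0)]
        with pytest.raises(ValueError, match="P2"):
            protein_ratio("P2", self._mapped(rows), CONDS)

    def test_noise_free_unchanged_protein_is_exactly_one(self, noise_free_scenario):
        sc = noise_free_scenario
        mapped = map_channels_to_conditions(
            simulate_evidence(sc, seed=1), sc.swap_map(), sc.conditions
        )
        r = protein_ratio("P3", mapped, sc.conditions)  # pool: wt == ko
        assert r.ratio == 1.0


class TestOracleEquivalence:
    """Profiles must equal a brute-force group-and-sum on small random tables."""

    @staticmethod
    def brute_force_profile(evidence, pid, pep, condition, replicates, n_slices):
        per_rep = []
        for rep in replicates:
            v = [0.0] * n_slices
            for row in evidence.itertuples():
                if (
                    row.protein_id == pid
                    and row.peptide_sequence == pep
                    and row.condition == condition
                    and row.replicate == rep
                ):
                    v[row.slice_index - 1] += row.intensity
            per_rep.append(v)
        mean = [sum(col) / len(per_rep) for col in zip(*per_rep)]
        peak = max(mean)
        return [x / peak for x in mean] if peak > 0 else mean

    @pytest.mark.parametrize("table_seed", range(5))
    def test_matches_brute_force(self, table_seed):
        rng = np.random.default_rng(table_seed)
        n = int(rng.integers(10, 51))
        rows = [
            (
                "exp1",
                int(rng.integers(1, 3)),
                int(rng.integers(1, 9)),
                f"P{rng.integers(1, 4)}",
                rng.choice(["AK", "CK", "DK"]),
                rng.choice(["light", "heavy"]),
                float(rng.integers(1, 100)),
            )
            for _ in range(n)
        ]
        mapped = map_channels_to_conditions(evidence_frame(rows), SWAP, CONDS)
        profiles = condition_profiles(mapped, CONDS, n_slices=8)
        for (pid, cond), prof in profiles.items():
            expected = self.brute_force_profile(
                mapped, pid, prof.source_peptide, cond, [1, 2], 8
            )
            np.testing.assert_array_equal(prof.values, expected)

    def test_row_order_never_matters(self):
        rng = np.random.default_rng(42)
        rows = [
            (
                "exp1",
                int(rng.integers(1, 3)),
                int(rng.integers(1, 9)),
                f"P{rng.integers(1, 4)}",
                rng.choice(["AK", "CK"]),
                rng.choice(["light", "heavy"]),
                float(rng.integers(1, 100)),
            )
            for _ in range(40)
        ]
        ev = evidence_frame(rows)
        shuffled = ev.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = condition_profiles(map_channels_to_conditions(ev, SWAP, CONDS), CONDS, 8)
        b = condition_profiles(map_channels_to_conditions(shuffled, SWAP, CONDS), CONDS, 8)
        assert a.keys() == b.keys()
        for key in a:
            np.testing.assert_array_equal(a[key].values, b[key].values)
            assert a[key].source_peptide == b[key].source_peptide


class TestMixingFidelity:
    def test_unchanged_proteins_near_unity_at_default_noise(self, default_scenario):
        """cII subunit all-peptide ratios stay within 10% of 1 for >=95% of cases.

        The single-representative-peptide ratio carries ~10% sampling noise
        at the default measurement error, so the tight band is checked on
        the all-peptide estimator; the representative-only default is
        checked at a correspondingly looser band below.
        """
        from complexome.scenario import CII_SUBUNITS

        sc = default_scenario
        all_pep, rep_only = [], []
        for seed in range(101, 121):
            mapped = map_channels_to_conditions(
                simulate_evidence(sc, seed=seed), sc.swap_map(), sc.conditions
            )
            for pid in CII_SUBUNITS:
                all_pep.append(
                    protein_ratio(pid, mapped, sc.conditions, all_peptides=True).ratio
                )
                rep_only.append(protein_ratio(pid, mapped, sc.conditions).ratio)
        assert len(all_pep) == 4 * 20
        assert sum(0.9 <= x <= 1.1 for x in all_pep) / len(all_pep) >= 0.95
        assert sum(0.8 <= x <= 1.25 for x in rep_only) / len(rep_only) >= 0.95
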