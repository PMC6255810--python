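import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phosphonet import phospho
from phosphonet.phospho import (
    ConfigurationError,
    adjust_fold_change_signs,
    compute_site_fold_changes,
    representative_site_per_protein,
    summarize_venn,
    treatment_response_sets,
)


def signals_table(rows):
    return pd.DataFrame(rows, columns=["protein", "site", "condition", "signal"])


class TestComputeSiteFoldChanges:
    def test_identity_signal_gives_zero(self):
        records = signals_table([
            ("AKT1", "S473", "CTRL", 100.0),
            ("AKT1", "S473", "BMP8", 100.0),
        ])
        out = compute_site_fold_changes(records, "CTRL", ["BMP8"])
        assert out.loc[0, "log2fc"] == 0.0

    def test_doubling_gives_one(self):
        records = signals_table([
            ("AKT1", "S473", "CTRL", 50.0),
            ("AKT1", "S473", "BMP8", 100.0),
        ])
        out = compute_site_fold_changes(records, "CTRL", ["BMP8"])
        assert out.loc[0, "log2fc"] == pytest.approx(1.0)

    def test_random_fixture_matches_log_ratio_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        expected = {}
        for i in range(5):
            protein, site = f"P{i}", f"S{i + 1}"
            ctrl = float(rng.uniform(10, 1000))
            trt = float(rng.uniform(10, 1000))
            rows += [(protein, site, "CTRL", ctrl), (protein, site, "BMP8", trt)]
            expected[(protein, site)] = math.log2(trt / ctrl)
        out = compute_site_fold_changes(signals_table(rows), "CTRL", ["BMP8"])
        for row in out.itertuples(index=False):
            assert row.log2fc == pytest.approx(expected[(row.protein, row.site)], abs=1e-12)

    def test_replicates_averaged_before_ratio(self):
        records = signals_table([
            ("AKT1", "S473", "CTRL", 40.0),
            ("AKT1", "S473", "CTRL", 60.0),
            ("AKT1", "S473", "BMP8", 100.0),
        ])
        out = compute_site_fold_changes(records, "CTRL", ["BMP8"])
        assert out.loc[0, "log2fc"] == pytest.approx(math.log2(100 / 50))

    def test_zero_control_dropped(self):
        records = signals_table([
            ("AKT1", "S473", "CTRL", 0.0),
            ("AKT1", "S473", "BMP8", 100.0),
            ("TP53", "S15", "CTRL", 10.0),
            ("TP53", "S15", "BMP8", 20.0),
        ])
        out = compute_site_fold_changes(records, "CTRL", ["BMP8"])
        assert list(out["protein"]) == ["TP53"]

    def test_unknown_condition_label_raises(self):
        records = signals_table([("AKT1", "S473", "CTRL", 1.0)])
        with pytest.raises(ConfigurationError, match="NOSUCH"):
            compute_site_fold_changes(records, "CTRL", ["NOSUCH"])

    def test_empty_table_gives_empty_output(self):
        out = compute_site_fold_changes(signals_table([]), "CTRL", ["BMP8"])
        assert out.empty and list(out.columns) == phospho.FC_COLUMNS


class TestAdjustSigns:
    @pytest.fixture
    def fcs(self):
        return pd.DataFrame({
            "protein": ["AKT1", "AKT1", "TP53", "XYZ1"],
            "site": ["S473", "T308", "S15", "S1"],
            "treatment": ["BMP8"] * 4,
            "log2fc": [1.68, 1.68, 2.3, 0.5],
        })

    def test_activating_preserves_sign(self, fcs, effects_table):
        out = adjust_fold_change_signs(fcs, effects_table)
        row = out[(out["protein"] == "AKT1") & (out["site"] == "S473")]
        assert row["adjusted_log2fc"].iloc[0] == pytest.approx(1.68)

    def test_inhibitory_flips_sign(self, fcs, effects_table):
        out = adjust_fold_change_signs(fcs, effects_table)
        row = out[(out["protein"] == "AKT1") & (out["site"] == "T308")]
        assert row["adjusted_log2fc"].iloc[0] == pytest.approx(-1.68)

    def test_unknown_sign_excluded(self, fcs, effects_table):
        out = adjust_fold_change_signs(fcs, effects_table)
        assert "TP53" not in set(out["protein"])

    def test_missing_effect_record_excluded_and_counted(self, fcs, effects_table):
        out = adjust_fold_change_signs(fcs, effects_table)
        assert "XYZ1" not in set(out["protein"])
        assert out.attrs["n_excluded"] == 2  # TP53 unknown + XYZ1 missing

    @given(
        values=st.lists(
            st.floats(-5, 5, allow_nan=False).filter(lambda x: x != 0), min_size=1, max_size=20
        ),
        signs=st.lists(st.sampled_from([1, -1, 0]), min_size=20, max_size=20),
    )
    def test_involution_and_magnitude_preserved(self, values, signs):
        n = len(values)
        fcs = pd.DataFrame({
            "protein": [f"P{i}" for i in range(n)],
            "site": [f"S{i + 1}" for i in range(n)],
            "treatment": ["T"] * n,
            "log2fc": values,
        })
        effects = pd.DataFrame({
            "protein": [f"P{i}" for i in range(n)],
            "site": [f"S{i + 1}" for i in range(n)],
            "sign": signs[:n],
        })
        out = adjust_fold_change_signs(fcs, effects)
        # magnitude preserved on every kept row
        assert np.allclose(out["adjusted_log2fc"].abs(), out["log2fc"].abs())
        # unknown-sign rows are exactly the excluded ones
        assert len(out) == sum(1 for s in signs[:n] if s != 0)
        # flipping twice restores the raw value
        twice = out.copy()
        twice["log2fc"] = twice["adjusted_log2fc"]
        out2 = adjust_fold_change_signs(twice.drop(columns="adjusted_log2fc"), effects)
        assert np.allclose(out2["adjusted_log2fc"], out["log2fc"])


class TestRepresentativeSite:
    def test_single_site_retained(self):
        fcs = pd.DataFrame({
            "protein": ["AKT1"], "site": ["S473"], "treatment": ["BMP8"], "log2fc": [0.4],
        })
        out = representative_site_per_protein(fcs)
        assert list(out["site"]) == ["S473"]

    def test_max_abs_rule(self):
        fcs = pd.DataFrame({
            "protein": ["P"] * 3, "site": ["S1", "S2", "S3"],
            "treatment": ["T"] * 3, "log2fc": [0.2, -1.5, 0.9],
        })
        out = representative_site_per_protein(fcs)
        assert list(out["site"]) == ["S2"]

    def test_tie_breaks_lexicographic(self):
        fcs = pd.DataFrame({
            "protein": ["P"] * 2, "site": ["S9", "S2"],
            "treatment": ["T"] * 2, "log2fc": [1.0, -1.0],
        })
        out = representative_site_per_protein(fcs)
        assert list(out["site"]) == ["S2"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(50):
            for s in range(rng.integers(1, 5)):
                for t in ("A", "B"):
                    rows.append((f"P{i:02d}", f"S{s + 1}", t, float(rng.normal(0, 2))))
        fcs = pd.DataFrame(rows, columns=["protein", "site", "treatment", "log2fc"])
        out = representative_site_per_protein(fcs)
        for (protein, treatment), group in fcs.groupby(["protein", "treatment"]):
            best = group.assign(a=group["log2fc"].abs()).sort_values(
                ["a", "site"], ascending=[False, True]
            ).iloc[0]
            got = out[(out["protein"] == protein) & (out["treatment"] == treatment)]
            assert len(got) == 1
            assert got["site"].iloc[0] == best["site"]

    def test_one_row_per_protein_treatment(self, small_fcs):
        out = representative_site_per_protein(small_fcs)
        pairs = set(zip(small_fcs["protein"], small_fcs["treatment"]))
        assert len(out) == len(pairs)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            representative_site_per_protein(pd.DataFrame(columns=phospho.FC_COLUMNS))


def adjusted_table(rows):
    df = pd.DataFrame(rows, columns=["protein", "site", "treatment", "adjusted_log2fc"])
    df["log2fc"] = df["adjusted_log2fc"]
    return df


class TestTreatmentResponseSets:
    def test_exclusive_up_membership(self):
        fcs = adjusted_table([("P1", "S1", "BMP8", math.log2(2.5))])
        venn = treatment_response_sets(fcs, 2.0, treatments=("BMP8", "NE"))
        assert venn.membership["up"][("BMP8",)] == {"P1"}
        assert venn.membership["up"][("NE",)] == set()

    def test_half_ratio_is_down(self):
        fcs = adjusted_table([("P1", "S1", "NE", math.log2(0.4))])
        venn = treatment_response_sets(fcs, 2.0)
        assert venn.membership["down"][("NE",)] == {"P1"}

    def test_threshold_at_most_one_rejected(self):
        fcs = adjusted_table([("P1", "S1", "NE", 1.0)])
        with pytest.raises(ConfigurationError):
            treatment_response_sets(fcs, 1.0)

    def test_subthreshold_table_gives_empty_sets(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"P{i}", "S1", t, float(rng.uniform(-0.99, 0.99)))
            for i in range(20) for t in ("A", "B")
        ]
        venn = treatment_response_sets(adjusted_table(rows), 2.0)
        assert venn.universe("up") == set() and venn.universe("down") == set()

    def test_planted_memberships_match_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        treatments = ("BMP8", "BMP8_NE", "NE")
        rows = []
        for i in range(12):
            for t in treatments:
                for s in range(2):
                    rows.append((f"P{i:02d}", f"S{s + 1}", t, float(rng.normal(0, 1.2))))
        fcs = adjusted_table(rows)
        venn = treatment_response_sets(fcs, 2.0, treatments=treatments)
        # oracle: brute force over proteins x treatments; dominant site decides
        # the direction when both directions pass
        direction_of = {}
        for protein in fcs["protein"].unique():
            for t in treatments:
                sub = fcs[(fcs["protein"] == protein) & (fcs["treatment"] == t)]
                passing = [
                    (abs(v), s, v) for s, v in zip(sub["site"], sub["adjusted_log2fc"])
                    if abs(v) >= 1.0
                ]
                if passing:
                    passing.sort(key=lambda x: (-x[0], x[1]))
                    direction_of[(protein, t)] = "up" if passing[0][2] > 0 else "down"
        for direction in ("up", "down"):
            expected = {}
            for protein in fcs["protein"].unique():
                hit = tuple(
                    t for t in treatments if direction_of.get((protein, t)) == direction
                )
                if hit:
                    expected.setdefault(hit, set()).add(protein)
            for combo, members in venn.membership[direction].items():
                assert members == expected.get(combo, set())

    def test_up_down_disjoint_and_union_complete(self):
        rng = np.random.default_rng(9)
        rows = [
            (f"P{i}", f"S{s + 1}", t, float(rng.normal(0, 1.5)))
            for i in range(30) for s in range(3) for t in ("A", "B")
        ]
        fcs = adjusted_table(rows)
        venn = treatment_response_sets(fcs, 2.0)
        for t in ("A", "B"):
            up_t = {p for c, m in venn.membership["up"].items() if t in c for p in m}
            down_t = {p for c, m in venn.membership["down"].items() if t in c for p in m}
            assert up_t & down_t == set()
        passing = set(fcs.loc[fcs["adjusted_log2fc"].abs() >= 1.0, "protein"])
        assert venn.universe("up") | venn.universe("down") == passing


class TestSummarizeVenn:
    def test_empty_sets_all_zero(self):
        venn = treatment_response_sets(adjusted_table([("P", "S1", "A", 0.0)]), 2.0)
        table = summarize_venn(venn)
        assert (table["count"] == 0).all()

    def test_counts_equal_manual_tally(self):
        rows = [
            ("P1", "S1", "A", 1.5), ("P2", "S1", "A", 1.5), ("P2", "S1", "B", 2.0),
            ("P3", "S1", "B", -1.2),
        ]
        venn = treatment_response_sets(adjusted_table(rows), 2.0, treatments=("A", "B"))
        table = summarize_venn(venn).set_index(["direction", "field"])["count"]
        assert table[("up", "A")] == 1        # P1 only in A
        assert table[("up", "A+B")] == 1      # P2 in both
        assert table[("down", "B")] == 1      # P3
        assert table[("up", "TOTAL")] == 2
        assert table[("down", "TOTAL")] == 1

    def test_totals_are_field_sums(self, synth_bundle):
        outdir, truth, _ = synth_bundle
        import phosphonet.io as pio
        from phosphonet.phospho import compute_site_fold_changes

        records = pio.read_phospho_signals(outdir / "phospho_signals.tsv")
        effects = pio.read_effects(outdir / "effects.tsv")
        fcs = compute_site_fold_changes(records, "CONTROL", ["BMP8", "BMP8_NE", "NE"])
        adjusted = adjust_fold_change_signs(fcs, effects)
        venn = treatment_response_sets(adjusted, 2.0)
        table = summarize_venn(venn).set_index(["direction", "field"])["count"]
        for direction in ("up", "down"):
            fields = [
                v for (d, f), v in table.items() if d == direction and f != "TOTAL"
            ]
            assert table[(direction, "TOTAL")] == sum(fields)
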