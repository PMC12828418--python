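"""Product filtering, exact-mass merging, cumulative selection and EIC targets."""

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_mass
from ppepkit.library import NON_PRIME_DESIGN, product_database
from ppepkit.quantify import (
    MergedProduct,
    annotate_isomers_by_rt,
    eic_target_table,
    eic_targets,
    exact_mass_collisions,
    filter_products,
    mass_key,
    merge_isobaric,
    select_top_cumulative,
)


def row(sequence, abundance=10.0, biotin=False, side="unknown", rt=20.0):
    return {
        "sequence": sequence,
        "side": side,
        "abundance": abundance,
        "retention_time": rt,
        "has_biotin": biotin,
    }


def make_product(side, sequences, abundance, rt=20.0):
    members = tuple(sorted(sequences))
    rep = []
    for col in zip(*members):
        letters = sorted(set(col))
        rep.append(letters[0] if len(letters) == 1 else "[" + "".join(letters) + "]")
    return MergedProduct(
        side=side,
        mass_key=mass_key(members[0]),
        member_sequences=members,
        representative="".join(rep),
        abundance=abundance,
        retention_time=rt,
    )


class TestFilterProducts:
    def test_keeps_valid_nine_mers_and_assigns_side(self):
        table = pd.DataFrame(
            [
                row("PTEDAVLIP"),
                row("PLPGGLEEF"),
                row("TEDAVLIP"),  # 8-mer
                row("PTEDAVLIPP"),  # 10-mer
                row("PTEDAVLIP", biotin=True),
                row("PAAAAAAAP"),  # no anchor
            ]
        )
        out = filter_products(table)
        assert list(out["sequence"]) == ["PTEDAVLIP", "PLPGGLEEF"]
        assert list(out["side"]) == ["non_prime", "prime"]

    def test_idempotent(self):
        table = pd.DataFrame([row("PTEDAVLIP"), row("PHPGGLEEF")])
        once = filter_products(table)
        twice = filter_products(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_both_anchors_is_malformed_input(self):
        table = pd.DataFrame([row("PTEDAVGGLEEF")])
        with pytest.raises(ValueError, match="both"):
            filter_products(table)

    def test_empty_output_allowed(self):
        out = filter_products(pd.DataFrame([row("AAAA")]))
        assert out.empty


class TestMergeIsobaric:
    def test_leu_ile_pair_kept_once(self):
        # The engine lists the combined abundance for each isobaric member.
        table = pd.DataFrame(
            [
                row("PLPGGLEEF", 40.0, side="prime"),
                row("PIPGGLEEF", 40.0, side="prime"),
            ]
        )
        merged = merge_isobaric(table)
        assert len(merged) == 1
        (product,) = merged
        assert product.abundance == 40.0
        assert product.member_sequences == ("PIPGGLEEF", "PLPGGLEEF")
        assert product.representative == "P[IL]PGGLEEF"

    def test_distinct_masses_stay_separate(self):
        table = pd.DataFrame(
            [row("PTEDAVGGP", 5.0, side="non_prime"),
             row("PTEDAVWWP", 7.0, side="non_prime")]
        )
        merged = merge_isobaric(table)
        assert len(merged) == 2
        assert {p.abundance for p in merged} == {5.0, 7.0}

    def test_inconsistent_abundances_rejected(self):
        table = pd.DataFrame(
            [row("PLPGGLEEF", 40.0, side="prime"),
             row("PIPGGLEEF", 41.0, side="prime")]
        )
        with pytest.raises(ValueError, match="inconsistent"):
            merge_isobaric(table)

    def test_gly_glu_vs_ala_asp_collision(self):
        # G+E and A+D residue pairs are elementally identical.
        seqs = ["PTEDAVGEP", "PTEDAVEGP", "PTEDAVADP", "PTEDAVDAP"]
        table = pd.DataFrame([row(s, 12.0, side="non_prime") for s in seqs])
        merged = merge_isobaric(table)
        assert len(merged) == 1
        assert len(merged[0].member_sequences) == 4

    def test_partition_property(self):
        products = product_database(NON_PRIME_DESIGN)
        by_mass = defaultdict(list)
        for p in products:
            by_mass[mass_key(p.sequence)].append(p.sequence)
        table = pd.DataFrame(
            [row(p.sequence, float(10 + len(by_mass[mass_key(p.sequence)])),
                 side="non_prime") for p in products]
        )
        merged = merge_isobaric(table)
        assert sum(len(m.member_sequences) for m in merged) == 361
        assert len(merged) == len(by_mass)

    def test_collisions_match_bruteforce_pair_mass_oracle(self):
        sequences = [p.sequence for p in product_database(NON_PRIME_DESIGN)]
        oracle_groups = defaultdict(set)
        for seq in sequences:  # independent mass table
            oracle_groups[round(oracle_mass(seq), 3)].add(seq)
        oracle = {frozenset(v) for v in oracle_groups.values() if len(v) > 1}
        ours = {frozenset(g) for g in exact_mass_collisions(sequences)}
        assert ours == oracle


class TestSelectTopCumulative:
    def test_strict_ninety_percent_rule(self):
        products = [
            make_product("non_prime", [f"PTEDAV{aa}GP"], ab)
            for aa, ab in zip("LFIV", [50.0, 30.0, 15.0, 5.0])
        ]
        selected = select_top_cumulative(products, 0.90)
        assert [p.abundance for p in selected] == [50.0, 30.0, 15.0]

    def test_single_product(self):
        products = [make_product("prime", ["PPPGGLEEF"], 3.0)]
        assert select_top_cumulative(products) == products

    def test_ten_equal_products_all_selected(self):
        # Nine of ten give exactly 0.90, which does not strictly exceed it.
        products = [
            make_product("non_prime", [f"PTEDAV{aa}GP"], 10.0)
            for aa in "LFIVMAHQW"
        ] + [make_product("non_prime", ["PTEDAVGGP"], 10.0)]
        assert len(select_top_cumulative(products, 0.90)) == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_top_cumulative([], 0.9)

    @given(
        abundances=st.lists(
            st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=30
        ),
        fraction=st.floats(min_value=0.0, max_value=0.99),
    )
    @settings(max_examples=100, derandomize=True)
    def test_prefix_minimality(self, abundances, fraction):
        products = [
            make_product("non_prime", [f"PTEDAV{a}{b}P"], ab)
            for (a, b), ab in zip(
                ((x, y) for x in "ACDEFGHIKLMNPQRSTVWY" for y in "ADEFGH"),
                abundances,
            )
        ]
        selected = select_top_cumulative(products, fraction)
        total = sum(p.abundance for p in products)
        share = sum(p.abundance for p in selected) / total
        assert share > fraction
        if len(selected) > 1:
            assert (share - selected[-1].abundance / total) <= fraction + 1e-12


class TestEicTargets:
    def test_two_targets_per_unique_mass(self):
        products = [
            make_product("non_prime", ["PTEDAVLGP"], 5.0),
            make_product("non_prime", ["PTEDAVWFP"], 5.0),
        ]
        targets = eic_targets(products)
        assert len(targets) == 4
        assert {t.charge for t in targets} == {1, 2}
        assert all(t.tol_ppm == 5.0 for t in targets)

    def test_major_product_mz_values(self):
        products = [make_product("non_prime", ["PTEDAVLIP", "PTEDAVLLP"], 100.0)]
        targets = {t.charge: t for t in eic_targets(products)}
        assert targets[1].mz == pytest.approx(954.5142, abs=1e-4)
        assert targets[2].mz == pytest.approx(477.7608, abs=1e-4)
        low, high = targets[1].window
        assert high - low == pytest.approx(2 * 954.5142 * 5e-6, abs=1e-6)

    def test_duplicate_mass_keys_collapse(self):
        products = [
            make_product("non_prime", ["PTEDAVLIP"], 10.0),
            make_product("non_prime", ["PTEDAVILP"], 10.0),  # same mass
        ]
        assert len(eic_targets(products)) == 2  # one mass x two charges

    def test_target_table_columns(self):
        products = [make_product("prime", ["PPPGGLEEF"], 10.0)]
        frame = eic_target_table(products)
        assert list(frame["charge"]) == [1, 2]
        assert (frame["window_low"] < frame["mz"]).all()
        assert (frame["mz"] < frame["window_high"]).all()

    def test_empty_products_rejected(self):
        with pytest.raises(ValueError):
            eic_targets([])


class TestAnnotateIsomersByRt:
    STANDARDS = [
        ("PTEDAVIIP", 20.0),
        ("PTEDAVILP", 21.0),
        ("PTEDAVLIP", 22.0),
        ("PTEDAVLLP", 23.0),
    ]

    def test_identity_assignment(self):
        key = mass_key("PTEDAVLIP")
        observed = [(key, rt) for _, rt in self.STANDARDS]
        out = annotate_isomers_by_rt(observed, self.STANDARDS)
        assert list(out["assigned_sequence"]) == [s for s, _ in self.STANDARDS]

    def test_major_signal_assigned_to_nearest_standard(self):
        key = mass_key("PTEDAVLIP")
        out = annotate_isomers_by_rt([(key, 22.05)], self.STANDARDS)
        assert out.loc[0, "assigned_sequence"] == "PTEDAVLIP"

    def test_far_signal_left_unassigned(self):
        key = mass_key("PTEDAVLIP")
        out = annotate_isomers_by_rt([(key, 30.0)], self.STANDARDS)
        assert out.loc[0, "assigned_sequence"] is None

    def test_rank_order_without_standards(self):
        key = mass_key("PTEDAVLIP")
        out = annotate_isomers_by_rt([(key, 23.0), (key, 20.0), (key, 21.5)])
        assert list(out["elution_rank"]) == [1, 2, 3]
        assert out["retention_time"].is_monotonic_increasing
        assert out["assigned_sequence"].isna().all()

    def test_duplicate_standard_rts_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            annotate_isomers_by_rt(
                [(mass_key("PTEDAVLIP"), 20.0)],
                [("PTEDAVLIP", 20.0), ("PTEDAVILP", 20.0)],
            )

    def test_non_isobaric_standards_rejected(self):
        with pytest.raises(ValueError, match="isobaric"):
            annotate_isomers_by_rt(
                [(mass_key("PTEDAVLIP"), 20.0)],
                [("PTEDAVLIP", 20.0), ("PTEDAVWWP", 21.0)],
            )
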