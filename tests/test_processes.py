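import itertools

import numpy as np
import pytest

from bluecarbon import (
    CODES,
    LULCGrid,
    LULCSeries,
    chain_attribute,
    chain_category,
    generate_series,
    pixel_chain,
    process_table,
    sequestration,
    single_process_scenario,
    step_process,
)
from bluecarbon.processes import STEP_PAIRS, UNCLASSIFIED, category_map, chain_raster

from conftest import make_random_series


def one_pixel_series(codes, cell_size=100.0):
    grids = [
        LULCGrid(np.array([[c]]), cell_size=cell_size, date_label=f"t{k}")
        for k, c in enumerate(codes)
    ]
    return LULCSeries(grids)


class TestStepProcess:
    def test_every_ordered_pair_gets_exactly_one_step(self):
        seen = {}
        for a, b in itertools.product(CODES, CODES):
            seen[(a, b)] = step_process(a, b)
        assert len(seen) == 100
        counts = {s: sum(1 for v in seen.values() if v == s) for s in set(seen.values())}
        assert counts == {"A": 4, "S": 3, "Rs": 1, "E": 3, "R": 25, "Re": 25,
                          "Stable": 10, "U": 29}

    def test_step_sets_mutually_disjoint(self):
        for (s1, p1), (s2, p2) in itertools.combinations(STEP_PAIRS.items(), 2):
            assert not (p1 & p2), f"{s1} and {s2} overlap"

    @pytest.mark.parametrize(
        "a,b,step",
        [
            (1, 2, "A"),
            (5, 3, "A"),
            (2, 4, "S"),
            (3, 2, "Rs"),
            (4, 1, "E"),
            (3, 7, "R"),
            (8, 4, "Re"),
            (3, 3, "Stable"),
            (9, 6, "U"),  # absent from the taxonomy
            (2, 5, "U"),
        ],
    )
    def test_examples(self, a, b, step):
        assert step_process(a, b) == step

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="0"):
            step_process(0, 1)

    def test_user_extension_reassigns_pair(self):
        assert step_process(9, 6, extra_steps={(9, 6): "R"}) == "R"


class TestPixelChain:
    @pytest.mark.parametrize(
        "codes,label",
        [
            ((3, 7, 3, 9), "R-Re-R"),
            ((2, 2, 2, 2), "Stable"),
            ((1, 2, 1, 2), "A-E-A"),
            ((1, 2, 2, 3), "A-S"),  # stable middle interval dropped
            ((2, 3, 4, 4), "S"),    # consecutive S steps collapse
        ],
    )
    def test_examples(self, codes, label):
        assert pixel_chain(codes) == label

    def test_four_dates_never_exceed_three_steps(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            codes = rng.integers(1, 11, size=4)
            label = pixel_chain(codes)
            if label != "Stable":
                assert len(label.split("-")) <= 3


class TestChainAttributeAndCategory:
    @pytest.mark.parametrize(
        "chain,attr",
        [("Rs-E", "Natural"), ("R-Re-R", "Human"), ("E-R", "Natural-Human"),
         ("A", "Natural"), ("Re", "Human")],
    )
    def test_attribute(self, chain, attr):
        assert chain_attribute(chain) == attr

    def test_stable_has_no_attribute(self):
        with pytest.raises(ValueError, match="Stable"):
            chain_attribute("Stable")

    def test_unclassified_step_rejected(self):
        with pytest.raises(ValueError, match="unclassified"):
            chain_attribute("A-U")

    @pytest.mark.parametrize(
        "chain,dc,category",
        [
            ("A", 315009.94, "Mono+"),
            ("A-S", 381527.51, "Multiple+"),
            ("R", -141945.05, "Mono−"),
            ("Rs-R", -17943.62, "Multiple−"),
            ("Stable", 0.0, "Stable"),
            ("A-E", 0.0, "Neutral"),
        ],
    )
    def test_category(self, chain, dc, category):
        assert chain_category(chain, dc) == category


class TestProcessTable:
    def test_identical_series_has_no_records(self, density_table):
        series = one_pixel_series([2, 2, 2, 2])
        assert process_table(series, density_table) == []

    def test_single_pixel_accretion_succession_arithmetic(self, density_table):
        series = one_pixel_series([1, 2, 3, 3])
        (rec,) = process_table(series, density_table)
        assert rec.chain == "A-S"
        assert rec.total_dc == pytest.approx(32.4 - 14.0)
        assert rec.area_ha == pytest.approx(1.0)
        assert rec.magnitude == pytest.approx(18.4)
        assert rec.category == "Multiple+"
        assert rec.attribute == "Natural"

    def test_records_sum_to_full_period_sequestration(self, density_table):
        # stable pixels contribute zero carbon change, so the record totals
        # (unclassified chains included) account for the whole net change
        series = make_random_series(17, shape=(12, 12))
        records = process_table(series, density_table, include_unclassified=True)
        total = sum(r.total_dc for r in records)
        assert total == pytest.approx(
            sequestration(series[0], series[-1], density_table), abs=1e-9
        )

    def test_unclassified_chains_excluded_by_default(self, density_table):
        series = one_pixel_series([9, 6, 6, 6])  # 9->6 is not in the taxonomy
        assert process_table(series, density_table) == []
        (rec,) = process_table(series, density_table, include_unclassified=True)
        assert rec.attribute == "Unclassified"

    @pytest.mark.parametrize(
        "process,letter,attr",
        [
            ("accretion", "A", "Natural"),
            ("succession", "S", "Natural"),
            ("regressive_succession", "Rs", "Natural"),
            ("erosion", "E", "Natural"),
            ("reclamation", "R", "Human"),
            ("restoration", "Re", "Human"),
        ],
    )
    def test_generator_recovery_single_process(self, process, letter, attr, density_table):
        series = generate_series(single_process_scenario(process, 0.4, seed=33))
        records = process_table(series, density_table)
        assert records, f"no {process} transitions generated"
        assert [r.chain for r in records] == [letter]
        assert records[0].attribute == attr
        sign = "+" if records[0].total_dc > 0 else "−"
        kind = "Mono" if records[0].category.startswith("Mono") else "Multiple"
        assert records[0].category == f"{kind}{sign}"
        assert kind == "Mono"


class TestCategoryMap:
    def test_per_cell_signs_and_stable(self, density_table):
        cells = [
            np.array([[1, 3, 5]]),
            np.array([[2, 7, 5]]),
            np.array([[2, 3, 5]]),
            np.array([[2, 9, 5]]),
        ]
        series = LULCSeries(
            [LULCGrid(c, cell_size=100.0, date_label=f"t{k}") for k, c in enumerate(cells)]
        )
        cats, legend = category_map(series, density_table)
        names = {v: k for k, v in legend.items()}
        assert cats[0, 0] == names["Mono+"]      # 1->2, dC = +4.4
        assert cats[0, 1] == names["Multiple−"]  # 3->7->3->9, dC = 8.0-32.4
        assert cats[0, 2] == names["Stable"]

    def test_chain_raster_codebook_round_trip(self, density_table):
        series = make_random_series(23, shape=(8, 8))
        raster, codebook = chain_raster(series)
        assert codebook[0] == "Stable"
        assert set(np.unique(raster)) <= set(codebook)
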