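"""Inventory ingest: cycle coding, panel assembly, and summaries."""

import numpy as np
import pandas as pd
import pytest

from invascape.errors import InvalidDomainError, SchemaError
from invascape.ingest import (
    SubplotPanel,
    assign_cycle,
    binary_presence,
    build_panel,
    categorical_cover_fraction,
    infestation_summary_from_counts,
    read_tables,
    select_major_species,
    summarize_infestation,
)
from invascape.synthetic import write_fia_tables
from invascape.units import grid_partition


class TestAssignCycle:
    @pytest.mark.parametrize(
        "year, cycle",
        [
            (2001, "T1"),
            (2005, "T1"),
            (2006, "T2"),
            (2012, "T2"),
            (2013, "T3"),
            (2019, "T3"),
            (2000, None),
            (2020, None),
        ],
    )
    def test_year_windows(self, year, cycle):
        assert assign_cycle(year) == cycle

    def test_pre_1990_rejected(self):
        with pytest.raises(InvalidDomainError):
            assign_cycle(1985)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadTables:
    def test_out_of_range_cover_is_quarantined(self, tmp_path):
        occ = _write(
            tmp_path,
            "occ.csv",
            "PLT_CN,SUBP,VEG_SPCD,COVER_PCT,INVYR\n"
            "p1,1,LOJA,5,2003\np1,2,LOJA,150,2003\np2,1,LIGUS2,30,2003\n",
        )
        plot = _write(tmp_path, "plot.csv", "PLT_CN,X,Y,INVYR\np1,0,0,2003\n")
        records, _, _, report = read_tables(occ, plot)
        assert len(records) == 2
        assert report["quarantined_cover"] == 1
        assert len(report["quarantine"]) == 1

    def test_empty_occurrence_file_warns(self, tmp_path):
        occ = _write(tmp_path, "occ.csv", "PLT_CN,SUBP,VEG_SPCD,COVER_PCT,INVYR\n")
        plot = _write(tmp_path, "plot.csv", "PLT_CN,X,Y,INVYR\np1,0,0,2003\n")
        with pytest.warns(UserWarning, match="empty"):
            records, _, _, _ = read_tables(occ, plot)
        assert records.empty

    def test_missing_column_is_named(self, tmp_path):
        occ = _write(tmp_path, "occ.csv", "PLT_CN,SUBP,COVER_PCT,INVYR\n")
        plot = _write(tmp_path, "plot.csv", "PLT_CN,X,Y,INVYR\n")
        with pytest.raises(SchemaError, match="VEG_SPCD"):
            read_tables(occ, plot)

    def test_round_trip_through_fia_export(self, tmp_path, tiny_panel):
        """Write a synthetic panel in inventory format, read it back, and
        recover the identical occurrence records."""
        _, _, panel = tiny_panel
        write_fia_tables(panel, tmp_path)
        occ, plots, cond, _ = read_tables(
            tmp_path / "fia_occurrence.csv",
            tmp_path / "fia_plot.csv",
            tmp_path / "fia_cond.csv",
        )
        rebuilt = build_panel(occ, plots)
        assert rebuilt.n_subplots == panel.n_subplots
        key = ["subplot_id", "cycle", "species_code"]
        left = panel.occurrences.sort_values(key).reset_index(drop=True)
        right = rebuilt.occurrences.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right, check_like=True)
        assert cond is not None and len(cond) == plots["PLT_CN"].nunique()


class TestBuildPanel:
    def _plots(self, rows):
        return pd.DataFrame(rows, columns=["PLT_CN", "X", "Y", "INVYR"])

    def test_keeps_only_plots_visited_in_all_cycles(self):
        plots = self._plots(
            [("p1", 0, 0, y) for y in (2003, 2009, 2016)]
            + [("p2", 10, 0, y) for y in (2003, 2009)]
        )
        occ = pd.DataFrame(
            columns=["PLT_CN", "SUBP", "VEG_SPCD", "COVER_PCT", "INVYR"]
        )
        panel = build_panel(occ, plots, subplots_per_plot=1)
        assert list(panel.subplots["plot_id"]) == ["p1"]

    def test_subplot_with_no_occurrences_counts_toward_denominator(self):
        plots = self._plots([("p1", 0, 0, y) for y in (2003, 2009, 2016)])
        occ = pd.DataFrame(
            [("p1", 1, "LOJA", 5.0, 2003)],
            columns=["PLT_CN", "SUBP", "VEG_SPCD", "COVER_PCT", "INVYR"],
        )
        panel = build_panel(occ, plots, subplots_per_plot=4)
        assert panel.n_subplots == 4
        summary = summarize_infestation(panel).set_index("cycle")
        assert summary.loc["T1", "infested_subplots"] == 1
        assert summary.loc["T1", "infestation_pct"] == 25.0
        assert summary.loc["T2", "infested_subplots"] == 0

    def test_duplicate_species_rows_keep_max_cover(self):
        plots = self._plots([("p1", 0, 0, y) for y in (2003, 2009, 2016)])
        occ = pd.DataFrame(
            [
                ("p1", 1, "LOJA", 5.0, 2003),
                ("p1", 1, "LOJA", 40.0, 2004),
                ("p1", 1, "LOJA", 10.0, 2003),
            ],
            columns=["PLT_CN", "SUBP", "VEG_SPCD", "COVER_PCT", "INVYR"],
        )
        panel = build_panel(occ, plots, subplots_per_plot=1)
        assert len(panel.occurrences) == 1
        assert panel.occurrences["cover_pct"].iloc[0] == 40.0

    def test_synthetic_panel_totals_match_generator(self, tiny_panel):
        units, severity, panel = tiny_panel
        assert panel.n_subplots == 400
        assert panel.subplots["plot_id"].nunique() == 100
        presence = binary_presence(panel)
        for cycle in panel.cycles:
            assert presence[cycle].sum() == len(panel.infested_ids(cycle))


class TestBinaryPresence:
    @pytest.fixture()
    def two_species_panel(self):
        subplots = pd.DataFrame(
            {"plot_id": ["p1"], "x": [0.0], "y": [0.0]}, index=["p1_1"]
        )
        occ = pd.DataFrame(
            [
                ("p1_1", "T1", "LOJA", 5.0),
                ("p1_1", "T1", "LIGUS2", 3.0),
            ],
            columns=["subplot_id", "cycle", "species_code", "cover_pct"],
        )
        return SubplotPanel(subplots=subplots, occurrences=occ)

    def test_any_species_scope(self, two_species_panel):
        ind = binary_presence(two_species_panel, "all")
        assert ind.loc["p1_1", "T1"] == 1
        assert ind.loc["p1_1", "T2"] == 0

    def test_single_species_scope(self, two_species_panel):
        assert binary_presence(two_species_panel, "TRSE6").loc["p1_1", "T1"] == 0
        assert binary_presence(two_species_panel, "LOJA").loc["p1_1", "T1"] == 1


class TestMajorSpecies:
    def _panel_with_counts(self, counts: dict):
        rows = []
        for code, n in counts.items():
            for i in range(n):
                rows.append((f"s{i}", "T3", code, 1.0))
        subplots = pd.DataFrame(
            {
                "plot_id": "p",
                "x": 0.0,
                "y": 0.0,
            },
            index=[f"s{i}" for i in range(max(counts.values()))],
        )
        occ = pd.DataFrame(
            rows, columns=["subplot_id", "cycle", "species_code", "cover_pct"]
        )
        return SubplotPanel(subplots=subplots, occurrences=occ)

    def test_threshold_boundary(self):
        panel = self._panel_with_counts({"A": 250, "B": 199})
        ranking, others = select_major_species(panel, min_subplots=200)
        assert list(ranking["species_code"]) == ["A"]
        assert others == ["B"]

    def test_threshold_one_keeps_everything(self):
        panel = self._panel_with_counts({"A": 250, "B": 199, "C": 3})
        ranking, others = select_major_species(panel, min_subplots=1)
        assert len(ranking) == 3 and others == []

    def test_published_count_ranking(self):
        """The seven-species count profile of a statewide inventory ranks
        honeysuckle > privet > climbing fern > lespedeza > silk-tree >
        tallow tree > rose."""
        counts = {
            "LOJA": 6751,
            "LIGUS2": 4248,
            "LYJA": 781,
            "LECU": 537,
            "ALJU": 351,
            "TRSE6": 255,
            "ROSA5": 203,
            "XX1": 120,
        }
        panel = self._panel_with_counts(counts)
        ranking, others = select_major_species(panel, min_subplots=200)
        assert list(ranking["species_code"]) == [
            "LOJA", "LIGUS2", "LYJA", "LECU", "ALJU", "TRSE6", "ROSA5",
        ]
        assert others == ["XX1"]

    def test_higher_threshold_selects_subset(self, tiny_panel):
        _, _, panel = tiny_panel
        low, _ = select_major_species(panel, min_subplots=5)
        high, _ = select_major_species(panel, min_subplots=40)
        assert set(high["species_code"]) <= set(low["species_code"])


class TestInfestationSummary:
    @pytest.mark.parametrize(
        "total, infested, occurrences, pct, mean_sp",
        [
            (15240, 6268, 8251, 41.1, 1.32),
            (15240, 7744, 11405, 50.8, 1.47),
            (15240, 8347, 14020, 54.8, 1.68),
        ],
    )
    def test_statewide_cycle_arithmetic(
        self, total, infested, occurrences, pct, mean_sp
    ):
        row = infestation_summary_from_counts(total, infested, occurrences)
        assert row["infestation_pct"] == pct
        assert row["mean_species_per_infested"] == mean_sp

    def test_zero_infested_means_undefined_mean(self):
        row = infestation_summary_from_counts(100, 0, 0)
        assert row["infestation_pct"] == 0.0
        assert row["mean_species_per_infested"] is None

    def test_empty_panel_is_all_zeros(self):
        panel = SubplotPanel(
            subplots=pd.DataFrame(columns=["plot_id", "x", "y"]),
            occurrences=pd.DataFrame(
                columns=["subplot_id", "cycle", "species_code", "cover_pct"]
            ),
        )
        summary = summarize_infestation(panel)
        assert (summary["infested_subplots"] == 0).all()
        assert summary["infestation_pct"].isna().all()

    def test_invariant_to_subplot_relabeling_and_row_order(self, tiny_panel):
        _, _, panel = tiny_panel
        mapping = {
            sid: f"relabel_{i}" for i, sid in enumerate(panel.subplots.index)
        }
        shuffled = SubplotPanel(
            subplots=panel.subplots.rename(index=mapping),
            occurrences=panel.occurrences.assign(
                subplot_id=panel.occurrences["subplot_id"].map(mapping)
            ).sample(frac=1.0, random_state=4),
            cycles=panel.cycles,
        )
        pd.testing.assert_frame_equal(
            summarize_infestation(panel), summarize_infestation(shuffled)
        )


class TestCategoricalCover:
    def _grid(self, labels, cell=10.0):
        rows = []
        for r, row in enumerate(labels):
            for c, lab in enumerate(row):
                rows.append(
                    {
                        "x": (c + 0.5) * cell,
                        "y": (r + 0.5) * cell,
                        "area": cell * cell,
                        "class_label": lab,
                    }
                )
        return pd.DataFrame(rows)

    def test_uniform_grid_gives_full_share(self, ):
        units = grid_partition((0, 0, 40, 40), 2, 2, "U")
        grid = self._grid([["fr"] * 4] * 4)
        pct = categorical_cover_fraction(grid, units)
        assert np.allclose(pct["fr"], 100.0)

    def test_checkerboard_splits_evenly(self):
        units = grid_partition((0, 0, 20, 20), 1, 1, "U")
        grid = self._grid([["a", "b"], ["b", "a"]])
        pct = categorical_cover_fraction(grid, units)
        assert pct.loc["U_000_000", "a"] == pytest.approx(50.0)
        assert pct.loc["U_000_000", "b"] == pytest.approx(50.0)

    def test_random_grid_percents_sum_to_100(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(list("abcdef"), size=(12, 12))
        units = grid_partition((0, 0, 120, 120), 3, 3, "U")
        pct = categorical_cover_fraction(self._grid(labels), units)
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-9)

    def test_uncovered_unit_warns(self):
        units = grid_partition((0, 0, 200, 200), 2, 2, "U")
        grid = self._grid([["a", "a"], ["a", "a"]])  # covers only 20x20 corner
        with pytest.warns(UserWarning, match="no grid cells"):
            pct = categorical_cover_fraction(grid, units)
        assert pct.loc["U_000_000", "a"] == pytest.approx(100.0)
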