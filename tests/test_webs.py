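"""Container validation, delimited IO and percentage-table inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aroidnet.webs import (
    FormatError,
    InteractionWeb,
    PercentageTable,
    RecordTable,
    ReconstructionError,
    ValidationError,
    percentage_table,
    read_records,
    read_web,
    reconstruct_counts,
    write_records,
    write_web,
)


class TestInteractionWeb:
    def test_basic_invariants(self, toy_web):
        assert toy_web.m == 9
        assert toy_web.row_totals.tolist() == [6, 3]
        assert toy_web.col_totals.tolist() == [6, 3]

    @pytest.mark.parametrize(
        "counts, labels",
        [
            (np.array([[1, -1], [0, 2]]), (("a", "b"), ("x", "y"))),
            (np.array([[0.5, 1], [0, 2]]), (("a", "b"), ("x", "y"))),
            (np.array([[1, 1], [0, 2]]), (("a", "a"), ("x", "y"))),
            (np.array([[1, 1], [0, 2]]), (("a", "b"), ("x",))),
        ],
    )
    def test_invalid_webs_rejected(self, counts, labels):
        with pytest.raises(ValidationError):
            InteractionWeb(counts, *labels)

    def test_trim_drops_empty_species(self):
        web = InteractionWeb(
            np.array([[2, 0, 0], [0, 0, 0], [1, 3, 0]]),
            ("a", "b", "c"),
            ("x", "y", "z"),
        )
        trimmed = web.trim()
        assert trimmed.shape == (2, 2)
        assert trimmed.row_labels == ("a", "c")
        assert trimmed.col_labels == ("x", "y")
        assert trimmed.m == web.m


class TestDelimitedIO:
    def test_round_trip_is_cell_identical(self, tmp_path, toy_web):
        path = tmp_path / "web.csv"
        write_web(toy_web, path)
        back = read_web(path)
        assert back == toy_web

    def test_identity_web(self, tmp_path):
        path = tmp_path / "id.csv"
        path.write_text("sp,h1,h2\na,1,0\nb,0,1\n")
        web = read_web(path)
        assert web.m == 2

    def test_negative_cell_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("sp,h1,h2\na,1,-2\nb,0,1\n")
        with pytest.raises(ValidationError):
            read_web(path)

    def test_non_numeric_cell_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sp,h1,h2\na,1,x\nb,0,1\n")
        with pytest.raises(FormatError):
            read_web(path)

    def test_orientation_transposes(self, tmp_path, toy_web):
        path = tmp_path / "t.csv"
        write_web(toy_web.transpose(), path)
        assert read_web(path, orientation="insects-cols") == toy_web

    def test_records_round_trip(self, tmp_path):
        frame = pd.DataFrame(
            {
                "host": ["h1", "h1", "h2"],
                "elevation": ["low", "low", "mid"],
                "unit_id": ["u1", "u2", "u3"],
                "species": ["a", "b", "a"],
                "count": [3, 1, 2],
            }
        )
        records = RecordTable(frame)
        path = tmp_path / "records.csv"
        write_records(records, path)
        assert read_records(path).frame.equals(records.frame)

    def test_records_aggregate_to_web(self):
        frame = pd.DataFrame(
            {
                "host": ["h1", "h1", "h2"],
                "elevation": ["low"] * 3,
                "unit_id": ["u1", "u2", "u3"],
                "species": ["a", "a", "b"],
                "count": [3, 1, 2],
            }
        )
        web = RecordTable(frame).to_web()
        assert web.to_frame().loc["a", "h1"] == 4
        assert web.to_frame().loc["b", "h2"] == 2
        assert web.m == 6


class TestReconstruction:
    def test_single_host_exact_inversion(self):
        table = PercentageTable(
            pd.DataFrame({"h": [75.0, 25.0]}, index=["a", "b"]),
            pd.Series([3, 1], index=["a", "b"]),
            4,
        )
        web = reconstruct_counts(table)
        assert web.counts.ravel().tolist() == [3, 1]

    def test_infeasible_percentages_raise(self):
        # species totals incompatible with any non-negative column totals
        table = PercentageTable(
            pd.DataFrame({"h1": [100.0, 0.0], "h2": [0.0, 100.0]}, index=["a", "b"]),
            pd.Series([100, 1], index=["a", "b"]),
            101,
        )
        bad = PercentageTable(
            pd.DataFrame({"h1": [50.0, 50.0], "h2": [50.0, 50.0]}, index=["a", "b"]),
            pd.Series([100, 1], index=["a", "b"]),
            101,
        )
        with pytest.raises(ReconstructionError):
            reconstruct_counts(bad, max_abs_residual=1.0)
        # and the compatible version goes through
        assert reconstruct_counts(table).m == 101

    def test_column_percentages_must_sum_to_100(self):
        with pytest.raises(ValidationError):
            PercentageTable(
                pd.DataFrame({"h": [60.0, 20.0]}, index=["a", "b"]),
                pd.Series([3, 1], index=["a", "b"]),
                4,
            )

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_full_precision_round_trip(self, data):
        """A web whose every host has a signature species (unique to it)
        is exactly recovered from its full-precision percentage table."""
        n_hosts = data.draw(st.integers(2, 4))
        n_extra = data.draw(st.integers(1, 4))
        rng_rows = []
        # signature rows pin down each column total uniquely
        for h in range(n_hosts):
            row = [0] * n_hosts
            row[h] = data.draw(st.integers(1, 9))
            rng_rows.append(row)
        for _ in range(n_extra):
            rng_rows.append([data.draw(st.integers(0, 9)) for _ in range(n_hosts)])
        counts = np.array(rng_rows)
        counts = counts[counts.sum(axis=1) > 0]
        web = InteractionWeb(
            counts,
            tuple(f"s{i}" for i in range(counts.shape[0])),
            tuple(f"h{j}" for j in range(n_hosts)),
        )
        recovered = reconstruct_counts(percentage_table(web))
        assert np.array_equal(recovered.counts, web.counts)
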