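import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecoassembly.core import (
    OTUTable,
    RunConfig,
    ValidationError,
    metadata_frame,
    read_metadata,
    read_otu_table,
    relative_abundance,
    write_metadata,
    write_otu_table,
)
from ecoassembly.simulate import SynthSpec, simulate_dataset

from conftest import make_table


class TestReadOTUTable:
    def test_basic_parse(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("otu_id\ts1\ts2\nA\t5\t0\nB\t1\t2\nC\t0\t7\n")
        table = read_otu_table(path)
        assert table.otu_ids == ["A", "B", "C"]
        assert table.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(table.sample_totals(), [6, 9])

    def test_round_trip(self, tmp_path, random_table):
        path = tmp_path / "t.tsv"
        write_otu_table(random_table, path)
        back = read_otu_table(path)
        assert back.otu_ids == random_table.otu_ids
        assert back.sample_ids == random_table.sample_ids
        np.testing.assert_array_equal(back.counts, random_table.counts)

    def test_negative_count_names_cell(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("otu_id\ts1\ts2\nA\t5\t0\nB\t-3\t2\n")
        with pytest.raises(ValidationError, match="'B'.*'s1'"):
            read_otu_table(path)

    def test_non_numeric_named(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("otu_id\ts1\ts2\nA\t5\t0\nB\tfoo\t2\n")
        with pytest.raises(ValidationError, match="foo"):
            read_otu_table(path)

    def test_samples_as_rows_normalised(self, tmp_path, random_table):
        path = tmp_path / "t.tsv"
        random_table.to_frame().T.to_csv(path, sep="\t", index_label="sample_id")
        back = read_otu_table(path, orientation="samples_as_rows")
        np.testing.assert_array_equal(back.counts, random_table.counts)
        assert back.otu_ids == random_table.otu_ids


class TestOTUTableInvariants:
    def test_duplicate_otu_ids(self):
        with pytest.raises(ValidationError, match="duplicate"):
            OTUTable(["A", "A"], ["s1", "s2"], np.ones((2, 2), int))

    def test_zero_total_sample(self):
        with pytest.raises(ValidationError, match="zero total"):
            OTUTable(["A", "B"], ["s1", "s2"], np.array([[1, 0], [2, 0]]))

    def test_too_small(self):
        with pytest.raises(ValidationError):
            OTUTable(["A"], ["s1", "s2"], np.ones((1, 2), int))

    @given(
        counts=arrays(np.int64, (4, 3), elements=st.integers(0, 50)),
        corruption=st.sampled_from(["negative", "dup_otu", "dup_sample"]),
    )
    @settings(max_examples=25, deadline=None)
    def test_random_corruptions_rejected(self, counts, corruption):
        counts = counts.copy()
        counts[0, 0] += 1  # ensure at least one positive entry
        otu_ids = [f"O{i}" for i in range(4)]
        sample_ids = [f"s{j}" for j in range(3)]
        if corruption == "negative":
            counts[1, 1] = -1
        elif corruption == "dup_otu":
            otu_ids[1] = otu_ids[0]
        else:
            sample_ids[1] = sample_ids[0]
        # any ValidationError is a correct rejection (a zero column in the
        # random draw may legitimately trigger before the planted fault)
        with pytest.raises(ValidationError):
            OTUTable(otu_ids, sample_ids, counts)


class TestMetadata:
    def _write(self, tmp_path, n=5, **overrides):
        table, metadata, _ = simulate_dataset(
            SynthSpec(n_samples=30, band_sizes=(12, 8, 10), n_otus=50,
                      reads_per_sample=200, rng_seed=0)
        )
        path = tmp_path / "meta.tsv"
        df = metadata_frame(metadata)
        for col, val in overrides.items():
            df.loc[0, col] = val
        df.to_csv(path, sep="\t", index=False)
        return path, table

    def test_full_read(self, tmp_path):
        path, table = self._write(tmp_path)
        records = read_metadata(path, table)
        assert len(records) == 30
        assert records[0].band in {"LEG", "MEG", "HEG"}

    def test_unit_interval_violation(self, tmp_path):
        path, _ = self._write(tmp_path, CC=1.2)
        with pytest.raises(ValidationError, match="CC"):
            read_metadata(path)

    def test_missing_soil_block_flagged(self, tmp_path):
        path, _ = self._write(tmp_path)
        df = pd.read_csv(path, sep="\t")
        df = df.drop(columns=["soil_pH", "organic_matter", "alkaline_N",
                              "available_P", "water_content"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="missing"):
            records = read_metadata(path)
        assert np.isnan(records[0].soil_pH)

    def test_orphan_sample_ids(self, tmp_path, random_table):
        path, _ = self._write(tmp_path)
        with pytest.raises(ValidationError, match="absent"):
            read_metadata(path, random_table)

    def test_round_trip(self, tmp_path):
        path, table = self._write(tmp_path)
        records = read_metadata(path, table)
        out = tmp_path / "meta2.tsv"
        write_metadata(records, out)
        again = read_metadata(out, table)
        assert metadata_frame(again).equals(metadata_frame(records))


class TestRelativeAbundance:
    def test_per_sample(self):
        table = make_table([[2, 2], [2, 6]])
        rel = relative_abundance(table, "per_sample")
        np.testing.assert_allclose(rel, [[0.5, 0.25], [0.5, 0.75]])

    def test_per_otu(self):
        table = make_table([[2, 1, 1], [1, 1, 1]])
        rel = relative_abundance(table, "per_otu")
        np.testing.assert_allclose(rel[0], [0.5, 0.25, 0.25])

    def test_zero_row_flagged(self):
        table = make_table([[0, 0], [1, 2]])
        with pytest.warns(UserWarning, match="all-zero"):
            rel = relative_abundance(table, "per_otu")
        np.testing.assert_array_equal(rel[0], [0.0, 0.0])

    @given(
        counts=arrays(np.int64, (3, 3), elements=st.integers(0, 20)),
        k=st.integers(2, 9),
    )
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, counts, k):
        counts = counts + 1  # keep columns positive
        t1 = make_table(counts)
        scaled = counts.copy()
        scaled[:, 0] *= k
        t2 = make_table(scaled)
        np.testing.assert_allclose(
            relative_abundance(t1, "per_sample"),
            relative_abundance(t2, "per_sample"),
        )


class TestRunConfig:
    def test_from_file(self, tmp_path):
        path = tmp_path / "config.txt"
        path.write_text(
            "rng_seed = 42\nn_permutations = 500  # permutations\nci_level = 0.9\n"
            "outdir = runs/a\nrarefy_depth = none\n"
        )
        cfg = RunConfig.from_file(path)
        assert cfg.rng_seed == 42
        assert cfg.n_permutations == 500
        assert cfg.ci_level == 0.9
        assert cfg.outdir == "runs/a"
        assert cfg.rarefy_depth is None

    def test_invalid_values(self):
        with pytest.raises(ValidationError):
            RunConfig(n_permutations=0)
        with pytest.raises(ValidationError):
            RunConfig(ci_level=1.0)

    def test_unknown_key(self, tmp_path):
        path = tmp_path / "config.txt"
        path.write_text("bogus = 1\n")
        with pytest.raises(ValidationError, match="bogus"):
            RunConfig.from_file(path)
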