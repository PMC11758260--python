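"""ASV filter chain, detection matrix and survey summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ednatrack import (
    ASVTable,
    SampleMetadata,
    accumulation_curve,
    apply_taxonomy_rules,
    attrition_log,
    build_detections,
    drop_singletons,
    filter_target_taxa,
    run_filter_chain,
    subtract_controls,
    summarize,
)
from ednatrack.edna_detect import (
    DetectError,
    TAXONOMY_COLUMNS,
    read_asv_table,
    read_sample_metadata,
    write_asv_table,
    write_sample_metadata,
)


def make_table(reads: dict, taxonomy: dict) -> ASVTable:
    """reads: {asv: {sample: n}}; taxonomy: {asv: (cls, genus, species, conf)}."""
    reads_df = pd.DataFrame(reads).T.fillna(0).astype(np.int64)
    tax_rows = {}
    for asv, (cls, genus, species, conf) in taxonomy.items():
        tax_rows[asv] = {"class": cls, "order": "", "family": "", "genus": genus,
                         "species": species, "confidence": conf}
    tax_df = pd.DataFrame(tax_rows).T[TAXONOMY_COLUMNS]
    tax_df = tax_df.loc[reads_df.index]
    return ASVTable(reads=reads_df, taxonomy=tax_df)


def make_meta(samples: list, months=None) -> SampleMetadata:
    """One sample + paired control per entry; sample ids 's1', controls 'c1'."""
    rows = []
    for i, station in enumerate(samples, start=1):
        month = months[i - 1] if months else "Jun"
        rows.append({"sample_id": f"s{i}", "station_id": station, "month": month,
                     "type": "sample", "paired_control_id": f"c{i}"})
        rows.append({"sample_id": f"c{i}", "station_id": station, "month": month,
                     "type": "field_control", "paired_control_id": ""})
    return SampleMetadata(table=pd.DataFrame(rows))


ELASMO = ("Elasmobranchii", "Scyliorhinus", "Scyliorhinus canicula", 80.0)


class TestSubtractControls:
    def test_control_read_zeroes_sample(self):
        table = make_table({"a1": {"s1": 100, "c1": 2}}, {"a1": ELASMO})
        out = subtract_controls(table, make_meta(["PO"]))
        assert out.reads.loc["a1", "s1"] == 0

    def test_asv_absent_from_control_untouched(self):
        table = make_table({"a1": {"s1": 100, "c1": 0}}, {"a1": ELASMO})
        out = subtract_controls(table, make_meta(["PO"]))
        assert out.reads.loc["a1", "s1"] == 100

    def test_control_columns_dropped(self):
        table = make_table({"a1": {"s1": 5, "c1": 0}}, {"a1": ELASMO})
        out = subtract_controls(table, make_meta(["PO"]))
        assert list(out.reads.columns) == ["s1"]

    def test_unpaired_sample_rejected_in_metadata(self):
        rows = [{"sample_id": "s1", "station_id": "PO", "month": "Jun",
                 "type": "sample", "paired_control_id": "missing"}]
        with pytest.raises(DetectError, match="s1"):
            SampleMetadata(table=pd.DataFrame(rows))

    def test_sample_missing_from_table_rejected(self):
        table = make_table({"a1": {"s1": 5, "c1": 0}}, {"a1": ELASMO})
        meta = make_meta(["PO", "CA"])
        with pytest.raises(DetectError, match="s2"):
            subtract_controls(table, meta)


class TestFilterTargetTaxa:
    def test_teleost_dropped_elasmobranch_retained(self):
        table = make_table(
            {"a1": {"s1": 5, "c1": 0}, "a2": {"s1": 9, "c1": 0}},
            {"a1": ELASMO, "a2": ("Actinopteri", "Clupea", "Clupea harengus", 90.0)},
        )
        out = filter_target_taxa(table)
        assert list(out.reads.index) == ["a1"]

    def test_unassigned_class_dropped(self):
        table = make_table({"a1": {"s1": 5}}, {"a1": ("", "Raja", "Raja clavata", 80.0)})
        out = filter_target_taxa(table)
        assert len(out.reads) == 0
        assert out.history[-1]["rows_unassigned_class"] == 1


class TestDropSingletons:
    @pytest.mark.parametrize("n_in, n_out", [(1, 0), (2, 2), (0, 0), (7, 7)])
    def test_cellwise_rule(self, n_in, n_out):
        table = make_table({"a1": {"s1": n_in}}, {"a1": ELASMO})
        assert drop_singletons(table).reads.loc["a1", "s1"] == n_out

    def test_all_ones_table_zeroed(self):
        table = make_table({"a1": {"s1": 1, "s2": 1}, "a2": {"s1": 1, "s2": 1}},
                           {"a1": ELASMO, "a2": ELASMO})
        out = drop_singletons(table)
        assert out.reads.to_numpy().sum() == 0
        assert out.history[-1]["cells_zeroed"] == 4

    def test_taxon_survives_via_other_samples(self):
        table = make_table({"a1": {"s1": 1, "s2": 30}}, {"a1": ELASMO})
        out = drop_singletons(table)
        assert out.reads.loc["a1", "s2"] == 30


class TestApplyTaxonomyRules:
    def test_family_level_only_dropped(self):
        table = make_table({"a1": {"s1": 5}}, {"a1": ("Elasmobranchii", "", "", 80.0)})
        assert len(apply_taxonomy_rules(table).reads) == 0

    def test_genus_only_retained_and_flagged(self):
        table = make_table({"a1": {"s1": 5}}, {"a1": ("Elasmobranchii", "Raja", "", 45.0)})
        out = apply_taxonomy_rules(table)
        assert len(out.reads) == 1
        assert bool(out.taxonomy.loc["a1", "genus_only"])

    def test_below_confidence_dropped(self):
        table = make_table({"a1": {"s1": 5}},
                           {"a1": ("Elasmobranchii", "Raja", "Raja clavata", 35.0)})
        assert len(apply_taxonomy_rules(table).reads) == 0

    def test_contaminant_species_dropped(self):
        table = make_table(
            {"a1": {"s1": 5}},
            {"a1": ("Elasmobranchii", "Taeniura", "Taeniura lymma", 95.0)},
        )
        out = apply_taxonomy_rules(table, contaminant_list={"Taeniura lymma"})
        assert len(out.reads) == 0


class TestBuildDetections:
    def test_surviving_reads_make_detection(self):
        table = make_table({"a1": {"s1": 5, "c1": 0}}, {"a1": ELASMO})
        meta = make_meta(["PO"])
        table = apply_taxonomy_rules(filter_target_taxa(subtract_controls(table, meta)))
        matrix = build_detections(table, meta)
        assert len(matrix.long) == 1
        row = matrix.long.iloc[0]
        assert (row["species"], row["station_id"], row["month"]) == \
            ("Scyliorhinus canicula", "PO", "Jun")

    def test_genus_only_rows_excluded(self):
        table = make_table(
            {"a1": {"s1": 50, "c1": 0}},
            {"a1": ("Elasmobranchii", "Raja", "", 45.0)},
        )
        meta = make_meta(["PO"])
        table = apply_taxonomy_rules(filter_target_taxa(subtract_controls(table, meta)))
        matrix = build_detections(table, meta)
        assert matrix.long.empty

    def test_all_zero_table_gives_empty_matrix(self):
        table = make_table({"a1": {"s1": 0, "c1": 0}}, {"a1": ELASMO})
        meta = make_meta(["PO"])
        matrix = build_detections(subtract_controls(table, meta), meta)
        assert matrix.long.empty


class TestFilterChainProperties:
    def test_chain_order_logged(self):
        table = make_table({"a1": {"s1": 5, "c1": 0}}, {"a1": ELASMO})
        filtered, _ = run_filter_chain(table, make_meta(["PO"]))
        steps = attrition_log(filtered)["step"].tolist()
        assert steps == ["subtract_controls", "filter_target_taxa",
                         "drop_singletons", "apply_taxonomy_rules"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_filters_never_increase_reads(self, data):
        n_asv = data.draw(st.integers(1, 4))
        counts = data.draw(
            st.lists(st.lists(st.integers(0, 50), min_size=4, max_size=4),
                     min_size=n_asv, max_size=n_asv)
        )
        classes = data.draw(
            st.lists(st.sampled_from(["Elasmobranchii", "Actinopteri", ""]),
                     min_size=n_asv, max_size=n_asv)
        )
        reads = {f"a{i}": {"s1": c[0], "c1": c[1], "s2": c[2], "c2": c[3]}
                 for i, c in enumerate(counts)}
        taxonomy = {f"a{i}": (classes[i], "Raja", "Raja clavata", 80.0)
                    for i in range(n_asv)}
        table = make_table(reads, taxonomy)
        meta = make_meta(["PO", "CA"])
        filtered, matrix = run_filter_chain(table, meta)
        log = attrition_log(filtered)
        assert (log["reads_out"] <= log["reads_in"]).all()
        assert (log["rows_out"] <= log["rows_in"]).all()

    def test_full_leakage_removes_everything(self):
        table = make_table(
            {"a1": {"s1": 50, "c1": 3}, "a2": {"s1": 20, "c1": 1}},
            {"a1": ELASMO, "a2": ELASMO},
        )
        _, matrix = run_filter_chain(table, make_meta(["PO"]))
        assert matrix.long.empty


class TestSummarize:
    def test_printed_proportion_one_decimal(self):
        # 105 positive of 240 water samples -> 43.8%
        stations = [f"S{i:02d}" for i in range(1, 21)]
        months = [f"M{j:02d}" for j in range(1, 13)]
        rows = []
        k = 0
        for st_ in stations:
            for mo in months:
                k += 1
                rows.append({"sample_id": f"w{k}", "station_id": st_, "month": mo,
                             "type": "sample", "paired_control_id": f"b{k}"})
                rows.append({"sample_id": f"b{k}", "station_id": st_, "month": mo,
                             "type": "field_control", "paired_control_id": ""})
        meta = SampleMetadata(table=pd.DataFrame(rows))
        per_sample = pd.DataFrame(
            {
                "species": ["Scyliorhinus canicula"] * 105,
                "sample_id": [f"w{i}" for i in range(1, 106)],
                "station_id": ["S01"] * 105,
                "month": ["M01"] * 105,
                "reads": [10] * 105,
            }
        )
        from ednatrack.edna_detect import DetectionMatrix

        matrix = DetectionMatrix(
            long=per_sample.groupby(["species", "station_id", "month"], as_index=False)["reads"]
            .sum()
            .assign(detected=True),
            per_sample=per_sample,
            n_samples_total=240,
        )
        s = summarize(matrix, meta)
        assert s["n_samples_total"] == 240
        assert s["n_samples_with_detection"] == 105
        assert s["pct_samples_with_detection"] == 43.8

    def test_empty_matrix(self):
        from ednatrack.edna_detect import DetectionMatrix

        meta = make_meta(["PO"])
        matrix = DetectionMatrix(
            long=pd.DataFrame(columns=["species", "station_id", "month", "detected", "reads"]),
            per_sample=pd.DataFrame(columns=["species", "sample_id", "station_id", "month", "reads"]),
            n_samples_total=1,
        )
        s = summarize(matrix, meta)
        assert s["discrete_detections_species_sample"] == 0
        assert s["pct_samples_with_detection"] == 0.0

    def test_every_sample_positive_is_100(self):
        meta = make_meta(["PO", "CA"])
        per_sample = pd.DataFrame(
            {
                "species": ["Raja clavata", "Raja clavata"],
                "sample_id": ["s1", "s2"],
                "station_id": ["PO", "CA"],
                "month": ["Jun", "Jun"],
                "reads": [4, 6],
            }
        )
        from ednatrack.edna_detect import DetectionMatrix

        matrix = DetectionMatrix(
            long=per_sample.groupby(["species", "station_id", "month"], as_index=False)["reads"]
            .sum()
            .assign(detected=True),
            per_sample=per_sample,
            n_samples_total=2,
        )
        assert summarize(matrix, meta)["pct_samples_with_detection"] == 100.0


class TestAccumulationCurve:
    def test_identical_single_species_samples_flat_at_1(self):
        curve = accumulation_curve([{"A"}, {"A"}, {"A"}], n_permutations=20, seed=1)
        assert np.allclose(curve, 1.0)

    def test_endpoint_equals_total_richness(self):
        samples = [{"A", "B"}, {"B"}, {"C"}, set()]
        curve = accumulation_curve(samples, n_permutations=50, seed=1)
        assert curve[-1] == pytest.approx(3.0)
        assert np.all(np.diff(curve) >= -1e-12)

    def test_two_disjoint_samples_exhaustive_enumeration(self):
        # both orders of {A},{B} give richness 1 at k=1 and 2 at k=2
        curve = accumulation_curve([{"A"}, {"B"}], n_permutations=64, seed=3)
        assert curve[0] == pytest.approx(1.0)
        assert curve[1] == pytest.approx(2.0)

    def test_k1_mean_equals_average_per_sample_richness(self):
        # exhaustive expectation over <= 3 samples: E[richness at k=1] is the
        # mean per-sample richness
        samples = [{"A", "B"}, {"B"}, set()]
        curve = accumulation_curve(samples, n_permutations=4000, seed=5)
        assert curve[0] == pytest.approx(np.mean([2, 1, 0]), abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(DetectError):
            accumulation_curve([], n_permutations=5, seed=0)


class TestIO:
    def test_round_trip(self, tmp_path):
        table = make_table(
            {"a1": {"s1": 5, "c1": 0}, "a2": {"s1": 0, "c1": 2}},
            {"a1": ELASMO, "a2": ("Actinopteri", "Clupea", "Clupea harengus", 91.5)},
        )
        meta = make_meta(["PO"])
        tpath = tmp_path / "asv.tsv"
        mpath = tmp_path / "meta.csv"
        write_asv_table(table, tpath)
        write_sample_metadata(meta, mpath)
        table2 = read_asv_table(tpath)
        meta2 = read_sample_metadata(mpath)
        assert table2.reads.equals(table.reads)
        assert table2.taxonomy["species"].equals(table.taxonomy["species"])
        assert list(meta2.samples["sample_id"]) == list(meta.samples["sample_id"])

    def test_missing_taxonomy_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("asv_id\ts1\na1\t5\n")
        with pytest.raises(DetectError, match="class"):
            read_asv_table(path)
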