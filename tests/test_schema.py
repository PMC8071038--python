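"""Feature schema, ingestion, normalization and L/R augmentation."""

import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest

from brainwcn import schema as sc
from brainwcn import synth

from oracles import ks_statistic_brute


@pytest.mark.parametrize("name,expected", [
    ("lh_bankssts_volume", ("left", "volume", "volume_like")),
    ("rh_cuneus_area", ("right", "surface_area", "area_like")),
    ("lh_insula_thickness", ("left", "thickness_mean", "thickness_like")),
    ("rh_insula_thicknessstd", ("right", "thickness_sd", "thickness_like")),
    ("lh_lingual_meancurv", ("left", "mean_curvature", "none")),
    ("rh_lingual_curvind", ("right", "curvature_index", "none")),
    ("Left-Hippocampus", ("left", "volume", "volume_like")),
    ("Right-Amygdala", ("right", "volume", "volume_like")),
    ("CC_Anterior", ("global", "volume", "volume_like")),
    ("Brain-Stem", ("global", "volume", "volume_like")),
    ("TotalGrayVol", ("global", "volume", "volume_like")),
    ("lhCortexVol", ("left", "volume", "volume_like")),
    ("lh_MeanThickness_thickness", ("left", "thickness_mean", "thickness_like")),
    ("BrainSegVolNotVent", ("global", "volume", "none")),
])
def test_feature_name_parsing(name, expected):
    meta = sc.parse_feature_name(name)
    assert (meta["hemisphere"], meta["measure"], meta["norm_class"]) == expected


def test_normalizer_is_flagged():
    assert sc.parse_feature_name("BrainSegVolNotVent")["is_normalizer"]
    assert not sc.parse_feature_name("TotalGrayVol")["is_normalizer"]


# ---------------------------------------------------------------------------
# FreeSurfer table ingestion
# ---------------------------------------------------------------------------

def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


def test_read_merges_on_subject_intersection(tmp_path):
    f1 = _write(tmp_path, "a.tsv", """\
        ID\tlh_cuneus_volume\trh_cuneus_volume
        s1\t1.0\t2.0
        s2\t3.0\t4.0
        s3\t5.0\t6.0
        s4\t7.0\t8.0
        """)
    f2 = _write(tmp_path, "b.tsv", """\
        ID\tlh_cuneus_area\trh_cuneus_area
        s2\t1.5\t2.5
        s3\t3.5\t4.5
        s1\t5.5\t6.5
        """)
    table = sc.read_freesurfer_tables([f1, f2])
    assert sorted(table.subject_ids) == ["s1", "s2", "s3"]
    assert table.n_features == 4
    # rows must be aligned on subject, not file order
    assert table.values.loc["s1", "lh_cuneus_area"] == 5.5


def test_read_rejects_non_numeric_cell_with_location(tmp_path):
    f1 = _write(tmp_path, "a.tsv", """\
        ID\tlh_cuneus_volume
        s1\t1.0
        s2\tNA
        """)
    with pytest.raises(sc.IngestionError, match="s2.*lh_cuneus_volume"):
        sc.read_freesurfer_tables([f1])


def test_read_drops_rows_with_empty_cells_and_reports(tmp_path):
    f1 = _write(tmp_path, "a.tsv", """\
        ID\tlh_cuneus_volume\trh_cuneus_volume
        s1\t1.0\t2.0
        s2\t\t4.0
        s3\t5.0\t6.0
        """)
    with pytest.warns(UserWarning, match="missing"):
        table = sc.read_freesurfer_tables([f1])
    assert sorted(table.subject_ids) == ["s1", "s3"]
    assert any("s2" in v for v in
               table.ingestion_report["dropped_incomplete_rows"].values())


def test_read_errors(tmp_path):
    dup = _write(tmp_path, "dup.tsv", """\
        ID\tlh_cuneus_volume\tlh_cuneus_volume
        s1\t1.0\t2.0
        """)
    with pytest.raises(sc.IngestionError, match="duplicate"):
        sc.read_freesurfer_tables([dup])
    f1 = _write(tmp_path, "a.tsv", "ID\tx_f\ns1\t1.0\n")
    f2 = _write(tmp_path, "b.tsv", "ID\ty_f\ns2\t1.0\n")
    with pytest.raises(sc.IngestionError, match="no subjects"):
        sc.read_freesurfer_tables([f1, f2])


def test_fixture_roundtrip_through_reader(tmp_path, cohort):
    table, pheno = cohort
    paths = synth.write_fixture(table, pheno, tmp_path)
    back = sc.read_freesurfer_tables([p for p in paths
                                      if p.suffix == ".tsv"])
    assert sorted(back.feature_ids) == sorted(table.feature_ids)
    aligned = back.values[table.feature_ids].loc[table.subject_ids]
    pd.testing.assert_frame_equal(aligned, table.values, check_exact=True)
    # metadata inferred from names matches the generating schema
    pd.testing.assert_frame_equal(back.metadata.loc[table.feature_ids],
                                  table.metadata)


# ---------------------------------------------------------------------------
# Cohort selection and age balance
# ---------------------------------------------------------------------------

@pytest.fixture()
def pheno_frame():
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(8)],
        "group": ["case"] * 3 + ["control"] * 5,
        "age": [10.0, 12, 14, 11, 13, 15, 17, 19],
        "sex": ["M", "F", "M", "M", "M", "F", "M", "M"],
        "handedness": ["R", "R", "L", "R", "R", "R", "R", "L"],
    })


def test_select_cohort_filters_and_partitions(pheno_frame):
    groups = sc.select_cohort(pheno_frame, {"sex": "M", "handedness": "R"})
    assert groups == {"case": ["s0"], "control": ["s3", "s4", "s6"]}
    everyone = sc.select_cohort(pheno_frame, {})
    assert sum(len(v) for v in everyone.values()) == 8
    with pytest.raises(ValueError, match="no subjects"):
        sc.select_cohort(pheno_frame, {"sex": "X"})
    with pytest.raises(KeyError):
        sc.select_cohort(pheno_frame, {"nope": 1})


def test_ks_balance_identical_and_disjoint_samples():
    same = sc.cohort_balance_check([1, 2, 3, 4], [1, 2, 3, 4])
    assert same["D"] == 0 and same["p"] == 1
    split = sc.cohort_balance_check([1, 2, 3], [10, 11, 12])
    assert split["D"] == 1
    with pytest.raises(ValueError):
        sc.cohort_balance_check([1.0], [1, 2, 3])


def test_ks_statistic_matches_bruteforce_ecdf_gap():
    rng = np.random.default_rng(0)
    a = list(rng.normal(size=11))
    b = list(rng.normal(0.7, 1.3, size=7))
    res = sc.cohort_balance_check(a, b)
    assert res["D"] == pytest.approx(ks_statistic_brute(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _tiny_table():
    names = ["lh_cuneus_volume", "rh_cuneus_volume",
             "lh_cuneus_thickness", "rh_cuneus_thickness",
             "lh_cuneus_area", "rh_cuneus_area",
             "lh_MeanThickness_thickness", "rh_MeanThickness_thickness",
             "BrainSegVolNotVent"]
    values = pd.DataFrame(
        [[100.0, 200.0, 2.0, 3.0, 40.0, 60.0, 2.0, 3.0, 1000.0],
         [150.0, 250.0, 2.2, 2.8, 50.0, 75.0, 2.2, 2.9, 2000.0],
         [120.0, 240.0, 2.35, 2.6, 45.0, 68.0, 2.4, 2.7, 1200.0]],
        index=["s1", "s2", "s3"], columns=names)
    return sc.FeatureTable(values)


def test_normalization_hand_computed():
    out = sc.normalize_features(_tiny_table())
    # volumes / BrainSegVolNotVent
    assert out.values.loc["s1", "lh_cuneus_volume"] == pytest.approx(0.1)
    assert out.values.loc["s2", "rh_cuneus_volume"] == pytest.approx(0.125)
    # thickness / mean(lh, rh MeanThickness): s1 mean is 2.5
    assert out.values.loc["s1", "lh_cuneus_thickness"] == pytest.approx(2.0 / 2.5)
    assert out.values.loc["s1", "rh_cuneus_thickness"] == pytest.approx(3.0 / 2.5)
    # area / sum of cortical areas: s1 total is 100
    assert out.values.loc["s1", "lh_cuneus_area"] == pytest.approx(0.4)
    # normalizer retained, unchanged, flagged
    assert out.values.loc["s1", "BrainSegVolNotVent"] == 1000.0
    assert "BrainSegVolNotVent" not in out.node_feature_ids()


def test_thickness_of_exactly_mean_becomes_one():
    out = sc.normalize_features(_tiny_table())
    # a thickness equal to the L/R mean thickness normalizes to mean/mean
    mean = (2.0 + 3.0) / 2
    assert out.values.loc["s1", "lh_cuneus_thickness"] * mean == pytest.approx(2.0)


def test_normalization_is_one_shot_and_errors():
    table = _tiny_table()
    out = sc.normalize_features(table)
    with pytest.raises(ValueError, match="already normalized"):
        sc.normalize_features(out)
    bad = _tiny_table()
    bad.values.loc["s2", "BrainSegVolNotVent"] = -1.0
    with pytest.raises(ValueError, match="s2"):
        sc.normalize_features(bad)


def test_rank_preservation_iff_constant_normalizer():
    table = _tiny_table()
    ranks_before = table.values["lh_cuneus_volume"].rank()
    out = sc.normalize_features(table)
    # normalizer varies across subjects -> ranks may change (they do here)
    assert not out.values["lh_cuneus_volume"].rank().equals(ranks_before)
    const = _tiny_table()
    const.values["BrainSegVolNotVent"] = 1000.0
    out2 = sc.normalize_features(const)
    assert out2.values["lh_cuneus_volume"].rank().equals(ranks_before)


# ---------------------------------------------------------------------------
# L/R augmentation
# ---------------------------------------------------------------------------

def test_augmentation_arithmetic_and_metadata():
    table = _tiny_table()
    out = sc.augment_lr(table)
    # L=100, R=200 -> avg 150, asym (L-R)/2 = -50
    assert out.values.loc["s1", "mean_cuneus_volume"] == 150.0
    assert out.values.loc["s1", "asym_cuneus_volume"] == -50.0
    meta = out.metadata
    assert meta.loc["mean_cuneus_volume", "hemisphere"] == "bilateral_avg"
    assert meta.loc["asym_cuneus_volume", "hemisphere"] == "bilateral_asym"
    # originals retained; count = base + 2 * pairs (4 pairs here)
    assert out.n_features == table.n_features + 2 * 4


def test_mirror_symmetric_input_gives_zero_asym():
    table = _tiny_table()
    for lh, rh in [("lh_cuneus_volume", "rh_cuneus_volume"),
                   ("lh_cuneus_thickness", "rh_cuneus_thickness"),
                   ("lh_cuneus_area", "rh_cuneus_area"),
                   ("lh_MeanThickness_thickness", "rh_MeanThickness_thickness")]:
        table.values[rh] = table.values[lh]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = sc.BilateralAugmenter(drop_degenerate=False).fit_transform(table)
    asym_cols = out.metadata.index[out.metadata.hemisphere == "bilateral_asym"]
    assert len(asym_cols) == 4
    assert (out.values[asym_cols] == 0).all().all()


def test_unpaired_feature_skipped_with_warning():
    values = pd.DataFrame({"lh_cuneus_volume": [1.0, 2, 3],
                           "rh_lingual_volume": [4.0, 5, 6]},
                          index=["a", "b", "c"])
    table = sc.FeatureTable(values)
    with pytest.warns(UserWarning, match="unpaired"):
        out = sc.augment_lr(table)
    assert out.n_features == 2


def test_degenerate_augmented_feature_dropped_after_normalization():
    out = sc.normalize_features(_tiny_table())
    with pytest.warns(UserWarning, match="degenerate"):
        aug = sc.augment_lr(out)
    # lh/rh MeanThickness average is identically 1 after normalization
    assert "mean_MeanThickness_thickness" not in aug.feature_ids
    assert "asym_MeanThickness_thickness" in aug.feature_ids


def test_table_roundtrip_bit_exact(tmp_path, cohort):
    table, _ = cohort
    table.write(tmp_path / "t.tsv", tmp_path / "m.csv")
    back = sc.FeatureTable.read(tmp_path / "t.tsv", tmp_path / "m.csv")
    pd.testing.assert_frame_equal(back.values, table.values, check_exact=True)
    back.write(tmp_path / "t2.tsv", tmp_path / "m2.csv")
    assert (tmp_path / "t.tsv").read_bytes() == (tmp_path / "t2.tsv").read_bytes()
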