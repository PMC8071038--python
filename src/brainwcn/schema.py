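"""Morphometric feature schema, ingestion, normalization and L/R augmentation.

The feature table is the central container: a subjects-by-features numeric
matrix (a pandas DataFrame) paired with per-feature metadata describing
anatomical region, hemisphere/laterality, the kind of measurement
(volume, surface area, thickness, curvature) and which normalization class
the feature belongs to.

Raw FreeSurfer morphometry scales with head size, so features are
normalized for inter-individual variability before any correlation is
computed: volumes by total segmented brain volume (without ventricles),
cortical thicknesses by the subject's mean cortical thickness, and
cortical areas by the subject's total cortical surface area. After
normalization, each left/right homologous pair is augmented with its
bilateral average (L+R)/2 and asymmetry (L-R)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FeatureTable",
    "SchemaError",
    "IngestionError",
    "parse_feature_name",
    "read_freesurfer_tables",
    "read_phenotype",
    "select_cohort",
    "cohort_balance_check",
    "FeatureNormalizer",
    "BilateralAugmenter",
    "normalize_features",
    "augment_lr",
]

HEMISPHERES = ("left", "right", "bilateral_avg", "bilateral_asym", "global")
MEASURE_KINDS = (
    "volume",
    "surface_area",
    "thickness_mean",
    "thickness_sd",
    "mean_curvature",
    "curvature_index",
    "other",
)
NORM_CLASSES = ("volume_like", "thickness_like", "area_like", "none")

METADATA_COLUMNS = ("region", "hemisphere", "measure", "norm_class", "category", "is_normalizer")


class SchemaError(ValueError):
    """Schema/metadata inconsistency (unknown class, broken pairing, ...)."""


class IngestionError(ValueError):
    """Malformed input table (non-numeric cell, duplicate feature, ...)."""


# Suffix conventions used by aparcstats2table output columns.
_CORTICAL_SUFFIXES = {
    "volume": ("volume", "volume_like"),
    "area": ("surface_area", "area_like"),
    "thickness": ("thickness_mean", "thickness_like"),
    "thicknessstd": ("thickness_sd", "thickness_like"),
    "meancurv": ("mean_curvature", "none"),
    "curvind": ("curvature_index", "none"),
}

# Whole-brain summary features emitted by FreeSurfer stats tables.
_GLOBAL_FEATURES = {
    "lhCortexVol": ("CortexVol", "left", "volume", "volume_like"),
    "rhCortexVol": ("CortexVol", "right", "volume", "volume_like"),
    "lhCerebralWhiteMatterVol": ("CerebralWhiteMatterVol", "left", "volume", "volume_like"),
    "rhCerebralWhiteMatterVol": ("CerebralWhiteMatterVol", "right", "volume", "volume_like"),
    "TotalGrayVol": ("TotalGrayVol", "global", "volume", "volume_like"),
}

_NORMALIZER_FEATURES = {
    "BrainSegVolNotVent": ("BrainSegVolNotVent", "global", "volume", "none"),
}


def parse_feature_name(name: str) -> dict:
    """Infer feature metadata from a FreeSurfer-style column name.

    Recognizes ``lh_<region>_<suffix>`` / ``rh_<region>_<suffix>`` cortical
    columns, ``Left-X`` / ``Right-X`` aseg volume columns, the whole-brain
    summary columns (``TotalGrayVol``, ``lhCortexVol``, ...), the global
    normalizer ``BrainSegVolNotVent``, and the ``mean_`` / ``asym_``
    prefixes this package itself emits for bilateral augmented features.
    Anything else is classified as measure ``other`` with no normalization.
    """
    if name in _NORMALIZER_FEATURES:
        region, hemi, measure, norm = _NORMALIZER_FEATURES[name]
        return dict(region=region, hemisphere=hemi, measure=measure,
                    norm_class=norm, category="normalizer", is_normalizer=True)
    if name in _GLOBAL_FEATURES:
        region, hemi, measure, norm = _GLOBAL_FEATURES[name]
        return dict(region=region, hemisphere=hemi, measure=measure,
                    norm_class=norm, category="global", is_normalizer=False)
    for prefix, hemi in (("lh_", "left"), ("rh_", "right")):
        if name.startswith(prefix):
            rest = name[len(prefix):]
            for suffix, (measure, norm) in _CORTICAL_SUFFIXES.items():
                if rest.endswith("_" + suffix):
                    region = rest[: -(len(suffix) + 1)]
                    category = "global" if region == "MeanThickness" else "cortical"
                    return dict(region=region, hemisphere=hemi, measure=measure,
                                norm_class=norm, category=category, is_normalizer=False)
            return dict(region=rest, hemisphere=hemi, measure="other",
                        norm_class="none", category="cortical", is_normalizer=False)
    for prefix, hemi in (("Left-", "left"), ("Right-", "right")):
        if name.startswith(prefix):
            region = name[len(prefix):]
            return dict(region=region, hemisphere=hemi, measure="volume",
                        norm_class="volume_like", category="subcortical_bilateral",
                        is_normalizer=False)
    for prefix, hemi in (("mean_", "bilateral_avg"), ("asym_", "bilateral_asym")):
        if name.startswith(prefix):
            base = parse_feature_name(name[len(prefix):])
            return dict(region=base["region"], hemisphere=hemi, measure=base["measure"],
                        norm_class="none", category="augmented", is_normalizer=False)
    # Remaining aseg rows: midline / unpaired subcortical volumes.
    if name.startswith("CC_") or name in (
        "Brain-Stem", "CSF", "3rd-Ventricle", "4th-Ventricle",
        "5th-Ventricle", "Optic-Chiasm", "WM-hypointensities",
        "non-WM-hypointensities",
    ):
        return dict(region=name, hemisphere="global", measure="volume",
                    norm_class="volume_like", category="subcortical_other",
                    is_normalizer=False)
    return dict(region=name, hemisphere="global", measure="other",
                norm_class="none", category="other", is_normalizer=False)


def metadata_from_names(names: Iterable[str]) -> pd.DataFrame:
    """Build a metadata frame (indexed by feature_id) by parsing names."""
    records = {name: parse_feature_name(name) for name in names}
    meta = pd.DataFrame.from_dict(records, orient="index")
    meta.index.name = "feature_id"
    return meta[list(METADATA_COLUMNS)]


@dataclass
class FeatureTable:
    """Subjects-by-features matrix plus per-feature metadata.

    Parameters
    ----------
    values
        DataFrame, index = subject IDs, columns = feature IDs, all numeric.
    metadata
        DataFrame indexed by feature ID with columns
        ``region, hemisphere, measure, norm_class, category, is_normalizer``.
        Missing metadata is inferred from feature names.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = None
    normalized: bool = False
    ingestion_report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values.index.name = "subject_id"
        self.values.columns.name = None
        if self.metadata is None:
            self.metadata = metadata_from_names(self.values.columns)
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise IngestionError(f"duplicate feature names: {dupes}")
        if self.values.index.duplicated().any():
            raise IngestionError("duplicate subject IDs")
        if list(self.metadata.index) != list(self.values.columns):
            missing = set(self.values.columns) - set(self.metadata.index)
            if missing:
                raise SchemaError(f"metadata missing for features: {sorted(missing)[:5]} ...")
            self.metadata = self.metadata.loc[self.values.columns]
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise IngestionError(f"missing values for subjects: {bad}")
        bad_hemi = set(self.metadata["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise SchemaError(f"unknown hemisphere labels: {bad_hemi}")
        bad_norm = set(self.metadata["norm_class"]) - set(NORM_CLASSES)
        if bad_norm:
            raise SchemaError(f"unknown norm classes: {bad_norm}")

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.metadata.copy(),
                            normalized=self.normalized,
                            ingestion_report=dict(self.ingestion_report))

    def select_subjects(self, subject_ids: Sequence[str]) -> "FeatureTable":
        missing = set(subject_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown subjects: {sorted(missing)[:5]}")
        return FeatureTable(self.values.loc[list(subject_ids)], self.metadata,
                            normalized=self.normalized)

    def node_feature_ids(self, include_normalizers: bool = False) -> list[str]:
        """Feature IDs eligible as network nodes (normalizers excluded by default)."""
        if include_normalizers:
            return self.feature_ids
        keep = ~self.metadata["is_normalizer"].astype(bool)
        return list(self.metadata.index[keep])

    def node_values(self, include_normalizers: bool = False) -> pd.DataFrame:
        return self.values[self.node_feature_ids(include_normalizers)]

    def homologous_pairs(self) -> list[tuple[str, str]]:
        """All (left_id, right_id) pairs with identical region and measure."""
        meta = self.metadata
        left = meta[meta["hemisphere"] == "left"]
        right = meta[meta["hemisphere"] == "right"]
        rkey = {(r.region, r.measure): fid for fid, r in right.iterrows()}
        pairs, unpaired = [], []
        for fid, row in left.iterrows():
            mate = rkey.pop((row.region, row.measure), None)
            if mate is None:
                unpaired.append(fid)
            else:
                pairs.append((fid, mate))
        unpaired.extend(rkey.values())
        if unpaired:
            warnings.warn(f"unpaired lateralized features skipped: {sorted(unpaired)}")
        return pairs

    # -- IO ----------------------------------------------------------------
    def write(self, values_path: str | Path, metadata_path: str | Path | None = None) -> None:
        """Write values as TSV (first column = subject ID) and metadata as CSV."""
        self.values.to_csv(values_path, sep="\t")
        if metadata_path is not None:
            meta = self.metadata.copy()
            meta.index.name = "feature_id"
            meta.to_csv(metadata_path)

    @classmethod
    def read(cls, values_path: str | Path,
             metadata_path: str | Path | None = None) -> "FeatureTable":
        values = pd.read_csv(values_path, sep="\t", index_col=0,
                             float_precision="round_trip", comment="#")
        values.index = values.index.astype(str)
        metadata = None
        if metadata_path is not None:
            metadata = pd.read_csv(metadata_path, index_col=0, comment="#")
            if "is_normalizer" in metadata:
                metadata["is_normalizer"] = metadata["is_normalizer"].astype(bool)
        return cls(values, metadata)


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

def read_freesurfer_tables(paths: Sequence[str | Path]) -> FeatureTable:
    """Read and merge FreeSurfer ``asegstats2table`` / ``aparcstats2table`` TSVs.

    Each file is tab-separated with the subject label in the first column
    and one numeric feature per remaining column. Files are merged on the
    intersection of their subject sets; feature names must be globally
    unique. Rows with empty cells are dropped (reported in
    ``ingestion_report``); a non-numeric token raises
    :class:`IngestionError` naming the subject and the feature.
    """
    if not paths:
        raise ValueError("no input files given")
    frames = []
    dropped: dict[str, list[str]] = {}
    for path in paths:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        feature_cols = header[1:]
        seen = set()
        for col in feature_cols:
            if col in seen:
                raise IngestionError(f"{path}: duplicate feature name {col!r}")
            seen.add(col)
        raw = pd.read_csv(path, sep="\t", dtype=str,
                          keep_default_na=False, na_values=[])
        raw = raw.set_index(raw.columns[0])
        raw.index = raw.index.astype(str)
        raw = raw.apply(lambda s: s.str.strip())
        screened = raw.replace("", np.nan).apply(pd.to_numeric, errors="coerce")
        # empty cells -> subject dropped; non-numeric tokens -> hard error
        for col in raw.columns:
            bad = raw.index[screened[col].isna() & (raw[col] != "")]
            if len(bad):
                raise IngestionError(
                    f"{path}: non-numeric value {raw.loc[bad[0], col]!r} for "
                    f"subject {bad[0]!r}, feature {col!r}")
        # exact (round-trip) parse now that every token is known numeric
        numeric = raw.replace("", np.nan).astype(float)
        incomplete = numeric.index[numeric.isna().any(axis=1)].tolist()
        if incomplete:
            dropped[str(path)] = incomplete
            numeric = numeric.drop(index=incomplete)
        frames.append(numeric)
    common = frames[0].index
    for frame in frames[1:]:
        common = common.intersection(frame.index)
    if len(common) == 0:
        raise IngestionError("no subjects common to all input files")
    merged = pd.concat([f.loc[common] for f in frames], axis=1)
    if merged.columns.duplicated().any():
        dupes = merged.columns[merged.columns.duplicated()].tolist()
        raise IngestionError(f"duplicate feature names across files: {dupes}")
    table = FeatureTable(merged)
    table.ingestion_report = {
        "n_files": len(paths),
        "n_subjects": len(common),
        "dropped_incomplete_rows": dropped,
    }
    if dropped:
        warnings.warn(f"dropped subjects with missing entries: {dropped}")
    return table


_PHENO_COLUMNS = ("subject_id", "group", "age", "sex", "handedness")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV with columns subject_id, group, age, sex, handedness."""
    pheno = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(_PHENO_COLUMNS) - set(pheno.columns)
    if missing:
        raise IngestionError(f"phenotype table missing columns: {sorted(missing)}")
    if pheno["subject_id"].duplicated().any():
        raise IngestionError("duplicate subject_id in phenotype table")
    if (pheno["age"] <= 0).any():
        bad = pheno.loc[pheno["age"] <= 0, "subject_id"].tolist()
        raise IngestionError(f"non-positive age for subjects: {bad}")
    return pheno


def select_cohort(pheno: pd.DataFrame, criteria: Mapping[str, object] | None = None
                  ) -> dict[str, list[str]]:
    """Filter subjects by phenotype criteria, partitioned by group label.

    ``criteria`` maps a phenotype column to an allowed value (or list of
    values), e.g. ``{"sex": "M", "handedness": "R"}``. An empty/None
    criteria returns everybody. Raises ``ValueError`` on empty selection.
    """
    mask = pd.Series(True, index=pheno.index)
    for column, allowed in (criteria or {}).items():
        if column not in pheno.columns:
            raise KeyError(f"criterion on unknown phenotype field {column!r}")
        if isinstance(allowed, (list, tuple, set, frozenset)):
            mask &= pheno[column].isin(list(allowed))
        else:
            mask &= pheno[column] == allowed
    selected = pheno[mask]
    if selected.empty:
        raise ValueError(f"no subjects match criteria {criteria!r}")
    return {str(grp): sub["subject_id"].tolist()
            for grp, sub in selected.groupby("group", sort=True)}


def cohort_balance_check(ages_a: Sequence[float], ages_b: Sequence[float]) -> dict:
    """Two-tailed two-sample Kolmogorov–Smirnov test on two age samples.

    Returns ``{"D": statistic, "p": two-tailed p-value}``. Used to check
    that restricting a cohort (e.g. to right-handed males) does not
    introduce an age bias between the groups.
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each age sample needs at least 2 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return {"D": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class FeatureNormalizer(BaseEstimator, TransformerMixin):
    """Normalize morphometric features for inter-individual variability.

    Per subject: ``volume_like`` features are divided by the global brain
    segmented volume without ventricles (``BrainSegVolNotVent``);
    ``thickness_like`` features by the mean cortical thickness, computed as
    the average of the left- and right-hemisphere mean thickness; and
    ``area_like`` features by the sum of all cortical surface areas.
    Features with ``norm_class='none'`` (curvatures, normalizers) pass
    through unchanged. Normalizer columns are retained but stay flagged, so
    they are excluded from network nodes by default.

    The transform is one-shot: applying it to an already-normalized table
    is refused.
    """

    def fit(self, table: FeatureTable, y=None):
        self._check(table)
        self.n_features_in_ = table.n_features
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        norms = self._check(table)
        values = table.values.copy()
        meta = table.metadata
        for klass, denom in norms.items():
            cols = meta.index[(meta["norm_class"] == klass) & ~meta["is_normalizer"]]
            if len(cols):
                values[cols] = values[cols].div(denom, axis=0)
        return FeatureTable(values, meta.copy(), normalized=True)

    def fit_transform(self, table: FeatureTable, y=None, **kwargs) -> FeatureTable:
        return self.fit(table).transform(table)

    def _check(self, table: FeatureTable) -> dict[str, pd.Series]:
        if table.normalized:
            raise ValueError("table is already normalized (one-shot transform)")
        meta = table.metadata
        norms: dict[str, pd.Series] = {}
        needed = set(meta.loc[~meta["is_normalizer"], "norm_class"]) - {"none"}
        if "volume_like" in needed:
            if "BrainSegVolNotVent" not in table.values.columns:
                raise SchemaError("volume normalizer BrainSegVolNotVent missing")
            norms["volume_like"] = table.values["BrainSegVolNotVent"]
        if "thickness_like" in needed:
            thick = meta.index[(meta["region"] == "MeanThickness")
                               & meta["hemisphere"].isin(["left", "right"])]
            if len(thick) != 2:
                raise SchemaError(
                    "thickness normalizers (lh/rh MeanThickness) missing or duplicated")
            norms["thickness_like"] = table.values[list(thick)].mean(axis=1)
        if "area_like" in needed:
            areas = meta.index[(meta["measure"] == "surface_area")
                               & (meta["category"] == "cortical")]
            if len(areas) == 0:
                raise SchemaError("no cortical surface areas to form the area normalizer")
            norms["area_like"] = table.values[list(areas)].sum(axis=1)
        for klass, denom in norms.items():
            bad = denom.index[denom <= 0]
            if len(bad):
                raise ValueError(
                    f"{klass} normalizer non-positive for subject {bad[0]!r}")
        # positivity contract on the raw features themselves
        for klass in needed:
            cols = meta.index[(meta["norm_class"] == klass) & ~meta["is_normalizer"]]
            vals = table.values[list(cols)]
            if (vals <= 0).any().any():
                col = vals.columns[(vals <= 0).any()][0]
                raise ValueError(f"non-positive {klass} feature before "
                                 f"normalization: {col!r}")
        return norms


class BilateralAugmenter(BaseEstimator, TransformerMixin):
    """Append bilateral average and asymmetry features for each L/R pair.

    For every homologous (left, right) feature pair with identical region
    and measure, two features are appended: ``mean_<id> = (L+R)/2``
    (hemisphere ``bilateral_avg``) and ``asym_<id> = (L-R)/2`` (hemisphere
    ``bilateral_asym``; sign convention left minus right). Original
    features are retained; unpaired lateralized features are skipped with
    a warning.

    With ``drop_degenerate=True`` (default), an augmented feature that is
    constant across subjects up to floating-point jitter is not appended
    (warned, recorded in ``degenerate_``). The canonical case is the
    bilateral average of the two hemisphere mean-thickness columns after
    thickness normalization, which is identically 1 by construction and
    would otherwise enter the network as a pure-noise node.
    """

    def __init__(self, drop_degenerate: bool = True):
        self.drop_degenerate = drop_degenerate

    def fit(self, table: FeatureTable, y=None):
        self.pairs_ = table.homologous_pairs()
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        pairs = table.homologous_pairs()
        values = table.values.copy()
        meta = table.metadata.copy()
        new_cols = {}
        new_meta = {}
        self.degenerate_ = []
        for left_id, right_id in pairs:
            stem = self._stem(left_id)
            base = meta.loc[left_id]
            left, right = values[left_id], values[right_id]
            for prefix, hemi, col in (
                    ("mean_", "bilateral_avg", (left + right) / 2.0),
                    ("asym_", "bilateral_asym", (left - right) / 2.0)):
                name = prefix + stem
                if (self.drop_degenerate and len(col) >= 3
                        and np.ptp(col.to_numpy())
                        <= 1e-12 * max(1.0, float(np.abs(col).max()))):
                    self.degenerate_.append(name)
                    continue
                new_cols[name] = col
                new_meta[name] = dict(
                    region=base["region"], hemisphere=hemi, measure=base["measure"],
                    norm_class="none", category="augmented", is_normalizer=False)
        if self.degenerate_:
            warnings.warn("degenerate (constant) augmented features skipped: "
                          f"{self.degenerate_}")
        if new_cols:
            values = pd.concat([values, pd.DataFrame(new_cols, index=values.index)], axis=1)
            extra = pd.DataFrame.from_dict(new_meta, orient="index")[list(METADATA_COLUMNS)]
            meta = pd.concat([meta, extra])
        return FeatureTable(values, meta, normalized=table.normalized)

    def fit_transform(self, table: FeatureTable, y=None, **kwargs) -> FeatureTable:
        return self.fit(table).transform(table)

    @staticmethod
    def _stem(left_id: str) -> str:
        for prefix in ("lh_", "Left-", "lh"):
            if left_id.startswith(prefix):
                return left_id[len(prefix):]
        return left_id


def normalize_features(table: FeatureTable) -> FeatureTable:
    """Functional wrapper around :class:`FeatureNormalizer`."""
    return FeatureNormalizer().fit_transform(table)


def augment_lr(table: FeatureTable) -> FeatureTable:
    """Functional wrapper around :class:`BilateralAugmenter`."""
    return BilateralAugmenter().fit_transform(table)
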