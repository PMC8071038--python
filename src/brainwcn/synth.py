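"""Synthetic two-group morphometric cohorts with plantable network differences.

The generator emulates the statistical shape of a FreeSurfer morphometry
study: a feature schema of bilateral cortical measures, subcortical
volumes and global summaries; strictly positive volumes/areas/thicknesses;
block-correlated features within anatomical groupings; two groups of
unequal size; and per-subject ages for the balance check.

The generative model is a Gaussian copula: a latent multivariate normal
whose correlation matrix is a sum of positive-semidefinite components —
a global factor shared by every feature (``rho_global``, emulating head
size), an anatomical-block factor (``rho_block``, features of the same
region or structure), and a mirrored lateralization factor
(``rho_lateral``, loading +1 on left features and -1 on right features,
so that a subject lateralized one way is consistently lateralized across
regions). The lateralization component is what gives the derived
asymmetry features (L-R)/2 genuine mutual correlation, as in real
lateralized anatomy. The latent draw is pushed through strictly monotone
per-feature maps to realistic positive scales. Because the downstream
analysis is rank-based,
the choice of monotone marginal map is immaterial to the networks — only
the latent correlation structure matters, which is exactly what the
planted case/control difference manipulates: in the case group only,
each planted node's non-global factor loadings are attenuated by
``1 - planted_delta``, decoupling it from its anatomical covariance
structure while it keeps tracking overall brain scale.

This is a stand-in for real structural-covariance data, not a simulation
of FreeSurfer output; site effects, measurement noise structure and
realistic marginals are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import FeatureTable, metadata_from_names

__all__ = [
    "CORTICAL_REGIONS",
    "SUBCORTICAL_BILATERAL",
    "SUBCORTICAL_OTHER",
    "GLOBAL_FEATURES",
    "SynthConfig",
    "make_schema",
    "make_canonical_schema",
    "block_partition",
    "latent_correlation",
    "generate_cohort",
    "write_fixture",
]

# 31 bilateral cortical regions of the Desikan-Killiany-Tourville atlas.
CORTICAL_REGIONS = (
    "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus", "entorhinal",
    "fusiform", "inferiorparietal", "inferiortemporal", "isthmuscingulate",
    "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal",
    "transversetemporal", "insula",
)

CORTICAL_SUFFIXES = ("volume", "area", "thickness", "thicknessstd",
                     "meancurv", "curvind")

# 14 left/right subcortical + cerebellar volume pairs from aseg.stats.
SUBCORTICAL_BILATERAL = (
    "Cerebellum-White-Matter", "Cerebellum-Cortex", "Thalamus-Proper",
    "Caudate", "Putamen", "Pallidum", "Hippocampus", "Amygdala",
    "Accumbens-area", "VentralDC", "Lateral-Ventricle", "Inf-Lat-Vent",
    "choroid-plexus", "vessel",
)

# 12 midline / unpaired subcortical volumes (corpus callosum, brainstem, ...).
SUBCORTICAL_OTHER = (
    "CC_Posterior", "CC_Mid_Posterior", "CC_Central", "CC_Mid_Anterior",
    "CC_Anterior", "Brain-Stem", "CSF", "3rd-Ventricle", "4th-Ventricle",
    "Optic-Chiasm", "WM-hypointensities", "non-WM-hypointensities",
)

# 7 whole-brain summary features.
GLOBAL_FEATURES = (
    "lhCortexVol", "rhCortexVol", "lhCerebralWhiteMatterVol",
    "rhCerebralWhiteMatterVol", "TotalGrayVol",
    "lh_MeanThickness_thickness", "rh_MeanThickness_thickness",
)

NORMALIZER_FEATURE = "BrainSegVolNotVent"


def make_schema(cortical_regions: Sequence[str] = CORTICAL_REGIONS,
                cortical_suffixes: Sequence[str] = CORTICAL_SUFFIXES,
                subcortical_bilateral: Sequence[str] = SUBCORTICAL_BILATERAL,
                subcortical_other: Sequence[str] = SUBCORTICAL_OTHER,
                include_globals: bool = True,
                include_normalizer: bool = True) -> pd.DataFrame:
    """Build a feature-metadata frame following FreeSurfer naming conventions.

    With the defaults this is the canonical 419-feature schema (372
    bilateral cortical + 28 bilateral subcortical + 12 other subcortical +
    7 global), plus the flagged ``BrainSegVolNotVent`` normalizer column.
    Smaller schemas for fast experiments are obtained by restricting the
    region / measure lists.
    """
    names: list[str] = []
    for hemi in ("lh", "rh"):
        for region in cortical_regions:
            for suffix in cortical_suffixes:
                names.append(f"{hemi}_{region}_{suffix}")
    for side in ("Left", "Right"):
        for struct in subcortical_bilateral:
            names.append(f"{side}-{struct}")
    names.extend(subcortical_other)
    if include_globals:
        names.extend(GLOBAL_FEATURES)
    if include_normalizer:
        names.append(NORMALIZER_FEATURE)
    return metadata_from_names(names)


def make_canonical_schema() -> pd.DataFrame:
    """The canonical 419-feature schema (+ flagged normalizer column)."""
    return make_schema()


def block_partition(schema: pd.DataFrame) -> pd.Series:
    """Assign each feature to an anatomical correlation block.

    Cortical features of one region (all measures, both hemispheres) form
    one block, as do the two sides of a subcortical pair; midline
    subcortical volumes are singleton blocks; global summaries and the
    normalizer share one block (they all track overall brain size).
    """
    def block(fid: str, row) -> str:
        if row["category"] in ("global", "normalizer"):
            return "global"
        if row["category"] in ("cortical", "subcortical_bilateral"):
            return f"{row['category']}:{row['region']}"
        return f"single:{fid}"

    return pd.Series({fid: block(fid, row) for fid, row in schema.iterrows()},
                     name="block").loc[schema.index]


@dataclass
class SynthConfig:
    """Configuration of the synthetic two-group cohort generator.

    Defaults mirror the reference study design: 235 case vs 418 control
    subjects, the canonical 419-feature schema, moderate within-block
    correlation over a weak global (head-size-like) correlation, and
    identical age distributions in the two groups so the
    Kolmogorov-Smirnov balance check passes.
    """

    n_case: int = 235
    n_control: int = 418
    schema: pd.DataFrame = dataclass_field(default_factory=make_canonical_schema)
    rho_global: float = 0.15
    rho_block: float = 0.45
    rho_lateral: float = 0.1
    rho_measure: float = 0.12
    loading_jitter: float = 0.25
    rho_aggregate: float = 0.85
    rho_global_volume: float = 0.3
    planted_nodes: tuple[str, ...] = ()
    planted_delta: float = 0.0
    age_mean: float = 17.0
    age_sd: float = 8.0
    age_min: float = 7.0
    age_shift_case: float = 0.0   # add to case ages to inject a deliberate bias
    frac_female: float = 0.0
    frac_left_handed: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_case < 3 or self.n_control < 3:
            raise ValueError("each group needs at least 3 subjects")
        rhos = ("rho_global", "rho_block", "rho_lateral", "rho_measure")
        for name in rhos:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if sum(getattr(self, name) for name in rhos) >= 1.0:
            raise ValueError("the rho_* components must sum to < 1")
        if not 0.0 <= self.planted_delta <= 1.0:
            raise ValueError("planted_delta is a relative attenuation in [0, 1]")
        if not 0.0 <= self.loading_jitter < 1.0:
            raise ValueError("loading_jitter must be in [0, 1)")
        unknown = set(self.planted_nodes) - set(self.schema.index)
        if unknown:
            raise ValueError(f"planted nodes not in schema: {sorted(unknown)}")


def latent_correlation(cfg: SynthConfig, perturbed: bool) -> np.ndarray:
    """Latent Gaussian correlation matrix for one group.

    The matrix is built from a factor model with unit-variance latent
    factors: one global (head-size) factor loading sqrt(rho_global) on
    every feature, one factor per anatomical block loading
    sqrt(rho_block), one factor per measure kind loading
    sqrt(rho_measure) (all volumes co-scale beyond head size, which
    keeps midline volumes embedded in the volume covariance web), and
    one mirrored lateralization factor loading s_i * sqrt(rho_lateral)
    with s = +1 (left), -1 (right), 0 (midline / global). For the
    unperturbed group this gives

    ``C_ij = rho_global + rho_block * [same block]
    + rho_measure * [same measure kind] + rho_lateral * s_i s_j``

    so that the rho_* values are the mean pairwise contributions. Each
    feature's factor loadings are additionally jittered by a per-feature
    multiplicative factor in ``1 +/- loading_jitter`` (drawn
    deterministically from the seed, identically for both groups), so
    pair correlations form a continuum rather than a few discrete
    levels — as in real covariance data, where no two region pairs share
    the exact same coupling.

    With ``perturbed=True``, every planted node's non-global loadings
    are attenuated by the factor ``1 - planted_delta``: its anatomical
    covariance structure shrinks toward pure head-size scaling
    (planted-to-other structured correlation scales by 1 - delta,
    planted-to-planted by its square). Positive semi-definiteness is
    guaranteed by the factor construction and still validated, a
    violation raising with the offending blocks.
    """
    schema = cfg.schema
    blocks = block_partition(schema)
    block_codes = pd.factorize(blocks)[0]
    kind_codes = pd.factorize(schema["measure"])[0]
    sign = schema["hemisphere"].map({"left": 1.0, "right": -1.0}).fillna(0.0)
    s = sign.to_numpy()
    n = len(schema)
    n_blocks, n_kinds = block_codes.max() + 1, kind_codes.max() + 1
    loadings = np.zeros((n, 1 + n_blocks + n_kinds + 1))
    loadings[:, 0] = np.sqrt(cfg.rho_global)
    # volumes carry far more head-size variance than thickness/curvature;
    # corr(volume, total brain volume) ~ sqrt(rho_global_volume *
    # rho_aggregate) ~ 0.5, at which ratio normalization leaves pairwise
    # correlations approximately unchanged instead of inducing spurious
    # shared-denominator structure
    is_volume = (schema["measure"] == "volume").to_numpy()
    loadings[is_volume, 0] = np.sqrt(cfg.rho_global_volume)
    loadings[np.arange(n), 1 + block_codes] = np.sqrt(cfg.rho_block)
    loadings[np.arange(n), 1 + n_blocks + kind_codes] = np.sqrt(cfg.rho_measure)
    loadings[:, -1] = s * np.sqrt(cfg.rho_lateral)
    # Aggregate summary features are dominated by the factor they sum over:
    # total brain volume IS the global size factor up to little residual
    # noise, and the hemisphere mean thicknesses track the thickness kind
    # factor. Without this, dividing by a noisy normalizer would induce
    # spurious shared-denominator correlation across all ratio features.
    is_norm = (schema["category"] == "normalizer").to_numpy()
    loadings[is_norm] = 0.0
    loadings[is_norm, 0] = np.sqrt(cfg.rho_aggregate)
    is_meanthick = (schema["region"] == "MeanThickness").to_numpy()
    if is_meanthick.any():
        kind_col = 1 + n_blocks + kind_codes[is_meanthick]
        share = min(cfg.rho_aggregate - cfg.rho_global, 0.6)
        loadings[np.flatnonzero(is_meanthick), kind_col] = np.sqrt(max(share, 0.0))
    if cfg.loading_jitter > 0:
        # structure randomness is part of the configuration, not the draw:
        # both groups see the identical jittered structure
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
        factor = 1.0 + cfg.loading_jitter * rng.uniform(-1, 1, size=loadings.shape)
        loadings = loadings * factor
    # keep every feature's structured variance share below 0.9 so the
    # idiosyncratic residual stays positive (guarantees PSD)
    share = (loadings ** 2).sum(axis=1)
    over = share > 0.9
    loadings[over] *= np.sqrt(0.9 / share[over])[:, None]
    if perturbed and cfg.planted_delta != 0.0 and cfg.planted_nodes:
        pos = {fid: i for i, fid in enumerate(schema.index)}
        idx = [pos[fid] for fid in cfg.planted_nodes]
        loadings[idx, 1:] *= 1.0 - cfg.planted_delta
    corr = loadings @ loadings.T
    np.fill_diagonal(corr, 1.0)
    eigmin = float(np.linalg.eigvalsh(corr)[0])
    if eigmin < -1e-8:
        planted_blocks = sorted({blocks.iloc[pos[fid]]
                                 for fid in cfg.planted_nodes}) \
            if cfg.planted_nodes else []
        raise ValueError(
            f"correlation matrix not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g}); offending blocks: "
            f"{planted_blocks}")
    return corr


# Monotone marginal maps: (base scale, lognormal sd) for positive-valued
# kinds, or a linear (offset, slope) for curvature-like kinds.
_LOGNORMAL_SCALE = {
    "volume": (8000.0, 0.15),
    "surface_area": (1500.0, 0.15),
    "thickness_mean": (2.5, 0.06),
    "thickness_sd": (0.5, 0.10),
}
_LINEAR_SCALE = {
    "mean_curvature": (0.12, 0.02),
    "curvature_index": (2.0, 0.5),
}
_VOLUME_SCALE_OVERRIDES = {
    "global": 2.0e5,
    "normalizer": 1.1e6,
}


def _marginal_map(z: np.ndarray, row: pd.Series) -> np.ndarray:
    measure = row["measure"]
    if measure in _LOGNORMAL_SCALE:
        scale, sd = _LOGNORMAL_SCALE[measure]
        scale = _VOLUME_SCALE_OVERRIDES.get(row["category"], scale)
        return scale * np.exp(sd * z)
    offset, slope = _LINEAR_SCALE.get(measure, (0.0, 1.0))
    return offset + slope * z


def generate_cohort(cfg: SynthConfig) -> tuple[FeatureTable, pd.DataFrame]:
    """Draw a synthetic (feature table, phenotype table) pair.

    Deterministic for a given ``cfg.seed``. The control group follows the
    base block-correlation structure; the case group follows the
    perturbed structure when a planted difference is configured.
    """
    rng = np.random.default_rng(cfg.seed)
    schema = cfg.schema
    n_feat = len(schema)

    def draw_group(n: int, perturbed: bool, prefix: str) -> pd.DataFrame:
        corr = latent_correlation(cfg, perturbed)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_feat))
        latent = rng.standard_normal((n, n_feat)) @ chol.T
        values = np.empty_like(latent)
        for j, (fid, row) in enumerate(schema.iterrows()):
            values[:, j] = _marginal_map(latent[:, j], row)
        ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
        return pd.DataFrame(values, index=ids, columns=schema.index)

    control = draw_group(cfg.n_control, perturbed=False, prefix="ctrl")
    case = draw_group(cfg.n_case, perturbed=True, prefix="case")
    values = pd.concat([control, case])
    table = FeatureTable(values, schema.copy())

    def draw_ages(n: int, shift: float) -> np.ndarray:
        ages = np.empty(n)
        for i in range(n):
            a = cfg.age_mean + shift + cfg.age_sd * rng.standard_normal()
            while a < cfg.age_min:
                a = cfg.age_mean + shift + cfg.age_sd * rng.standard_normal()
            ages[i] = a
        return ages

    rows = []
    for ids, group, shift in ((control.index, "control", 0.0),
                              (case.index, "case", cfg.age_shift_case)):
        ages = draw_ages(len(ids), shift)
        sex = np.where(rng.random(len(ids)) < cfg.frac_female, "F", "M")
        hand = np.where(rng.random(len(ids)) < cfg.frac_left_handed, "L", "R")
        rows.append(pd.DataFrame(dict(subject_id=list(ids), group=group,
                                      age=ages, sex=sex, handedness=hand)))
    pheno = pd.concat(rows, ignore_index=True)
    return table, pheno


def write_fixture(table: FeatureTable, pheno: pd.DataFrame,
                  out_dir: str | Path) -> list[Path]:
    """Write a cohort as FreeSurfer-dialect stats TSVs plus a phenotype CSV.

    Emits one ``{lh,rh}.aparc.<measure>.tsv`` per hemisphere and cortical
    measure (with the hemisphere mean-thickness summary appended to the
    thickness tables, as aparcstats2table does), one ``aseg.tsv`` with
    the volumetric and global columns, and ``phenotype.csv``. The files
    round-trip bit-exactly through
    :func:`brainwcn.schema.read_freesurfer_tables`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = table.metadata
    values = table.values
    paths: list[Path] = []

    suffix_of = {"volume": "volume", "surface_area": "area",
                 "thickness_mean": "thickness", "thickness_sd": "thicknessstd",
                 "mean_curvature": "meancurv", "curvature_index": "curvind"}
    cortical = meta[meta["category"] == "cortical"]
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for measure, suffix in suffix_of.items():
            cols = list(cortical.index[(cortical["hemisphere"] == hemi)
                                       & (cortical["measure"] == measure)])
            if not cols:
                continue
            if suffix == "thickness":
                summary = f"{prefix}_MeanThickness_thickness"
                if summary in values.columns:
                    cols.append(summary)
            frame = values[cols].copy()
            frame.insert(0, f"{prefix}.aparc.{suffix}", frame.index)
            path = out_dir / f"{prefix}.aparc.{suffix}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths.append(path)

    aseg_cols = list(meta.index[meta["category"].isin(
        ["subcortical_bilateral", "subcortical_other", "normalizer"])])
    aseg_cols += [c for c in meta.index[meta["category"] == "global"]
                  if not c.endswith("_thickness")]
    aseg_cols = [c for c in values.columns if c in set(aseg_cols)]
    if aseg_cols:
        frame = values[aseg_cols].copy()
        frame.insert(0, "Measure:volume", frame.index)
        path = out_dir / "aseg.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths.append(path)

    pheno_path = out_dir / "phenotype.csv"
    pheno.to_csv(pheno_path, index=False)
    paths.append(pheno_path)
    return paths
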