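"""Subsampling null distributions and case-vs-control network comparison.

The two groups are compared through a subsampling scheme: from the
control group, M_sub subjects are drawn (with replacement by default) and
a full network + centrality profile is built; this is repeated K times,
yielding a null distribution of K values for every whole-network
statistic (the node-average of each centrality measure) and for every
single node x measure entry. The case group contributes a single network
built from all its subjects (or, in the symmetric "both" mode, its own
subsampled distribution summarized by its mean).

Each control distribution is regularized toward normality with a
maximum-likelihood Box-Cox power transform (fitted on the control values
only; the case value is mapped with the same lambda and shift) before the
z-score z = (c_case - <c>_control) / sd_control is taken. Significance is
additionally quantified by a one-tailed empirical p-value: the fraction
of control values more extreme than the case value in the direction of
the case's deviation, with resolution floor 1/K.

Degree is the built-in negative control: quantile thresholding fixes the
edge count, so the node-averaged degree is identical in every network
and its whole-network z is 0 "by construction".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .centrality import MEASURES, CentralityProfiler
from .netbuild import build_network
from .schema import FeatureTable

__all__ = [
    "BoxCoxTransform",
    "ComparisonResult",
    "GroupComparison",
    "subsample_profiles",
    "whole_network_stats",
    "boxcox_fit",
    "zscore",
    "empirical_pvalue",
    "single_node_stats",
    "rank_nodes",
    "centrality_cluster_map",
    "ClusterMap",
]


# ---------------------------------------------------------------------------
# Box-Cox and elementary statistics
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxTransform:
    """Fitted Box-Cox transform y = ((x + shift)^lambda - 1) / lambda.

    ``lmbda`` is the maximum-likelihood exponent (log transform at 0);
    ``shift`` makes the data strictly positive when needed. ``flag`` is
    ``"identity"`` when the input was constant and no transform applies.
    """

    lmbda: float
    shift: float = 0.0
    flag: str = ""

    def transform(self, x):
        if self.flag == "identity":
            return np.asarray(x, dtype=float)
        shifted = np.asarray(x, dtype=float) + self.shift
        if np.any(shifted <= 0):
            raise ValueError("value non-positive after Box-Cox shift")
        return stats.boxcox(shifted, lmbda=self.lmbda)


def boxcox_fit(values: Sequence[float], extra_min: float | None = None
               ) -> tuple[BoxCoxTransform, np.ndarray]:
    """Fit a maximum-likelihood Box-Cox transform to a sample.

    If the sample minimum (or ``extra_min``, e.g. a case value that must
    be mapped through the same transform) is non-positive, the data are
    shifted by -min + eps first; the shift is recorded on the returned
    transform. Constant input yields an identity transform flagged
    ``"identity"``. Returns ``(transform, transformed_values)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        return BoxCoxTransform(lmbda=1.0, shift=0.0, flag="identity"), x.copy()
    low = min(x.min(), extra_min) if extra_min is not None else x.min()
    shift = 0.0
    if low <= 0:
        eps = 1e-6 * max(np.ptp(x), 1.0)
        shift = -low + eps
    transformed, lmbda = stats.boxcox(x + shift)
    return BoxCoxTransform(lmbda=float(lmbda), shift=shift), transformed


def zscore(case_value: float, control_values: Sequence[float]) -> tuple[float, str]:
    """z = (case - mean(control)) / sd(control), with degenerate-sd rules.

    When the control sd is zero: z = 0 flagged ``"by_construction"`` if
    the numerator is also zero, else signed infinity flagged
    ``"sd_zero"``. Returns ``(z, flag)``.
    """
    control = np.asarray(control_values, dtype=float)
    mean = control.mean()
    sd = control.std(ddof=0)
    diff = case_value - mean
    # relative tolerance: a constant distribution stored in floats carries
    # rounding at the ulp level, which must not masquerade as variance
    scale = max(abs(mean), abs(case_value), 1e-300)
    if sd <= 1e-12 * scale:
        if abs(diff) <= 1e-9 * scale:
            return 0.0, "by_construction"
        return float(np.sign(diff)) * np.inf, "sd_zero"
    return float(diff / sd), ""


def empirical_pvalue(case_value: float, control_values: Sequence[float],
                     n_repetitions: int | None = None) -> tuple[float, str]:
    """One-tailed empirical p in the direction of the case's deviation.

    p = #{control values strictly more extreme than the case, on the side
    of the case's deviation from the control mean} / K. A zero count is
    reported as the resolution floor p = 1/K flagged ``"<1/K"``. A case
    value equal to the control mean of a degenerate (constant) control
    distribution gives p = 1 flagged ``"by_construction"``. Returns
    ``(p, flag)``.
    """
    control = np.asarray(control_values, dtype=float)
    K = int(n_repetitions) if n_repetitions is not None else control.size
    mean = control.mean()
    diff = case_value - mean
    scale = max(abs(mean), abs(case_value), 1e-300)
    if abs(diff) <= 1e-9 * scale and control.std(ddof=0) <= 1e-12 * scale:
        return 1.0, "by_construction"
    if diff > 0:
        count = int(np.sum(control > case_value))
    else:
        count = int(np.sum(control < case_value))
    if count == 0:
        return 1.0 / K, "<1/K"
    return count / K, ""


def _stable_boxcox_z(case_value: float, control: np.ndarray,
                     lmbda: float, shift: float) -> tuple[float, str]:
    """z-score on the Box-Cox scale, evaluated stably for extreme lambda.

    (x^l - 1)/l is affine in exp(l log x), and z-scores are invariant
    under affine maps, so the z is computed on exp(l(log x - M)) with M
    the largest exponent; this avoids the catastrophic loss of precision
    the textbook formula suffers when |lambda| is large (the ML lambda
    can be large whenever the data sit far from zero with small relative
    spread). sign(lambda) restores monotonicity in x.
    """
    logs = np.log(control + shift)
    log_c = np.log(case_value + shift)
    if abs(lmbda) < 1e-12:
        return zscore(log_c, logs)
    a, a_c = lmbda * logs, lmbda * log_c
    m = max(a.max(), a_c)
    sign = 1.0 if lmbda > 0 else -1.0
    return zscore(sign * np.exp(a_c - m), sign * np.exp(a - m))


def _compare_one(case_value: float, control_values: np.ndarray,
                 use_boxcox: bool) -> dict:
    """Box-Cox (optional) + z + empirical p for one statistic."""
    control = np.asarray(control_values, dtype=float)
    record = dict(case_value=float(case_value),
                  control_mean=float(control.mean()),
                  control_sd=float(control.std(ddof=0)),
                  boxcox_lambda=np.nan, boxcox_shift=0.0)
    if use_boxcox:
        bc, _ = boxcox_fit(control, extra_min=case_value)
        if bc.flag == "identity":
            z, z_flag = zscore(case_value, control)
        else:
            record["boxcox_lambda"] = bc.lmbda
            record["boxcox_shift"] = bc.shift
            z, z_flag = _stable_boxcox_z(case_value, control, bc.lmbda, bc.shift)
    else:
        z, z_flag = zscore(case_value, control)
    # empirical p is rank-based, hence identical on raw and transformed values
    p, p_flag = empirical_pvalue(case_value, control, control.size)
    record.update(z=z, z_flag=z_flag, p=p, p_flag=p_flag)
    return record


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def _profile_once(values: pd.DataFrame, quantile: float, sigma: float,
                  profiler: CentralityProfiler) -> pd.DataFrame:
    net = build_network(values, quantile=quantile, sigma=sigma)
    return profiler.transform(net)


def subsample_profiles(table: FeatureTable, n_subsample: int,
                       n_repetitions: int, quantile: float = 0.85,
                       sigma: float = 1.0, replace: bool = True,
                       random_state: int = 0,
                       weighted_distance: str = "inverse",
                       ipr_variant: str = "disparity",
                       include_normalizers: bool = False,
                       max_retries: int = 100,
                       on_disconnected: str = "raise",
                       report: dict | None = None
                       ) -> Iterator[pd.DataFrame]:
    """Stream centrality profiles of networks built on resampled subjects.

    Each repetition draws ``n_subsample`` subjects (with replacement by
    default) from the table and builds a full network + profile. A
    repetition whose network cannot be profiled (disconnected graph,
    constant resampled feature, ...) is logged and redrawn, up to
    ``max_retries`` attempts. Deterministic for a given ``random_state``;
    pass a dict as ``report`` to receive retry counts.
    """
    values = (table.node_values(include_normalizers)
              if isinstance(table, FeatureTable) else table)
    n = values.shape[0]
    if n_subsample > n and not replace:
        raise ValueError("n_subsample exceeds group size without replacement")
    children = np.random.SeedSequence(random_state).spawn(n_repetitions)
    profiler = CentralityProfiler(weighted_distance=weighted_distance,
                                  ipr_variant=ipr_variant,
                                  on_disconnected=on_disconnected)
    retries = 0
    for child in children:
        rng = np.random.default_rng(child)
        for attempt in range(max_retries):
            idx = rng.choice(n, size=n_subsample, replace=replace)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    yield _profile_once(values.iloc[idx], quantile, sigma, profiler)
                break
            except ValueError:
                retries += 1
        else:
            raise RuntimeError(
                f"could not build a valid network in {max_retries} draws")
    if report is not None:
        report["n_retries"] = retries


def whole_network_stats(profiles: Sequence[pd.DataFrame] | np.ndarray
                        ) -> pd.DataFrame:
    """Node-averaged value of each measure for each profile (missing excluded).

    Returns a K x 12 DataFrame: one row per repetition, one column per
    measure, entries ``nanmean`` over nodes.
    """
    if isinstance(profiles, np.ndarray):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            rows = np.nanmean(profiles, axis=1)
        return pd.DataFrame(rows, columns=list(MEASURES))
    rows = []
    for prof in profiles:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            rows.append(prof.to_numpy(dtype=float))
    arr = np.stack(rows)
    return whole_network_stats(arr)


def single_node_stats(control_values: np.ndarray, case_profile: pd.DataFrame,
                      use_boxcox: bool = True, max_missing_frac: float = 0.5
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node x per-measure z-scores and empirical p-values.

    ``control_values`` has shape (K, n_nodes, n_measures) aligned with
    ``case_profile`` (node x measure). Entries missing (NaN) in more than
    ``max_missing_frac`` of repetitions, or missing in the case profile,
    are excluded and reported. Returns ``(long_results, excluded)``.
    """
    K, n_nodes, n_meas = control_values.shape
    if (n_nodes, n_meas) != case_profile.shape:
        raise ValueError("node/measure set mismatch between control and case")
    records, excluded = [], []
    case = case_profile.to_numpy(dtype=float)
    for m, measure in enumerate(case_profile.columns):
        for i, node in enumerate(case_profile.index):
            vals = control_values[:, i, m]
            miss = np.isnan(vals).mean()
            if miss > max_missing_frac or np.isnan(case[i, m]):
                excluded.append(dict(feature_id=node, measure=measure,
                                     missing_frac=float(miss),
                                     case_missing=bool(np.isnan(case[i, m]))))
                continue
            vals = vals[~np.isnan(vals)]
            rec = _compare_one(case[i, m], vals, use_boxcox)
            rec.update(feature_id=node, measure=measure, missing_frac=float(miss))
            records.append(rec)
    long = pd.DataFrame.from_records(records)
    return long, pd.DataFrame.from_records(excluded)


# ---------------------------------------------------------------------------
# Result container and engine
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Whole-network and single-node comparison of case vs control networks.

    ``whole_network``: per-measure table with z, p, flags, control
    mean/sd, Box-Cox lambda/shift. ``per_node``: long table with one row
    per node x measure. ``conventions`` records every convention used.
    """

    whole_network: pd.DataFrame
    per_node: pd.DataFrame | None
    excluded_nodes: pd.DataFrame | None
    control_whole_network: pd.DataFrame
    conventions: dict = field(default_factory=dict)

    def write(self, out_dir) -> list:
        import json
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        wn_path = out_dir / "whole_network.csv"
        self.whole_network.to_csv(wn_path, na_rep="NA")
        paths.append(wn_path)
        if self.per_node is not None:
            pn_path = out_dir / "per_node.csv"
            self.per_node.to_csv(pn_path, index=False, na_rep="NA")
            paths.append(pn_path)
        if self.excluded_nodes is not None and len(self.excluded_nodes):
            ex_path = out_dir / "excluded_nodes.csv"
            self.excluded_nodes.to_csv(ex_path, index=False)
            paths.append(ex_path)
        meta_path = out_dir / "comparison_metadata.json"
        meta_path.write_text(json.dumps(self.conventions, indent=2, default=str))
        paths.append(meta_path)
        return paths


class GroupComparison(BaseEstimator):
    """Fit a subsampled-control null, then score a case group against it.

    Parameters
    ----------
    n_subsample : int or None
        Subjects per control resample (M_sub). None uses the case-group
        size, reproducing the standard design M_sub = min(group sizes).
    n_repetitions : int, default 50000
        Number K of subsampling repetitions (use far fewer for quick
        experiments; the empirical-p floor is 1/K).
    quantile, sigma : network construction parameters (see netbuild).
    replace : bool, default True
        Resample subjects with replacement.
    subsample_mode : {'control', 'both'}, default 'control'
        'control': single case network from all case subjects. 'both':
        the case group is subsampled identically and summarized by the
        mean of its distribution (symmetric design).
    tail : {'one', 'two'}, default 'one'
        Empirical p-value sidedness.
    use_boxcox : bool, default True
        Box-Cox-regularize control distributions before z-scoring.
    max_missing_frac : float, default 0.5
        Per-node exclusion threshold on the missing-value fraction.
    random_state : int, default 0

    After :meth:`fit` (control group) and :meth:`compare` (case group):

    Attributes
    ----------
    control_whole_network_ : DataFrame, K x 12 null statistics
    node_ids_ : list of node feature IDs
    report_ : dict with retry counts and sizes
    """

    def __init__(self, n_subsample: int | None = None, n_repetitions: int = 50000,
                 quantile: float = 0.85, sigma: float = 1.0, replace: bool = True,
                 subsample_mode: str = "control", tail: str = "one",
                 use_boxcox: bool = True, weighted_distance: str = "inverse",
                 ipr_variant: str = "disparity", include_normalizers: bool = False,
                 max_missing_frac: float = 0.5, max_retries: int = 100,
                 random_state: int = 0, n_jobs: int = 1):
        self.n_subsample = n_subsample
        self.n_repetitions = n_repetitions
        self.quantile = quantile
        self.sigma = sigma
        self.replace = replace
        self.subsample_mode = subsample_mode
        self.tail = tail
        self.use_boxcox = use_boxcox
        self.weighted_distance = weighted_distance
        self.ipr_variant = ipr_variant
        self.include_normalizers = include_normalizers
        self.max_missing_frac = max_missing_frac
        self.max_retries = max_retries
        self.random_state = random_state
        self.n_jobs = n_jobs

    # -- fitting -----------------------------------------------------------
    def fit(self, control_table: FeatureTable, y=None):
        """Register the control group (the null is materialized on compare)."""
        values = (control_table.node_values(self.include_normalizers)
                  if isinstance(control_table, FeatureTable) else control_table)
        if values.shape[0] < 3:
            raise ValueError("control group needs at least 3 subjects")
        self._control_values = values
        self.node_ids_ = list(values.columns)
        self._null_cache: dict[int, tuple[np.ndarray, pd.DataFrame]] = {}
        return self

    def _run_subsampling(self, values: pd.DataFrame, m_sub: int, seed: int,
                         on_disconnected: str = "raise"
                         ) -> tuple[np.ndarray, dict]:
        """K profiles as a (K, n_nodes, 12) array, in repetition order."""
        report: dict = {}
        K = self.n_repetitions
        out = np.empty((K, values.shape[1], len(MEASURES)), dtype=float)
        gen = subsample_profiles(
            values, m_sub, K, quantile=self.quantile, sigma=self.sigma,
            replace=self.replace, random_state=seed,
            weighted_distance=self.weighted_distance,
            ipr_variant=self.ipr_variant, max_retries=self.max_retries,
            on_disconnected=on_disconnected, report=report)
        if self.n_jobs in (None, 1):
            for k, prof in enumerate(gen):
                out[k] = prof.to_numpy(dtype=float)
        else:
            from joblib import Parallel, delayed

            # independent repetitions; combined in repetition-index order
            children = np.random.SeedSequence(seed).spawn(K)
            profiler = CentralityProfiler(
                weighted_distance=self.weighted_distance,
                ipr_variant=self.ipr_variant,
                on_disconnected=on_disconnected)

            def one(child):
                rng = np.random.default_rng(child)
                for _ in range(self.max_retries):
                    idx = rng.choice(values.shape[0], size=m_sub,
                                     replace=self.replace)
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            return _profile_once(values.iloc[idx], self.quantile,
                                                 self.sigma,
                                                 profiler).to_numpy(dtype=float)
                    except ValueError:
                        continue
                raise RuntimeError("could not build a valid network")

            results = Parallel(n_jobs=self.n_jobs)(delayed(one)(c) for c in children)
            for k, arr in enumerate(results):
                out[k] = arr
        return out, report

    def _null(self, m_sub: int) -> tuple[np.ndarray, pd.DataFrame]:
        if m_sub not in self._null_cache:
            arr, report = self._run_subsampling(self._control_values, m_sub,
                                                self._seed(0))
            wn = whole_network_stats(arr)
            self._control_report = report
            self._null_cache[m_sub] = (arr, wn)
        return self._null_cache[m_sub]

    def _seed(self, stream: int) -> int:
        return (int(self.random_state) * 2 + stream) % (2 ** 31)

    # -- comparison --------------------------------------------------------
    def compare(self, case_table: FeatureTable,
                single_node: bool = True) -> ComparisonResult:
        """Score the case group against the subsampled-control null."""
        if not hasattr(self, "_control_values"):
            raise RuntimeError("call fit(control_table) first")
        case_values = (case_table.node_values(self.include_normalizers)
                       if isinstance(case_table, FeatureTable) else case_table)
        if list(case_values.columns) != self.node_ids_:
            raise ValueError("case and control node sets differ")
        m_sub = self.n_subsample or case_values.shape[0]
        if not self.replace:
            m_sub = min(m_sub, self._control_values.shape[0], case_values.shape[0])
        control_arr, control_wn = self._null(m_sub)
        self.control_whole_network_ = control_wn

        # the single case instance cannot be redrawn, so spectral measures
        # fall back to the giant component if it is disconnected (flagged)
        profiler = CentralityProfiler(weighted_distance=self.weighted_distance,
                                      ipr_variant=self.ipr_variant,
                                      on_disconnected="giant")
        case_n_components = 1
        if self.subsample_mode == "control":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                case_net = build_network(case_values, quantile=self.quantile,
                                         sigma=self.sigma)
                case_n_components = case_net.components()[0]
                case_profile = profiler.transform(case_net)
                case_wn = case_profile.apply(np.nanmean, axis=0)
        elif self.subsample_mode == "both":
            # case resamples inherit the planted/structural topology, so a
            # disconnected draw is not a transient failure: giant fallback
            case_arr, _ = self._run_subsampling(case_values, m_sub,
                                                self._seed(1),
                                                on_disconnected="giant")
            case_wn = whole_network_stats(case_arr).mean(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                case_matrix = np.nanmean(case_arr, axis=0)
            case_profile = pd.DataFrame(case_matrix, index=self.node_ids_,
                                        columns=list(MEASURES))
        else:
            raise ValueError(f"unknown subsample_mode {self.subsample_mode!r}")

        wn_records = {}
        for measure in MEASURES:
            rec = _compare_one(case_wn[measure],
                               control_wn[measure].to_numpy(), self.use_boxcox)
            if self.tail == "two":
                rec["p"] = min(1.0, 2 * rec["p"]) if rec["p_flag"] != "by_construction" \
                    else rec["p"]
            wn_records[measure] = rec
        whole = pd.DataFrame.from_dict(wn_records, orient="index")
        whole.index.name = "measure"

        per_node = excluded = None
        if single_node:
            per_node, excluded = single_node_stats(
                control_arr, case_profile, use_boxcox=self.use_boxcox,
                max_missing_frac=self.max_missing_frac)
            if self.tail == "two":
                mask = per_node["p_flag"] != "by_construction"
                per_node.loc[mask, "p"] = np.minimum(1.0, 2 * per_node.loc[mask, "p"])

        conventions = dict(
            n_subsample=int(m_sub), n_repetitions=int(self.n_repetitions),
            quantile=self.quantile, sigma=self.sigma, replace=self.replace,
            subsample_mode=self.subsample_mode, tail=self.tail,
            use_boxcox=self.use_boxcox, weighted_distance=self.weighted_distance,
            ipr_variant=self.ipr_variant, random_state=self.random_state,
            empirical_p_floor=1.0 / self.n_repetitions,
            control_retries=getattr(self, "_control_report", {}).get("n_retries", 0),
            case_n_components=case_n_components,
        )
        self.report_ = conventions
        self.case_profile_ = case_profile
        return ComparisonResult(whole, per_node, excluded, control_wn, conventions)

    def fit_compare(self, control_table: FeatureTable, case_table: FeatureTable,
                    single_node: bool = True) -> ComparisonResult:
        return self.fit(control_table).compare(case_table, single_node=single_node)


# ---------------------------------------------------------------------------
# Ranking and measure-correlation cluster map
# ---------------------------------------------------------------------------

def rank_nodes(result: ComparisonResult | pd.DataFrame, measure: str,
               k: int = 5, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Top-k nodes by |z| for one measure, formatted as a ranking table.

    Columns: rank, feature_id, hemisphere, region (if metadata given),
    measure, z (sign retained). Ties in |z| break on feature_id.
    """
    per_node = result.per_node if isinstance(result, ComparisonResult) else result
    sub = per_node[per_node["measure"] == measure].copy()
    if sub.empty:
        raise ValueError(f"measure {measure!r} not present in results")
    sub["abs_z"] = sub["z"].abs()
    sub = sub.sort_values(["abs_z", "feature_id"],
                          ascending=[False, True]).head(k)
    out = sub[["feature_id", "measure", "z"]].reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    if metadata is not None:
        out.insert(2, "hemisphere",
                   metadata.loc[out["feature_id"], "hemisphere"].to_numpy())
        out.insert(3, "region",
                   metadata.loc[out["feature_id"], "region"].to_numpy())
        out.insert(4, "feature_kind",
                   metadata.loc[out["feature_id"], "measure"].to_numpy())
    return out


@dataclass
class ClusterMap:
    """Measure x measure Spearman matrix with hierarchical cluster labels."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series
    leaf_order: list[str]


def centrality_cluster_map(profile: pd.DataFrame, n_clusters: int = 4
                           ) -> ClusterMap:
    """Cluster centrality measures by the Spearman correlation of their
    node-value vectors.

    ``profile`` is a node x measure table (for a subsampled group, the
    mean profile over repetitions). Correlations are pairwise-complete
    over nodes; clustering is average-linkage on the distance
    1 - r_S, cut into ``n_clusters`` flat clusters.
    """
    corr = profile.corr(method="spearman")
    if corr.isna().any().any():
        warnings.warn("cluster map: NaN correlations replaced by 0 "
                      "(insufficient pairwise-complete nodes)")
        corr = corr.fillna(0.0)
        np.fill_diagonal(corr.values, 1.0)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = linkage(squareform(dist, checks=False), method="average")
    labels = pd.Series(fcluster(link, t=n_clusters, criterion="maxclust"),
                       index=corr.columns, name="cluster")
    order = [corr.columns[i] for i in leaves_list(link)]
    return ClusterMap(corr, link, labels, order)
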