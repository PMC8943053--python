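"""Per-well behavioural features and the feature-matrix pipeline.

Tracks are summarised into one averaged feature vector per well (track
identity across gaps is unreliable, so the well — not the worm — is the
unit of measurement).  The reduced catalogue covers morphology (length,
width), posture (mean absolute curvature by body part, including the
neck), and motion (overall and per-mode speed, time fraction per mode);
the downstream machinery is width-agnostic, so wider catalogues satisfy
the same contracts.

Matrix processing mirrors a standard behavioural-screen pipeline:
sample/feature QC by missingness, within-interval mean imputation,
z-normalisation, PCA with a fixed sign convention, Kruskal-Wallis group
statistics with Benjamini-Yekutieli FDR control, hierarchical clustering
of fingerprints (complete linkage, correlation distance), and a
linear-mixed-model compound screen with imaging day as a random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import kruskal
from sklearn.decomposition import PCA
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .tracking import Track, midline_length

PERIODS = ("prestim", "bluelight", "poststim")

#: body-part spans along the midline (fractions head -> tail), after the
#: usual multi-worm-tracker conventions
BODY_PARTS = {
    "head": (0.0, 0.2),
    "neck": (0.2, 0.4),
    "midbody": (0.4, 0.6),
    "hips": (0.6, 0.8),
    "tail": (0.8, 1.0),
}


@dataclass
class FeatureTable:
    """Wells x features matrix with missingness mask and metadata.

    ``values`` holds NaN at missing entries; ``mask`` mirrors them
    (True = missing).  ``row_meta`` carries group labels (strain /
    compound / day) and bad-well flags; ``col_meta`` carries the period
    tag and base feature name per column.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame

    def __post_init__(self):
        if list(self.values.columns) != list(self.mask.columns):
            raise ValueError("values and mask must share columns")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share shape")
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def shape(self):
        return self.values.shape

    def drop_bad_wells(self) -> "FeatureTable":
        keep = ~self.row_meta["bad_well"].to_numpy(dtype=bool)
        return FeatureTable(self.values.iloc[keep], self.mask.iloc[keep],
                            self.row_meta.iloc[keep], self.col_meta)


@dataclass
class QcReport:
    dropped_samples: list = field(default_factory=list)
    dropped_features: list = field(default_factory=list)
    zero_variance_features: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"dropped_samples": list(self.dropped_samples),
                "dropped_features": list(self.dropped_features),
                "zero_variance_features": list(self.zero_variance_features)}


# ---------------------------------------------------------------------------
# track -> well summaries


def _curvature(midline: np.ndarray) -> np.ndarray:
    """Unsigned discrete curvature (turn angle per arc length) along a polyline."""
    d = np.diff(midline, axis=0)
    seg = np.linalg.norm(d, axis=1)
    ang = np.arctan2(d[:, 1], d[:, 0])
    dang = np.abs(np.angle(np.exp(1j * np.diff(ang))))
    ds = 0.5 * (seg[:-1] + seg[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ds > 0, dang / ds, 0.0)


def track_features(track: Track, frame_rate: float) -> dict[str, float]:
    """Feature vector for a single track (px and px/s units)."""
    feats: dict[str, float] = {}
    mids = [o.midline for o in track.objects if o.midline is not None and len(o.midline) >= 3]
    lengths = [midline_length(m) for m in mids]
    feats["length"] = float(np.median(lengths)) if lengths else np.nan
    areas = [o.area for o in track.objects]
    feats["width_midbody"] = (float(np.median(areas)) / feats["length"]
                              if lengths and feats["length"] > 0 else np.nan)
    for part, (a, b) in BODY_PARTS.items():
        vals = []
        for m in mids:
            i0, i1 = int(a * len(m)), max(int(b * len(m)), int(a * len(m)) + 3)
            vals.append(np.mean(_curvature(m[i0:i1])))
        feats[f"curvature_{part}"] = float(np.median(vals)) if vals else np.nan

    c = track.centroids
    if len(c) >= 2:
        speed = np.linalg.norm(np.gradient(c, axis=0), axis=1) * frame_rate
        feats["speed"] = float(np.mean(speed))
    else:
        speed = np.array([])
        feats["speed"] = np.nan

    modes = track.modes if track.modes is not None else [None] * len(track.objects)
    marr = np.array([m if m is not None else "na" for m in modes])
    defined = marr != "na"
    for mode in ("fw", "bw", "st"):
        sel = marr == mode
        feats[f"frac_{mode}"] = (float(sel.sum() / defined.sum())
                                 if defined.any() else np.nan)
        feats[f"speed_{mode}"] = (float(np.mean(speed[sel]))
                                  if sel.any() and len(speed) == len(marr) else np.nan)
    return feats


FEATURE_NAMES = (["length", "width_midbody"]
                 + [f"curvature_{p}" for p in BODY_PARTS]
                 + ["speed"]
                 + [f"frac_{m}" for m in ("fw", "bw", "st")]
                 + [f"speed_{m}" for m in ("fw", "bw", "st")])


def summarize_features(tracks: list[Track], grid, frame_rate: float,
                       period: str = "prestim") -> FeatureTable:
    """One averaged feature vector per well of the grid.

    Wells without tracks yield an all-missing row; bad-flagged wells are
    emitted with ``bad_well=True`` so aggregation can exclude them.
    """
    by_well: dict[str, list[Track]] = {w: [] for w in grid.names}
    for t in tracks:
        if t.well in by_well:
            by_well[t.well].append(t)
    rows = []
    for w in grid.names:
        vecs = [track_features(t, frame_rate) for t in by_well[w]]
        if vecs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows.append({k: np.nanmean([v[k] for v in vecs]) for k in FEATURE_NAMES})
        else:
            rows.append({k: np.nan for k in FEATURE_NAMES})
    values = pd.DataFrame(rows, index=pd.Index(grid.names, name="well_name"))
    mask = values.isna()
    row_meta = pd.DataFrame({
        "bad_well": [grid.well(w).bad_flag for w in grid.names],
        "n_tracks": [len(by_well[w]) for w in grid.names],
    }, index=values.index)
    col_meta = pd.DataFrame({"period": period, "base_feature": values.columns},
                            index=values.columns)
    return FeatureTable(values, mask, row_meta, col_meta)


def concatenate_periods(tables: dict[str, FeatureTable]) -> FeatureTable:
    """Concatenate per-period tables column-wise with period suffixes.

    All tables must cover the same wells; width of the result is the sum
    of the per-period widths (3 x w for the standard three periods).
    """
    if not tables:
        raise ValueError("no period tables given")
    items = list(tables.items())
    base_idx = items[0][1].values.index
    vals, masks, cmetas = [], [], []
    for period, t in items:
        if t.values.shape[1] == 0:
            raise ValueError(f"period {period!r} table is empty")
        if not t.values.index.equals(base_idx):
            raise ValueError("period tables must cover the same wells")
        suffixed = [f"{c}_{period}" if not str(c).endswith(f"_{period}") else str(c)
                    for c in t.values.columns]
        v = t.values.copy()
        v.columns = suffixed
        m = t.mask.copy()
        m.columns = suffixed
        cm = t.col_meta.copy()
        cm.index = suffixed
        cm["period"] = period
        vals.append(v)
        masks.append(m)
        cmetas.append(cm)
    return FeatureTable(pd.concat(vals, axis=1), pd.concat(masks, axis=1),
                        items[0][1].row_meta.copy(), pd.concat(cmetas, axis=0))


# ---------------------------------------------------------------------------
# QC / imputation / normalisation


def qc_impute_normalize(table: FeatureTable, sample_miss_max: float = 0.40,
                        feature_miss_max: float = 0.20,
                        interval: str | None = None) -> tuple[FeatureTable, QcReport]:
    """QC, impute and z-normalise, in this order.

    1. Drop samples whose missing fraction exceeds ``sample_miss_max``.
    2. Drop features missing in more than ``feature_miss_max`` of the
       samples within *any* interval group (``interval`` names a row-meta
       column — e.g. the 10 s time window — or None for one group).
    3. Impute remaining missing values by the within-interval column mean;
       a feature with no valid value in some interval cannot be imputed
       and is dropped.
    4. Z-normalise columns (zero-variance columns are dropped, reported).
    """
    report = QcReport()
    vals = table.values.copy()
    miss = table.mask.copy()

    row_frac = miss.mean(axis=1)
    bad_rows = row_frac > sample_miss_max
    report.dropped_samples = list(vals.index[bad_rows])
    vals, miss = vals.loc[~bad_rows], miss.loc[~bad_rows]
    row_meta = table.row_meta.loc[vals.index]

    groups = (row_meta[interval] if interval is not None
              else pd.Series("all", index=vals.index))
    feat_drop = pd.Series(False, index=vals.columns)
    for _, sub in miss.groupby(groups, observed=True):
        feat_drop |= sub.mean(axis=0) > feature_miss_max
        feat_drop |= sub.all(axis=0)  # cannot impute: no valid value in interval
    report.dropped_features = list(vals.columns[feat_drop])
    vals, miss = vals.loc[:, ~feat_drop], miss.loc[:, ~feat_drop]

    for _, idx in groups.groupby(groups, observed=True).groups.items():
        sub = vals.loc[idx]
        vals.loc[idx] = sub.fillna(sub.mean(axis=0))

    sd = vals.std(axis=0, ddof=0)
    zero_var = sd == 0
    report.zero_variance_features = list(vals.columns[zero_var])
    vals = vals.loc[:, ~zero_var]
    vals = (vals - vals.mean(axis=0)) / sd[~zero_var]

    clean = FeatureTable(vals, pd.DataFrame(False, index=vals.index, columns=vals.columns),
                         row_meta, table.col_meta.loc[vals.columns])
    return clean, report


# ---------------------------------------------------------------------------
# PCA / statistics / clustering / screen


def pca_project(values: pd.DataFrame, k: int):
    """PCA scores and explained-variance fractions with deterministic signs.

    Each component is flipped so its largest-magnitude loading is
    positive.  ``k`` beyond the matrix rank is an error.
    """
    x = values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("PCA input must have no missing values")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    for j in range(k):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            scores[:, j] *= -1
    scores_df = pd.DataFrame(scores, index=values.index,
                             columns=[f"PC{j + 1}" for j in range(k)])
    return scores_df, pca.explained_variance_ratio_.copy(), pca


def kw_exact_p_two_groups(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value of the Kruskal-Wallis statistic, 2 groups.

    With two tie-free groups H is a monotone function of the group-1 rank
    sum, so the permutation null is enumerated by counting k-subsets of
    ranks 1..N at each rank sum (dynamic programming); the p-value is the
    exact tail P(H >= H_obs) over all C(N, n1) relabellings.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    combined = np.concatenate([x, y])
    if len(np.unique(combined)) != len(combined):
        raise ValueError("exact enumeration requires tie-free data")
    n1, n = len(x), len(combined)
    ranks = combined.argsort().argsort() + 1
    s_obs = int(ranks[:n1].sum())
    total = n * (n + 1) // 2

    def h_stat(s):
        s2 = total - s
        return (12.0 / (n * (n + 1))) * (s * s / n1 + s2 * s2 / (n - n1)) - 3 * (n + 1)

    # ways[k][s]: number of k-subsets of {1..n} with rank sum s
    max_s = total
    ways = np.zeros((n1 + 1, max_s + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, :-r] if r > 0 else ways[k - 1]
    h_obs = h_stat(s_obs)
    tail = sum(ways[n1, s] for s in range(max_s + 1)
               if ways[n1, s] > 0 and h_stat(s) >= h_obs - 1e-12)
    from math import comb
    return float(tail / comb(n, n1))


def kw_by_significance(values: pd.DataFrame, groups, q: float = 0.05,
                       method: str = "asymptotic") -> pd.DataFrame:
    """Kruskal-Wallis per feature with Benjamini-Yekutieli FDR control.

    ``method="asymptotic"`` uses the tie-corrected chi-square p;
    ``method="exact"`` uses the exact permutation tail (two tie-free
    groups only) — appropriate for small samples where the chi-square
    approximation is poor.  Constant features get p = 1 (no evidence, not
    an error).  Returns a per-feature frame with raw p, BY-adjusted p and
    the decision at FDR q.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if method == "exact" and len(uniq) != 2:
        raise ValueError("exact method supports exactly 2 groups")
    pvals = np.empty(values.shape[1])
    for j, col in enumerate(values.columns):
        x = values[col].to_numpy(dtype=float)
        samples = [x[groups == g] for g in uniq]
        if any(len(s) < 2 for s in samples):
            raise ValueError("need at least 2 samples per group")
        if np.nanstd(x) == 0:
            pvals[j] = 1.0
            continue
        if method == "exact":
            pvals[j] = kw_exact_p_two_groups(samples[0], samples[1])
            continue
        try:
            pvals[j] = kruskal(*samples, nan_policy="omit").pvalue
        except ValueError:  # all values identical after ties
            pvals[j] = 1.0
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_by")
    return pd.DataFrame({"p": pvals, "p_adj": p_adj, "significant": reject},
                        index=values.columns)


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray


def cluster_fingerprints(values: pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of rows and columns.

    Distance is 1 - Pearson correlation; linkage is complete.  Rows (or
    columns) with zero variance have undefined correlation and raise,
    naming the offender.
    """
    x = values.to_numpy(dtype=float)
    for axis, labels in ((0, values.index), (1, values.columns)):
        sd = x.std(axis=1 - axis)
        if np.any(sd == 0):
            bad = list(np.asarray(labels)[sd == 0])
            raise ValueError(f"zero-variance {'rows' if axis == 0 else 'columns'}: {bad}")
    row_link = linkage(pdist(x, metric="correlation"), method="complete")
    col_link = linkage(pdist(x.T, metric="correlation"), method="complete")
    return ClusterResult(row_link, col_link, leaves_list(row_link), leaves_list(col_link))


def lmm_screen(table: FeatureTable, q: float = 0.05, control: str = "DMSO",
               compound_col: str = "compound", day_col: str = "day",
               method: str = "fdr_bh") -> pd.DataFrame:
    """Linear-mixed-model compound screen with day as a random intercept.

    Per (compound, feature): ``feature ~ intercept + compound`` with a
    random intercept per imaging day, compound wells tested against the
    control group.  P-values are corrected across features per compound
    (FDR step-up; method configurable); a compound is a hit if any
    feature survives.  Compounds present on a single day only are
    unestimable and excluded (flagged in the output).
    """
    meta = table.row_meta
    if control not in set(meta[compound_col]):
        raise ValueError(f"control group {control!r} absent")
    if meta[day_col].nunique() < 2:
        raise ValueError("need at least 2 imaging days")
    results = []
    for cmpd in sorted(set(meta[compound_col]) - {control}):
        sel = meta[compound_col].isin([cmpd, control]).to_numpy()
        sub_meta = meta.loc[sel]
        if sub_meta.loc[sub_meta[compound_col] == cmpd, day_col].nunique() < 2:
            results.append({"compound": cmpd, "estimable": False, "hit": False,
                            "n_significant": 0, "min_p_adj": np.nan})
            continue
        is_cmpd = (sub_meta[compound_col] == cmpd).to_numpy(dtype=float)
        exog = np.column_stack([np.ones_like(is_cmpd), is_cmpd])
        days = sub_meta[day_col].to_numpy()
        pvals = []
        for col in table.values.columns:
            y = table.values.loc[sel, col].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = MixedLM(y, exog, groups=days).fit(reml=True)
                    pvals.append(float(np.asarray(fit.pvalues)[1]))
                except Exception:
                    pvals.append(1.0)
        reject, p_adj, _, _ = multipletests(pvals, alpha=q, method=method)
        results.append({"compound": cmpd, "estimable": True,
                        "hit": bool(reject.any()),
                        "n_significant": int(reject.sum()),
                        "min_p_adj": float(np.min(p_adj))})
    return pd.DataFrame(results).set_index("compound")
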