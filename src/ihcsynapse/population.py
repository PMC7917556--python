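"""Population-level analysis of the per-synapse table.

Spatial position along the pillar–modiolar axis (an ellipse fitted to the
baseline Rhod-FF image; synapse position is the normalized projection of
its Ca2+ hot spot onto the major axis, 0 = pillar, 1 = modiolar), Pearson
correlations among synaptic properties, K-means phenotyping (K = 3 on 11
z-scored properties, clusters ordered by ascending Ca2+ cooperativity m),
PCA for display, and the normality-gated group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import SegmentationError, TableError

#: The 11 synaptic properties used for clustering and PCA: the Ca2+-influx
#: transfer parameters, the Rhod-FF peak, the release transfer parameters,
#: the maximal release, and the Ca2+ cooperativity.  Positional and
#: whole-cell information is deliberately excluded.
CLUSTER_PROPERTIES = (
    "v_half_ca_mV", "k_ca_mV", "v10_ca_mV", "dr_ca_mV", "peak_rhod_dff",
    "v_half_rel_mV", "k_rel_mV", "v10_rel_mV", "dr_rel_mV", "max_auc_rel",
    "m",
)


@dataclass
class CellEllipse:
    """Cell boundary ellipse; the major axis is the pillar–modiolar axis."""

    center_xy_px: tuple[float, float]
    semi_major_px: float
    semi_minor_px: float
    angle_rad: float
    pillar_side: str = "left"      # which major-axis end is the pillar
    degenerate: bool = False       # circle: orientation undefined

    def axis_unit(self) -> np.ndarray:
        return np.array([math.cos(self.angle_rad), math.sin(self.angle_rad)])

    def _vertices(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_xy_px, dtype=float)
        v1 = c - self.semi_major_px * self.axis_unit()
        v2 = c + self.semi_major_px * self.axis_unit()
        return v1, v2

    def pillar_vertex(self) -> np.ndarray:
        v1, v2 = self._vertices()
        axis = {"left": 0, "right": 0, "top": 1, "bottom": 1}[self.pillar_side]
        lo_first = v1[axis] <= v2[axis]
        if self.pillar_side in ("left", "top"):
            return v1 if lo_first else v2
        return v2 if lo_first else v1

    def modiolar_vertex(self) -> np.ndarray:
        p = self.pillar_vertex()
        v1, v2 = self._vertices()
        return v2 if np.allclose(p, v1) else v1


def fit_cell_ellipse(baseline_image: np.ndarray, pillar_side: str = "left",
                     ) -> CellEllipse:
    """Fit the cell ellipse to a baseline fluorescence image.

    Otsu threshold → largest connected component → second-moment ellipse
    (semi-axes from the component's principal axis lengths).  A circular
    component gets ``angle = 0`` and a ``degenerate`` flag.
    """
    img = np.asarray(baseline_image, dtype=float)
    if img.max() <= img.min():
        raise SegmentationError("constant baseline image")
    mask = img > threshold_otsu(img)
    if not mask.any():
        raise SegmentationError("empty mask after Otsu threshold")
    labels = cc_label(mask)
    props = max(regionprops(labels), key=lambda p: p.area)
    cy, cx = props.centroid
    a = props.axis_major_length / 2.0
    b = props.axis_minor_length / 2.0
    if a <= 0 or b <= 0:
        raise SegmentationError("degenerate component (zero axis length)")
    if (a - b) / a < 0.02:
        return CellEllipse(center_xy_px=(cx, cy), semi_major_px=a,
                           semi_minor_px=b, angle_rad=0.0,
                           pillar_side=pillar_side, degenerate=True)
    # skimage orientation: angle between the major axis and the row (y) axis
    angle = math.pi / 2.0 - props.orientation
    return CellEllipse(center_xy_px=(cx, cy), semi_major_px=a,
                       semi_minor_px=b, angle_rad=angle,
                       pillar_side=pillar_side)


def axis_position(ellipse: CellEllipse, hotspot_xy) -> float:
    """Normalized position of a hot spot along the pillar–modiolar axis.

    Orthogonal projection of the hot-spot center onto the major axis (the
    foot of the shortest distance), normalized between the pillar vertex
    (0) and the modiolar vertex (1) and clipped to [0, 1].
    """
    p = np.asarray(hotspot_xy, dtype=float)
    v0 = ellipse.pillar_vertex()
    v1 = ellipse.modiolar_vertex()
    axis = v1 - v0
    t = float(np.dot(p - v0, axis) / np.dot(axis, axis))
    return float(np.clip(t, 0.0, 1.0))


def build_table(records: list[dict]) -> pd.DataFrame:
    """Assemble the per-synapse profile table.

    Each record carries ``cell_id`` and ``synapse_id`` plus whatever fit
    results exist.  Rows missing any clustering property, or carrying
    ``excluded=True`` from an R²-gated fit, get ``qc_pass=False`` and are
    left out of clustering/PCA (not dropped from the table).
    """
    df = pd.DataFrame.from_records(records)
    if df.empty:
        cols = ["cell_id", "synapse_id", *CLUSTER_PROPERTIES, "position_01",
                "qc_pass"]
        return pd.DataFrame(columns=cols)
    if df.duplicated(subset=["cell_id", "synapse_id"]).any():
        raise TableError("duplicate (cell_id, synapse_id) rows")
    for col in CLUSTER_PROPERTIES:
        if col not in df.columns:
            df[col] = np.nan
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    complete = df[list(CLUSTER_PROPERTIES)].notna().all(axis=1)
    df["qc_pass"] = complete & ~df["excluded"]
    return df


def correlate(table: pd.DataFrame, properties=CLUSTER_PROPERTIES,
              extra=()) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix over complete pairs.

    Zero-variance columns yield NaN entries.  The matrix is symmetric with
    a unit diagonal (where defined).
    """
    cols = [c for c in (*properties, *extra) if c in table.columns]
    sub = table.loc[table.get("qc_pass", pd.Series(True, index=table.index)),
                    cols]
    if len(sub) < 3:
        raise TableError("need >= 3 complete rows for correlations")
    return sub.corr(method="pearson")


def cluster(table: pd.DataFrame, k: int = 3, seed: int = 0,
            properties=CLUSTER_PROPERTIES, n_init: int = 10) -> pd.DataFrame:
    """K-means phenotyping on the z-scored property matrix.

    Returns the table with ``cluster_label`` (1..k; NaN for QC-failed
    rows).  Labels are ordered by ascending cluster-mean cooperativity m,
    so cluster 1 is the nanodomain-like (low m) subtype; this makes the
    labeling independent of the K-means seed for separable data.
    """
    ok = table["qc_pass"].to_numpy(dtype=bool)
    X = table.loc[ok, list(properties)].to_numpy(dtype=float)
    if X.shape[0] < k:
        raise TableError(f"need >= {k} complete rows for K-means")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(Z)
    m_col = list(properties).index("m")
    centroid_m = np.array([X[raw == j, m_col].mean() for j in range(k)])
    order = np.argsort(centroid_m)           # ascending m
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    out = table.copy()
    out["cluster_label"] = np.nan
    out.loc[ok, "cluster_label"] = relabel[raw].astype(float)
    return out


def pca_project(table: pd.DataFrame, properties=CLUSTER_PROPERTIES,
                n_components: int | None = None):
    """PCA of the z-scored property matrix.

    Returns ``(scores, loadings, explained_variance_ratio)``; components
    are ordered by descending explained variance.
    """
    ok = table["qc_pass"].to_numpy(dtype=bool)
    X = table.loc[ok, list(properties)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise TableError("need >= 3 complete rows for PCA")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.all(sd == 0):
        raise TableError("constant table: PCA undefined")
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_comp = n_components or min(Z.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z)
    return scores, pca.components_, pca.explained_variance_ratio_


def _normal(x, alpha: float = 0.05) -> bool:
    """D'Agostino-Pearson omnibus normality check (requires n >= 8)."""
    if len(x) < 8:
        return True     # too few samples to reject; default to t-test
    try:
        return stats.normaltest(x).pvalue > alpha
    except ValueError:
        return False


def compare_groups(table: pd.DataFrame, group_col: str = "position_group",
                   properties=CLUSTER_PROPERTIES,
                   position_threshold: float = 0.5) -> pd.DataFrame:
    """Two-group comparison of synaptic properties (pillar vs modiolar halves).

    If ``group_col`` is absent it is derived by splitting ``position_01``
    at ``position_threshold``.  Per property: D'Agostino–Pearson normality
    on each group gates an unpaired t-test (both normal) versus a
    Mann-Whitney U test; Levene's test compares dispersion.  Groups with
    fewer than 3 members are skipped with a flag.
    """
    df = table[table["qc_pass"]].copy() if "qc_pass" in table else table.copy()
    if group_col not in df.columns:
        df[group_col] = np.where(df["position_01"] < position_threshold,
                                 "pillar", "modiolar")
    names = sorted(df[group_col].dropna().unique())
    if len(names) != 2:
        raise TableError(f"expected exactly 2 groups, got {names}")
    rows = []
    for prop in properties:
        if prop not in df.columns:
            continue
        a = df.loc[df[group_col] == names[0], prop].dropna().to_numpy()
        b = df.loc[df[group_col] == names[1], prop].dropna().to_numpy()
        if len(a) < 3 or len(b) < 3:
            rows.append({"property": prop, "test": None, "statistic": np.nan,
                         "p_value": np.nan, "levene_p": np.nan,
                         "skipped": True})
            continue
        if _normal(a) and _normal(b):
            res = stats.ttest_ind(a, b)
            test = "t-test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
        lev = stats.levene(a, b)
        rows.append({"property": prop, "test": test,
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "levene_p": float(lev.pvalue), "skipped": False,
                     f"mean_{names[0]}": float(a.mean()),
                     f"mean_{names[1]}": float(b.mean())})
    return pd.DataFrame(rows)


def compare_clusters(table: pd.DataFrame, properties=CLUSTER_PROPERTIES
                     ) -> pd.DataFrame:
    """One-way ANOVA across clusters with post-hoc Tukey HSD per property."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table[table["qc_pass"] & table["cluster_label"].notna()]
    rows = []
    for prop in properties:
        groups = [g[prop].dropna().to_numpy()
                  for _, g in df.groupby("cluster_label")]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            rows.append({"property": prop, "anova_p": np.nan, "skipped": True})
            continue
        f = stats.f_oneway(*groups)
        tk = pairwise_tukeyhsd(df[prop].to_numpy(),
                               df["cluster_label"].to_numpy())
        rows.append({"property": prop, "anova_F": float(f.statistic),
                     "anova_p": float(f.pvalue),
                     "tukey_reject_any": bool(np.any(tk.reject)),
                     "skipped": False})
    return pd.DataFrame(rows)
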