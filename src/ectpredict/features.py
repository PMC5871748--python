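"""Voxelwise and node-level fMRI metrics, and their assembly into the
subjects x features matrix the classifier consumes.

Metric blocks mirror a multimodal resting-state design: perfusion (CBF by
ASL simple subtraction), local connectivity (regional homogeneity,
Kendall's W), spectral content (fALFF over 0.01-0.1 Hz), pairwise
connectivity strength (Pearson correlation between node timecourses, for
ROI-ROI, ROI-RSN and RSN-RSN pairs), and weighted graph-theory node
metrics (strength, Onnela clustering, local efficiency) on a
proportionally thresholded whole-brain network.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.sparse.csgraph import dijkstra
from scipy.stats import rankdata

from .cohort import SubjectRecord
from .naming import node_feature, pair_feature, roi_node, rsn_node

DEFAULT_BAND = (0.01, 0.1)


@dataclass
class VoxelMap:
    values: np.ndarray  # 3-D; np.nan marks masked/undefined voxels
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


@dataclass
class AtlasLabels:
    labels: np.ndarray  # 3-D integer array, 0 = background

    @property
    def roi_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class NodeSet:
    roi_timecourses: np.ndarray  # (T, n_rois)
    rsn_timecourses: np.ndarray  # (T, n_rsns)

    def __post_init__(self) -> None:
        if self.roi_timecourses.shape[0] != self.rsn_timecourses.shape[0]:
            raise ValueError("ROI and RSN timecourses must share length")


@dataclass
class WeightMatrix:
    weights: np.ndarray  # symmetric, zero diagonal after thresholding
    threshold_policy: dict


@dataclass
class FeatureBlock:
    block_name: str
    feature_names: list[str]
    values: np.ndarray  # (n_subjects, n_features)

    def __post_init__(self) -> None:
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names must match values columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names within block")


@dataclass
class FeatureMatrix:
    """Subjects x named features with per-feature block provenance."""

    data: pd.DataFrame  # index = subject ids, columns = feature names
    blocks: pd.Series  # feature name -> block name

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names across blocks")

    @classmethod
    def from_blocks(cls, blocks: list[FeatureBlock], subject_ids: list[str]) -> "FeatureMatrix":
        frames, provenance = [], {}
        for b in blocks:
            frames.append(
                pd.DataFrame(b.values, index=subject_ids, columns=b.feature_names)
            )
            provenance.update({n: b.block_name for n in b.feature_names})
        data = pd.concat(frames, axis=1)
        return cls(data=data, blocks=pd.Series(provenance))

    def write(self, csv_path, sidecar_path=None, extra_meta: dict | None = None) -> None:
        """Wide CSV (subjects x features) plus a JSON provenance sidecar."""
        import json
        import pathlib

        self.data.to_csv(csv_path, index_label="subject_id")
        if sidecar_path is not None:
            meta = {"blocks": self.blocks.to_dict()}
            if extra_meta:
                meta.update(extra_meta)
            pathlib.Path(sidecar_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, csv_path, sidecar_path=None) -> "FeatureMatrix":
        import json
        import pathlib

        data = pd.read_csv(csv_path, index_col="subject_id")
        if sidecar_path is not None:
            blocks = pd.Series(json.loads(pathlib.Path(sidecar_path).read_text())["blocks"])
        else:
            blocks = pd.Series({c: "unknown" for c in data.columns})
        return cls(data=data, blocks=blocks)


# --- voxelwise metrics -------------------------------------------------


def cbf_simple_subtraction(asl_series: np.ndarray, tags: list[str]) -> VoxelMap:
    """Perfusion-weighted map: mean of pairwise control-minus-label volumes.

    ``tags`` declares the acquisition order ('label'/'control'); equal
    counts are required.  Output is the unscaled mean difference; absolute
    CBF quantification requires calibration constants and is applied
    elsewhere only if supplied.
    """
    tags = list(tags)
    if asl_series.shape[-1] != len(tags):
        raise ValueError("tag sequence length must match number of volumes")
    label_ix = [i for i, t in enumerate(tags) if t == "label"]
    control_ix = [i for i, t in enumerate(tags) if t == "control"]
    if len(label_ix) != len(control_ix) or not label_ix:
        raise ValueError(
            f"unbalanced tag sequence: {len(label_ix)} label vs "
            f"{len(control_ix)} control volumes"
        )
    if not np.any(asl_series):
        warnings.warn("all-zero ASL series; subtraction map is zero", stacklevel=2)
    diffs = asl_series[..., control_ix] - asl_series[..., label_ix]
    return VoxelMap(values=diffs.mean(axis=-1))


_NEIGHBORHOOD_OFFSETS = {
    size: [
        (dx, dy, dz)
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3)
        if abs(dx) + abs(dy) + abs(dz) <= reach
    ]
    for size, reach in ((7, 1), (19, 2), (27, 3))
}


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance for k series of length n.

    W = 12 S / (k^2 (n^3 - n)) with S the sum of squared deviations of the
    per-timepoint rank sums; ties take midranks (no tie correction).  A
    fully constant set of series leaves W undefined (nan).
    """
    k, n = series.shape
    if n < 3:
        raise ValueError("need at least 3 timepoints")
    if np.all(series == series[:, :1]):
        return float("nan")
    ranks = rankdata(series, axis=1, method="average")
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    return 12.0 * s / (k**2 * (n**3 - n))


def reho_map(
    bold: np.ndarray,
    neighborhood_size: int = 27,
    mask: np.ndarray | None = None,
) -> VoxelMap:
    """Regional homogeneity: Kendall's W of each voxel with its neighbors.

    Neighborhoods of 7 (faces), 19 (faces+edges) or 27 (full cube) voxels
    are clipped at the volume edges and restricted to in-mask voxels.
    """
    if neighborhood_size not in _NEIGHBORHOOD_OFFSETS:
        raise ValueError("neighborhood_size must be one of 7, 19, 27")
    if bold.shape[-1] < 3:
        raise ValueError("need at least 3 timepoints")
    offsets = _NEIGHBORHOOD_OFFSETS[neighborhood_size]
    nx, ny, nz, n = bold.shape
    if mask is None:
        mask = np.ones((nx, ny, nz), dtype=bool)
    ranks = rankdata(bold, axis=3, method="average")
    constant = np.ptp(bold, axis=3) == 0
    out = np.full((nx, ny, nz), np.nan)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                neigh = [
                    (x + dx, y + dy, z + dz)
                    for dx, dy, dz in offsets
                    if 0 <= x + dx < nx and 0 <= y + dy < ny and 0 <= z + dz < nz
                    and mask[x + dx, y + dy, z + dz]
                ]
                if all(constant[c] for c in neigh):
                    continue  # W undefined; stays masked
                rs = np.sum([ranks[c] for c in neigh], axis=0)
                k = len(neigh)
                s = float(((rs - rs.mean()) ** 2).sum())
                out[x, y, z] = 12.0 * s / (k**2 * (n**3 - n))
    return VoxelMap(values=out)


def falff_map(
    bold: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = DEFAULT_BAND,
    mask: np.ndarray | None = None,
) -> VoxelMap:
    """Fractional amplitude of low-frequency fluctuations.

    Per voxel: (sum of discrete-Fourier amplitudes with band-inclusive
    frequencies) / (sum over all positive frequencies), after linear
    detrending.  Zero total power leaves the voxel masked.
    """
    lo, hi = band
    nyquist = 0.5 / tr_seconds
    if not (0 < lo < hi <= nyquist + 1e-12):
        raise ValueError(
            f"band {band} outside (0, Nyquist={nyquist:.4g}] for TR {tr_seconds}"
        )
    n = bold.shape[-1]
    detrended = sps.detrend(bold, axis=-1, type="linear")
    amp = np.abs(np.fft.rfft(detrended, axis=-1))
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    positive = freqs > 0
    in_band = positive & (freqs >= lo) & (freqs <= hi)
    total = amp[..., positive].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, amp[..., in_band].sum(axis=-1) / total, np.nan)
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return VoxelMap(values=out)


def roi_average(vmap: VoxelMap, atlas: AtlasLabels) -> pd.Series:
    """Mean of unmasked voxel values within each atlas ROI.

    ROIs whose voxels are all masked come back as nan (flagged missing).
    """
    if vmap.values.shape != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: map {vmap.values.shape} vs atlas {atlas.labels.shape}"
        )
    means = {}
    for roi in atlas.roi_ids:
        vals = vmap.values[atlas.labels == roi]
        vals = vals[np.isfinite(vals)]
        means[roi] = float(vals.mean()) if vals.size else np.nan
    return pd.Series(means, name="roi_mean")


# --- connectivity strength --------------------------------------------


def connectivity_strength(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two node timecourses."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant timecourse: connectivity undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _masked_corrcoef(x: np.ndarray) -> np.ndarray:
    """Column-wise correlation matrix with degenerate columns set to nan."""
    sd = x.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.atleast_2d(c)
    c[degenerate, :] = np.nan
    c[:, degenerate] = np.nan
    return c


def build_strength_blocks(nodes: NodeSet | list[NodeSet]) -> tuple[FeatureBlock, FeatureBlock, FeatureBlock]:
    """Connectivity-strength features for ROI-ROI, ROI-RSN and RSN-RSN pairs.

    For ``n`` ROIs the ROI-ROI block has C(n, 2) unordered-pair features
    (20,301 for the default 202-ROI atlas); ROI-RSN has n x R and RSN-RSN
    C(R, 2).  Accepts one NodeSet (one subject -> one row) or a list.
    """
    nodesets = [nodes] if isinstance(nodes, NodeSet) else list(nodes)
    n_roi = nodesets[0].roi_timecourses.shape[1]
    n_rsn = nodesets[0].rsn_timecourses.shape[1]
    roi_names = [roi_node(i + 1) for i in range(n_roi)]
    rsn_names = [rsn_node(i + 1) for i in range(n_rsn)]

    iu_roi = np.triu_indices(n_roi, k=1)
    iu_rsn = np.triu_indices(n_rsn, k=1)
    rows_rr, rows_rn, rows_nn = [], [], []
    for ns in nodesets:
        c = _masked_corrcoef(np.hstack([ns.roi_timecourses, ns.rsn_timecourses]))
        rows_rr.append(c[:n_roi, :n_roi][iu_roi])
        rows_rn.append(c[:n_roi, n_roi:].ravel())
        rows_nn.append(c[n_roi:, n_roi:][iu_rsn])

    roi_roi = FeatureBlock(
        "roi_roi_strength",
        [pair_feature("strength", roi_names[i], roi_names[j]) for i, j in zip(*iu_roi)],
        np.array(rows_rr),
    )
    roi_rsn = FeatureBlock(
        "roi_rsn_strength",
        [pair_feature("strength", r, s) for r in roi_names for s in rsn_names],
        np.array(rows_rn),
    )
    rsn_rsn = FeatureBlock(
        "rsn_rsn_strength",
        [pair_feature("strength", rsn_names[i], rsn_names[j]) for i, j in zip(*iu_rsn)],
        np.array(rows_nn),
    )
    return roi_roi, roi_rsn, rsn_rsn


# --- graph metrics -----------------------------------------------------


def threshold_weights(
    corr: np.ndarray, proportion: float = 0.25, policy_name: str = "positive-proportional"
) -> WeightMatrix:
    """Build the thresholded whole-brain network from a correlation matrix.

    Default policy: discard negative weights, then retain the strongest
    ``proportion`` of the remaining off-diagonal edges (symmetric pairs).
    Retained weights keep their correlation values, hence lie in [0, 1];
    the diagonal is zeroed.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    w = np.array(corr, dtype=float)
    if w.shape[0] != w.shape[1] or not np.allclose(w, w.T, equal_nan=True):
        raise ValueError("correlation matrix must be square and symmetric")
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0
    w[w < 0] = 0.0
    iu = np.triu_indices_from(w, k=1)
    vals = w[iu]
    n_keep = int(round(proportion * vals.size))
    if n_keep < vals.size:
        # stable strongest-first ordering; ties broken by edge index
        order = np.lexsort((np.arange(vals.size), -vals))
        drop = order[n_keep:]
        vals = vals.copy()
        vals[drop] = 0.0
        w = np.zeros_like(w)
        w[iu] = vals
        w = w + w.T
    return WeightMatrix(
        weights=w,
        threshold_policy={"name": policy_name, "proportion": proportion},
    )


def graph_node_metrics(wm: WeightMatrix) -> pd.DataFrame:
    """Weighted node strength, Onnela clustering, and local efficiency.

    Clustering uses the geometric mean of triangle weights normalised by
    the maximum weight; local efficiency is the standard weighted
    neighborhood formulation, with shortest paths on 1/w edge lengths
    inside each node's neighborhood subgraph.  Nodes of degree < 2 get
    clustering and local efficiency 0.
    """
    w = np.asarray(wm.weights, dtype=float)
    n = w.shape[0]
    strength = w.sum(axis=1)
    degree = (w > 0).sum(axis=1)

    wmax = w.max()
    w_hat = w / wmax if wmax > 0 else w
    cr = np.cbrt(w_hat)
    triangles = np.diagonal(cr @ cr @ cr)
    denom = degree * (degree - 1)
    clustering = np.where(denom > 0, np.divide(
        triangles, np.where(denom > 0, denom, 1)), 0.0)

    local_eff = np.zeros(n)
    for i in range(n):
        neigh = np.flatnonzero(w[i] > 0)
        k = neigh.size
        if k < 2:
            continue
        sub = w[np.ix_(neigh, neigh)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / sub, np.inf)
        d = dijkstra(lengths, directed=False)
        wi = w[i, neigh]
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_d = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        terms = np.cbrt(np.outer(wi, wi) * inv_d)
        np.fill_diagonal(terms, 0.0)
        local_eff[i] = terms.sum() / (k * (k - 1))

    return pd.DataFrame(
        {"strength": strength, "clustering": clustering, "local_efficiency": local_eff}
    )


# --- cohort-level assembly --------------------------------------------


def assemble_feature_matrix(
    cohort: list[SubjectRecord],
    threshold_proportion: float = 0.25,
    gm_volume: FeatureBlock | None = None,
    include_voxel_blocks: bool | None = None,
) -> FeatureMatrix:
    """Derive the full subjects x features matrix from a cohort.

    Always builds the three connectivity-strength blocks and the two
    graph-metric blocks (clustering, local efficiency on the thresholded
    ROI network).  Voxelwise blocks (CBF, ReHo, fALFF averaged within
    atlas ROIs) are added when subjects carry phantom volumes.  A
    precomputed GM-volume block may be appended; it is never derived here.
    """
    subject_ids = [r.subject_id for r in cohort]
    nodesets = [NodeSet(r.roi_timecourses, r.rsn_timecourses) for r in cohort]
    blocks = list(build_strength_blocks(nodesets))

    n_roi = cohort[0].roi_timecourses.shape[1]
    clust_rows, eff_rows = [], []
    for ns in nodesets:
        corr = _masked_corrcoef(ns.roi_timecourses)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        metrics = graph_node_metrics(threshold_weights(corr, threshold_proportion))
        clust_rows.append(metrics["clustering"].to_numpy())
        eff_rows.append(metrics["local_efficiency"].to_numpy())
    roi_names = [roi_node(i + 1) for i in range(n_roi)]
    blocks.append(FeatureBlock(
        "clustering", [node_feature("clustering", r) for r in roi_names],
        np.array(clust_rows)))
    blocks.append(FeatureBlock(
        "local_efficiency", [node_feature("local_efficiency", r) for r in roi_names],
        np.array(eff_rows)))

    if include_voxel_blocks is None:
        include_voxel_blocks = all(r.phantom is not None for r in cohort)
    if include_voxel_blocks:
        cbf_rows, reho_rows, falff_rows = [], [], []
        for rec in cohort:
            ph = rec.phantom
            if ph is None:
                raise ValueError("voxel blocks requested but subject lacks phantom volumes")
            atlas = AtlasLabels(labels=ph.labels)
            mask = ph.labels > 0
            cbf_rows.append(roi_average(cbf_simple_subtraction(ph.asl, ph.asl_tags), atlas).to_numpy())
            reho_rows.append(roi_average(reho_map(ph.bold, mask=mask), atlas).to_numpy())
            falff_rows.append(roi_average(falff_map(ph.bold, tr_seconds=2.0, mask=mask), atlas).to_numpy())
        atlas_ids = AtlasLabels(labels=cohort[0].phantom.labels).roi_ids
        for bname, rows in (("cbf", cbf_rows), ("reho", reho_rows), ("falff", falff_rows)):
            blocks.append(FeatureBlock(
                bname, [node_feature(bname, roi_node(i)) for i in atlas_ids],
                np.array(rows)))

    if gm_volume is not None:
        blocks.append(gm_volume)
    return FeatureMatrix.from_blocks(blocks, subject_ids)
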