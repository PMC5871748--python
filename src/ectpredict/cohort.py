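"""Synthetic resting-state cohorts with planted connectivity--outcome signal.

The generator emulates the data structure of a pre-treatment multimodal fMRI
study of ECT response: per subject it produces ROI and RSN node timecourses
(for connectivity-strength and graph-metric features), optional small
voxel-grid BOLD/ASL phantoms (for the voxelwise metrics), and clinical
depression scores (HAMD-17, MADRS, QIDS) before and after treatment.

Signal is planted at the level of pairwise connectivity: for each planted
node pair, the two node series share a low-frequency latent component whose
per-subject loading sets their Pearson correlation, and the same per-subject
latent also drives percent improvement in the clinical scores.  A block of
deliberately collinear connectivity features and a set of exactly constant
features are planted to exercise the pre-classification filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .naming import pair_feature, parse_pair_feature, roi_node, rsn_node

CLINICAL_SCALES = ("HAMD17", "MADRS", "QIDS")
# Cohort-level score means used as generative anchors (baseline severity of a
# treatment-resistant depressed sample; improvement centred near the response
# threshold so the balanced split is not degenerate).
PRE_SCORE_MEANS = {"HAMD17": 24.02, "MADRS": 37.50, "QIDS": 19.74}
PRE_SCORE_SDS = {"HAMD17": 4.0, "MADRS": 5.0, "QIDS": 3.0}
MEAN_IMPROVEMENT = 45.0
IMPROVEMENT_SD = 12.0
SCALE_IMPROVEMENT_JITTER_SD = 5.0
AGE_MEAN, AGE_SD = 41.74, 6.78


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the emulated acquisition: 46 subjects, 202 atlas ROIs,
    31 RSNs, 178 retained BOLD volumes at TR 2.0 s, 30 ASL label/control
    pairs.  ``effect_size`` is the standardized weight of each planted
    feature's latent z-score in the improvement model; ``noise_sd`` the
    standardized residual scale.
    """

    n_subjects: int = 46
    n_rois: int = 202
    n_rsns: int = 31
    n_timepoints: int = 178
    tr_seconds: float = 2.0
    n_asl_pairs: int = 30
    phantom_grid: tuple[int, int, int] = (12, 12, 8)
    planted_features: list[str] | None = None
    effect_size: float = 1.0
    noise_sd: float = 0.5
    planted_cohesion: float = 0.6
    collinear_block_size: int = 6
    n_constant_features: int = 3
    include_phantoms: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects % 2 != 0:
            raise ValueError(
                "n_subjects must be even: the outcome labeling divides the "
                "cohort into equally sized responder/non-responder classes"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.planted_cohesion < 0.7:
            raise ValueError(
                "planted_cohesion must lie in [0, 0.7): at 0.7 the planted "
                "features themselves trip the collinearity filter"
            )
        if self.planted_features is None:
            # Five ROI-ROI connectivity features on disjoint node pairs.
            self.planted_features = [
                pair_feature("strength", roi_node(2 * k + 1), roi_node(2 * k + 2))
                for k in range(5)
            ]
        n_special = (
            2 * len(self.planted_features)
            + 2 * self.collinear_block_size
            + 2 * self.n_constant_features
        )
        if n_special > self.n_rois:
            raise ValueError(
                f"n_rois={self.n_rois} too small for {n_special} designated "
                "planted/collinear/constant nodes"
            )
        if self.n_timepoints * self.tr_seconds * 0.01 < 1.5:
            warnings.warn(
                "timecourse shorter than ~1.5 cycles of 0.01 Hz; low-frequency "
                "metrics will be poorly defined",
                stacklevel=2,
            )

    # --- designated feature bookkeeping -------------------------------

    def planted_node_pairs(self) -> list[tuple[int, int]]:
        """0-based ROI column indices of the planted connectivity pairs."""
        pairs = []
        for name in self.planted_features:
            _, a, b = parse_pair_feature(name)
            pairs.append((int(a[1:]) - 1, int(b[1:]) - 1))
        return pairs

    def collinear_node_pairs(self) -> list[tuple[int, int]]:
        start = 2 * len(self.planted_features)
        return [
            (start + 2 * m, start + 2 * m + 1)
            for m in range(self.collinear_block_size)
        ]

    def constant_node_pairs(self) -> list[tuple[int, int]]:
        start = 2 * len(self.planted_features) + 2 * self.collinear_block_size
        return [
            (start + 2 * m, start + 2 * m + 1)
            for m in range(self.n_constant_features)
        ]

    def collinear_feature_names(self) -> list[str]:
        return [
            pair_feature("strength", roi_node(a + 1), roi_node(b + 1))
            for a, b in self.collinear_node_pairs()
        ]

    def constant_feature_names(self) -> list[str]:
        return [
            pair_feature("strength", roi_node(a + 1), roi_node(b + 1))
            for a, b in self.constant_node_pairs()
        ]


@dataclass
class VoxelPhantom:
    """Small voxel-grid fixture for the voxelwise metrics.

    ``bold`` is (x, y, z, t); ``asl`` alternates label/control volumes per
    ``asl_tags``; ``labels`` assigns each voxel an ROI id (0 = background).
    ``roi_perfusion`` maps roi id -> the true control-minus-label difference.
    """

    bold: np.ndarray
    asl: np.ndarray
    labels: np.ndarray
    asl_tags: list[str]
    roi_perfusion: dict[int, float]
    signal_roi: int
    signal_freq_hz: float
    signal_amplitude: float


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    roi_timecourses: np.ndarray  # (timepoints, n_rois)
    rsn_timecourses: np.ndarray  # (timepoints, n_rsns)
    clinical_pre: dict[str, float]
    clinical_post: dict[str, float]
    phantom: VoxelPhantom | None = None
    latent_improvement: float = field(default=np.nan, repr=False)

    def __post_init__(self) -> None:
        if self.roi_timecourses.shape[0] != self.rsn_timecourses.shape[0]:
            raise ValueError("ROI and RSN timecourses must share length")
        for scale, pre in self.clinical_pre.items():
            if pre <= 0:
                raise ValueError(
                    f"pre-treatment {scale} score must be strictly positive"
                )


def _lowfreq_series(rng: np.random.Generator, t: np.ndarray, n_t: int) -> np.ndarray:
    """AR(1) + random low-frequency sinusoid mixture, z-scored."""
    innov = rng.standard_normal(n_t)
    x = np.empty(n_t)
    x[0] = innov[0]
    for i in range(1, n_t):
        x[i] = 0.3 * x[i - 1] + innov[i]
    for _ in range(2):
        f = rng.uniform(0.01, 0.08)
        x = x + rng.uniform(0.3, 0.8) * np.sin(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
        )
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _lowfreq_panel(
    rng: np.random.Generator, t: np.ndarray, n_t: int, n_series: int
) -> np.ndarray:
    """Vectorised stack of independent z-scored AR(1)+sinusoid series."""
    innov = rng.standard_normal((n_t, n_series))
    x = np.empty((n_t, n_series))
    x[0] = innov[0]
    for i in range(1, n_t):
        x[i] = 0.3 * x[i - 1] + innov[i]
    for _ in range(2):
        f = rng.uniform(0.01, 0.08, size=n_series)
        amp = rng.uniform(0.3, 0.8, size=n_series)
        ph = rng.uniform(0, 2 * np.pi, size=n_series)
        x = x + amp * np.sin(2 * np.pi * f * t[:, None] + ph)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a deterministic synthetic cohort.

    Planted connectivity features correlate positively with subsequent
    percent improvement at the configured effect size; the collinear block
    is pairwise correlated above 0.70 across subjects; the constant features
    have zero between-subject variance (both node series identical, so the
    Pearson correlation is exactly 1 for every subject).
    """
    rng = np.random.default_rng(config.seed)
    n_t = config.n_timepoints
    t = np.arange(n_t) * config.tr_seconds

    planted_pairs = config.planted_node_pairs()
    collinear_pairs = config.collinear_node_pairs()
    constant_pairs = config.constant_node_pairs()
    k = len(planted_pairs)

    # Per-subject latents.  The k planted connectivity latents share a
    # common factor u (mutual correlation = planted_cohesion, kept below
    # the 0.70 collinearity cutoff): consistently selected features in
    # this kind of study belong to one interacting network system, not to
    # k unrelated circuits.  Improvement is driven by the shared factor.
    rho = config.planted_cohesion
    u = rng.standard_normal(config.n_subjects)
    xi = rng.standard_normal((config.n_subjects, k))
    z_planted = np.sqrt(rho) * u[:, None] + np.sqrt(1 - rho) * xi
    v_block = rng.standard_normal(config.n_subjects)  # collinear driver
    eps_imp = rng.standard_normal(config.n_subjects)

    # Standardized improvement: corr(u, improvement) =
    # effect_size / sqrt(effect_size^2 + noise_sd^2).
    denom = np.sqrt(config.effect_size**2 + config.noise_sd**2)
    if denom == 0:
        standardized = np.zeros(config.n_subjects)
    else:
        standardized = (config.effect_size * u + config.noise_sd * eps_imp) / denom
    improvement = MEAN_IMPROVEMENT + IMPROVEMENT_SD * standardized

    ages = rng.normal(AGE_MEAN, AGE_SD, size=config.n_subjects)

    records: list[SubjectRecord] = []
    for s in range(config.n_subjects):
        roi = _lowfreq_panel(rng, t, n_t, config.n_rois)
        rsn = _lowfreq_panel(rng, t, n_t, config.n_rsns)

        # Weak global component: realistic positive baseline connectivity.
        g = _lowfreq_series(rng, t, n_t)
        roi = np.sqrt(0.9) * roi + np.sqrt(0.1) * g[:, None]
        rsn = np.sqrt(0.9) * rsn + np.sqrt(0.1) * g[:, None]

        # Planted pairs: shared component with subject-specific loading.
        for j, (a, b) in enumerate(planted_pairs):
            lam = float(np.clip(0.5 + 0.18 * z_planted[s, j], 0.05, 0.95))
            c = _lowfreq_series(rng, t, n_t)
            roi[:, a] = np.sqrt(lam) * c + np.sqrt(1 - lam) * _lowfreq_series(rng, t, n_t)
            roi[:, b] = np.sqrt(lam) * c + np.sqrt(1 - lam) * _lowfreq_series(rng, t, n_t)

        # Collinear block: loadings all driven by one subject latent.
        for a, b in collinear_pairs:
            lam = float(
                np.clip(0.55 + 0.12 * v_block[s] + 0.02 * rng.standard_normal(), 0.05, 0.95)
            )
            c = _lowfreq_series(rng, t, n_t)
            roi[:, a] = np.sqrt(lam) * c + np.sqrt(1 - lam) * _lowfreq_series(rng, t, n_t)
            roi[:, b] = np.sqrt(lam) * c + np.sqrt(1 - lam) * _lowfreq_series(rng, t, n_t)

        # Constant features: duplicate node series, correlation exactly 1.
        for a, b in constant_pairs:
            roi[:, b] = roi[:, a]

        pre: dict[str, float] = {}
        post: dict[str, float] = {}
        for scale in CLINICAL_SCALES:
            p = max(
                5.0, rng.normal(PRE_SCORE_MEANS[scale], PRE_SCORE_SDS[scale])
            )
            imp_scale = min(
                100.0,
                improvement[s] + rng.normal(0, SCALE_IMPROVEMENT_JITTER_SD),
            )
            pre[scale] = round(float(p), 2)
            post[scale] = round(float(p * (1 - imp_scale / 100.0)), 2)

        phantom = generate_voxel_phantom(config, rng=rng) if config.include_phantoms else None
        records.append(
            SubjectRecord(
                subject_id=f"sub-{s + 1:03d}",
                age=round(float(ages[s]), 1),
                roi_timecourses=roi,
                rsn_timecourses=rsn,
                clinical_pre=pre,
                clinical_post=post,
                phantom=phantom,
                latent_improvement=float(improvement[s]),
            )
        )
    return records


def generate_voxel_phantom(
    config: CohortConfig,
    signal_roi: int = 1,
    signal_freq_hz: float = 0.05,
    signal_amplitude: float = 3.0,
    rng: np.random.Generator | None = None,
) -> VoxelPhantom:
    """Build a small voxel-grid phantom with known ground truth.

    The label volume tiles ~90% of the grid with ``n_rois`` equally sized
    ROIs (flat C-order runs; remaining voxels are background 0).  Every
    voxel of ``signal_roi`` shares one common sinusoidal component at
    ``signal_freq_hz``, so regional homogeneity and in-band fALFF are high
    there by construction.  ASL volumes alternate label/control
    (label-first); the control-minus-label difference for ROI ``r`` is
    ``10 + r`` in every voxel of that ROI.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.phantom_grid
    n_vox = nx * ny * nz
    per_roi = int(n_vox * 0.9) // config.n_rois
    if per_roi < 2:
        raise ValueError(
            f"phantom grid {config.phantom_grid} too small to hold "
            f"{config.n_rois} ROIs with >=2 voxels each"
        )
    flat_labels = np.zeros(n_vox, dtype=np.int32)
    for r in range(config.n_rois):
        flat_labels[r * per_roi : (r + 1) * per_roi] = r + 1
    labels = flat_labels.reshape(nx, ny, nz)

    n_t = config.n_timepoints
    t = np.arange(n_t) * config.tr_seconds
    bold = rng.standard_normal((nx, ny, nz, n_t))
    common = signal_amplitude * np.sin(
        2 * np.pi * signal_freq_hz * t + rng.uniform(0, 2 * np.pi)
    )
    bold[labels == signal_roi] += common

    roi_perfusion = {r: 10.0 + r for r in range(1, config.n_rois + 1)}
    perfusion = np.zeros((nx, ny, nz))
    for r, d in roi_perfusion.items():
        perfusion[labels == r] = d
    n_vol = 2 * config.n_asl_pairs
    asl = np.empty((nx, ny, nz, n_vol))
    tags = []
    base = 100.0  # noise-free: the subtraction map is exactly `perfusion`
    for i in range(n_vol):
        if i % 2 == 0:  # label-first tag order
            asl[..., i] = base
            tags.append("label")
        else:
            asl[..., i] = base + perfusion
            tags.append("control")
    return VoxelPhantom(
        bold=bold,
        asl=asl,
        labels=labels,
        asl_tags=tags,
        roi_perfusion=roi_perfusion,
        signal_roi=signal_roi,
        signal_freq_hz=signal_freq_hz,
        signal_amplitude=signal_amplitude,
    )


# --- disk round-trip ---------------------------------------------------


def clinical_table(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format clinical table: subject_id, age, scale, pre, post."""
    rows = []
    for rec in cohort:
        for scale in CLINICAL_SCALES:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "age": rec.age,
                    "scale": scale,
                    "pre": rec.clinical_pre[scale],
                    "post": rec.clinical_post[scale],
                }
            )
    return pd.DataFrame(rows)


def write_cohort(cohort: list[SubjectRecord], outdir) -> None:
    """Write timecourse TSVs (one per subject), the clinical CSV, and any
    phantom volumes as NIfTI."""
    import pathlib

    import nibabel as nib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in cohort:
        n_rois = rec.roi_timecourses.shape[1]
        n_rsns = rec.rsn_timecourses.shape[1]
        df = pd.DataFrame(
            np.hstack([rec.roi_timecourses, rec.rsn_timecourses]),
            columns=[roi_node(i + 1) for i in range(n_rois)]
            + [rsn_node(i + 1) for i in range(n_rsns)],
        )
        df.to_csv(outdir / f"{rec.subject_id}_timecourses.tsv", sep="\t", index=False)
        if rec.phantom is not None:
            affine = np.eye(4)
            nib.save(
                nib.Nifti1Image(rec.phantom.bold, affine),
                outdir / f"{rec.subject_id}_bold.nii",
            )
            nib.save(
                nib.Nifti1Image(rec.phantom.asl, affine),
                outdir / f"{rec.subject_id}_asl.nii",
            )
            nib.save(
                nib.Nifti1Image(rec.phantom.labels.astype(np.int16), affine),
                outdir / f"{rec.subject_id}_atlas.nii",
            )
    clinical_table(cohort).to_csv(outdir / "clinical.csv", index=False)


def read_timecourses(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a timecourse TSV back into (roi, rsn) arrays."""
    df = pd.read_csv(path, sep="\t")
    roi_cols = [c for c in df.columns if c.startswith("R")]
    rsn_cols = [c for c in df.columns if c.startswith("N")]
    return df[roi_cols].to_numpy(), df[rsn_cols].to_numpy()
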