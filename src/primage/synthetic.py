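"""Synthetic baboon brain cohorts: phantoms plus metadata with programmed aging.

The study system is the adult baboon (*Papio hamadryas*) lifespan, ages 4-22
years, where fractional gray-matter volume declines with age (linearly in
females, quadratically in males), fractional white matter rises, and - in
females - fractional CSF rises.  A second, young-adult (4-7 y) experimental
design contrasts offspring of nutrient-restricted pregnancies (MNR) against
ad-libitum controls (CTR); the programmed MNR effect in females is a
gray-matter deficit rebalanced into CSF, i.e. an atrophy pattern equivalent to
a few extra years of aging.

No imaging data for such cohorts is publicly deposited, so this module renders
seeded three-compartment phantoms (WM core, GM ribbon, CSF shell inside a
skull-stripped field of view) whose compartment fractions follow the
programmed per-sex trajectories, and carries the exact voxel-level ground
truth forward so every downstream stage (segmentation, template building, age
regression, group statistics) can be tested for parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import CLASS_NAMES, TISSUE_CLASSES, TissueProbabilityMap, VolumeImage

__all__ = [
    "SubjectRecord",
    "SexTrajectory",
    "AgingModelParams",
    "PhantomSpec",
    "Cohort",
    "trajectory_fractions",
    "render_phantom",
    "generate_cohort",
    "generate_experiment_cohort",
    "noisy_gm_maps",
]


class GeometryError(ValueError):
    """Raised when the requested compartment volumes cannot fit the grid."""


@dataclass(frozen=True)
class SubjectRecord:
    """One scanned subject: identity, sex, chronological age and group."""

    id: str
    sex: str                      # "female" | "male"
    age: float                    # chronological age, years
    group: str = "CTR"            # "CTR" | "MNR"
    birth_weight: float = None    # kg, optional
    weight_at_scan: float = None  # kg, optional

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.group not in ("CTR", "MNR"):
            raise ValueError(f"group must be 'CTR' or 'MNR', got {self.group!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")


@dataclass(frozen=True)
class SexTrajectory:
    """Polynomial age trajectories of fractional GM and WM for one sex.

    Each entry is ``(intercept, linear, quadratic)`` so that
    ``frac(age) = c0 + c1*age + c2*age**2``; fractional CSF is the complement
    ``1 - GM - WM`` (the three tissue fractions are defined relative to TIV,
    so they sum to one by construction).
    """

    gm: tuple
    wm: tuple

    def eval(self, compartment: str, age) -> np.ndarray:
        c0, c1, c2 = getattr(self, compartment)
        age = np.asarray(age, dtype=float)
        return c0 + c1 * age + c2 * age ** 2


# Calibration anchors: the per-sex lifespan cohort mean ages at which the
# default trajectories reproduce the target mean fractional volumes
# (female 0.47 GM / 0.32 WM at 9.43 y; male 0.46 / 0.32 at 9.62 y).
_FEMALE_ANCHOR_AGE = 9.43
_MALE_ANCHOR_AGE = 9.62

_FEMALE_GM_SLOPE = -0.0065          # fractional GM per year, linear decline
_FEMALE_WM_SLOPE = 0.002
_MALE_GM_LIN = -0.000323            # mild linear term; decline is mostly quadratic
_MALE_GM_QUAD = -0.0002

_DEFAULT_FEMALE = SexTrajectory(
    gm=(0.47 - _FEMALE_GM_SLOPE * _FEMALE_ANCHOR_AGE, _FEMALE_GM_SLOPE, 0.0),
    wm=(0.32 - _FEMALE_WM_SLOPE * _FEMALE_ANCHOR_AGE, _FEMALE_WM_SLOPE, 0.0),
)
# Male WM mirrors the GM age terms so fractional CSF stays flat at 0.22 in
# males (no programmed male CSF age effect).
_MALE_GM_C0 = 0.46 + 0.000323 * _MALE_ANCHOR_AGE + 0.0002 * _MALE_ANCHOR_AGE ** 2
_DEFAULT_MALE = SexTrajectory(
    gm=(_MALE_GM_C0, _MALE_GM_LIN, _MALE_GM_QUAD),
    wm=(0.78 - _MALE_GM_C0, -_MALE_GM_LIN, -_MALE_GM_QUAD),
)


@dataclass
class AgingModelParams:
    """All knobs of the synthetic cohort generator.

    Defaults encode the programmed study conditions: per-sex fractional
    trajectories whose cohort-level means and SDs approximate the lifespan
    sample (GM 0.47/0.46, WM 0.32, CSF 0.21/0.22; TIV 186.7 +/- 14.4 ml in
    females, 210.4 +/- 14.0 ml in males), an MNR gray-matter deficit in
    females equivalent to +2.7 years of female-pattern aging, and acquisition
    artifacts (additive noise, a smooth multiplicative bias field, per-slice
    gain jitter) at plausible T1 levels.
    """

    age_range: tuple = (4.0, 22.0)
    female: SexTrajectory = field(default_factory=lambda: _DEFAULT_FEMALE)
    male: SexTrajectory = field(default_factory=lambda: _DEFAULT_MALE)
    tiv_mean_ml: dict = field(default_factory=lambda: {"female": 186.7, "male": 210.4})
    tiv_sd_ml: dict = field(default_factory=lambda: {"female": 14.4, "male": 14.0})
    #: fractional-GM decrement applied to MNR females, rebalanced into CSF.
    #: Default = 2.7 years x |female GM slope| (an atrophy offset equivalent
    #: to +2.7 brain-years on the female trajectory).
    mnr_gm_offset: float = 2.7 * abs(_FEMALE_GM_SLOPE)
    # acquisition artifact amplitudes
    intensity_noise_sd: float = 0.02   # additive, on a 0-1 intensity scale
    bias_amplitude: float = 0.05       # multiplicative smooth field, relative
    slice_gain_sd: float = 0.03        # per-slice multiplicative gain SD
    #: voxelwise SD of the additive noise on "preprocessed" GM probability
    #: maps; calibrated so the feature-space age SNR of a default lifespan
    #: cohort is ~2 (see brainage.feature_age_snr).
    gm_map_noise_sd: float = 0.045
    # grid geometry
    grid_shape: tuple = (48, 48, 48)
    voxel_size_mm: float = 2.0
    #: T1-like class mean intensities (CSF < GM < WM).
    class_means: dict = field(default_factory=lambda: {
        "background": 0.0, "csf": 0.3, "gm": 0.6, "wm": 0.9})

    def __post_init__(self):
        if np.isscalar(self.grid_shape):
            self.grid_shape = (int(self.grid_shape),) * 3
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.validate()

    def validate(self):
        lo, hi = self.age_range
        if not lo < hi or lo <= 0:
            raise ValueError("age_range must be an increasing pair of positive years")
        for sd in (self.intensity_noise_sd, self.bias_amplitude, self.slice_gain_sd,
                   self.gm_map_noise_sd, *self.tiv_sd_ml.values()):
            if sd < 0:
                raise ValueError("all SD / amplitude parameters must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if min(self.grid_shape) < 16:
            raise ValueError("grid must be at least 16 voxels per axis")
        # tissue fractions stay in (0, 1) over the supported age range
        ages = np.linspace(lo, hi, 64)
        for sex in ("female", "male"):
            traj = getattr(self, sex)
            gm, wm = traj.eval("gm", ages), traj.eval("wm", ages)
            csf = 1.0 - gm - wm
            for name, frac in (("GM", gm), ("WM", wm), ("CSF", csf)):
                if frac.min() <= 0 or frac.max() >= 1:
                    raise ValueError(
                        f"{sex} {name} fraction leaves (0,1) on {self.age_range}")
        if not (self.class_means["csf"] < self.class_means["gm"] < self.class_means["wm"]):
            raise ValueError("class means must follow T1 ordering CSF < GM < WM")


@dataclass(frozen=True)
class PhantomSpec:
    """Fully resolved rendering request for one subject's phantom."""

    subject: SubjectRecord
    gm_frac: float
    wm_frac: float
    csf_frac: float
    tiv_ml: float
    seed: int

    def __post_init__(self):
        fr = (self.gm_frac, self.wm_frac, self.csf_frac)
        if min(fr) <= 0:
            raise ValueError("tissue fractions must be positive")
        if abs(sum(fr) - 1.0) > 1e-6:
            raise ValueError("tissue fractions must sum to 1 within 1e-6")
        if self.tiv_ml <= 0:
            raise ValueError("TIV must be positive")


def trajectory_fractions(params: AgingModelParams, sex: str, age: float,
                         group: str = "CTR") -> tuple:
    """Programmed (GM, WM, CSF) fractional volumes at a given age.

    Follows the per-sex polynomial trajectories; MNR females additionally
    lose ``params.mnr_gm_offset`` of fractional GM, rebalanced into CSF
    (fractional GM down, CSF up, WM untouched).

    Raises
    ------
    ValueError
        If ``age`` lies outside ``params.age_range``.
    """
    lo, hi = params.age_range
    if not (lo - 1e-9 <= age <= hi + 1e-9):
        raise ValueError(f"age {age} outside supported range [{lo}, {hi}]")
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex {sex!r}")
    traj = getattr(params, sex)
    gm = float(traj.eval("gm", age))
    wm = float(traj.eval("wm", age))
    csf = 1.0 - gm - wm
    if group == "MNR" and sex == "female" and params.mnr_gm_offset != 0.0:
        gm -= params.mnr_gm_offset
        csf += params.mnr_gm_offset
    if min(gm, wm, csf) <= 0:
        raise ValueError("programmed fractions left (0,1); check params")
    return gm, wm, csf


# class indices used for phantom labels (match image.CLASS_NAMES order)
_GM, _WM, _CSF, _BG = 0, 1, 2, 3


def render_phantom(spec: PhantomSpec, params: AgingModelParams):
    """Render one subject's T1-like phantom and its ground-truth tissue map.

    Geometry is a mildly anisotropic (seeded, volume-preserving) set of
    concentric compartments: WM core, GM ribbon, CSF shell.  Voxels are
    assigned by sorting on the deformed radial metric, so the voxel-count
    fractions match the spec essentially exactly (to +/-1 voxel per class).
    Intensities follow the T1 ordering CSF < GM < WM, then a smooth
    multiplicative bias field, per-slice gains (third axis) and additive
    Gaussian noise are applied.  Identical spec + params give bit-identical
    output.

    Returns
    -------
    (VolumeImage, TissueProbabilityMap)
        The simulated image and the exact (one-hot) tissue ground truth.
    """
    shape = params.grid_shape
    vs = params.voxel_size_mm
    voxel_ml = vs ** 3 / 1000.0
    n_total = int(round(spec.tiv_ml / voxel_ml))
    n_vox = int(np.prod(shape))
    if n_total > 0.92 * n_vox:
        raise GeometryError(
            f"TIV {spec.tiv_ml:.1f} ml needs {n_total} voxels; grid holds only "
            f"{n_vox} ({vs} mm voxels) - enlarge the grid or voxels")

    rng = np.random.default_rng(spec.seed)

    # volume-preserving anisotropy + small center jitter (subject shape variation)
    log_axes = rng.normal(0.0, 0.04, size=3)
    axes = np.exp(log_axes - log_axes.mean())          # product == 1
    center = (np.asarray(shape, dtype=float) - 1) / 2 + rng.uniform(-1, 1, size=3)

    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    order = np.argsort(d2, axis=None, kind="stable")

    n_wm = int(round(spec.wm_frac * n_total))
    n_gm = int(round(spec.gm_frac * n_total))
    n_csf = n_total - n_wm - n_gm

    labels = np.full(n_vox, _BG, dtype=np.int8)
    labels[order[:n_wm]] = _WM
    labels[order[n_wm:n_wm + n_gm]] = _GM
    labels[order[n_wm + n_gm:n_total]] = _CSF
    labels = labels.reshape(shape)

    means = params.class_means
    intensity = np.choose(labels, [means["gm"], means["wm"], means["csf"],
                                   means["background"]])

    # smooth multiplicative bias field from a coarse seeded lattice
    coarse = rng.normal(0.0, 1.0, size=(3, 3, 3))
    if params.bias_amplitude > 0:
        fieldv = ndimage.zoom(coarse, [s / 3 for s in shape], order=3)
        pad = [(0, max(0, s - f)) for s, f in zip(shape, fieldv.shape)]
        if any(p[1] for p in pad):
            fieldv = np.pad(fieldv, pad, mode="edge")
        fieldv = fieldv[:shape[0], :shape[1], :shape[2]]
        peak = np.max(np.abs(fieldv)) or 1.0
        intensity = intensity * (1.0 + params.bias_amplitude * fieldv / peak)

    # per-slice multiplicative gains along the third grid axis
    gains = 1.0 + rng.normal(0.0, params.slice_gain_sd, size=shape[2]) \
        if params.slice_gain_sd > 0 else np.ones(shape[2])
    intensity = intensity * gains[None, None, :]

    if params.intensity_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.intensity_noise_sd, size=shape)

    img = VolumeImage(intensity, (vs, vs, vs))
    truth = TissueProbabilityMap.from_labels(labels, (vs, vs, vs))
    return img, truth


@dataclass
class Cohort:
    """A generated cohort: metadata table, images and voxel-level ground truth."""

    metadata: pd.DataFrame
    images: list
    ground_truth: list
    params: AgingModelParams
    master_seed: int

    @property
    def n(self) -> int:
        return len(self.metadata)

    def subject_index(self, subject_id: str) -> int:
        idx = np.flatnonzero(self.metadata["id"].values == subject_id)
        if idx.size != 1:
            raise KeyError(subject_id)
        return int(idx[0])

    def gm_truth_maps(self) -> list:
        """Ground-truth GM probability grids, one per subject."""
        return [t.gm for t in self.ground_truth]

    def write(self, out_dir) -> dict:
        """Write per-subject NIfTI volumes and the CSV metadata table."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {"metadata": out_dir / "metadata.csv", "images": []}
        cols = ["id", "sex", "age", "group", "birth_weight", "weight_at_scan"]
        self.metadata[cols].to_csv(paths["metadata"], index=False)
        for sid, img in zip(self.metadata["id"], self.images):
            p = out_dir / f"{sid}.nii"
            img.to_nifti(p)
            paths["images"].append(p)
        return paths


def _subject_seed(ss_child: np.random.SeedSequence) -> int:
    return int(ss_child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _draw_subject(rng, params, sex, group, age, sid, seed, birth_w=None, scan_w=None):
    tiv = -1.0
    while tiv <= 0:
        tiv = rng.normal(params.tiv_mean_ml[sex], params.tiv_sd_ml[sex])
    gm, wm, csf = trajectory_fractions(params, sex, age, group)
    rec = SubjectRecord(id=sid, sex=sex, age=float(age), group=group,
                        birth_weight=birth_w, weight_at_scan=scan_w)
    return rec, PhantomSpec(rec, gm, wm, csf, float(tiv), seed)


def _assemble(records, specs, params, master_seed) -> Cohort:
    rows, images, truths = [], [], []
    for rec, spec in zip(records, specs):
        img, truth = render_phantom(spec, params)
        images.append(img)
        truths.append(truth)
        rows.append({
            "id": rec.id, "sex": rec.sex, "age": rec.age, "group": rec.group,
            "birth_weight": rec.birth_weight, "weight_at_scan": rec.weight_at_scan,
            "tiv_true_ml": spec.tiv_ml,
            "gm_frac_true": spec.gm_frac, "wm_frac_true": spec.wm_frac,
            "csf_frac_true": spec.csf_frac, "seed": spec.seed,
        })
    meta = pd.DataFrame(rows)
    if meta["id"].duplicated().any():
        raise ValueError("subject ids must be unique within a cohort")
    return Cohort(meta, images, truths, params, master_seed)


def generate_cohort(params: AgingModelParams, n_per_sex=(15, 14), age_range=None,
                    groups=("CTR",), master_seed: int = 0) -> Cohort:
    """Generate a lifespan-style cohort (ages uniform over the range, CTR only
    by default).

    ``n_per_sex`` is ``(n_female, n_male)``; ages are drawn uniformly over
    ``age_range`` (default: the params' supported range) and TIV from the
    per-sex normal distribution.  All randomness descends from
    ``master_seed`` through spawned child sequences, so equal seeds give
    identical cohorts, voxel for voxel.
    """
    n_f, n_m = int(n_per_sex[0]), int(n_per_sex[1])
    if n_f + n_m < 1 or min(n_f, n_m) < 0:
        raise ValueError("need at least one subject")
    age_range = tuple(age_range) if age_range is not None else params.age_range
    ss = np.random.SeedSequence(master_seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(n_f + n_m)

    records, specs = [], []
    i = 0
    for sex, n_sex, prefix in (("female", n_f, "F"), ("male", n_m, "M")):
        for k in range(n_sex):
            age = meta_rng.uniform(*age_range)
            group = groups[k % len(groups)]
            sid = f"{prefix}{k + 1:02d}"
            rec, spec = _draw_subject(meta_rng, params, sex, group, age, sid,
                                      _subject_seed(children[i]))
            records.append(rec)
            specs.append(spec)
            i += 1
    return _assemble(records, specs, params, master_seed)


#: Experimental-design weight distributions (kg): birth weight and weight at
#: scan per (sex, group), used only for the young-adult MNR/CTR cohort.
_WEIGHTS = {
    ("female", "CTR"): {"birth": (0.87, 0.12), "scan": (12.72, 1.53)},
    ("female", "MNR"): {"birth": (0.78, 0.15), "scan": (13.90, 0.98)},
    ("male", "CTR"): {"birth": (0.90, 0.10), "scan": (17.91, 5.56)},
    ("male", "MNR"): {"birth": (0.83, 0.09), "scan": (20.77, 4.65)},
}


def generate_experiment_cohort(params: AgingModelParams,
                               n_per_cell=(5, 5, 7, 6),
                               age_range=(4.0, 7.0),
                               master_seed: int = 0) -> Cohort:
    """Generate the young-adult MNR/CTR experimental cohort.

    ``n_per_cell`` orders the cells (female CTR, female MNR, male CTR,
    male MNR); the default reproduces the experimental design's 5/5/7/6.
    MNR females carry the programmed GM->CSF atrophy offset.
    """
    cells = [("female", "CTR"), ("female", "MNR"), ("male", "CTR"), ("male", "MNR")]
    ss = np.random.SeedSequence(master_seed, spawn_key=(1,))
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    n_tot = int(sum(n_per_cell))
    children = ss.spawn(n_tot)

    records, specs = [], []
    i = 0
    for (sex, group), n_cell in zip(cells, n_per_cell):
        w = _WEIGHTS[(sex, group)]
        for k in range(int(n_cell)):
            age = meta_rng.uniform(*age_range)
            birth_w = max(0.3, meta_rng.normal(*w["birth"]))
            scan_w = max(5.0, meta_rng.normal(*w["scan"]))
            sid = f"{group}_{'F' if sex == 'female' else 'M'}{k + 1:02d}"
            rec, spec = _draw_subject(meta_rng, params, sex, group, age, sid,
                                      _subject_seed(children[i]),
                                      birth_w=round(birth_w, 3),
                                      scan_w=round(scan_w, 2))
            records.append(rec)
            specs.append(spec)
            i += 1
    return _assemble(records, specs, params, master_seed)


def noisy_gm_maps(cohort: Cohort, sd: float = None, seed: int = 0,
                  normalize_to_ml: float = 200.0) -> list:
    """Template-space GM maps with additive voxel noise, as 'preprocessed' inputs.

    Emulates the product of the imaging chain without re-running it: each
    subject's ground-truth GM probability map is affinely size-normalized to
    a common template brain volume (``normalize_to_ml``; isotropic scaling
    about the grid center, the synthetic analogue of registration into
    template space - unmodulated, so map values are preserved and only the
    geometry is normalized), then voxelwise Gaussian noise stands in for the
    residual variability of preprocessed maps.  ``sd`` defaults to the
    generator's calibrated ``gm_map_noise_sd``; values are left unclipped so
    the age signal stays exactly linear in the programmed trajectories.
    Pass ``normalize_to_ml=None`` to keep native-space geometry.
    """
    if sd is None:
        sd = cohort.params.gm_map_noise_sd
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    maps = []
    tivs = cohort.metadata["tiv_true_ml"].to_numpy(dtype=float)
    for g, tiv in zip(cohort.gm_truth_maps(), tivs):
        if normalize_to_ml is not None:
            factor = (normalize_to_ml / tiv) ** (1.0 / 3.0)
            center = (np.asarray(g.shape, dtype=float) - 1) / 2
            A = np.eye(3) / factor
            g = ndimage.affine_transform(g, A, offset=center - A @ center,
                                         order=1, mode="constant", cval=0.0)
        maps.append(g + rng.normal(0.0, sd, size=g.shape))
    return maps
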