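"""Synthetic digital-phantom cohort for time-encoded pCASL.

Stands in for an in-vivo test-retest study: a schematic brain phantom
(GM shell / WM core / CSF ventricles plus eight ellipsoidal subcortical
ROIs), a cohort of elderly subjects scanned twice per session on two
scanners, Hadamard-encoded 4D ASL series with calibration (M0) volumes, and
rigid-motion traces.  Every generator is a pure function of its seed.

The generator's defaults encode the acquisition conditions the analysis targets:
GM CBF ~70 and WM CBF ~28 ml/100 g/min, GM ATT ~1.4 s and WM ~1.5 s, 26
subjects (15 female) aged 56-84, two runs per session, a two-scanner design
with a +50 ms ATT offset on one scanner, and noise calibrated to a gray
matter temporal SNR of ~1.7 in the decoded perfusion-weighted series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import AcquisitionModel, subbolus_signals
from .scheme import EncodingScheme

__all__ = [
    "DigitalPhantom",
    "CohortEffects",
    "M0Set",
    "EncodedAcquisition",
    "ROI_LABELS",
    "generate_phantom",
    "generate_cohort",
    "apply_modifiers",
    "simulate_encoded_series",
    "simulate_m0",
    "simulate_motion",
    "calibrate_noise_sigma",
]

#: Integer codes of the ROI label volume.
ROI_LABELS = {
    "gray_matter": 1,
    "white_matter": 2,
    "left_hippocampus": 3,
    "right_hippocampus": 4,
    "left_amygdala": 5,
    "right_amygdala": 6,
    "left_caudate": 7,
    "right_caudate": 8,
    "left_accumbens": 9,
    "right_accumbens": 10,
}

#: Reference tissue perfusion: CBF (ml/100 g/min), ATT (s).
TISSUE_TRUTH = {
    "gray_matter": (70.0, 1.4),
    "white_matter": (28.0, 1.53),  # GM->WM transit lag of 0.13 s
    "left_hippocampus": (57.0, 1.15),
    "right_hippocampus": (56.0, 1.2),
    "left_amygdala": (46.5, 1.1),
    "right_amygdala": (46.0, 1.15),
    "left_caudate": (55.0, 1.1),
    "right_caudate": (52.5, 1.15),
    "left_accumbens": (72.5, 1.0),
    "right_accumbens": (60.0, 1.05),
}

#: Proton-density weights per tissue relative to GM, and the M0 signal scale.
M0_SCALE = 1000.0
_PD_WEIGHTS = {"gm": 1.0, "wm": 0.7, "csf": 1.2}

# subcortical ellipsoids: (name, center as fraction of the brain semi-axes,
# radii likewise); mirrored left/right in x
_SUBCORTICAL = [
    ("hippocampus", (0.38, -0.25, -0.15), (0.13, 0.17, 0.14)),
    ("amygdala", (0.36, 0.05, -0.22), (0.12, 0.12, 0.12)),
    ("caudate", (0.22, 0.25, 0.12), (0.11, 0.16, 0.13)),
    ("accumbens", (0.16, 0.33, -0.12), (0.09, 0.10, 0.10)),
]


@dataclass
class DigitalPhantom:
    """Voxelwise tissue fractions, ROI labels, and ground-truth maps."""

    dims: tuple
    voxel_mm: float
    pv_gm: np.ndarray
    pv_wm: np.ndarray
    pv_csf: np.ndarray
    roi_labels: np.ndarray
    truth_cbf: np.ndarray
    truth_att: np.ndarray
    seed: int

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine with isotropic voxels centered on the grid."""
        a = np.diag([self.voxel_mm] * 3 + [1.0])
        a[:3, 3] = -np.asarray(self.dims) * self.voxel_mm / 2.0
        return a

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.pv_gm + self.pv_wm + self.pv_csf) > 0

    def tissue_mask(self, which: str, threshold: float = 0.9) -> np.ndarray:
        pv = {"gm": self.pv_gm, "wm": self.pv_wm}[which]
        return pv > threshold

    def roi_mask(self, roi: str, pv_threshold: float = 0.9) -> np.ndarray:
        """Binary mask of a named ROI.

        GM/WM masks come from thresholding the tissue-fraction maps at
        ``pv_threshold`` and binarizing; subcortical ROIs come from the label
        volume (cortical GM excludes subcortical labels).
        """
        code = ROI_LABELS[roi]
        if roi == "gray_matter":
            return self.tissue_mask("gm", pv_threshold) & (
                (self.roi_labels <= 2)
            )
        if roi == "white_matter":
            return self.tissue_mask("wm", pv_threshold)
        return self.roi_labels == code


def _ellipsoid(coords, center, radii):
    x, y, z = coords
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2


def generate_phantom(
    dims=(32, 32, 16),
    voxel_mm: float = 3.3,
    seed: int = 0,
    tissue_truth: dict | None = None,
    voxel_cbf_sd: float = 5.0,
    voxel_att_sd: float = 0.05,
) -> DigitalPhantom:
    """Build the schematic brain phantom with ground-truth CBF/ATT maps.

    Concentric geometry in a normalized ellipsoidal radius ``r``: cortical
    GM shell (r in ~[0.68, 1]), WM core, CSF ventricles, and eight
    ellipsoidal deep-GM ROIs embedded in the core.  Tissue fractions ramp
    smoothly at interfaces so boundary voxels are genuinely mixed while the
    interiors are pure.  Truth maps are drawn per voxel around the per-ROI
    reference values and mixed by tissue fraction.
    """
    dims = tuple(int(d) for d in dims)
    if any(d < m for d, m in zip(dims, (8, 8, 4))):
        raise ValueError(f"dims {dims} too small; need at least (8, 8, 4)")
    rng = np.random.default_rng(seed)
    truth = dict(TISSUE_TRUTH)
    if tissue_truth:
        truth.update(tissue_truth)

    nx, ny, nz = dims
    # normalized coordinates in [-1, 1] per axis
    grids = np.meshgrid(
        *(np.linspace(-1, 1, n) for n in dims), indexing="ij"
    )
    r = np.sqrt(_ellipsoid(grids, (0, 0, 0), (0.95, 0.95, 0.9)))

    w = 0.10  # interface ramp half-width in normalized radius
    inside = np.clip((1.0 - r) / w, 0.0, 1.0)          # brain vs background
    gm_frac = np.clip((r - 0.68) / w, 0.0, 1.0)        # shell vs core
    pv_gm = inside * gm_frac
    pv_wm = inside * (1.0 - gm_frac)
    # CSF ventricles: two para-midline ellipsoids in the core
    vent = np.minimum(
        _ellipsoid(grids, (0.18, 0.1, 0.15), (0.14, 0.30, 0.18)),
        _ellipsoid(grids, (-0.18, 0.1, 0.15), (0.14, 0.30, 0.18)),
    )
    csf_frac = np.clip((1.0 - np.sqrt(vent)) / 0.25, 0.0, 1.0)
    pv_csf = pv_wm * csf_frac
    pv_wm = pv_wm * (1.0 - csf_frac)

    labels = np.zeros(dims, dtype=np.int16)
    labels[pv_wm > 0.9] = ROI_LABELS["white_matter"]
    labels[pv_gm > 0.9] = ROI_LABELS["gray_matter"]

    roi_value_maps = {}
    for name, (cx, cy, cz), radii in _SUBCORTICAL:
        for side, sign in (("left", -1), ("right", 1)):
            roi = f"{side}_{name}"
            mask = _ellipsoid(grids, (sign * cx, cy, cz), radii) <= 1.0
            if not mask.any():
                raise ValueError(
                    f"dims {dims} too small to place ROI {roi}"
                )
            # deep gray matter: overrides core tissue
            pv_gm[mask] = 1.0
            pv_wm[mask] = 0.0
            pv_csf[mask] = 0.0
            labels[mask] = ROI_LABELS[roi]
            roi_value_maps[roi] = mask

    # per-voxel tissue values around the reference means
    gm_cbf = rng.normal(truth["gray_matter"][0], voxel_cbf_sd, dims)
    wm_cbf = rng.normal(truth["white_matter"][0], voxel_cbf_sd * 0.6, dims)
    gm_att = rng.normal(truth["gray_matter"][1], voxel_att_sd, dims)
    wm_att = rng.normal(truth["white_matter"][1], voxel_att_sd, dims)
    for roi, mask in roi_value_maps.items():
        cbf_m, att_m = truth[roi]
        gm_cbf[mask] = rng.normal(cbf_m, voxel_cbf_sd, int(mask.sum()))
        gm_att[mask] = rng.normal(att_m, voxel_att_sd, int(mask.sum()))

    tissue = pv_gm + pv_wm
    truth_cbf = np.clip(pv_gm * gm_cbf + pv_wm * wm_cbf, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        truth_att = np.where(
            tissue > 0,
            (pv_gm * gm_att + pv_wm * wm_att) / np.where(tissue > 0, tissue, 1),
            0.0,
        )
    truth_att = np.clip(truth_att, 0.0, None)

    return DigitalPhantom(
        dims=dims, voxel_mm=float(voxel_mm),
        pv_gm=pv_gm, pv_wm=pv_wm, pv_csf=pv_csf,
        roi_labels=labels, truth_cbf=truth_cbf, truth_att=truth_att,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Cohort: subjects, sessions, effect sizes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortEffects:
    """Effect sizes and variance components injected by the generator.

    CBF effects act multiplicatively (stored as factors relative to the
    reference maps), ATT effects additively in seconds.  Age effects are
    centered on the cohort mean age.  The subject-level CBF and ATT
    residuals are drawn jointly with correlation ``cbf_att_coupling`` so the
    cohort exhibits the negative CBF-ATT association seen in elderly
    cohorts (longer transit times with lower flow).
    """

    age_mean: float = 68.3
    age_sd: float = 6.3
    age_range: tuple = (56.0, 84.0)
    female_fraction: float = 15 / 26

    cbf_reference: float = 70.0  # GM CBF the multiplicative effects refer to
    cbf_age_slope: float = -0.35  # ml/100 g/min per year
    cbf_female_shift: float = 6.0  # ml/100 g/min
    cbf_subject_sd: float = 0.10  # lognormal sigma
    cbf_session_sd: float = 0.02
    cbf_run_sd: float = 0.035

    att_age_slope: float = 0.010  # s per year
    att_female_shift: float = -0.08  # s
    att_subject_sd: float = 0.05  # s
    att_session_sd: float = 0.020
    att_run_sd: float = 0.015
    scanner_att_offset: float = 0.05  # s, added on the "skyra" system

    cbf_att_coupling: float = -0.5  # subject-level residual correlation

    def __post_init__(self):
        if not -1.0 <= self.cbf_att_coupling <= 1.0:
            raise ValueError("cbf_att_coupling must be a correlation in [-1, 1]")
        for name in ("cbf_subject_sd", "cbf_session_sd", "cbf_run_sd",
                     "att_subject_sd", "att_session_sd", "att_run_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")


#: scanner assignment per session
SESSION_SCANNERS = {1: "skyra", 2: "mmr"}


def generate_cohort(
    n_subjects: int = 26,
    seed: int = 0,
    effects: CohortEffects | None = None,
    n_sessions: int = 2,
    n_runs: int = 2,
):
    """Sample the subject table and per-acquisition truth modifiers.

    Returns ``(subjects, modifiers)``: ``subjects`` has one row per subject
    (id, age, gender); ``modifiers`` one row per subject x session x run with
    the scanner id, the total multiplicative CBF factor and additive ATT
    shift (seconds), and their per-level components so effect recovery can
    be tested against the injected truth.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    eff = effects or CohortEffects()
    rng = np.random.default_rng(seed)

    ages = np.clip(
        rng.normal(eff.age_mean, eff.age_sd, n_subjects), *eff.age_range
    )
    n_female = int(round(n_subjects * eff.female_fraction))
    female = np.zeros(n_subjects, dtype=bool)
    female[rng.permutation(n_subjects)[:n_female]] = True

    # subject-level coupled residuals
    cov = np.array([[1.0, eff.cbf_att_coupling], [eff.cbf_att_coupling, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=n_subjects)
    cbf_subj = np.exp(eff.cbf_subject_sd * z[:, 0])
    att_subj = eff.att_subject_sd * z[:, 1]

    subjects = pd.DataFrame({
        "subject": [f"sub-{i + 1:02d}" for i in range(n_subjects)],
        "age": np.round(ages, 1),
        "gender": np.where(female, "female", "male"),
    })

    inter_session_days = np.clip(rng.normal(78, 17.6, n_subjects), 20, None)

    rows = []
    for i in range(n_subjects):
        centered_age = ages[i] - eff.age_mean
        cbf_fixed = 1.0 + (
            eff.cbf_age_slope * centered_age
            + eff.cbf_female_shift * female[i]
        ) / eff.cbf_reference
        att_fixed = eff.att_age_slope * centered_age \
            + eff.att_female_shift * female[i]
        for ses in range(1, n_sessions + 1):
            scanner = SESSION_SCANNERS.get(ses, "mmr")
            cbf_ses = np.exp(eff.cbf_session_sd * rng.standard_normal())
            att_ses = eff.att_session_sd * rng.standard_normal()
            att_scan = eff.scanner_att_offset if scanner == "skyra" else 0.0
            for run in range(1, n_runs + 1):
                cbf_run = np.exp(eff.cbf_run_sd * rng.standard_normal())
                att_run = eff.att_run_sd * rng.standard_normal()
                rows.append({
                    "subject": subjects.subject[i],
                    "age": subjects.age[i],
                    "gender": subjects.gender[i],
                    "session": ses,
                    "run": run,
                    "scanner": scanner,
                    "day_offset": 0 if ses == 1 else round(
                        float(inter_session_days[i])
                    ),
                    "cbf_factor_fixed": cbf_fixed,
                    "cbf_factor_subject": cbf_subj[i],
                    "cbf_factor_session": cbf_ses,
                    "cbf_factor_run": cbf_run,
                    "att_shift_fixed": att_fixed,
                    "att_shift_subject": att_subj[i],
                    "att_shift_session": att_ses,
                    "att_shift_run": att_run,
                    "att_shift_scanner": att_scan,
                })
    modifiers = pd.DataFrame(rows)
    modifiers["cbf_factor"] = (
        modifiers.cbf_factor_fixed * modifiers.cbf_factor_subject
        * modifiers.cbf_factor_session * modifiers.cbf_factor_run
    )
    modifiers["att_shift"] = (
        modifiers.att_shift_fixed + modifiers.att_shift_subject
        + modifiers.att_shift_session + modifiers.att_shift_run
        + modifiers.att_shift_scanner
    )
    return subjects, modifiers


def apply_modifiers(phantom: DigitalPhantom, cbf_factor: float,
                    att_shift: float):
    """Per-acquisition truth maps: scale CBF, shift ATT (clipped to stay
    physiological and inside the fitter's search box)."""
    cbf = phantom.truth_cbf * float(cbf_factor)
    att = np.where(
        phantom.truth_att > 0,
        np.clip(phantom.truth_att + float(att_shift), 0.4, 2.6),
        0.0,
    )
    return cbf, att


# ---------------------------------------------------------------------------
# Encoded series, M0, motion
# ---------------------------------------------------------------------------


@dataclass
class M0Set:
    """Proton-density calibration volumes: 1 non-steady-state dummy followed
    by two anterior-posterior and two posterior-anterior acquisitions."""

    volumes: np.ndarray  # (x, y, z, 5)
    labels: tuple = ("dummy", "ap", "ap", "pa", "pa")
    tr_s: float = 6.0

    @property
    def dummy_index(self) -> int:
        return self.labels.index("dummy")


@dataclass
class EncodedAcquisition:
    """Simulated (or loaded) Hadamard-encoded 4D ASL acquisition."""

    signal: np.ndarray  # (x, y, z, n_encodings * n_cycles), cycle-major
    scheme: EncodingScheme
    n_cycles: int
    m0: M0Set
    motion_trace: np.ndarray  # (n_reps, 6): rot x/y/z deg, trans x/y/z mm
    noise_sigma: float
    seed: int


def m0_map(phantom: DigitalPhantom) -> np.ndarray:
    """Noise-free equilibrium-magnetization map from the tissue fractions."""
    return M0_SCALE * (
        _PD_WEIGHTS["gm"] * phantom.pv_gm
        + _PD_WEIGHTS["wm"] * phantom.pv_wm
        + _PD_WEIGHTS["csf"] * phantom.pv_csf
    )


def _noiseless_subbolus_signals(phantom, scheme, model, cbf=None, att=None):
    """Voxelwise decoded-signal truth, shape (x, y, z, n_blocks)."""
    cbf = phantom.truth_cbf if cbf is None else cbf
    att = phantom.truth_att if att is None else att
    safe_att = np.where(att > 0, att, 1.0)
    dm = subbolus_signals(scheme, cbf, safe_att, model)
    dm *= (m0_map(phantom) / model.lambda_partition)[..., None]
    dm[att <= 0] = 0.0
    return dm


def calibrate_noise_sigma(
    phantom: DigitalPhantom,
    scheme: EncodingScheme,
    model: AcquisitionModel | None = None,
    target_tsnr: float = 1.72,
) -> float:
    """Raw-volume noise SD hitting a target decoded GM temporal SNR.

    The decoded per-voxel, per-cycle noise of a pruned Hadamard decode with
    ``2/n_encodings`` normalization is ``sigma_raw / sqrt(2)`` (for 8
    encodings), so the raw sigma giving a mean GM tSNR of ``target_tsnr``
    across sub-bolus PLDs is ``sqrt(2) * mean_signal / target_tsnr``.
    """
    model = model or AcquisitionModel()
    dm = _noiseless_subbolus_signals(phantom, scheme, model)
    gm = phantom.tissue_mask("gm", 0.9)
    mean_signal = float(dm[gm].mean())  # over GM voxels and all PLDs
    n_enc = scheme.n_encodings
    decode_gain = 2.0 / np.sqrt(n_enc)  # noise SD factor of the decode
    return mean_signal / target_tsnr / decode_gain


def simulate_encoded_series(
    phantom: DigitalPhantom,
    scheme: EncodingScheme,
    model: AcquisitionModel | None = None,
    n_cycles: int = 7,
    noise_sigma: float | str = "auto",
    seed: int = 0,
    static_tissue_fraction: float = 0.10,
    cbf: np.ndarray | None = None,
    att: np.ndarray | None = None,
    scanner: str = "skyra",
) -> EncodedAcquisition:
    """Forward-simulate the Hadamard-encoded 4D series plus M0 and motion.

    Per voxel and encoding row ``r`` the signal is the background-suppressed
    static tissue term plus ``sum_j matrix[r, j] * dM_j / 2`` with ``dM_j``
    from the general kinetic model on the voxel's truth state, plus i.i.d.
    Gaussian noise.  Volumes are ordered cycle-major (all encodings of cycle
    1, then cycle 2, ...).  ``noise_sigma="auto"`` calibrates to a decoded
    GM tSNR of ~1.7.
    """
    model = model or AcquisitionModel()
    if isinstance(noise_sigma, str):
        if noise_sigma != "auto":
            raise ValueError("noise_sigma must be a float or 'auto'")
        noise_sigma = calibrate_noise_sigma(phantom, scheme, model)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)

    dm = _noiseless_subbolus_signals(phantom, scheme, model, cbf, att)
    static = static_tissue_fraction * m0_map(phantom)
    matrix = np.asarray(scheme.encoding_matrix, dtype=float)
    encoded = static[..., None] + 0.5 * dm @ matrix.T  # (x, y, z, n_enc)

    n_enc = scheme.n_encodings
    n_reps = n_enc * n_cycles
    signal = np.repeat(encoded[..., None, :], n_cycles, axis=-2)
    signal = signal.reshape(*phantom.dims, n_reps)
    if noise_sigma > 0:
        signal = signal + rng.normal(0.0, noise_sigma, signal.shape)

    m0 = simulate_m0(phantom, seed=int(rng.integers(2**31)))
    motion = simulate_motion(n_reps, scanner=scanner,
                             seed=int(rng.integers(2**31)))
    return EncodedAcquisition(
        signal=signal, scheme=scheme, n_cycles=n_cycles, m0=m0,
        motion_trace=motion, noise_sigma=float(noise_sigma), seed=int(seed),
    )


def simulate_m0(phantom: DigitalPhantom, tr_s: float = 6.0,
                seed: int = 0, noise_sigma: float = 0.01 * M0_SCALE,
                dummy_gain: float = 1.35) -> M0Set:
    """Five calibration volumes: inflated non-steady-state dummy, then two
    AP and two PA acquisitions (no distortion simulated, so AP and PA agree
    in expectation)."""
    rng = np.random.default_rng(seed)
    base = m0_map(phantom)
    vols = np.stack(
        [base * (dummy_gain if k == 0 else 1.0)
         + rng.normal(0.0, noise_sigma, base.shape) for k in range(5)],
        axis=-1,
    )
    return M0Set(volumes=vols, tr_s=float(tr_s))


#: per-scanner mean and SD of the subject-level mean |y-translation| (mm)
MOTION_Y_DISTRIBUTIONS = {"skyra": (0.33, 0.13), "mmr": (0.49, 0.22)}
MOTION_CAP_MM = 2.0
MOTION_CAP_DEG = 2.0


def simulate_motion(n_repetitions: int, scanner: str = "skyra",
                    seed: int = 0) -> np.ndarray:
    """Rigid-body motion trace: random walk plus drift per parameter.

    Columns: rotations x/y/z (degrees), translations x/y/z (mm).  The
    y-translation channel is scaled so its mean |value| is drawn from the
    scanner-specific distribution (Skyra subjects move less than mMR
    Biograph subjects); all parameters are capped at 2 mm / 2 degrees.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    try:
        mu, sd = MOTION_Y_DISTRIBUTIONS[scanner]
    except KeyError:
        raise ValueError(
            f"unknown scanner {scanner!r}; expected one of "
            f"{sorted(MOTION_Y_DISTRIBUTIONS)}"
        ) from None
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 0.03, (n_repetitions, 6))
    drift = rng.normal(0.0, 0.15, 6) / max(n_repetitions, 1)
    trace = np.cumsum(steps + drift, axis=0)
    target_y = max(rng.normal(mu, sd), 0.02)
    mean_abs_y = np.abs(trace[:, 4]).mean()
    if mean_abs_y > 0:
        trace[:, 4] *= target_y / mean_abs_y
    trace[:, :3] = np.clip(trace[:, :3], -MOTION_CAP_DEG, MOTION_CAP_DEG)
    trace[:, 3:] = np.clip(trace[:, 3:], -MOTION_CAP_MM, MOTION_CAP_MM)
    return trace
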