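"""End-to-end synthetic replication: design, simulate, quantify, analyze.

``replicate`` runs the whole study in memory — scheme construction, digital
phantom, two-scanner / two-session / two-run cohort, encoded-series
simulation, decoding, voxelwise CBF/ATT fitting, PVC, ROI summaries, and
the reliability/reproducibility statistics.  ``run_replication`` wraps it
with file outputs (NIfTI volumes, TSV tables, a JSON manifest) so every
stage can be re-run from persisted intermediates.

Everything is a pure function of the configuration: stage seeds are derived
deterministically from the master seed, so identical configs give identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortEffects,
    apply_modifiers,
    generate_cohort,
    generate_phantom,
    simulate_encoded_series,
)
from .kinetics import AcquisitionModel
from .perfusion import (
    FitPriors,
    apply_pvc,
    compute_tsnr,
    decode,
    fit_voxelwise,
    prepare_m0,
    roi_means,
)
from .scheme import EncodingScheme
from . import stats as st

__all__ = ["ReplicationConfig", "ReplicationResult", "replicate",
           "run_replication", "stage_seed"]


def stage_seed(master_seed: int, *parts) -> int:
    """Deterministic per-stage seed below 2**31, independent of hash
    randomization."""
    key = ":".join([str(master_seed), *map(str, parts)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class ReplicationConfig:
    """All knobs of the synthetic replication (round-trips through YAML)."""

    # encoding scheme
    base_pld_s: float = 0.5
    n_blocks: int = 7
    t1_blood_s: float = 1.65
    alpha: float = 0.85
    use_reference_durations: bool = True  # printed 7-block train
    total_label_duration_s: float = 3.5   # used when designing instead

    # phantom
    dims: tuple = (32, 32, 16)
    voxel_mm: float = 3.3

    # cohort
    n_subjects: int = 26
    n_sessions: int = 2
    n_runs: int = 2
    effects: CohortEffects = field(default_factory=CohortEffects)

    # acquisition + kinetic model
    n_cycles: int = 7
    noise_sigma: float | str = "auto"
    static_tissue_fraction: float = 0.10
    t1_tissue_s: float = 1.3
    lambda_ml_per_g: float = 0.9

    # fitting / PVC / ROIs
    att_prior_mean_s: float = 1.3
    att_prior_sd_s: float = 0.3
    att_grid_step_s: float = 0.002
    pv_threshold: float = 0.9
    do_pvc: bool = True
    pvc_kernel: tuple = (3, 3, 3)
    min_gm_cbf: float = 20.0

    master_seed: int = 7

    def scheme(self) -> EncodingScheme:
        if self.use_reference_durations and self.n_blocks == 7 \
                and self.base_pld_s == 0.5:
            return EncodingScheme.reference_seven_block(self.alpha)
        return EncodingScheme.design(
            self.base_pld_s, self.n_blocks, self.t1_blood_s,
            anchor_duration=None, total_duration=self.total_label_duration_s,
            alpha=self.alpha,
        )

    def model(self) -> AcquisitionModel:
        return AcquisitionModel(
            t1_blood=self.t1_blood_s, t1_tissue=self.t1_tissue_s,
            lambda_partition=self.lambda_ml_per_g, alpha=self.alpha,
        )

    def priors(self) -> FitPriors:
        return FitPriors(att_mean=self.att_prior_mean_s,
                         att_sd=self.att_prior_sd_s)

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = dataclasses.asdict(self)
        doc["dims"] = list(self.dims)
        doc["pvc_kernel"] = list(self.pvc_kernel)
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ReplicationConfig":
        p = Path(str(source))
        doc = yaml.safe_load(p.read_text() if p.is_file() else source)
        if not isinstance(doc, dict):
            raise ValueError("config must be a YAML mapping")
        if "effects" in doc and isinstance(doc["effects"], dict):
            eff = dict(doc["effects"])
            if "age_range" in eff:
                eff["age_range"] = tuple(eff["age_range"])
            doc["effects"] = CohortEffects(**eff)
        for key in ("dims", "pvc_kernel"):
            if key in doc:
                doc[key] = tuple(doc[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class ReplicationResult:
    """In-memory outputs of one full synthetic replication."""

    config: ReplicationConfig
    scheme: EncodingScheme
    phantom: object
    subjects: pd.DataFrame
    modifiers: pd.DataFrame
    roi_table: pd.DataFrame
    acquisitions: pd.DataFrame  # per-acquisition tSNR / motion summary
    reliability: pd.DataFrame
    reproducibility: pd.DataFrame
    glm: pd.DataFrame
    correlations: pd.DataFrame
    contrasts: pd.DataFrame
    excluded_subjects: list


def _quantify_one(phantom, scheme, model, priors, cfg, cbf, att, scanner,
                  seed):
    acq = simulate_encoded_series(
        phantom, scheme, model, n_cycles=cfg.n_cycles,
        noise_sigma=cfg.noise_sigma, seed=seed,
        static_tissue_fraction=cfg.static_tissue_fraction,
        cbf=cbf, att=att, scanner=scanner,
    )
    dec = decode(acq)
    m0 = prepare_m0(acq.m0)
    mask = (phantom.pv_gm + phantom.pv_wm) > 0.05
    maps = fit_voxelwise(dec, m0, model, priors, mask,
                         att_step=cfg.att_grid_step_s)
    if cfg.do_pvc:
        maps = apply_pvc(maps, phantom.pv_gm, phantom.pv_wm, cfg.pvc_kernel)
    gm = phantom.tissue_mask("gm", cfg.pv_threshold)
    try:
        tsnr = compute_tsnr(dec, gm)
    except ValueError:
        tsnr = np.nan  # noiseless configuration
    table = roi_means(maps, phantom, cfg.pv_threshold, use_pvc=cfg.do_pvc)
    mean_abs_y = float(np.abs(acq.motion_trace[:, 4]).mean())
    return maps, table, tsnr, mean_abs_y


def _compute_stats(cfg, roi_table, result_rows):
    """Reliability / reproducibility / GLM / correlation tables."""
    kept, excluded = st.exclude_unphysiological(roi_table, cfg.min_gm_cbf)

    metrics = {"cbf": "cbf_ml_100g_min", "att": "att_s"}
    rel_rows, rep_rows, glm_rows, cor_rows = [], [], [], []
    for roi in kept.roi.unique():
        sub = kept[kept.roi == roi]
        wide = sub.pivot_table(index=["subject", "scanner"], columns="run",
                               values=list(metrics.values()))
        # within-session (two-run) reliability per scanner
        for scanner, grp in wide.groupby(level="scanner"):
            for metric, col in metrics.items():
                pair = grp[col].dropna()
                if len(pair) >= 2 and pair.shape[1] >= 2:
                    rel_rows.append({
                        "roi": roi, "scanner": scanner, "metric": metric,
                        "wscv_percent": st.wscv(pair[1], pair[2]),
                        "n": len(pair),
                    })
        # between-scanner reproducibility of run means
        run_mean = sub.groupby(["subject", "scanner"])[
            list(metrics.values())].mean().reset_index()
        scanners = sorted(run_mean.scanner.unique())
        if len(scanners) == 2:
            for metric, col in metrics.items():
                piv = run_mean.pivot(index="subject", columns="scanner",
                                     values=col).dropna()
                if len(piv) >= 3:
                    x = piv[scanners[0]].to_numpy()
                    y = piv[scanners[1]].to_numpy()
                    icc = st.icc_two_way(np.column_stack([x, y]))
                    normal = True
                    try:
                        normal = (st.normality_gate(x)[0]
                                  and st.normality_gate(y)[0])
                    except ValueError:
                        normal = False
                    rep_rows.append({
                        "roi": roi, "metric": metric,
                        "wscv_percent": st.wscv(x, y),
                        "icc": icc.icc, "icc_ci_low": icc.ci_low,
                        "icc_ci_high": icc.ci_high, "n": icc.n,
                        "normality_pass": normal,
                    })
        # scanner/age/gender GLM on per-session run means
        glm_data = run_mean.merge(
            kept[["subject", "age", "gender"]].drop_duplicates(), on="subject"
        )
        if glm_data.scanner.nunique() == 2 and len(glm_data) >= 8:
            for metric, col in metrics.items():
                try:
                    tab = st.factor_effect(
                        glm_data.rename(columns={col: "response"}),
                        "response",
                    )
                except ValueError:
                    continue
                for fac, row in tab.iterrows():
                    glm_rows.append({
                        "roi": roi, "metric": metric, "factor": fac,
                        "F": row.F, "p": row.p,
                    })
        # per scanner x run ATT-CBF correlations, with/without covariates
        for (scanner, run), grp in sub.groupby(["scanner", "run"]):
            if len(grp) < 6:
                continue
            plain = st.att_cbf_correlation(grp.att_s, grp.cbf_ml_100g_min)
            adj = st.att_cbf_correlation(
                grp.att_s, grp.cbf_ml_100g_min,
                grp[["age", "gender"]].reset_index(drop=True),
            )
            cor_rows.append({
                "roi": roi, "scanner": scanner, "run": run,
                "r": plain.r, "p": plain.p,
                "r_partial": adj.r_partial, "p_partial": adj.p_partial,
                "n": plain.n,
            })

    contrasts = st.derived_contrasts(kept)
    return (
        pd.DataFrame(rel_rows), pd.DataFrame(rep_rows),
        pd.DataFrame(glm_rows), pd.DataFrame(cor_rows),
        contrasts, excluded,
    )


def replicate(config: ReplicationConfig | None = None,
              master_seed: int | None = None,
              map_callback=None) -> ReplicationResult:
    """Run the full synthetic two-scanner replication in memory.

    ``map_callback(maps, row)`` is invoked with each acquisition's fitted
    ``PerfusionMaps`` (used by the file pipeline to persist them without
    refitting).
    """
    cfg = config or ReplicationConfig()
    if master_seed is not None:
        cfg = dataclasses.replace(cfg, master_seed=int(master_seed))
    scheme = cfg.scheme()
    model = cfg.model()
    priors = cfg.priors()
    phantom = generate_phantom(cfg.dims, cfg.voxel_mm,
                               seed=stage_seed(cfg.master_seed, "phantom"))
    subjects, modifiers = generate_cohort(
        cfg.n_subjects, stage_seed(cfg.master_seed, "cohort"), cfg.effects,
        cfg.n_sessions, cfg.n_runs,
    )

    roi_rows, acq_rows = [], []
    for row in modifiers.itertuples(index=False):
        cbf, att = apply_modifiers(phantom, row.cbf_factor, row.att_shift)
        seed = stage_seed(cfg.master_seed, "acq", row.subject, row.session,
                          row.run)
        maps, table, tsnr, mean_abs_y = _quantify_one(
            phantom, scheme, model, priors, cfg, cbf, att, row.scanner, seed
        )
        if map_callback is not None:
            map_callback(maps, row)
        table = table.assign(
            subject=row.subject, age=row.age, gender=row.gender,
            session=row.session, run=row.run, scanner=row.scanner,
        )
        roi_rows.append(table)
        acq_rows.append({
            "subject": row.subject, "session": row.session, "run": row.run,
            "scanner": row.scanner, "tsnr_gm": tsnr,
            "mean_abs_y_translation_mm": mean_abs_y,
        })
    roi_table = pd.concat(roi_rows, ignore_index=True)
    acquisitions = pd.DataFrame(acq_rows)

    rel, rep, glm, cor, contrasts, excluded = _compute_stats(
        cfg, roi_table, acq_rows
    )
    return ReplicationResult(
        config=cfg, scheme=scheme, phantom=phantom, subjects=subjects,
        modifiers=modifiers, roi_table=roi_table, acquisitions=acquisitions,
        reliability=rel, reproducibility=rep, glm=glm, correlations=cor,
        contrasts=contrasts, excluded_subjects=excluded,
    )


def _save_nifti(path, data, affine):
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def run_replication(config: ReplicationConfig | None = None,
                    outdir="results", write_maps: bool = True) -> Path:
    """File-based replication: writes scheme, phantom, cohort, ROI table,
    statistics tables, and a manifest with seeds and per-stage wall times.

    Output layout::

        outdir/
          scheme.yaml  config.yaml  manifest.json
          phantom/*.nii.gz
          cohort.tsv  roi_table.tsv  acquisitions.tsv
          maps/sub-XX_ses-Y_run-Z_{cbf,att}.nii.gz   (if write_maps)
          stats/{reliability,reproducibility,glm,correlations,contrasts}.tsv
    """
    cfg = config or ReplicationConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": __version__,
                "master_seed": cfg.master_seed, "stages": {}}
    t0 = time.perf_counter()

    mapdir = out / "maps"
    map_callback = None
    if write_maps:
        mapdir.mkdir(exist_ok=True)

        def map_callback(maps, row):
            stem = f"{row.subject}_ses-{row.session}_run-{row.run}"
            affine = cfg_phantom_affine()
            _save_nifti(mapdir / f"{stem}_cbf.nii.gz", maps.cbf, affine)
            _save_nifti(mapdir / f"{stem}_att.nii.gz", maps.att, affine)

        def cfg_phantom_affine():
            a = np.diag([cfg.voxel_mm] * 3 + [1.0])
            a[:3, 3] = -np.asarray(cfg.dims) * cfg.voxel_mm / 2.0
            return a

    result = replicate(cfg, map_callback=map_callback)
    manifest["stages"]["replicate"] = round(time.perf_counter() - t0, 3)

    cfg.to_yaml(out / "config.yaml")
    result.scheme.to_yaml(out / "scheme.yaml")

    ph = result.phantom
    phdir = out / "phantom"
    phdir.mkdir(exist_ok=True)
    for name, vol in [("pv_gm", ph.pv_gm), ("pv_wm", ph.pv_wm),
                      ("pv_csf", ph.pv_csf), ("roi_labels", ph.roi_labels),
                      ("truth_cbf", ph.truth_cbf), ("truth_att", ph.truth_att)]:
        _save_nifti(phdir / f"{name}.nii.gz", vol, ph.affine)

    result.subjects.merge(
        result.modifiers[["subject", "session", "run", "scanner",
                          "day_offset"]], on="subject",
    ).to_csv(out / "cohort.tsv", sep="\t", index=False)
    result.roi_table.to_csv(out / "roi_table.tsv", sep="\t", index=False)
    result.acquisitions.to_csv(out / "acquisitions.tsv", sep="\t", index=False)

    statsdir = out / "stats"
    statsdir.mkdir(exist_ok=True)
    for name, df in [("reliability", result.reliability),
                     ("reproducibility", result.reproducibility),
                     ("glm", result.glm),
                     ("correlations", result.correlations),
                     ("contrasts", result.contrasts)]:
        df.to_csv(statsdir / f"{name}.tsv", sep="\t", index=False)

    summary = {
        "excluded_subjects": result.excluded_subjects,
        "mean_tsnr_gm": float(np.nanmean(result.acquisitions.tsnr_gm)),
        "n_acquisitions": int(len(result.acquisitions)),
    }
    (statsdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
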