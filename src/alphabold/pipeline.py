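"""Orchestration: simulate -> per-subject first level -> group level.

A :class:`StudyConfig` carries every stage parameter (defaulting to the
recording and analysis settings of the study design: 250 Hz decimation,
sliding-window AAS over 21 epochs, 0.5-70 Hz band with a 50 Hz notch, three
alpha bands, 6 dropped volumes, 8 mm smoothing, 128 s high-pass, p < 0.01
with cluster extent >= 50 inside a gray-matter mask thresholded at 0.3).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bandpower, eeg, fmri, glm, group, regressors, synth
from .bandpower import ALPHA_BANDS, Band
from .synth import SimConfig, Subject


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name and subject id."""


@dataclass
class StudyConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    bands: tuple[Band, ...] = ALPHA_BANDS
    eeg_target_fs: float = 250.0
    aas_n_avg: int = 21
    bcg_n_avg: int = 21
    bcg_delay: float = 0.21
    bcg_template_len: float = 0.7
    hp: float = 0.5
    lp: float = 70.0
    notch: float = 50.0
    do_ica: bool = True
    do_bcg: bool = True
    ica_fit_stride: int = 4
    drop_k: int = 6
    fwhm_mm: float = 8.0
    highpass_cutoff_s: float = 128.0
    gm_thresh: float = 0.3
    p_thresh: float = 0.01
    cluster_k: int = 50
    connectivity: int = 18
    covariates: tuple[str, ...] = ("age", "gender", "education")
    hippo_covariate: str = "hippo_norm"
    seed: int = 0


@dataclass
class FirstLevelResult:
    subject_id: str
    group: str
    beta_maps: dict  # band name -> 3D alpha-beta map
    t_pos: dict  # band name -> StatMap
    t_neg: dict  # band name -> StatMap
    relative_power: dict  # band name -> float
    df: int
    report: dict


def _stage(name: str, subject_id: str):
    """Context that rewraps stage errors with stage and subject identity."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(
                    f"stage {name} failed for subject {subject_id}: {exc}"
                ) from exc
            return False

    return _Ctx()


def preprocess_eeg(subject: Subject, config: StudyConfig):
    """EEG cleaning chain; returns (pooled series, fs, artifact mask, report)."""
    sid = subject.subject_id
    report: dict = {}
    with _stage("decimate", sid):
        rec = eeg.decimate(subject.eeg, config.eeg_target_fs)
    with _stage("aas_subtract", sid):
        onsets = eeg.epoch_onsets_from_markers(rec, synth.SCANNER_MARKER)
        # epochs must fit: the last volume window may exceed the recording
        tr = config.sim.tr
        usable = onsets[onsets + tr <= rec.duration + 1e-9]
        rec = eeg.aas_subtract(rec, usable, tr, config.aas_n_avg)
        report["n_gradient_epochs"] = len(usable)
    if config.do_bcg:
        with _stage("bcg_subtract", sid):
            ecg = rec.get_channel(eeg.ECG_LABEL)
            r_peaks = eeg.detect_r_peaks(ecg, rec.fs)
            report["n_r_peaks"] = len(r_peaks)
            rec = eeg.bcg_subtract(rec, r_peaks, config.bcg_delay,
                                   config.bcg_template_len, config.bcg_n_avg)
    with _stage("filter_eeg", sid):
        rec = eeg.filter_eeg(rec, config.hp, config.lp, config.notch)
    if config.do_ica:
        with _stage("ica_autoclean", sid):
            rec = eeg.ica_autoclean(rec, seed=config.seed,
                                    fit_stride=config.ica_fit_stride)
            report["ica_removed"] = rec.history[-1].get("removed", [])
    with _stage("rereference", sid):
        rec = eeg.rereference_common_average(rec)
    with _stage("pool_occipital", sid):
        pooled = eeg.pool_occipital(rec)
    with _stage("mark_artifacts", sid):
        mask = eeg.mark_artifacts(pooled, rec.fs)
        report["n_artifact_intervals"] = len(mask.intervals)
    return pooled, rec.fs, mask, report


def run_first_level(subject: Subject, config: StudyConfig) -> FirstLevelResult:
    """EEG preprocessing, band power, regressors, fMRI prep and GLM for one
    subject; returns per-band alpha beta maps and signed t maps."""
    sid = subject.subject_id
    pooled, fs, artifact_mask, report = preprocess_eeg(subject, config)

    with _stage("fmri_prep", sid):
        bold = fmri.drop_initial_volumes(subject.bold, config.drop_k)
        bold = fmri.gaussian_smooth(bold, config.fwhm_mm)
        bold = fmri.highpass_time(bold, cutoff_s=config.highpass_cutoff_s,
                                  tr=bold.tr)

    onsets_all = subject.bold.volume_onsets
    hrf = regressors.canonical_hrf()
    with _stage("artifact_regressor", sid):
        art_reg = regressors.build_artifact_regressor(
            artifact_mask, onsets_all, config.sim.tr, config.drop_k)
        art_vals = art_reg.values
        if not np.allclose(art_vals, 0):
            art_vals = fmri.highpass_time(art_vals, tr=config.sim.tr,
                                          cutoff_s=config.highpass_cutoff_s)
        art_reg = regressors.Regressor(values=art_vals, label="artifact",
                                       volume_onsets=art_reg.volume_onsets)

    beta_maps, t_pos, t_neg, rel_power = {}, {}, {}, {}
    df = 0
    for band in config.bands:
        with _stage(f"bandpower[{band.name}]", sid):
            power, edge_valid = bandpower.complex_demodulate(pooled, fs, band)
            ps = bandpower.segment_power(power, fs, band, mask=artifact_mask,
                                         edge_valid=edge_valid)
            rel_power[band.name] = bandpower.fft_relative_power(pooled, fs, band)
        with _stage(f"alpha_regressor[{band.name}]", sid):
            alpha_reg = regressors.build_alpha_regressor(
                ps, hrf, onsets_all, config.drop_k)
            filt_vals = fmri.highpass_time(alpha_reg.values, tr=config.sim.tr,
                                           cutoff_s=config.highpass_cutoff_s)
            alpha_reg = regressors.Regressor(values=filt_vals,
                                             label=alpha_reg.label,
                                             volume_onsets=alpha_reg.volume_onsets)
        with _stage(f"glm[{band.name}]", sid):
            X = glm.build_design(alpha_reg, art_reg)
            gm = np.ones(bold.grid_shape, dtype=bool)
            fit = glm.fit_glm(bold, X, mask=gm)
            df = fit.df
            beta_maps[band.name] = fit.beta_map("alpha")
            c = np.zeros(len(X.labels))
            c[X.labels.index("alpha")] = 1.0
            t_pos[band.name] = glm.t_contrast(fit, c, label="alpha>0",
                                              band=band.name)
            neg = glm.t_contrast(fit, -c, label="alpha<0", band=band.name)
            t_neg[band.name] = neg
    report["df"] = df
    return FirstLevelResult(subject_id=sid, group=subject.group,
                            beta_maps=beta_maps, t_pos=t_pos, t_neg=t_neg,
                            relative_power=rel_power, df=df, report=report)


# ---------------------------------------------------------------------------
# group level


def _covariate_matrix(cov_table: pd.DataFrame, subject_ids: list[str],
                      names: tuple[str, ...]) -> np.ndarray | None:
    if not names:
        return None
    sub = cov_table.set_index("subject_id").loc[list(subject_ids)]
    return sub[list(names)].to_numpy(dtype=float)


def run_group(
    first_levels: list[FirstLevelResult],
    cov_table: pd.DataFrame,
    config: StudyConfig,
    gm_prob: np.ndarray | None = None,
    roi_masks: dict | None = None,
) -> dict:
    """Second-level tests per band: one-sample per group and HC > AD,
    positive and negative contrasts, with and without the hippocampal
    covariate; cluster tables, per-subject hit counts and scalar group
    comparisons of relative alpha power."""
    groups = sorted({r.group for r in first_levels})
    for g in ("AD", "HC"):
        if sum(r.group == g for r in first_levels) == 0:
            raise ValueError(f"group {g!r} has no completed first-level results")
    grid = next(iter(first_levels[0].beta_maps.values())).shape
    if gm_prob is None:
        gm_prob = np.ones(grid)
    gm_mask = group.make_gm_mask(gm_prob, config.gm_thresh)
    affine = np.diag([config.sim.voxel_size] * 3 + [1.0])

    by_group = {g: [r for r in first_levels if r.group == g] for g in groups}
    out: dict = {"bands": {}, "gm_mask": gm_mask}

    covar_sets = {"base": tuple(config.covariates),
                  "with_hippo": tuple(config.covariates) + (config.hippo_covariate,)}

    for band in config.bands:
        band_out: dict = {}
        maps = {g: [r.beta_maps[band.name] for r in by_group[g]] for g in groups}
        ids = {g: [r.subject_id for r in by_group[g]] for g in groups}
        for cov_name, cov_cols in covar_sets.items():
            cset: dict = {}
            for g in groups:
                C = _covariate_matrix(cov_table, ids[g], cov_cols)
                sm = group.one_sample_t(maps[g], covars=C)
                cset[f"one_sample_{g}"] = sm
                cset[f"clusters_{g}_pos"] = group.threshold_clusters(
                    sm, config.p_thresh, config.cluster_k, config.connectivity,
                    mask=gm_mask, affine=affine)
                neg = glm.StatMap(values=-sm.values, df=sm.df,
                                  contrast=sm.contrast + "_neg", band=band.name)
                cset[f"clusters_{g}_neg"] = group.threshold_clusters(
                    neg, config.p_thresh, config.cluster_k, config.connectivity,
                    mask=gm_mask, affine=affine)
            C_all = _covariate_matrix(cov_table, ids["HC"] + ids["AD"], cov_cols)
            ts = group.two_sample_t(maps["HC"], maps["AD"], covars=C_all)
            cset["two_sample_HC_gt_AD"] = ts
            cset["clusters_HC_gt_AD_pos"] = group.threshold_clusters(
                ts, config.p_thresh, config.cluster_k, config.connectivity,
                mask=gm_mask, affine=affine)
            neg = glm.StatMap(values=-ts.values, df=ts.df,
                              contrast="AD_gt_HC", band=band.name)
            cset["clusters_HC_gt_AD_neg"] = group.threshold_clusters(
                neg, config.p_thresh, config.cluster_k, config.connectivity,
                mask=gm_mask, affine=affine)
            band_out[cov_name] = cset
        out["bands"][band.name] = band_out

    if roi_masks:
        subject_maps = {(g, b.name): [r.t_pos[b.name] for r in by_group[g]]
                        for g in groups for b in config.bands}
        out["first_level_hits"] = group.count_first_level_hits(
            subject_maps, roi_masks, p=config.p_thresh)

    scalars = {}
    for band in config.bands:
        vals = {g: [r.relative_power[band.name] for r in by_group[g]]
                for g in groups}
        t, p = group.compare_scalars(vals["AD"], vals["HC"])
        scalars[f"relative_power_{band.name}"] = dict(
            t=t, p=p,
            mean_AD=float(np.mean(vals["AD"])), mean_HC=float(np.mean(vals["HC"])))
    hip = cov_table.set_index("subject_id")
    ad_ids = [r.subject_id for r in by_group["AD"]]
    hc_ids = [r.subject_id for r in by_group["HC"]]
    t, p = group.compare_scalars(hip.loc[ad_ids, "hippo_norm"],
                                 hip.loc[hc_ids, "hippo_norm"])
    scalars["hippo_norm"] = dict(t=t, p=p)
    out["scalars"] = scalars
    return out


# ---------------------------------------------------------------------------
# demonstration study


def run_demo(
    seed: int = 0,
    n_per_group: int = 8,
    config: StudyConfig | None = None,
) -> dict:
    """Simulate the demonstration cohort and run it end to end.

    Controls carry +2% coupling in region A and -2% in region B; patients
    carry none. Subjects are materialized one at a time (full-rate EEG for a
    whole cohort would not fit in memory). Returns the group results plus
    recovery metrics against the ground-truth regions.
    """
    if config is None:
        config = StudyConfig(sim=synth.demo_config(n_per_group=n_per_group),
                             seed=seed)
    region_a, region_b = synth.demo_regions(config.sim.grid_shape)
    plan = synth.cohort_plan(config.sim, seed)
    cov_table = synth.cohort_covariates(config.sim, seed)
    first_levels = []
    for sid, grp, sseed in plan:
        subject = synth.simulate_subject(config.sim, grp, sid, sseed)
        first_levels.append(run_first_level(subject, config))
        del subject
    roi_masks = {"DMN": region_a, "thalamus": region_b}
    results = run_group(first_levels, cov_table, config, roi_masks=roi_masks)

    total = results["bands"]["total_alpha"]["base"]
    hc_clusters = total["clusters_HC_gt_AD_pos"]
    dice_a = group.atlas_overlap(hc_clusters, region_a)
    results["recovery"] = {
        "hc_gt_ad_pos_n_clusters": len(hc_clusters),
        "dice_region_a": float(dice_a["dice"].max()) if len(dice_a) else 0.0,
        "ad_one_sample_pos_in_region_a": int(
            np.sum((total["clusters_AD_pos"].labels > 0) & region_a)),
        "hc_gt_ad_neg_n_clusters": len(total["clusters_HC_gt_AD_neg"]),
    }
    results["first_level_results"] = first_levels
    results["covariates"] = cov_table
    return results
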