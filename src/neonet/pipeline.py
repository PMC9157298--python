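"""End-to-end study orchestration.

``run_study`` drives the full analysis on a synthetic (or loaded)
cohort: preprocessing into band-limited epochs, source reconstruction
and parcel collapse, debiased-wPLI connectivity with the edge-fidelity
mask, network-based statistics for the sleep, group, and interaction
contrasts in every band, Delta-to-outcome Spearman correlations for the
significant interaction networks, and cytoarchitectonic profiling of
those networks. A manifest (config hash, seeds, stage order) makes the
run reproducible bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field  # noqa: F401
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import network_stats as ns
from .config import STATES, AnalysisParams, StudyConfig
from .cytoarchitecture import (fdr_over_family, project_atlas, results_frame,
                               surrogate_network_test)
from .outcomes import correlate_outcomes, delta_connectivity
from .preprocess import (average_reference, bandpass_zero_phase,
                         extract_windows, prefilter, resample_to,
                         select_epochs)
from .source_model import apply_inverse, collapse_parcels, \
    compute_fidelity_weights, make_inverse
from .synthetic import SyntheticStudy, generate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class StudyReport:
    """Bundle of all stage outputs plus the run manifest."""

    manifest: dict
    matrices: dict  # (subject, state, band) -> ConnectivityMatrix (masked)
    masks: dict  # band -> EdgeMask
    nbs: list  # NBSResult
    deltas: pd.DataFrame | None
    outcome_report: pd.DataFrame | None
    cyto: pd.DataFrame | None
    subgroup_nbs: dict = field(default_factory=dict)

    def significant_networks(self, alpha: float = 0.05,
                             contrast: str = "interaction") -> list:
        return [r for r in self.nbs
                if r.contrast == contrast and r.p_fwe < alpha]

    def summary(self) -> dict:
        """JSON-serializable digest used for determinism checks."""
        return dict(
            manifest={k: v for k, v in self.manifest.items()
                      if k != "timestamps"},
            masks={b: int(m.n_excluded) for b, m in self.masks.items()},
            nbs=[dict(contrast=r.contrast, band=r.band, extent=r.extent,
                      p_fwe=round(r.p_fwe, 10), d=round(r.cohens_d, 10),
                      direction=r.direction,
                      edges=sorted(r.component_edges)) for r in self.nbs],
            outcomes=(None if self.outcome_report is None else
                      self.outcome_report.round(10).to_dict("records")),
            cyto=(None if self.cyto is None else
                  self.cyto.round(10).to_dict("records")),
        )


def preprocess_recording(rec, bands, target_rate: float = 100.0,
                         epoch_windows: int = 6, window_length: float = 30.0,
                         state: str | None = None):
    """Standard chain: prefilter, decimate, average montage, band filter,
    equidistant epoch selection. Returns {band: [windows]}."""
    rec = prefilter(rec)
    if rec.sampling_rate > target_rate:
        rec = resample_to(rec, target_rate)
    rec = average_reference(rec)
    if state is None:
        state = rec.annotations[0][0]
    epochs = select_epochs(rec, state, epoch_windows, window_length)
    out = {}
    for band in bands:
        filtered = bandpass_zero_phase(rec, band)
        out[band.name] = extract_windows(filtered, epochs, state)
    return out


def run_study(config: StudyConfig, params: AnalysisParams | None = None,
              out_dir: str | Path | None = None,
              study: SyntheticStudy | None = None,
              subgroups: dict[str, list[str]] | None = None) -> StudyReport:
    """Run the full pipeline on a (generated) cohort.

    Parameters
    ----------
    config, params
        Study configuration and analysis parameters (paper defaults:
        t-threshold 2.5, 5000 permutations, 500 fidelity iterations,
        99th percentile, 1000 surrogates).
    study
        Pre-generated cohort; generated from `config` when None.
    subgroups
        Optional exposure subgroups (name -> subject ids within the
        exposed group); each is contrasted against the controls with
        the interaction contrast only. Subgroups below
        ``params.min_subgroup`` are skipped.
    """
    params = params or AnalysisParams()
    t_start = time.time()
    stage_log: list[str] = []

    def stage(name):
        stage_log.append(name)
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        if study is None:
            study = generate_cohort(config)
        lf, parc = study.lead_field, study.parcellation
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    try:
        stage("inverse")
        lam = (params.inverse_lambda if params.inverse_lambda is not None
               else 1.0 / 9.0)
        inv = make_inverse(lf, None, lam)
        parc.fidelity_weights = compute_fidelity_weights(
            lf, inv, parc, n_iter=params.fidelity_weight_iterations,
            seed=config.seed + 1)
    except Exception as e:  # noqa: BLE001
        raise StageError("inverse", e) from e

    try:
        stage("preprocess+connectivity")
        matrices: dict[tuple[str, str, str], conn.ConnectivityMatrix] = {}
        for (subj, state), rec in study.recordings.items():
            per_band = preprocess_recording(
                rec, config.bands, target_rate=config.sampling_rate,
                epoch_windows=config.epoch_windows,
                window_length=config.window_length, state=state)
            for band_name, windows in per_band.items():
                src_windows = [collapse_parcels(apply_inverse(inv, w), parc)
                               for w in windows]
                trim = min(params.trim_seconds, 0.1 * config.window_length)
                matrices[(subj, state, band_name)] = conn.connectivity_matrix(
                    src_windows, config.sampling_rate, band=band_name,
                    state=state, subject=subj, trim_seconds=trim)
    except Exception as e:  # noqa: BLE001
        raise StageError("connectivity", e) from e

    try:
        stage("fidelity_mask")
        masks: dict[str, conn.EdgeMask] = {}
        for band in config.bands:
            if params.apply_fidelity_mask:
                masks[band.name] = conn.fidelity_mask(
                    lf, inv, parc, band, config.sampling_rate,
                    n_iter=params.fidelity_iterations,
                    percentile=params.fidelity_percentile,
                    seed=config.seed + 2,
                    signal_seconds=params.fidelity_seconds)
            else:
                m = np.ones((config.n_parcels, config.n_parcels), bool)
                masks[band.name] = conn.EdgeMask(mask=m)
        matrices = {key: conn.apply_mask(cm, masks[key[2]])
                    for key, cm in matrices.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError("fidelity_mask", e) from e

    try:
        stage("network_stats")
        values = _stack_values(matrices, study.subjects, config)
        nbs_results: list[ns.NBSResult] = []
        for contrast in ns.CONTRASTS:
            design = ns.Design(subjects=study.subjects, group=study.groups,
                               contrast=contrast)
            for b_idx, band in enumerate(config.bands):
                res = ns.nbs_extent_test(
                    values[:, :, b_idx], design,
                    threshold=params.t_threshold,
                    n_perm=params.n_permutations, seed=config.seed + 3,
                    mask=masks[band.name].mask, band=band.name)
                nbs_results.extend(res)
    except Exception as e:  # noqa: BLE001
        raise StageError("network_stats", e) from e

    try:
        stage("outcomes")
        sig = [r for r in nbs_results
               if r.contrast == "interaction" and r.p_fwe < params.alpha]
        deltas = None
        outcome_report = None
        if sig:
            cols = {}
            for k, r in enumerate(sig):
                name = f"{r.band}_net{k}"
                col = []
                for subj in study.subjects:
                    col.append(delta_connectivity(
                        matrices[(subj, "AS", r.band)],
                        matrices[(subj, "QS", r.band)], r.component_edges))
                cols[name] = col
            deltas = pd.DataFrame(cols, index=pd.Index(study.subjects,
                                                       name="subject"))
            outcome_report = correlate_outcomes(deltas, study.outcomes)
    except Exception as e:  # noqa: BLE001
        raise StageError("outcomes", e) from e

    try:
        stage("subgroups")
        subgroup_results = {}
        if subgroups:
            hc_idx = [i for i, g in enumerate(study.groups) if g == 0]
            for name, members in subgroups.items():
                if len(members) < params.min_subgroup:
                    logger.info("subgroup %s: n=%d below minimum %d, skipped",
                                name, len(members), params.min_subgroup)
                    continue
                sub_idx = [study.subjects.index(m) for m in members] + hc_idx
                sub_subjects = [study.subjects[i] for i in sub_idx]
                sub_groups = np.array([1] * len(members) + [0] * len(hc_idx))
                design = ns.Design(subjects=sub_subjects, group=sub_groups,
                                   contrast="interaction")
                res_all = []
                for b_idx, band in enumerate(config.bands):
                    res_all.extend(ns.nbs_extent_test(
                        values[sub_idx][:, :, b_idx], design,
                        threshold=params.t_threshold,
                        n_perm=params.n_permutations, seed=config.seed + 4,
                        mask=masks[band.name].mask, band=band.name))
                subgroup_results[name] = res_all
    except Exception as e:  # noqa: BLE001
        raise StageError("subgroups", e) from e

    try:
        stage("cytoarchitecture")
        cyto = None
        targets = sig if not subgroup_results else [
            r for rs in subgroup_results.values() for r in rs
            if r.p_fwe < params.alpha]
        if targets:
            densities = project_atlas(study.atlas, parc)
            all_results = []
            for k, r in enumerate(targets):
                all_results.extend(surrogate_network_test(
                    r.component_edges, parc, densities,
                    n_surrogates=params.n_surrogates, seed=config.seed + 5,
                    name=f"{r.contrast}_{r.band}_net{k}"))
            cyto = results_frame(fdr_over_family(all_results))
    except Exception as e:  # noqa: BLE001
        raise StageError("cytoarchitecture", e) from e

    manifest = dict(
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest(),
        seed=config.seed, params=params.to_dict(), stages=stage_log,
        timestamps=dict(started=t_start, finished=time.time()),
    )
    report = StudyReport(manifest=manifest, matrices=matrices, masks=masks,
                         nbs=nbs_results, deltas=deltas,
                         outcome_report=outcome_report, cyto=cyto,
                         subgroup_nbs=subgroup_results)
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def edge_recovery_f1(report: StudyReport, study: SyntheticStudy,
                     which: str = "interaction",
                     alpha: float = 0.05) -> float:
    """Edge-level F1 between significant networks and the planted truth."""
    planted = {tuple(sorted(e))
               for e in study.truth["planted_edges"].get(which, [])}
    recovered = {tuple(sorted(e))
                 for r in report.nbs
                 if r.contrast == which and r.p_fwe < alpha
                 for e in r.component_edges}
    if not planted and not recovered:
        return 1.0
    tp = len(recovered & planted)
    fp = len(recovered - planted)
    fn = len(planted - recovered)
    return 2.0 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 0.0


def _stack_values(matrices, subjects, config) -> np.ndarray:
    """(subjects, states, bands, P, P) value array from the matrix dict."""
    P = config.n_parcels
    out = np.full((len(subjects), 2, len(config.bands), P, P), np.nan)
    for si, subj in enumerate(subjects):
        for st_i, state in enumerate(STATES):
            for b_idx, band in enumerate(config.bands):
                out[si, st_i, b_idx] = matrices[(subj, state, band.name)].values
    return out


def _write_report(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=1, default=str))
    (out_dir / "nbs.json").write_text(json.dumps(
        report.summary()["nbs"], indent=1))
    rows = [dict(contrast=r.contrast, band=r.band, direction=r.direction,
                 extent=r.extent, p_fwe=r.p_fwe, cohens_d=r.cohens_d)
            for r in report.nbs]
    pd.DataFrame(rows).to_csv(out_dir / "nbs.csv", index=False)
    if report.outcome_report is not None:
        report.outcome_report.to_csv(out_dir / "outcome_correlations.csv",
                                     index=False)
    if report.cyto is not None:
        report.cyto.to_csv(out_dir / "cytoarchitecture.csv", index=False)
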