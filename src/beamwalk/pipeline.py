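"""Study-shaped batch analysis over a directory (or list) of trials.

Per participant: low-pass filtering, windowing (central 15-85% of
successful trials, last 3 s of unsuccessful ones), ML-plane projection,
segment states, relative orientations, angular momenta about the three
reference axes (dimensionless), covariance PCA with 95% VAF retention and
VARIMAX per axis (with optional trunk-exclusion and block-split variants),
sparsity, cross-participant similarity pairing and cross-validation VAF,
body-part group VAF, the axis correlation/RMS table, and the balance
statistics (VCOM_RMS Welch test; PC1-weight regression).

Everything is deterministic given inputs + config; the resolved config and
its hash are embedded in the report for provenance.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .angular_momentum import (AxisSpec, am_summary, normalize_am, segment_am,
                               total_am)
from .anthropometry import SEGMENTS, AnthropometricTable
from .body_model import (AnalysisWindow, TrialRecord, analysis_window,
                         forward_speed, lowpass_filter, project_to_ml_plane,
                         relative_orientations, segment_states, whole_body_com)
from .decomposition import (DecompositionResults, SegmentalDecomposition,
                            greedy_pair, group_vaf)
from .io import read_trial_directory
from .stability import (StabilityRecord, pc1_weight_regression,
                        records_to_frame, vcom_rms, welch_ttest)

log = logging.getLogger("beamwalk")

AXES = ("head", "com", "beam")


@dataclass(frozen=True)
class RunConfig:
    """Resolved analysis configuration; defaults match the study protocol."""

    input_dir: str | None = None
    axes: tuple[str, ...] = AXES
    vaf_threshold: float = 95.0
    cutoff_hz: float = 20.0
    window_lo: float = 0.15
    window_hi: float = 0.85
    tail_s: float = 3.0
    min_unsuccessful_s: float = 2.5
    exclude_trunk: bool = False
    block_split: bool = False
    beam_y: float = 0.0
    beam_z: float = 0.0
    anthropometry_path: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) if not isinstance(getattr(self, k), tuple)
                else list(getattr(self, k))
                for k in self.__dataclass_fields__}

    @property
    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PreparedTrial:
    """One windowed, projected trial with its derived per-frame quantities."""

    record: TrialRecord
    window: AnalysisWindow
    speed: float
    rel_orient: np.ndarray              # (Tw, 14), analysis window only
    am: dict[str, np.ndarray]           # axis -> (Tw, 14) dimensionless
    am_raw: dict[str, np.ndarray]       # axis -> (Tw, 14) kg m^2/s
    vcom_y: np.ndarray                  # (Tw,)
    vcom_rms: float


@dataclass
class AnalysisReport:
    config: dict
    config_hash: str
    summary: dict
    stability_records: list[StabilityRecord]
    fits: dict = field(default_factory=dict, repr=False)  # in-memory results
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {"config": self.config, "config_hash": self.config_hash,
                   "summary": self.summary, "warnings": self.warnings}
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        for sub in ("am", "components", "stats"):
            (out_dir / sub).mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(self.to_json() + "\n",
                                             encoding="utf-8")
        records_to_frame(self.stability_records).to_csv(
            out_dir / "stats" / "stability_records.csv", index=False)
        for key, fit in self.fits.items():
            if isinstance(fit, DecompositionResults):
                fit.components.to_json(out_dir / "components" / f"{key}.json")
        return out_dir / "report.json"


def _mean_sd(values) -> dict:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return {"mean": None, "sd": None, "n": 0}
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd, "n": int(arr.size)}


def _prepare_trials(trials: list[TrialRecord], cfg: RunConfig,
                    anthro: AnthropometricTable, warnings: list[str]
                    ) -> dict[str, list[PreparedTrial]]:
    """Filter, window, project and differentiate; head/COM/beam AM follow in
    a second pass once the participant's mean head position is known."""
    by_pid: dict[str, list] = {}
    for rec in trials:
        win = analysis_window(rec, cfg.window_lo, cfg.window_hi, cfg.tail_s,
                              cfg.min_unsuccessful_s)
        if win.excluded:
            warnings.append(f"{rec.trial_id}: excluded ({win.note})")
            continue
        if win.note:
            warnings.append(f"{rec.trial_id}: {win.note}")
        kin = lowpass_filter(rec.kinematics, cfg.cutoff_hz)
        speed = forward_speed(kin, anthro, win)
        planar = project_to_ml_plane(kin)
        states = segment_states(planar, anthro)
        mask = (states.frame_times >= win.start_s - 1e-9) & \
               (states.frame_times <= win.end_s + 1e-9)
        rel = relative_orientations(states)[mask]
        com_pos, com_vel = whole_body_com(states)
        by_pid.setdefault(rec.participant_id, []).append(
            (rec, win, speed, states, mask, rel, com_pos, com_vel))

    prepared: dict[str, list[PreparedTrial]] = {}
    for pid, items in by_pid.items():
        # head centre = distal endpoint of the head segment, averaged over
        # every windowed frame of every trial of this participant
        heads = []
        for rec, w, s, st, m, *_ in items:
            i_he = st.segment_names.index("He")
            frac = anthro["He"].com_fraction
            # reconstruct the distal endpoint from COM and orientation
            length = np.sqrt(st.inertia_x[m, i_he] / st.masses[i_he]) \
                / anthro["He"].gyration_fraction
            dy = np.sin(st.orientation[m, i_he]) * length
            dz = np.cos(st.orientation[m, i_he]) * length
            heads.append(np.stack([
                st.com_y[m, i_he] + (1 - frac) * dy,
                st.com_z[m, i_he] + (1 - frac) * dz], axis=1))
        head_point = np.concatenate(heads, axis=0).mean(axis=0)

        out = []
        for rec, win, speed, states, mask, rel, com_pos, com_vel in items:
            axes: dict[str, AxisSpec] = {}
            if "head" in cfg.axes:
                axes["head"] = AxisSpec.head(head_point)
            if "com" in cfg.axes:
                axes["com"] = AxisSpec.com(com_pos)
            if "beam" in cfg.axes:
                axes["beam"] = AxisSpec.beam(cfg.beam_y, cfg.beam_z)
            am_raw, am_norm = {}, {}
            speed_eff = abs(speed)
            if speed_eff < 1e-9:
                warnings.append(f"{rec.trial_id}: zero walking speed; "
                                "normalizing by 1 m/s")
                speed_eff = 1.0
            for name, axis in axes.items():
                dec = segment_am(states, axis)
                am_raw[name] = dec.values[mask]
                norm = normalize_am(dec, rec.kinematics.participant_mass,
                                    speed_eff,
                                    rec.kinematics.participant_height)
                am_norm[name] = norm.values[mask]
            v = com_vel[mask, 0]
            out.append(PreparedTrial(
                record=rec, window=win, speed=speed, rel_orient=rel,
                am=am_norm, am_raw=am_raw, vcom_y=v,
                vcom_rms=vcom_rms(v)))
        prepared[pid] = out
    return prepared


def _fit(data: np.ndarray, channels, threshold: float, label: str
         ) -> DecompositionResults:
    return SegmentalDecomposition(data, tuple(channels), label=label).fit(
        vaf_threshold=threshold)


def _fit_summary(fit: DecompositionResults) -> dict:
    cs = fit.components
    return {"K": fit.n_components,
            "vaf_percent": [round(float(v), 4) for v in cs.vaf],
            "pc1_vaf_percent": round(float(cs.vaf[0]), 4),
            "cumulative_vaf_percent": round(float(cs.vaf.sum()), 4),
            "sparsity": [round(float(s), 4) for s in cs.sparsity()]}


def run_full_analysis(cfg: RunConfig,
                      trials: list[TrialRecord] | None = None,
                      anthro: AnthropometricTable | None = None
                      ) -> AnalysisReport:
    """Execute the full study-shaped analysis and return the report bundle."""
    t_start = time.perf_counter()
    warnings: list[str] = []
    if anthro is None:
        anthro = (AnthropometricTable.from_yaml(cfg.anthropometry_path)
                  if cfg.anthropometry_path else AnthropometricTable.default())
    if trials is None:
        if cfg.input_dir is None:
            raise ValueError("either trials or cfg.input_dir must be given")
        trials, errors = read_trial_directory(cfg.input_dir)
        warnings.extend(errors)
    prepared = _prepare_trials(trials, cfg, anthro, warnings)

    fits: dict[str, DecompositionResults] = {}
    participants_summary: dict[str, dict] = {}
    channels = list(SEGMENTS)
    channels_nt = [c for c in SEGMENTS if c != "Tr"]
    group_tables: dict[str, list[dict]] = {a: [] for a in cfg.axes}
    stability_records: list[StabilityRecord] = []

    for pid, ptrials in sorted(prepared.items()):
        succ = [p for p in ptrials if p.record.success]
        unsucc = [p for p in ptrials if not p.record.success]
        psum: dict = {"n_successful": len(succ), "n_unsuccessful": len(unsucc)}
        if not succ:
            warnings.append(f"{pid}: no successful trials; participant-level "
                            "decomposition skipped")
            participants_summary[pid] = psum
            continue

        kin_pool = np.concatenate([p.rel_orient for p in succ], axis=0)
        kin_fit = _fit(kin_pool, channels, cfg.vaf_threshold, f"{pid}/kinematic")
        fits[f"{pid}_kinematic"] = kin_fit
        psum["kinematic"] = _fit_summary(kin_fit)

        psum["am"] = {}
        for axis in cfg.axes:
            pool = np.concatenate([p.am[axis] for p in succ], axis=0)
            fit = _fit(pool, channels, cfg.vaf_threshold, f"{pid}/am/{axis}")
            fits[f"{pid}_am_{axis}"] = fit
            psum["am"][axis] = _fit_summary(fit)
            group_tables[axis].append(group_vaf(pool))
            if cfg.exclude_trunk:
                i_tr = SEGMENTS.index("Tr")
                pool_nt = np.delete(pool, i_tr, axis=1)
                fit_nt = _fit(pool_nt, channels_nt, cfg.vaf_threshold,
                              f"{pid}/am-no-trunk/{axis}")
                fits[f"{pid}_amnt_{axis}"] = fit_nt
                psum.setdefault("am_excluding_trunk", {})[axis] = \
                    _fit_summary(fit_nt)
            if cfg.block_split and len(succ) >= 4:
                half = len(succ) // 2
                pools = [np.concatenate([p.am[axis] for p in succ[:half]]),
                         np.concatenate([p.am[axis] for p in succ[half:]])]
                fit1 = _fit(pools[0], channels, cfg.vaf_threshold,
                            f"{pid}/block1/{axis}")
                fit2 = _fit(pools[1], channels, cfg.vaf_threshold,
                            f"{pid}/block2/{axis}")
                pairing = greedy_pair(fit1.components, fit2.components)
                psum.setdefault("blocks", {})[axis] = {
                    "K_block1": fit1.n_components, "K_block2": fit2.n_components,
                    "similarity_mean": round(pairing.mean, 6),
                    "similarity_sd": round(pairing.sd, 6)}

        if unsucc:
            psum["unsuccessful"] = {}
            for axis in cfg.axes:
                pool_u = np.concatenate([p.am[axis] for p in unsucc], axis=0)
                fit_u = _fit(pool_u, channels, cfg.vaf_threshold,
                             f"{pid}/am-unsuccessful/{axis}")
                fits[f"{pid}_amu_{axis}"] = fit_u
                pairing = greedy_pair(fits[f"{pid}_am_{axis}"].components,
                                      fit_u.components)
                psum["unsuccessful"][axis] = {
                    **_fit_summary(fit_u),
                    "similarity_to_successful": round(pairing.mean, 6),
                    "crossfit_vaf_from_successful": round(
                        fits[f"{pid}_am_{axis}"].crossfit(pool_u), 4)}

        # stability records: PC1 weight of the beam-axis successful components
        score_axis = "beam" if "beam" in cfg.axes else cfg.axes[0]
        score_fit = fits[f"{pid}_am_{score_axis}"]
        for p in succ + unsucc:
            weights = score_fit.scores(p.am[score_axis])
            stability_records.append(StabilityRecord(
                trial_id=p.record.trial_id, success=p.record.success,
                vcom_rms=p.vcom_rms,
                pc1_weight_rms=float(weights.rms[0])))
        participants_summary[pid] = psum
        log.info("participant %s analysed (%.2f s elapsed)", pid,
                 time.perf_counter() - t_start)

    # cross-participant similarity and cross-validation, per axis
    pids = [pid for pid in sorted(prepared) if f"{pid}_am_beam" in fits
            or any(f"{pid}_am_{a}" in fits for a in cfg.axes)]
    cross: dict[str, dict] = {}
    for axis in cfg.axes:
        have = [pid for pid in pids if f"{pid}_am_{axis}" in fits]
        sims, pc1_sims, cv = [], [], []
        for i, a in enumerate(have):
            for b in have[i + 1:]:
                fa, fb = fits[f"{a}_am_{axis}"], fits[f"{b}_am_{axis}"]
                sims.append(greedy_pair(fa.components, fb.components).mean)
                la = fa.components.loadings[:, 0]
                lb = fb.components.loadings[:, 0]
                pc1_sims.append(abs(float(
                    la @ lb / (np.linalg.norm(la) * np.linalg.norm(lb)))))
        for a in have:
            for b in have:
                if a == b:
                    continue
                pool_b = np.concatenate(
                    [p.am[axis] for p in prepared[b] if p.record.success], axis=0)
                cv.append(fits[f"{a}_am_{axis}"].crossfit(pool_b))
        cross[axis] = {"similarity": _mean_sd(sims),
                       "pc1_similarity": _mean_sd(pc1_sims),
                       "crossfit_vaf": _mean_sd(cv)}

    kin_sims, kin_cv = [], []
    have_kin = [pid for pid in sorted(prepared) if f"{pid}_kinematic" in fits]
    for i, a in enumerate(have_kin):
        for b in have_kin[i + 1:]:
            kin_sims.append(greedy_pair(fits[f"{a}_kinematic"].components,
                                        fits[f"{b}_kinematic"].components).mean)
    for a in have_kin:
        for b in have_kin:
            if a != b:
                pool_b = np.concatenate(
                    [p.rel_orient for p in prepared[b] if p.record.success])
                kin_cv.append(fits[f"{a}_kinematic"].crossfit(pool_b))

    group_summary = {
        axis: {grp: _mean_sd([row[grp] for row in rows])
               for grp in ("head", "trunk", "arms", "legs")}
        for axis, rows in group_tables.items() if rows}

    all_prepared = [p for ps in prepared.values() for p in ps]
    am_table = am_summary([{a: _as_dec(p, a) for a in cfg.axes}
                           for p in all_prepared]) if all_prepared else None

    stats_summary: dict = {"n_records": len(stability_records)}
    vc_s = [r.vcom_rms for r in stability_records if r.success]
    vc_u = [r.vcom_rms for r in stability_records if not r.success]
    stats_summary["vcom_rms_successful"] = _mean_sd(vc_s)
    stats_summary["vcom_rms_unsuccessful"] = _mean_sd(vc_u)
    if len(vc_s) >= 2 and len(vc_u) >= 2:
        welch = welch_ttest(vc_s, vc_u)
        stats_summary["welch"] = {"t": welch.t, "df": welch.df, "p": welch.p}
        try:
            regression = pc1_weight_regression(stability_records)
            stats_summary["regression"] = regression.to_dict()
        except ValueError as exc:
            warnings.append(f"regression skipped: {exc}")

    summary = {
        "participants": participants_summary,
        "cross_participant_am": cross,
        "cross_participant_kinematic": {"similarity": _mean_sd(kin_sims),
                                        "crossfit_vaf": _mean_sd(kin_cv)},
        "group_vaf": group_summary,
        "am_axis_table": am_table.round(6).to_dict() if am_table is not None
        else None,
        "stability": stats_summary,
        "elapsed_s": round(time.perf_counter() - t_start, 3),
    }
    return AnalysisReport(config=cfg.to_dict(), config_hash=cfg.config_hash,
                          summary=summary, stability_records=stability_records,
                          fits=fits, warnings=warnings)


def _as_dec(p: PreparedTrial, axis: str):
    """Adapter: raw windowed AM matrix -> minimal decomposition for am_summary."""
    from .angular_momentum import AMDecomposition, AxisSpec

    t = p.am_raw[axis].shape[0]
    spec = AxisSpec.beam() if axis != "com" else AxisSpec.com(np.zeros((t, 2)))
    return AMDecomposition(values=p.am_raw[axis], axis=spec,
                           frame_times=np.arange(t, dtype=float))
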