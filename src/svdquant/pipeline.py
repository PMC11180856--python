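"""End-to-end orchestration: phantom -> quantification -> endpoints -> stats.

One :func:`run_end_to_end` call simulates a full two-timepoint trial on
digital-phantom subjects, pushes every scan through the same quantification
chain a patient study would use (VFA T1 fit, sinus AIF, Patlak Ki map;
supervised-cluster reference, basis-function SRTM BP map; eroded-NAWM
hotspot endpoints), and runs the trial statistics on the resulting
endpoint table.  All randomness flows from a single seed through spawned
child generators, so the run is bit-reproducible.

A note on ratio-scale effects for binding potential: BP_ND is negative in
normal white matter, so mean-BP endpoints are shifted to the strictly
positive scale 1 + BP before the log-outcome regression (BP > -1 by
model definition); the shift is recorded in the output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dce_patlak import concentration_from_t1, extract_aif, ki_map
from .hotspots import (DEFAULT_EROSION_MM, DEFAULT_PERCENTILE, build_nawm,
                       hotspot_metrics, percentile_threshold)
from .pet_kinetics import bp_map, default_theta3_grid, svca_reference
from .phantom import (ClassLibrary, Labels, PhantomSpec, generate_cohort,
                      generate_biomarker_panel, generate_phantom_masks,
                      make_class_library, make_truth_maps, simulate_dce_study,
                      simulate_pet_study)
from .phantom.cohort import ARM_ACTIVE
from .schedules import FrameSchedule
from .t1_mapping import fit_vfa_t1
from .trial_stats import (TreatmentEffect, adverse_event_summary,
                          baseline_comparison, biomarker_analysis,
                          pca_treatment, pooled_mean, qalb, qalb_validation)

__all__ = ["RunConfig", "run_end_to_end", "analyze_subject_scan"]

ENDPOINTS = [
    ("ki_hotspot_pct", "BBB permeability hotspot volume (% eroded NAWM)", False),
    ("bp_hotspot_pct", "TSPO binding hotspot volume (% eroded NAWM)", False),
    ("ki_mean_nawm", "Mean Ki in eroded NAWM (mL/g/min)", False),
    ("bp_mean_nawm", "Mean BP_ND in eroded NAWM", True),
    ("ki_mean_hotspot", "Mean Ki of BBB hotspots (mL/g/min)", False),
    ("bp_mean_hotspot", "Mean BP_ND of TSPO hotspots", True),
]


@dataclass
class RunConfig:
    """Serializable configuration of an end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_subjects: int = 44
    seed: int = 0
    # quantification
    r1_relaxivity: float = 3.5
    percentile_q: float = DEFAULT_PERCENTILE
    erosion_mm: float = DEFAULT_EROSION_MM
    patlak_window_start_min: float = 0.0
    theta3_n: int = 100
    pet_dt_s: float = 2.0
    n_frames: int = 55
    scan_total_s: float = 4500.0
    white_weight_min: float = 0.9
    n_control_voxels: int = 20000
    n_control_subjects: int = 3
    # simulated intervention (1.0 = null)
    bbb_treatment_effect: float = 1.0
    # stats
    bonferroni_m: int = 92
    biomarker_treatment_effects: float = 1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d:
            d["phantom"] = PhantomSpec.from_dict(d["phantom"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def analyze_subject_scan(spec: PhantomSpec, schedule: FrameSchedule,
                         library: ClassLibrary, rng: np.random.Generator,
                         config: RunConfig, ki_mu: float, bp_mu: float,
                         hotspot_fraction: float, hct: float,
                         ki_threshold: float | None = None,
                         bp_threshold: float | None = None,
                         collect_values: bool = False) -> dict:
    """Simulate and quantify one subject scan; returns endpoint dict.

    Hotspot thresholds default to the library's control voxel
    distributions; the trial runner instead passes thresholds derived from
    control subjects pushed through this same quantification chain, so
    control and patient values share the measurement-noise distribution.
    With ``collect_values`` the measured eroded-NAWM voxel values are
    returned as well (used to pool the control distributions).
    """
    subj_spec = dataclasses.replace(
        spec, seed=int(rng.integers(2**31 - 1)), hct=float(hct))
    masks = generate_phantom_masks(subj_spec)
    truth = make_truth_maps(masks, subj_spec, rng, ki_mu=ki_mu, bp_mu=bp_mu,
                            hotspot_fraction=hotspot_fraction)

    # --- DCE-MRI chain -----------------------------------------------------
    dce = simulate_dce_study(masks, truth.ki, truth.vp, truth.t1_ms, subj_spec, rng)
    n_cycles = dce.signals.shape[0]
    t1_fits = [fit_vfa_t1(np.moveaxis(dce.signals[c], 0, -1),
                          dce.flip_angles_deg, dce.tr_ms)
               for c in range(n_cycles)]
    base = t1_fits[0]
    sss = masks.mask(Labels.SSS)
    sss_ok = sss & base.valid
    sss_conc = np.stack([
        concentration_from_t1(t1_fits[c].t1_ms[sss_ok], base.t1_ms[sss_ok],
                              config.r1_relaxivity).mean()
        for c in range(1, n_cycles)])
    times = np.concatenate([[0.0], dce.cycle_times_min])
    aif = extract_aif(times, np.concatenate([[0.0], sss_conc]), subj_spec.hct)

    fit_mask = masks.mask(Labels.WM, Labels.WMH)
    t1_cycles = np.stack([t1_fits[c].t1_ms for c in range(1, n_cycles)])
    cycles_valid = np.stack([t1_fits[c].valid for c in range(1, n_cycles)])
    kimap = ki_map(t1_cycles, base.t1_ms, dce.cycle_times_min, aif, fit_mask,
                   baseline_valid=base.valid, cycles_valid=cycles_valid,
                   r1_per_s_per_mM=config.r1_relaxivity,
                   window_start_min=config.patlak_window_start_min)

    # --- PET chain ---------------------------------------------------------
    pet = simulate_pet_study(masks, truth.r1, truth.k2, truth.bp, truth.vb,
                             library, schedule, subj_spec, rng)
    head = masks.labels > 0
    ref = svca_reference(pet.tacs, library, head,
                         white_weight_min=config.white_weight_min,
                         mode="projected")
    bpm = bp_map(pet.tacs, ref, schedule, fit_mask,
                 blood_curve=library.blood,
                 theta3_grid=default_theta3_grid(config.theta3_n),
                 vascular=True, dt_s=config.pet_dt_s)

    # --- endpoints ---------------------------------------------------------
    wm = masks.mask(Labels.WM)
    wmh = masks.mask(Labels.WMH)
    nawm = build_nawm(wm | wmh, wmh, masks.voxel_size_mm, config.erosion_mm)
    nawm_raw = (wm | wmh) & ~wmh
    ki_thr = (percentile_threshold(library.control_ki_values, config.percentile_q)
              if ki_threshold is None else ki_threshold)
    bp_thr = (percentile_threshold(library.control_bp_values, config.percentile_q)
              if bp_threshold is None else bp_threshold)

    out: dict = {"n_ref_voxels": ref.n_voxels_contributing}
    if collect_values:
        out["ki_values"] = kimap.ki[nawm & kimap.valid]
        out["bp_values"] = bpm.bp_nd[nawm & bpm.valid]
    for tag, mask in (("", nawm), ("_uneroded", nawm_raw)):
        hk = hotspot_metrics(kimap.ki, mask & kimap.valid, ki_thr)
        hb = hotspot_metrics(bpm.bp_nd, mask & bpm.valid, bp_thr)
        out.update({
            f"ki_hotspot_pct{tag}": hk.pct_volume,
            f"ki_mean_nawm{tag}": hk.mean_in_nawm,
            f"ki_mean_hotspot{tag}": hk.mean_in_hotspots,
            f"bp_hotspot_pct{tag}": hb.pct_volume,
            f"bp_mean_nawm{tag}": hb.mean_in_nawm,
            f"bp_mean_hotspot{tag}": hb.mean_in_hotspots,
        })
    out.update({
        "ki_threshold": ki_thr, "bp_threshold": bp_thr,
        "true_ki_mean_nawm": float(truth.ki[nawm].mean()),
        "true_bp_mean_nawm": float(truth.bp[nawm].mean()),
        "true_hotspot_fraction": float(hotspot_fraction),
    })
    return out


def _effects_table(endpoints: pd.DataFrame, config: RunConfig,
                   eroded: bool = True) -> pd.DataFrame:
    """Table-3-style RR estimates for every endpoint/adjustment/population."""
    tag = "" if eroded else "_uneroded"
    rows = []
    for key, label, is_bp_mean in ENDPOINTS:
        col = key + tag
        for pop in ("ITT", "per-protocol"):
            for adj in (False, True):
                sub = endpoints[["subject_id", "arm", "age_years",
                                 "completed_treatment"]].copy()
                b = endpoints[f"{col}_baseline"].to_numpy(float)
                f = endpoints[f"{col}_followup"].to_numpy(float)
                if is_bp_mean:      # shift BP to the positive 1+BP scale
                    b, f = 1.0 + b, 1.0 + f
                sub["baseline_value"], sub["followup_value"] = b, f
                try:
                    est = TreatmentEffect(sub).fit(adjust_age=adj, population=pop)
                    rows.append({
                        "endpoint": label, "eroded": eroded, "population": pop,
                        "adjusted_for_age": adj, "rr": est.rr,
                        "ci_low": est.ci_low, "ci_high": est.ci_high,
                        "p": est.p_value, "n": est.n_used,
                        "scale": "1+BP ratio" if is_bp_mean else "ratio",
                    })
                except ValueError as err:
                    rows.append({"endpoint": label, "eroded": eroded,
                                 "population": pop, "adjusted_for_age": adj,
                                 "rr": np.nan, "ci_low": np.nan,
                                 "ci_high": np.nan, "p": np.nan, "n": 0,
                                 "scale": f"failed: {err}"})
    return pd.DataFrame(rows)


def run_end_to_end(config: RunConfig, out_dir=None) -> dict:
    """Run the full simulated trial; returns the report bundle.

    When ``out_dir`` is given, writes endpoint/effect/biomarker CSVs, the
    provenance YAML and a JSON summary there.
    """
    ss = np.random.SeedSequence(config.seed)
    r_cohort, r_library, r_scans, r_biomk = [np.random.default_rng(s)
                                             for s in ss.spawn(4)]
    spec = config.phantom
    schedule = FrameSchedule.geometric(config.n_frames, config.scan_total_s)
    library = make_class_library(spec, schedule, r_library,
                                 n_control=config.n_control_voxels)
    cohort = generate_cohort(config.n_subjects, spec=spec, seed=r_cohort)

    # control cohort: lesion-free phantoms through the same quantification
    # chain, pooled voxelwise -> the 95th-percentile hotspot thresholds
    ki_pool, bp_pool = [], []
    for _ in range(config.n_control_subjects):
        res = analyze_subject_scan(spec, schedule, library, r_scans, config,
                                   ki_mu=spec.truth_Ki_nawm,
                                   bp_mu=spec.truth_BP_nawm,
                                   hotspot_fraction=0.0, hct=spec.hct,
                                   collect_values=True)
        ki_pool.append(res["ki_values"])
        bp_pool.append(res["bp_values"])
    ki_thr = percentile_threshold(np.concatenate(ki_pool), config.percentile_q)
    bp_thr = percentile_threshold(np.concatenate(bp_pool), config.percentile_q)

    records = []
    for _, row in cohort.iterrows():
        for timepoint in ("baseline", "followup"):
            frac = row["true_hotspot_fraction"]
            ki_mu = row["true_mean_ki"]
            if timepoint == "followup" and row["arm"] == ARM_ACTIVE:
                frac = frac * config.bbb_treatment_effect
            res = analyze_subject_scan(
                spec, schedule, library, r_scans, config,
                ki_mu=ki_mu, bp_mu=row["true_mean_bp"],
                hotspot_fraction=frac, hct=row["hct"],
                ki_threshold=ki_thr, bp_threshold=bp_thr)
            res.update(subject_id=row["subject_id"], timepoint=timepoint)
            records.append(res)
    scans = pd.DataFrame(records)

    wide = scans.pivot(index="subject_id", columns="timepoint")
    endpoints = cohort[["subject_id", "arm", "age_years",
                        "completed_treatment"]].copy()
    value_cols = [c for c in scans.columns
                  if c not in ("subject_id", "timepoint")]
    for col in value_cols:
        for tp in ("baseline", "followup"):
            endpoints[f"{col}_{tp}"] = wide[(col, tp)].reindex(
                endpoints["subject_id"]).to_numpy()

    effects = pd.concat([_effects_table(endpoints, config, eroded=True),
                         _effects_table(endpoints, config, eroded=False)],
                        ignore_index=True)
    table1 = baseline_comparison(cohort)
    ae = adverse_event_summary(cohort)

    base_panel, follow_panel = generate_biomarker_panel(
        cohort, treatment_effects=config.biomarker_treatment_effects,
        seed=r_biomk, m_proteins=config.bonferroni_m)
    prot = [c for c in base_panel.columns if c.startswith("P")]
    biomk = biomarker_analysis(base_panel, follow_panel, cohort,
                               m=config.bonferroni_m, protein_cols=prot)
    pca_res, pca_effects = pca_treatment(base_panel, follow_panel, cohort,
                                         protein_cols=prot)

    lp = endpoints.merge(cohort[["subject_id", "csf_albumin_mg_L",
                                 "serum_albumin_g_L"]], on="subject_id")
    lp = lp.dropna(subset=["csf_albumin_mg_L"])
    qalb_report = {}
    if len(lp) >= 3:
        ratios = qalb(lp["csf_albumin_mg_L"], lp["serum_albumin_g_L"])
        for name, col in (("mean_ki", "ki_mean_nawm_baseline"),
                          ("hotspot_pct", "ki_hotspot_pct_baseline")):
            qalb_report[name] = qalb_validation(ratios, lp[col])

    # ground-truth recovery appendix
    recovery = {
        "ki_mean_nawm_r": float(np.corrcoef(
            endpoints["ki_mean_nawm_baseline"],
            endpoints["true_ki_mean_nawm_baseline"])[0, 1]),
        "bp_mean_nawm_r": float(np.corrcoef(
            endpoints["bp_mean_nawm_baseline"],
            endpoints["true_bp_mean_nawm_baseline"])[0, 1]),
        "ki_mean_abs_err": float(np.mean(np.abs(
            endpoints["ki_mean_nawm_baseline"]
            - endpoints["true_ki_mean_nawm_baseline"]))),
    }
    pooled = {
        "age_years": pooled_mean(
            [cohort.loc[cohort.arm == a, "age_years"].mean()
             for a in sorted(cohort.arm.unique())],
            [int((cohort.arm == a).sum()) for a in sorted(cohort.arm.unique())]),
    }

    bundle = {
        "config": config.to_dict(), "cohort": cohort, "endpoints": endpoints,
        "effects": effects, "table1": table1, "adverse_events": ae,
        "biomarkers": biomk, "pca_effects": pca_effects,
        "pca_variance_share": pca_res.variance_share.tolist(),
        "qalb": qalb_report, "recovery": recovery, "pooled": pooled,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        for name in ("cohort", "endpoints", "effects", "table1",
                     "adverse_events", "biomarkers", "pca_effects"):
            bundle[name].to_csv(out / f"{name}.csv", index=False)
        summary = {k: bundle[k] for k in ("pca_variance_share", "qalb",
                                          "recovery", "pooled")}
        summary["seed"] = config.seed
        summary["package_version"] = _version()
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return bundle


def _version() -> str:
    from . import __version__
    return __version__
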