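"""Trial cohort generation: block randomization and per-arm demographics.

Allocation uses randomly permuted block randomization with block sizes two
and four, giving a 1:1 ratio with prefix imbalance never exceeding two.
Demographics are drawn per arm from summary statistics of a moderate-to-
severe small-vessel-disease trial population (ages ~73 vs ~66.5 years,
WMH load ~31 cc, mostly male, high vascular-risk-factor prevalence).
Continuous traits are Gaussian per arm; strictly positive skewed traits
(WMH volume, time since stroke) are log-normal matched to the arm mean/SD;
binary traits are Bernoulli at the arm prevalence.

Subject-level ground-truth imaging modifiers (mean NAWM Ki / BP_ND and
hotspot load) are included so downstream simulation and validation stages
can correlate non-imaging variables (e.g. CSF/serum albumin) with each
subject's true permeability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spec import PhantomSpec

__all__ = ["randomize_arms", "generate_cohort", "TABLE_PARAMS"]

ARM_ACTIVE = "minocycline"
ARM_PLACEBO = "placebo"

# per-arm generator parameters: (mean, sd) or prevalence
TABLE_PARAMS = {
    "age_years": {ARM_ACTIVE: (73.0, 8.90), ARM_PLACEBO: (66.5, 11.9)},
    "male": {ARM_ACTIVE: 0.609, ARM_PLACEBO: 0.667},
    "white_british": {ARM_ACTIVE: 0.870, ARM_PLACEBO: 0.905},
    "hypertension": {ARM_ACTIVE: 0.957, ARM_PLACEBO: 0.762},
    "hyperlipidemia": {ARM_ACTIVE: 0.652, ARM_PLACEBO: 0.857},
    "ihd": {ARM_ACTIVE: 0.130, ARM_PLACEBO: 0.048},
    "diabetes": {ARM_ACTIVE: 0.130, ARM_PLACEBO: 0.238},
    "bmi": {ARM_ACTIVE: (30.9, 10.1), ARM_PLACEBO: (30.2, 7.5)},
    "smoker": {ARM_ACTIVE: 0.174, ARM_PLACEBO: 0.095},
    "time_since_stroke_months": {ARM_ACTIVE: (24.8, 28.3), ARM_PLACEBO: (21.1, 20.4)},
    "wmh_volume_cc": {ARM_ACTIVE: (31.2, 22.6), ARM_PLACEBO: (31.5, 30.0)},
    "adverse_event": {ARM_ACTIVE: 0.478, ARM_PLACEBO: 0.333},
    "completed_treatment": {ARM_ACTIVE: 0.91, ARM_PLACEBO: 0.95},
}


def randomize_arms(n_subjects: int, block_sizes: tuple[int, ...] = (2, 4),
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """1:1 permuted-block allocation sequence of length ``n_subjects``."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels: list[str] = []
    while len(labels) < n_subjects:
        b = int(rng.choice(block_sizes))
        block = [ARM_ACTIVE] * (b // 2) + [ARM_PLACEBO] * (b // 2)
        rng.shuffle(block)
        labels.extend(block)
    return np.array(labels[:n_subjects])


def _lognormal_from_moments(rng, mean, sd, size):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_cohort(n: int = 44, params: dict | None = None,
                    spec: PhantomSpec | None = None,
                    seed: int | np.random.Generator = 0,
                    n_lumbar_puncture: int = 12,
                    qalb_rho: float = 0.6,
                    qalb_mean: float = 5.39, qalb_sd: float = 1.71) -> pd.DataFrame:
    """Generate a per-subject trial table with known imaging ground truth.

    A random subgroup of ``n_lumbar_puncture`` subjects receives CSF and
    serum albumin values whose ratio correlates with the subject's true
    mean NAWM Ki at Pearson correlation ``qalb_rho``.
    """
    if n < 2:
        raise ValueError("need at least two subjects")
    params = TABLE_PARAMS if params is None else params
    spec = spec or PhantomSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    arms = randomize_arms(n, seed=rng)
    rows: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i:03d}" for i in range(1, n + 1)]),
        "arm": arms,
    }
    cont_gauss = ["age_years", "bmi"]
    cont_lognorm = ["time_since_stroke_months", "wmh_volume_cc"]
    binary = ["male", "white_british", "hypertension", "hyperlipidemia",
              "ihd", "diabetes", "smoker", "adverse_event", "completed_treatment"]

    def per_arm(col, draw):
        out = np.empty(n)
        for arm in (ARM_ACTIVE, ARM_PLACEBO):
            sel = arms == arm
            out[sel] = draw(params[col][arm], int(sel.sum()))
        return out

    for col in cont_gauss:
        rows[col] = per_arm(col, lambda p, m: rng.normal(p[0], p[1], m))
    for col in cont_lognorm:
        rows[col] = per_arm(col, lambda p, m: _lognormal_from_moments(rng, p[0], p[1], m))
    for col in binary:
        rows[col] = per_arm(col, lambda p, m: rng.uniform(size=m) < p).astype(bool)

    rows["fazekas"] = rng.choice([2, 3], size=n, p=[0.55, 0.45])
    rows["hct"] = np.clip(rng.normal(spec.hct, 0.03, size=n), 0.25, 0.60)
    rows["sex"] = np.where(rows["male"], "M", "F")

    # subject-level imaging ground truth (latent; drives the simulators)
    true_ki = rng.normal(spec.truth_Ki_nawm, 0.5 * spec.truth_Ki_sd_nawm, size=n)
    true_bp = rng.normal(spec.truth_BP_nawm, 0.5 * spec.truth_BP_sd_nawm, size=n)
    frac = spec.hotspot_fraction * rng.lognormal(0.0, 0.3, size=n)
    rows["true_mean_ki"] = true_ki
    rows["true_mean_bp"] = true_bp
    rows["true_hotspot_fraction"] = np.clip(frac, 0.0, 0.5)

    # CSF/serum albumin subgroup correlated with true mean Ki
    csf = np.full(n, np.nan)
    serum = np.full(n, np.nan)
    if n_lumbar_puncture > 0:
        lp = rng.choice(n, size=min(n_lumbar_puncture, n), replace=False)
        z_ki = (true_ki[lp] - true_ki[lp].mean()) / (true_ki[lp].std() or 1.0)
        z = qalb_rho * z_ki + np.sqrt(max(0.0, 1 - qalb_rho**2)) * rng.normal(size=lp.size)
        qalb = np.clip(qalb_mean + qalb_sd * z, 0.5, None)          # mg/g
        serum_lp = np.clip(rng.normal(40.0, 3.0, size=lp.size), 25, 55)  # g/L
        serum[lp] = serum_lp
        csf[lp] = qalb * serum_lp                                   # mg/L
    rows["csf_albumin_mg_L"] = csf
    rows["serum_albumin_g_L"] = serum

    return pd.DataFrame(rows)
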