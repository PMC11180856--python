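"""Synthetic 92-protein biomarker panel with factor structure.

Protein levels follow a linear factor model X = mu + f @ Lambda' + eps with
k latent factors and unit idiosyncratic noise; the loading scale is chosen
so the factors account for a target share of total variance in expectation
(default 0.45, so the first three principal components explain roughly
that share).  Follow-up values share factor scores with baseline at
correlation ``rho_follow`` and can carry a per-protein multiplicative
treatment effect in the active arm, giving a known non-null to power
simulations and an exact null when all effects are 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ARM_ACTIVE

__all__ = ["generate_biomarker_panel", "N_PROTEINS", "protein_names"]

N_PROTEINS = 92
BASELINE_LEVEL = 6.0  # log2-like NPX offset, kept well above zero


def protein_names(m: int = N_PROTEINS) -> list[str]:
    return [f"P{i:03d}" for i in range(1, m + 1)]


def generate_biomarker_panel(
    cohort: pd.DataFrame,
    k_factors: int = 3,
    target_var_share: float = 0.45,
    treatment_effects: np.ndarray | float | None = None,
    rho_follow: float = 0.7,
    seed: int | np.random.Generator = 0,
    m_proteins: int = N_PROTEINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate matched baseline and follow-up panels.

    Returns ``(baseline, follow_up)`` DataFrames indexed like ``cohort``
    with ``m_proteins`` protein columns plus ``hsCRP``.
    """
    if not 0.0 < target_var_share < 1.0:
        raise ValueError("target_var_share must lie in (0, 1)")
    if k_factors >= m_proteins:
        raise ValueError("k_factors must be smaller than the panel size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cohort)

    # loading scale: per-protein factor variance share = target
    c = np.sqrt(target_var_share / ((1.0 - target_var_share) * k_factors))
    lam = c * rng.normal(size=(m_proteins, k_factors))

    f0 = rng.normal(size=(n, k_factors))
    x0 = BASELINE_LEVEL + f0 @ lam.T + rng.normal(size=(n, m_proteins))

    f1 = rho_follow * f0 + np.sqrt(1 - rho_follow**2) * rng.normal(size=(n, k_factors))
    x1 = BASELINE_LEVEL + f1 @ lam.T + rng.normal(size=(n, m_proteins))

    if treatment_effects is not None:
        eff = np.broadcast_to(np.asarray(treatment_effects, float), (m_proteins,))
        if np.any(eff <= 0):
            raise ValueError("multiplicative effects must be positive")
        active = (cohort["arm"].to_numpy() == ARM_ACTIVE)
        x1[active] = x1[active] * eff[None, :]

    cols = protein_names(m_proteins)
    base = pd.DataFrame(x0, columns=cols, index=cohort.index)
    follow = pd.DataFrame(x1, columns=cols, index=cohort.index)
    for df in (base, follow):
        df.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    base["hsCRP"] = rng.lognormal(np.log(2.0), 0.8, size=n)
    follow["hsCRP"] = base["hsCRP"].to_numpy() * rng.lognormal(0.0, 0.2, size=n)
    base["timepoint"] = "baseline"
    follow["timepoint"] = "follow-up"
    return base, follow
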