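"""Synthetic survey cohorts with burnout-dependent structure.

The generator draws a burnout label per respondent (Bernoulli at the
configured prevalence, default 728/5,794) and then each survey variable from
its marginal distribution, shifted for the high-burnout group by the
variable's effect size: per-level log-odds shifts for categorical variables,
a location shift in range units for numeric ones.  Zero effect sizes give an
exact null (both groups share one distribution); :func:`cohort_effect_sizes`
reproduces the reference cohort's printed group contrast.

MBI-GS item responses can be simulated separately so that burnout scoring
round-trips: high-risk respondents receive latent subscale means above the
critical boundaries on the exhaustion and cynicism subscales and a low
professional-efficacy mean (which exceeds its boundary after reversal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .schema import (
    BURNOUT_HIGH,
    BURNOUT_LOW,
    SchemaError,
    SimulationConfig,
    SurveySchema,
    default_schema,
    cohort_effect_sizes,
)

__all__ = [
    "generate_survey",
    "generate_mbi_items",
    "default_schema",
    "cohort_effect_sizes",
    "DEFAULT_BOUNDARIES",
    "DEFAULT_SEPARATION",
    "MBI_SUBSCALE_ITEMS",
]

#: Critical boundaries for (exhaustion, cynicism, reversed efficacy) subscale
#: means on the 0–6 item scale.  The instrument's boundaries for this cohort
#: were never published; these are the simulator's generating values and the
#: scorer's defaults, so label round-trips are self-consistent.
DEFAULT_BOUNDARIES = (3.0, 3.0, 3.0)

#: Latent subscale-mean separation (in item-scale units) between each group
#: and its boundary.  1.2 puts ~95% of subscale means on the correct side
#: once item noise (sd 1) is averaged over a subscale.
DEFAULT_SEPARATION = 1.2

#: Item columns per subscale: 5 exhaustion + 5 cynicism + 6 efficacy,
#: the standard 16-item MBI-GS layout.
MBI_SUBSCALE_ITEMS = {
    "exhaustion": tuple(f"mbi_{i}" for i in range(1, 6)),
    "cynicism": tuple(f"mbi_{i}" for i in range(6, 11)),
    "efficacy": tuple(f"mbi_{i}" for i in range(11, 17)),
}


def _shifted_probs(base: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Apply per-level log-odds shifts and renormalize."""
    logit = np.log(np.clip(base, 1e-12, None)) + shift
    w = np.exp(logit - logit.max())
    return w / w.sum()


def _draw_numeric(rng, var, n, shift_units: float) -> np.ndarray:
    lo, hi = var.range
    loc = var.loc + shift_units * (hi - lo)
    scale = max(var.scale, 1e-9)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def generate_survey(
    schema: SurveySchema | None = None,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Draw a synthetic survey table.

    Returns a DataFrame with ``respondent_id``, one column per schema
    variable, and the burnout label column (``low`` / ``high``).
    Deterministic for a fixed ``config.seed``.
    """
    if schema is None:
        schema = default_schema()
    if config is None:
        config = SimulationConfig()
    config.validate_against(schema)

    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    high = rng.random(n) < config.burnout_prevalence

    data: dict[str, object] = {
        "respondent_id": [f"R{i:06d}" for i in range(n)],
    }
    for var in schema.variables:
        eff = config.effect_sizes.get(var.name)
        col = np.empty(n, dtype=object if var.is_categorical else float)
        if var.is_categorical:
            base = np.asarray(var.level_probs)
            shift = np.zeros(len(base)) if eff is None else np.asarray(
                eff, dtype=float)
            p_low, p_high = base, _shifted_probs(base, shift)
            levels = np.asarray(var.levels, dtype=object)
            # one uniform per respondent, inverted through the group's CDF
            u = rng.random(n)
            for mask, probs in ((~high, p_low), (high, p_high)):
                if mask.any():
                    idx = np.searchsorted(np.cumsum(probs), u[mask],
                                          side="right")
                    col[mask] = levels[np.minimum(idx, len(levels) - 1)]
        else:
            shift = 0.0 if eff is None else float(eff)
            col[~high] = _draw_numeric(rng, var, int((~high).sum()), 0.0)
            col[high] = _draw_numeric(rng, var, int(high.sum()), shift)
        data[var.name] = col
    data[schema.burnout_label_name] = np.where(
        high, BURNOUT_HIGH, BURNOUT_LOW)
    return pd.DataFrame(data)


def generate_mbi_items(
    n: int,
    burnout_status=None,
    seed: int = 0,
    boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES,
    separation: float = DEFAULT_SEPARATION,
) -> pd.DataFrame:
    """Simulate 16-item MBI-GS responses consistent with a burnout label.

    Parameters
    ----------
    n : int
        Number of respondents; may be 0.
    burnout_status : sequence of {"low", "high"}, optional
        Target label per respondent (length ``n``).  All-low if omitted.
    seed : int
        Random seed.
    boundaries : triple of float
        Critical boundaries for the (exhaustion, cynicism, reversed
        efficacy) subscale means.
    separation : float
        Distance of each group's latent subscale mean from its boundary.

    High-risk respondents get exhaustion and cynicism latent means at
    ``boundary + separation`` and an efficacy mean at
    ``6 - boundary - separation`` (so the reversed score ``6 - mean``
    exceeds its boundary): all three subscales lean toward exceedance, and
    the >= 2-subscale rule recovers the label with high probability.
    """
    if burnout_status is None:
        burnout_status = [BURNOUT_LOW] * n
    status = np.asarray(burnout_status, dtype=object)
    if status.shape != (n,):
        raise SchemaError("burnout_status length must equal n")
    bad = set(status) - {BURNOUT_LOW, BURNOUT_HIGH}
    if bad:
        raise SchemaError(f"unknown burnout status values: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    high = status == BURNOUT_HIGH
    b_exh, b_cyn, b_eff = boundaries

    latent = {
        "exhaustion": np.where(high, b_exh + separation, b_exh - separation),
        "cynicism": np.where(high, b_cyn + separation, b_cyn - separation),
        # efficacy is scored reversed: low raw mean = poor efficacy = burnout
        "efficacy": np.where(high, 6.0 - b_eff - separation,
                             6.0 - b_eff + separation),
    }
    cols: dict[str, np.ndarray] = {}
    for subscale, items in MBI_SUBSCALE_ITEMS.items():
        mu = latent[subscale]
        for item in items:
            raw = np.rint(mu + rng.normal(0.0, 1.0, size=n))
            cols[item] = np.clip(raw, 0, 6).astype(int)
    frame = pd.DataFrame(cols, columns=[c for items in
                                        MBI_SUBSCALE_ITEMS.values()
                                        for c in items])
    if n == 0:
        return frame.astype(int)
    return frame
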