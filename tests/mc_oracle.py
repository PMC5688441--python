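"""Monte-Carlo microsimulation oracle for the deaths-averted closed form.

Independent of the engine: it simulates the cohort directly.  The
counterfactual at-risk population is N = D / (1 - E*AF*c0) deaths-to-be at
zero coverage.  Coverage is simulated with common random numbers (each
individual holds one uniform draw, and is covered at level c when the draw
is below c), so the same cohort is observed at c0 and at c1 and everyone
already covered at c0 cancels exactly.  The individuals newly covered in the
scale-up — Binomial(N, c1 - c0) of them — each avert their death with
probability E*AF.  Deaths averted is the resulting count, rescaled from the
N-person cohort to the baseline-deaths scale.
"""

from __future__ import annotations

import math

import numpy as np


def mc_deaths_averted(
    baseline_deaths: float,
    effectiveness: float,
    affected_fraction: float,
    c0: float,
    c1: float,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Simulated deaths averted and its standard error, for a cohort of
    ``n_draws`` at-risk individuals rescaled to ``baseline_deaths``."""
    impact = effectiveness * affected_fraction
    newly_covered = rng.binomial(n_draws, c1 - c0)
    averted = float(rng.binomial(newly_covered, impact))
    p = impact * (c1 - c0)
    se = math.sqrt(n_draws * p * (1 - p))
    # D observed deaths at c0 correspond to N = D / (1 - E*AF*c0) at risk
    scale = baseline_deaths / ((1 - impact * c0) * n_draws)
    return averted * scale, se * scale
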