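"""Synthetic developmental cohorts with full ground truth.

Each synthetic cell carries a roster of synaptic inputs whose strengths
(EPSP rates of rise, V/s) follow the developmental statistics of the first
postnatal week in the MNTB: one input grows linearly with age while the
second strongest stays flat, and the remaining inputs are weak. Terminal
contact areas are tied to strength through the power law
``ror = beta * area**alpha``, inverted exactly so that downstream recovery
tests have a noise-free reference.
"""

from __future__ import annotations

import math

import numpy as np

from ..datatypes import CellGroundTruth, CohortParams, SynapticInput
from ..errors import ParameterError

__all__ = ["make_cohort", "true_area_for_ror", "structure_function_records"]


def true_area_for_ror(ror, beta: float = 6.8, alpha: float = 0.35):
    """Invert the power law: the contact area (µm²) at which a terminal of
    strength ``ror`` (V/s) sits exactly on ``ror = beta * area**alpha``."""
    if beta <= 0 or alpha <= 0:
        raise ParameterError("alpha and beta must be positive")
    return (np.asarray(ror, dtype=float) / beta) ** (1.0 / alpha)


def _lognormal_about(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Mean-preserving lognormal draw around ``mean`` (sigma on log scale)."""
    if sigma == 0:
        return mean
    return mean * math.exp(rng.normal(-0.5 * sigma**2, sigma))


def _draw_latency(rng: np.random.Generator, strong: bool) -> float:
    """Latency (ms) from the two observed populations: 1-3 ms for mature,
    short-path axons and 4-8 ms for the slower population. Strong inputs
    always belong to the short-latency population."""
    if strong or rng.random() < 0.6:
        return float(rng.uniform(1.2, 3.0))
    return float(rng.uniform(4.0, 8.0))


def make_cohort(params: CohortParams) -> list[CellGroundTruth]:
    """Draw a cohort of synthetic cells with known ground truth.

    Per cell: age uniform over ``age_range``; input count from a truncated
    normal (minimum 2); the strongest input's mean RoR follows
    ``strongest_intercept + strongest_growth * (age - 2)`` with lognormal
    cell-to-cell spread; the second strongest is drawn around
    ``second_mean``; remaining inputs fall in the weak range. True contact
    areas invert the power law exactly. Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    cells: list[CellGroundTruth] = []
    for i in range(params.n_cells):
        age = float(rng.uniform(*params.age_range))
        # truncated normal, minimum 2 inputs
        while True:
            n_inputs = int(round(rng.normal(params.n_inputs_mean, params.n_inputs_sd)))
            if n_inputs >= 2:
                break

        strongest_mean = params.strongest_intercept + params.strongest_growth * (age - 2.0)
        strongest = _lognormal_about(rng, strongest_mean, params.strongest_spread)
        second = _lognormal_about(rng, params.second_mean, params.second_spread)
        second = min(second, 0.85 * strongest)
        lo, hi = params.weak_ror_range
        if hi > lo:
            weak = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_inputs - 2))
        else:
            weak = np.full(n_inputs - 2, lo)
        rors = np.concatenate([[strongest, second], weak])

        # presence of a presynaptic (calyceal) prespike on the strongest
        # input follows a logistic developmental switch
        p_calyx = 1.0 / (1.0 + math.exp(-(age - params.calyx_midpoint) / params.calyx_steepness))
        calyceal = rng.random() < p_calyx

        inputs = []
        for j, ror in enumerate(rors):
            strong_pop = j == 0 or ror > 10.0
            is_cal = calyceal and j == 0
            inputs.append(
                SynapticInput(
                    true_ror=float(ror),
                    recruitment_threshold=float(rng.uniform(*params.threshold_range)),
                    activation_prob=float(rng.uniform(*params.activation_prob_range)),
                    latency_mean=_draw_latency(rng, strong_pop),
                    latency_cv=float(rng.uniform(*params.latency_jitter_cv)),
                    trial_cv=float(rng.uniform(*params.ror_noise_cv)),
                    is_calyceal=is_cal,
                    prespike_amp=float(rng.uniform(0.1, 0.4)) if is_cal else None,
                )
            )

        areas = true_area_for_ror(rors, params.beta, params.alpha)
        observed = rors * np.exp(rng.normal(0.0, params.sf_noise_sigma, size=rors.size)) \
            if params.sf_noise_sigma > 0 else rors.copy()
        cells.append(
            CellGroundTruth(
                cell_id=f"cell{i:03d}",
                age=age,
                inputs=inputs,
                true_contact_areas=areas,
                soma_radius=float(rng.uniform(*params.soma_radius_range)),
                observed_rors=observed,
            )
        )
    return cells


def structure_function_records(cells: list[CellGroundTruth]):
    """(area, observed RoR) pairs of the strongest input per cell.

    The observation noise (``CohortParams.sf_noise_sigma``) emulates the
    combined trial-to-trial and measurement scatter that limits the log-log
    structure-function correlation in real cohorts to about 0.8.
    """
    areas, rors = [], []
    for c in cells:
        if not c.inputs:
            continue
        k = int(np.argmax([i.true_ror for i in c.inputs]))
        areas.append(float(c.true_contact_areas[k]))
        obs = c.observed_rors[k] if c.observed_rors is not None else c.inputs[k].true_ror
        rors.append(float(obs))
    return np.asarray(areas), np.asarray(rors)
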