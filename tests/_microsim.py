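"""Individual-level micro-simulation oracle for the cohort engine.

Simulates each patient separately with the same within-cycle convention
as the cohort engine (background death first, then recurrence or cancer
death), so the cohort trace must match the empirical state fractions up
to Monte-Carlo error.  Kept deliberately independent of the engine's
implementation: plain per-patient state arrays, no tunnel algebra.
"""

from __future__ import annotations

import numpy as np

DF, HEP, FL, SL, DCC, DO = range(6)


def microsimulate(
    n_patients: int,
    horizon: int,
    p_recur,
    p_death_cc,
    p_death_other,
    frac_hepatectomy: float = 1.0 / 9.0,
    first_line_duration: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Empirical state-occupancy fractions, shape (horizon + 1, 6)."""
    rng = np.random.default_rng(seed)
    p_recur = np.asarray(p_recur, dtype=float)
    if p_recur.size < horizon:
        p_recur = np.concatenate([p_recur, np.zeros(horizon - p_recur.size)])
    p_dcc = np.asarray(p_death_cc, dtype=float)
    if p_dcc.size < horizon + 1:
        p_dcc = np.concatenate([p_dcc, np.full(horizon + 1 - p_dcc.size, p_dcc[-1])])
    p_do = np.asarray(p_death_other, dtype=float)

    state = np.full(n_patients, DF, dtype=np.int8)
    rec_months = np.zeros(n_patients, dtype=np.int32)

    occ = np.zeros((horizon + 1, 6))
    occ[0, DF] = 1.0
    for t in range(horizon):
        u = rng.random(n_patients)
        v = rng.random(n_patients)
        w = rng.random(n_patients)

        df_mask = state == DF
        rec_mask = (state == HEP) | (state == FL) | (state == SL)

        die_other = (df_mask | rec_mask) & (u < p_do[t])
        new_rec = df_mask & ~die_other & (v < p_recur[t])
        die_cc = rec_mask & ~die_other & (v < p_dcc[rec_months])

        survivors_rec = rec_mask & ~die_other & ~die_cc
        rec_months[survivors_rec] += 1
        to_second = survivors_rec & (state == FL) & (rec_months == first_line_duration)

        state[die_other] = DO
        state[die_cc] = DCC
        state[to_second] = SL
        state[new_rec & (w < frac_hepatectomy)] = HEP
        state[new_rec & (w >= frac_hepatectomy)] = FL
        rec_months[new_rec] = 0

        occ[t + 1] = np.bincount(state, minlength=6) / n_patients
    return occ
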