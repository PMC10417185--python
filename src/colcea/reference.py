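"""Published base-case cost-effectiveness values.

Printed per-strategy discounted lifetime cost (I$) and DALYs averted
(vs no adjuvant chemotherapy) for the South African public-sector
adjuvant colon cancer analysis.  These pairs exercise the frontier,
ICER and NMB logic independently of any curve calibration
(``--from-values`` mode and the exact acceptance checks).
"""

PUBLISHED_BASE_CASE: dict[str, dict[str, tuple[float, float]]] = {
    # strategy -> (total cost I$, DALYs averted)
    "high_risk_stage_ii": {
        "no_adjuvant": (2693.0, 0.00),
        "cape_6mo": (3748.0, 0.87),
        "capox_3mo": (4083.0, 2.21),
        "capox_6mo": (5398.0, 2.28),
    },
    "stage_iii": {
        "cape_6mo": (3737.0, 3.98),
        "no_adjuvant": (5117.0, 0.00),
        "capox_3mo": (5279.0, 5.46),
        "capox_6mo": (6647.0, 5.19),
    },
}

#: Printed ZAR -> I$ cost pairs usable as currency-conversion checks.
PUBLISHED_COST_PAIRS_ZAR_TO_INTL = (
    (9_748.0, 1_374.0),   # adjuvant CAPOX 3 months course
    (13_266.0, 1_869.0),  # first-line metastatic course after capecitabine
)
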