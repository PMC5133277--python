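"""Centered ±0.5 contrast coding of the 2x2x2 verification design.

Two-level factors are coded +0.5/−0.5 so that each main effect is estimated
at the grand mean of the other factors and interaction coefficients are
differences of simple effects.  The fixed mapping is:

=============  ==============  ======
factor         level           code
=============  ==============  ======
plausibility   plausible       +0.5
plausibility   implausible     −0.5
congruency     congruent       +0.5
congruency     incongruent     −0.5
order          scene_first     +0.5
order          sentence_first  −0.5
=============  ==============  ======
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PLAUSIBILITY_CODE = {"plausible": 0.5, "implausible": -0.5}
CONGRUENCY_CODE = {"congruent": 0.5, "incongruent": -0.5}
ORDER_CODE = {"scene_first": 0.5, "sentence_first": -0.5}

#: Names of the seven coded predictors, in model order (no intercept).
CODE_COLUMNS = ("c_plaus", "c_cong", "c_order", "c_pc", "c_po", "c_co", "c_pco")

#: Human-readable term labels, intercept first, aligned with `code_vector`.
TERM_NAMES = (
    "Intercept",
    "Plausibility",
    "Congruency",
    "Order",
    "Plausibility:Congruency",
    "Plausibility:Order",
    "Congruency:Order",
    "Plausibility:Congruency:Order",
)

COLUMN_TO_TERM = dict(zip(("(Intercept)",) + CODE_COLUMNS, TERM_NAMES))


def _lookup(mapping: dict[str, float], value, factor: str) -> float:
    try:
        return mapping[value]
    except KeyError:
        raise ValueError(f"unknown {factor} level {value!r}; expected one of {sorted(mapping)}")


def code_vector(plausibility: str, congruency: str, order: str) -> np.ndarray:
    """Length-8 design row (intercept, 3 mains, 3 two-way, 1 three-way)."""
    p = _lookup(PLAUSIBILITY_CODE, plausibility, "plausibility")
    c = _lookup(CONGRUENCY_CODE, congruency, "congruency")
    o = _lookup(ORDER_CODE, order, "order")
    return np.array([1.0, p, c, o, p * c, p * o, c * o, p * c * o])


def code_contrasts(trials: pd.DataFrame) -> pd.DataFrame:
    """Append the seven ±0.5 contrast/product columns to a trial table.

    Expects ``plausibility``, ``congruency`` and ``order`` columns with the
    factor levels above; raises ``ValueError`` on an unknown level.
    """
    for col, mapping in (
        ("plausibility", PLAUSIBILITY_CODE),
        ("congruency", CONGRUENCY_CODE),
        ("order", ORDER_CODE),
    ):
        bad = set(trials[col].unique()) - set(mapping)
        if bad:
            raise ValueError(f"unknown {col} level(s) {sorted(bad)}")
    out = trials.copy()
    p = trials["plausibility"].map(PLAUSIBILITY_CODE).to_numpy()
    c = trials["congruency"].map(CONGRUENCY_CODE).to_numpy()
    o = trials["order"].map(ORDER_CODE).to_numpy()
    out["c_plaus"], out["c_cong"], out["c_order"] = p, c, o
    out["c_pc"], out["c_po"], out["c_co"] = p * c, p * o, c * o
    out["c_pco"] = p * c * o
    return out
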