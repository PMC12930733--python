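"""Shared column conventions and design-matrix construction.

Every module agrees on one compact integer coding of the cohort table and one
fixed dummy expansion.  The analysis (Cox) design contains the four ECOG
contrasts plus all baseline adjusters; the imputation design swaps the ECOG
dummies for the Nelson-Aalen cumulative-hazard estimate and the event
indicator (outcome-side auxiliaries of the imputation model).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: reserved sentinel for a deleted ECOG value; distinct from every category code
MISSING: int = -1

#: columns of a cohort table, in storage order
COHORT_COLUMNS = [
    "age", "sex", "diagnosis_year", "ecog", "grading", "stage",
    "topography", "morphology", "radiotherapy", "intention", "residual",
    "systemic", "time", "event",
]

#: integer code -> label, per categorical column (the CSV sidecar code book)
CODEBOOK = {
    "sex": ["female", "male"],
    "diagnosis_year": ["2019", "2020", "2021", "2022"],
    "ecog": ["0", "1", "2", "3", "4"],
    "grading": ["G1", "G2", "G3", "G4"],
    "stage": ["IA1", "IA2", "IA3", "IB", "IIA", "IIB",
              "IIIA", "IIIB", "IIIC", "IV", "IVA", "IVB"],
    "topography": ["C34.0", "C34.1", "C34.2", "C34.3", "C34.8", "C34.9"],
    "morphology": ["adenocarcinoma", "squamous_cell", "small_cell", "other"],
    "radiotherapy": ["no", "yes"],
    "intention": ["no_therapy", "palliative", "curative"],
    "residual": ["no_surgery", "R1", "R0"],
    "systemic": ["none", "chemotherapy", "immuno_chemotherapy",
                 "mono_immunotherapy", "targeted"],
    "event": ["censored", "death"],
}

# adjuster dummy expansion: (term name, source column, code) -- reference
# levels: topography other than C34.0/.1/.3, morphology "other", no therapy /
# no surgery / no systemic therapy, year 2019, grading G1, stage IA1.
_ADJUSTER_TERMS = (
    [("age", "age", None), ("sex_male", "sex", 1)]
    + [(f"topo_c34{d}", "topography", c) for d, c in (("0", 0), ("1", 1), ("3", 3))]
    + [("morph_adeno", "morphology", 0), ("morph_squamous", "morphology", 1),
       ("morph_smallcell", "morphology", 2)]
    + [("radiotherapy_yes", "radiotherapy", 1)]
    + [("intention_palliative", "intention", 1), ("intention_curative", "intention", 2)]
    + [("residual_r1", "residual", 1), ("residual_r0", "residual", 2)]
    + [("systemic_chemo", "systemic", 1), ("systemic_immunochemo", "systemic", 2),
       ("systemic_monoimmuno", "systemic", 3), ("systemic_targeted", "systemic", 4)]
    + [(f"year_{y}", "diagnosis_year", c) for y, c in
       (("2020", 1), ("2021", 2), ("2022", 3))]
    + [(f"grading_g{g}", "grading", c) for g, c in (("2", 1), ("3", 2), ("4", 3))]
    + [(f"stage_{lab.lower()}", "stage", c)
       for c, lab in enumerate(CODEBOOK["stage"]) if c > 0]
)

ECOG_TERMS = ["ecog_1", "ecog_2", "ecog_3", "ecog_4"]
ADJUSTER_TERMS = [t for t, _, _ in _ADJUSTER_TERMS]
#: Cox analysis design: ECOG contrasts (vs ECOG=0) followed by all adjusters
ANALYSIS_TERMS = ECOG_TERMS + ADJUSTER_TERMS


def _adjuster_matrix(cohort: pd.DataFrame) -> np.ndarray:
    n = len(cohort)
    out = np.empty((n, len(_ADJUSTER_TERMS)), dtype=float)
    for j, (_, col, code) in enumerate(_ADJUSTER_TERMS):
        v = cohort[col].to_numpy()
        out[:, j] = v.astype(float) if code is None else (v == code)
    return out


def ecog_dummies(ecog: np.ndarray) -> np.ndarray:
    """4-column dummy block for ECOG 1..4 (reference category 0)."""
    return (np.asarray(ecog)[:, None] == np.arange(1, 5)).astype(float)


def analysis_design(cohort: pd.DataFrame, include_ecog: bool = True):
    """Design matrix of the Cox analysis model.

    Returns ``(X, names)``; with ``include_ecog=False`` only the adjusters
    are returned (the ``ecog_only`` analysis switch uses the complement).
    """
    adj = _adjuster_matrix(cohort)
    if not include_ecog:
        return adj, list(ADJUSTER_TERMS)
    X = np.hstack([ecog_dummies(cohort["ecog"].to_numpy()), adj])
    return X, list(ANALYSIS_TERMS)


PREDICTOR_TERMS = ["age", "sex_male", "nelson_aalen", "event"] + [
    t for t in ADJUSTER_TERMS if t not in ("age", "sex_male")
]


def validate_complete(cohort: pd.DataFrame, allow_missing_ecog: bool = True) -> None:
    """Raise if any cell other than (optionally) ECOG is missing."""
    for col in COHORT_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
        v = cohort[col]
        if v.isna().any():
            raise ValueError(f"column {col!r} contains NaN values")
        if col == "ecog":
            bad = ~v.isin([MISSING, 0, 1, 2, 3, 4])
            if bad.any():
                raise ValueError("ecog contains codes outside {missing,0..4}")
            if not allow_missing_ecog and (v == MISSING).any():
                raise ValueError("ecog contains missing values")
        elif col in CODEBOOK and col != "event":
            k = len(CODEBOOK[col])
            if ((v < 0) | (v >= k)).any():
                raise ValueError(f"column {col!r} contains out-of-range codes")
    if (cohort["time"].to_numpy() <= 0).any():
        raise ValueError("survival times must be positive")
    if not cohort["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
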