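"""NCEP-ATP-III rule engine for labelling metabolic syndrome.

A subject is labelled MetS when at least ``n_required`` (default 3) of five
risk factors are present: elevated triglycerides (TGL ≥ 150 mg/dL), low HDL
cholesterol (< 50 mg/dL in women, < 40 mg/dL in men), elevated blood pressure
(systolic > 130 mmHg or diastolic > 85 mmHg, counted as ONE factor), elevated
fasting glucose (> 110 mg/dL or diagnosed diabetes) and increased waist
circumference.  Waist circumference is routinely missing from clinical
registers and is excluded from the measured table handled here, so the
engine scores the four remaining factors (TGL, HDL, blood pressure, glucose);
counts therefore range 0..4 and the ``>= 3`` rule operates on those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CLINICAL_COLUMNS, ClinicalTable


@dataclass(frozen=True)
class CriteriaThresholds:
    """Cut-offs for the five diagnostic criteria.

    ``bp_inclusive``/``glu_inclusive`` switch the strict ``>`` comparisons to
    ``>=`` for registries that follow the inclusive reading of the scale.
    """

    tgl_min: float = 150.0        # mg/dL, inclusive (>=)
    hdl_max_female: float = 50.0  # mg/dL, strict (<)
    hdl_max_male: float = 40.0    # mg/dL, strict (<)
    bp_sys: float = 130.0         # mmHg, strict (>)
    bp_dia: float = 85.0          # mmHg, strict (>)
    glu_min: float = 110.0        # mg/dL, strict (>)
    n_required: int = 3
    bp_inclusive: bool = False
    glu_inclusive: bool = False
    unknown_sex_cutoff: str = "M"  # HDL cut-off used when sex is unknown

    def __post_init__(self) -> None:
        for name in ("tgl_min", "hdl_max_female", "hdl_max_male",
                     "bp_sys", "bp_dia", "glu_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 1 <= self.n_required <= 5:
            raise ValueError("n_required must be in 1..5")


DEFAULT_THRESHOLDS = CriteriaThresholds()

MET_S = "MetS"
NO_MET_S = "noMetS"


def _hdl_cutoff(sex: str, thresholds: CriteriaThresholds) -> float:
    sex = (sex or "unknown").upper()
    if sex.startswith("F"):
        return thresholds.hdl_max_female
    if sex.startswith("M"):
        return thresholds.hdl_max_male
    return (thresholds.hdl_max_female
            if thresholds.unknown_sex_cutoff.upper().startswith("F")
            else thresholds.hdl_max_male)


def count_criteria(record, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
                   diabetes: bool = False) -> int:
    """Number of risk factors met (0..4 from these data) for one subject.

    ``record`` is a mapping with keys TGL, HDL, SP, DP, GLU and optionally
    ``sex``.  Blood pressure counts as a single factor, met when either the
    systolic or the diastolic cut-off is exceeded; the fifth NCEP-ATP-III
    factor (waist circumference) is not measured here, so the count tops
    out at 4.
    """
    vals = {}
    for key in CLINICAL_COLUMNS:
        if key not in record or record[key] is None or (
                isinstance(record[key], float) and np.isnan(record[key])):
            raise ValueError(f"missing clinical parameter {key}")
        vals[key] = float(record[key])

    gt = lambda x, c, incl: (x >= c) if incl else (x > c)  # noqa: E731
    n = 0
    n += vals["TGL"] >= thresholds.tgl_min
    n += vals["HDL"] < _hdl_cutoff(record.get("sex", "unknown"), thresholds)
    n += (gt(vals["SP"], thresholds.bp_sys, thresholds.bp_inclusive)
          or gt(vals["DP"], thresholds.bp_dia, thresholds.bp_inclusive))
    n += gt(vals["GLU"], thresholds.glu_min, thresholds.glu_inclusive) or diabetes
    return int(n)


def classify_mets(record, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
                  diabetes: bool = False) -> str:
    """MetS iff at least ``thresholds.n_required`` criteria are met."""
    n = count_criteria(record, thresholds, diabetes=diabetes)
    return MET_S if n >= thresholds.n_required else NO_MET_S


def label_table(table: ClinicalTable,
                thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS) -> pd.Series:
    """Apply the rule engine to every row of a clinical table."""
    table.require_complete()
    out = {}
    for sid, row in table.data.iterrows():
        out[sid] = classify_mets(row.to_dict(), thresholds)
    return pd.Series(out, name="rule_label")
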