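"""ChIP-qPCR percent-input and fold-enrichment arithmetic, plus ΔΔCt
relative expression for RT-qPCR.

Percent input expresses immunoprecipitated DNA as a percentage of the
chromatin that went into the IP. Because only a fraction of the lysate
(typically 10%) is carried as input, the raw input Ct is first adjusted by
subtracting log2(1/fraction) cycles — log2(10) ≈ 3.32 for a 10% aliquot —
after which

    %input = 100 · 2^(adjusted input Ct − ChIP Ct).

Fold enrichment divides the target antibody's %input by that of an
unrelated control antibody (e.g. anti-GFP) at the same amplicon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

ANTIBODY_ROLES = ("target", "control", "input")


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    antibody: str  # one of ANTIBODY_ROLES
    amplicon: str
    replicate: int
    ct: float

    def __post_init__(self):
        if self.antibody not in ANTIBODY_ROLES:
            raise ValueError(f"antibody must be one of {ANTIBODY_ROLES}")
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValueError(f"ct must be positive and finite, got {self.ct}")


@dataclass(frozen=True)
class EnrichmentResult:
    amplicon: str
    percent_input_target: float
    percent_input_control: float
    fold: float
    n_target: int
    n_control: int


def adjust_input_ct(input_ct: float, input_fraction: float = 0.10) -> float:
    """Correct the input Ct for the aliquot fraction: subtract log2(1/f).

    A 10% input gives the familiar −3.32 cycles (log2 10). log2 is kept at
    full precision; 3.32 is a display rounding.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    return input_ct - math.log2(1.0 / input_fraction)


def percent_input(adjusted_input_ct: float, chip_ct: float) -> float:
    """100 · 2^(adjusted input Ct − ChIP Ct)."""
    for v in (adjusted_input_ct, chip_ct):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    return 100.0 * 2.0 ** (adjusted_input_ct - chip_ct)


def fold_enrichment(
    records: pd.DataFrame,
    input_fraction: float = 0.10,
    aggregate: Literal["mean", "geometric"] = "mean",
) -> EnrichmentResult:
    """Fold enrichment for one amplicon from a tidy Ct table.

    ``records`` holds rows (sample_id, antibody, amplicon, replicate, ct)
    for a single amplicon, with antibody in {target, control, input}. The
    input Ct (matched by replicate where present, else the amplicon-wide
    mean) is adjusted for the aliquot fraction; %input is computed per
    replicate, averaged per antibody, and the target/control ratio is the
    fold. ``geometric`` averages on the log scale instead.
    """
    amplicons = records["amplicon"].unique()
    if len(amplicons) != 1:
        raise ValueError(f"expected one amplicon, got {list(amplicons)}")
    amplicon = amplicons[0]
    inputs = records[records["antibody"] == "input"]
    if inputs.empty:
        raise ValueError(f"{amplicon}: no input records")
    input_by_rep = inputs.set_index("replicate")["ct"].to_dict()
    input_mean = float(inputs["ct"].mean())

    def _pi(rows: pd.DataFrame) -> np.ndarray:
        vals = []
        for _, r in rows.iterrows():
            in_ct = input_by_rep.get(r["replicate"], input_mean)
            vals.append(percent_input(adjust_input_ct(in_ct, input_fraction), r["ct"]))
        return np.array(vals)

    tgt = records[records["antibody"] == "target"]
    ctl = records[records["antibody"] == "control"]
    if tgt.empty:
        raise ValueError(f"{amplicon}: no target-antibody records")
    if ctl.empty:
        raise ValueError(f"{amplicon}: no control-antibody records")
    pi_t, pi_c = _pi(tgt), _pi(ctl)
    if aggregate == "mean":
        mt, mc = float(pi_t.mean()), float(pi_c.mean())
    elif aggregate == "geometric":
        mt, mc = float(np.exp(np.log(pi_t).mean())), float(np.exp(np.log(pi_c).mean()))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return EnrichmentResult(amplicon, mt, mc, mt / mc, len(pi_t), len(pi_c))


def enrichment_table(
    records: pd.DataFrame,
    input_fraction: float = 0.10,
    aggregate: Literal["mean", "geometric"] = "mean",
) -> pd.DataFrame:
    """fold_enrichment applied per amplicon; tidy output for plotting/stats."""
    rows = []
    for amplicon, grp in records.groupby("amplicon", sort=True):
        r = fold_enrichment(grp, input_fraction, aggregate)
        rows.append(
            {
                "amplicon": amplicon,
                "percent_input_target": r.percent_input_target,
                "percent_input_control": r.percent_input_control,
                "fold": r.fold,
                "n_target": r.n_target,
                "n_control": r.n_control,
            }
        )
    return pd.DataFrame(rows)


def relative_expression(
    target_ct: float,
    reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
) -> float:
    """ΔΔCt fold change: 2^−[(CtT−CtRef)_sample − (CtT−CtRef)_calibrator].

    Reference is a housekeeping transcript (e.g. Gapdh); the calibrator is
    the condition everything is expressed relative to.
    """
    for v in (target_ct, reference_ct, calibrator_target_ct, calibrator_reference_ct):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (target_ct - reference_ct) - (calibrator_target_ct - calibrator_reference_ct)
    return 2.0 ** (-ddct)
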