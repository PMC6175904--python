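"""Partial-residual views of the neural-distance ~ Hamming relationship.

A partial residual plot shows the relation between the response and one
regressor after removing the fitted contribution of every other regressor.
Here the fit is the full vividness-interaction model

    neuraldistance = a + b_Hamm Hamm + b_Vivid Vivid + b_HxV Hamm*Vivid
                       + b_VisSim VisSim + b_scanner log10(scannertime) + e

and the Hamming-related component is read out separately for vivid pairs
(Vivid = 0, where the interaction vanishes) and for the less-vivid pairs
(Vivid != 0, where it does not):

* vivid:     partial residual = residual + b_Hamm * Hamm,
             displayed line slope b_Hamm, intercept 0;
* non-vivid: partial residual = residual + b_Hamm * Hamm
             + b_HxV * Hamm * Vivid; the Hamming slope now depends on the
             pair's own Vivid level, b_Hamm + b_HxV * Vivid, so the
             piecewise per-pair slopes are kept and a single summary slope
             is reported at the subset's mean Vivid.

If every other regressor explained the response perfectly, the residuals
would equal -b_Hamm*Hamm and the partial residuals would sit at 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .searchlight_rsa import PairGlmFit

__all__ = [
    "PartialResidualSet",
    "partial_residuals",
    "mean_group_slope",
    "partial_residuals_to_csv",
]

SUBSETS = ("vivid", "nonvivid")


@dataclass
class PartialResidualSet:
    """Partial residuals and regression-line geometry for one pair subset."""

    subset: str  # "vivid" (Vivid == 0) or "nonvivid" (Vivid != 0)
    pair_index: np.ndarray
    hamm: np.ndarray
    partial_residuals: np.ndarray
    line_slope: float  # b_Hamm (vivid) or b_Hamm + b_HxV * mean(Vivid)
    line_intercept: float  # always 0 by construction
    pair_slopes: np.ndarray  # per-pair slope b_Hamm + b_HxV * Vivid


def partial_residuals(
    fit: PairGlmFit, pairs: pd.DataFrame, subset: str
) -> PartialResidualSet:
    """Partial residuals of the Hamming component for one vividness subset.

    ``fit`` must come from the full interaction model estimated on *all*
    included pairs (never from a refit on the subset); the subset only
    selects which pairs are displayed.
    """
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    for needed in ("Hamm", "Vivid", "Hamm:Vivid"):
        if needed not in fit.spec.terms:
            raise ValueError(
                f"fit lacks the {needed!r} term; use the full interaction model"
            )
    rows = pairs.loc[fit.pair_index]
    vivid = rows["vivid_code"].to_numpy(dtype=float)
    hamm = rows["hamm"].to_numpy(dtype=float)
    sel = vivid == 0 if subset == "vivid" else vivid != 0
    if not sel.any():
        raise ValueError(f"no pairs in the {subset!r} subset")

    b_hamm = fit["Hamm"]
    b_int = fit["Hamm:Vivid"]
    resid = fit.residuals[sel]
    h = hamm[sel]
    v = vivid[sel]
    component = b_hamm * h + b_int * h * v  # the v term vanishes for vivid
    slopes = b_hamm + b_int * v
    if subset == "vivid":
        line_slope = b_hamm
    else:
        line_slope = b_hamm + b_int * float(v.mean())
    return PartialResidualSet(
        subset=subset,
        pair_index=np.asarray(fit.pair_index)[sel],
        hamm=h,
        partial_residuals=resid + component,
        line_slope=float(line_slope),
        line_intercept=0.0,
        pair_slopes=slopes,
    )


def mean_group_slope(per_subject: Sequence[PartialResidualSet]) -> float:
    """Unweighted mean of the per-participant regression-line slopes."""
    if not per_subject:
        raise ValueError("no subjects")
    return float(np.mean([s.line_slope for s in per_subject]))


def partial_residuals_to_csv(
    sets: Sequence[PartialResidualSet], path: str | Path
) -> None:
    """Export (pair id, subset, hamm, partial residual) rows as CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pair_id", "subset", "hamm", "partial_residual"])
        for s in sets:
            for pid, h, pr in zip(s.pair_index, s.hamm, s.partial_residuals):
                w.writerow([pid, s.subset, f"{h:g}", f"{pr:.10g}"])
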