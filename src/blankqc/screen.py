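"""Blank-based feature screening: informative / contaminant / carry-over.

Extraction blanks contain no biological matrix, so any feature they share
with the samples is background (plasticizers, solvent impurities,
autosampler carry-over) or column carry-over.  A feature is retained as
*informative* when all three clean-up conditions hold on the
drift-corrected table:

(i)   min(area in biological samples) / max(area in blanks) > 9;
(ii)  more than 90% of biological replicates exceed 9 x max(blank);
(iii) RSD of the reference (QC) injections < 20% after correction.

Column carry-over is material retained on the column that elutes over the
blanks and early post-blank samples: a *carry-over +k* feature (k = 1..3)
is detected in blanks 1..k but not k+1..3, absent from post-blank samples
1..k, and detected in samples k+1..8, consistently across the intense
(3-blank) cycles.  Features shared between samples and blanks without that
sequential pattern are *contaminants*; everything else is *excluded*.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import PeakTable
from .svrc import reference_orders, rsd

__all__ = [
    "ScreenError",
    "clean_up_conditions",
    "classify_carryover",
    "classify_features",
    "screen_table",
]

LABELS = (
    "informative",
    "contaminant",
    "carryover+1",
    "carryover+2",
    "carryover+3",
    "excluded",
)

BLANK_RATIO_THRESHOLD = 9.0
COVERAGE_THRESHOLD = 0.90
QC_RSD_THRESHOLD = 20.0


class ScreenError(ValueError):
    """Raised when the table cannot be screened (e.g. no blanks)."""


def clean_up_conditions(
    table: PeakTable,
    blank_ratio_threshold: float = BLANK_RATIO_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    qc_rsd_threshold: float = QC_RSD_THRESHOLD,
    include_qc_as_samples: bool = False,
    reference_j: int = 1,
) -> pd.DataFrame:
    """Evaluate the three clean-up conditions per feature.

    Expects a drift-corrected table (condition iii reads "RSD(QCs) < 20%
    after batch effect correction").  "Biological samples" are the
    sample-class injections; leading QCs count only when
    ``include_qc_as_samples`` is set.  All inequalities are strict: a
    blank ratio of exactly 9 fails (i), coverage of exactly 90% fails (ii).
    """
    seq = table.sequence
    blank_cols = seq.index[seq["sample_class"] == "blank"]
    if len(blank_cols) == 0:
        raise ScreenError("no blank injections: clean-up conditions i-ii undefined")
    classes = ["sample", "QC"] if include_qc_as_samples else ["sample"]
    sample_cols = seq.index[seq["sample_class"].isin(classes)]
    refs = reference_orders(table, j=reference_j)

    a_samp = table.area[sample_cols].to_numpy(dtype=float)
    a_blank = table.area[blank_cols].to_numpy(dtype=float)
    max_blank = a_blank.max(axis=1)
    min_samp = a_samp.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(max_blank > 0, min_samp / max_blank, np.inf)
    cond_i = ratio > blank_ratio_threshold
    coverage = (a_samp > blank_ratio_threshold * max_blank[:, None]).mean(axis=1)
    cond_ii = coverage > coverage_threshold
    qc_rsd = table.area[refs].apply(rsd, axis=1).to_numpy(dtype=float)
    cond_iii = qc_rsd < qc_rsd_threshold

    return pd.DataFrame(
        {
            "cond_i": cond_i,
            "cond_ii": cond_ii,
            "cond_iii": cond_iii,
            "blank_ratio": ratio,
            "coverage_fraction": coverage,
            "qc_rsd": qc_rsd,
        },
        index=table.feature_ids,
    )


def _cycle_pattern_matches(det_blanks, det_samples, k: int) -> bool:
    """+k pattern within one intense cycle.

    Detected in blanks 1..k, absent from blanks k+1.., absent from
    post-blank samples 1..k, detected in samples k+1 onward.
    """
    nb, ns = len(det_blanks), len(det_samples)
    if k > nb or k >= ns:
        return False
    return (
        det_blanks[:k].all()
        and not det_blanks[k:].any()
        and not det_samples[:k].any()
        and det_samples[k:].all()
    )


def classify_carryover(
    detected: pd.DataFrame,
    sequence: pd.DataFrame,
    match_fraction: float = 1.0,
) -> pd.Series:
    """Carry-over order per feature (1/2/3) or 0 for no sequential pattern.

    Patterns are evaluated per intense (3-blank) cycle on the pre-fill
    detection mask; a feature is labelled +k when the +k pattern holds in
    at least ``match_fraction`` of the intense cycles (default: all of
    them).  Mild cycles carry no information about blanks 2 and 3 and are
    ignored here.
    """
    intense = sequence[(sequence["cycle_type"] == "intense")]
    cycle_ids = intense["cycle_id"].unique()
    out = pd.Series(0, index=detected.index, name="carryover_order")
    if len(cycle_ids) == 0:
        warnings.warn("no intense (3-blank) cycles: carry-over patterns undefined",
                      stacklevel=2)
        return out

    cycles = []
    for cid in cycle_ids:
        grp = intense[intense["cycle_id"] == cid]
        blanks = grp.index[grp["sample_class"] == "blank"]
        samples = grp.index[grp["sample_class"] == "sample"]
        cycles.append((blanks, samples))

    det = detected.to_numpy(dtype=bool)
    col_pos = {c: i for i, c in enumerate(detected.columns)}
    for fi in range(det.shape[0]):
        frac = {}
        for k in (1, 2, 3):
            hits = sum(
                _cycle_pattern_matches(
                    det[fi, [col_pos[c] for c in blanks]],
                    det[fi, [col_pos[c] for c in samples]],
                    k,
                )
                for blanks, samples in cycles
            )
            frac[k] = hits / len(cycles)
        best_k = max(frac, key=lambda k: (frac[k], -k))
        if frac[best_k] >= match_fraction and frac[best_k] > 0:
            out.iloc[fi] = best_k
    return out


def classify_features(
    table: PeakTable,
    conditions: pd.DataFrame,
    carryover_order: pd.Series,
) -> pd.DataFrame:
    """Assign the final label per feature.

    Precedence: informative (all three conditions) > carry-over +k >
    contaminant (detected in at least one blank and one sample) > excluded.
    """
    seq = table.sequence
    blank_cols = seq.index[seq["sample_class"] == "blank"]
    sample_cols = seq.index[seq["sample_class"] == "sample"]
    in_blank = table.detected[blank_cols].any(axis=1)
    in_sample = table.detected[sample_cols].any(axis=1)

    informative = conditions["cond_i"] & conditions["cond_ii"] & conditions["cond_iii"]
    label = pd.Series("excluded", index=table.feature_ids, name="label")
    label[in_blank & in_sample] = "contaminant"
    for k in (1, 2, 3):
        label[(carryover_order == k) & ~informative] = f"carryover+{k}"
    label[informative] = "informative"

    out = conditions.copy()
    out.insert(0, "label", label)
    out["carryover_order"] = carryover_order
    out.index.name = "feature_id"
    return out


def screen_table(
    table: PeakTable,
    match_fraction: float = 1.0,
    **condition_kwargs,
) -> pd.DataFrame:
    """Run conditions, carry-over patterning and final labelling in one call."""
    conditions = clean_up_conditions(table, **condition_kwargs)
    carry = classify_carryover(table.detected, table.sequence, match_fraction)
    return classify_features(table, conditions, carry)
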