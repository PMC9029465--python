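"""ChIP-qPCR fold enrichment and qPCR relative expression from Ct tables.

Both quantities come from threshold-cycle (Ct) arithmetic at an assumed
amplification efficiency of 2 (perfect doubling per cycle; the efficiency is
exposed as a parameter but primer efficiencies close to 100% justify the
default):

* fold enrichment of a ChIP pulldown over the non-immune IgG control:
  ``E**(Ct_IgG - Ct_sample)``
* relative expression by the delta-delta-Ct method:
  ``E**-[(Ct_target - Ct_ref) - (Ct_target,cal - Ct_ref,cal)]``

Replicate summarization follows standard practice: the point estimate is
computed from replicate-mean Cts (geometric-mean of folds), while
per-replicate fold values are used only for dispersion (SEM = sd/sqrt(n),
undefined at n = 1).

Tables are plain CSV with columns ``sample_id, condition, target,
replicate, ct``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "CtTableError",
    "MissingRoleError",
    "read_ct_table",
    "fold_enrichment",
    "relative_expression",
    "summarize_enrichment",
    "summarize_expression",
]

REQUIRED_COLUMNS = ["sample_id", "condition", "target", "replicate", "ct"]


class CtTableError(ValueError):
    """Malformed Ct table."""


class MissingRoleError(CtTableError):
    """A condition lacks measurements for a required role."""

    def __init__(self, role: str, condition: str):
        self.role = role
        self.condition = condition
        super().__init__(f"missing role {role} for condition {condition}")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CtTableError(f"Ct table lacks required columns: {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    bad = table[~np.isfinite(ct) | (ct <= 0)]
    if len(bad):
        raise CtTableError(
            f"non-finite or non-positive ct values in rows {list(bad.index[:5])}"
        )
    out = table.copy()
    out["ct"] = ct.astype(float)
    return out


def read_ct_table(path: "str | Path") -> pd.DataFrame:
    """Read and validate a Ct CSV table."""
    return _validate(pd.read_csv(path))


def fold_enrichment(sample_ct: float, igg_ct: float, efficiency: float = 2.0) -> float:
    """Fold enrichment of a ChIP sample over the IgG control: E**(IgG - sample)."""
    return float(efficiency ** (igg_ct - sample_ct))


def relative_expression(
    target_ct: float,
    ref_ct: float,
    calibrator_target_ct: float,
    calibrator_ref_ct: float,
    efficiency: float = 2.0,
) -> float:
    """Delta-delta-Ct fold change of a sample versus the calibrator."""
    ddct = (target_ct - ref_ct) - (calibrator_target_ct - calibrator_ref_ct)
    return float(efficiency ** (-ddct))


def _condition_order(table: pd.DataFrame) -> list[str]:
    return list(dict.fromkeys(table["condition"]))


def _paired_cts(
    table: pd.DataFrame, condition: str, target_a: str, target_b: str
) -> pd.DataFrame:
    """Replicate-paired Cts of two targets within one condition."""
    sub = table[table["condition"] == condition]
    a = sub[sub["target"] == target_a][["replicate", "ct"]].rename(columns={"ct": "ct_a"})
    b = sub[sub["target"] == target_b][["replicate", "ct"]].rename(columns={"ct": "ct_b"})
    return a.merge(b, on="replicate", how="inner").sort_values("replicate")


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def summarize_enrichment(
    table: pd.DataFrame,
    chip_target: str,
    igg_target: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-condition ChIP fold enrichment with replicate dispersion.

    Returns a frame with columns ``condition, fold_enrichment, n, sem``.
    The point estimate uses replicate-mean Cts; SEM comes from per-replicate
    fold values (replicates paired by index) and is NaN when n = 1.
    Conditions missing either target raise :class:`MissingRoleError`.
    """
    table = _validate(table)
    rows = []
    for condition in _condition_order(table):
        sub = table[table["condition"] == condition]
        for role, target in (("chip_target", chip_target), ("igg", igg_target)):
            if not (sub["target"] == target).any():
                raise MissingRoleError(role, condition)
        chip_mean = sub.loc[sub["target"] == chip_target, "ct"].mean()
        igg_mean = sub.loc[sub["target"] == igg_target, "ct"].mean()
        point = fold_enrichment(chip_mean, igg_mean, efficiency)
        pairs = _paired_cts(table, condition, chip_target, igg_target)
        folds = efficiency ** (pairs["ct_b"].to_numpy() - pairs["ct_a"].to_numpy())
        n = len(folds)
        if n == 0:
            raise CtTableError(
                f"no replicate pairing between {chip_target!r} and {igg_target!r} "
                f"for condition {condition!r}"
            )
        rows.append(
            {"condition": condition, "fold_enrichment": point, "n": n, "sem": _sem(folds)}
        )
    return pd.DataFrame(rows, columns=["condition", "fold_enrichment", "n", "sem"])


def summarize_expression(
    table: pd.DataFrame,
    gene_target: str,
    housekeeping_target: str,
    calibrator_condition: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-condition delta-delta-Ct fold change versus a calibrator condition.

    Returns ``condition, fold_change, n, sem``. The calibrator's own fold
    change, computed from its mean Cts, is exactly 1.
    """
    table = _validate(table)
    conditions = _condition_order(table)
    if calibrator_condition not in conditions:
        raise MissingRoleError("calibrator-condition", calibrator_condition)

    def mean_dct(condition: str) -> float:
        sub = table[table["condition"] == condition]
        for role, target in (("gene", gene_target), ("housekeeping", housekeeping_target)):
            if not (sub["target"] == target).any():
                raise MissingRoleError(role, condition)
        return (
            sub.loc[sub["target"] == gene_target, "ct"].mean()
            - sub.loc[sub["target"] == housekeeping_target, "ct"].mean()
        )

    calibrator_dct = mean_dct(calibrator_condition)
    rows = []
    for condition in conditions:
        dct = mean_dct(condition)
        point = float(efficiency ** (-(dct - calibrator_dct)))
        pairs = _paired_cts(table, condition, gene_target, housekeeping_target)
        rep_dct = pairs["ct_a"].to_numpy() - pairs["ct_b"].to_numpy()
        folds = efficiency ** (-(rep_dct - calibrator_dct))
        n = len(folds)
        if n == 0:
            raise CtTableError(
                f"no replicate pairing between {gene_target!r} and "
                f"{housekeeping_target!r} for condition {condition!r}"
            )
        rows.append(
            {"condition": condition, "fold_change": point, "n": n, "sem": _sem(folds)}
        )
    return pd.DataFrame(rows, columns=["condition", "fold_change", "n", "sem"])
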