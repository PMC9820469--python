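"""Relative RT-qPCR quantification by the comparative Ct (delta-delta-Ct) method.

For each group the target gene's threshold cycle is normalized by a
reference gene (dCt = Ct_target - Ct_reference, averaged over replicates);
the treated-vs-control difference of those differences gives
ddCt = dCt_treated - dCt_control and the fold-change 2**(-ddCt), under the
classic assumption of perfect doubling per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

GROUPS = ("control", "treated")


@dataclass
class CtTable:
    """Threshold cycles: one row per replicate per group."""

    rows: pd.DataFrame  # columns: sample_group, target_ct, reference_ct, replicate

    def __post_init__(self):
        required = {"sample_group", "target_ct", "reference_ct"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"Ct table lacks columns {sorted(missing)}")
        groups = set(self.rows["sample_group"])
        if not set(GROUPS).issubset(groups):
            raise ValidationError(
                f"Ct table needs both groups {GROUPS}, found {sorted(groups)}"
            )
        ct = self.rows[["target_ct", "reference_ct"]].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValidationError("Ct values must be finite and positive")

    @classmethod
    def from_records(cls, records) -> "CtTable":
        """Build from (group, target_ct, reference_ct[, replicate]) tuples."""
        df = pd.DataFrame(records,
                          columns=["sample_group", "target_ct", "reference_ct"])
        df["replicate"] = df.groupby("sample_group").cumcount() + 1
        return cls(rows=df)


def ddct_fold_change(table: CtTable) -> tuple[float, float]:
    """Fold-change of treated vs control: returns (fold, ddct).

    dCt per group is the mean target Ct minus the mean reference Ct;
    ddCt = dCt_treated - dCt_control; fold = 2**(-ddCt). A fold below 1
    means the target is less expressed in the treated group.
    """
    dct = {}
    for group in GROUPS:
        sub = table.rows[table.rows["sample_group"] == group]
        dct[group] = float(sub["target_ct"].mean() - sub["reference_ct"].mean())
    ddct = dct["treated"] - dct["control"]
    return 2.0 ** (-ddct), ddct


def per_replicate_folds(table: CtTable) -> pd.DataFrame:
    """Per-replicate treated fold-changes against the mean control dCt.

    Returns replicate-level 2**(-ddCt) values with their mean and SD, for
    plotting error bars around the group estimate.
    """
    control = table.rows[table.rows["sample_group"] == "control"]
    dct_control = float(control["target_ct"].mean() - control["reference_ct"].mean())
    treated = table.rows[table.rows["sample_group"] == "treated"].copy()
    treated["dct"] = treated["target_ct"] - treated["reference_ct"]
    treated["fold"] = 2.0 ** (-(treated["dct"] - dct_control))
    return treated[["replicate", "fold"]].reset_index(drop=True)
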