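"""Relative expression (2^-ddCt) and MTT viability quantification.

The Livak 2^-ddCt method expresses a target transcript relative to a
reference gene and a control group:

    dCt   = Ct(target) - Ct(reference)          per biological replicate
    ddCt  = dCt(treated) - mean dCt(control)
    fold  = 2 ** (-ddCt)

Technical replicates are averaged on the Ct scale first.  Group
statistics (one-way ANOVA with Tukey HSD contrasts versus the control,
and a Lilliefors-corrected Kolmogorov-Smirnov normality check) run on
dCt values, which are approximately normal, not on folds.  Reported
fold change and SD are the mean and standard deviation across
biological replicates on the fold scale.

MTT viability uses background-corrected absorbance (570 nm signal minus
630 nm reference) of treated wells as a percentage of control wells at
the matching timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import InsufficientDataError, NormalizationError

CT_COLUMNS = ["sample", "group", "bio_rep", "tech_rep", "assay", "ct"]
VIABILITY_COLUMNS = ["group", "timepoint_h", "well", "a570", "a630"]

#: p-value cutoffs for the significance tiers used in figure legends.
TIER_CUTOFFS = ((0.01, "**"), (0.05, "*"))


def significance_tier(p_value: float) -> str:
    """Map a p-value to 'ns', '*' (p<0.05) or '**' (p<0.01)."""
    if np.isnan(p_value):
        return "ns"
    for cutoff, label in TIER_CUTOFFS:
        if p_value < cutoff:
            return label
    return "ns"


@dataclass(frozen=True)
class FoldChangeResult:
    assay: str
    group: str
    fold_change: float
    sd: float
    p_value: float
    tier: str
    n_replicates: int
    sd_defined: bool


def read_ct_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a long-format Ct table (sample, group, bio_rep, tech_rep, assay, ct)."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise NormalizationError(f"{path}: missing Ct column(s) {missing}")
    df["ct"] = df["ct"].astype(float)
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise NormalizationError("Ct values must be positive and finite")
    return df


def _delta_ct(ct: pd.DataFrame, target_assay: str, reference_assay: str) -> pd.DataFrame:
    """dCt per biological replicate, technical replicates averaged first."""
    mean_ct = (
        ct.groupby(["group", "bio_rep", "assay"], as_index=False)["ct"].mean()
    )
    wide = mean_ct.pivot(index=["group", "bio_rep"], columns="assay", values="ct")
    if reference_assay not in wide.columns or wide[reference_assay].isna().any():
        raise NormalizationError(
            f"reference assay {reference_assay!r} missing for some replicate"
        )
    if target_assay not in wide.columns:
        raise NormalizationError(f"target assay {target_assay!r} absent from table")
    out = (wide[target_assay] - wide[reference_assay]).dropna().rename("dct")
    return out.reset_index()


def ddct_fold_change(
    ct: pd.DataFrame,
    target_assay: str,
    reference_assay: str,
    control_group: str,
) -> list[FoldChangeResult]:
    """2^-ddCt fold change of every treated group versus the control.

    Returns one :class:`FoldChangeResult` per non-control group, with
    mean and SD of per-replicate folds and a Tukey HSD p-value versus
    the control computed on dCt values (NaN when either side has a
    single replicate).
    """
    dct = _delta_ct(ct, target_assay, reference_assay)
    groups = dct.groupby("group")["dct"].apply(list).to_dict()
    if control_group not in groups:
        raise NormalizationError(f"control group {control_group!r} absent")
    control_mean = float(np.mean(groups[control_group]))

    p_by_group: dict[str, float] = {}
    testable = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(testable) >= 2 and control_group in testable:
        try:
            _, p_by_group = group_compare(testable, control_group)
        except InsufficientDataError:
            p_by_group = {}

    results = []
    for group, values in groups.items():
        if group == control_group:
            continue
        folds = 2.0 ** -(np.asarray(values) - control_mean)
        n = len(folds)
        sd_defined = n >= 2
        results.append(
            FoldChangeResult(
                assay=target_assay,
                group=group,
                fold_change=float(np.mean(folds)),
                sd=float(np.std(folds, ddof=1)) if sd_defined else float("nan"),
                p_value=p_by_group.get(group, float("nan")),
                tier=significance_tier(p_by_group.get(group, float("nan"))),
                n_replicates=n,
                sd_defined=sd_defined,
            )
        )
    return results


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    control_group: str | None = None,
) -> tuple[float, dict[str, float]]:
    """One-way ANOVA omnibus p-value plus Tukey HSD contrasts.

    Returns ``(anova_p, {group: tukey_p versus control})``; the control
    defaults to the first group in mapping order.  Contrasts are meant
    to run on dCt values, not folds.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise InsufficientDataError("group comparison needs at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise InsufficientDataError("every group needs at least two observations")
    if all(np.ptp(a) == 0 for a in arrays) and len(set(a[0] for a in arrays)) == 1:
        raise InsufficientDataError("all observations identical: ANOVA undefined")
    control = control_group if control_group is not None else names[0]
    if control not in names:
        raise InsufficientDataError(f"control group {control!r} not supplied")
    # zero within-group variance (noiseless synthetic data) makes the test
    # statistics infinite; the p-values degenerate to 0 as intended
    with np.errstate(divide="ignore", invalid="ignore"):
        anova_p = float(stats.f_oneway(*arrays).pvalue)
        tukey = stats.tukey_hsd(*arrays)
    ci = names.index(control)
    p_vs_control = {
        g: float(tukey.pvalue[ci, j]) for j, g in enumerate(names) if g != control
    }
    return anova_p, p_vs_control


def normality_check(values: Sequence[float]) -> float:
    """Kolmogorov-Smirnov normality p-value with the Lilliefors
    correction for estimated mean and variance.  Requires n >= 4 and a
    non-constant sample."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 4:
        raise InsufficientDataError("normality check needs at least 4 observations")
    if np.ptp(arr) == 0:
        raise InsufficientDataError("constant sample: normality test undefined")
    _, p = lilliefors(arr, dist="norm")
    return float(p)


def read_viability_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a long-format MTT absorbance table
    (group, timepoint_h, well, a570, a630)."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in VIABILITY_COLUMNS if c not in df.columns]
    if missing:
        raise NormalizationError(f"{path}: missing column(s) {missing}")
    return df


def viability_percent(
    viability: pd.DataFrame, control_group: str
) -> pd.DataFrame:
    """Background-corrected viability percentage per group x timepoint.

    signal = a570 - a630 per well; viability% = 100 * mean treated
    signal / mean control signal at the matching timepoint.  Wells with
    negative corrected signal are kept but flagged in ``n_flagged``.
    """
    df = viability.copy()
    df["signal"] = df["a570"].astype(float) - df["a630"].astype(float)
    grouped = df.groupby(["group", "timepoint_h"])["signal"]
    means = grouped.mean().rename("mean_signal").reset_index()
    flagged = (
        df.assign(neg=df["signal"] < 0)
        .groupby(["group", "timepoint_h"])["neg"]
        .sum()
        .rename("n_flagged")
        .reset_index()
    )
    means = means.merge(flagged, on=["group", "timepoint_h"])
    control = means[means["group"] == control_group].set_index("timepoint_h")[
        "mean_signal"
    ]
    if len(control) == 0:
        raise NormalizationError(f"control group {control_group!r} absent")
    if (control <= 0).any():
        raise NormalizationError("control mean signal is non-positive")
    out = means.copy()
    ctrl_at_t = out["timepoint_h"].map(control)
    if ctrl_at_t.isna().any():
        raise NormalizationError("control group missing at some timepoint")
    out["viability_percent"] = 100.0 * out["mean_signal"] / ctrl_at_t
    return out.sort_values(["group", "timepoint_h"], ignore_index=True)
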