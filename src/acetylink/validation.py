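"""qPCR arithmetic (2^-ddCt fold enrichment) and two-group tests.

ddCt per sample = (Ct_target - Ct_reference) - mean ddCt-baseline of the
control group, so the control group's mean fold is exactly 1.  Group
comparison is a Welch t-test (Satterthwaite degrees of freedom) by
default, with the pooled-variance Student variant behind a flag.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def ddct_fold(records: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-sample fold = 2^-ddCt against the control-group baseline.

    ``records`` needs columns sample, group, ct_target, ct_reference (and
    optionally target, in which case each target is baselined separately).
    Samples with a missing Ct are excluded with a warning.  By
    construction, mean(ddCt) over the control group is 0, so the
    control-group mean fold is exactly 1 on the log scale.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    df = records.copy()
    bad = df["ct_target"].isna() | df["ct_reference"].isna()
    if bad.any():
        log.warning("excluding %d record(s) with missing Ct", int(bad.sum()))
        df = df[~bad]
    if not (df["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} is empty")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    key = ["target"] if "target" in df.columns else []
    out = []
    for _, sub in df.groupby(key) if key else [((), df)]:
        baseline = sub.loc[sub["group"] == control_group, "dct"].mean()
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - baseline
        sub["fold"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray,
                 equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t-test: returns (t, df, p).

    Welch with Satterthwaite df by default; ``equal_var=True`` gives the
    pooled-variance Student test.  Two constant, equal groups give
    t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(na + nb - 2), 0.0
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (a.mean() - b.mean()) / se
    p = 2.0 * float(stats.t.sf(abs(t), df=df))
    return float(t), float(df), min(p, 1.0)


def significance_stars(p: float) -> str:
    """Figure-caption star labels with closed boundaries."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def qpcr_summary(folds: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-target group means, Welch test and star label."""
    key = ["target"] if "target" in folds.columns else []
    rows = []
    groups = [g for g in folds["group"].unique() if g != control_group]
    for tgt, sub in folds.groupby(key) if key else [((), folds)]:
        ctrl = sub.loc[sub["group"] == control_group, "fold"].to_numpy()
        for g in groups:
            trt = sub.loc[sub["group"] == g, "fold"].to_numpy()
            t, df, p = welch_t_test(ctrl, trt)
            rows.append(
                {
                    "target": tgt[0] if key else "",
                    "group": g,
                    "control_mean_fold": ctrl.mean(),
                    "mean_fold": trt.mean(),
                    "t": t,
                    "df": df,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)
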