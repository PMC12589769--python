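"""Baseline normalization and discriminant-score feature selection.

Descriptor time series are first normalized per well: every post-baseline
session is divided, feature by feature, by the same well's mean value at the
0h (pre-treatment) session, which cancels inter-culture heterogeneity. The
0h rows are consumed as baseline only and never analyzed.

For each session, each (feature, within-segment time offset) cell receives a
discriminant score DS = max(AUC, 1 - AUC), where AUC is the tie-corrected
rank (Mann-Whitney) estimate of the probability that the feature separates
the two conditions at that offset, pooling all wells. Selection is two-step:
keep the time offsets whose DS (max over features) exceeds the 95th
percentile of the overall DS distribution, then keep the features whose DS
exceeds 0.75 at at least one selected offset. Both inequalities are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError

logger = logging.getLogger(__name__)

BASELINE_SESSION = "0h"
DEFAULT_PERCENTILE = 95.0
DEFAULT_DS_CUT = 0.75


def baseline_normalize(features: pd.DataFrame, feature_cols: list) -> pd.DataFrame:
    """Divide each well's post-baseline rows by its 0h per-feature mean.

    Returns only the post-baseline rows. A feature whose 0h mean is zero for
    some well is coded NaN for that well (excluded rather than rescaled) and
    logged. Wells without a 0h session are rejected.
    """
    out_blocks = []
    for well, group in features.groupby("well_id", sort=False):
        base = group[group["session"] == BASELINE_SESSION]
        if base.empty:
            raise DataError(f"well {well!r} has no {BASELINE_SESSION} baseline session")
        base_mean = base[feature_cols].mean(axis=0)
        zero = base_mean[base_mean == 0].index
        if len(zero):
            logger.warning("well %s: zero 0h baseline for %s; coded unusable",
                           well, list(zero))
        rest = group[group["session"] != BASELINE_SESSION].copy()
        rest[feature_cols] = rest[feature_cols] / base_mean
        rest.loc[:, list(zero)] = np.nan
        out_blocks.append(rest)
    return pd.concat(out_blocks, ignore_index=True)


def ds_score(values_class0: np.ndarray, values_class1: np.ndarray) -> tuple[float, float]:
    """(AUC, DS) of a feature between two classes.

    AUC is the rank-based (Mann-Whitney) estimator with tie correction: the
    probability that a class-1 value ranks above a class-0 value, counting
    ties as 1/2. DS = max(AUC, 1 - AUC) maps it to [0.5, 1] so a unilateral
    threshold can be applied regardless of effect direction.
    """
    x0 = np.asarray(values_class0, dtype=np.float64)
    x1 = np.asarray(values_class1, dtype=np.float64)
    if x0.size == 0 or x1.size == 0:
        raise DataError("both classes must be nonempty")
    ranks = rankdata(np.concatenate([x0, x1]))
    r1 = ranks[x0.size:].sum()
    auc = (r1 - x1.size * (x1.size + 1) / 2) / (x0.size * x1.size)
    return float(auc), float(max(auc, 1.0 - auc))


@dataclass
class SelectionResult:
    """Outcome of the two-step selection for one session."""

    session: str
    offsets: list
    features: list
    percentile: float = DEFAULT_PERCENTILE
    ds_cut: float = DEFAULT_DS_CUT

    def to_dict(self) -> dict:
        return {"session": self.session, "offsets": list(map(int, self.offsets)),
                "features": list(self.features),
                "thresholds": {"percentile": self.percentile, "ds_cut": self.ds_cut}}


def ds_table(norm_features: pd.DataFrame, feature_cols: list,
             session: str, positive_class: str = "VPA") -> pd.DataFrame:
    """DS per (feature, time offset) for one session, pooling all wells.

    Returns a tidy table (session, feature, time_offset, auc, ds). Cells
    where either class is empty or a feature is unusable (NaN) are skipped.
    """
    rows = []
    sdf = norm_features[norm_features["session"] == session]
    if sdf.empty:
        raise DataError(f"no rows for session {session!r}")
    for off, odf in sdf.groupby("time_offset", sort=True):
        mask1 = odf["condition"] == positive_class
        for feat in feature_cols:
            v0 = odf.loc[~mask1, feat].dropna().to_numpy()
            v1 = odf.loc[mask1, feat].dropna().to_numpy()
            if v0.size == 0 or v1.size == 0:
                continue
            auc, ds = ds_score(v0, v1)
            rows.append({"session": session, "feature": feat,
                         "time_offset": int(off), "auc": auc, "ds": ds})
    if not rows:
        raise DataError("DS table is empty (no comparable cells)")
    return pd.DataFrame(rows)


def select_time_points(ds: pd.DataFrame, percentile: float = DEFAULT_PERCENTILE,
                       agg: str = "max") -> list:
    """Offsets whose aggregated DS strictly exceeds the given percentile of
    the overall (feature x offset) DS distribution.

    ``agg`` chooses the across-feature aggregator per offset (max or mean).
    """
    if agg not in ("max", "mean"):
        raise DataError("agg must be 'max' or 'mean'")
    cutoff = float(np.percentile(ds["ds"].to_numpy(), percentile))
    per_offset = ds.groupby("time_offset")["ds"].agg(agg)
    selected = sorted(int(o) for o, v in per_offset.items() if v > cutoff)
    if not selected:
        logger.warning("degenerate DS landscape: no offset exceeds the %gth percentile",
                       percentile)
    return selected


def select_features(ds: pd.DataFrame, offsets: list,
                    cut: float = DEFAULT_DS_CUT) -> list:
    """Features whose DS strictly exceeds the cut at >= 1 selected offset.

    Returned in the order of first appearance in the DS table.
    """
    sub = ds[ds["time_offset"].isin(offsets) & (ds["ds"] > cut)]
    features = list(dict.fromkeys(sub["feature"]))
    if not features:
        logger.warning("no feature exceeds DS %g at the selected offsets", cut)
    return features


def select(norm_features: pd.DataFrame, feature_cols: list, session: str,
           percentile: float = DEFAULT_PERCENTILE, ds_cut: float = DEFAULT_DS_CUT,
           agg: str = "max") -> tuple[SelectionResult, pd.DataFrame]:
    """Run both selection steps for one session; returns the result and the
    full DS table."""
    ds = ds_table(norm_features, feature_cols, session)
    offsets = select_time_points(ds, percentile=percentile, agg=agg)
    features = select_features(ds, offsets, cut=ds_cut)
    return SelectionResult(session=session, offsets=offsets, features=features,
                           percentile=percentile, ds_cut=ds_cut), ds
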