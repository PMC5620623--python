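"""Paired-significance feature screening.

Every (channel, feature) is reduced to one observation per subject and
state (the mean of that subject's five per-minute values), giving n paired
alert/drowsy observations.  The paired differences are first checked for
normality with a Lilliefors-style Kolmogorov-Smirnov test (parameters
estimated from the sample, null distribution by seeded Monte Carlo); if
normality is not rejected, a paired t-test flags the feature when
p < alpha.  No multiple-testing correction is applied by default, mirroring
the original screening protocol; Benjamini-Hochberg is available as an
option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import DegenerateInputError, ParameterError

DEFAULT_KS_MC_DRAWS = 10_000

_ks_null_cache: dict = {}


def subject_state_means(features: pd.DataFrame) -> pd.DataFrame:
    """Collapse the tidy per-minute table to one value per subject, state
    and (channel, feature) - the paired observation unit.

    Subjects missing either state are excluded with a warning.  Minutes
    flagged missing upstream simply do not appear, so the mean runs over
    the remaining minutes.
    """
    required = {"subject_id", "state", "channel", "feature", "value"}
    if not required.issubset(features.columns):
        raise ParameterError(
            f"feature table needs columns {sorted(required)}"
        )
    means = (
        features
        .groupby(["subject_id", "state", "channel", "feature"],
                 sort=True)["value"]
        .mean()
        .reset_index()
    )
    states_per_subject = means.groupby("subject_id")["state"].nunique()
    incomplete = states_per_subject[states_per_subject < 2].index.tolist()
    if incomplete:
        warnings.warn(
            f"excluding subjects missing a state: {incomplete}",
            stacklevel=2,
        )
        means = means[~means["subject_id"].isin(incomplete)]
    return means


def _lilliefors_stat(values: np.ndarray) -> float:
    """KS distance between the sample ECDF and a normal with the sample's
    own mean and SD."""
    x = np.sort(values)
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sp_stats.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def _ks_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _ks_null_cache:
        rng = np.random.default_rng([seed, 1951, n])
        draws = rng.standard_normal((n_mc, n))
        stats = np.empty(n_mc)
        for i in range(n_mc):
            stats[i] = _lilliefors_stat(draws[i])
        _ks_null_cache[key] = np.sort(stats)
    return _ks_null_cache[key]


def ks_normality(values: np.ndarray, n_mc: int = DEFAULT_KS_MC_DRAWS,
                 seed: int = 0) -> tuple[float, float]:
    """Lilliefors-style KS normality test of a small sample.

    Returns ``(statistic, p)``.  The p-value comes from a seeded
    ``n_mc``-draw Monte Carlo null of the statistic (cached per sample
    size).  Identical values are non-normal by convention: returns p = 0.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ParameterError("need >= 3 values for a normality check")
    if x.std(ddof=1) == 0:
        return float("inf"), 0.0
    d = _lilliefors_stat(x)
    null = _ks_null(x.size, n_mc, seed)
    # one-sided exceedance probability with the +1 correction
    n_ge = null.size - np.searchsorted(null, d, side="left")
    p = (n_ge + 1) / (null.size + 1)
    return d, float(p)


def paired_t(alert: np.ndarray, drowsy: np.ndarray) -> dict:
    """Two-sided paired t-test on per-subject values.

    Differences are drowsy - alert, so the sign of t is the direction of
    the drowsiness-related change; df = n - 1.
    """
    a = np.asarray(alert, dtype=np.float64)
    b = np.asarray(drowsy, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("alert/drowsy must be equal-length vectors")
    if a.size < 2:
        raise ParameterError("need >= 2 paired observations (df >= 1)")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(
            "paired differences have zero variance"
        )
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p)}


@dataclass
class SelectionReport:
    """Per-(channel, feature) screening results.

    ``table`` columns: channel, feature, n_subjects, ks_stat, ks_p,
    normality_ok, t, df, p, p_adjusted, direction, significant, note.
    """

    table: pd.DataFrame
    alpha: float
    correction: str
    ks_seed: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def significant_pairs(self) -> list[tuple[str, str]]:
        return list(map(tuple, self.significant[["channel", "feature"]]
                        .itertuples(index=False, name=None)))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "correction": self.correction,
            "ks_seed": self.ks_seed,
            "features": self.table.to_dict(orient="records"),
        }
        import json
        from pathlib import Path
        Path(path).write_text(json.dumps(payload, indent=2))


def select(features: pd.DataFrame, alpha: float = 0.05,
           correction: str = "none", ks_alpha: float = 0.05,
           ks_seed: int = 0,
           ks_mc_draws: int = DEFAULT_KS_MC_DRAWS) -> SelectionReport:
    """Screen every (channel, feature) for a significant paired
    alert-vs-drowsy difference across subjects.

    A feature is flagged significant when its paired differences pass the
    KS normality gate (p >= ks_alpha) and the paired t-test gives
    p < alpha (after the optional Benjamini-Hochberg correction).
    Degenerate features (zero-variance differences) are reported but never
    significant.
    """
    if correction not in ("none", "bh"):
        raise ParameterError("correction must be 'none' or 'bh'")
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("alpha must lie in [0, 1]")
    means = subject_state_means(features)
    wide = means.pivot_table(
        index=["channel", "feature", "subject_id"], columns="state",
        values="value",
    )
    rows = []
    for (channel, feature), grp in wide.groupby(level=["channel", "feature"]):
        grp = grp.dropna()
        if grp.empty or not {"alert", "drowsy"}.issubset(grp.columns):
            continue
        alert = grp["alert"].to_numpy()
        drowsy = grp["drowsy"].to_numpy()
        n = alert.size
        row = {"channel": channel, "feature": feature, "n_subjects": n}
        if n < 2:
            raise DegenerateInputError(
                f"feature ({channel}, {feature}) has a single paired "
                "observation: df = 0 is forbidden"
            )
        diffs = drowsy - alert
        try:
            ks_stat, ks_p = ks_normality(diffs, n_mc=ks_mc_draws,
                                         seed=ks_seed)
            row.update(ks_stat=ks_stat, ks_p=ks_p,
                       normality_ok=ks_p >= ks_alpha)
        except ParameterError:
            row.update(ks_stat=float("nan"), ks_p=float("nan"),
                       normality_ok=False)
        try:
            tt = paired_t(alert, drowsy)
            row.update(t=tt["t"], df=tt["df"], p=tt["p"],
                       direction=int(np.sign(tt["t"])), note="")
        except DegenerateInputError:
            row.update(t=float("nan"), df=n - 1, p=float("nan"),
                       direction=0, note="degenerate: zero-variance diffs",
                       normality_ok=False)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ParameterError("no testable (channel, feature) pairs")

    pvals = table["p"].to_numpy()
    if correction == "bh":
        finite = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if finite.any():
            adj[finite] = sp_stats.false_discovery_control(pvals[finite],
                                                           method="bh")
        table["p_adjusted"] = adj
    else:
        table["p_adjusted"] = pvals
    table["significant"] = (
        table["normality_ok"]
        & np.isfinite(table["p_adjusted"])
        & (table["p_adjusted"] < alpha)
    )
    table = table.sort_values(["channel", "feature"]).reset_index(drop=True)
    return SelectionReport(table=table, alpha=alpha, correction=correction,
                           ks_seed=ks_seed)
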