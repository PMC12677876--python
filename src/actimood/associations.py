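"""Categorical association statistics between activity extremes and
mood/energy severity.

Group comparisons use Kruskal-Wallis with pairwise Mann-Whitney U tests at
a Bonferroni-corrected threshold (default .004, taken as an input rather
than derived). Activity features are binned into equal-frequency quartiles;
severity categories come from :func:`actimood.met.categorize_severity`.
Association strength is the Pearson chi-square (no continuity correction)
with the Cramér V effect size, sqrt(chi2 / (n * (min(r, c) - 1))), without
bias correction, labelled by the conventional cut-offs (boundaries assigned
to the lower label): negligible [0, .1], weak (.1, .2], moderate (.2, .3],
strong (> .3).

``AssociationAnalysis`` is the model object: construct it from the daily
feature, daily MET and patient tables, call :meth:`~AssociationAnalysis.fit`
and inspect the returned :class:`AssociationResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BinningDegenerateError,
    DegenerateInputError,
    EffectSizeDomainError,
)

log = logging.getLogger(__name__)

#: The eight extremal-window features tested against severity categories.
WINDOW_FEATURES = [f"max{i}" for i in range(1, 5)] + [f"min{i}" for i in range(1, 5)]

#: Severity-category columns of the daily MET table.
SEVERITY_VARIABLES = [
    "mood_pos_max_class", "mood_pos_min_class",
    "mood_neg_max_class", "mood_neg_min_class", "mood_range_class",
    "energy_pos_max_class", "energy_pos_min_class",
    "energy_neg_max_class", "energy_neg_min_class", "energy_range_class",
]

EFFECT_LABELS = ("negligible", "weak", "moderate", "strong")


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Rank-based H with tie correction; p from the chi-square approximation."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise DegenerateInputError("Kruskal-Wallis needs >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise DegenerateInputError("every group needs >= 1 observation")
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def pairwise_mannwhitney(
    values, groups, corrected_alpha: float = 0.004
) -> pd.DataFrame:
    """Two-sided U per group pair (normal approximation with tie/continuity
    correction); the significance flag is the strict inequality
    ``p < corrected_alpha``. Empty groups are skipped with a warning."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise DegenerateInputError("pairwise tests need >= 2 groups")
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            xa, xb = values[groups == a], values[groups == b]
            if len(xa) == 0 or len(xb) == 0:
                warnings.warn(f"skipping empty pair ({a}, {b})")
                continue
            res = stats.mannwhitneyu(
                xa, xb, alternative="two-sided", method="asymptotic"
            )
            rows.append(
                {"group_a": a, "group_b": b,
                 "u_statistic": float(res.statistic),
                 "p_value": float(res.pvalue),
                 "significant_after_bonferroni": bool(
                     res.pvalue < corrected_alpha
                 )}
            )
    return pd.DataFrame(rows)


def quartile_bin(values) -> np.ndarray:
    """Equal-frequency quartile bins 1-4 (1 = lowest).

    Ties are resolved by rank order (``rank(method="first")``) before
    ``pandas.qcut``, which guarantees bin counts differing by at most 1.
    Fewer than 4 distinct values is a degenerate error.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if s.isna().any():
        raise BinningDegenerateError("missing values cannot be binned")
    if s.nunique() < 4:
        raise BinningDegenerateError(
            f"need >= 4 distinct values, got {s.nunique()}"
        )
    return (
        pd.qcut(s.rank(method="first"), 4, labels=False).to_numpy() + 1
    )


def chi_square_association(bins, severity) -> tuple[float, int, float]:
    """Pearson chi-square on the bins x severity table, no Yates correction.

    Empty rows/columns (e.g. a severity category never observed) are dropped
    and the degrees of freedom computed on the reduced table.
    """
    table = pd.crosstab(pd.Series(bins), pd.Series(severity))
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateInputError(
            f"contingency table too small after reduction: {table.shape}"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p)


def cramers_v(chi2: float, n: int, rows: int, cols: int) -> float:
    """V = sqrt(chi2 / (n * (min(rows, cols) - 1))); no bias correction."""
    if n <= 0:
        raise EffectSizeDomainError("n must be positive")
    if min(rows, cols) < 2:
        raise EffectSizeDomainError("Cramér V undefined for min(r, c) < 2")
    return float(np.sqrt(chi2 / (n * (min(rows, cols) - 1))))


def effect_size_label(v: float) -> str:
    """Conventional label for V; boundary values take the lower label."""
    if not 0.0 <= v <= 1.0:
        raise EffectSizeDomainError(f"Cramér V must be in [0, 1], got {v}")
    if v <= 0.1:
        return "negligible"
    if v <= 0.2:
        return "weak"
    if v <= 0.3:
        return "moderate"
    return "strong"


def variability_summary(
    df: pd.DataFrame, value_cols, group_col: str = "group"
) -> pd.DataFrame:
    """Sample SD (ddof=1) and IQR (linear quantile interpolation) per
    variable per group."""
    rows = []
    for g, sub in df.groupby(group_col):
        for col in value_cols:
            x = sub[col].dropna().to_numpy(dtype=float)
            if len(x) < 2:
                continue
            q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
            rows.append(
                {"group": g, "variable": col,
                 "sd": float(np.std(x, ddof=1)), "iqr": float(q3 - q1)}
            )
    return pd.DataFrame(rows)


def group_comparisons(
    met_daily: pd.DataFrame,
    patients: pd.DataFrame,
    variables=None,
    corrected_alpha: float = 0.004,
) -> pd.DataFrame:
    """Kruskal-Wallis + pairwise Mann-Whitney for each MET variable across
    diagnostic groups, in one tidy table."""
    variables = variables or [
        c for c in met_daily.columns
        if c.startswith(("mood_", "energy_")) and not c.endswith(("_class", "present"))
    ]
    merged = met_daily.merge(
        patients[["patient_id", "group"]], on="patient_id"
    )
    rows = []
    for var in variables:
        sub = merged[[var, "group"]].dropna()
        h, p = kruskal_wallis(sub[var], sub["group"])
        pw = pairwise_mannwhitney(sub[var], sub["group"], corrected_alpha)
        rows.append({"variable": var, "h_statistic": h, "p_value": p,
                     "n_pairs_significant": int(
                         pw["significant_after_bonferroni"].sum()
                     )})
        for r in pw.itertuples(index=False):
            rows.append({"variable": var, "h_statistic": np.nan,
                         "p_value": r.p_value, "group_a": r.group_a,
                         "group_b": r.group_b, "u_statistic": r.u_statistic,
                         "significant_after_bonferroni":
                             r.significant_after_bonferroni})
    return pd.DataFrame(rows)


def group_association_matrix(
    group_df: pd.DataFrame,
    features=None,
    severity_vars=None,
    min_days: int = 50,
) -> pd.DataFrame:
    """Chi-square / Cramér V for every (feature, severity variable) pair in
    one diagnostic group's patient-day table. Quartiles are computed within
    the table passed in (within-group by default in the model object)."""
    features = features or WINDOW_FEATURES
    severity_vars = severity_vars or SEVERITY_VARIABLES
    if len(group_df) < min_days:
        log.info("group skipped: %d days < %d", len(group_df), min_days)
        return pd.DataFrame()
    rows = []
    for feat in features:
        sub = group_df[[feat] + severity_vars].dropna(subset=[feat])
        try:
            bins = quartile_bin(sub[feat])
        except BinningDegenerateError as exc:
            log.info("feature %s dropped: %s", feat, exc)
            continue
        for sev in severity_vars:
            mask = sub[sev].notna().to_numpy()
            try:
                chi2, dof, p = chi_square_association(
                    bins[mask], sub[sev].to_numpy()[mask]
                )
            except DegenerateInputError:
                continue
            table = pd.crosstab(bins[mask], sub[sev][mask])
            table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
            n = int(table.to_numpy().sum())
            v = cramers_v(chi2, n, *table.shape)
            rows.append(
                {"feature": feat, "severity_variable": sev, "chi2": chi2,
                 "dof": dof, "p_value": p, "n": n, "cramers_v": v,
                 "effect_label": effect_size_label(min(v, 1.0))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class AssociationAnalysis:
    """Per-group association model between activity quartiles and severity.

    Parameters
    ----------
    daily_features, met_daily, patients : DataFrame
        Stage outputs keyed by (patient_id, date).
    features, severity_vars : sequences of column names.
    min_days : minimum patient-days for a group to be analysed.
    within_group_binning : bin quartiles within each diagnostic group
        (the default, matching per-group reporting) or pooled.
    """

    def __init__(
        self, daily_features, met_daily, patients,
        features=None, severity_vars=None, min_days: int = 50,
        within_group_binning: bool = True, corrected_alpha: float = 0.004,
    ):
        self.features = list(features or WINDOW_FEATURES)
        self.severity_vars = list(severity_vars or SEVERITY_VARIABLES)
        self.min_days = min_days
        self.within_group_binning = within_group_binning
        self.corrected_alpha = corrected_alpha
        self.patients = patients
        self.met_daily = met_daily
        self.data = daily_features.merge(
            met_daily, on=["patient_id", "date"]
        ).merge(patients[["patient_id", "group"]], on="patient_id")

    def fit(self) -> "AssociationResults":
        tables = []
        if self.within_group_binning:
            iterator = self.data.groupby("group")
        else:
            iterator = [("pooled", self.data)]
        for g, sub in iterator:
            t = group_association_matrix(
                sub, self.features, self.severity_vars, self.min_days
            )
            if not t.empty:
                t.insert(0, "group", g)
                tables.append(t)
        table = (
            pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        )
        comparisons = group_comparisons(
            self.met_daily, self.patients, corrected_alpha=self.corrected_alpha
        )
        return AssociationResults(self, table, comparisons)


@dataclass
class AssociationResults:
    model: AssociationAnalysis
    table: pd.DataFrame
    comparisons: pd.DataFrame = field(default=None)

    def matrix(self, group: str, value: str = "cramers_v") -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        return sub.pivot(index="feature", columns="severity_variable",
                         values=value)

    def summary(self) -> str:
        if self.table.empty:
            return "AssociationResults: no groups met the minimum day count"
        lines = ["Activity-quartile x severity associations (Cramér V)", ""]
        for g, sub in self.table.groupby("group"):
            top = sub.loc[sub["cramers_v"].idxmax()]
            n_sig = int((sub["p_value"] < self.model.corrected_alpha).sum())
            lines.append(
                f"{g}: {len(sub)} cells, {n_sig} with p < "
                f"{self.model.corrected_alpha}; strongest "
                f"{top['feature']} x {top['severity_variable']} "
                f"(V={top['cramers_v']:.3f}, {top['effect_label']})"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot_heatmaps(self, outdir) -> list:
        """p-value and Cramér V grids per group, as simple PNG heatmaps."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for g in self.table["group"].unique():
            for value, cmap in (("p_value", "Reds_r"), ("cramers_v", "Reds")):
                m = self.matrix(g, value)
                fig, ax = plt.subplots(figsize=(8, 4))
                im = ax.imshow(m.to_numpy(), cmap=cmap, aspect="auto")
                ax.set_xticks(range(m.shape[1]), m.columns, rotation=90,
                              fontsize=7)
                ax.set_yticks(range(m.shape[0]), m.index, fontsize=7)
                ax.set_title(f"{g}: {value}")
                fig.colorbar(im)
                fig.tight_layout()
                path = outdir / f"{g}_{value}.png"
                fig.savefig(path, dpi=110)
                plt.close(fig)
                written.append(path)
        return written
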