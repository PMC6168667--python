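"""%PPI computation and the within-subject statistical battery.

%PPI = 100·(P − PP)/P = 100·(1 − PP/P): the percent reduction of the
response to prepulse+pulse relative to pulse alone.  It is undefined
(missing, never 0) when the pulse-alone amplitude is not positive, is at
most 100, and may be negative (facilitation).

The omnibus comparison across conditions is gated on normality: Shapiro–
Wilk per condition at α = 0.05, all conditions must pass for a repeated-
measures ANOVA, otherwise the Friedman test is used.  Post hocs are Tukey
HSD (parametric) or paired Wilcoxon signed-rank with Bonferroni adjustment
(nonparametric); cross-modality association uses Kendall's tau-b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_events import CONDITIONS, PPI_INTERVALS, logger


def percent_ppi(p_amp: float, pp_amp: float) -> float:
    """Percent prepulse inhibition, 100·(1 − PP/P).

    Returns NaN (missing) when ``p_amp`` is not positive.
    """
    if not np.isfinite(p_amp) or not np.isfinite(pp_amp) or p_amp <= 0:
        return float("nan")
    return 100.0 * (1.0 - pp_amp / p_amp)


@dataclass
class PPITable:
    """Per subject × modality amplitudes and %PPI values.

    ``table`` columns: subject, modality (``ASR`` or ``p2n1@<channel>``),
    amp_P, amp_P30, amp_P60, amp_P120, ppi_30, ppi_60, ppi_120.
    """

    table: pd.DataFrame

    def ppi_frame(self, modality: str) -> pd.DataFrame:
        """Subjects × intervals %PPI values for one modality (columns
        ``ppi_30``/``ppi_60``/``ppi_120``, indexed by subject)."""
        sub = self.table[self.table["modality"] == modality]
        return sub.set_index("subject")[[f"ppi_{i}" for i in PPI_INTERVALS]]

    def amplitude_frame(self, modality: str) -> pd.DataFrame:
        sub = self.table[self.table["modality"] == modality]
        return sub.set_index("subject")[[f"amp_{c}" for c in CONDITIONS]]

    @property
    def modalities(self) -> list[str]:
        return list(dict.fromkeys(self.table["modality"]))


def build_ppi_table(amplitudes: pd.DataFrame) -> PPITable:
    """Assemble a :class:`PPITable` from long-format amplitudes
    (columns: subject, modality, condition, amplitude)."""
    rows = []
    for (subj, mod), grp in amplitudes.groupby(["subject", "modality"], sort=False):
        amps = dict(zip(grp["condition"], grp["amplitude"]))
        row = {"subject": subj, "modality": mod}
        for cond in CONDITIONS:
            row[f"amp_{cond}"] = float(amps.get(cond, np.nan))
        for iv in PPI_INTERVALS:
            row[f"ppi_{iv}"] = percent_ppi(row["amp_P"], row[f"amp_P{iv}"])
        rows.append(row)
    df = pd.DataFrame(rows)
    n_missing = int(df[[f"ppi_{i}" for i in PPI_INTERVALS]].isna().sum().sum())
    if n_missing:
        logger.warning("%d %%PPI value(s) undefined (pulse amplitude <= 0)", n_missing)
    return PPITable(df)


@dataclass
class StatReport:
    """Result of one test: omnibus statistic, normality gate, post hocs."""

    test: str
    statistic: float
    df: tuple
    p_value: float
    parametric: bool
    normality: dict = field(default_factory=dict)   # condition -> (W, p)
    posthoc: pd.DataFrame | None = None
    n_subjects: int = 0


def _complete_cases(values: pd.DataFrame) -> pd.DataFrame:
    out = values.dropna(axis=0)
    dropped = len(values) - len(out)
    if dropped:
        logger.info("dropped %d incomplete subject row(s) listwise", dropped)
    return out


def shapiro_gate(values: pd.DataFrame, alpha: float = 0.05) -> tuple[bool, dict]:
    """Shapiro–Wilk per condition column; the gate passes (→ parametric)
    only when every condition passes at ``alpha``.  A constant column
    cannot be tested and fails the gate."""
    normality = {}
    all_normal = True
    for col in values.columns:
        x = values[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            normality[col] = (np.nan, np.nan)
            all_normal = False
            continue
        w, p = sps.shapiro(x)
        normality[col] = (float(w), float(p))
        if p < alpha:
            all_normal = False
    return all_normal, normality


def omnibus_condition_test(values: pd.DataFrame, alpha: float = 0.05) -> StatReport:
    """Compare conditions within subjects: RM-ANOVA when every condition is
    Gaussian by Shapiro–Wilk, Friedman otherwise.

    ``values``: subjects × conditions (complete cases used; < 3 complete
    subjects is an error).
    """
    values = _complete_cases(values)
    n, k = values.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete subjects, have {n}")
    if k < 2:
        raise ValueError("need at least 2 conditions")
    arr = values.to_numpy(dtype=float)
    if np.all(np.ptp(arr, axis=1) == 0):
        # every subject identical across conditions: no information either way
        return StatReport("friedman", 0.0, (float(k - 1),), 1.0, False,
                          {c: (np.nan, np.nan) for c in values.columns},
                          n_subjects=n)
    normal, normality = shapiro_gate(values, alpha)

    if normal:
        from statsmodels.stats.anova import AnovaRM

        long = values.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="value")
        res = AnovaRM(long, depvar="value", subject="subject",
                      within=["condition"]).fit()
        row = res.anova_table.iloc[0]
        return StatReport("rm_anova", float(row["F Value"]),
                          (float(row["Num DF"]), float(row["Den DF"])),
                          float(row["Pr > F"]), True, normality, n_subjects=n)

    stat, p = sps.friedmanchisquare(*[arr[:, j] for j in range(k)])
    return StatReport("friedman", float(stat), (float(k - 1),), float(p),
                      False, normality, n_subjects=n)


def posthoc_pairwise(values: pd.DataFrame, pairs: list[tuple[str, str]],
                     parametric: bool) -> StatReport:
    """Pairwise contrasts after a significant omnibus.

    Parametric: Tukey HSD over the condition groups (all columns form the
    family), reporting the requested pairs.  Nonparametric: paired Wilcoxon
    signed-rank per pair, Bonferroni-multiplied by the number of requested
    pairs and capped at 1.  All-tied Wilcoxon input yields p = 1 with a
    warning.
    """
    values = _complete_cases(values)
    cols = list(values.columns)
    rows = []
    if parametric:
        res = sps.tukey_hsd(*[values[c].to_numpy(dtype=float) for c in cols])
        for a, b in pairs:
            ia, ib = cols.index(a), cols.index(b)
            p = float(res.pvalue[ia, ib])
            rows.append({"a": a, "b": b, "p_raw": p, "p_adj": p,
                         "adjustment": "tukey"})
        name = "tukey_hsd"
    else:
        m = len(pairs)
        for a, b in pairs:
            d = values[a].to_numpy(dtype=float) - values[b].to_numpy(dtype=float)
            if np.all(d == 0):
                warnings.warn(f"all paired differences are zero for {a} vs {b}; p = 1")
                p = 1.0
            else:
                _, p = sps.wilcoxon(values[a], values[b], zero_method="wilcox",
                                    alternative="two-sided")
                p = float(p)
            rows.append({"a": a, "b": b, "p_raw": p,
                         "p_adj": min(1.0, p * m), "adjustment": "bonferroni"})
        name = "wilcoxon_bonferroni"
    table = pd.DataFrame(rows)
    return StatReport(name, float("nan"), (), float("nan"), parametric,
                      posthoc=table, n_subjects=len(values))


def cross_modality_correlation(ppi: PPITable,
                               electrodes: tuple[str, ...] = ("Fz", "Cz", "Pz"),
                               min_subjects: int = 5) -> pd.DataFrame:
    """Kendall tau-b between muscular (ASR) %PPI and each electrode's
    neural %PPI, per interval (9 correlations).

    Returns a DataFrame (interval, electrode, n, tau, p); tau is NaN when a
    vector is constant or fewer than ``min_subjects`` complete pairs exist.
    """
    asr = ppi.ppi_frame("ASR")
    rows = []
    for iv in PPI_INTERVALS:
        for el in electrodes:
            neural = ppi.ppi_frame(f"p2n1@{el}")
            joined = asr[[f"ppi_{iv}"]].join(neural[[f"ppi_{iv}"]],
                                             lsuffix="_asr", rsuffix="_eeg").dropna()
            x = joined.iloc[:, 0].to_numpy()
            y = joined.iloc[:, 1].to_numpy()
            if len(joined) < min_subjects or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"interval": iv, "electrode": el, "n": len(joined),
                             "tau": np.nan, "p": np.nan})
                continue
            tau, p = sps.kendalltau(x, y, variant="b")
            rows.append({"interval": iv, "electrode": el, "n": len(joined),
                         "tau": float(tau), "p": float(p)})
    return pd.DataFrame(rows)


def condition_battery(values: pd.DataFrame, pairs: list[tuple[str, str]],
                      alpha: float = 0.05) -> StatReport:
    """Omnibus test plus post hocs (only when the omnibus is significant),
    matching the published decision tree."""
    report = omnibus_condition_test(values, alpha)
    if report.p_value < alpha:
        ph = posthoc_pairwise(values, pairs, report.parametric)
        report.posthoc = ph.posthoc
    return report
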