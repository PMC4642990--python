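"""Behavioral-data pipeline: loading, exclusions, normalization, gLPII, ANOVAs.

The canonical per-duration table (the package's CSV dialect) has columns

    subject, repetition, delta_f, onset_s, duration_s, percept,
    is_first, is_incomplete

with ``percept`` in {integrated, segregated}.  Model output decoded by
:mod:`abastream.decode` serializes to the same dialect, so simulated and
experimental data flow through identical downstream code.

Analysis conventions: each trial's first duration (build-up) and final
incomplete duration are excluded; durations shorter than one triplet
(0.5 s) are excluded; each subject's durations are normalized by that
subject's grand mean duration T_glob (across both percepts, all
repetitions and all conditions) so that fast and slow switchers contribute
comparably; each subject then contributes one mean integrated and one mean
segregated score per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.io as sio

__all__ = [
    "DIALECT_COLUMNS", "read_durations", "write_durations",
    "apply_exclusions", "ExclusionResult", "subject_normalize",
    "SubjectSummary", "analyze_glp2", "rm_anova_oneway", "rm_anova_twoway",
    "RMAnovaResult",
]

DIALECT_COLUMNS = ("subject", "repetition", "delta_f", "onset_s",
                   "duration_s", "percept", "is_first", "is_incomplete")

PERCEPTS = ("integrated", "segregated")

#: the experiment's frequency-difference conditions (semitones)
EXPERIMENT_DF_VALUES = (1, 2, 3, 5, 7, 9, 11, 15)


def _validate(frame: pd.DataFrame, allowed_df) -> pd.DataFrame:
    missing = set(DIALECT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"malformed duration table: missing columns {sorted(missing)}")
    frame = frame.copy()
    for col in ("is_first", "is_incomplete"):
        frame[col] = frame[col].astype(bool)
    frame["duration_s"] = frame["duration_s"].astype(float)
    frame["delta_f"] = frame["delta_f"].astype(float)
    if (frame["duration_s"] <= 0).any():
        bad = frame.loc[frame["duration_s"] <= 0]
        raise ValueError(f"non-positive durations for subjects "
                         f"{sorted(bad['subject'].unique())}")
    unknown_p = set(frame["percept"]) - set(PERCEPTS)
    if unknown_p:
        raise ValueError(f"unknown percept labels: {sorted(unknown_p)}")
    if allowed_df is not None:
        unknown = set(frame["delta_f"]) - {float(x) for x in allowed_df}
        if unknown:
            raise ValueError(f"unknown delta_f conditions: {sorted(unknown)}")
    return frame


def read_durations(path, dialect: str = "csv",
                   allowed_df=EXPERIMENT_DF_VALUES) -> pd.DataFrame:
    """Load a per-duration table from CSV or a MAT-file (v5).

    The MAT layout mirrors the CSV dialect: one array per column, equal
    lengths (``percept`` as a cell/char array).  ``allowed_df`` restricts
    the admissible conditions (``None`` disables the check).
    """
    if dialect == "csv":
        frame = pd.read_csv(path)
    elif dialect == "mat":
        raw = sio.loadmat(path, squeeze_me=True)
        cols = {}
        for col in DIALECT_COLUMNS:
            if col not in raw:
                raise ValueError(f"malformed MAT file: missing variable {col!r}")
            val = np.atleast_1d(raw[col])
            if val.dtype.kind in "OU":
                val = np.array([str(x).strip() for x in val])
            cols[col] = val
        lengths = {len(v) for v in cols.values()}
        if len(lengths) != 1:
            raise ValueError("malformed MAT file: column length mismatch")
        frame = pd.DataFrame(cols)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use 'csv' or 'mat')")
    return _validate(frame, allowed_df)


def write_durations(frame: pd.DataFrame, path, dialect: str = "csv") -> None:
    """Write a per-duration table in the canonical dialect (CSV or MAT v5)."""
    frame = frame[list(DIALECT_COLUMNS)]
    if dialect == "csv":
        frame.to_csv(path, index=False)
    elif dialect == "mat":
        payload = {c: frame[c].to_numpy() for c in DIALECT_COLUMNS}
        payload["percept"] = np.array(frame["percept"], dtype=object)
        sio.savemat(path, payload)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class ExclusionResult:
    """Retained durations plus an audit trail of every exclusion."""

    frame: pd.DataFrame            # durations retained for analysis
    report: pd.DataFrame           # one row per excluded duration / flag
    t_glob: pd.Series              # per-subject grand mean of retained durations
    outlier_subjects: list         # flagged (not dropped) by the fence rule


def apply_exclusions(frame: pd.DataFrame, min_duration: float = 0.5,
                     exclude_first: bool = True, tukey_k: float = 1.5,
                     drop_outliers: bool = False,
                     outlier_subjects=None) -> ExclusionResult:
    """Apply the standard exclusion rules and report every exclusion.

    Drops each trial's final incomplete duration, the first duration
    (build-up) when ``exclude_first``, and durations below ``min_duration``
    (one triplet).  Subjects whose grand mean T_glob lies above the Tukey
    fence (upper quartile + ``tukey_k`` x IQR of the subject T_glob
    distribution) are flagged; they are dropped only when
    ``drop_outliers`` or when listed explicitly in ``outlier_subjects``.
    """
    frame = _validate(frame, allowed_df=None)
    records = []

    def note(mask, rule):
        for _, row in frame.loc[mask].iterrows():
            records.append({"subject": row["subject"],
                            "repetition": row["repetition"],
                            "delta_f": row["delta_f"],
                            "duration_s": row["duration_s"], "rule": rule})

    drop = frame["is_incomplete"]
    note(drop, "final-incomplete")
    if exclude_first:
        note(frame["is_first"] & ~drop, "first-duration")
        drop = drop | frame["is_first"]
    short = (frame["duration_s"] < min_duration) & ~drop
    note(short, f"shorter-than-{min_duration}s")
    drop = drop | short
    kept = frame.loc[~drop].copy()

    t_glob = kept.groupby("subject")["duration_s"].mean().rename("t_glob")
    q1, q3 = t_glob.quantile([0.25, 0.75])
    fence = q3 + tukey_k * (q3 - q1)
    flagged = sorted(t_glob.index[t_glob > fence])
    for s in flagged:
        records.append({"subject": s, "repetition": None, "delta_f": None,
                        "duration_s": t_glob[s], "rule": "t-glob-outlier-flag"})

    to_drop = set(outlier_subjects or [])
    if drop_outliers:
        to_drop |= set(flagged)
    if to_drop:
        for s in sorted(to_drop):
            records.append({"subject": s, "repetition": None, "delta_f": None,
                            "duration_s": t_glob.get(s, np.nan),
                            "rule": "subject-excluded"})
        kept = kept[~kept["subject"].isin(to_drop)]
        t_glob = t_glob.drop(index=[s for s in to_drop if s in t_glob.index])

    report = pd.DataFrame(
        records, columns=["subject", "repetition", "delta_f", "duration_s", "rule"])
    return ExclusionResult(frame=kept.reset_index(drop=True), report=report,
                           t_glob=t_glob, outlier_subjects=flagged)


@dataclass
class SubjectSummary:
    """Per-subject and group-level normalized scores.

    ``per_subject`` has one row per (subject, delta_f): normalized mean
    integrated and segregated durations (that subject's durations divided
    by their T_glob, pooled across repetitions) and the proportion of
    classified time integrated (per-trial proportions averaged over
    repetitions).  ``group`` aggregates with mean and SEM (SD / sqrt(N))
    over subjects.
    """

    per_subject: pd.DataFrame
    group: pd.DataFrame
    t_glob: pd.Series


def subject_normalize(excl: ExclusionResult | pd.DataFrame) -> SubjectSummary:
    """Normalized per-subject mean durations and proportions (post-exclusion)."""
    if isinstance(excl, ExclusionResult):
        frame, t_glob = excl.frame, excl.t_glob
    else:
        frame = excl
        t_glob = frame.groupby("subject")["duration_s"].mean().rename("t_glob")

    rows = []
    for (subj, df), grp in frame.groupby(["subject", "delta_f"]):
        tg = t_glob[subj]
        rec = {"subject": subj, "delta_f": df}
        for percept in PERCEPTS:
            sel = grp[grp["percept"] == percept]["duration_s"]
            key = "nbar_int" if percept == "integrated" else "nbar_seg"
            rec[key] = sel.mean() / tg if len(sel) else np.nan
        props = []
        for _, trial in grp.groupby("repetition"):
            vi = trial.loc[trial["percept"] == "integrated", "duration_s"].sum()
            vs = trial.loc[trial["percept"] == "segregated", "duration_s"].sum()
            if vi + vs > 0:
                props.append(vi / (vi + vs))
        rec["prop_int"] = float(np.mean(props)) if props else np.nan
        rows.append(rec)
    per_subject = pd.DataFrame(rows).sort_values(
        ["subject", "delta_f"], ignore_index=True)

    agg = []
    for df, grp in per_subject.groupby("delta_f"):
        rec = {"delta_f": df}
        for col in ("nbar_int", "nbar_seg", "prop_int"):
            vals = grp[col].dropna()
            rec[f"{col}_mean"] = vals.mean()
            rec[f"{col}_sem"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                 if len(vals) > 1 else np.nan)
            rec[f"{col}_n"] = len(vals)
        agg.append(rec)
    group = pd.DataFrame(agg).sort_values("delta_f", ignore_index=True)
    return SubjectSummary(per_subject=per_subject, group=group, t_glob=t_glob)


def analyze_glp2(summary: SubjectSummary, eq_df: float = 5.0) -> dict:
    """Generalized-Levelt-II analysis of a subject summary.

    ``eq_df`` names the condition treated as the data's equidominance
    point.  Each subject's T_eq is the mean of their normalized integrated
    and segregated scores there (the two agree only approximately within a
    subject), and η(Δf) = (T̄int + T̄seg − 2 T_eq) / T_eq.  Returns the
    per-subject η table, its group mean ± SEM, and the group curves.
    """
    ps = summary.per_subject
    if float(eq_df) not in set(ps["delta_f"]):
        raise ValueError(f"summary lacks the equidominance condition {eq_df}")
    eta_rows = []
    for subj, grp in ps.groupby("subject"):
        at_eq = grp[grp["delta_f"] == float(eq_df)]
        t_eq = float(np.mean([at_eq["nbar_int"].iloc[0],
                              at_eq["nbar_seg"].iloc[0]]))
        if not np.isfinite(t_eq) or t_eq <= 0:
            continue
        for _, row in grp.iterrows():
            eta_rows.append({
                "subject": subj, "delta_f": row["delta_f"], "t_eq": t_eq,
                "eta": (row["nbar_int"] + row["nbar_seg"] - 2 * t_eq) / t_eq,
            })
    eta = pd.DataFrame(eta_rows)
    eta_group = (eta.groupby("delta_f")["eta"]
                 .agg(["mean", lambda v: v.std(ddof=1) / np.sqrt(len(v)), "count"])
                 .rename(columns={"<lambda_0>": "sem"}).reset_index())
    return {"eta_per_subject": eta, "eta_group": eta_group,
            "group_curves": summary.group}


@dataclass
class RMAnovaResult:
    """One effect of a repeated-measures ANOVA with sphericity diagnostics."""

    source: str
    ss: float
    ss_error: float
    df1: int
    df2: int
    ms: float
    ms_error: float
    F: float
    p: float
    mauchly_w: float | None
    mauchly_p: float | None
    gg_epsilon: float | None
    p_gg: float | None

    def row(self) -> dict:
        return {"Source": self.source, "SS": self.ss, "df": self.df1,
                "MS": self.ms, "F": self.F, "p": self.p,
                "SS_error": self.ss_error, "df_error": self.df2,
                "MS_error": self.ms_error, "Mauchly_W": self.mauchly_w,
                "Mauchly_p": self.mauchly_p, "GG_eps": self.gg_epsilon,
                "p_GG": self.p_gg}


def _require_complete(wide: pd.DataFrame) -> None:
    if wide.isna().any().any():
        bad = sorted(wide.index[wide.isna().any(axis=1)])
        raise ValueError(f"incomplete cases (drop or impute first): {bad}")
    if len(wide) < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")


def rm_anova_oneway(wide: pd.DataFrame) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Classical within-subject decomposition (condition tested against the
    condition x subject interaction), with Mauchly's sphericity test and
    the Greenhouse-Geisser corrected p-value.  Complete cases only.
    """
    _require_complete(wide)
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="cond", value_name="score")
    aov = pg.rm_anova(data=long, dv="score", within="cond", subject="subject",
                      correction=True, detailed=True)
    eff = aov.loc[aov["Source"] == "cond"].iloc[0]
    err = aov.loc[aov["Source"] == "Error"].iloc[0]
    sph = pg.sphericity(long, dv="score", within="cond", subject="subject")
    eps = float(pg.epsilon(long, dv="score", within="cond",
                           subject="subject", correction="gg"))
    F, p, p_gg = float(eff["F"]), float(eff["p_unc"]), float(eff["p_GG_corr"])
    if float(eff["SS"]) <= 1e-12:        # no effect at all: F := 0, not 0/0
        F, p, p_gg = 0.0, 1.0, 1.0
    return RMAnovaResult(
        source="condition", ss=float(eff["SS"]), ss_error=float(err["SS"]),
        df1=int(eff["DF"]), df2=int(err["DF"]), ms=float(eff["MS"]),
        ms_error=float(err["MS"]), F=F, p=p,
        mauchly_w=float(sph.W), mauchly_p=float(sph.pval), gg_epsilon=eps,
        p_gg=p_gg)


def rm_anova_twoway(long: pd.DataFrame, dv: str = "value",
                    within=("percept", "delta_f"), subject: str = "subject",
                    log_transform: bool = True) -> pd.DataFrame:
    """Two-way fully repeated ANOVA (both factors within subjects).

    Each effect is tested against its own subject-interaction error term.
    ``log_transform`` applies the natural log to the dependent variable
    first (standard for duration data; the base cannot affect F).  Returns
    a tidy table with one row per effect: SS, dfs, MS, F, uncorrected and
    GG-corrected p.  Missing cells raise.
    """
    data = long.copy()
    within = list(within)
    cells = data.groupby([subject] + within)[dv].count().unstack(within[0]).unstack()
    if cells.isna().any().any() or (cells < 1).any().any():
        raise ValueError("missing percept x condition cells")
    if log_transform:
        if (data[dv] <= 0).any():
            raise ValueError("log transform requires positive values")
        data[dv] = np.log(data[dv])
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      correction=True, detailed=True)
    out = aov.rename(columns={
        "Source": "source", "SS": "ss", "ddof1": "df1", "ddof2": "df2",
        "DF": "df1", "MS": "ms", "p_unc": "p", "p_GG_corr": "p_gg",
        "eps": "gg_epsilon"})
    keep = [c for c in ("source", "ss", "df1", "df2", "ms", "F", "p",
                        "p_gg", "gg_epsilon") if c in out.columns]
    out = out[keep].copy()
    null = out["ss"] <= 1e-12            # no effect at all: F := 0, not 0/0
    out.loc[null, "F"] = 0.0
    out.loc[null, ["p", "p_gg"]] = 1.0
    return out
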