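"""Response-time extraction, success rates, and feedback-modality statistics.

A feedback trial interrupts a face-directed reach with a visual, auditory,
or vibrotactile stimulus.  The response time is the interval from stimulus
onset to the hand's complete stop or direction reversal; the success rate is
the fraction of feedback trials where the stop beats face contact.  The three
modalities are compared with a one-way repeated-measures ANOVA on
per-participant mean response times (after a D'Agostino-Pearson normality
check), with Holm-corrected pairwise paired t-tests and Greenhouse-Geisser
correction when sphericity is violated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MODALITIES, PsychTrial


@dataclass
class ModalityStats:
    """Per-modality summaries plus the within-subject comparison tables."""

    means_ms: dict
    sds_ms: dict
    normality_p: dict
    anova: pd.DataFrame
    anova_p: float
    sphericity_p: float | None
    gg_applied: bool
    pairwise: pd.DataFrame
    pairwise_p: pd.DataFrame  # symmetric matrix of corrected p-values
    n_participants: int


def extract_response_time(
    trial: PsychTrial, stop_frac: float = 0.02, sustain: int = 3
) -> float | None:
    """Response time (ms) from a feedback trial's kinematic trace.

    The response event is the earlier of (a) the first post-stimulus sample
    where speed stays below ``stop_frac`` x the post-stimulus peak speed for
    ``sustain`` consecutive samples (a complete stop) and (b) the first
    sample where the approach-axis velocity reverses sign.  Only events
    before ``movement_end_ms`` count: if neither occurs by then the hand
    reached the face and the trial is a failure (returns ``None``).
    """
    if trial.stimulus_onset_ms is None:
        raise ValueError("response time is only defined for feedback trials")
    t = np.asarray(trial.t_ms, dtype=float)
    v = np.asarray(trial.speed, dtype=float)
    if t[-1] < trial.stimulus_onset_ms:
        raise ValueError(
            f"trace ends at {t[-1]:.1f} ms, before stimulus onset "
            f"{trial.stimulus_onset_ms:.1f} ms"
        )
    post = np.flatnonzero(t >= trial.stimulus_onset_ms)
    pre_end = post[t[post] < trial.movement_end_ms]
    if pre_end.size == 0:
        return None
    peak = np.abs(v[pre_end]).max()
    if peak <= 0:
        return None

    candidates = []
    below = np.abs(v[post[0]:]) < stop_frac * peak
    if sustain > 1:
        runs = np.convolve(below.astype(int), np.ones(sustain, dtype=int), "valid") == sustain
        stop_rel = np.flatnonzero(runs)
    else:
        stop_rel = np.flatnonzero(below)
    if stop_rel.size:
        candidates.append(t[post[0] + stop_rel[0]])
    rev_rel = np.flatnonzero(v[post[0]:] < 0)
    if rev_rel.size:
        candidates.append(t[post[0] + rev_rel[0]])
    if not candidates:
        return None
    event = min(candidates)
    if event >= trial.movement_end_ms:
        return None
    return max(event - trial.stimulus_onset_ms, 0.0)


def extract_session(trials: list[PsychTrial], stop_frac: float = 0.02, sustain: int = 3) -> pd.DataFrame:
    """Tidy per-trial extraction: one row per feedback trial."""
    rows = []
    for trial in trials:
        if trial.modality == "none":
            continue
        rt = extract_response_time(trial, stop_frac=stop_frac, sustain=sustain)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "trial_index": trial.trial_index,
                "modality": trial.modality,
                "stimulus_onset_ms": trial.stimulus_onset_ms,
                "response_time_ms": rt,
                "success": rt is not None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_index",
            "modality",
            "stimulus_onset_ms",
            "response_time_ms",
            "success",
        ],
    )


def success_rate(
    extracted: pd.DataFrame, per_participant: bool = False
) -> dict | pd.DataFrame:
    """Successes / feedback trials per modality.

    Modalities with no trials are simply absent from the result (missing,
    not zero).  With ``per_participant=True`` returns a participant x
    modality table of rates.
    """
    if extracted.empty:
        return pd.DataFrame() if per_participant else {}
    if per_participant:
        return (
            extracted.groupby(["participant_id", "modality"])["success"]
            .mean()
            .unstack("modality")
        )
    return extracted.groupby("modality")["success"].mean().to_dict()


def participant_means(extracted: pd.DataFrame) -> pd.DataFrame:
    """Participant x modality table of mean response times (ms), using
    successful (extracted) trials only."""
    ok = extracted.dropna(subset=["response_time_ms"])
    return (
        ok.groupby(["participant_id", "modality"])["response_time_ms"]
        .mean()
        .unstack("modality")
    )


def rm_anova_F(wide: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA from first principles.

    ``wide`` is participants x conditions.  Returns (F, p) with
    df = (k - 1, (k - 1)(n - 1)).  Serves as the independent sum-of-squares
    oracle for the library-backed route in :func:`compare_modalities`.
    """
    wide = np.asarray(wide, dtype=float)
    n, k = wide.shape
    grand = wide.mean()
    ss_cond = n * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((wide.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((wide - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        return (0.0, 1.0) if ms_cond == 0 else (np.inf, 0.0)
    f = ms_cond / ms_err
    return float(f), float(stats.f.sf(f, df1, df2))


def compare_modalities(means: pd.DataFrame, alpha_sphericity: float = 0.05) -> ModalityStats:
    """Within-subject comparison of the three feedback modalities.

    ``means`` is a participant x modality table of mean response times
    (e.g. from :func:`participant_means`).  Every participant must have all
    three modalities; incomplete rows raise with an instruction to exclude
    them listwise first.
    """
    import pingouin as pg

    missing_cols = [m for m in MODALITIES if m not in means.columns]
    if missing_cols:
        raise ValueError(f"missing modalities in the design: {missing_cols}")
    wide = means[list(MODALITIES)]
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(
            f"incomplete within-participant design for participants {bad[:5]}; "
            "exclude them listwise before comparing modalities"
        )
    long = (
        wide.reset_index()
        .melt(id_vars=wide.index.name or "participant_id", var_name="modality", value_name="rt_ms")
        .rename(columns={wide.index.name or "participant_id": "participant_id"})
    )

    normality = {
        m: float(stats.normaltest(wide[m].to_numpy()).pvalue) for m in MODALITIES
    }

    spher = pg.sphericity(long, dv="rt_ms", within="modality", subject="participant_id")
    sphericity_p = float(spher.pval)
    aov = pg.rm_anova(
        data=long, dv="rt_ms", within="modality", subject="participant_id",
        correction=True, detailed=True,
    )
    gg_col = next((c for c in aov.columns if c in ("p_GG_corr", "p-GG-corr")), None)
    gg_applied = sphericity_p < alpha_sphericity and gg_col is not None
    p_unc_col = next((c for c in ("p_unc", "p-unc") if c in aov.columns), None)
    if p_unc_col is None:
        anova_p = np.nan
    else:
        anova_p = float(aov.loc[0, gg_col if gg_applied else p_unc_col])
    if not np.isfinite(anova_p):
        # degenerate designs (e.g. identical columns) leave 0/0 F ratios and
        # pingouin drops the F/p columns; fall back to the first-principles
        # computation, which defines F = 0 there
        anova_p = rm_anova_F(wide.to_numpy())[1]
        gg_applied = False

    pairwise = pg.pairwise_tests(
        data=long, dv="rt_ms", within="modality", subject="participant_id",
        padjust="holm",
    )
    pcorr = next((c for c in ("p_corr", "p-corr") if c in pairwise.columns), None)
    puncp = next((c for c in ("p_unc", "p-unc") if c in pairwise.columns), None)
    pmat = pd.DataFrame(1.0, index=list(MODALITIES), columns=list(MODALITIES))
    for _, row in pairwise.iterrows():
        # zero-difference pairs leave pingouin without t/p columns: p := 1
        p = 1.0
        if pcorr is not None and pd.notna(row[pcorr]):
            p = float(row[pcorr])
        elif puncp is not None and pd.notna(row[puncp]):
            p = float(row[puncp])
        pmat.loc[row["A"], row["B"]] = p if np.isfinite(p) else 1.0
        pmat.loc[row["B"], row["A"]] = p if np.isfinite(p) else 1.0

    return ModalityStats(
        means_ms={m: float(wide[m].mean()) for m in MODALITIES},
        sds_ms={m: float(wide[m].std(ddof=1)) for m in MODALITIES},
        normality_p=normality,
        anova=aov,
        anova_p=anova_p,
        sphericity_p=sphericity_p,
        gg_applied=bool(gg_applied),
        pairwise=pairwise,
        pairwise_p=pmat,
        n_participants=len(wide),
    )
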