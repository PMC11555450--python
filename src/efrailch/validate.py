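"""Score distributions, change statistics, and FIM-anchored ROC validation.

Everything here consumes scored cohorts (see :mod:`efrailch.scoring`) or
plain arrays. Standard statistics route through scipy; rounding to the
report's precision (percentages and means to 2 decimals, correlations to 3)
happens only at render time.

The Functional Independence Measure (FIM) is the convergent-validity
reference: an 18-item, 7-level disability scale totalling 18 (entirely
dependent) to 126 (completely independent), banded as dependent (18-53),
modified independence (54-107), and independent (108-126). Because high
frailty corresponds to low FIM, the ROC "positive" class defaults to the
FIM-impaired side and the test calls an episode positive when its frailty
score reaches the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .records_io import Hospitalization
from .scoring import (
    FRAIL_CUTOFF,
    MAX_TOTAL,
    SEVERE_CUTOFF,
    compute_total,
)

__all__ = [
    "FIM_MIN",
    "FIM_MAX",
    "ScoreDistribution",
    "RocCurve",
    "ChangeStats",
    "distribution",
    "dist_mean_sd",
    "prevalence",
    "roc",
    "fim_categorize",
    "spearman",
    "paired_t",
    "wilcoxon_signed_rank",
    "ks_normality",
    "build_report",
    "Report",
]

FIM_MIN, FIM_MAX = 18, 126
_FIM_BANDS = (
    ("dependent", 18, 53),
    ("modified independence", 54, 107),
    ("independent", 108, 126),
)


@dataclass(frozen=True)
class ScoreDistribution:
    """Counts over the 0-12 score levels for one phase."""

    counts: tuple[int, ...]
    phase: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) != MAX_TOTAL + 1:
            raise ValueError(f"need {MAX_TOTAL + 1} counts (scores 0..{MAX_TOTAL})")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")

    @property
    def total_n(self) -> int:
        return sum(self.counts)

    def expand(self) -> np.ndarray:
        """Record-level score array with the distribution's counts."""
        return np.repeat(np.arange(MAX_TOTAL + 1), self.counts)


def distribution(scores: Iterable[int], phase: str = "") -> ScoreDistribution:
    counts = [0] * (MAX_TOTAL + 1)
    for s in scores:
        s = int(s)
        if not 0 <= s <= MAX_TOTAL:
            raise ValueError(f"score {s} outside [0, {MAX_TOTAL}]")
        counts[s] += 1
    return ScoreDistribution(counts=tuple(counts), phase=phase)


def dist_mean_sd(d: ScoreDistribution) -> tuple[float, float]:
    """Count-weighted mean and sample (n-1) standard deviation."""
    n = d.total_n
    if n < 2:
        raise ValueError("standard deviation needs at least 2 observations")
    levels = np.arange(MAX_TOTAL + 1, dtype=float)
    counts = np.asarray(d.counts, dtype=float)
    mean = float(levels @ counts / n)
    var = float(counts @ (levels - mean) ** 2 / (n - 1))
    return mean, math.sqrt(var)


def prevalence(d: ScoreDistribution, cutoff: int) -> tuple[int, float]:
    """(count, proportion) of scores at or above ``cutoff``."""
    if not 0 <= cutoff <= MAX_TOTAL:
        raise ValueError(f"cutoff {cutoff} outside [0, {MAX_TOTAL}]")
    if d.total_n == 0:
        raise ValueError("empty distribution")
    count = int(sum(d.counts[cutoff:]))
    return count, count / d.total_n


# ----------------------------------------------------------------- ROC ----


@dataclass(frozen=True)
class RocCurve:
    thresholds: tuple[float, ...]  # descending score cutoffs
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float
    optimal_cutoff: float
    youden_j: float


def roc(scores: Sequence[float], reference_positive: Sequence[bool]) -> RocCurve:
    """ROC of "score >= cutoff" against a binary reference.

    Sensitivity and specificity are evaluated at every observed cutoff
    (descending). The AUC is the trapezoidal area over (1-specificity,
    sensitivity), which equals the tie-adjusted pair-counting probability
    P(score_pos > score_neg) + 1/2 P(tie). The optimal cutoff maximizes
    Youden's J = sensitivity + specificity - 1, lowest cutoff on ties.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(reference_positive, dtype=bool)
    if scores.shape != pos.shape:
        raise ValueError("scores and reference lengths differ")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes in the reference")
    cutoffs = np.unique(scores)[::-1]
    sens, spec = [], []
    for c in cutoffs:
        called = scores >= c
        sens.append(float((called & pos).sum() / n_pos))
        spec.append(float((~called & ~pos).sum() / n_neg))
    fpr = np.concatenate(([0.0], 1.0 - np.asarray(spec), [1.0]))
    tpr = np.concatenate(([0.0], np.asarray(sens), [1.0]))
    auc = float(np.trapezoid(tpr, fpr))
    j = np.asarray(sens) + np.asarray(spec) - 1.0
    best = len(j) - 1 - int(np.argmax(j[::-1]))  # lowest cutoff on ties
    return RocCurve(
        thresholds=tuple(float(c) for c in cutoffs),
        sensitivity=tuple(sens),
        specificity=tuple(spec),
        auc=auc,
        optimal_cutoff=float(cutoffs[best]),
        youden_j=float(j[best]),
    )


def fim_categorize(fim_total: int) -> str:
    """Band a FIM total: 18-53 dependent, 54-107 modified independence,
    108-126 independent."""
    for name, lo, hi in _FIM_BANDS:
        if lo <= fim_total <= hi:
            return name
    raise ValueError(f"FIM total {fim_total} outside [{FIM_MIN}, {FIM_MAX}]")


# ----------------------------------------------------------- statistics ---


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties, and the two-sided
    p-value from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("spearman needs two equal-length samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman is undefined for constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ChangeStats:
    n: int
    mean_admission: float
    sd_admission: float
    mean_discharge: float
    sd_discharge: float
    mean_difference: float
    ci95: tuple[float, float]
    t_statistic: float
    p_value: float
    wilcoxon_p: dict[str, float] = field(default_factory=dict)


def paired_t(
    admission_scores: Sequence[float], discharge_scores: Sequence[float]
) -> ChangeStats:
    """Two-tailed paired t test of discharge - admission on matched episodes."""
    adm = np.asarray(admission_scores, dtype=float)
    dis = np.asarray(discharge_scores, dtype=float)
    if adm.shape != dis.shape or len(adm) < 2:
        raise ValueError("paired test needs matched samples, n >= 2")
    diff = dis - adm
    sd_diff = float(np.std(diff, ddof=1))
    if sd_diff == 0:
        raise ValueError("zero-variance differences")
    n = len(diff)
    mean_diff = float(diff.mean())
    se = sd_diff / math.sqrt(n)
    tcrit = float(sps.t.ppf(0.975, n - 1))
    res = sps.ttest_rel(dis, adm)
    return ChangeStats(
        n=n,
        mean_admission=float(adm.mean()),
        sd_admission=float(np.std(adm, ddof=1)),
        mean_discharge=float(dis.mean()),
        sd_discharge=float(np.std(dis, ddof=1)),
        mean_difference=mean_diff,
        ci95=(mean_diff - tcrit * se, mean_diff + tcrit * se),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired samples, two-sided.

    Returns (W+, p) where W+ is the midrank sum of positive differences of
    y - x after dropping zeros. The p-value is exact (enumeration) for
    n <= 25 without ties in |d|, else a normal approximation with
    continuity and tie corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        res = sps.wilcoxon(y, x, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            ((tie_counts**3 - tie_counts).sum()) / 48.0
        )
        if var <= 0:
            raise ValueError("degenerate signed-rank variance")
        # continuity correction toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w_plus, min(p, 1.0)


def ks_normality(
    values: Sequence[float], seed: int = 0, n_sim: int = 500
) -> tuple[float, float]:
    """Kolmogorov-Smirnov statistic against a normal with estimated mean/sd,
    with a seeded Monte-Carlo p-value (the estimated-parameter null makes
    the textbook KS p invalid)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 5:
        raise ValueError("normality check needs n >= 5")
    if np.ptp(values) == 0:
        raise ValueError("constant input")

    def stat(sample: np.ndarray) -> float:
        return float(
            sps.kstest(
                sample, "norm", args=(sample.mean(), sample.std(ddof=1))
            ).statistic
        )

    d_obs = stat(values)
    rng = np.random.default_rng(seed)
    sims = np.array([stat(rng.standard_normal(n)) for _ in range(n_sim)])
    p = (1.0 + float((sims >= d_obs).sum())) / (n_sim + 1.0)
    return d_obs, p


# -------------------------------------------------------------- report ----


@dataclass
class Report:
    tables: dict[str, "object"]  # name -> pandas DataFrame
    summary_md: str
    change: Optional[ChangeStats]
    roc_frail: Optional[RocCurve]
    roc_severe: Optional[RocCurve]
    spearman_fim: Optional[tuple[float, float]]
    notes: list[str]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        (out / "summary.md").write_text(self.summary_md, encoding="utf-8")


def _score_phase(records, phase, rule_tables):
    out = {}
    for rec in records:
        if rec.panel(phase) is None:
            continue
        out[rec.episode_id] = compute_total(rec, phase, rule_tables=rule_tables)
    return out


def build_report(
    cohort: Sequence[Hospitalization],
    out_dir=None,
    frail_cutoff: int = FRAIL_CUTOFF,
    severe_cutoff: int = SEVERE_CUTOFF,
    rule_tables=None,
    roc_positive: str = "impaired",
) -> Report:
    """Score a cohort at both phases and assemble the validation report.

    Emits score-distribution tables per phase, per-dimension distribution
    tables with paired Wilcoxon p-values, admission->discharge change
    statistics on survivors, ROC/cutpoint validation of discharge scores
    against the FIM bands, and a Spearman rank correlation with the FIM.
    ``roc_positive`` picks the reference direction: ``"impaired"`` calls
    FIM <= 107 (below independence) positive for the frail cutoff and
    FIM <= 53 (dependent) positive for the severe cutoff; ``"independent"``
    reverses the coding. All rounding happens at render time.
    """
    import pandas as pd

    notes: list[str] = []
    adm = _score_phase(cohort, "admission", rule_tables)
    dis = _score_phase(cohort, "discharge", rule_tables)

    tables: dict[str, pd.DataFrame] = {}
    dists = {}
    for phase, scored in (("admission", adm), ("discharge", dis)):
        if not scored:
            notes.append(f"no {phase} panels available; {phase} section absent")
            continue
        dist = distribution((r.total for r in scored.values()), phase)
        dists[phase] = dist
        n = dist.total_n
        tables[f"score_distribution_{phase}"] = pd.DataFrame(
            {
                "score": range(MAX_TOTAL + 1),
                "n": dist.counts,
                "percent": [round(100.0 * c / n, 2) for c in dist.counts],
            }
        )

    # per-dimension distributions + paired Wilcoxon over matched survivors
    matched = [e for e in adm if e in dis]
    dim_rows = []
    from .scoring import DIMENSIONS

    for dim in DIMENSIONS:
        row: dict = {"dimension": dim}
        for phase, scored in (("admission", adm), ("discharge", dis)):
            if scored:
                vals = [r.score_of(dim) for r in scored.values()]
                for level in range(3):
                    pct = 100.0 * sum(v == level for v in vals) / len(vals)
                    row[f"{phase}_pct_{level}"] = round(pct, 2)
        if len(matched) >= 10:
            a = [adm[e].score_of(dim) for e in matched]
            b = [dis[e].score_of(dim) for e in matched]
            try:
                row["wilcoxon_p"] = wilcoxon_signed_rank(a, b)[1]
            except ValueError:
                row["wilcoxon_p"] = float("nan")
        dim_rows.append(row)
    tables["dimension_distributions"] = pd.DataFrame(dim_rows)

    change = None
    if len(matched) >= 2:
        a = np.array([adm[e].total for e in matched], dtype=float)
        b = np.array([dis[e].total for e in matched], dtype=float)
        try:
            change = paired_t(a, b)
        except ValueError:
            notes.append("change statistics skipped: zero-variance differences")

    # FIM validation on discharged survivors with a FIM total
    fim_pairs = [
        (dis[rec.episode_id].total, rec.fim_total)
        for rec in cohort
        if rec.episode_id in dis and rec.fim_total is not None
    ]
    roc_frail = roc_severe = None
    spearman_fim = None
    if len(fim_pairs) >= 10:
        s = np.array([p[0] for p in fim_pairs], dtype=float)
        f = np.array([p[1] for p in fim_pairs], dtype=float)
        flip = roc_positive == "independent"
        try:
            pos_frail = (f <= 107) ^ flip
            roc_frail = roc(s if not flip else -s, pos_frail)
            pos_severe = (f <= 53) ^ flip
            if pos_severe.any() and not pos_severe.all():
                roc_severe = roc(s if not flip else -s, pos_severe)
        except ValueError as exc:
            notes.append(f"ROC skipped: {exc}")
        try:
            spearman_fim = spearman(s, f)
        except ValueError as exc:
            notes.append(f"Spearman skipped: {exc}")
        if roc_frail is not None:
            tables["roc_points"] = pd.DataFrame(
                {
                    "cutoff": roc_frail.thresholds,
                    "sensitivity": roc_frail.sensitivity,
                    "specificity": roc_frail.specificity,
                }
            )

    # demographics summary
    ages = [r.age for r in cohort if r.age is not None]
    demo_rows = [
        ("episodes", len(cohort)),
        ("women_pct", round(
            100.0 * sum(r.gender == "woman" for r in cohort) / max(len(cohort), 1), 2
        )),
        ("age_mean", round(float(np.mean(ages)), 2) if ages else float("nan")),
        ("age_sd", round(float(np.std(ages, ddof=1)), 2) if len(ages) > 1 else float("nan")),
        ("died_pct", round(100.0 * sum(r.died for r in cohort) / max(len(cohort), 1), 2)),
    ]
    tables["demographics"] = pd.DataFrame(demo_rows, columns=["item", "value"])

    md = _render_summary(
        dists, change, roc_frail, roc_severe, spearman_fim, frail_cutoff, notes
    )
    report = Report(
        tables=tables,
        summary_md=md,
        change=change,
        roc_frail=roc_frail,
        roc_severe=roc_severe,
        spearman_fim=spearman_fim,
        notes=notes,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def _render_summary(
    dists, change, roc_frail, roc_severe, spearman_fim, frail_cutoff, notes
) -> str:
    lines = ["# e-Frail-CH validation report", ""]
    for phase, dist in dists.items():
        mean, sd = dist_mean_sd(dist) if dist.total_n >= 2 else (float("nan"),) * 2
        count, prop = prevalence(dist, frail_cutoff)
        lines.append(
            f"- {phase}: n={dist.total_n}, mean {mean:.2f} (SD {sd:.2f}), "
            f"frail (>= {frail_cutoff}): {count} ({100 * prop:.2f}%)"
        )
    if change is not None:
        lines.append(
            f"- admission->discharge mean change {change.mean_difference:.2f} "
            f"(95% CI {change.ci95[0]:.2f} to {change.ci95[1]:.2f}), "
            f"t({change.n - 1}) = {change.t_statistic:.2f}, p = {change.p_value:.3g}"
        )
    if roc_frail is not None:
        lines.append(
            f"- ROC vs FIM below independence: AUC {roc_frail.auc:.2f}, optimal "
            f"cutoff >= {roc_frail.optimal_cutoff:.0f} "
            f"(sens {roc_frail.sensitivity[roc_frail.thresholds.index(roc_frail.optimal_cutoff)]:.2f}, "
            f"spec {roc_frail.specificity[roc_frail.thresholds.index(roc_frail.optimal_cutoff)]:.2f})"
        )
    if roc_severe is not None:
        lines.append(
            f"- ROC vs FIM dependent band: AUC {roc_severe.auc:.2f}, optimal "
            f"cutoff >= {roc_severe.optimal_cutoff:.0f}"
        )
    if spearman_fim is not None:
        lines.append(
            f"- Spearman discharge score vs FIM: rs = {spearman_fim[0]:.3f}, "
            f"p = {spearman_fim[1]:.3g}"
        )
    for note in notes:
        lines.append(f"- NOTE: {note}")
    lines.append("")
    return "\n".join(lines)
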