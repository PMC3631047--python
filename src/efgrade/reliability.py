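"""Observer-agreement statistics for reader studies.

Implements the validation analyses of the grading model: paired and
unpaired two-sided t-tests between readings, intraclass correlation
coefficients (ICC) from the two-way ANOVA decomposition with F-based 95 %
confidence intervals, and Bland-Altman bias / limits-of-agreement summaries
for repeatability and agreement plots.

The ICC forms follow the Shrout & Fleiss / McGraw & Wong taxonomy:

* ``icc1`` / ``icc1k`` -- one-way random effects, single / average measures
* ``icc2`` / ``icc2k`` -- two-way random effects, absolute agreement
* ``icc3`` / ``icc3k`` -- two-way mixed effects, consistency

For a matrix of ``n`` subjects rated by ``k`` raters, with between-subject,
between-rater and residual mean squares MSR, MSC and MSE, e.g.

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

All statistics are computed in closed form here; scipy supplies only the
t and F distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReaderStudyTable",
    "PairedTestResult",
    "IccResult",
    "AgreementSummary",
    "paired_ttest",
    "unpaired_ttest",
    "icc",
    "bland_altman",
    "ICC_FORMS",
]


class ReliabilityError(ValueError):
    """Invalid input to a reliability statistic."""


ICC_FORMS = {
    "icc1": "one-way random effects, single measures (ICC(1,1))",
    "icc1k": "one-way random effects, average measures (ICC(1,k))",
    "icc2": "two-way random effects, absolute agreement, single measures (ICC(2,1))",
    "icc2k": "two-way random effects, absolute agreement, average measures (ICC(2,k))",
    "icc3": "two-way mixed effects, consistency, single measures (ICC(3,1))",
    "icc3k": "two-way mixed effects, consistency, average measures (ICC(3,k))",
}


@dataclass
class ReaderStudyTable:
    """Long-format reader-study scores: one row per patient/reader/occasion.

    Thin wrapper over a pandas DataFrame with columns ``patient_id``,
    ``reader_id``, ``occasion`` and ``score``.  Identifiers are opaque
    strings; occasions sort lexicographically unless an explicit order is
    given, which defines the sign of "first minus second" differences.
    """

    data: "pandas.DataFrame"  # noqa: F821 - imported lazily to keep numpy-only paths light
    occasion_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        import pandas as pd

        df = pd.DataFrame(self.data)
        required = {"patient_id", "reader_id", "occasion", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ReliabilityError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        for col in ("patient_id", "reader_id", "occasion"):
            df[col] = df[col].astype(str)
        df["score"] = df["score"].astype(float)
        dup = df.duplicated(["patient_id", "reader_id", "occasion"])
        if dup.any():
            raise ReliabilityError(
                f"duplicate patient/reader/occasion cells: {df[dup].head().to_dict('records')}"
            )
        self.data = df

    @property
    def patients(self) -> list[str]:
        return sorted(self.data["patient_id"].unique(), key=_natural_key)

    @property
    def readers(self) -> list[str]:
        return sorted(self.data["reader_id"].unique())

    @property
    def occasions(self) -> list[str]:
        occ = sorted(self.data["occasion"].unique(), key=_natural_key)
        if self.occasion_order is not None:
            extra = set(occ) - set(self.occasion_order)
            if extra:
                raise ReliabilityError(f"occasions {sorted(extra)} not in occasion_order")
            occ = [o for o in self.occasion_order if o in occ]
        return occ

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def scores(self, reader_id: str, occasion: str) -> np.ndarray:
        """Score vector for one reader and occasion, in patient order."""
        sub = self.data[
            (self.data["reader_id"] == reader_id)
            & (self.data["occasion"] == occasion)
        ].set_index("patient_id")["score"]
        try:
            return sub.loc[self.patients].to_numpy(float)
        except KeyError as exc:
            raise ReliabilityError(
                f"missing scores for reader {reader_id!r} occasion {occasion!r}: {exc}"
            ) from None

    def rating_matrix(self, occasion: str | None = "first") -> np.ndarray:
        """Patients x readers matrix for ICC.

        ``occasion`` selects ``"first"`` / ``"second"`` (per occasion order),
        an explicit occasion label, or ``None`` / ``"stacked"`` to stack all
        occasions as extra rows (patient-occasion pairs as subjects).
        """
        occ = self.occasions
        if occasion in (None, "stacked", "all"):
            chosen = occ
        elif occasion == "first":
            chosen = [occ[0]]
        elif occasion == "second":
            if len(occ) < 2:
                raise ReliabilityError("no second occasion in table")
            chosen = [occ[1]]
        else:
            if occasion not in occ:
                raise ReliabilityError(f"unknown occasion {occasion!r}")
            chosen = [occasion]
        # rows = patients within each chosen occasion, cols = readers
        mats = []
        for o in chosen:
            mats.append(np.column_stack([self.scores(r, o) for r in self.readers]))
        return np.vstack(mats)


def _natural_key(s: str):
    return (0, int(s)) if s.isdigit() else (1, s)


@dataclass(frozen=True)
class PairedTestResult:
    """Summary of a two-sided t-test in the style of a reliability table."""

    mean_diff: float
    sd_diff: float
    sem: float
    ci95: tuple[float, float]
    t_stat: float
    p_value: float
    df: float
    n: int
    kind: str = "paired"
    degenerate: bool = False  # zero-variance differences


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with its 95 % confidence interval."""

    icc: float
    ci95: tuple[float, float]
    form: str
    model_label: str
    n_subjects: int
    n_raters: int
    negative_variance: bool = False  # a variance-component estimate was < 0


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman bias, 95 % limits of agreement and repeatability."""

    bias: float
    sd_diff: float
    loa95: tuple[float, float]
    repeatability_coefficient: float
    means: tuple[float, ...] = field(repr=False, default=())
    diffs: tuple[float, ...] = field(repr=False, default=())


def _check_pair(a, b, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ReliabilityError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < min_n:
        raise ReliabilityError(f"need at least {min_n} pairs, got {a.size}")
    return a, b


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> PairedTestResult:
    """Classical paired two-sided Student t-test on the differences a - b.

    Zero-variance differences are reported with a ``degenerate`` flag rather
    than raising: all-zero differences are a legitimate perfect-agreement
    outcome (t = 0, p = 1); a constant non-zero difference yields an
    infinite t and p = 0.
    """
    a, b = _check_pair(scores_a, scores_b)
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    dof = n - 1
    tcrit = float(stats.t.ppf(0.975, dof))
    if sd == 0.0:
        t_stat = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
        return PairedTestResult(
            mean_diff=mean, sd_diff=0.0, sem=0.0, ci95=(mean, mean),
            t_stat=t_stat, p_value=p, df=dof, n=n, degenerate=True,
        )
    sem = sd / math.sqrt(n)
    t_stat = mean / sem
    p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    return PairedTestResult(
        mean_diff=mean, sd_diff=sd, sem=sem,
        ci95=(mean - tcrit * sem, mean + tcrit * sem),
        t_stat=t_stat, p_value=p, df=dof, n=n,
    )


def unpaired_ttest(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    flavor: str = "pooled",
) -> PairedTestResult:
    """Two-sample two-sided t-test between independent score vectors.

    ``flavor="pooled"`` is the classical equal-variance Student form;
    ``flavor="welch"`` uses the Welch-Satterthwaite correction.  The result
    reuses the :class:`PairedTestResult` shape: ``mean_diff`` is the
    difference of sample means and ``sem`` its standard error;
    ``sd_diff`` is the pooled (or averaged, for Welch) standard deviation.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ReliabilityError("each sample needs at least 2 observations")
    if flavor not in {"pooled", "welch"}:
        raise ReliabilityError(f"unknown t-test flavor {flavor!r}")
    na, nb = a.size, b.size
    mean = float(a.mean() - b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        dof = na + nb - 2
        t_stat = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
        return PairedTestResult(
            mean_diff=mean, sd_diff=0.0, sem=0.0, ci95=(mean, mean),
            t_stat=t_stat, p_value=p, df=dof, n=na + nb,
            kind=f"unpaired-{flavor}", degenerate=True,
        )
    if flavor == "pooled":
        dof = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / dof
        sem = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        sd = math.sqrt(sp2)
    else:
        sem2 = va / na + vb / nb
        sem = math.sqrt(sem2)
        dof = sem2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        sd = math.sqrt((va + vb) / 2.0)
    t_stat = mean / sem
    p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    tcrit = float(stats.t.ppf(0.975, dof))
    return PairedTestResult(
        mean_diff=mean, sd_diff=sd, sem=sem,
        ci95=(mean - tcrit * sem, mean + tcrit * sem),
        t_stat=t_stat, p_value=p, df=dof, n=na + nb,
        kind=f"unpaired-{flavor}",
    )


def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))
    return msr, msc, mse, msw


def icc(
    scores: np.ndarray,
    form: str = "icc2",
    confidence: float = 0.95,
) -> IccResult:
    """Intraclass correlation for an ``n`` subjects x ``k`` raters matrix.

    The default ``icc2`` is the two-way random-effects, absolute-agreement,
    single-measures coefficient ICC(2,1); see :data:`ICC_FORMS` for the
    alternatives.  Confidence bounds use the standard F-distribution
    formulas for each form (Satterthwaite degrees of freedom for the
    absolute-agreement forms).  Negative variance-component estimates are
    not truncated; they are reported via the ``negative_variance`` flag.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ReliabilityError("scores must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 3:
        raise ReliabilityError(f"need at least 3 subjects for ICC, got {n}")
    if k < 2:
        raise ReliabilityError(f"need at least 2 raters for ICC, got {k}")
    if not np.isfinite(x).all():
        raise ReliabilityError("scores matrix contains missing or non-finite cells")
    if form not in ICC_FORMS:
        raise ReliabilityError(f"unknown ICC form {form!r}; choose from {sorted(ICC_FORMS)}")

    msr, msc, mse, msw = _anova_mean_squares(x)
    alpha = 1.0 - confidence
    q = 1.0 - alpha / 2.0

    neg_var = (msr < msw) or (msr < mse) or (msc < mse)

    if form in ("icc1", "icc1k"):
        df2 = n * (k - 1)
        fstat = msr / msw if msw > 0 else math.inf
        fl = fstat / stats.f.ppf(q, n - 1, df2)
        fu = fstat * stats.f.ppf(q, df2, n - 1)
        if form == "icc1":
            value = (msr - msw) / (msr + (k - 1) * msw)
            lo, hi = (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
        else:
            value = (msr - msw) / msr
            lo, hi = 1 - 1 / fl, 1 - 1 / fu
    elif form in ("icc3", "icc3k"):
        df2 = (n - 1) * (k - 1)
        fstat = msr / mse if mse > 0 else math.inf
        fl = fstat / stats.f.ppf(q, n - 1, df2)
        fu = fstat * stats.f.ppf(q, df2, n - 1)
        if form == "icc3":
            value = (msr - mse) / (msr + (k - 1) * mse)
            lo, hi = (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
        else:
            value = (msr - mse) / msr
            lo, hi = 1 - 1 / fl, 1 - 1 / fu
    else:  # icc2 / icc2k
        single = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        # Satterthwaite df for the absolute-agreement denominator
        a = (k * single) / (n * (1.0 - single)) if single < 1.0 else math.inf
        b = 1.0 + (k * single * (n - 1)) / (n * (1.0 - single)) if single < 1.0 else math.inf
        if math.isinf(a) or mse == 0.0:
            lo_s, hi_s = 1.0, 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den
            f1 = stats.f.ppf(q, n - 1, v)
            f2 = stats.f.ppf(q, v, n - 1)
            lo_s = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi_s = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
        if form == "icc2":
            value, lo, hi = single, lo_s, hi_s
        else:
            sb = lambda r: k * r / (1.0 + (k - 1) * r) if math.isfinite(r) else 1.0
            value, lo, hi = sb(single), sb(lo_s), sb(hi_s)

    return IccResult(
        icc=float(value),
        ci95=(float(lo), float(hi)),
        form=form,
        model_label=ICC_FORMS[form],
        n_subjects=n,
        n_raters=k,
        negative_variance=bool(neg_var),
    )


def interobserver_icc(
    table: ReaderStudyTable,
    form: str = "icc2k",
    occasion: str | None = "first",
) -> IccResult:
    """Reference interobserver ICC between the readers of a study table.

    Defaults reproduce the bundled validation study's reported reliability:
    two-way random effects, absolute agreement, average measures over the
    two radiologists, on the first reading occasion.  Pass
    ``occasion="stacked"`` to use both occasions as repeated rows, or
    ``form="icc2"`` for the single-measures coefficient.
    """
    return icc(table.rating_matrix(occasion=occasion), form=form)


def bland_altman(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> AgreementSummary:
    """Bland-Altman agreement between two paired score vectors.

    ``bias`` is the mean difference a - b, the 95 % limits of agreement are
    ``bias +/- 1.96 sd(a - b)``, and the repeatability coefficient is
    ``1.96 sqrt(2) s_w`` with the within-subject SD ``s_w = sd_diff/sqrt(2)``
    (so numerically ``1.96 sd_diff`` for duplicate measurements).  The
    per-pair (mean, difference) points for the agreement plot are returned
    alongside.
    """
    a, b = _check_pair(scores_a, scores_b)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementSummary(
        bias=bias,
        sd_diff=sd,
        loa95=(bias - 1.96 * sd, bias + 1.96 * sd),
        repeatability_coefficient=1.96 * math.sqrt(2.0) * (sd / math.sqrt(2.0)),
        means=tuple((a + b) / 2.0),
        diffs=tuple(d),
    )
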