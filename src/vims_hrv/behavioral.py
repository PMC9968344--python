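"""Motion Sickness Assessment Questionnaire scoring and the behavioral /
association statistics battery.

MSAQ: 16 symptoms on a 1-9 scale in four dimensions (gastrointestinal,
central, peripheral, sopite).  The total score is the percentage of summed
points over all items, category scores the percentage within each category,
so every score lives in [100/9, 100].  The item-to-category map ships as an
editable CSV (default: 4 gastrointestinal / 5 central / 3 peripheral /
4 sopite).

Inference follows the study conventions: condition contrasts on delta
(post - pre) scores use a Shapiro-Wilk normality check reported alongside a
one-tailed Wilcoxon signed-rank test (exact for n <= 25, zeros discarded and
counted); HRV metric contrasts use one-tailed paired t-tests with explicit
directions; associations use Pearson / Spearman / ordinary least squares;
the condition-order check is a one-way fixed-effect F test.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ParameterError
from .synthetic import MSAQResponse

CATEGORIES = ("gastrointestinal", "central", "peripheral", "sopite")
SCALES = ("total",) + CATEGORIES

_TINY_P = 1e-12  # reported p for a forced direction with zero variance


def load_item_categories(path: str | Path | None = None) -> dict[int, str]:
    """Item number (1-16) -> category, from the packaged (or a custom) CSV."""
    if path is None:
        src = resources.files("vims_hrv").joinpath("data/msaq_items.csv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    mapping: dict[int, str] = {}
    for row in csv.DictReader(text.splitlines()):
        cat = row["category"].strip()
        if cat not in CATEGORIES:
            raise ParameterError(f"unknown MSAQ category {cat!r}")
        mapping[int(row["item"])] = cat
    if sorted(mapping) != list(range(1, 17)):
        raise ParameterError("item map must cover items 1-16 exactly once")
    return mapping


@dataclass
class MSAQScores:
    """Percentage scores: total plus the four category subscores."""

    total: float
    gastrointestinal: float
    central: float
    peripheral: float
    sopite: float

    def __getitem__(self, scale: str) -> float:
        return getattr(self, scale)

    def as_dict(self) -> dict:
        return {s: getattr(self, s) for s in SCALES}


def score_msaq(
    resp: MSAQResponse, item_categories: dict[int, str] | None = None
) -> MSAQScores:
    """Score one questionnaire: percentage of summed points, overall and per
    category."""
    cats = item_categories or load_item_categories()
    items = np.asarray(resp.item_scores, dtype=float)
    if items.size != 16:
        missing = sorted(set(range(1, 17)) - set(range(1, items.size + 1)))
        raise ParameterError(f"missing MSAQ items: {missing}")
    out = {"total": float(items.sum() / (9 * 16) * 100.0)}
    for cat in CATEGORIES:
        idx = [i - 1 for i, c in cats.items() if c == cat]
        out[cat] = float(items[idx].sum() / (9 * len(idx)) * 100.0)
    return MSAQScores(**out)


def delta_scores(pre: MSAQScores, post: MSAQScores) -> MSAQScores:
    """Delta change from baseline: post - pre, per scale."""
    return MSAQScores(**{s: post[s] - pre[s] for s in SCALES})


@dataclass
class TestResult:
    """A single statistical test outcome with its tail bookkeeping."""

    name: str
    statistic: float
    p_value: float
    tail: str                      # "one" | "two"
    df: float | None = None
    direction: str | None = None   # stated alternative, e.g. "tes < sham"
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "tail": self.tail,
            "df": self.df,
            "direction": self.direction,
            "degenerate": self.degenerate,
        }
        d.update(self.extras)
        return d


def msaq_condition_comparison(
    deltas_sham: dict[str, np.ndarray] | None = None,
    deltas_tes: dict[str, np.ndarray] | None = None,
) -> dict[str, TestResult]:
    """Per-scale sham-vs-tES comparison of MSAQ delta scores.

    Primary inference: one-tailed Wilcoxon signed-rank with the alternative
    that tES deltas are *lower* than sham deltas.  A Shapiro-Wilk statistic
    on the paired differences is reported alongside.
    """
    results: dict[str, TestResult] = {}
    for scale in SCALES:
        x = np.asarray(deltas_sham[scale], dtype=float)
        y = np.asarray(deltas_tes[scale], dtype=float)
        if x.size != y.size:
            raise ParameterError(f"{scale}: paired sets must have equal size")
        if x.size < 5:
            raise InsufficientDataError(f"{scale}: need n >= 5 pairs")
        d = x - y
        shapiro_stat, shapiro_p = (
            stats.shapiro(d) if np.ptp(d) > 0 else (np.nan, np.nan)
        )
        n_zero = int(np.sum(d == 0))
        if np.all(d == 0):
            results[scale] = TestResult(
                name="wilcoxon_signed_rank",
                statistic=0.0,
                p_value=1.0,
                tail="one",
                direction="tes < sham",
                degenerate=True,
                extras={"shapiro_W": float(shapiro_stat),
                        "shapiro_p": float(shapiro_p),
                        "n_zero_differences": n_zero},
            )
            continue
        mode = "exact" if x.size <= 25 else "approx"
        stat, p = stats.wilcoxon(
            x, y, alternative="greater", zero_method="wilcox", mode=mode
        )
        results[scale] = TestResult(
            name="wilcoxon_signed_rank",
            statistic=float(stat),
            p_value=float(p),
            tail="one",
            direction="tes < sham",
            extras={
                "shapiro_W": float(shapiro_stat),
                "shapiro_p": float(shapiro_p),
                "n_zero_differences": n_zero,
            },
        )
    return results


def paired_t_one_tailed(
    x: np.ndarray, y: np.ndarray, direction: str = "greater", name: str = "paired_t"
) -> TestResult:
    """One-tailed paired t-test on x - y.

    ``direction``: "greater" tests the alternative mean(x - y) > 0, "less"
    the opposite.  Zero-variance differences are flagged degenerate with the
    forced p (0.5 when the mean difference is zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("paired sets must have equal size")
    if x.size < 3:
        raise InsufficientDataError("need n >= 3 pairs")
    if direction not in ("greater", "less"):
        raise ParameterError("direction must be 'greater' or 'less'")
    d = x - y
    df = x.size - 1
    if np.ptp(d) == 0:
        mean = float(d[0])
        if mean == 0:
            return TestResult(name, 0.0, 0.5, "one", df=df, direction=direction,
                              degenerate=True)
        forced = (mean > 0) == (direction == "greater")
        return TestResult(
            name,
            float(np.sign(mean) * np.inf),
            _TINY_P if forced else 1.0,
            "one",
            df=df,
            direction=direction,
            degenerate=True,
        )
    stat, p = stats.ttest_rel(x, y, alternative=direction)
    return TestResult(name, float(stat), float(p), "one", df=df,
                      direction=direction)


def association_analysis(
    x: np.ndarray, y: np.ndarray, method: str = "pearson", name: str | None = None
) -> TestResult:
    """Pearson r, Spearman rank r (both two-tailed) or OLS linear regression."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 4:
        raise InsufficientDataError("need n >= 4 observations")
    name = name or method
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(name, np.nan, 1.0, "two", degenerate=True,
                          extras={"note": "constant input: undefined correlation"})
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return TestResult(name, float(r), float(p), "two", df=x.size - 2)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
        return TestResult(name, float(r), float(p), "two", df=x.size - 2)
    if method == "linreg":
        res = stats.linregress(x, y)
        return TestResult(
            name,
            float(res.slope),
            float(res.pvalue),
            "two",
            df=x.size - 2,
            extras={
                "intercept": float(res.intercept),
                "r_squared": float(res.rvalue**2),
            },
        )
    raise ParameterError(f"unknown association method {method!r}")


def order_effect_test(
    values: np.ndarray, order_labels: np.ndarray, name: str = "order_effect_F"
) -> TestResult:
    """One-way fixed-effect F test of a metric between condition-order groups."""
    values = np.asarray(values, dtype=float)
    order_labels = np.asarray(order_labels)
    groups = [values[order_labels == g] for g in np.unique(order_labels)]
    if len(groups) != 2 or any(g.size < 2 for g in groups):
        raise InsufficientDataError("need two order groups with >= 2 members each")
    means = [g.mean() for g in groups]
    if means[0] == means[1]:
        return TestResult(name, 0.0, 1.0, "two", df=1,
                          degenerate=bool(np.ptp(values) == 0))
    stat, p = stats.f_oneway(*groups)
    return TestResult(name, float(stat), float(p), "two", df=1,
                      extras={"df_within": int(values.size - 2)})
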