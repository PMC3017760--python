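"""Bias and correlation statistics over SSR catalogues and genotypes.

Covers the statistical layer of the analysis: starting-nucleotide
preference within motif classes, the end-vs-middle placement model for
repeat interruptions, heterozygosity-vs-repeat-number curve fits, per
scaffold abundance flags, and the SSR-density vs recombination-rate
regression.

Goodness-of-fit tests are chi-square throughout; for two-cell tables
the exact binomial tail is substituted automatically whenever an
expected cell falls below 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .catalog import SsrLocus
from .motifs import MotifClass, motif_class_members


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (display rule;
    tests and expectations are always computed unrounded)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class BiasTestResult:
    """Chi-square goodness of fit of member counts within a motif class."""

    motif_class: MotifClass
    observed: dict[str, int]
    expected: dict[str, float]
    statistic: float
    p_value: float
    df: int


def starting_preference_test(member_counts: Mapping[str, int]) -> BiasTestResult:
    """Test whether a motif class's members are equally abundant.

    Because both strands are scanned, every rotation and complement of a
    motif tags the same underlying repeat tract; under no starting-base
    preference each member of the class is expected to carry an equal
    share of the class total.
    """
    motifs = list(member_counts)
    if not motifs:
        raise ValueError("empty count table")
    cls = motif_class_members(motifs[0])
    if set(motifs) != set(cls.members):
        missing = set(cls.members) - set(motifs)
        extra = set(motifs) - set(cls.members)
        raise ValueError(f"counts do not cover class {cls.label!r} exactly "
                         f"(missing {sorted(missing)}, extraneous {sorted(extra)})")
    total = sum(member_counts.values())
    if total == 0:
        raise ValueError("class total is zero: test undefined")
    k = cls.size
    exp_each = total / k
    observed = {m: int(member_counts[m]) for m in sorted(cls.members)}
    obs = np.array(list(observed.values()), dtype=float)
    stat = float(((obs - exp_each) ** 2 / exp_each).sum())
    if k == 2 and exp_each < 5:
        p = _st.binomtest(int(obs[0]), total, 0.5, alternative="two-sided").pvalue
    else:
        p = float(_st.chi2.sf(stat, df=k - 1))
    return BiasTestResult(cls, observed, {m: exp_each for m in observed},
                          stat, p, k - 1)


def end_middle_expected(repeat_number: int, total: float) -> tuple[float, float]:
    """Random-placement expectation for interruption positions.

    A locus of ``repeat_number`` units has two terminal units; under
    uniform placement an interruption lands in an end unit with
    probability ``2 / repeat_number`` and in an interior unit otherwise.
    Returns (end, middle) expected counts for ``total`` interruptions.
    """
    if repeat_number < 2:
        raise ValueError("repeat_number must be >= 2")
    if total < 0:
        raise ValueError("total must be non-negative")
    end = total * 2.0 / repeat_number
    return end, total - end


def end_middle_test(end_obs: int, middle_obs: int,
                    repeat_number: int) -> tuple[float, float]:
    """1-df chi-square of observed end/middle interruption counts.

    Expectations come from :func:`end_middle_expected` on the unrounded
    scale; the exact binomial tail replaces the chi-square whenever an
    expected cell is below 5.
    """
    if end_obs < 0 or middle_obs < 0:
        raise ValueError("counts must be non-negative")
    total = end_obs + middle_obs
    if total == 0:
        raise ValueError("zero interruptions: test undefined")
    exp_end, exp_mid = end_middle_expected(repeat_number, total)
    if exp_mid == 0:  # repeat_number == 2: everything is an end unit
        stat = 0.0 if middle_obs == 0 else math.inf
        return stat, 1.0 if middle_obs == 0 else 0.0
    stat = (end_obs - exp_end) ** 2 / exp_end + (middle_obs - exp_mid) ** 2 / exp_mid
    if min(exp_end, exp_mid) < 5:
        p = _st.binomtest(end_obs, total, 2.0 / repeat_number,
                          alternative="two-sided").pvalue
    else:
        p = float(_st.chi2.sf(stat, df=1))
    return float(stat), float(p)


@dataclass(frozen=True)
class RegressionFit:
    """Least-squares fit of a response against repeat number or rate."""

    model: str                  # 'linear' | 'exponential'
    slope: float                # rate constant for the exponential model
    intercept: float            # log(scale) for the exponential model
    r2: float
    p_value: float
    n: int

    @property
    def scale(self) -> float:
        return math.exp(self.intercept) if self.model == "exponential" else self.intercept


def fit_het_curve(points: Sequence[tuple[float, float]],
                  model: str = "linear") -> RegressionFit:
    """Fit % heterozygosity (or any response) against repeat number.

    ``model='linear'`` fits ``y = a + b x``; ``model='exponential'``
    fits ``y = c e^(b x)`` by ordinary least squares on ``log y``
    (all responses must be positive).  r² and the two-sided slope
    p-value are reported on the fitted scale.
    """
    if model not in ("linear", "exponential"):
        raise ValueError(f"unknown model {model!r}")
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: all x equal")
    if model == "exponential":
        if (y <= 0).any():
            raise ValueError("exponential model requires positive responses")
        y = np.log(y)
    res = _st.linregress(x, y)
    return RegressionFit(model, float(res.slope), float(res.intercept),
                         float(res.rvalue ** 2), float(res.pvalue), len(pts))


def select_het_model(points: Sequence[tuple[float, float]]) -> RegressionFit:
    """Fit both curve families and return the better-r² one.

    Falls back to the linear fit when the exponential model is not
    applicable (non-positive responses).
    """
    linear = fit_het_curve(points, "linear")
    try:
        expo = fit_het_curve(points, "exponential")
    except ValueError:
        return linear
    return expo if expo.r2 > linear.r2 else linear


@dataclass(frozen=True)
class MapInterval:
    """Genetic-map interval tying a physical span to a map distance."""

    seq_id: str
    phys_start: int
    phys_end: int
    cm: float

    def __post_init__(self) -> None:
        if self.phys_end <= self.phys_start:
            raise ValueError("phys_end must exceed phys_start")
        if self.cm < 0:
            raise ValueError("cM must be non-negative")

    @property
    def span_mb(self) -> float:
        return (self.phys_end - self.phys_start) / 1e6

    @property
    def cm_per_mb(self) -> float:
        return self.cm / self.span_mb


def density_recombination_correlation(
        loci: Iterable[SsrLocus],
        intervals: Sequence[MapInterval],
        min_motif_size: int = 2,
        max_motif_size: int | None = None,
) -> tuple[RegressionFit, pd.DataFrame]:
    """Regress per-interval SSR density on recombination rate.

    For each genetic-map interval the density of catalogued loci (in
    loci/Mb, filtered to the requested motif-size window) is paired with
    the interval's cM/Mb; a linear least-squares fit is returned along
    with a per-interval table carrying 95% confidence and prediction
    bands around the fitted line.

    Intervals on sequences absent from the catalogue's sequence set are
    kept (density 0 is meaningful only if the sequence was scanned), so
    callers should pass intervals lying within the catalogued assembly.
    """
    locus_list = [l for l in loci
                  if l.motif_size >= min_motif_size
                  and (max_motif_size is None or l.motif_size <= max_motif_size)]
    starts_by_seq: dict[str, np.ndarray] = {}
    for sid in {l.seq_id for l in locus_list}:
        starts_by_seq[sid] = np.sort(np.array(
            [l.start for l in locus_list if l.seq_id == sid]))
    rows = []
    for iv in intervals:
        starts = starts_by_seq.get(iv.seq_id, np.array([], dtype=int))
        k = int(np.searchsorted(starts, iv.phys_end) -
                np.searchsorted(starts, iv.phys_start))
        rows.append({"seq_id": iv.seq_id, "phys_start": iv.phys_start,
                     "phys_end": iv.phys_end, "cm": iv.cm,
                     "cm_per_mb": iv.cm_per_mb, "n_loci": k,
                     "density_per_mb": k / iv.span_mb})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need at least 3 intervals")
    x = table["cm_per_mb"].to_numpy()
    y = table["density_per_mb"].to_numpy()
    if np.allclose(x, x[0]):
        raise ValueError("degenerate recombination rates: all equal")
    res = _st.linregress(x, y)
    fit = RegressionFit("linear", float(res.slope), float(res.intercept),
                        float(res.rvalue ** 2), float(res.pvalue), len(table))
    # 95% confidence (mean) and prediction bands around the fitted line
    n = len(x)
    yhat = res.intercept + res.slope * x
    resid = y - yhat
    s2 = float((resid ** 2).sum() / (n - 2))
    sxx = float(((x - x.mean()) ** 2).sum())
    lever = 1.0 / n + (x - x.mean()) ** 2 / sxx
    tq = _st.t.ppf(0.975, n - 2)
    table["fitted"] = yhat
    table["ci_low"] = yhat - tq * np.sqrt(s2 * lever)
    table["ci_high"] = yhat + tq * np.sqrt(s2 * lever)
    table["pi_low"] = yhat - tq * np.sqrt(s2 * (1 + lever))
    table["pi_high"] = yhat + tq * np.sqrt(s2 * (1 + lever))
    return fit, table


def slope_confidence_interval(fit_table: pd.DataFrame,
                              x_col: str = "cm_per_mb",
                              y_col: str = "density_per_mb",
                              level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for the slope of a simple linear regression."""
    x = fit_table[x_col].to_numpy(dtype=float)
    y = fit_table[y_col].to_numpy(dtype=float)
    n = len(x)
    res = _st.linregress(x, y)
    tq = _st.t.ppf(0.5 + level / 2, n - 2)
    return res.slope - tq * res.stderr, res.slope + tq * res.stderr


@dataclass(frozen=True)
class ScaffoldFlag:
    seq_id: str
    observed: int
    expected: float
    p_value: float           # Bonferroni-adjusted, capped at 1
    flag: str                # '+', '-', or ''


def scaffold_abundance_flags(counts: Mapping[str, int],
                             sizes: Mapping[str, int],
                             alpha: float = 0.05,
                             n_tests: int | None = None) -> list[ScaffoldFlag]:
    """Flag scaffolds whose SSR count departs from the genome-wide rate.

    Each scaffold's locus count is tested against a binomial expectation
    proportional to its length (two-sided exact binomial); p-values are
    Bonferroni-corrected across ``n_tests`` (default: the number of
    scaffolds).  ``+`` marks significant over-abundance, ``-`` a dearth.
    """
    if len(sizes) < 2:
        raise ValueError("need at least 2 scaffolds")
    if any(sz <= 0 for sz in sizes.values()):
        raise ValueError("zero-length scaffold")
    total = sum(counts.get(s, 0) for s in sizes)
    glen = sum(sizes.values())
    m = n_tests if n_tests is not None else len(sizes)
    flags = []
    for sid in sizes:
        k = counts.get(sid, 0)
        p0 = sizes[sid] / glen
        exp = total * p0
        if total == 0:
            padj, flag = 1.0, ""
        else:
            p = _st.binomtest(k, total, p0, alternative="two-sided").pvalue
            padj = min(1.0, p * m)
            flag = ("+" if k > exp else "-") if padj < alpha else ""
        flags.append(ScaffoldFlag(sid, k, exp, padj, flag))
    return flags
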