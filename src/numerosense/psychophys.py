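"""Psychophysics-style evaluations of the numerosity read-out.

Mirrors the classic human paradigms: two-alternative forced choice (2AFC)
relative comparison against a reference numerosity, and absolute magnitude
estimation with its compressive (power-law) bias.  Binomial proportions are
reported with equal-tailed 95% Bayesian credible intervals under a uniform
prior, i.e. quantiles of Beta(k+1, n-k+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .analysis import AnalysisError, LineModel, fit_power_law, perceived_numerosity


@dataclass(frozen=True)
class CredibleInterval:
    lower: float
    upper: float
    level: float = 0.95


def bayesian_binomial_ci(k: int, n: int, level: float = 0.95) -> CredibleInterval:
    """Equal-tailed credible interval for a binomial proportion.

    Uniform Beta(1, 1) prior, so the posterior after k successes in n
    trials is Beta(k+1, n-k+1).  With n = 0 the prior quantiles themselves
    are returned.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo = float(beta_dist.ppf(tail, k + 1, n - k + 1))
    hi = float(beta_dist.ppf(1.0 - tail, k + 1, n - k + 1))
    return CredibleInterval(lower=lo, upper=hi, level=level)


@dataclass
class PsychometricCurve:
    """Proportion of "more" responses per test count against a reference."""

    reference_count: int
    table: "object"          # DataFrame: test_count, proportion_more, n, ci bounds

    def to_frame(self):
        return self.table


def relative_comparison_curve(line: LineModel, embeddings: np.ndarray,
                              counts: np.ndarray, rng: np.random.Generator,
                              reference_count: int = 16,
                              test_counts=None, n_trials: int = 200,
                              mode: str = "distance") -> PsychometricCurve:
    """2AFC numerosity comparison using the embedding line as the signal.

    For each test count, ``n_trials`` random (test, reference) image pairs
    are compared; the model answers "more" when the test embedding's
    perceived numerosity exceeds the reference's.  Exact ties are answered
    "more" with probability 1/2.
    """
    import pandas as pd

    counts = np.asarray(counts, dtype=int)
    perceived = perceived_numerosity(line, embeddings, mode=mode)
    ref_idx = np.flatnonzero(counts == reference_count)
    if len(ref_idx) == 0:
        raise AnalysisError(f"no images with the reference count {reference_count}")
    if test_counts is None:
        test_counts = np.unique(counts)
    rows = []
    for tc in test_counts:
        t_idx = np.flatnonzero(counts == tc)
        if len(t_idx) == 0:
            raise AnalysisError(f"no images with test count {tc}")
        ti = rng.choice(t_idx, size=n_trials, replace=True)
        ri = rng.choice(ref_idx, size=n_trials, replace=True)
        diff = perceived[ti] - perceived[ri]
        more = (diff > 0) | ((diff == 0) & (rng.random(n_trials) < 0.5))
        k = int(more.sum())
        ci = bayesian_binomial_ci(k, n_trials)
        rows.append({"test_count": int(tc), "proportion_more": k / n_trials,
                     "n": n_trials, "ci_lower": ci.lower, "ci_upper": ci.upper})
    return PsychometricCurve(reference_count=reference_count,
                             table=pd.DataFrame(rows))


@dataclass
class EstimationReport:
    """Absolute-estimation summary: per-count distribution of perceived
    numerosity, overall relative error, and the power-law fit."""

    table: "object"                    # DataFrame indexed by true count
    mean_abs_relative_error: float     # over counts >= 1
    power_law: "object"                # PowerLawFit


def absolute_estimation_report(line: LineModel, embeddings: np.ndarray,
                               counts: np.ndarray,
                               mode: str = "distance") -> EstimationReport:
    """Distribution of perceived numerosity for each ground-truth count.

    Relative error is |perceived - true| / true, averaged over all images
    with count >= 1; the power-law fit captures the underestimation bias
    (exponent < 1 means large numbers are compressed).
    """
    import pandas as pd

    counts = np.asarray(counts, dtype=int)
    perceived = perceived_numerosity(line, embeddings, mode=mode)
    df = pd.DataFrame({"count": counts, "perceived": perceived})
    pos = df[df["count"] >= 1]
    rel = (pos["perceived"] - pos["count"]).abs() / pos["count"]
    table = df.groupby("count")["perceived"].agg(["mean", "std", "min", "max"])
    table["mean_relative_error"] = (
        pos.assign(rel=rel).groupby("count")["rel"].mean())
    return EstimationReport(
        table=table,
        mean_abs_relative_error=float(rel.mean()),
        power_law=fit_power_law(df["count"].to_numpy(), df["perceived"].to_numpy()),
    )
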