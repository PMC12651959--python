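"""Paired one-tailed comparisons of translational shifts across treatment arms.

Replicate experiments share day-to-day systematic variation (gradient pouring,
stress response strength, RT efficiency), so shifts measured in two siRNA arms
on the same day form natural pairs. Two statistics are reported:

* a one-tailed paired Student t-test on the per-replicate differences
  d_r = x_r − y_r, with t = d̄ / (s_d/√n) on n−1 degrees of freedom; and
* the Pearson correlation between the paired values — the "pairing
  effectiveness" diagnostic: r near 1 means the pairing soaks up shared
  replicate-level variation and the paired test gains power.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .quantification import RAW, SPIKEIN_NORMALIZED
from .distribution_metrics import ShiftResult

ALTERNATIVES = ("greater", "less")


@dataclass(frozen=True)
class PairedComparison:
    """Result of a one-tailed paired t-test plus the pairing diagnostic.

    ``alternative`` states the tail tested on mean(x − y): "greater" means x
    is hypothesized larger. ``degenerate_variance`` flags a zero-variance
    difference vector, for which the t statistic is reported as ±inf (or 0)
    and the p-value as its limit.
    """

    label_x: str
    label_y: str
    x: tuple[float, ...]
    y: tuple[float, ...]
    n: int
    df: int
    t_statistic: float
    mean_difference: float
    p_one_tailed: float
    pairing_r: float
    pairing_p_one_tailed: float
    alternative: str
    degenerate_variance: bool = False


def paired_one_tailed_ttest(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
    labels: tuple[str, str] = ("x", "y"),
) -> PairedComparison:
    """One-tailed paired Student t-test on d = x − y.

    Uses the sample standard deviation (n−1 denominator) and the Student t
    distribution with n−1 degrees of freedom. If the differences have exactly
    zero variance the limit p-value is reported (0 for a nonzero mean in the
    hypothesized direction, 1 against it, 0.5 for all-zero differences) and
    ``degenerate_variance`` is set.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 2:
        raise ValueError(f"paired t-test needs at least 2 pairs, got {n}")
    d = x - y
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    degenerate = sd == 0.0
    if degenerate:
        if mean_d == 0.0:
            t, p = 0.0, 0.5
        else:
            t = math.inf if mean_d > 0 else -math.inf
            hit = (mean_d > 0) == (alternative == "greater")
            p = 0.0 if hit else 1.0
    else:
        t = mean_d / (sd / math.sqrt(n))
        p = float(stats.t.sf(t, df)) if alternative == "greater" else float(stats.t.cdf(t, df))
    try:
        r, rp = pairing_correlation(x, y)
    except ValueError:
        r, rp = math.nan, math.nan
    return PairedComparison(
        label_x=labels[0],
        label_y=labels[1],
        x=tuple(x),
        y=tuple(y),
        n=n,
        df=df,
        t_statistic=float(t),
        mean_difference=mean_d,
        p_one_tailed=float(p),
        pairing_r=r,
        pairing_p_one_tailed=rp,
        alternative=alternative,
        degenerate_variance=degenerate,
    )


def pairing_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r of the pairs and a one-tailed p-value for positive association.

    p is the upper-tail probability of t = r√((n−2)/(1−r²)) under Student t
    with n−2 df. Perfect correlation (r = ±1) is a degenerate case for which
    the limiting p-value 0 is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"pairing correlation needs at least 3 pairs for a finite p, got {n}")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("pairing correlation undefined: zero variance in one arm")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-14:
        return (math.copysign(1.0, r), 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return (r, float(stats.t.sf(t, n - 2)))


def compare_normalization_modes(
    results: Iterable[ShiftResult],
    arms: tuple[str, str],
    direction: str = "greater",
    gene: str | None = None,
) -> dict:
    """Side-by-side paired comparison of two arms, with and without spike-in.

    ``arms`` is (reference arm, test arm); ``direction="greater"`` tests the
    hypothesis that the test arm's per-replicate shift dF_W exceeds the
    reference arm's. Replicates are matched by replicate index; the same
    replicate set is required in both arms and both normalization modes.

    Returns a report dict with one entry per mode (t, df, one-tailed p, mean
    difference, pairing r and its p), the count of tests run, and whether the
    spike-in-normalized mode was the more statistically discernible one
    (strictly lower p); a tie is reported as such.
    """
    ref_arm, test_arm = arms
    results = [r for r in results if gene is None or r.gene == gene]
    per_mode: dict[str, dict[str, dict[int, float]]] = {}
    for r in results:
        if r.sample_id in arms:
            per_mode.setdefault(r.mode, {}).setdefault(r.sample_id, {})[r.replicate] = r.delta_fw
    report_modes = {}
    rep_sets = set()
    for mode in (RAW, SPIKEIN_NORMALIZED):
        arms_found = per_mode.get(mode, {})
        for arm in arms:
            if arm not in arms_found:
                raise ValueError(f"no {mode} shift results for arm {arm!r}")
        reps_ref = set(arms_found[ref_arm])
        reps_test = set(arms_found[test_arm])
        if reps_ref != reps_test:
            missing = sorted(reps_ref ^ reps_test)
            raise ValueError(f"mismatched replicates between arms in mode {mode}: {missing}")
        rep_sets.add(frozenset(reps_ref))
        reps = sorted(reps_ref)
        x = [arms_found[test_arm][r] for r in reps]
        y = [arms_found[ref_arm][r] for r in reps]
        cmp = paired_one_tailed_ttest(x, y, alternative=direction, labels=(test_arm, ref_arm))
        report_modes[mode] = {"replicates": reps, **asdict(cmp)}
    if len(rep_sets) > 1:
        raise ValueError("replicate sets differ between normalization modes")
    p_raw = report_modes[RAW]["p_one_tailed"]
    p_norm = report_modes[SPIKEIN_NORMALIZED]["p_one_tailed"]
    return {
        "arms": {"reference": ref_arm, "test": test_arm},
        "direction": direction,
        "gene": gene,
        "modes": report_modes,
        "normalized_more_discernible": bool(p_norm < p_raw),
        "tie": bool(p_norm == p_raw),
        "n_tests_run": 2 * len(report_modes),
    }
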