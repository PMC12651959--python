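"""Percentage RNA-signal distributions and the weighted-average shift statistic.

A gradient run is summarized by expressing each fraction's signal as a
percentage of the summed signal over an analysis window (fractions 2-16 by
default, spanning the 40S/60S/80S and polysome regions of a 20-fraction
sucrose gradient), then collapsing the distribution to its signal-weighted
mean fraction number

    F_W = sum_i f_i * p_i / 100

where f_i is the fraction number and p_i the percentage in fraction i.
Heavier (higher-numbered) fractions carry more ribosomes, so a larger F_W
means more of the transcript sits in actively translated polysomes. The
treatment effect is the shift

    dF_W = F_W(treated) - F_W(control)

computed per replicate so the paired test downstream has matched deltas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .quantification import (
    MODES,
    RAW,
    SPIKEIN_NORMALIZED,
    FractionProfile,
    relative_quantity_values,
)

DEFAULT_WINDOW = (2, 16)


def percent_values(values, axis: int = -1) -> np.ndarray:
    """Percent-of-total along ``axis``, ignoring NaN (renormalized over observed)."""
    v = np.asarray(values, dtype=float)
    total = np.nansum(v, axis=axis, keepdims=True)
    if np.any(~(total > 0)):
        raise ValueError("window signal is all-missing or sums to zero")
    return 100.0 * v / total


def fw_values(fractions, percent, axis: int = -1) -> np.ndarray:
    """Weighted-average fraction number from fraction numbers and percentages."""
    f = np.asarray(fractions, dtype=float)
    p = np.asarray(percent, dtype=float)
    return np.nansum(f * p, axis=axis) / 100.0


@dataclass(frozen=True)
class PercentDistribution:
    """Percentage signal per fraction over an analysis window; sums to 100."""

    gene: str
    sample_id: str
    treatment: str
    replicate: int
    fractions: np.ndarray
    percent: np.ndarray
    mode: str = RAW
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=int)
        p = np.asarray(self.percent, dtype=float)
        if f.shape != p.shape or f.ndim != 1 or f.size == 0:
            raise ValueError("fractions and percent must be matching non-empty 1-d arrays")
        if np.any(p < 0):
            raise ValueError("percentages must be nonnegative")
        if abs(p.sum() - 100.0) > 1e-9:
            raise ValueError(f"percentages must sum to 100, got {p.sum()!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "percent", p)


def percent_signal(
    profile: FractionProfile,
    window: tuple[int, int] = DEFAULT_WINDOW,
    fractions: Sequence[int] | None = None,
) -> PercentDistribution:
    """Express a profile's signal as percent of total over the analysis window.

    ``fractions``, if given, restricts the calculation to an explicit subset
    (e.g. the even fractions 2, 4, ..., 16); otherwise every fraction in the
    inclusive ``window`` is used. Fractions absent from the profile or with a
    missing value are excluded and the percentages renormalized over what was
    observed, preserving percentage-of-total semantics.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    wanted = np.asarray(sorted(fractions), dtype=int) if fractions is not None else np.arange(lo, hi + 1)
    if fractions is not None and (wanted.min() < lo or wanted.max() > hi):
        raise ValueError(f"fraction subset {list(wanted)} outside window {window}")
    vals = profile.values.reindex(wanted)
    keep = vals.notna().to_numpy()
    if not keep.any():
        raise ValueError(f"no observed fractions in window {window} for gene {profile.gene!r}")
    v = vals.to_numpy()[keep]
    if not (v > 0).any():
        raise ValueError(f"window signal all zero for gene {profile.gene!r}")
    return PercentDistribution(
        gene=profile.gene,
        sample_id=profile.sample_id,
        treatment=profile.treatment,
        replicate=profile.replicate,
        fractions=wanted[keep],
        percent=percent_values(v),
        mode=profile.mode,
        window=(lo, hi),
    )


def weighted_average_fw(dist: PercentDistribution) -> float:
    """F_W = sum f_i p_i / 100 over the distribution's fractions."""
    return float(fw_values(dist.fractions, dist.percent))


def delta_fw(fw_treated: float, fw_control: float) -> float:
    """Shift in weighted-average fraction: F_W(treated) − F_W(control)."""
    if not (np.isfinite(fw_treated) and np.isfinite(fw_control)):
        raise ValueError("F_W values must be finite")
    return float(fw_treated) - float(fw_control)


@dataclass(frozen=True)
class ShiftResult:
    """F_W per condition and the per-replicate shift, for one gene and mode."""

    sample_id: str
    gene: str
    replicate: int
    mode: str
    fw_control: float
    fw_treated: float

    @property
    def delta_fw(self) -> float:
        return self.fw_treated - self.fw_control


def compute_shift_results(
    profiles: Iterable[FractionProfile],
    window: tuple[int, int] = DEFAULT_WINDOW,
    fractions: Sequence[int] | None = None,
    control: str = "DMEM",
    treated: str = "SOR",
) -> list[ShiftResult]:
    """Pair control/treated profiles by (sample, gene, replicate, mode) and
    compute F_W for each condition plus the per-replicate shift."""
    by_key: dict[tuple, dict[str, FractionProfile]] = {}
    for p in profiles:
        if p.treatment not in (control, treated):
            raise ValueError(f"unexpected treatment {p.treatment!r}")
        by_key.setdefault((p.sample_id, p.gene, p.replicate, p.mode), {})[p.treatment] = p
    results = []
    incomplete = [k for k, v in by_key.items() if len(v) < 2]
    if incomplete:
        raise ValueError(f"missing control/treated counterpart for: {sorted(incomplete)}")
    for (sample_id, gene, replicate, mode), pair in sorted(by_key.items()):
        fw_c = weighted_average_fw(percent_signal(pair[control], window, fractions))
        fw_t = weighted_average_fw(percent_signal(pair[treated], window, fractions))
        results.append(
            ShiftResult(
                sample_id=sample_id,
                gene=gene,
                replicate=replicate,
                mode=mode,
                fw_control=fw_c,
                fw_treated=fw_t,
            )
        )
    return results


def shift_table(results: Iterable[ShiftResult]) -> pd.DataFrame:
    """Tabulate shift results, one row per (sample, gene, replicate, mode)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "gene": r.gene,
            "replicate": r.replicate,
            "mode": r.mode,
            "fw_control": r.fw_control,
            "fw_treated": r.fw_treated,
            "delta_fw": r.delta_fw,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def fraction_recovery_report(
    spikein_profiles: Iterable[FractionProfile],
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-fraction RNA-recovery diagnostic from spike-in relative quantities.

    The spike-in was added in equal amount to every fraction, so its RQ
    directly reads out per-fraction isolation efficiency. Reports, per sample
    and fraction, the RQ, its fold-change against the within-sample median,
    a flag for deviations beyond ``fold_threshold`` in either direction, and
    the within-sample coefficient of variation across fractions.
    """
    if not fold_threshold > 1:
        raise ValueError("fold_threshold must exceed 1")
    profiles = list(spikein_profiles)
    if not profiles:
        raise ValueError("no spike-in profiles given")
    frames = []
    for p in profiles:
        rq = p.values.dropna()
        med = float(rq.median())
        mean = float(rq.mean())
        cv = float(rq.std(ddof=1) / mean) if len(rq) > 1 and mean > 0 else 0.0
        fold = rq / med if med > 0 else np.full(len(rq), np.inf)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": p.sample_id,
                    "treatment": p.treatment,
                    "replicate": p.replicate,
                    "gene": p.gene,
                    "fraction": rq.index,
                    "rq": rq.to_numpy(),
                    "fold_vs_median": np.asarray(fold, dtype=float),
                    "flagged": (fold > fold_threshold) | (fold < 1.0 / fold_threshold),
                    "sample_cv": cv,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fw_from_cq(
    cq_target: np.ndarray,
    cq_spikein: np.ndarray | None,
    efficiency: float = 2.0,
    window: tuple[int, int] = DEFAULT_WINDOW,
    n_fractions: int | None = None,
) -> np.ndarray:
    """Vectorized Cq-to-F_W pipeline core; fractions along the last axis.

    Runs the same arithmetic as the profile-based pipeline
    (relative quantity -> optional spike-in quotient -> window percentages ->
    F_W) on arrays whose last axis indexes fractions 1..n, vectorised over any
    leading axes. Pass ``cq_spikein=None`` for raw (unnormalized) mode. Used
    by simulation studies where building per-profile objects would dominate
    runtime.
    """
    cq_target = np.asarray(cq_target, dtype=float)
    n = n_fractions or cq_target.shape[-1]
    v = relative_quantity_values(cq_target, efficiency)
    if cq_spikein is not None:
        v = v / relative_quantity_values(np.asarray(cq_spikein, dtype=float), efficiency)
    lo, hi = window
    sel = slice(lo - 1, hi)
    frs = np.arange(1, n + 1, dtype=float)[sel]
    return fw_values(frs, percent_values(v[..., sel]))


def plot_percent_distributions(dists: Iterable[PercentDistribution], path=None, ax=None):
    """Line plot of percent signal vs fraction, one line per condition/replicate.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dists = list(dists)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for d in dists:
        ax.plot(d.fractions, d.percent, marker="o",
                label=f"{d.gene} {d.treatment} rep{d.replicate} ({d.mode})")
    ax.set_xlabel("fraction number")
    ax.set_ylabel("% RNA signal")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
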