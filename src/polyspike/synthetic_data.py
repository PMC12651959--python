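"""Generative model of fraction-resolved RT-qPCR readout from a sucrose gradient.

No replicate-level measurements accompany the analysis this package
implements, so recovery of known truth is tested against simulated
experiments. The generator encodes exactly the measurement structure the
spike-in correction assumes:

* each target mRNA has a baseline distribution over the 20 gradient
  fractions, parameterized as a two-component profile (a light/monosome bump
  and a heavy/polysome bump with a mixing weight);
* treatment shifts the distribution toward heavier fractions by a controlled
  amount of F_W, implemented as deterministic mass transport so the true
  shift is known exactly;
* RNA isolation from each fraction loses a multiplicative, log-normally
  distributed portion of the RNA — the fraction-to-fraction inconsistency an
  equal-amount spike-in reveals — and target and spike-in in the same
  fraction share that loss (the identifiability assumption that makes the
  correction valid; ``loss_correlation`` lets tests break it);
* a constant amount of spike-in RNA (the analog of 320 ng of yeast total
  RNA) is present in every fraction;
* qPCR reads out Cq = anchor − log_E(quantity) plus Gaussian cycle noise.

A per-replicate perturbation of the treatment shift (``replicate_effect_sd``),
shared across arms simulated together, models day-to-day variation in the
stress response; it is what makes replicate pairing informative, as a paired
design presumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .quantification import CQ_COLUMNS, DEFAULT_SPIKEIN_GENE
from .distribution_metrics import DEFAULT_WINDOW, fw_values, percent_values

CONDITIONS = ("control", "treated")  # axis order used throughout


def two_peak_weights(
    n_fractions: int = 20,
    light_peak: float = 5.0,
    heavy_peak: float = 12.0,
    heavy_weight: float = 0.45,
    width: float = 1.5,
) -> np.ndarray:
    """Two-component discrete fraction profile: monosome + polysome bumps.

    Gaussian-shaped bumps centered on the light and heavy peak fractions,
    mixed with ``heavy_weight`` on the polysome component, evaluated at
    fractions 1..n and returned as nonnegative weights (unnormalized).
    """
    if not 0.0 <= heavy_weight <= 1.0:
        raise ValueError("heavy_weight must lie in [0, 1]")
    if width <= 0:
        raise ValueError("width must be positive")
    f = np.arange(1, n_fractions + 1, dtype=float)
    bump = lambda c: np.exp(-0.5 * ((f - c) / width) ** 2)
    return (1.0 - heavy_weight) * bump(light_peak) + heavy_weight * bump(heavy_peak)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated polysome-profiling RT-qPCR experiment.

    ``genes`` maps target gene name to baseline weights over fractions 1..n
    (default: a single Bcl-xL-like two-peak profile). ``shift_delta`` is the
    target increase in window F_W under treatment (scalar or per-gene).
    ``loss_sigma`` is the SD of the log-normal per-fraction isolation loss;
    ``cq_sigma`` the Cq measurement noise SD in cycles; ``efficiency`` the
    per-cycle amplification factor E; ``spikein_amount`` the constant
    per-fraction spike-in quantity in arbitrary units; ``cq_anchor`` the Cq
    assigned to unit quantity. ``replicate_effect_sd`` perturbs the shift per
    replicate (shared across arms); ``loss_correlation`` < 1 decouples the
    spike-in's loss from the target's, violating the correction's premise.
    """

    n_fractions: int = 20
    window: tuple[int, int] = DEFAULT_WINDOW
    genes: Mapping[str, np.ndarray] | None = None
    shift_delta: float | Mapping[str, float] = 1.0
    n_replicates: int = 3
    loss_sigma: float = 0.5
    cq_sigma: float = 0.2
    efficiency: float = 2.0
    spikein_amount: float = 320.0
    cq_anchor: float = 18.0
    spikein_gene: str = DEFAULT_SPIKEIN_GENE
    control_label: str = "DMEM"
    treated_label: str = "SOR"
    replicate_effect_sd: float = 0.2
    loss_correlation: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.n_fractions):
            raise ValueError(f"window {self.window} outside 1..{self.n_fractions}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.loss_sigma < 0 or self.cq_sigma < 0 or self.replicate_effect_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if not self.efficiency > 1:
            raise ValueError("amplification efficiency must exceed 1")
        if not self.spikein_amount > 0:
            raise ValueError("spike-in amount must be positive")
        if not 0.0 <= self.loss_correlation <= 1.0:
            raise ValueError("loss_correlation must lie in [0, 1]")
        for gene, w in self.gene_weights().items():
            w = np.asarray(w, dtype=float)
            if w.shape != (self.n_fractions,):
                raise ValueError(f"gene {gene!r}: weights must have length {self.n_fractions}")
            if np.any(w < 0) or not np.any(w[lo - 1 : hi] > 0):
                raise ValueError(
                    f"gene {gene!r}: weights must be nonnegative with mass in the window"
                )
            if gene == self.spikein_gene:
                raise ValueError(f"target gene {gene!r} collides with the spike-in gene id")

    def gene_weights(self) -> dict[str, np.ndarray]:
        if self.genes is None:
            return {"Bcl-xL": two_peak_weights(self.n_fractions)}
        return {g: np.asarray(w, dtype=float) for g, w in self.genes.items()}

    def delta_for(self, gene: str) -> float:
        if isinstance(self.shift_delta, Mapping):
            return float(self.shift_delta[gene])
        return float(self.shift_delta)


def window_fw(weights: np.ndarray, window: tuple[int, int] = DEFAULT_WINDOW) -> float:
    """F_W of a weight vector over the analysis window (fractions 1-based)."""
    lo, hi = window
    w = np.asarray(weights, dtype=float)[lo - 1 : hi]
    return float(fw_values(np.arange(lo, hi + 1, dtype=float), percent_values(w)))


def apply_shift(
    weights: np.ndarray,
    delta: float,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> np.ndarray:
    """Shift a fraction profile's window F_W by exactly ``delta``.

    Deterministic mass transport: for a positive delta, mass is moved from the
    lightest occupied window fractions into the heaviest window fraction until
    the target F_W is reached, the final donor being split fractionally (the
    mirror image for a negative delta). Mass outside the window is untouched
    and window mass is conserved, so the window percentage distribution
    changes only through the reallocation.

    Raises ``ValueError`` if the target F_W falls outside the window — no
    profile on these fractions can achieve it.
    """
    w = np.array(weights, dtype=float)
    lo, hi = window
    if not (1 <= lo <= hi <= len(w)):
        raise ValueError(f"window {window} outside 1..{len(w)}")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    win = w[lo - 1 : hi]
    total = win.sum()
    if not total > 0:
        raise ValueError("no mass in the analysis window")
    frs = np.arange(lo, hi + 1, dtype=float)
    fw = float((frs * win).sum() / total)
    target = fw + float(delta)
    eps = 1e-9
    if target > hi + eps or target < lo - eps:
        raise ValueError(
            f"shift of {delta} from F_W={fw:.6g} unreachable within window {window}"
        )
    if delta == 0:
        return w
    if delta > 0:
        recv = len(win) - 1
        donors = range(0, len(win) - 1)  # lightest first
    else:
        recv = 0
        donors = range(len(win) - 1, 0, -1)  # heaviest first
    needed = target - fw
    for d in donors:
        if win[d] == 0 or needed == 0:
            continue
        per_mass = (frs[recv] - frs[d]) / total  # F_W gain per unit mass moved
        full = win[d] * per_mass
        if abs(full) < abs(needed):
            win[recv] += win[d]
            win[d] = 0.0
            needed -= full
        else:
            m = needed / per_mass
            win[d] -= m
            win[recv] += m
            needed = 0.0
            break
    w[lo - 1 : hi] = win
    return w


@dataclass(frozen=True)
class GeneTruth:
    """True (noise-free) distributions and shifts for one gene in one arm.

    Arrays are indexed [replicate, condition, ...] with condition order
    (control, treated); ``percent`` covers the window fractions only.
    """

    percent: np.ndarray  # (n_rep, 2, n_window)
    fw: np.ndarray  # (n_rep, 2)
    delta_fw: np.ndarray  # (n_rep,)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated arm, for parameter-recovery testing."""

    window: tuple[int, int]
    fractions: np.ndarray  # window fraction numbers
    conditions: tuple[str, str]
    genes: dict[str, GeneTruth]
    loss: np.ndarray  # (n_rep, 2, n_fractions) target-side loss factors L_i
    spikein_loss: np.ndarray  # same shape; equals `loss` when loss_correlation == 1

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "fractions": self.fractions.tolist(),
            "conditions": list(self.conditions),
            "genes": {
                g: {
                    "percent": t.percent.tolist(),
                    "fw": t.fw.tolist(),
                    "delta_fw": t.delta_fw.tolist(),
                }
                for g, t in self.genes.items()
            },
            "loss": self.loss.tolist(),
            "spikein_loss": self.spikein_loss.tolist(),
        }


@dataclass(frozen=True)
class ArmArrays:
    """Array-layout simulation output for one arm: Cq[replicate, condition, fraction]."""

    cq: dict[str, np.ndarray]  # per target gene
    spikein_cq: np.ndarray
    truth: TruthRecord


def _quantity_to_cq(q: np.ndarray, config: SimulationConfig, noise: np.ndarray) -> np.ndarray:
    log_e = math.log(config.efficiency)
    with np.errstate(divide="ignore"):
        cq = config.cq_anchor - np.log(q) / log_e + config.cq_sigma * noise
    return np.where(np.isfinite(cq), cq, np.nan)


def _simulate_arm(
    config: SimulationConfig,
    delta_override: float | None,
    rep_effects: np.ndarray,
    rng: np.random.Generator,
) -> ArmArrays:
    n_r, n_f = config.n_replicates, config.n_fractions
    lo, hi = config.window
    frs_win = np.arange(lo, hi + 1, dtype=int)

    z = rng.standard_normal((n_r, 2, n_f))
    z_extra = rng.standard_normal((n_r, 2, n_f))
    loss = np.exp(config.loss_sigma * z)
    rho = config.loss_correlation
    spike_loss = np.exp(config.loss_sigma * (rho * z + math.sqrt(1.0 - rho * rho) * z_extra))

    gene_cq: dict[str, np.ndarray] = {}
    gene_truth: dict[str, GeneTruth] = {}
    for gene, base in config.gene_weights().items():
        delta = config.delta_for(gene) if delta_override is None else float(delta_override)
        w = np.empty((n_r, 2, n_f))
        w[:, 0, :] = base
        for r in range(n_r):
            w[r, 1, :] = apply_shift(base, delta + rep_effects[r], config.window)
        pct = percent_values(w[:, :, lo - 1 : hi])
        fw = fw_values(frs_win.astype(float), pct)
        gene_truth[gene] = GeneTruth(percent=pct, fw=fw, delta_fw=fw[:, 1] - fw[:, 0])
        noise = rng.standard_normal((n_r, 2, n_f))
        gene_cq[gene] = _quantity_to_cq(w * loss, config, noise)
    spike_noise = rng.standard_normal((n_r, 2, n_f))
    spike_cq = _quantity_to_cq(config.spikein_amount * spike_loss, config, spike_noise)

    truth = TruthRecord(
        window=config.window,
        fractions=frs_win,
        conditions=(config.control_label, config.treated_label),
        genes=gene_truth,
        loss=loss,
        spikein_loss=spike_loss,
    )
    return ArmArrays(cq=gene_cq, spikein_cq=spike_cq, truth=truth)


def simulate_arrays(
    config: SimulationConfig,
    arm_deltas: Mapping[str, float | None] | None = None,
    seed: int | None = None,
) -> dict[str, ArmArrays]:
    """Simulate one experiment in array layout, one entry per arm.

    ``arm_deltas`` maps arm (sample) name to its treatment shift; ``None``
    falls back to the config's ``shift_delta``. Arms simulated together share
    the per-replicate shift effects, mimicking arms processed in parallel on
    the same days. Deterministic given the seed (argument overrides config).
    """
    if arm_deltas is None:
        arm_deltas = {"S1": None}
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rep_effects = config.replicate_effect_sd * rng.standard_normal(config.n_replicates)
    return {arm: _simulate_arm(config, d, rep_effects, rng) for arm, d in arm_deltas.items()}


def _arm_frame(config: SimulationConfig, arm: str, arrays: ArmArrays) -> pd.DataFrame:
    n_r, n_f = config.n_replicates, config.n_fractions
    conds = (config.control_label, config.treated_label)
    genes = [*arrays.cq.keys(), config.spikein_gene]
    reps = np.repeat(np.arange(1, n_r + 1), 2 * n_f)
    treatments = np.tile(np.repeat(conds, n_f), n_r)
    fracs = np.tile(np.arange(1, n_f + 1), 2 * n_r)
    frames = []
    for gene in genes:
        cq = arrays.spikein_cq if gene == config.spikein_gene else arrays.cq[gene]
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": arm,
                    "treatment": treatments,
                    "replicate": reps,
                    "fraction": fracs,
                    "gene": gene,
                    "cq": cq.reshape(-1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[list(CQ_COLUMNS)]


def simulate_study(
    config: SimulationConfig,
    arm_deltas: Mapping[str, float | None] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, TruthRecord]]:
    """Simulate a (possibly multi-arm) experiment as a tidy Cq table plus truth.

    Returns the table with columns (sample_id, treatment, replicate, fraction,
    gene, cq) — one row per well — and a TruthRecord per arm.
    """
    if arm_deltas is None:
        arm_deltas = {"S1": None}
    arrays = simulate_arrays(config, arm_deltas, seed)
    table = pd.concat(
        [_arm_frame(config, arm, arr) for arm, arr in arrays.items()], ignore_index=True
    )
    return table, {arm: arr.truth for arm, arr in arrays.items()}


def simulate_experiment(
    config: SimulationConfig,
    seed: int | None = None,
    sample_id: str = "S1",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate a single-arm experiment; convenience wrapper over simulate_study."""
    table, truths = simulate_study(config, {sample_id: None}, seed)
    return table, truths[sample_id]


def write_truth_record(truth: TruthRecord | Mapping[str, TruthRecord], path) -> None:
    """Write a TruthRecord (or an arm → TruthRecord mapping) as JSON."""
    if isinstance(truth, TruthRecord):
        payload = truth.to_dict()
    else:
        payload = {arm: t.to_dict() for arm, t in truth.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
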