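"""Cq-to-quantity conversion and spike-in normalization for fraction-resolved RT-qPCR.

qPCR reports a quantification cycle (Cq): the cycle at which the amplification
signal crosses threshold. Under exponential amplification with per-cycle
efficiency ``E``, template quantity relates to Cq as ``Q ∝ E**(-Cq)``, so the
*relative quantity* of a target within one per-fraction profile is

    RQ_i = E ** (Cq_min - Cq_i)

with the profile's minimum Cq acting as calibrator (hence ``max(RQ) == 1``).
Any other positive calibrator differs only by a global scale, which the
downstream percentage step removes.

The *normalized relative quantity* divides each fraction's target RQ by the
RQ of an exogenous spike-in reference amplicon (yeast RLP24 by default) that
was added in equal amount to every gradient fraction before RNA isolation.
Because target and spike-in in the same fraction experience the same
isolation loss, the quotient cancels per-fraction recovery differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RAW = "raw"
SPIKEIN_NORMALIZED = "spikein_normalized"
MODES = (RAW, SPIKEIN_NORMALIZED)

#: canonical tidy-table columns for a table of Cq records
CQ_COLUMNS = ("sample_id", "treatment", "replicate", "fraction", "gene", "cq")
#: columns identifying one physical sample-replicate
SAMPLE_KEY = ("sample_id", "treatment", "replicate")

DEFAULT_SPIKEIN_GENE = "RLP24"
DEFAULT_EFFICIENCY = 2.0


def relative_quantity_values(cq, efficiency: float = DEFAULT_EFFICIENCY, axis: int = -1) -> np.ndarray:
    """Convert Cq values to relative quantities, vectorised over leading axes.

    ``axis`` indexes the fractions of one profile; the minimum non-missing Cq
    along that axis is the calibrator. Missing Cq (NaN) yields missing RQ.

    Raises
    ------
    ValueError
        If ``efficiency <= 1`` or any profile has no non-missing Cq.
    """
    cq = np.asarray(cq, dtype=float)
    if not efficiency > 1.0:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency!r}")
    if cq.size == 0 or np.any(np.all(np.isnan(cq), axis=axis)):
        raise ValueError("profile with all Cq values missing")
    cq_min = np.nanmin(cq, axis=axis, keepdims=True)
    return np.power(float(efficiency), cq_min - cq)


@dataclass(frozen=True)
class FractionProfile:
    """Per-fraction relative quantities for one gene in one sample-replicate.

    ``values`` is a float Series indexed by integer fraction number; NaN marks
    a missing (undetermined) measurement.
    """

    gene: str
    sample_id: str
    treatment: str
    replicate: int
    values: pd.Series
    mode: str = RAW

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        vals = pd.Series(self.values, dtype=float).sort_index()
        if vals.empty:
            raise ValueError("profile has no fractions")
        if not all(int(f) == f for f in vals.index):
            raise ValueError("fraction index must be integer")
        vals.index = vals.index.astype(int)
        if (vals.dropna() < 0).any():
            raise ValueError("relative quantities must be nonnegative")
        object.__setattr__(self, "values", vals)

    @property
    def sample_key(self) -> tuple[str, str, int]:
        return (self.sample_id, self.treatment, self.replicate)

    @property
    def fractions(self) -> np.ndarray:
        return self.values.index.to_numpy()


def relative_quantity(
    cq_values,
    efficiency: float = DEFAULT_EFFICIENCY,
    *,
    gene: str = "",
    sample_id: str = "",
    treatment: str = "",
    replicate: int = 0,
) -> FractionProfile:
    """Build a raw-mode :class:`FractionProfile` from one gene+sample Cq profile.

    ``cq_values`` maps fraction number to Cq (Series, dict, or array indexed
    1..n). RQ_i = efficiency**(Cq_min − Cq_i); missing Cq propagates.
    """
    cq = pd.Series(cq_values, dtype=float)
    if not isinstance(cq_values, (pd.Series, Mapping)):
        cq.index = np.arange(1, len(cq) + 1)
    if (cq.dropna() <= 0).any():
        raise ValueError("Cq values must be positive cycles")
    rq = relative_quantity_values(cq.to_numpy(), efficiency)
    return FractionProfile(
        gene=gene,
        sample_id=sample_id,
        treatment=treatment,
        replicate=replicate,
        values=pd.Series(rq, index=cq.index),
        mode=RAW,
    )


def normalize_to_spikein(target: FractionProfile, spikein: FractionProfile) -> FractionProfile:
    """Divide a target profile by the spike-in profile of the same sample-replicate.

    NRQ_i = RQ_target,i / RQ_spikein,i. Missing target values propagate; a
    zero or missing spike-in value where the target is present is an error
    (the fraction cannot be corrected).
    """
    if target.mode != RAW or spikein.mode != RAW:
        raise ValueError("normalization expects raw-mode profiles")
    if target.sample_key != spikein.sample_key:
        raise ValueError(
            f"sample keys differ: target {target.sample_key}, spike-in {spikein.sample_key}"
        )
    if target.gene == spikein.gene:
        raise ValueError(f"target and spike-in must be distinct genes, both {target.gene!r}")
    if not target.values.index.equals(spikein.values.index):
        raise ValueError("target and spike-in cover different fraction sets")
    t, s = target.values, spikein.values
    bad = t.notna() & ~(s > 0)
    if bad.any():
        frs = ", ".join(str(f) for f in t.index[bad])
        raise ValueError(
            f"spike-in quantity missing or zero in fraction(s) {frs} where target is present"
        )
    return replace(target, values=t / s, mode=SPIKEIN_NORMALIZED)


def profiles_from_table(
    table: pd.DataFrame,
    efficiency: float = DEFAULT_EFFICIENCY,
    efficiency_by_gene: Mapping[str, float] | None = None,
) -> list[FractionProfile]:
    """Split a tidy Cq table into raw-mode per-gene, per-sample profiles.

    Per-gene amplification efficiencies override the global default.
    """
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table lacks column(s): {missing}")
    out = []
    for (sample_id, treatment, replicate, gene), grp in table.groupby(
        [*SAMPLE_KEY, "gene"], sort=True
    ):
        eff = (efficiency_by_gene or {}).get(gene, efficiency)
        cq = pd.Series(grp["cq"].to_numpy(dtype=float), index=grp["fraction"].to_numpy())
        out.append(
            relative_quantity(
                cq,
                eff,
                gene=gene,
                sample_id=sample_id,
                treatment=treatment,
                replicate=int(replicate),
            )
        )
    return out


def normalize_profiles(
    profiles: Iterable[FractionProfile],
    spikein_gene: str = DEFAULT_SPIKEIN_GENE,
) -> list[FractionProfile]:
    """Spike-in-normalize every target profile against its sample's spike-in profile."""
    profiles = list(profiles)
    spike = {p.sample_key: p for p in profiles if p.gene == spikein_gene}
    out = []
    for p in profiles:
        if p.gene == spikein_gene:
            continue
        if p.sample_key not in spike:
            raise ValueError(f"no spike-in ({spikein_gene}) profile for sample {p.sample_key}")
        out.append(normalize_to_spikein(p, spike[p.sample_key]))
    return out


def quantify_table(
    table: pd.DataFrame,
    spikein_gene: str = DEFAULT_SPIKEIN_GENE,
    efficiency: float = DEFAULT_EFFICIENCY,
    efficiency_by_gene: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Tidy quantification of a Cq table: relative quantity (``rq``) for every
    gene and spike-in-normalized relative quantity (``nrq``) for targets."""
    raw = profiles_from_table(table, efficiency, efficiency_by_gene)
    norm = normalize_profiles(raw, spikein_gene)
    nrq_lookup = {(p.sample_key, p.gene): p.values for p in norm}
    frames = []
    for p in raw:
        nrq = nrq_lookup.get((p.sample_key, p.gene))
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": p.sample_id,
                    "treatment": p.treatment,
                    "replicate": p.replicate,
                    "fraction": p.values.index,
                    "gene": p.gene,
                    "rq": p.values.to_numpy(),
                    "nrq": np.nan if nrq is None else nrq.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
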