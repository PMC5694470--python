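"""Dose-response arithmetic: Hill block, inverse concentration, hERG ratio.

Fractional channel block follows the Hill equation

    block = 100 * c**h / (IC50**h + c**h)        (percent)

and drug-scaled maximal conductances follow the conductance-block model

    g_drug = (1 - block/100) * g.

The step-1 gating statistic of the two-step classifier is the hERG ratio,
IC60_hERG / EFTPC, where IC60_hERG is always derived from the IC50 and Hill
coefficient via the closed-form inverse, never read from input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .drug_data import ChannelAssay, DrugRecord

__all__ = [
    "BlockProfile", "ConductanceScaling", "fractional_block",
    "concentration_at_block", "herg_ratio", "block_profile",
    "scale_conductances", "CHANNELS",
]

#: blockable channels, in canonical order
CHANNELS = ("IKr", "ICaV", "INaL", "INa_fast", "IKs", "IK1", "Ito")


@dataclass(frozen=True)
class BlockProfile:
    """Per-channel percent block at a stated concentration (nM).

    Channels absent from the drug's assays are 0.
    """

    concentration: float
    block: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for ch, b in self.block.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if not 0.0 <= b <= 100.0:
                raise ValueError(f"block for {ch} outside [0, 100]: {b}")

    def __getitem__(self, channel: str) -> float:
        if channel not in CHANNELS:
            raise KeyError(channel)
        return self.block.get(channel, 0.0)


@dataclass(frozen=True)
class ConductanceScaling:
    """Per-channel conductance multipliers, 1 - block/100."""

    multiplier: Mapping[str, float] = field(default_factory=dict)

    def __getitem__(self, channel: str) -> float:
        if channel not in CHANNELS:
            raise KeyError(channel)
        return self.multiplier.get(channel, 1.0)

    def as_dict(self) -> dict[str, float]:
        return {ch: self[ch] for ch in CHANNELS}


def fractional_block(c: float, assay: "ChannelAssay") -> float:
    """Percent block of a channel at drug concentration ``c`` (nM).

    Monotone nondecreasing in c; 0 at c = 0; approaches 100 as c grows.
    Evaluated in log space so extreme c/IC50 ratios cannot overflow.
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if c == 0.0:
        return 0.0
    h = assay.hill
    # block/100 = 1 / (1 + (IC50/c)**h); compute the exponent in log space
    x = h * (math.log(assay.ic50) - math.log(c))
    if x > 700.0:
        return 0.0
    if x < -700.0:
        return 100.0
    return 100.0 / (1.0 + math.exp(x))


def concentration_at_block(assay: "ChannelAssay", f: float) -> float:
    """Concentration (nM) producing fractional block ``f`` in (0, 1).

    Closed-form inverse of the Hill equation:
    ``IC50 * (f / (1 - f)) ** (1 / h)``.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"target fraction must lie in (0, 1), got {f}")
    return assay.ic50 * (f / (1.0 - f)) ** (1.0 / assay.hill)


def herg_ratio(drug: "DrugRecord") -> float | None:
    """IC60_hERG / EFTPC, or None when IKr assay or EFTPC is missing.

    A None return means the drug cannot enter step 1 of the classifier.
    """
    assay = drug.assay("IKr")
    if assay is None or drug.eftpc is None:
        return None
    return concentration_at_block(assay, 0.6) / drug.eftpc


def block_profile(drug: "DrugRecord", c: float) -> BlockProfile:
    """Percent block of every channel at concentration ``c`` (nM).

    Channels without assays are reported as 0 (assumed-zero policy).
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    block = {}
    for assay in drug.assays:
        block[assay.channel] = fractional_block(c, assay)
    return BlockProfile(concentration=c, block=block)


def scale_conductances(profile: BlockProfile) -> ConductanceScaling:
    """Conductance multipliers (1 - block/100) from a block profile."""
    return ConductanceScaling(
        multiplier={ch: 1.0 - b / 100.0 for ch, b in profile.block.items()})
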