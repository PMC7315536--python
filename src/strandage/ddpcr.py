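"""Poisson quantification for duplex methylation-specific droplet PCR.

A droplet reaction partitions template molecules over tens of thousands of
droplets; each droplet is scored positive or negative per fluorescent
probe.  Because a positive droplet may hold several template copies, the
positive-droplet *fraction* understates the concentration.  Under random
(Poisson) partitioning the mean copies per droplet for a channel is

    lambda = -ln(1 - p_pos)

where ``p_pos`` is that channel's positive fraction.  In a duplex assay
with one probe for the methylated and one for the unmethylated allele, the
methylation level is the rate ratio lambda_meth / (lambda_meth +
lambda_unmeth) — the quantity the naive positives ratio gets wrong at high
droplet occupancy.  Double-positive droplets count as positive in both
channels (standard duplex accounting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DropletCounts

__all__ = [
    "ChannelConcentration",
    "SaturatedAssayError",
    "channel_rates",
    "methylation_fraction",
    "naive_fraction",
    "simulate_droplets",
    "bootstrap_fraction",
]


class SaturatedAssayError(ValueError):
    """All droplets positive in a channel: concentration unbounded."""


@dataclass(frozen=True)
class ChannelConcentration:
    """Mean target copies per droplet for each probe channel."""

    lambda_meth: float
    lambda_unmeth: float
    n_total: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_meth) and np.isfinite(self.lambda_unmeth)):
            raise ValueError("channel rates must be finite")
        if self.lambda_meth < 0 or self.lambda_unmeth < 0:
            raise ValueError("channel rates must be non-negative")


def channel_rates(d: DropletCounts) -> ChannelConcentration:
    """Poisson occupancy correction per channel.

    Raises :class:`SaturatedAssayError` when a channel has no negative
    droplets — the rate is then unbounded and the sample must be diluted.
    """
    pos_meth = d.n_meth_only + d.n_double
    pos_unmeth = d.n_unmeth_only + d.n_double
    rates = []
    for name, pos in (("methylated", pos_meth), ("unmethylated", pos_unmeth)):
        p = pos / d.n_total
        if p >= 1.0:
            raise SaturatedAssayError(
                f"assay {d.assay_id!r}: every droplet positive in the {name} "
                "channel; dilute the sample and repeat"
            )
        rates.append(-np.log1p(-p))
    return ChannelConcentration(float(rates[0]), float(rates[1]), d.n_total)


def methylation_fraction(c: ChannelConcentration) -> float:
    """Methylated fraction as the channel rate ratio."""
    total = c.lambda_meth + c.lambda_unmeth
    if total == 0:
        raise ValueError("no template detected in either channel")
    return c.lambda_meth / total


def naive_fraction(d: DropletCounts) -> float:
    """Positive-droplet ratio without occupancy correction.

    Kept for the bias comparison: at high copies per droplet this estimate
    is pulled toward 0.5 because both channels saturate together.
    """
    pos_meth = d.n_meth_only + d.n_double
    pos_unmeth = d.n_unmeth_only + d.n_double
    if pos_meth + pos_unmeth == 0:
        raise ValueError("no positive droplets")
    return pos_meth / (pos_meth + pos_unmeth)


def simulate_droplets(
    true_fraction: float,
    total_copies: int,
    n_droplets: int,
    seed: int | np.random.Generator,
    assay_id: str = "sim",
) -> DropletCounts:
    """Distribute template copies over droplets uniformly at random.

    Each of ``total_copies`` molecules is methylated with probability
    ``true_fraction`` and lands in a uniformly chosen droplet; droplets are
    then classified into the four duplex categories.  Serves as the
    independent oracle for the Poisson correction.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    if n_droplets <= 0 or total_copies < 0:
        raise ValueError("need positive droplet count and non-negative copies")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # composition is exact: the stated fraction of the input copies is
    # methylated; randomness enters only through droplet placement, the
    # process the occupancy correction models
    n_meth = int(round(total_copies * true_fraction))
    n_unmeth = total_copies - n_meth
    per_drop_meth = rng.multinomial(n_meth, np.full(n_droplets, 1.0 / n_droplets))
    per_drop_unmeth = rng.multinomial(n_unmeth, np.full(n_droplets, 1.0 / n_droplets))
    has_m = per_drop_meth > 0
    has_u = per_drop_unmeth > 0
    return DropletCounts(
        assay_id=assay_id,
        n_total=n_droplets,
        n_meth_only=int(np.sum(has_m & ~has_u)),
        n_unmeth_only=int(np.sum(~has_m & has_u)),
        n_double=int(np.sum(has_m & has_u)),
        n_negative=int(np.sum(~has_m & ~has_u)),
    )


def bootstrap_fraction(
    d: DropletCounts, n_boot: int = 200, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Seeded droplet-resampling interval for the methylation fraction.

    Resamples droplets with replacement and returns the (2.5%, 97.5%)
    percentile interval of the corrected estimate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.array([d.n_meth_only, d.n_unmeth_only, d.n_double, d.n_negative],
                     dtype=float) / d.n_total
    estimates = []
    for _ in range(n_boot):
        counts = rng.multinomial(d.n_total, probs)
        boot = DropletCounts(d.assay_id, d.n_total, *map(int, counts))
        try:
            estimates.append(methylation_fraction(channel_rates(boot)))
        except (SaturatedAssayError, ValueError):
            continue
    if not estimates:
        raise ValueError("bootstrap produced no valid replicates")
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)
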