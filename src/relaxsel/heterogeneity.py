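"""Heterogeneity partitioning (I²) and phylogenetic heritability (H²).

Multilevel meta-analytic heterogeneity: each random level's variance
share of the total — study, species, phylogeny, and a residual share that
absorbs both the residual variance and the typical sampling variance.
Phylogenetic heritability is the phylogenetic fraction of the
species-linked variance, the multilevel analogue of Pagel's lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HeterogeneityPartition",
    "partition_heterogeneity",
    "phylo_heritability",
    "posterior_partition",
]

PARTITION_LEVELS = ("study", "species", "phylogeny", "residual")


@dataclass
class HeterogeneityPartition:
    """I² percentages per level (summing to 100) and H² in [0, 1]."""

    i2: dict  # level -> percent
    h2: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"level": k, "I2_percent": v} for k, v in self.i2.items()]
        rows.append({"level": "H2", "I2_percent": np.nan, "H2": self.h2})
        return pd.DataFrame(rows)


def partition_heterogeneity(
    variances: dict, mean_sampling_variance: float = 0.0
) -> HeterogeneityPartition:
    """Share of total heterogeneity per level, in percent.

    ``variances`` maps level names (any subset of study/species/phylogeny
    plus "residual") to non-negative variance components.  The denominator
    is the sum of all components plus the typical sampling variance; the
    residual share absorbs the sampling variance so shares sum to 100.
    """
    if mean_sampling_variance < 0:
        raise ValueError("mean sampling variance must be non-negative")
    named = {k: float(variances.get(k, 0.0)) for k in PARTITION_LEVELS}
    if any(v < 0 for v in named.values()):
        raise ValueError("variance components must be non-negative")
    total = sum(named.values()) + mean_sampling_variance
    if total <= 0:
        raise ValueError("all variance components are zero; partition undefined")
    i2 = {
        k: 100.0 * named[k] / total
        for k in ("study", "species", "phylogeny")
    }
    i2["residual"] = 100.0 * (named["residual"] + mean_sampling_variance) / total
    return HeterogeneityPartition(i2=i2, h2=phylo_heritability(named))


def phylo_heritability(variances: dict) -> float | None:
    """H² = sigma2_phylo / (sigma2_phylo + sigma2_species).

    Returns None (flagged missing) when both species-linked components are
    zero, where the ratio is undefined.
    """
    vp = float(variances.get("phylogeny", 0.0))
    vs = float(variances.get("species", 0.0))
    if vp < 0 or vs < 0:
        raise ValueError("variance components must be non-negative")
    if vp + vs == 0:
        return None
    return vp / (vp + vs)


def posterior_partition(
    samples, mean_sampling_variance: float = 0.0, ci: float = 0.95,
    residual_scale: float = 1.0,
) -> pd.DataFrame:
    """Per-draw I²/H² partitions summarized with mean and equal-tailed CI.

    ``samples`` is a :class:`relaxsel.mixed.GibbsSamples`; levels absent
    from the model contribute a zero share.  ``residual_scale`` rescales
    the residual variance draw before partitioning — with precision
    weights ``w`` the typical per-record residual variance is
    ``sigma2_e * mean(1/w)``, so the pipeline passes ``mean(1/w)`` here.
    H² draws where both species-linked variances are zero are excluded
    from the H² summary.
    """
    sig = samples.sigma2
    n_draws = next(iter(sig.values())).size
    shares = {k: np.empty(n_draws) for k in PARTITION_LEVELS}
    h2_draws = np.full(n_draws, np.nan)
    for s in range(n_draws):
        vc = {k: sig[k][s] for k in sig}
        if "residual" in vc:
            vc["residual"] = vc["residual"] * residual_scale
        part = partition_heterogeneity(vc, mean_sampling_variance)
        for k in PARTITION_LEVELS:
            shares[k][s] = part.i2[k]
        if part.h2 is not None:
            h2_draws[s] = part.h2
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for k in PARTITION_LEVELS:
        d = shares[k]
        lo, hi = np.quantile(d, [lo_q, hi_q])
        rows.append(
            {"level": k, "post_mean": d.mean(), "lower": lo, "upper": hi}
        )
    h2 = h2_draws[~np.isnan(h2_draws)]
    if h2.size:
        lo, hi = np.quantile(h2, [lo_q, hi_q])
        rows.append({"level": "H2", "post_mean": h2.mean(), "lower": lo, "upper": hi})
    else:
        rows.append(
            {"level": "H2", "post_mean": np.nan, "lower": np.nan, "upper": np.nan}
        )
    return pd.DataFrame(rows)
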