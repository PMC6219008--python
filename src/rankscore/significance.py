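"""Permutation significance against random gene sets, and rank dispersion.

The null hypothesis is that the signature's expected up-regulated genes are
not enriched among high-abundance transcripts (and down-regulated genes not
among low-abundance ones): random gene sets of the same post-intersection
sizes are drawn from the ranked gene universe and scored with the same mode
as the observed signature.  The empirical p-value uses the add-one estimator
so it is never exactly zero.

Rank dispersion is the median absolute deviation (MAD) of the signature
genes' within-sample ranks; by default the raw MAD (consistency constant 1)
since it is used as a relative diagnostic only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ScoringError, ValidationError
from .io import GeneSignature
from .scoring import RankProfile, score_signature

__all__ = [
    "NullDistribution",
    "DispersionResult",
    "permutation_null",
    "empirical_pvalue",
    "rank_dispersion",
]


@dataclass(frozen=True)
class NullDistribution:
    """Scores of B random same-size gene sets in one sample."""

    signature_name: str
    sample_id: str
    set_sizes: tuple[int, ...]
    permuted_scores: np.ndarray
    seed: int

    @property
    def b(self) -> int:
        return int(self.permuted_scores.size)


@dataclass(frozen=True)
class DispersionResult:
    """MAD of signature-gene ranks within one sample (rank units).

    Directions absent from the signature are reported as NaN.
    """

    mad_up: float
    mad_down: float
    mad_total: float


def _mad(x: np.ndarray, constant: float) -> float:
    med = np.median(x)
    return float(constant * np.median(np.abs(x - med)))


def permutation_null(
    rp: RankProfile,
    sig: GeneSignature,
    b: int = 1000,
    seed: int = 0,
    center: bool = True,
) -> NullDistribution:
    """Score ``b`` random gene sets of the observed (post-intersection) sizes.

    For bidirectional signatures the random up- and down-sets of one draw are
    disjoint, matching real signatures.  Reproducible given ``seed``.
    """
    if b < 1:
        raise ValidationError("number of permutations must be >= 1")
    universe = np.asarray(rp.ranks.index)
    n_total = rp.n_total
    n_up = sum(1 for g in sig.up_genes if g in rp.ranks.index)
    n_down = sum(1 for g in sig.down_genes if g in rp.ranks.index)
    if sig.mode == "bidirectional":
        sizes: tuple[int, ...] = (n_up, n_down)
    elif sig.mode == "down":
        sizes = (n_down,)
    else:
        sizes = (n_up,)
    if min(sizes) < 1:
        raise ScoringError(
            f"signature {sig.name!r}: empty set after intersection with data"
        )
    if sum(sizes) > n_total:
        raise ValidationError(
            f"requested random set sizes {sizes} exceed N_total={n_total}"
        )

    rng = np.random.default_rng(seed)
    scores = np.empty(b, dtype=float)
    for i in range(b):
        if sig.mode == "bidirectional":
            draw = rng.choice(universe, size=n_up + n_down, replace=False)
            rand = GeneSignature(sig.name, "bidirectional",
                                 frozenset(draw[:n_up]), frozenset(draw[n_up:]))
        elif sig.mode == "down":
            draw = rng.choice(universe, size=n_down, replace=False)
            rand = GeneSignature(sig.name, "down", down_genes=frozenset(draw))
        else:
            draw = rng.choice(universe, size=n_up, replace=False)
            rand = GeneSignature(sig.name, sig.mode, frozenset(draw))
        scores[i] = score_signature(rp, rand, center=center).total
    return NullDistribution(
        signature_name=sig.name,
        sample_id=rp.sample_id,
        set_sizes=sizes,
        permuted_scores=scores,
        seed=seed,
    )


def empirical_pvalue(
    nd: NullDistribution,
    observed: float,
    alternative: Literal["greater", "less", "two_sided"] = "greater",
) -> float:
    """Add-one empirical p-value of ``observed`` against the permutation null.

    ``greater``: ``p = (1 + #{permuted >= observed}) / (B + 1)``; ``less``
    analogous; ``two_sided`` doubles the smaller tail (capped at 1).
    """
    perm = nd.permuted_scores
    if perm.size == 0:
        raise ValidationError("empty null distribution")
    b = perm.size
    p_greater = (1 + np.count_nonzero(perm >= observed)) / (b + 1)
    if alternative == "greater":
        return float(p_greater)
    p_less = (1 + np.count_nonzero(perm <= observed)) / (b + 1)
    if alternative == "less":
        return float(p_less)
    if alternative == "two_sided":
        return float(min(1.0, 2 * min(p_greater, p_less)))
    raise ValueError(f"unknown alternative: {alternative!r}")


def rank_dispersion(
    rp: RankProfile, sig: GeneSignature, consistency: bool = False
) -> DispersionResult:
    """MAD of the signature genes' ranks within the sample.

    ``mad_total`` is computed over the union of the up- and down-sets.  With
    ``consistency=True`` the 1.4826 normal-consistency constant is applied.
    """
    constant = 1.4826 if consistency else 1.0
    up = rp.ranks_of(sig.up_genes)
    down = rp.ranks_of(sig.down_genes)
    both = np.concatenate([up, down])
    if both.size == 0:
        raise ScoringError(
            f"signature {sig.name!r}: no genes present in sample {rp.sample_id!r}"
        )
    mad_up = _mad(up, constant) if up.size else math.nan
    mad_down = _mad(down, constant) if down.size else math.nan
    return DispersionResult(
        mad_up=mad_up, mad_down=mad_down, mad_total=_mad(both, constant)
    )
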