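"""Cohort-dependent comparator scorers and the scorer registry.

Two minimal baselines are provided for the benchmark harness: the combined
z-score (per-gene standardisation across samples, then ``sum(z)/sqrt(n)``)
and PLAGE (projection of samples onto the first right singular vector of the
standardised set submatrix).  Both use every sample in the cohort to score
each sample — the registry lets the benchmarks contrast that behaviour with
the truly single-sample rank scorer.

Bidirectional signatures are handled as up-score minus down-score for both
comparators.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ScoringError, ValidationError
from .io import ExpressionMatrix, GeneSignature
from .scoring import rank_matrix

__all__ = [
    "CohortScores",
    "zscore_combined",
    "plage_score",
    "rankscore_vector",
    "register_scorer",
    "get_scorer",
    "list_scorers",
]

# A scorer maps (matrix, signature) -> one score per sample, aligned with
# em.sample_ids.
ScorerFn = Callable[[ExpressionMatrix, GeneSignature], np.ndarray]

_SCORERS: dict[str, ScorerFn] = {}


@dataclass(frozen=True)
class CohortScores:
    """Per-sample scores of one signature under one method."""

    method: str
    signature: str
    sample_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sample_ids) != self.scores.size:
            raise ValidationError("scores and sample_ids differ in length")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.sample_ids), name=self.method)


def _standardised_submatrix(em: ExpressionMatrix, genes: frozenset[str],
                            label: str) -> pd.DataFrame:
    if em.n_samples < 2:
        raise ScoringError(
            f"{label}: cohort-dependent methods need >= 2 samples to estimate "
            "per-gene background distributions"
        )
    present = [g for g in em.gene_ids if g in genes]
    if not present:
        raise ScoringError(f"{label}: no signature genes present in the data")
    sub = em.data.loc[present]
    sd = sub.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{label}: dropping {int(zero_var.sum())} zero-variance gene(s)",
            stacklevel=3,
        )
        sub = sub.loc[~zero_var]
        sd = sd[~zero_var]
        if sub.empty:
            raise ScoringError(f"{label}: all signature genes have zero variance")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def _zscore_one(em: ExpressionMatrix, genes: frozenset[str], label: str,
                combine: Literal["sqrt", "mean"]) -> np.ndarray:
    z = _standardised_submatrix(em, genes, label)
    if combine == "mean":
        return z.mean(axis=0).to_numpy()
    return (z.sum(axis=0) / np.sqrt(z.shape[0])).to_numpy()


def zscore_combined(
    em: ExpressionMatrix,
    sig: GeneSignature,
    combine: Literal["sqrt", "mean"] = "sqrt",
) -> CohortScores:
    """Combined z-score of a signature for every sample in the cohort.

    Each gene is standardised across samples; per sample the z-values are
    combined as ``sum(z)/sqrt(n)`` (or plain mean with ``combine="mean"``).
    Bidirectional signatures score as up minus down.
    """
    if sig.mode == "bidirectional":
        s = (_zscore_one(em, sig.up_genes, f"{sig.name} (up)", combine)
             - _zscore_one(em, sig.down_genes, f"{sig.name} (down)", combine))
    elif sig.mode == "down":
        s = -_zscore_one(em, sig.down_genes, sig.name, combine)
    else:
        s = _zscore_one(em, sig.up_genes, sig.name, combine)
    return CohortScores("zscore", sig.name, tuple(em.sample_ids), s)


def _plage_one(em: ExpressionMatrix, genes: frozenset[str], label: str) -> np.ndarray:
    z = _standardised_submatrix(em, genes, label)
    # scores = first right singular vector scaled by its singular value
    _, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    scores = s[0] * vt[0]
    # orient so the score correlates positively with mean standardised
    # expression of the set (the raw vector's sign is arbitrary)
    ref = z.mean(axis=0).to_numpy()
    if np.dot(scores, ref) < 0:
        scores = -scores
    return scores


def plage_score(em: ExpressionMatrix, sig: GeneSignature) -> CohortScores:
    """PLAGE-style activity: projection onto the first singular vector.

    The submatrix restricted to the signature genes is standardised across
    samples and decomposed; sample scores are the first right singular vector
    scaled by its singular value, with the sign fixed by positive correlation
    with the set's mean standardised expression.  Bidirectional signatures
    score as up minus down.
    """
    if sig.mode == "bidirectional":
        s = (_plage_one(em, sig.up_genes, f"{sig.name} (up)")
             - _plage_one(em, sig.down_genes, f"{sig.name} (down)"))
    elif sig.mode == "down":
        s = -_plage_one(em, sig.down_genes, sig.name)
    else:
        s = _plage_one(em, sig.up_genes, sig.name)
    return CohortScores("plage", sig.name, tuple(em.sample_ids), s)


def rankscore_vector(em: ExpressionMatrix, sig: GeneSignature) -> np.ndarray:
    """Vectorised rank-based total score for every sample (single-sample safe).

    Equals ``score_signature`` per column exactly; computed via one ranking
    pass for speed in the benchmark loops.
    """
    ranks = rank_matrix(em)
    n_total = em.n_genes

    def directed(genes: frozenset[str], down: bool) -> np.ndarray:
        present = [g for g in em.gene_ids if g in genes]
        if not present:
            raise ScoringError(f"{sig.name}: no genes present")
        r = ranks.loc[present].to_numpy()
        if down:
            r = n_total + 1 - r
        n_dir = r.shape[0]
        if n_dir == n_total:
            raise ScoringError(f"{sig.name}: set spans the whole universe")
        raw = r.mean(axis=0)
        s_min = (n_dir + 1) / 2
        s_max = (2 * n_total - n_dir + 1) / 2
        return (raw - s_min) / (s_max - s_min)

    if sig.mode == "bidirectional":
        return (directed(sig.up_genes, False) - 0.5) + (directed(sig.down_genes, True) - 0.5)
    if sig.mode == "down":
        return directed(sig.down_genes, True)
    if sig.mode == "up":
        return directed(sig.up_genes, False)
    c = int(np.ceil(n_total / 2))
    present = [g for g in em.gene_ids if g in sig.up_genes]
    if not present:
        raise ScoringError(f"{sig.name}: no genes present")
    r_hat = np.abs(ranks.loc[present].to_numpy() - c)
    n_dir = r_hat.shape[0]
    s_min = (np.ceil(n_dir / 2) + 1) / 2
    s_max = (n_total - np.ceil(n_dir / 2) + 1) / 2
    if s_max == s_min:
        raise ScoringError(f"{sig.name}: undirected bounds collapse")
    return (r_hat.mean(axis=0) - s_min) / (s_max - s_min)


def register_scorer(name: str, fn: ScorerFn | None = None):
    """Register a scorer for the benchmark harness (usable as a decorator).

    A scorer is any callable mapping ``(ExpressionMatrix, GeneSignature)`` to
    a per-sample score vector; external score tables can be wrapped the same
    way, so methods not implemented here can still be benchmarked.
    """
    if fn is None:
        def deco(f: ScorerFn) -> ScorerFn:
            _SCORERS[name] = f
            return f
        return deco
    _SCORERS[name] = fn
    return fn


def get_scorer(name: str) -> ScorerFn:
    try:
        return _SCORERS[name]
    except KeyError:
        raise KeyError(
            f"unknown scorer {name!r}; registered: {sorted(_SCORERS)}"
        ) from None


def list_scorers() -> Sequence[str]:
    return sorted(_SCORERS)


register_scorer("rankscore", rankscore_vector)
register_scorer("zscore", lambda em, sig: zscore_combined(em, sig).scores)
register_scorer("plage", lambda em, sig: plage_score(em, sig).scores)
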