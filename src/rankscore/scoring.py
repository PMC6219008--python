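"""Rank-based single-sample signature scoring.

Each sample is scored in complete isolation: genes are ranked by increasing
abundance within the sample (rank 1 = lowest, ties averaged) and the mean
rank of the signature genes is rescaled between the theoretical minimum and
maximum mean ranks attainable by a set of that size.  For a directed set of
size ``n`` in a universe of ``N`` ranked genes::

    raw   = mean rank of the set          (down-sets use N + 1 - R)
    S_min = (n + 1) / 2
    S_max = (2N - n + 1) / 2
    norm  = (raw - S_min) / (S_max - S_min)

Bidirectional signatures centre each directional score on zero and sum them,
giving a total in [-1, 1].  Undirected sets replace each rank by its absolute
deviation from ceil(N / 2) and use the altered bounds::

    S_min = (ceil(n / 2) + 1) / 2
    S_max = (N - ceil(n / 2) + 1) / 2

The undirected bounds are theoretical, not always attainable, so undirected
normalised scores may fall slightly outside [0, 1]; they are deliberately not
clamped.

Because only within-sample ranks are used, scores are invariant under any
strictly increasing within-sample transform (e.g. log2(x + 1)) and do not
depend on which other samples are present.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateBoundsError, ScoringError
from .io import ExpressionMatrix, GeneSignature

__all__ = [
    "RankProfile",
    "ScoreResult",
    "rank_genes",
    "rank_matrix",
    "score_directed",
    "score_bidirectional",
    "score_undirected",
    "score_signature",
    "score_matrix",
]

logger = logging.getLogger(__name__)

Direction = Literal["up", "down"]


@dataclass(frozen=True)
class RankProfile:
    """Within-sample gene ranks: rank 1 = lowest abundance, ties averaged."""

    sample_id: str
    ranks: pd.Series  # index: gene ids; values: ranks in [1, n_total]
    n_total: int

    def ranks_of(self, genes: Iterable[str]) -> np.ndarray:
        """Ranks of the subset of ``genes`` present in this profile."""
        present = [g for g in genes if g in self.ranks.index]
        return self.ranks.loc[present].to_numpy(dtype=float)


@dataclass(frozen=True)
class ScoreResult:
    """Raw and normalised scores for one (sample, signature) pair.

    ``bounds`` maps each scored direction (``"up"``, ``"down"`` or
    ``"undirected"``) to its theoretical ``(S_min, S_max)``; ``n_used`` maps
    it to the number of signature genes actually observed in the data.
    """

    sample_id: str
    signature_name: str
    mode: str
    total: float
    raw_up: float | None = None
    norm_up: float | None = None
    raw_down: float | None = None
    norm_down: float | None = None
    raw_undirected: float | None = None
    norm_undirected: float | None = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_used: dict[str, int] = field(default_factory=dict)
    centered: bool = False


def rank_genes(em: ExpressionMatrix, sample_id: str) -> RankProfile:
    """Rank genes of one sample by increasing abundance (average ties).

    Uses only this sample's column, so the result is independent of every
    other sample in the matrix.
    """
    if sample_id not in em.sample_ids:
        raise KeyError(f"unknown sample id: {sample_id!r}")
    if em.n_genes < 2:
        raise ScoringError("at least 2 genes are required for ranking")
    col = em.data[sample_id].to_numpy(dtype=float)
    ranks = pd.Series(rankdata(col, method="average"), index=em.gene_ids)
    return RankProfile(sample_id=sample_id, ranks=ranks, n_total=em.n_genes)


def rank_matrix(em: ExpressionMatrix) -> pd.DataFrame:
    """Column-wise ranks of the whole matrix (vectorised fast path).

    Column ``s`` equals ``rank_genes(em, s).ranks`` exactly.
    """
    return pd.DataFrame(
        rankdata(em.values, method="average", axis=0),
        index=em.gene_ids,
        columns=em.sample_ids,
    )


def _present(rp: RankProfile, genes: Iterable[str], label: str) -> np.ndarray:
    r = rp.ranks_of(genes)
    n_named = len(set(genes))
    if r.size == 0:
        raise ScoringError(
            f"no genes of {label!r} are present in sample {rp.sample_id!r}"
        )
    if r.size < n_named:
        logger.debug(
            "%s: dropped %d/%d genes absent from sample %s",
            label, n_named - r.size, n_named, rp.sample_id,
        )
    return r


def _directed_parts(rp: RankProfile, genes: Iterable[str], direction: Direction,
                    label: str) -> tuple[float, float, float, float, int]:
    r = _present(rp, genes, label)
    if direction == "down":
        r = rp.n_total + 1 - r
    n_dir = r.size
    raw = float(r.mean())
    s_min = (n_dir + 1) / 2
    s_max = (2 * rp.n_total - n_dir + 1) / 2
    if s_max == s_min:
        raise DegenerateBoundsError(
            f"signature {label!r} covers the whole gene universe "
            f"(N_dir = N_total = {rp.n_total}); bounds collapse"
        )
    norm = (raw - s_min) / (s_max - s_min)
    return raw, norm, s_min, s_max, n_dir


def score_directed(
    rp: RankProfile,
    genes: Iterable[str],
    direction: Direction = "up",
    signature_name: str = "",
    center: bool = False,
) -> ScoreResult:
    """Score a unidirectional gene set against one sample.

    Signature genes absent from the data are silently dropped (logged at
    DEBUG level).  ``center`` shifts the normalised score by -0.5.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    genes = list(genes)
    label = signature_name or f"{direction}-set"
    raw, norm, s_min, s_max, n_dir = _directed_parts(rp, genes, direction, label)
    total = norm - 0.5 if center else norm
    kwargs = (
        dict(raw_up=raw, norm_up=norm) if direction == "up"
        else dict(raw_down=raw, norm_down=norm)
    )
    return ScoreResult(
        sample_id=rp.sample_id,
        signature_name=label,
        mode=direction,
        total=total,
        bounds={direction: (s_min, s_max)},
        n_used={direction: n_dir},
        centered=center,
        **kwargs,
    )


def score_bidirectional(
    rp: RankProfile, sig: GeneSignature, center: bool = True
) -> ScoreResult:
    """Score a bidirectional signature: per-direction scores, centred, summed."""
    if sig.mode != "bidirectional":
        raise ScoringError(f"signature {sig.name!r} is not bidirectional")
    raw_u, norm_u, smin_u, smax_u, n_u = _directed_parts(
        rp, sig.up_genes, "up", f"{sig.name} (up)")
    raw_d, norm_d, smin_d, smax_d, n_d = _directed_parts(
        rp, sig.down_genes, "down", f"{sig.name} (down)")
    if center:
        total = (norm_u - 0.5) + (norm_d - 0.5)
    else:
        total = norm_u + norm_d
    return ScoreResult(
        sample_id=rp.sample_id,
        signature_name=sig.name,
        mode="bidirectional",
        total=total,
        raw_up=raw_u,
        norm_up=norm_u,
        raw_down=raw_d,
        norm_down=norm_d,
        bounds={"up": (smin_u, smax_u), "down": (smin_d, smax_d)},
        n_used={"up": n_u, "down": n_d},
        centered=center,
    )


def score_undirected(
    rp: RankProfile, genes: Iterable[str], signature_name: str = ""
) -> ScoreResult:
    """Score an undirected set by absolute median-centred ranks.

    The theoretical bounds are applied verbatim, so the normalised score can
    fall slightly below 0 and cannot always reach 1; no clamping is done.
    """
    genes = list(genes)
    label = signature_name or "undirected-set"
    r = _present(rp, genes, label)
    center_rank = math.ceil(rp.n_total / 2)
    r_hat = np.abs(r - center_rank)
    n_dir = r.size
    raw = float(r_hat.mean())
    s_min = (math.ceil(n_dir / 2) + 1) / 2
    s_max = (rp.n_total - math.ceil(n_dir / 2) + 1) / 2
    if s_max == s_min:
        raise DegenerateBoundsError(
            f"signature {label!r}: undirected bounds collapse at "
            f"N_total={rp.n_total}, N_dir={n_dir}"
        )
    norm = (raw - s_min) / (s_max - s_min)
    return ScoreResult(
        sample_id=rp.sample_id,
        signature_name=label,
        mode="undirected",
        total=norm,
        raw_undirected=raw,
        norm_undirected=norm,
        bounds={"undirected": (s_min, s_max)},
        n_used={"undirected": n_dir},
    )


def score_signature(rp: RankProfile, sig: GeneSignature, center: bool = True) -> ScoreResult:
    """Dispatch to the scorer matching ``sig.mode``.

    ``center`` applies to bidirectional signatures only; unidirectional
    signatures are reported uncentred in [0, 1] (use :func:`score_directed`
    with ``center=True`` to shift them).
    """
    if sig.mode == "bidirectional":
        return score_bidirectional(rp, sig, center=center)
    if sig.mode == "up":
        return score_directed(rp, sig.up_genes, "up", sig.name)
    if sig.mode == "down":
        return score_directed(rp, sig.down_genes, "down", sig.name)
    return score_undirected(rp, sig.up_genes, sig.name)


def score_matrix(
    em: ExpressionMatrix,
    sigs: Sequence[GeneSignature],
    center: bool = True,
    dispersion: bool = False,
) -> pd.DataFrame:
    """Score every (sample, signature) pair; one tidy row each.

    A failing pair (e.g. no signature genes in the data) is logged and
    skipped without aborting the remaining work.  Because scoring uses only
    within-sample ranks, each row is identical whether the sample is scored
    alone or within any superset of samples.
    """
    from .significance import rank_dispersion  # local import to avoid a cycle

    rows: list[dict] = []
    for sample_id in em.sample_ids:
        rp = rank_genes(em, sample_id)
        for sig in sigs:
            try:
                res = score_signature(rp, sig, center=center)
            except ScoringError as exc:
                logger.warning("skipping (%s, %s): %s", sample_id, sig.name, exc)
                continue
            row = {
                "sample_id": res.sample_id,
                "signature": res.signature_name,
                "mode": res.mode,
                "score_up": res.norm_up if res.mode != "undirected" else res.norm_undirected,
                "score_down": res.norm_down,
                "total_score": res.total,
            }
            if dispersion:
                disp = rank_dispersion(rp, sig)
                row.update(mad_up=disp.mad_up, mad_down=disp.mad_down,
                           mad_total=disp.mad_total)
            rows.append(row)
    columns = ["sample_id", "signature", "mode", "score_up", "score_down", "total_score"]
    if dispersion:
        columns += ["mad_up", "mad_down", "mad_total"]
    return pd.DataFrame(rows, columns=columns)
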