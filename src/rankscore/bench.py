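"""Synthetic RNA-seq generation and the three benchmark protocols.

Counts are simulated in the style of classic RNA-seq simulators: per-gene
baseline proportions from a log-normal, per-gene dispersions from a scaled
inverse chi-squared distribution (``phi_g = d0 * s0^2 / chi2_d0``), log
fold-changes injected into half of the flagged genes in each direction, and
negative-binomial sampling realised as a gamma-Poisson mixture conditioned on
a fixed library size (gamma rates, then a multinomial of ``library_size``
reads) so every column sums exactly to the target.

Benchmarks:

* ``power_type1`` — per repetition, simulate, build gene sets at several
  DE fractions, score all samples with a registered scorer and t-test the two
  groups; power and type-I error are rejection fractions across repetitions.
* ``recall_f1`` — large simulation, hundreds of gene sets per scenario,
  BH-adjusted t-test p-values thresholded at an FDR cutoff; F1 against the
  true set labels.
* ``stability_experiment`` — every sample scored within random backgrounds of
  varying size on two noisy views of a shared latent expression structure;
  cross-platform Spearman and concordance index summarise stability.

All reports are tidy :class:`pandas.DataFrame` tables (one metric per row)
suitable for direct TSV export.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparators import ScorerFn, get_scorer
from .errors import ScoringError, ValidationError
from .io import ExpressionMatrix, GeneSignature

__all__ = [
    "SimulatedExperiment",
    "simulate_counts",
    "to_expression",
    "make_gene_sets",
    "group_ttest",
    "power_type1",
    "recall_f1",
    "paired_platform_generator",
    "stability_experiment",
    "concordance_index",
]

REPORT_COLUMNS = ["method", "scenario", "metric", "value", "mc_se", "n_reps", "effect_size"]


@dataclass(frozen=True)
class SimulatedExperiment:
    """A simulated two-group count matrix with ground truth."""

    counts: pd.DataFrame          # genes x samples, integer
    group: np.ndarray             # 0/1 per sample
    is_de: np.ndarray             # bool per gene
    true_logfc: np.ndarray        # log2 fold-change per gene (0 for non-DE)
    library_size: int
    dispersions: np.ndarray       # per-gene NB dispersion phi
    seed: int

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def de_genes(self) -> pd.Index:
        return self.counts.index[self.is_de]

    @property
    def non_de_genes(self) -> pd.Index:
        return self.counts.index[~self.is_de]


def simulate_counts(
    n_genes: int = 1000,
    n_samples: int = 30,
    n_de: int = 30,
    logfc: float = 1.0,
    library_size: int = 11_000_000,
    dispersion_df: float = 40.0,
    dispersion_scale: float = 0.04,
    baseline_sigma: float = 1.0,
    seed: int = 0,
) -> SimulatedExperiment:
    """Simulate a two-group RNA-seq count matrix.

    ``n_samples`` is split 50/50 into two conditions; ``n_de`` genes receive
    a log2 fold-change of ``+logfc`` (half) or ``-logfc`` (half) in group 2.
    Dispersions are ``d0 * s0^2 / chi2_d0`` with ``d0 = dispersion_df`` and
    ``s0^2 = dispersion_scale``.  Each sample's counts are a gamma-Poisson
    (negative binomial) draw conditioned on the column total, so column sums
    equal ``library_size`` exactly.
    """
    if n_genes < 2 or n_samples < 2:
        raise ValidationError("need at least 2 genes and 2 samples")
    if n_samples % 2:
        raise ValidationError("n_samples must be even (50/50 group split)")
    if not 0 <= n_de <= n_genes:
        raise ValidationError("n_de must lie in [0, n_genes]")
    if library_size < 1:
        raise ValidationError("library_size must be positive")

    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n_genes)
    base_prop = base / base.sum()

    phi = dispersion_df * dispersion_scale / rng.chisquare(dispersion_df, size=n_genes)

    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    true_logfc = np.zeros(n_genes)
    half = n_de // 2
    true_logfc[de_idx[:half]] = logfc
    true_logfc[de_idx[half:]] = -logfc

    group = np.repeat([0, 1], n_samples // 2)
    prop_g2 = base_prop * 2.0 ** true_logfc
    prop_g2 = prop_g2 / prop_g2.sum()

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = prop_g2 if group[j] else base_prop
        mu = p * library_size
        # gamma-Poisson mixture conditioned on the total: NB marginals with a
        # column sum fixed at library_size
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts[:, j] = rng.multinomial(library_size, lam / lam.sum())

    gene_ids = pd.Index([f"g{i:05d}" for i in range(n_genes)])
    sample_ids = [f"s{j:03d}_grp{group[j]}" for j in range(n_samples)]
    return SimulatedExperiment(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        group=group,
        is_de=is_de,
        true_logfc=true_logfc,
        library_size=library_size,
        dispersions=phi,
        seed=seed,
    )


def to_expression(se: SimulatedExperiment, log: bool = True) -> ExpressionMatrix:
    """CPM-normalise simulated counts into an :class:`ExpressionMatrix`."""
    cpm = se.counts / se.counts.sum(axis=0) * 1e6
    if log:
        return ExpressionMatrix(np.log2(cpm + 1), log_transformed=True)
    return ExpressionMatrix(cpm)


def make_gene_sets(
    se: SimulatedExperiment,
    set_size: int = 30,
    de_fraction: float = 0.5,
    n_sets: int = 1,
    seed: int = 0,
    name_prefix: str | None = None,
) -> list[GeneSignature]:
    """Build bidirectional gene sets mixing DE and non-DE genes.

    Each set draws ``round(set_size * de_fraction)`` DE genes (placed in the
    up/down sub-set according to the sign of their true log fold-change) and
    fills the remainder with non-DE genes split evenly between the two
    sub-sets.  Draws are without replacement within a set.
    """
    n_de_set = round(set_size * de_fraction)
    n_null = set_size - n_de_set
    de_pool = np.asarray(se.de_genes)
    null_pool = np.asarray(se.non_de_genes)
    if n_de_set > de_pool.size:
        raise ValidationError(
            f"need {n_de_set} DE genes per set but only {de_pool.size} simulated"
        )
    if n_null > null_pool.size:
        raise ValidationError(
            f"need {n_null} non-DE genes per set but only {null_pool.size} available"
        )
    lfc = pd.Series(se.true_logfc, index=se.gene_ids)
    rng = np.random.default_rng(seed)
    prefix = name_prefix or f"set_de{int(round(de_fraction * 100))}"
    sigs = []
    for k in range(n_sets):
        up: list[str] = []
        down: list[str] = []
        if n_de_set:
            chosen = rng.choice(de_pool, size=n_de_set, replace=False)
            for g in chosen:
                (up if lfc[g] > 0 else down).append(g)
        if n_null:
            chosen = rng.choice(null_pool, size=n_null, replace=False)
            split = (len(chosen) + 1) // 2
            up.extend(chosen[:split])
            down.extend(chosen[split:])
        # guarantee both sub-sets are non-empty so the bidirectional mode is
        # always scoreable (can occur when all DE draws share one sign)
        if not up or not down:
            src, dst = (down, up) if not up else (up, down)
            dst.append(src.pop())
        sigs.append(
            GeneSignature(f"{prefix}_{k:04d}", "bidirectional",
                          frozenset(up), frozenset(down))
        )
    return sigs


def group_ttest(
    scores: np.ndarray, group: np.ndarray, equal_var: bool = False
) -> float:
    """Two-sample t-test p-value between the two groups (Welch by default)."""
    a, b = scores[group == 0], scores[group == 1]
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def _mc_se(p_hat: float, n: int) -> float:
    return math.sqrt(p_hat * (1 - p_hat) / n) if n else math.nan


def power_type1(
    method: str | ScorerFn,
    effect_sizes: Sequence[float] = (0.5, 1.0, 2.0, 3.0),
    de_fractions: Sequence[float] = (0.5, 0.8, 0.0),
    n_reps: int = 100,
    alpha: float = 0.05,
    n_genes: int = 1000,
    n_samples: int = 30,
    n_de: int = 30,
    set_size: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate power and type-I error of a scorer across a scenario grid.

    Per repetition: simulate, build one gene set per DE fraction, score all
    samples and t-test the groups.  Power rows are reported for DE fractions
    > 0 and a ``type1`` row for the non-DE scenario; each row carries its
    Monte-Carlo standard error.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    scorer = get_scorer(method) if isinstance(method, str) else method
    method_name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    ss = np.random.SeedSequence(seed)
    rows = []
    for ei, effect in enumerate(effect_sizes):
        rejections: dict[float, list[bool]] = {f: [] for f in de_fractions}
        failed = 0
        for rep in range(n_reps):
            child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(ei, rep))
            rep_seed = int(child.generate_state(1)[0])
            se = simulate_counts(n_genes=n_genes, n_samples=n_samples, n_de=n_de,
                                 logfc=effect, seed=rep_seed)
            em = to_expression(se)
            for frac in de_fractions:
                sigs = make_gene_sets(se, set_size=set_size, de_fraction=frac,
                                      n_sets=1, seed=rep_seed + 1)
                try:
                    scores = np.asarray(scorer(em, sigs[0]))
                    p = group_ttest(scores, se.group)
                except ScoringError as exc:
                    warnings.warn(f"rep {rep} failed for {method_name}: {exc}",
                                  stacklevel=2)
                    failed += 1
                    continue
                rejections[frac].append(p < alpha)
        for frac in de_fractions:
            res = rejections[frac]
            if not res:
                continue
            value = float(np.mean(res))
            metric = "type1" if frac == 0 else "power"
            scenario = "non-DE" if frac == 0 else f"{int(round(frac * 100))}% DE"
            rows.append({
                "method": method_name, "scenario": scenario, "metric": metric,
                "value": value, "mc_se": _mc_se(value, len(res)),
                "n_reps": len(res), "effect_size": effect,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _f1(called: np.ndarray, truth: np.ndarray) -> float:
    tp = int(np.sum(called & truth))
    fp = int(np.sum(called & ~truth))
    fn = int(np.sum(~called & truth))
    if tp == 0:
        if fn == 0 and fp == 0:
            return math.nan
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def recall_f1(
    method: str | ScorerFn,
    n_reps: int = 100,
    n_genes: int = 10_000,
    n_samples: int = 30,
    n_de: int = 2000,
    logfc: float = 1.1,
    n_sets: int = 500,
    set_size: int = 30,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-set recall benchmark: F1 of calling DE sets at an FDR threshold.

    Per repetition, three scenario pools of ``n_sets`` bidirectional sets are
    built (50% DE, 80% DE, non-DE).  Each DE pool's t-test p-values are
    combined with the null pool's, BH-adjusted, and thresholded at
    ``q < fdr``; the F1 score is computed against the true labels.
    """
    scorer = get_scorer(method) if isinstance(method, str) else method
    method_name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_reps)]
    f1s: dict[str, list[float]] = {"50% DE": [], "80% DE": []}
    for rep_seed in rep_seeds:
        se = simulate_counts(n_genes=n_genes, n_samples=n_samples, n_de=n_de,
                             logfc=logfc, seed=rep_seed)
        em = to_expression(se)
        pvals: dict[float, np.ndarray] = {}
        for frac in (0.5, 0.8, 0.0):
            sigs = make_gene_sets(se, set_size=set_size, de_fraction=frac,
                                  n_sets=n_sets, seed=rep_seed + int(frac * 10) + 1)
            ps = np.empty(len(sigs))
            for i, sig in enumerate(sigs):
                scores = np.asarray(scorer(em, sig))
                ps[i] = group_ttest(scores, se.group)
            pvals[frac] = ps
        for frac, label in ((0.5, "50% DE"), (0.8, "80% DE")):
            pooled = np.concatenate([pvals[frac], pvals[0.0]])
            truth = np.concatenate([np.ones(n_sets, bool), np.zeros(n_sets, bool)])
            called = multipletests(pooled, alpha=fdr, method="fdr_bh")[0]
            if not called.any():
                warnings.warn(f"{label}: no sets called at FDR {fdr}", stacklevel=2)
            f1s[label].append(_f1(called, truth))
    rows = []
    for label, vals in f1s.items():
        arr = np.asarray(vals, dtype=float)
        rows.append({
            "method": method_name, "scenario": label, "metric": "F1",
            "value": float(np.nanmean(arr)),
            "mc_se": float(np.nanstd(arr, ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else math.nan,
            "n_reps": len(arr), "effect_size": logfc,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def paired_platform_generator(
    n_samples: int = 50,
    n_genes: int = 2000,
    signal_sd: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two platform views of a shared latent expression structure.

    A latent log-expression matrix (per-gene baseline plus gene-by-sample
    signal of scale ``signal_sd``) receives independent per-platform noise of
    scale ``noise_sd``; each platform then applies its own strictly monotone
    distortion so absolute values differ while shared signal is preserved.
    With ``noise_sd=0`` the within-sample gene rankings coincide exactly.
    """
    if signal_sd <= 0 or noise_sd < 0:
        raise ValidationError("signal_sd must be > 0 and noise_sd >= 0")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(6.0, 2.0, size=(n_genes, 1))
    latent = baseline + rng.normal(0.0, signal_sd, size=(n_genes, n_samples))
    noise_a = rng.normal(0.0, noise_sd, size=latent.shape) if noise_sd else 0.0
    noise_b = rng.normal(0.0, noise_sd, size=latent.shape) if noise_sd else 0.0
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    # platform A: linear abundance scale; platform B: compressed log-like
    # scale with an offset — both strictly increasing in the latent value
    mat_a = pd.DataFrame(2.0 ** (latent + noise_a), index=genes, columns=samples)
    mat_b = pd.DataFrame(0.8 * (latent + noise_b) + 4.0, index=genes, columns=samples)
    return (
        ExpressionMatrix(mat_a),
        ExpressionMatrix(mat_b, log_transformed=True),
    )


def concordance_index(x: np.ndarray, y: np.ndarray) -> float:
    """Fraction of sample pairs whose ordering agrees between two score vectors.

    Pairs tied in ``x`` are excluded from the denominator; pairs tied in
    ``y`` (but not ``x``) contribute 0.5.  1.0 = perfect agreement, 0.5 =
    none, 0.0 = perfect reversal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("x and y must be 1-D vectors of equal length >= 2")
    iu = np.triu_indices(x.size, k=1)
    dx = (x[:, None] - x[None, :])[iu]
    dy = (y[:, None] - y[None, :])[iu]
    usable = dx != 0
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValidationError("all values of x are tied; concordance undefined")
    concordant = (dx[usable] * dy[usable]) > 0
    y_tied = dy[usable] == 0
    return float((concordant.sum() + 0.5 * y_tied.sum()) / n_usable)


def stability_experiment(
    scorers: Mapping[str, str | ScorerFn],
    platform_pair: tuple[ExpressionMatrix, ExpressionMatrix],
    sig: GeneSignature,
    sample_sizes: Sequence[int] = (2, 5, 25),
    gene_counts: Sequence[int] | None = None,
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-platform score stability under background sub-sampling.

    For each scorer, background size ``n`` and repetition, every sample is
    scored within a random background of ``n - 1`` other samples on both
    platforms; the Spearman correlation and concordance index between the two
    matched score vectors measure stability.  ``gene_counts`` optionally adds
    a sweep over sub-sampled gene universes (at full sample size).  Scorers
    that cannot run at a given ``n`` (e.g. cohort methods at ``n = 1``) are
    recorded as not-applicable and skipped.
    """
    em_a, em_b = platform_pair
    if list(em_a.sample_ids) != list(em_b.sample_ids):
        raise ValidationError("platforms must share sample ids")
    samples = list(em_a.sample_ids)
    n_total_samples = len(samples)
    resolved = {
        name: (get_scorer(fn) if isinstance(fn, str) else fn)
        for name, fn in scorers.items()
    }
    rng = np.random.default_rng(seed)
    rows = []

    def scored_in_backgrounds(em: ExpressionMatrix, fn: ScorerFn, n: int,
                              bg_choice: np.ndarray) -> np.ndarray:
        out = np.empty(n_total_samples)
        for i, sample in enumerate(samples):
            others = bg_choice[i]
            sub = em.subset(samples=[sample] + [samples[k] for k in others])
            out[i] = np.asarray(fn(sub, sig))[0]
        return out

    for n in sample_sizes:
        if not 1 <= n <= n_total_samples:
            raise ValidationError(f"sample size {n} outside [1, {n_total_samples}]")
        for rep in range(n_reps):
            bg_choice = np.empty((n_total_samples, n - 1), dtype=int)
            for i in range(n_total_samples):
                pool = np.delete(np.arange(n_total_samples), i)
                bg_choice[i] = rng.choice(pool, size=n - 1, replace=False)
            for name, fn in resolved.items():
                try:
                    sa = scored_in_backgrounds(em_a, fn, n, bg_choice)
                    sb = scored_in_backgrounds(em_b, fn, n, bg_choice)
                except ScoringError as exc:
                    rows.append({
                        "method": name, "scenario": f"n={n}", "metric": "not_applicable",
                        "value": math.nan, "mc_se": math.nan, "n_reps": 1,
                        "effect_size": math.nan,
                    })
                    warnings.warn(f"{name} at n={n}: {exc}", stacklevel=2)
                    continue
                rho = float(stats.spearmanr(sa, sb).statistic)
                ci = concordance_index(sa, sb)
                for metric, value in (("spearman", rho), ("c_index", ci)):
                    rows.append({
                        "method": name, "scenario": f"n={n}", "metric": metric,
                        "value": value, "mc_se": math.nan, "n_reps": 1,
                        "effect_size": math.nan,
                    })
    if gene_counts:
        gene_universe = np.asarray(em_a.gene_ids)
        sig_genes = np.asarray([g for g in gene_universe
                                if g in (sig.up_genes | sig.down_genes)])
        other = np.asarray([g for g in gene_universe if g not in set(sig_genes)])
        for n_g in gene_counts:
            if not len(sig_genes) + 1 <= n_g <= gene_universe.size:
                raise ValidationError(
                    f"gene count {n_g} outside [{len(sig_genes) + 1}, "
                    f"{gene_universe.size}]")
            for rep in range(n_reps):
                # the signature itself is kept; the rest of the universe is
                # sub-sampled to size n_g
                keep = np.concatenate([
                    sig_genes,
                    rng.choice(other, size=n_g - sig_genes.size, replace=False),
                ])
                sub_a = em_a.subset(genes=list(keep))
                sub_b = em_b.subset(genes=list(keep))
                for name, fn in resolved.items():
                    try:
                        sa = np.asarray(fn(sub_a, sig))
                        sb = np.asarray(fn(sub_b, sig))
                    except ScoringError:
                        continue
                    rho = float(stats.spearmanr(sa, sb).statistic)
                    ci = concordance_index(sa, sb)
                    for metric, value in (("spearman", rho), ("c_index", ci)):
                        rows.append({
                            "method": name, "scenario": f"genes={n_g}",
                            "metric": metric, "value": value, "mc_se": math.nan,
                            "n_reps": 1, "effect_size": math.nan,
                        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
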