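"""From-scratch preranked gene-set enrichment analysis.

Genes are ranked by a condition-vs-overall fold change: the mean intensity
of each gene within one medium (across donors) divided by its mean across
all samples.  A weighted Kolmogorov-Smirnov-style running sum walks down
the ranked list, stepping up by |metric|^weight (normalized over the set's
hits) at member genes and down by 1/(N - N_hit) elsewhere; the enrichment
score ES is the walk's maximum signed deviation from zero.  Significance
comes from gene-label permutations: NES = ES / mean |null ES| of matching
sign, with an add-one permutation p-value, and a run-wide
Benjamini-Hochberg threshold on the nominal p-values sets the FDR flag.

Only preranked (gene-label permutation) mode is provided: with a single
array per donor x medium cell, phenotype permutation is not possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genesets import GeneSet

__all__ = [
    "GseaRunConfig",
    "GseaResult",
    "rank_metric",
    "enrichment_score",
    "gsea_preranked",
    "run_gsea",
    "bh_threshold",
]

#: below this many matching-sign permutations the NES/p estimates are flagged unstable
_MIN_SIGN_PERMS = 10


@dataclass(frozen=True)
class GseaRunConfig:
    """Settings of a preranked run: walk weight, permutations, seed, FDR level."""

    weight: float = 1.0
    nperm: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.nperm < 100:
            raise ValueError("nperm must be >= 100")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class GseaResult:
    """Outcome for one gene set on one ranked list."""

    set_name: str
    size: int
    es: float
    nes: float
    pvalue: float
    passes_fdr: bool
    nperm: int
    seed: int
    unstable: bool = False


def rank_metric(matrix: pd.DataFrame, samples: pd.DataFrame, medium: str) -> pd.Series:
    """Fold change of each gene: mean within one medium / mean over all samples.

    Returned sorted descending; ties break by gene id (ascending).  Raw-scale
    averages are used, so the metric is a dimensionless expression ratio
    centered around 1 for unaffected genes.
    """
    cols = samples.index[samples["medium"] == medium]
    if len(cols) == 0:
        raise ValueError(f"medium {medium!r} has no samples")
    overall = matrix.mean(axis=1)
    if (overall <= 0).any():
        raise ValueError("overall mean must be positive for every gene")
    metric = matrix[cols].mean(axis=1) / overall
    order = metric.to_frame("metric").reset_index(names="gene").sort_values(
        ["metric", "gene"], ascending=[False, True], kind="mergesort"
    )
    return pd.Series(order["metric"].to_numpy(), index=pd.Index(order["gene"], name="gene"), name=medium)


def _walk_steps(metric: np.ndarray, hit_mask: np.ndarray, weight: float) -> np.ndarray:
    """Per-position increments of the running sum (hits up, misses down)."""
    n = metric.size
    n_hit = int(hit_mask.sum())
    w = np.abs(metric[hit_mask]) ** weight
    total = w.sum()
    if total == 0:  # all hit metrics zero: fall back to equal mass
        w = np.full(n_hit, 1.0 / n_hit)
    else:
        w = w / total
    steps = np.full(n, -1.0 / (n - n_hit)) if n > n_hit else np.zeros(n)
    steps[hit_mask] = w
    return steps


def enrichment_score(ranked: pd.Series, gene_set: GeneSet | frozenset, weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Signed maximum deviation of the running sum, plus the full walk.

    Raises if the set does not intersect the ranked list.  A tie between the
    positive and negative extreme resolves to the positive one.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    hit_mask = ranked.index.isin(members)
    if not hit_mask.any():
        raise ValueError("gene set has no members in the ranked list")
    steps = _walk_steps(ranked.to_numpy(dtype=float), hit_mask, weight)
    walk = np.cumsum(steps)
    top, bottom = float(walk.max()), float(walk.min())
    es = top if top >= -bottom else bottom
    return es, walk


def _es_from_positions(positions: np.ndarray, metric_abs_w: np.ndarray, n: int) -> np.ndarray:
    """ES for many permutations at once, from sorted hit positions.

    ``positions`` is (B, m) of sorted 0-based ranks; the walk's extremes can
    only occur immediately before or at a hit, so only those 2m points per
    permutation are evaluated.  Identical to the full running sum.
    """
    b, m = positions.shape
    w = metric_abs_w[positions]
    totals = w.sum(axis=1, keepdims=True)
    safe = totals > 0
    w = np.where(safe, w / np.where(safe, totals, 1.0), 1.0 / m)
    cumw = np.cumsum(w, axis=1)
    miss_dec = 1.0 / (n - m)
    misses_before = positions - np.arange(m)[None, :]
    tops = cumw - misses_before * miss_dec
    bottoms = tops - w
    top_max = tops.max(axis=1)
    bottom_min = np.minimum(bottoms.min(axis=1), 0.0)
    return np.where(top_max >= -bottom_min, top_max, bottom_min)


def gsea_preranked(
    ranked: pd.Series, sets: list[GeneSet], config: GseaRunConfig, rng: np.random.Generator | None = None
) -> list[GseaResult]:
    """Score each set against one ranked list with gene-label permutation nulls.

    NES normalizes ES by the mean |null ES| of the matching sign; the
    nominal p uses the add-one estimator over matching-sign nulls, so it is
    never exactly zero.  passes_fdr is set by a BH threshold across this
    call's tests; for multi-condition runs :func:`run_gsea` recomputes the
    flag across all condition x set tests.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(ranked)
    metric_abs_w = np.abs(ranked.to_numpy(dtype=float)) ** config.weight
    results = []
    for s in sets:
        es, _ = enrichment_score(ranked, s, config.weight)
        m = int(ranked.index.isin(s.members).sum())
        # null: m random positions among n ranks, nperm times
        positions = np.sort(rng.random((config.nperm, n)).argsort(axis=1)[:, :m], axis=1)
        null_es = _es_from_positions(positions, metric_abs_w, n)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        unstable = n_same < _MIN_SIGN_PERMS
        denom = float(np.abs(null_es[same_sign]).mean()) if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
        results.append(
            GseaResult(
                set_name=s.name, size=m, es=es, nes=float(nes), pvalue=float(p),
                passes_fdr=False, nperm=config.nperm, seed=config.seed, unstable=unstable,
            )
        )
    thr = bh_threshold(np.array([r.pvalue for r in results]), config.alpha)
    for r in results:
        r.passes_fdr = r.pvalue <= thr
    return results


def bh_threshold(pvalues: np.ndarray, alpha: float = 0.05) -> float:
    """Largest sorted p_(i) with p_(i) <= i * alpha / m; 0 if none qualifies."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    crit = (np.arange(1, m + 1) * alpha) / m
    ok = p <= crit
    return float(p[ok].max()) if ok.any() else 0.0


def run_gsea(
    matrix: pd.DataFrame, samples: pd.DataFrame, sets: list[GeneSet], config: GseaRunConfig
) -> pd.DataFrame:
    """Preranked GSEA of every medium against the overall average.

    One ranked list per medium (condition-vs-overall fold change), each set
    scored on each list; the BH threshold is computed across all
    medium x set nominal p-values and sets passes_fdr.  A single seeded
    generator drives all permutations, so results are reproducible.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for medium in sorted(samples["medium"].unique()):
        ranked = rank_metric(matrix, samples, medium)
        for r in gsea_preranked(ranked, sets, config, rng=rng):
            rows.append(
                {
                    "medium": medium, "set": r.set_name, "size": r.size, "es": r.es,
                    "nes": r.nes, "pvalue": r.pvalue, "unstable": r.unstable,
                }
            )
    out = pd.DataFrame(rows)
    thr = bh_threshold(out["pvalue"].to_numpy(), config.alpha)
    out["bh_threshold"] = thr
    out["passes_fdr"] = out["pvalue"] <= thr
    return out
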