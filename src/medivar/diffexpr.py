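"""Pairwise differential expression with replicate swapping and a moderated t.

With two crossed factors (culture medium, donor) and one array per cell,
neither factor has conventional replicates.  The design is analysed by
*replicate swapping*: when two media are compared, the donors cultured in
the same medium act as replicates; when two donors are compared, the media
act as replicates.  Each pairwise contrast is then a two-group comparison.

Gene-wise variances are unstable at n = 3-4 per group, so the t-statistic
is moderated by empirical-Bayes shrinkage: the pooled gene variance s_g^2
(d_g residual df) is shrunk toward a prior s_0^2 with prior df d_0,

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),

and the moderated t = log2FC / (s~_g sqrt(1/n_A + 1/n_B)) is referred to a
t distribution on d_0 + d_g degrees of freedom.  (d_0, s_0^2) are estimated
by moment matching on the distribution of log s_g^2 across genes; d_0 = 0
recovers the ordinary pooled t and d_0 = inf fully pools the variance.

The module follows the model/results idiom: build a
:class:`PairwiseContrast` from a log2 matrix and sample annotations, call
``fit()``, and read estimates, p-values and volcano classes off the
returned :class:`ContrastResult`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastSpec",
    "ModerationPrior",
    "PairwiseContrast",
    "ContrastResult",
    "fit_contrast",
    "fit_all_contrasts",
    "estimate_prior",
    "adjust_bh",
    "classify_volcano",
    "collect_de_sets",
    "pairwise_summary",
    "top_fc_subset",
    "top_genes_table",
    "enumerate_contrasts",
]

VOLCANO_CLASSES = ("red", "green", "blue", "grey")


class DesignError(ValueError):
    """The sample layout cannot support the requested contrast."""


class DegenerateFitError(RuntimeError):
    """No gene-wise variance information to estimate the prior from."""


@dataclass(frozen=True)
class ContrastSpec:
    """One pairwise comparison: ``level_a`` vs ``level_b`` of ``factor``.

    The other factor's levels serve as replicates.  log2FC is reported as
    A minus B on the log scale.
    """

    factor: str  # "medium" | "donor"
    level_a: str
    level_b: str

    def __post_init__(self) -> None:
        if self.level_a == self.level_b:
            raise ValueError("contrast levels must differ")

    @property
    def name(self) -> str:
        return f"{self.level_a}_vs_{self.level_b}"


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes prior: df ``d0`` (0 = no moderation, inf = full pooling) and variance ``s0_sq``."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0 (or inf)")
        if self.s0_sq <= 0 and self.d0 > 0:
            raise ValueError("s0_sq must be > 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing target)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, dg: float) -> ModerationPrior:
    """Moment-match (d0, s0^2) to the spread of log gene-wise variances.

    Under the scaled-F model, e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)
    has mean log s_0^2 - digamma(d_0/2) + log(d_0/2) and excess variance
    trigamma(d_0/2) beyond the sampling term trigamma(d_g/2); d_0 follows
    by trigamma inversion.  Zero variances carry no information on the log
    scale and are excluded; if every gene has zero variance the fit is
    degenerate.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise DegenerateFitError("all gene-wise variances are zero; cannot estimate a prior")
    z = np.log(pos)
    e = z - float(special.digamma(dg / 2.0)) + math.log(dg / 2.0)
    e_mean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, dg / 2.0)) if pos.size > 1 else 0.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess spread: variances are exchangeable, pool them completely
        d0 = math.inf
        s0_sq = float(np.mean(pos))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def adjust_bh(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_volcano(
    log2fc: np.ndarray, adj_p: np.ndarray, fc_threshold: float = 2.0, alpha: float = 0.05
) -> np.ndarray:
    """Four-way volcano labels.

    red: |log2FC| >= log2(threshold) and adjusted p < alpha; green: fold
    change only; blue: significance only; grey: neither.  Boundary
    p == alpha counts as non-significant.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    adj_p = np.asarray(adj_p, dtype=float)
    fc_met = np.abs(log2fc) >= np.log2(fc_threshold)
    sig = adj_p < alpha
    out = np.where(fc_met & sig, "red", np.where(fc_met, "green", np.where(sig, "blue", "grey")))
    return out.astype(object)


class ContrastResult:
    """Fitted contrast: per-gene estimates, inference and volcano classes.

    ``table`` columns: mean_a, mean_b, log2fc, s2, s2_moderated, t, df,
    pvalue, adj_pvalue, volcano_class.  ``prior`` holds the (estimated or
    supplied) moderation hyperparameters.
    """

    def __init__(
        self,
        spec: ContrastSpec,
        table: pd.DataFrame,
        prior: ModerationPrior,
        n_a: int,
        n_b: int,
        fc_threshold: float,
        alpha: float,
    ):
        self.spec = spec
        self.table = table
        self.prior = prior
        self.n_a = n_a
        self.n_b = n_b
        self.fc_threshold = fc_threshold
        self.alpha = alpha

    # -- convenience views -------------------------------------------------
    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def adj_pvalue(self) -> pd.Series:
        return self.table["adj_pvalue"]

    @property
    def volcano_class(self) -> pd.Series:
        return self.table["volcano_class"]

    def red_genes(self) -> pd.Index:
        """Genes significant (BH-adjusted p < alpha) at >= the fold-change threshold."""
        return self.table.index[self.table["volcano_class"] == "red"]

    def class_counts(self) -> pd.Series:
        return self.table["volcano_class"].value_counts().reindex(VOLCANO_CLASSES, fill_value=0)

    def summary(self) -> str:
        c = self.class_counts()
        lines = [
            f"Contrast {self.spec.name} ({self.spec.factor}; n={self.n_a} vs n={self.n_b})",
            f"  moderation prior: d0={self.prior.d0:.4g}, s0^2={self.prior.s0_sq:.4g}",
            f"  thresholds: FC >= {self.fc_threshold}, BH-adjusted p < {self.alpha}",
            "  volcano classes: " + ", ".join(f"{k}={c[k]}" for k in VOLCANO_CLASSES),
        ]
        top = top_genes_table({self.spec.name: self}, k=3)
        if len(top):
            lines.append("  top genes by |log2FC|:")
            for _, row in top.iterrows():
                lines.append(
                    f"    {row['gene']}: FC={row['fold_change']:.2f} ({row['direction']}), "
                    f"adj p={row['adj_pvalue']:.3g}"
                )
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Volcano plot (log2FC vs -log10 adjusted p) colored by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        logp = -np.log10(np.maximum(self.table["adj_pvalue"].to_numpy(), 1e-300))
        for cls in VOLCANO_CLASSES:
            m = self.table["volcano_class"] == cls
            ax.scatter(self.table.loc[m, "log2fc"], logp[m.to_numpy()], s=4, c=cls, label=cls)
        ax.axhline(-np.log10(self.alpha), ls="--", lw=0.5, c="k")
        for s in (-1, 1):
            ax.axvline(s * np.log2(self.fc_threshold), ls="--", lw=0.5, c="k")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 adjusted p")
        ax.set_title(self.spec.name)
        return ax


class PairwiseContrast:
    """Two-group moderated-t model for one pairwise contrast.

    Parameters
    ----------
    log2_matrix : genes x samples frame of log2 intensities.
    samples : sample annotation with a column named after ``spec.factor``.
    spec : which levels to compare; the other factor supplies replicates.
    """

    def __init__(self, log2_matrix: pd.DataFrame, samples: pd.DataFrame, spec: ContrastSpec):
        if spec.factor not in samples.columns:
            raise DesignError(f"factor {spec.factor!r} not in sample annotation")
        labels = samples.loc[log2_matrix.columns, spec.factor]
        self._cols_a = log2_matrix.columns[labels == spec.level_a]
        self._cols_b = log2_matrix.columns[labels == spec.level_b]
        for level, cols in ((spec.level_a, self._cols_a), (spec.level_b, self._cols_b)):
            if len(cols) < 2:
                raise DesignError(f"level {level!r} has {len(cols)} replicate sample(s); >= 2 required")
        self.data = log2_matrix
        self.spec = spec

    @classmethod
    def from_intensities(cls, matrix: pd.DataFrame, samples: pd.DataFrame, spec: ContrastSpec):
        """Build from a raw (positive) intensity matrix, taking log2 internally."""
        if (matrix.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive to take logs")
        return cls(np.log2(matrix), samples, spec)

    def fit(
        self,
        prior: ModerationPrior | str = "estimate",
        fc_threshold: float = 2.0,
        alpha: float = 0.05,
    ) -> ContrastResult:
        """Estimate per-gene log2FC and moderated-t inference for the contrast."""
        a = self.data[self._cols_a].to_numpy(dtype=float)
        b = self.data[self._cols_b].to_numpy(dtype=float)
        n_a, n_b = a.shape[1], b.shape[1]
        dg = n_a + n_b - 2

        mean_a = a.mean(axis=1)
        mean_b = b.mean(axis=1)
        log2fc = mean_a - mean_b
        ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
        s2 = ss / dg

        if isinstance(prior, str):
            if prior != "estimate":
                raise ValueError("prior must be a ModerationPrior or 'estimate'")
            prior = estimate_prior(s2, dg)

        if math.isinf(prior.d0):
            s2_mod = np.full_like(s2, prior.s0_sq)
            df_total = math.inf
        elif prior.d0 == 0:
            s2_mod = s2
            df_total = float(dg)
        else:
            s2_mod = (prior.d0 * prior.s0_sq + dg * s2) / (prior.d0 + dg)
            df_total = prior.d0 + dg

        se = np.sqrt(s2_mod * (1.0 / n_a + 1.0 / n_b))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(log2fc == 0.0, 0.0, log2fc / se)
        t = np.where(np.isnan(t), 0.0, t)  # 0/0: no difference, no evidence
        if math.isinf(df_total):
            pvalue = 2.0 * stats.norm.sf(np.abs(t))
        else:
            pvalue = 2.0 * stats.t.sf(np.abs(t), df_total)
        adj = adjust_bh(pvalue)

        table = pd.DataFrame(
            {
                "mean_a": mean_a,
                "mean_b": mean_b,
                "log2fc": log2fc,
                "s2": s2,
                "s2_moderated": s2_mod,
                "t": t,
                "df": df_total,
                "pvalue": pvalue,
                "adj_pvalue": adj,
                "volcano_class": classify_volcano(log2fc, adj, fc_threshold, alpha),
            },
            index=self.data.index,
        )
        return ContrastResult(self.spec, table, prior, n_a, n_b, fc_threshold, alpha)


def fit_contrast(
    log2_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    spec: ContrastSpec,
    prior: ModerationPrior | str = "estimate",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> ContrastResult:
    """Functional wrapper: build the model and fit in one call."""
    return PairwiseContrast(log2_matrix, samples, spec).fit(prior, fc_threshold, alpha)


def enumerate_contrasts(samples: pd.DataFrame, factor: str) -> list[ContrastSpec]:
    """All unordered level pairs of ``factor``, in sorted-level order."""
    levels = sorted(samples[factor].unique())
    return [ContrastSpec(factor, a, b) for a, b in combinations(levels, 2)]


def fit_all_contrasts(
    log2_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    factor: str,
    prior: ModerationPrior | str = "estimate",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> dict[str, ContrastResult]:
    """Fit every pairwise contrast of a factor; keyed by contrast name."""
    return {
        spec.name: fit_contrast(log2_matrix, samples, spec, prior, fc_threshold, alpha)
        for spec in enumerate_contrasts(samples, factor)
    }


def collect_de_sets(
    media_contrasts: dict[str, ContrastResult], donor_contrasts: dict[str, ContrastResult]
) -> tuple[set, set, set]:
    """Union of red-class genes across media contrasts, donor contrasts, and both."""
    if not media_contrasts or not donor_contrasts:
        raise ValueError("both factors' contrasts are required")
    media_set = set().union(*(set(r.red_genes()) for r in media_contrasts.values()))
    line_set = set().union(*(set(r.red_genes()) for r in donor_contrasts.values()))
    return media_set, line_set, media_set | line_set


def pairwise_summary(contrasts: dict[str, ContrastResult]) -> tuple[float, float]:
    """Mean and sample SD of red-gene counts per pairwise comparison."""
    counts = [len(r.red_genes()) for r in contrasts.values()]
    if len(counts) < 2:
        raise ValueError("need >= 2 contrasts to summarize")
    return float(np.mean(counts)), float(np.std(counts, ddof=1))


def _ranked_red(result: ContrastResult) -> pd.DataFrame:
    red = result.table[result.table["volcano_class"] == "red"].copy()
    red["abs_log2fc"] = red["log2fc"].abs()
    red = red.reset_index(names="gene")
    # largest effect first; ties by smaller adjusted p then gene id
    return red.sort_values(
        ["abs_log2fc", "adj_pvalue", "gene"], ascending=[False, True, True], kind="mergesort"
    )


def top_fc_subset(contrasts: dict[str, ContrastResult], fraction: float = 0.05) -> set:
    """Per contrast, the ceil(fraction * n_red) largest-|log2FC| red genes; union over contrasts."""
    out: set = set()
    for result in contrasts.values():
        red = _ranked_red(result)
        if len(red):
            out |= set(red["gene"].head(math.ceil(fraction * len(red))))
    return out


def top_genes_table(contrasts: dict[str, ContrastResult], k: int = 3) -> pd.DataFrame:
    """Per contrast, the k red genes of largest |log2FC|, with magnitude FC and direction."""
    rows = []
    for name, result in contrasts.items():
        red = _ranked_red(result).head(k)
        for rank, (_, r) in enumerate(red.iterrows(), start=1):
            rows.append(
                {
                    "contrast": name,
                    "rank": rank,
                    "gene": r["gene"],
                    "log2fc": r["log2fc"],
                    "fold_change": 2.0 ** abs(r["log2fc"]),
                    "direction": "up" if r["log2fc"] >= 0 else "down",
                    "adj_pvalue": r["adj_pvalue"],
                }
            )
    return pd.DataFrame(rows, columns=["contrast", "rank", "gene", "log2fc", "fold_change", "direction", "adj_pvalue"])
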