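"""Normalization and expression filtering for gene-level fluorescence matrices.

The pipeline reduces a raw intensity matrix to an "expressed transcriptome":

1. pick the reference housekeeping genes (lowest log2 SD among candidates),
2. scale each sample so its housekeeping mean matches the grand mean,
3. define a detection limit as a high percentile of the pooled intensities
   of negative-control genes (lineage markers not expected in the cells),
4. keep genes clearing the limit under a three-criterion rule,
5. drop Y-chromosome genes and XIST so donor sex does not masquerade as a
   genetic-background effect.

Counts at every stage are recorded in a :class:`PreprocessReport` and
telescope: retained + removed equals the input gene count at each step.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import logging

import numpy as np
import pandas as pd

__all__ = [
    "select_housekeeping",
    "normalize_by_hkg",
    "detection_limit",
    "filter_expressed",
    "exclude_sex_genes",
    "run_preprocess",
    "PreprocessReport",
]

log = logging.getLogger(__name__)


class LookupError_(KeyError):
    """A referenced gene id is absent from the matrix."""


def _check_present(matrix: pd.DataFrame, ids, what: str) -> None:
    missing = [g for g in ids if g not in matrix.index]
    if missing:
        raise LookupError_(f"{what} not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")


def select_housekeeping(matrix: pd.DataFrame, candidates: list[str], k: int) -> list[str]:
    """Return the ``k`` candidate genes with the lowest log2-scale standard deviation.

    SD is the sample standard deviation (n-1 denominator) of log2 intensity
    across samples; ties break lexicographically by gene id and the output
    is ordered by ascending SD.
    """
    _check_present(matrix, candidates, "housekeeping candidate")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds number of candidates ({len(candidates)})")
    sub = np.log2(matrix.loc[candidates].to_numpy(dtype=float))
    sd = pd.Series(np.std(sub, axis=1, ddof=1), index=pd.Index(candidates))
    order = sd.to_frame("sd").reset_index(names="gene").sort_values(["sd", "gene"], kind="mergesort")
    return order["gene"].head(k).tolist()


def normalize_by_hkg(matrix: pd.DataFrame, hkg_ids: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample so its mean housekeeping intensity equals the grand mean.

    The scale factor for sample s is (grand mean of per-sample HKG means) /
    (HKG mean in s); multiplicative on the raw scale, hence additive on the
    log scale.  Idempotent.  Returns ``(normalized matrix, factors)``.
    """
    if not hkg_ids:
        raise ValueError("hkg_ids must be non-empty")
    _check_present(matrix, hkg_ids, "housekeeping gene")
    hkg_means = matrix.loc[hkg_ids].mean(axis=0)
    if (hkg_means <= 0).any():
        bad = hkg_means.index[hkg_means <= 0].tolist()
        raise ValueError(f"degenerate sample(s) with non-positive HKG mean: {bad}")
    factors = hkg_means.mean() / hkg_means
    return matrix.mul(factors, axis=1), factors.rename("scale_factor")


def detection_limit(matrix: pd.DataFrame, negative_ids: list[str], q: float = 0.95) -> float:
    """Percentile of pooled negative-control intensities across all samples.

    All intensities of the negative genes over all samples are pooled into
    one vector; the q-th percentile is taken by linear interpolation between
    closest ranks (position 1 + (n-1)q on the sorted vector).
    """
    if not negative_ids:
        raise ValueError("negative gene set must be non-empty")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    _check_present(matrix, negative_ids, "negative gene")
    pooled = matrix.loc[negative_ids].to_numpy(dtype=float).ravel()
    return float(np.percentile(pooled, 100.0 * q, method="linear"))


def filter_expressed(matrix: pd.DataFrame, limit: float) -> pd.Series:
    """Boolean keep-mask: a gene passes if it clears any of three criteria.

    (1) intensity strictly above ``limit`` in >= 4 samples, or
    (2) strictly above ``2 * limit`` in >= 2 samples, or
    (3) strictly above ``3 * limit`` in >= 1 sample.
    """
    if limit < 0:
        raise ValueError(f"limit must be >= 0, got {limit}")
    vals = matrix.to_numpy(dtype=float)
    c1 = (vals > limit).sum(axis=1) >= 4
    c2 = (vals > 2 * limit).sum(axis=1) >= 2
    c3 = (vals > 3 * limit).sum(axis=1) >= 1
    return pd.Series(c1 | c2 | c3, index=matrix.index, name="expressed")


def exclude_sex_genes(matrix: pd.DataFrame, genes: pd.DataFrame, keep: bool = False) -> pd.DataFrame:
    """Drop Y-chromosome genes and XIST (sex-linked expression markers).

    ``genes`` must carry ``chromosome`` and ``symbol`` columns covering the
    matrix rows.  With ``keep=True`` the matrix is returned unchanged (the
    re-inclusion used for sex-gene quality-control contrasts).  Genes absent
    from the annotation are retained, never silently dropped.
    """
    if keep:
        return matrix
    ann = genes.reindex(matrix.index)
    is_sex = (ann["chromosome"] == "Y") | (ann["symbol"] == "XIST")
    is_sex = is_sex.fillna(False)
    return matrix.loc[~is_sex.to_numpy(dtype=bool)]


@dataclass
class PreprocessReport:
    """Stage-by-stage accounting of a preprocessing run."""

    hkg_selected: list[str]
    scale_factors: dict[str, float]
    detection_limit_raw: float
    detection_limit_normalized: float
    q: float
    n_input: int
    n_pass_c1: int
    n_pass_c2: int
    n_pass_c3: int
    n_expressed: int
    n_sex_excluded: int
    n_retained: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_preprocess(
    matrix: pd.DataFrame,
    genes: pd.DataFrame,
    hkg_candidates: list[str] | None = None,
    hkg_k: int = 12,
    q: float = 0.95,
    keep_sex_genes: bool = False,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full preprocessing: normalize -> detection limit -> filter -> sex-gene exclusion.

    The detection limit used for filtering is computed on normalized values;
    the report also records the raw-scale limit for cross-checks.  Candidate
    housekeeping and negative-control genes default to the annotation flags
    in ``genes``.
    """
    if hkg_candidates is None:
        hkg_candidates = genes.index[genes["hkg_candidate"]].tolist()
    negative_ids = genes.index[genes["negative_control"]].tolist()

    hkg = select_housekeeping(matrix, hkg_candidates, min(hkg_k, len(hkg_candidates)))
    normalized, factors = normalize_by_hkg(matrix, hkg)

    limit_raw = detection_limit(matrix, negative_ids, q)
    limit = detection_limit(normalized, negative_ids, q)

    vals = normalized.to_numpy(dtype=float)
    c1 = int(((vals > limit).sum(axis=1) >= 4).sum())
    c2 = int(((vals > 2 * limit).sum(axis=1) >= 2).sum())
    c3 = int(((vals > 3 * limit).sum(axis=1) >= 1).sum())
    mask = filter_expressed(normalized, limit)
    expressed = normalized.loc[mask]

    retained = exclude_sex_genes(expressed, genes, keep=keep_sex_genes)
    report = PreprocessReport(
        hkg_selected=hkg,
        scale_factors=factors.to_dict(),
        detection_limit_raw=limit_raw,
        detection_limit_normalized=limit,
        q=q,
        n_input=int(matrix.shape[0]),
        n_pass_c1=c1,
        n_pass_c2=c2,
        n_pass_c3=c3,
        n_expressed=int(expressed.shape[0]),
        n_sex_excluded=int(expressed.shape[0] - retained.shape[0]),
        n_retained=int(retained.shape[0]),
    )
    log.info(
        "preprocess: %d genes in, %d expressed, %d sex-linked removed, %d retained (limit %.4f)",
        report.n_input, report.n_expressed, report.n_sex_excluded, report.n_retained, limit,
    )
    return retained, report
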