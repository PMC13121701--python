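"""Gene-set ingestion, evidence filtering, over-representation, and the
nine-category endothelial-function roll-up.

Gene sets are consumed as GMT files or assembled from GO-style annotation
records filtered to experimentally supported, protein-coding, single-taxon
entries.  Enrichment of a query gene list is scored with the upper-tail
hypergeometric test against a background universe (by convention the
post-filter expressed transcriptome), BH-adjusted across sets.  Significant
terms can be rolled up into nine endothelial-function categories
(proliferation, angiogenesis, adhesion, inflammation, EMT, cell death,
hemostasis, permeability, blood pressure).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources
import logging
import re

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import adjust_bh

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "filter_annotations",
    "ora",
    "categorize",
    "load_category_map",
    "normalize_go_id",
    "EXPERIMENTAL_EVIDENCE_CODES",
]

log = logging.getLogger(__name__)

#: GO evidence codes denoting direct experimental support
EXPERIMENTAL_EVIDENCE_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


class GmtParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    """A named gene collection (e.g. one GO term's experimentally supported genes)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def normalize_go_id(accession: str) -> str:
    """Canonicalize GO accessions, tolerating comma-grouped digits (GO:0,000,278 -> GO:0000278)."""
    m = re.fullmatch(r"(GO):([\d,]+)", accession.strip())
    if not m:
        return accession.strip()
    digits = m.group(2).replace(",", "")
    return f"GO:{digits.zfill(7)}"


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated name, description, members."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtParseError(f"{path}:{lineno}: expected name, description and >= 1 member")
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if not members:
                raise GmtParseError(f"{path}:{lineno}: set {name!r} has no members")
            if len(set(members)) < len(members):
                log.warning("GMT %s line %d: duplicate members in %s deduplicated", path, lineno, name)
            sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def filter_annotations(
    records: pd.DataFrame,
    allowed_evidence: frozenset[str] = EXPERIMENTAL_EVIDENCE_CODES,
    taxon: str = "9606",
    gene_type: str = "protein_coding",
) -> list[GeneSet]:
    """Build gene sets from annotation records, keeping direct experimental evidence only.

    ``records`` columns: gene, accession, evidence, taxon, gene_type.  A gene
    joins a set if *any* of its records for that accession qualifies.  Output
    is sorted by accession and independent of record order.
    """
    required = {"gene", "accession", "evidence", "taxon", "gene_type"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    keep = (
        records["evidence"].isin(allowed_evidence)
        & (records["taxon"].astype(str) == str(taxon))
        & (records["gene_type"] == gene_type)
    )
    kept = records.loc[keep].copy()
    kept["accession"] = kept["accession"].map(normalize_go_id)
    out = []
    for acc, grp in sorted(kept.groupby("accession"), key=lambda kv: kv[0]):
        out.append(GeneSet(name=acc, description=acc, members=frozenset(grp["gene"])))
    return out


def ora(query: set[str], background: set[str], sets: list[GeneSet]) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    p = P(X >= overlap) drawing |query| genes from the background; sets are
    intersected with the background first.  BH adjustment across sets.
    Returns a frame sorted by p with columns set, overlap, query_size,
    set_size, background_size, pvalue, adj_pvalue.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes outside background, e.g. {extra}")
    n_bg, n_q = len(background), len(query)
    rows = []
    for s in sets:
        members = s.members & background
        if not members:
            continue
        overlap = len(query & members)
        p = float(hypergeom.sf(overlap - 1, n_bg, len(members), n_q))
        rows.append((s.name, overlap, n_q, len(members), n_bg, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "overlap", "query_size", "set_size", "background_size", "pvalue"])
    if len(out):
        out["adj_pvalue"] = adjust_bh(out["pvalue"].to_numpy())
        out = out.sort_values(["pvalue", "set"], kind="mergesort").reset_index(drop=True)
    else:
        out["adj_pvalue"] = pd.Series(dtype=float)
    return out


def load_category_map(path=None) -> pd.Series:
    """Term accession -> endothelial-function category; ships the nine anchor GO terms."""
    if path is None:
        ref = importlib_resources.files("medivar.resources") / "endothelial_categories.tsv"
        with importlib_resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    table["accession"] = table["accession"].map(normalize_go_id)
    if table["accession"].duplicated().any():
        dup = table.loc[table["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"term(s) mapped to more than one category: {dup}")
    return table.set_index("accession")["category"]


def categorize(
    results: pd.DataFrame, category_map: pd.Series, alpha: float = 0.05, p_column: str = "adj_pvalue"
) -> tuple[pd.Series, list[str]]:
    """Count significant terms per function category.

    Terms with ``p_column`` < alpha are tallied by their mapped category;
    significant terms missing from the map are returned separately, never
    silently dropped.  All mapped categories appear in the output, zero
    counts included.
    """
    sig = results.loc[results[p_column] < alpha, "set"].map(normalize_go_id)
    categories = pd.unique(category_map)
    counts = pd.Series(0, index=pd.Index(categories, name="category"), dtype=int)
    unmapped = []
    for term in sig:
        if term in category_map.index:
            counts[category_map[term]] += 1
        else:
            unmapped.append(term)
    return counts, unmapped
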