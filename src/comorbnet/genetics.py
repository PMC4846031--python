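"""Disease gene-set construction and pairwise overlap enrichment.

Each disease's genetic architecture is summarized as a set of gene groups
drawn from a curated variant-association table.  A "gene group" is one or
more gene symbols joined by colons — a single variant can map to several
genes, and the group (e.g. ``GLT8D1:GNL3``) is kept as one indivisible unit
distinct from its members.  Overlap between two diseases' sets is tested for
enrichment with a Fisher exact test against a gene universe, Bonferroni
corrected for the number of pairs tested.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ingest import pair_key
from .stats import fisher_exact_from_margins

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetOverlap",
    "canonicalize_group",
    "read_variant_table",
    "build_gene_sets",
    "overlap_test",
    "all_pairs_overlap",
    "overlaps_to_frame",
]

P_THRESHOLD_DEFAULT = 1e-6


def canonicalize_group(genes: Iterable[str]) -> str:
    """Canonical colon-joined form of a gene group: unique symbols, sorted."""
    symbols = sorted({g.strip() for g in genes if g and g.strip()})
    if not symbols:
        raise ValueError("empty gene group")
    return ":".join(symbols)


@dataclass(frozen=True)
class GeneSet:
    disease_name: str
    gene_groups: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.gene_groups)


@dataclass(frozen=True)
class GeneSetOverlap:
    pair: tuple[str, str]
    size_1: int
    size_2: int
    overlap: int
    shared_names: tuple[str, ...]
    p_value: float
    odds_ratio: float
    universe_size: int
    significant: bool = False


def read_variant_table(path: str | Path, p_threshold: float | None = "auto") -> pd.DataFrame:
    """Read a variant-association table and canonicalize its gene groups.

    The minimal schema is ``disease, gene`` (with optional ``chromosome``,
    ``pubmed_id``, ``snp``, ``p_value``).  When a ``p_value`` column is
    present, associations at or above the threshold (default 1e-6, strict
    ``p < threshold``) are dropped — only firmly established associations
    should define a disease's gene set.  Tables without p-values are assumed
    pre-filtered; pass ``p_threshold=None`` to disable filtering explicitly.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("disease", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: variant table missing column {col!r}")
    if p_threshold == "auto":
        p_threshold = P_THRESHOLD_DEFAULT if "p_value" in df.columns else None
    if p_threshold is not None:
        if "p_value" not in df.columns:
            raise ValueError("p filtering requested but the table has no p_value column")
        p = pd.to_numeric(df["p_value"], errors="coerce")
        before = len(df)
        df = df[p < p_threshold]
        logger.info("p < %g filter kept %d of %d associations", p_threshold, len(df), before)
    df = df.assign(gene=[canonicalize_group(g.split(":")) for g in df["gene"]])
    return df.reset_index(drop=True)


def build_gene_sets(associations: pd.DataFrame, explode_groups: bool = False) -> dict[str, GeneSet]:
    """Distinct gene groups per disease.

    With ``explode_groups=True`` multi-gene groups are split into individual
    symbols before set construction; the default keeps each colon-joined group
    as one unit, so ``GLT8D1`` and ``GLT8D1:GNL3`` count as two entries.
    """
    sets: dict[str, set[str]] = {}
    for disease, gene in zip(associations["disease"], associations["gene"]):
        units = gene.split(":") if explode_groups else [gene]
        sets.setdefault(str(disease), set()).update(units)
    return {d: GeneSet(d, frozenset(s)) for d, s in sorted(sets.items())}


def overlap_test(
    set_1: GeneSet,
    set_2: GeneSet,
    universe_size: int,
    alternative: str = "greater",
) -> GeneSetOverlap:
    """Fisher exact enrichment of the overlap between two disease gene sets.

    The 2x2 table partitions the gene universe into shared / only-disease-1 /
    only-disease-2 / neither.  The default alternative is one-sided
    ("greater": an overlap at least as large as observed), matching an
    enrichment question; the odds ratio is (shared x neither) / (only1 x
    only2), 0 when nothing is shared and infinite when one set contains the
    other.
    """
    shared = sorted(set_1.gene_groups & set_2.gene_groups)
    union = len(set_1.gene_groups | set_2.gene_groups)
    if universe_size < union:
        raise ValueError(f"universe {universe_size} smaller than the union of sets ({union})")
    n_shared = len(shared)
    only_1 = set_1.size - n_shared
    only_2 = set_2.size - n_shared
    neither = universe_size - union
    p = fisher_exact_from_margins(universe_size, set_1.size, set_2.size, n_shared, alternative)
    if n_shared == 0:
        odds = 0.0
    elif only_1 == 0 or only_2 == 0:
        odds = float("inf")
    else:
        odds = (n_shared * neither) / (only_1 * only_2)
    return GeneSetOverlap(
        pair=pair_key(set_1.disease_name, set_2.disease_name),
        size_1=set_1.size if set_1.disease_name < set_2.disease_name else set_2.size,
        size_2=set_2.size if set_1.disease_name < set_2.disease_name else set_1.size,
        overlap=n_shared,
        shared_names=tuple(shared),
        p_value=p,
        odds_ratio=odds,
        universe_size=universe_size,
    )


def all_pairs_overlap(
    gene_sets: dict[str, GeneSet],
    universe_size: int | None = None,
    alpha: float = 0.05,
    restrict_pairs: Sequence[tuple[str, str]] | None = None,
    alternative: str = "greater",
) -> list[GeneSetOverlap]:
    """Overlap-test every disease pair with Bonferroni correction.

    ``universe_size=None`` uses the number of distinct gene units present in
    any loaded set (database-relative universe); an explicit integer overrides
    it.  The Bonferroni denominator is the number of tests actually performed
    (all unordered pairs, or the supplied restriction).  Zero-overlap pairs
    are reported, not dropped: downstream categorization needs them.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene sets")
    if universe_size is None:
        universe_size = len(frozenset().union(*(s.gene_groups for s in gene_sets.values())))
    if restrict_pairs is not None:
        pairs = [pair_key(a, b) for a, b in restrict_pairs]
    else:
        pairs = [pair_key(a, b) for a, b in itertools.combinations(sorted(gene_sets), 2)]
    m = len(pairs)
    out = []
    for d1, d2 in pairs:
        res = overlap_test(gene_sets[d1], gene_sets[d2], universe_size, alternative)
        out.append(
            GeneSetOverlap(
                **{**res.__dict__, "significant": res.p_value < alpha / m}
            )
        )
    return out


def overlaps_to_frame(overlaps: Sequence[GeneSetOverlap]) -> pd.DataFrame:
    """Tabular view: disease1, disease2, set sizes, overlap, p, OR, gene names."""
    return pd.DataFrame(
        {
            "disease1": [o.pair[0] for o in overlaps],
            "disease2": [o.pair[1] for o in overlaps],
            "disease1_genes": [o.size_1 for o in overlaps],
            "disease2_genes": [o.size_2 for o in overlaps],
            "gene_overlap": [o.overlap for o in overlaps],
            "pvalue": [o.p_value for o in overlaps],
            "OR": [o.odds_ratio for o in overlaps],
            "significant": [o.significant for o in overlaps],
            "gene_names": [", ".join(o.shared_names) for o in overlaps],
        }
    )
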