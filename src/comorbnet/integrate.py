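"""Integration of clinical (EMR) and genetic (variant-overlap) evidence.

Every disease pair with at least one kind of significant evidence is placed
in exactly one of three categories:

===============  ==================  =================================
EMR concordant   gene overlap        category
===============  ==================  =================================
significant      significant         clinical_and_genetic
significant      not significant     clinical_without_genetic
not (in both)    significant         genetic_without_clinical
===============  ==================  =================================

For the genetic-only category the pair may still have been significant in a
single record system; that source is recorded.  The module also exports the
concordant-pair network (GraphML plus a flat edge list) with node sizes from
a reference source's disease frequencies and edge weights from the
observed/expected ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .comorbidity import ComorbidityResult, ConcordantPair
from .genetics import GeneSetOverlap
from .ingest import pair_key

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryAssignment",
    "categorize",
    "export_network",
    "render_report_tables",
    "format_pvalue",
]

CATEGORIES = ("clinical_and_genetic", "clinical_without_genetic", "genetic_without_clinical")


@dataclass(frozen=True)
class CategoryAssignment:
    pair: tuple[str, str]
    emr_significant: bool
    genetic_significant: bool
    category: str
    direction: str | None = None  # over/under, for EMR-significant pairs
    cluster_id: int | None = None
    single_source_flag: str | None = None  # source label when exactly one EMR was significant


def categorize(
    concordant: Sequence[ConcordantPair],
    overlaps: Sequence[GeneSetOverlap],
    labels: dict[str, int] | None = None,
    source_results: tuple[Sequence[ComorbidityResult], Sequence[ComorbidityResult]] | None = None,
    restrict_to_shared_diseases: bool = False,
) -> list[CategoryAssignment]:
    """Assign each evidenced pair to one of the three categories.

    ``labels`` (age-incidence cluster ids) gate the genetic-only category:
    a genetically overlapping pair whose diseases sit in different clusters
    was never clinically testable, so it is excluded rather than reported as
    clinically silent.  ``source_results`` (per-source comorbidity results)
    supply the single-EMR flag for genetic-only pairs.  With
    ``restrict_to_shared_diseases`` only pairs whose diseases appear both in
    the EMR results and in the variant table are considered.
    """
    emr = {c.pair: c for c in concordant}
    gen = {o.pair: o for o in overlaps}
    bad = [p for p in emr if p != pair_key(*p)] + [p for p in gen if p != pair_key(*p)]
    if bad:
        raise ValueError(f"non-canonical pair keys: {bad}")

    if restrict_to_shared_diseases:
        emr_vocab = {d for c in concordant for d in c.pair}
        if source_results:
            emr_vocab |= {d for res in source_results for r in res for d in r.pair}
        gen_vocab = {d for o in overlaps for d in o.pair}
        shared = emr_vocab & gen_vocab
        emr = {p: c for p, c in emr.items() if set(p) <= shared}
        gen = {p: o for p, o in gen.items() if set(p) <= shared}

    single_source: dict[tuple[str, str], str] = {}
    if source_results:
        sig_by_source = [
            {r.pair: r for r in res if r.significant} for res in source_results
        ]
        for pair in set(sig_by_source[0]) ^ set(sig_by_source[1]):
            which = 0 if pair in sig_by_source[0] else 1
            single_source[pair] = sig_by_source[which][pair].source_label

    out: list[CategoryAssignment] = []
    for pair in sorted(set(emr) | {p for p, o in gen.items() if o.significant}):
        emr_sig = pair in emr
        gen_sig = pair in gen and gen[pair].significant
        if emr_sig and gen_sig:
            category = "clinical_and_genetic"
        elif emr_sig:
            category = "clinical_without_genetic"
        else:
            # genetic-only pairs must be clinically comparable: same cluster
            if labels is not None:
                d1, d2 = pair
                if d1 not in labels or d2 not in labels:
                    raise ValueError(f"pair {pair} references a disease without a cluster label")
                if labels[d1] != labels[d2]:
                    continue
            category = "genetic_without_clinical"
        cluster_id = None
        if labels is not None and pair[0] in labels and labels.get(pair[0]) == labels.get(pair[1]):
            cluster_id = labels[pair[0]]
        out.append(
            CategoryAssignment(
                pair=pair,
                emr_significant=emr_sig,
                genetic_significant=gen_sig,
                category=category,
                direction=emr[pair].direction if emr_sig else None,
                cluster_id=cluster_id,
                single_source_flag=single_source.get(pair) if not emr_sig else None,
            )
        )
    return out


def export_network(
    concordant: Sequence[ConcordantPair],
    reference_counts: dict[str, int],
    labels: dict[str, int],
    graphml_path: str | Path | None = None,
    edgelist_path: str | Path | None = None,
) -> nx.Graph:
    """Concordant-pair network with frequency/cluster node attributes.

    Nodes are every disease with a reference count and cluster label; edges
    connect concordant significant pairs, weighted by the reference source's
    observed/expected ratio.
    """
    g = nx.Graph()
    for disease in sorted(set(reference_counts) & set(labels)):
        g.add_node(disease, frequency=int(reference_counts[disease]), cluster=int(labels[disease]))
    for c in concordant:
        for d in c.pair:
            if d not in g:
                g.add_node(
                    d,
                    frequency=int(reference_counts.get(d, 0)),
                    cluster=int(labels.get(d, -1)),
                )
        g.add_edge(*c.pair, ratio=float(c.result_source_1.ratio), direction=c.direction)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        pd.DataFrame(
            [(a, b, data["ratio"], data["direction"]) for a, b, data in sorted(g.edges(data=True))],
            columns=["disease1", "disease2", "ratio", "direction"],
        ).to_csv(edgelist_path, sep="\t", index=False)
    return g


def format_pvalue(p: float) -> str:
    """Scientific notation with a two-decimal mantissa, e.g. 6.22E-10."""
    return f"{p:.2E}"


def _emr_table(
    assignments: Sequence[CategoryAssignment],
    emr_lookup: dict[tuple[str, str], tuple[ComorbidityResult, ComorbidityResult]],
    category: str,
    direction: str,
    cluster_names: dict[int, str] | None,
) -> pd.DataFrame:
    rows = []
    for a in sorted(assignments, key=lambda a: (a.cluster_id if a.cluster_id is not None else -1, a.pair)):
        if a.category != category or a.direction != direction:
            continue
        r1, r2 = emr_lookup[a.pair]
        rows.append(
            {
                "disease1": a.pair[0],
                "disease2": a.pair[1],
                "cluster": _cluster_name(a.cluster_id, cluster_names),
                f"obs_exp_{r1.source_label}": round(r1.ratio, 2),
                f"pvalue_{r1.source_label}": format_pvalue(r1.p_value),
                f"obs_exp_{r2.source_label}": round(r2.ratio, 2),
                f"pvalue_{r2.source_label}": format_pvalue(r2.p_value),
            }
        )
    return pd.DataFrame(rows)


def _cluster_name(cluster_id: int | None, cluster_names: dict[int, str] | None) -> str:
    if cluster_id is None:
        return ""
    if cluster_names and cluster_id in cluster_names:
        return cluster_names[cluster_id]
    return str(cluster_id)


def render_report_tables(
    assignments: Sequence[CategoryAssignment],
    concordant: Sequence[ConcordantPair],
    overlaps: Sequence[GeneSetOverlap],
    cluster_names: dict[int, str] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Report tables, one per category and direction.

    EMR-evidence tables carry per-source observed/expected ratios and raw
    p-values (scientific notation, two-decimal mantissa); the genetic-only
    table carries set sizes, overlap, p, odds ratio and the single-EMR flag.
    Overrepresented and underrepresented pairs are reported separately.  Rows
    sort by cluster then disease names — a deterministic order.
    """
    emr_lookup = {c.pair: (c.result_source_1, c.result_source_2) for c in concordant}
    gen_lookup = {o.pair: o for o in overlaps}
    tables: dict[str, pd.DataFrame] = {}
    for category in ("clinical_and_genetic", "clinical_without_genetic"):
        for direction in ("over", "under"):
            tables[f"{category}_{direction}"] = _emr_table(
                assignments, emr_lookup, category, direction, cluster_names
            )

    rows = []
    for a in sorted(assignments, key=lambda a: a.pair):
        if a.category != "genetic_without_clinical":
            continue
        o = gen_lookup[a.pair]
        rows.append(
            {
                "disease1": a.pair[0],
                "disease2": a.pair[1],
                "cluster": _cluster_name(a.cluster_id, cluster_names),
                "disease1_genes": o.size_1,
                "disease2_genes": o.size_2,
                "gene_overlap": o.overlap,
                "pvalue": format_pvalue(o.p_value),
                "OR": "" if o.odds_ratio == float("inf") else round(o.odds_ratio, 2),
                "EMR": a.single_source_flag or "",
            }
        )
    tables["genetic_without_clinical"] = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables
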