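"""Pairwise disease co-occurrence testing within age-incidence clusters.

Every disease pair whose two members fall in the same age-incidence cluster is
scored with a 2x2 presence/absence table over the patient roster:

=============  ==============  ==========
               not disease 2   disease 2
not disease 1  a               b
disease 1      c               d
=============  ==============  ==========

Under independence the expected both-diseases count is ``n1 * n2 / N``; pairs
with ``d`` above expectation are called synergistic (overrepresented), pairs
below are protective (underrepresented, "inverse comorbidity").  Significance
is a two-sided Fisher exact test with a per-cluster Bonferroni correction, and
only pairs significant with the same direction in two independent record
systems are retained.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .ingest import PairCountTable, pair_key
from .stats import fisher_exact_from_margins

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "ComorbidityResult",
    "ConcordantPair",
    "build_table",
    "cell_filter",
    "fisher_exact_two_sided",
    "obs_exp_ratio",
    "test_within_clusters",
    "concordant_pairs",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 presence/absence table; ``d`` counts patients with both diseases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n1(self) -> int:
        """Patients with disease 1 (row margin)."""
        return self.c + self.d

    @property
    def n2(self) -> int:
        """Patients with disease 2 (column margin)."""
        return self.b + self.d

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


def build_table(n1: int, n2: int, d: int, total: int, pair: tuple[str, str] | None = None) -> ContingencyTable:
    """Reconstruct the 2x2 table from marginal counts and the pair count.

    ``a = N - n1 - n2 + d`` counts patients with neither disease, which is why
    the roster total ``N`` must include patients carrying no disease of
    interest at all.
    """
    label = f" for pair {pair}" if pair else ""
    if d > min(n1, n2):
        raise ValueError(f"pair count d={d} exceeds a marginal (n1={n1}, n2={n2}){label}")
    if n1 + n2 - d > total:
        raise ValueError(f"union n1+n2-d={n1 + n2 - d} exceeds roster total {total}{label}")
    return ContingencyTable(a=total - n1 - n2 + d, b=n2 - d, c=n1 - d, d=d)


def cell_filter(table: ContingencyTable, threshold: int = 5) -> bool:
    """True when every observed and expected cell reaches ``threshold``.

    The expected value of each cell is (row total x column total) / N.  Pairs
    failing this filter are too sparse for the asymptotics of the ratio (and
    the stability of the direction call) to be meaningful.
    """
    total = table.total
    if total == 0:
        return False
    cells = (table.a, table.b, table.c, table.d)
    rows = (table.a + table.b, table.c + table.d)
    cols = (table.a + table.c, table.b + table.d)
    expected = (
        rows[0] * cols[0] / total,
        rows[0] * cols[1] / total,
        rows[1] * cols[0] / total,
        rows[1] * cols[1] / total,
    )
    return all(x >= threshold for x in cells) and all(x >= threshold for x in expected)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    return fisher_exact_from_margins(table.total, table.n1, table.n2, table.d)


def obs_exp_ratio(table: ContingencyTable) -> tuple[int, float, float]:
    """Observed pair count, expected count under independence, and their ratio.

    The ratio is the pair's effect size.  ``expected = 0`` (an empty margin)
    leaves the ratio as NaN; callers should treat such pairs as untestable.
    """
    if table.total == 0:
        raise ValueError("empty table: N = 0")
    expected = table.n1 * table.n2 / table.total
    ratio = table.d / expected if expected > 0 else float("nan")
    return table.d, expected, ratio


@dataclass(frozen=True)
class ComorbidityResult:
    pair: tuple[str, str]
    cluster_id: int
    observed: int
    expected: float
    ratio: float
    p_value: float
    direction: str  # "over" | "under"
    significant: bool
    source_label: str


@dataclass(frozen=True)
class ConcordantPair:
    """A pair significant with the same direction in two independent sources."""

    pair: tuple[str, str]
    direction: str
    result_source_1: ComorbidityResult
    result_source_2: ComorbidityResult


def test_within_clusters(
    table: PairCountTable,
    labels: dict[str, int],
    alpha: float = 0.05,
    bonferroni_mode: str = "diseases",
    cell_threshold: int = 5,
) -> list[ComorbidityResult]:
    """Fisher-test every same-cluster disease pair in a count table.

    Testing is restricted to pairs whose members share an age-incidence
    cluster, which removes the age confounding induced by the record system's
    observation window.  The Bonferroni denominator ``m`` is computed per
    cluster from cluster membership, not from the number of pairs that survive
    the cell filter:

    * ``bonferroni_mode="diseases"`` (default): m = number of diseases in the
      cluster;
    * ``bonferroni_mode="pairs"``: m = k(k-1)/2 for a cluster of k diseases,
      the conventional count of tests.

    Reported p-values are raw; the mode only moves the significance cut
    ``alpha / m``.
    """
    if bonferroni_mode not in ("diseases", "pairs"):
        raise ValueError(f"unknown bonferroni_mode: {bonferroni_mode!r}")
    unlabeled = sorted(set(table.disease_counts) - set(labels))
    if unlabeled:
        logger.warning("skipping %d diseases without cluster labels: %s", len(unlabeled), unlabeled)

    by_cluster: dict[int, list[str]] = {}
    for disease in sorted(table.disease_counts):
        if disease in labels:
            by_cluster.setdefault(labels[disease], []).append(disease)

    results: list[ComorbidityResult] = []
    for cluster_id, diseases in sorted(by_cluster.items()):
        k = len(diseases)
        if k < 2:
            continue
        m = k if bonferroni_mode == "diseases" else k * (k - 1) // 2
        cut = alpha / m
        for d1, d2 in itertools.combinations(diseases, 2):
            key = pair_key(d1, d2)
            ct = build_table(
                table.disease_counts[key[0]],
                table.disease_counts[key[1]],
                table.pair_counts.get(key, 0),
                table.total_patients,
                pair=key,
            )
            if not cell_filter(ct, cell_threshold):
                continue
            observed, expected, ratio = obs_exp_ratio(ct)
            p = fisher_exact_two_sided(ct)
            results.append(
                ComorbidityResult(
                    pair=key,
                    cluster_id=cluster_id,
                    observed=observed,
                    expected=expected,
                    ratio=ratio,
                    p_value=p,
                    direction="over" if observed > expected else "under",
                    significant=p < cut,
                    source_label=table.source_label,
                )
            )
    return results


test_within_clusters.__test__ = False  # keep pytest from collecting the API name


def concordant_pairs(
    results_1: list[ComorbidityResult], results_2: list[ComorbidityResult]
) -> list[ConcordantPair]:
    """Intersect two sources, keeping pairs significant in both with one direction.

    Discordant pairs (significant in both but with opposite directions) are
    logged and dropped; pairs significant in only one source are dropped
    silently — they reappear, flagged with their source, in the integration
    stage.
    """
    sig_1 = {r.pair: r for r in results_1 if r.significant}
    sig_2 = {r.pair: r for r in results_2 if r.significant}
    out: list[ConcordantPair] = []
    for pair in sorted(set(sig_1) & set(sig_2)):
        r1, r2 = sig_1[pair], sig_2[pair]
        if r1.direction != r2.direction:
            logger.info("discordant pair dropped: %s (%s vs %s)", pair, r1.direction, r2.direction)
            continue
        out.append(ConcordantPair(pair=pair, direction=r1.direction, result_source_1=r1, result_source_2=r2))
    return out
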