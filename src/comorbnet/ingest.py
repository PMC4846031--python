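"""Ingestion of encounter-level EMR extracts and aggregate count tables.

Two ingestion routes feed the comorbidity analysis:

* patient-level encounter records (one row per visit: patient id, ICD9 code,
  age at visit, visit year), reduced to earliest-onset events per
  (patient, disease) and then to marginal and pairwise patient counts plus
  per-disease onset-age histograms;
* pre-aggregated count tables (per-disease patient counts and per-pair
  co-occurrence counts with a roster total) for sources where patient-level
  data cannot be shared.  Aggregate sources carry no onset ages, so their
  age-incidence clustering must borrow the histograms of a patient-level
  source.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_AGE_BINS = 91  # integer ages 0..90; older ages are censored to 90

ENCOUNTER_COLUMNS = ["patient_id", "icd9", "age_at_visit", "visit_year"]

__all__ = [
    "N_AGE_BINS",
    "ENCOUNTER_COLUMNS",
    "DiseaseCatalog",
    "PairCountTable",
    "OnsetHistogramSet",
    "pair_key",
    "read_encounters",
    "read_catalog",
    "earliest_onset",
    "count_diseases_and_pairs",
    "filter_rare",
    "read_aggregate_counts",
    "frequency_percent",
]


def pair_key(d1: str, d2: str) -> tuple[str, str]:
    """Canonical (lexicographic) key for an unordered disease pair."""
    if d1 == d2:
        raise ValueError(f"a pair needs two distinct diseases, got {d1!r} twice")
    return (d1, d2) if d1 < d2 else (d2, d1)


@dataclass(frozen=True)
class DiseaseCatalog:
    """Many-to-one mapping from ICD9 code to disease name."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty catalog")

    @property
    def diseases(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def map_codes(self, codes: pd.Series) -> pd.Series:
        return codes.map(self.mapping)


@dataclass
class PairCountTable:
    """Marginal and pairwise patient counts for one record system.

    ``total_patients`` is the full roster size, including patients with no
    mapped disease: the neither-disease cell of every 2x2 table is derived
    from it, so it must come from the source system rather than be inferred
    from the disease counts.
    """

    total_patients: int
    disease_counts: dict[str, int]
    pair_counts: dict[tuple[str, str], int]
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.total_patients < 0:
            raise ValueError("negative roster total")
        for disease, n in self.disease_counts.items():
            if not 0 <= n <= self.total_patients:
                raise ValueError(f"count for {disease!r} ({n}) outside [0, N={self.total_patients}]")
        for key, d in self.pair_counts.items():
            if key != pair_key(*key):
                raise ValueError(f"pair key not canonical: {key}")
            cap = min(self.disease_counts.get(key[0], 0), self.disease_counts.get(key[1], 0))
            if d > cap:
                raise ValueError(f"pair count {key}={d} exceeds min marginal {cap}")

    @property
    def diseases(self) -> list[str]:
        return sorted(self.disease_counts)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        diseases = pd.DataFrame(
            sorted(self.disease_counts.items()), columns=["disease", "count"]
        )
        pairs = pd.DataFrame(
            [(a, b, n) for (a, b), n in sorted(self.pair_counts.items())],
            columns=["disease1", "disease2", "count"],
        )
        return diseases, pairs

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        diseases, pairs = self.to_frames()
        diseases.to_csv(out / "disease_counts.csv", index=False)
        pairs.to_csv(out / "pair_counts.csv", index=False)
        (out / "roster.txt").write_text(
            f"total_patients={self.total_patients}\nsource_label={self.source_label}\n"
        )


@dataclass
class OnsetHistogramSet:
    """Per-disease earliest-onset counts over integer ages 0..90."""

    histograms: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for disease, h in self.histograms.items():
            h = np.asarray(h)
            if h.shape != (N_AGE_BINS,):
                raise ValueError(f"histogram for {disease!r} has shape {h.shape}, expected ({N_AGE_BINS},)")
            if (h < 0).any():
                raise ValueError(f"negative onset count for {disease!r}")
            self.histograms[disease] = h.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {d: self.histograms[d] for d in sorted(self.histograms)},
            index=pd.RangeIndex(N_AGE_BINS, name="age"),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OnsetHistogramSet":
        return cls({str(c): frame[c].to_numpy() for c in frame.columns})

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read(cls, path: str | Path) -> "OnsetHistogramSet":
        return cls.from_frame(pd.read_csv(path, index_col="age"))


def read_encounters(path: str | Path, year_min: int = 2008, age_cap: int = 90) -> pd.DataFrame:
    """Read an encounter extract, dropping pre-rollout years and censoring ages.

    Visits before ``year_min`` predate comprehensive EMR coverage and are
    dropped; ages above ``age_cap`` are censored to the cap (as source systems
    do for privacy).  Rows with unparseable ages or years are dropped and
    reported with their file line numbers.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "icd9": str})
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[ENCOUNTER_COLUMNS]
    age = pd.to_numeric(df["age_at_visit"], errors="coerce")
    year = pd.to_numeric(df["visit_year"], errors="coerce")
    bad = age.isna() | year.isna() | df["icd9"].isna() | df["patient_id"].isna()
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        lines = (df.index[bad] + 2).tolist()
        logger.warning("%s: dropped %d malformed rows at lines %s", path, bad.sum(), lines[:20])
        df, age, year = df[~bad], age[~bad], year[~bad]
    df = df.assign(
        age_at_visit=age.astype(int).clip(lower=0, upper=age_cap),
        visit_year=year.astype(int),
    )
    return df[df["visit_year"] >= year_min].reset_index(drop=True)


def read_catalog(path: str | Path) -> DiseaseCatalog:
    df = pd.read_csv(path, dtype=str)
    for col in ("icd9", "disease"):
        if col not in df.columns:
            raise ValueError(f"{path}: catalog missing column {col!r}")
    dup = df["icd9"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: ICD9 codes mapped more than once: {df['icd9'][dup].tolist()}")
    return DiseaseCatalog(dict(zip(df["icd9"], df["disease"])))


def earliest_onset(records: pd.DataFrame, catalog: DiseaseCatalog) -> pd.DataFrame:
    """Reduce encounters to one row per (patient, disease) at the earliest age.

    All of a patient's ICD9 codes are first mapped to disease names (several
    codes may map to one disease), then the minimum age across those mapped
    encounters is kept.  Codes absent from the catalog are ignored; the
    catalog deliberately covers a fixed study vocabulary.
    """
    disease = catalog.map_codes(records["icd9"])
    unmapped = disease.isna()
    if unmapped.any():
        codes = records["icd9"][unmapped]
        logger.info(
            "ignored %d encounters with %d ICD9 codes outside the catalog",
            int(unmapped.sum()),
            codes.nunique(),
        )
    mapped = records.loc[~unmapped].assign(disease=disease[~unmapped])
    if mapped.empty:
        return pd.DataFrame(columns=["patient_id", "disease", "onset_age"])
    onsets = (
        mapped.groupby(["patient_id", "disease"], sort=True)["age_at_visit"]
        .min()
        .rename("onset_age")
        .reset_index()
    )
    return onsets


def count_diseases_and_pairs(
    onsets: pd.DataFrame, roster_total: int, source_label: str = ""
) -> tuple[PairCountTable, OnsetHistogramSet]:
    """Marginal counts, pair counts, and onset histograms from onset events.

    ``roster_total`` is the number of patients in the source system (with or
    without mapped diseases) and must be at least the number of distinct
    patients seen here.  Pair counts are computed with one boolean
    patient-by-disease incidence matrix product.
    """
    if onsets.empty:
        return PairCountTable(roster_total, {}, {}, source_label), OnsetHistogramSet({})
    patients = pd.Categorical(onsets["patient_id"])
    diseases = pd.Categorical(onsets["disease"])
    n_pat = len(patients.categories)
    if roster_total < n_pat:
        raise ValueError(f"roster_total={roster_total} < {n_pat} distinct patients observed")
    names = [str(d) for d in diseases.categories]
    incidence = np.zeros((n_pat, len(names)), dtype=bool)
    incidence[patients.codes, diseases.codes] = True

    disease_counts = {n: int(c) for n, c in zip(names, incidence.sum(axis=0))}
    co = incidence.T.astype(np.int64) @ incidence
    pair_counts = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        if co[i, j] > 0:
            pair_counts[pair_key(names[i], names[j])] = int(co[i, j])

    hists = {}
    ages = onsets["onset_age"].to_numpy()
    for code, name in enumerate(names):
        hists[name] = np.bincount(ages[diseases.codes == code], minlength=N_AGE_BINS)
    table = PairCountTable(roster_total, disease_counts, pair_counts, source_label)
    return table, OnsetHistogramSet(hists)


def filter_rare(table: PairCountTable, min_patients: int = 50) -> PairCountTable:
    """Drop diseases with fewer than ``min_patients`` patients (strict) and their pairs.

    Rare diseases carry too little signal for incidence-by-age shapes or pair
    statistics; the roster total is unchanged by the filter.
    """
    if min_patients < 0:
        raise ValueError("min_patients must be nonnegative")
    keep = {d for d, n in table.disease_counts.items() if n >= min_patients}
    return PairCountTable(
        total_patients=table.total_patients,
        disease_counts={d: n for d, n in table.disease_counts.items() if d in keep},
        pair_counts={k: v for k, v in table.pair_counts.items() if k[0] in keep and k[1] in keep},
        source_label=table.source_label,
    )


def read_aggregate_counts(
    disease_count_path: str | Path,
    pair_count_path: str | Path,
    roster_total: int,
    total_adjustment: int = 0,
    source_label: str = "",
) -> PairCountTable:
    """Load a pre-aggregated source (per-disease and per-pair count files).

    ``total_adjustment`` is subtracted from the roster total before use — some
    published rosters include populations (e.g. screened healthy employees)
    that never generate disease codes and would deflate every expected count.
    The per-disease and per-pair counts are loaded verbatim.
    """
    if total_adjustment < 0:
        raise ValueError("total_adjustment must be nonnegative")
    if total_adjustment > roster_total:
        raise ValueError(f"adjustment {total_adjustment} exceeds roster total {roster_total}")
    n = roster_total - total_adjustment
    ddf = pd.read_csv(disease_count_path)
    pdf = pd.read_csv(pair_count_path)
    for col in ("disease", "count"):
        if col not in ddf.columns:
            raise ValueError(f"{disease_count_path}: missing column {col!r}")
    for col in ("disease1", "disease2", "count"):
        if col not in pdf.columns:
            raise ValueError(f"{pair_count_path}: missing column {col!r}")
    disease_counts = dict(zip(ddf["disease"].astype(str), ddf["count"].astype(int)))
    over = [d for d, c in disease_counts.items() if c > n]
    if over:
        raise ValueError(f"adjusted total {n} smaller than counts for {over}")
    pair_counts = {
        pair_key(str(r.disease1), str(r.disease2)): int(r.count) for r in pdf.itertuples()
    }
    return PairCountTable(n, disease_counts, pair_counts, source_label)


def frequency_percent(count: int, total: int) -> float:
    """Disease frequency as a percent of the roster, rounded half-even to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))
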