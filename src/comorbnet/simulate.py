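"""Synthetic EMR and variant-association generators with known ground truth.

The generators emulate the structure of the real inputs — encounter-level
records with life-stage-shaped onset ages, two independent record systems
sharing one underlying population model, and a disease-to-gene association
table — while planting exactly the effects the downstream statistics are meant
to recover:

* pairwise dependence between diseases, expressed as a relative-risk
  multiplier rho on the joint prevalence: P(both) = rho * P(a) * P(b)
  (rho > 1 synergistic, rho < 1 protective, rho = 1 independent);
* distinct incidence-by-age shapes (bell-shaped bumps at different life
  stages) for the clustering stage;
* exact pairwise gene-set overlaps for the enrichment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import N_AGE_BINS, pair_key

__all__ = [
    "AgeProfile",
    "PlantedPair",
    "SimConfig",
    "SimVariantConfig",
    "GroundTruth",
    "simulate_emr",
    "simulate_pair_of_sources",
    "simulate_variants",
    "disease_catalog_frame",
    "write_ground_truth",
]


@dataclass(frozen=True)
class AgeProfile:
    """Parametric incidence-by-age density for one disease.

    ``bumps`` is a mixture of one or two Gaussian bumps, each given as
    (center age, width in years, weight); the mixture is discretized on the
    integer ages 0..90 and renormalized to sum to one.  ``baseline_prevalence``
    is the probability that a roster patient ever acquires the disease.
    """

    disease_name: str
    bumps: tuple[tuple[float, float, float], ...]
    baseline_prevalence: float

    def __post_init__(self) -> None:
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError(f"{self.disease_name}: baseline_prevalence must be in (0,1)")
        if not self.bumps:
            raise ValueError(f"{self.disease_name}: at least one bump required")
        for center, width, weight in self.bumps:
            if width <= 0 or weight <= 0:
                raise ValueError(f"{self.disease_name}: bump widths and weights must be positive")

    def density(self) -> np.ndarray:
        """Discretized onset-age density over integer ages 0..90 (sums to 1)."""
        ages = np.arange(N_AGE_BINS, dtype=float)
        dens = np.zeros(N_AGE_BINS)
        for center, width, weight in self.bumps:
            dens += weight * np.exp(-0.5 * ((ages - center) / width) ** 2)
        total = dens.sum()
        if total <= 0:
            raise ValueError(f"{self.disease_name}: degenerate density")
        return dens / total


@dataclass(frozen=True)
class PlantedPair:
    """A pairwise dependence target: P(both) = risk_multiplier * P(a) * P(b)."""

    disease_a: str
    disease_b: str
    risk_multiplier: float

    def __post_init__(self) -> None:
        if self.disease_a == self.disease_b:
            raise ValueError("planted pair needs two distinct diseases")
        if self.risk_multiplier <= 0:
            raise ValueError("risk_multiplier must be positive")


@dataclass(frozen=True)
class SimConfig:
    n_patients: int
    profiles: tuple[AgeProfile, ...]
    planted_pairs: tuple[PlantedPair, ...] = ()
    observation_window: tuple[int, int] = (2008, 2013)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        names = [p.disease_name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("disease names must be unique")
        declared = set(names)
        for pp in self.planted_pairs:
            if pp.disease_a not in declared or pp.disease_b not in declared:
                raise ValueError(f"planted pair references undeclared disease: {pp}")
        if self.observation_window[0] > self.observation_window[1]:
            raise ValueError("observation window reversed")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: marginal prevalences and pairwise multipliers."""

    n_patients: int
    prevalences: dict[str, float]
    planted_pairs: tuple[PlantedPair, ...]


def _joint_cell_probs(pa: float, pb: float, rho: float, pair: tuple[str, str]) -> tuple[float, float, float, float]:
    """(p11, p10, p01, p00) for the planted pairwise joint; errors when infeasible."""
    p11 = rho * pa * pb
    if p11 > min(pa, pb) + 1e-12:
        raise ValueError(
            f"pair {pair}: joint probability {p11:.4g} exceeds min marginal "
            f"min({pa:.4g}, {pb:.4g}) — lower the risk multiplier"
        )
    p10, p01 = pa - p11, pb - p11
    p00 = 1.0 - pa - pb + p11
    if p00 < -1e-12:
        raise ValueError(f"pair {pair}: neither-cell probability negative (p00={p00:.4g})")
    return p11, p10, p01, max(p00, 0.0)


def _sample_disease_matrix(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean patient-by-disease matrix honouring the planted pairwise joints.

    Planted pairs are realised by sequential conditional sampling: the first
    pair touching a disease draws it from the exact pairwise joint; a later
    pair that shares one disease draws its partner from the conditional
    distribution implied by the target joint.  A pair both of whose diseases
    are already constrained (a cycle) cannot be satisfied exactly and raises.
    """
    n = config.n_patients
    names = [p.disease_name for p in config.profiles]
    prev = {p.disease_name: p.baseline_prevalence for p in config.profiles}
    cols: dict[str, np.ndarray] = {}

    for pp in config.planted_pairs:
        a, b = pp.disease_a, pp.disease_b
        p11, p10, p01, _ = _joint_cell_probs(prev[a], prev[b], pp.risk_multiplier, (a, b))
        if a in cols and b in cols:
            raise ValueError(
                f"pair ({a}, {b}): both diseases already constrained by earlier "
                "planted pairs; cyclic pairwise constraints are not supported"
            )
        if b in cols and a not in cols:
            a, b = b, a
            p10, p01 = p01, p10
        if a in cols:  # sample b conditionally on the existing a column
            xa = cols[a]
            thresh = np.where(xa, p11 / prev[a], p01 / (1.0 - prev[a]))
            cols[b] = rng.random(n) < thresh
        else:  # fresh pair: draw from the joint
            u = rng.random(n)
            cols[a] = u < p11 + p10
            cols[b] = (u < p11) | ((u >= p11 + p10) & (u < p11 + p10 + p01))

    for name in names:
        if name not in cols:
            cols[name] = rng.random(n) < prev[name]
    return np.column_stack([cols[name] for name in names]) if names else np.zeros((n, 0), bool)


def simulate_emr(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an encounter table (patient_id, icd9, age_at_visit, visit_year).

    Each (patient, disease) event produces an encounter at the onset age drawn
    from the disease's discretized age profile, coded with one of the
    disease's two ICD9 codes; a random third of events also produce a later
    repeat encounter (same disease, higher age, possibly the sibling code), so
    earliest-onset reduction has real work to do.  Identical config and seed
    reproduce the table byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    names = [p.disease_name for p in config.profiles]
    truth = GroundTruth(
        n_patients=config.n_patients,
        prevalences={p.disease_name: p.baseline_prevalence for p in config.profiles},
        planted_pairs=config.planted_pairs,
    )
    if config.n_patients == 0 or not names:
        return pd.DataFrame(columns=["patient_id", "icd9", "age_at_visit", "visit_year"]), truth

    matrix = _sample_disease_matrix(config, rng)
    densities = {p.disease_name: p.density() for p in config.profiles}
    codes = _icd9_codes(names)
    y0, y1 = config.observation_window

    pat_idx: list[np.ndarray] = []
    icd9: list[np.ndarray] = []
    age: list[np.ndarray] = []
    for j, name in enumerate(names):
        carriers = np.flatnonzero(matrix[:, j])
        if carriers.size == 0:
            continue
        onset = rng.choice(N_AGE_BINS, size=carriers.size, p=densities[name])
        code_pick = rng.integers(0, 2, size=carriers.size)
        pat_idx.append(carriers)
        icd9.append(np.array(codes[name], dtype=object)[code_pick])
        age.append(onset)
        # repeat visits at a later age for ~1/3 of carriers
        rep = rng.random(carriers.size) < 1 / 3
        if rep.any():
            pat_idx.append(carriers[rep])
            icd9.append(np.array(codes[name], dtype=object)[rng.integers(0, 2, size=int(rep.sum()))])
            age.append(np.minimum(onset[rep] + rng.integers(1, 6, size=int(rep.sum())), N_AGE_BINS - 1))

    pats = np.concatenate(pat_idx)
    df = pd.DataFrame(
        {
            "patient_id": np.array([f"P{i:07d}" for i in pats], dtype=object),
            "icd9": np.concatenate(icd9),
            "age_at_visit": np.concatenate(age).astype(int),
            "visit_year": rng.integers(y0, y1 + 1, size=pats.size),
        }
    )
    df = df.sort_values(["patient_id", "icd9", "age_at_visit"], kind="stable").reset_index(drop=True)
    return df, truth


def simulate_pair_of_sources(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two independent record systems drawn from the same population model.

    The two draws share every planted effect but no randomness (seeds are
    derived from ``config.seed``), mirroring a discovery EMR and an
    independent validation EMR.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    df1, truth = simulate_emr(SimConfig(config.n_patients, config.profiles, config.planted_pairs, config.observation_window, int(seeds[0])))
    df2, _ = simulate_emr(SimConfig(config.n_patients, config.profiles, config.planted_pairs, config.observation_window, int(seeds[1])))
    return df1, df2, truth


def _icd9_codes(names: list[str]) -> dict[str, tuple[str, str]]:
    """Two synthetic ICD9-style codes per disease (exercises many-to-one mapping)."""
    return {name: (f"{100 + i}.0", f"{100 + i}.1") for i, name in enumerate(names)}


def disease_catalog_frame(profiles: tuple[AgeProfile, ...]) -> pd.DataFrame:
    """ICD9-to-disease catalog matching :func:`simulate_emr`'s code assignment."""
    names = [p.disease_name for p in profiles]
    rows = [(code, name) for name, codes in _icd9_codes(names).items() for code in codes]
    return pd.DataFrame(rows, columns=["icd9", "disease"])


@dataclass(frozen=True)
class SimVariantConfig:
    """Targets for the synthetic variant-association table.

    ``planted_overlaps`` maps canonical disease pairs to the exact number of
    shared gene units; all unlisted pairs get zero overlap.  Shared genes are
    dedicated to a single pair, so the construction is feasible iff each
    disease's overlaps sum to at most its set size and the universe is large
    enough to hold all distinct genes.
    """

    universe_size: int
    genes_per_disease: dict[str, int]
    planted_overlaps: dict[tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        for d, k in self.genes_per_disease.items():
            if k <= 0:
                raise ValueError(f"{d}: set size must be positive")
            if k > self.universe_size:
                raise ValueError(f"{d}: set size {k} exceeds universe {self.universe_size}")
        for key, o in self.planted_overlaps.items():
            if key != pair_key(*key):
                raise ValueError(f"overlap key not canonical: {key}")
            if o < 0:
                raise ValueError("negative overlap")
            cap = min(self.genes_per_disease[key[0]], self.genes_per_disease[key[1]])
            if o > cap:
                raise ValueError(f"planted overlap {key}={o} exceeds min set size {cap}")


def simulate_variants(config: SimVariantConfig) -> pd.DataFrame:
    """Variant table (disease, gene, chromosome, pubmed_id) with exact overlaps.

    Every planted overlap is realised with genes shared by exactly that pair;
    the remainder of each set is filled with genes private to the disease.
    Row order and gene identities are deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    shared_budget: dict[str, int] = {d: 0 for d in config.genes_per_disease}
    for (d1, d2), o in config.planted_overlaps.items():
        shared_budget[d1] += o
        shared_budget[d2] += o
    for d, used in shared_budget.items():
        if used > config.genes_per_disease[d]:
            raise ValueError(
                f"{d}: planted overlaps require {used} shared genes but the set size "
                f"is only {config.genes_per_disease[d]}"
            )
    n_distinct = sum(config.genes_per_disease.values()) - sum(config.planted_overlaps.values())
    if n_distinct > config.universe_size:
        raise ValueError(f"{n_distinct} distinct genes needed but universe holds {config.universe_size}")

    pool = rng.permutation(config.universe_size)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [f"G{g:05d}" for g in pool[cursor : cursor + k]]
        cursor += k
        return out

    sets: dict[str, list[str]] = {d: [] for d in config.genes_per_disease}
    for (d1, d2), o in sorted(config.planted_overlaps.items()):
        shared = take(o)
        sets[d1] += shared
        sets[d2] += shared
    for d in sorted(config.genes_per_disease):
        sets[d] += take(config.genes_per_disease[d] - len(sets[d]))

    rows = []
    for d in sorted(sets):
        for gene in sorted(sets[d]):
            rows.append((d, gene, str(rng.integers(1, 23)), str(rng.integers(10_000_000, 30_000_000))))
    return pd.DataFrame(rows, columns=["disease", "gene", "chromosome", "pubmed_id"])


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth summary as key=value text (one planted effect per line)."""
    lines = [f"n_patients={truth.n_patients}"]
    for name, p in sorted(truth.prevalences.items()):
        lines.append(f"prevalence\t{name}\t{p}")
    for pp in truth.planted_pairs:
        lines.append(f"planted_pair\t{pp.disease_a}\t{pp.disease_b}\t{pp.risk_multiplier}")
    Path(path).write_text("\n".join(lines) + "\n")
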