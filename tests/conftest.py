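import numpy as np
import pytest

from comorbnet.ingest import DiseaseCatalog, OnsetHistogramSet
from comorbnet.simulate import AgeProfile, PlantedPair, SimConfig, disease_catalog_frame


def make_profiles(
    n_diseases: int, prevalence: float = 0.02, centers=(15, 38, 60, 82), width: float = 7.0
) -> tuple[AgeProfile, ...]:
    """Diseases cycling through a few bell-shaped life-stage onset profiles."""
    return tuple(
        AgeProfile(f"D{i:02d}", ((centers[i % len(centers)], width, 1.0),), prevalence)
        for i in range(n_diseases)
    )


def catalog_for(profiles) -> DiseaseCatalog:
    frame = disease_catalog_frame(profiles)
    return DiseaseCatalog(dict(zip(frame["icd9"], frame["disease"])))


def planted_histograms(
    n_diseases: int, centers, rng: np.random.Generator, n_onsets: int = 400, width: float = 6.0
) -> tuple[OnsetHistogramSet, dict[str, int]]:
    """Multinomial onset histograms around planted profile centers + true labels."""
    hists, truth = {}, {}
    for i in range(n_diseases):
        name = f"D{i:02d}"
        profile = AgeProfile(name, ((centers[i % len(centers)], width, 1.0),), 0.01)
        hists[name] = rng.multinomial(n_onsets, profile.density())
        truth[name] = i % len(centers)
    return OnsetHistogramSet(hists), truth


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two planted effects (one synergistic, one protective) among 8 diseases."""
    return SimConfig(
        n_patients=30_000,
        profiles=make_profiles(8, prevalence=0.05),
        planted_pairs=(PlantedPair("D00", "D04", 3.0), PlantedPair("D01", "D05", 0.3)),
        seed=11,
    )
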