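"""Simulate two independent EMR sources sharing one planted ground truth.

Eight diseases with life-stage onset profiles; one synergistic pair planted at
relative risk 3 and one protective pair at 0.3.
"""

from comorbnet import simulate_pair_of_sources
from comorbnet.simulate import AgeProfile, PlantedPair, SimConfig

profiles = tuple(
    AgeProfile(f"D{i:02d}", ((center, 7.0, 1.0),), 0.04)
    for i, center in enumerate([15, 38, 60, 82] * 2)
)
config = SimConfig(
    n_patients=20_000,
    profiles=profiles,
    planted_pairs=(PlantedPair("D00", "D04", 3.0), PlantedPair("D01", "D05", 0.3)),
    seed=1,
)
source1, source2, truth = simulate_pair_of_sources(config)

print(source1.head())
print(f"\nsource1: {len(source1)} encounters, {source1['patient_id'].nunique()} patients with a disease")
print(f"source2: {len(source2)} encounters, {source2['patient_id'].nunique()} patients with a disease")
for pp in truth.planted_pairs:
    kind = "synergistic" if pp.risk_multiplier > 1 else "protective"
    print(f"planted {kind}: {pp.disease_a}-{pp.disease_b} at rho={pp.risk_multiplier}")
# Each encounter row is one coded visit; the two sources are independent draws
# from the same population model, so both carry the same planted effects.
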