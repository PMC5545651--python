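"""Generate a synthetic case-control CNV cohort with planted effects.

The bundle contains a sample manifest (SZ/BD cases + controls over
batches), two caller outputs per sample, a DGV-style reference set, gene
intervals, SNP dosages and the planted ground truth.
"""

from cnvassoc import PlantedCNVR, SimConfig, simulate_cohort

config = SimConfig(
    n_cases_sz=300, n_cases_bd=100, n_controls=300,
    background_call_rate=5.0,
    planted_cnvrs=[
        PlantedCNVR("risk_del", "22", 17_000_000, 20_000_000, "del",
                    freq_control=0.00, freq_sz=0.02),
        PlantedCNVR("common_dup", "2", 88_900_000, 89_200_000, "dup",
                    freq_control=0.10, freq_sz=0.25, linked_snp_target_r2=0.5),
    ],
    seed=7,
)
bundle = simulate_cohort(config)

print(f"samples: {len(bundle.manifest)}")
print(f"caller A calls: {len(bundle.calls_a)}, caller B calls: {len(bundle.calls_b)}")
for name, carriers in bundle.truth.carriers.items():
    print(f"planted {name}: {len(carriers)} carriers "
          f"(expected direction: {bundle.truth.expected_direction[name]})")
# Carrier counts follow the per-group Bernoulli frequencies in the config;
# caller B differs from caller A by boundary jitter and occasional dropout.
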