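"""Generate the synthetic survey that stands in for the field campaign.

Fifteen Danish populations x 3 plants x 2 leaves (undamaged / herbivore
damaged) x triplicate injections, plus 48 pooled-QC injections: 541 mass
features of which 344 are planted QC-RSD violators, with region, soil-pH,
habitat and leaf-area effects planted in known feature sets.

Writes results/study/: the injection-level feature table, the sample
metadata, and the ground-truth table.
"""

from pathlib import Path

from plantmet.synthetic import SimulationConfig, generate_study

OUT = Path("results/study")
SEED = 1

TARGET_STANDARDS = (  # synthetic RT / m/z coordinates for 6 detectable standards
    (0.90, 345.10), (1.10, 623.20), (2.05, 373.13),
    (2.41, 343.82), (3.50, 389.12), (5.20, 515.17),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED, planted_targets=TARGET_STANDARDS)
    table, meta, truth = generate_study(cfg)
    table.intensities.to_csv(OUT / "intensities.tsv", sep="\t",
                             index_label="sample_id")
    meta.to_csv(OUT / "metadata.tsv", sep="\t", index=False)
    truth.features.to_csv(OUT / "ground_truth.tsv", sep="\t")
    n_bio = (meta["role"] == "biological").sum()
    print(f"wrote {OUT}/: {n_bio} biological injections + "
          f"{(meta['role'] == 'qc').sum()} QC injections x "
          f"{len(table.feature_ids)} features "
          f"({truth.features['is_rsd_violator'].sum()} planted RSD violators)")


if __name__ == "__main__":
    main()
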