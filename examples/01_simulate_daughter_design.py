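"""Simulate a small daughter design and look at its structure.

Genotyped sires, crossbred daughters in 12-hen cages split between a
high-energy (HE) and a low-energy (LE) diet, one quality trait measured
at 50 and 70 weeks and one cage-level production trait.
"""

import numpy as np

from layerqtl import QTLSpec, SimConfig, TraitSpec, simulate_dataset

cfg = SimConfig(
    n_sires=100, n_daughters_per_sire=24, cage_size=12,
    n_markers_per_chromosome={"1": 30, "2": 20},
    traits=[
        TraitSpec("EPR", kind="production", mean=84.0, sigma2_g=11.0, sigma2_e=26.0),
        TraitSpec("HU", kind="quality", mean=73.0, sigma2_g=18.0, sigma2_e=41.0),
    ],
    qtl_spec=[QTLSpec(marker_index=5, trait="HU", alpha=2.0)],
    n_hatches=2, seed=1,
)
pedigree, genotypes, records = simulate_dataset(cfg)

print(f"pedigree rows: {len(pedigree.table)} "
      f"(grandsires + {cfg.n_sires} sires + daughters)")
print(f"genotypes: {genotypes.n_sires} sires x {genotypes.n_markers} markers, "
      f"mean MAF {genotypes.maf().mean():.3f}")
print(records.groupby(["trait", "diet"]).agg(
    n=("value", "size"), mean=("value", "mean")).round(2))

# the planted QTL moves daughters' Haugh units by 2 units per minor
# allele; sires transmit half their dosage, so sire means shift by ~1
hu = records[records["trait"] == "HU"]
means = hu.groupby("sire")["value"].mean()
dose = dict(zip(genotypes.sire_ids, genotypes.dosages[:, 5]))
x = np.array([dose[s] for s in means.index])
slope = np.polyfit(x, means.to_numpy(), 1)[0]
print(f"\nregression of HU sire means on sire dosage at the planted marker: "
      f"{slope:.2f} (expected ~ alpha/2 = 1.0)")
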