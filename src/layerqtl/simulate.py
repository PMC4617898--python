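"""Synthetic daughter-design data with condition-dependent QTL effects.

The generator emulates the study design the analysis assumes: a few
hundred genotyped sires, each with tens of crossbred daughters housed
twelve half-sisters to a cage, cages split evenly between a high-energy
(HE) and a low-energy (LE) diet, egg-quality traits collected at 50 and
70 weeks of age, and production traits recorded at cage level. Trait
values are built additively from

* a per-trait polygenic sire value (daughters inherit half of it plus a
  Mendelian-sampling term),
* planted QTL whose allele substitution effect may differ between
  conditions (sign inversions or magnitude changes between diets or
  collection ages),
* fixed environment effects (diet, age class, battery, column, floor,
  operator) and the two covariates (measurement waiting time W, hen age
  R), and
* an independent residual.

Daughters are not genotyped (only sires are); at each planted QTL the
daughter receives one sire allele with probability dosage/2 and one
allele from an unrelated dam pool segregating at the marker's simulated
minor-allele frequency. QTL contributions are centred at the population
mean dosage so that planting a QTL does not shift the trait location.

All randomness flows from the single ``SimConfig.seed`` through a
splittable bit generator, so the same configuration reproduces the same
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree, UNKNOWN_PARENT, validate_phenotypes
from .traits import EPR_PERIODS

__all__ = ["TraitSpec", "QTLSpec", "SimConfig", "simulate_dataset",
           "default_trait_panel"]


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait.

    ``kind`` is ``"production"`` (one record per cage, no age class) or
    ``"quality"`` (one record per daughter per collection age).
    ``sigma2_g``/``sigma2_e`` override the config-level variances so
    traits can live on their natural scales; ``ordinal`` produces a
    0-3 integer score by rounding a latent Gaussian (blood/meat-spot
    style scoring), analysed downstream as numeric.
    """

    name: str
    kind: str = "quality"
    mean: float = 0.0
    sigma2_g: float | None = None
    sigma2_e: float | None = None
    ordinal: bool = False


@dataclass(frozen=True)
class QTLSpec:
    """A planted QTL: marker index, target trait and per-condition effect.

    ``alpha`` is either a single allele-substitution effect (trait units
    per minor allele, same in every condition) or a mapping with keys
    from ``{"HE", "LE"}`` and/or ``{"AGE50", "AGE70"}``; diet- and
    age-keyed components add when both are present.
    """

    marker_index: int
    trait: str
    alpha: float | dict[str, float]

    def effect(self, diet: str, age: int | None) -> float:
        if isinstance(self.alpha, (int, float)):
            return float(self.alpha)
        total = 0.0
        if diet in self.alpha:
            total += self.alpha[diet]
        if age is not None and f"AGE{age}" in self.alpha:
            total += self.alpha[f"AGE{age}"]
        return total


def default_trait_panel() -> list[TraitSpec]:
    """The 16-trait layer panel on its reported scales.

    Means and phenotypic SDs follow the published summary statistics for
    the HE diet at 50 weeks; variance is split 30/70 into polygenic and
    residual parts (a moderate heritability typical of egg traits).
    """
    table = [
        # name, kind, mean, phenotypic sd
        ("EPR", "production", 84.2, 6.1),
        ("EPR1", "production", 72.1, 9.4),
        ("EPR2", "production", 91.1, 6.1),
        ("EPR3", "production", 85.3, 6.4),
        ("ESshape", "quality", 1.1, 0.02),
        ("EW", "quality", 61.1, 4.8),
        ("SLE", "quality", 43.4, 1.3),
        ("ESC", "quality", 24.8, 9.7),
        ("LSS", "quality", 66.8, 4.6),
        ("RSS", "quality", 13.7, 3.2),
        ("YSS", "quality", 28.3, 2.7),
        ("ESS", "quality", 39.2, 7.5),
        ("ESSTIF", "quality", 193.4, 29.5),
        ("EMTSP", "quality", 1.6, 0.74),
        ("HU", "quality", 73.0, 7.7),
        ("YOLKIND", "quality", 0.27, 0.02),
    ]
    panel = []
    for name, kind, mean, sd in table:
        panel.append(TraitSpec(name=name, kind=kind, mean=mean,
                               sigma2_g=0.3 * sd**2, sigma2_e=0.7 * sd**2,
                               ordinal=(name == "EMTSP")))
    return panel


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults follow the real design: 438 sires, ~72 daughters per sire
    in cages of 12 half-sisters, cages split 50/50 between the HE and LE
    diets, three hatches, quality traits collected at 50 and 70 weeks.
    Marker density defaults small; it is configurable, not a goal.
    """

    n_sires: int = 438
    #: sires are grouped into paternal half-sib families under ungenotyped
    #: grandsires, giving the relationship matrix the within-line structure
    #: REML needs to separate the variance components; ``0`` makes every
    #: sire an unrelated founder. ``None`` -> one grandsire per ~10 sires.
    n_grandsires: int | None = None
    n_daughters_per_sire: int = 72
    cage_size: int = 12
    n_markers_per_chromosome: dict[str, int] = field(
        default_factory=lambda: {"1": 60, "2": 50, "3": 40})
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    traits: list[TraitSpec] = field(default_factory=default_trait_panel)
    qtl_spec: list[QTLSpec] = field(default_factory=list)
    sigma2_g: float = 1.0
    sigma2_e: float = 1.0
    n_hatches: int = 3
    # fixed-effect standard deviations, in units of each trait's
    # phenotypic SD; levels are drawn once per dataset
    fixed_effect_sd: dict[str, float] = field(default_factory=lambda: {
        "diet": 0.15, "age": 0.15, "battery": 0.1, "column": 0.05,
        "floor": 0.05, "operator": 0.1})
    n_operators: int = 8
    beta_w: float = 0.0   # per day of measurement delay, trait-SD units
    beta_r: float = 0.0   # per day of hen age, trait-SD units
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be non-negative")
        lo, hi = self.maf_bounds
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < lo <= hi <= 0.5")
        if self.cage_size < 1:
            raise ValueError("cage_size must be >= 1")
        if self.n_sires < 1 or self.n_daughters_per_sire < 1:
            raise ValueError("need at least one sire and one daughter")
        if self.n_daughters_per_sire % self.cage_size != 0:
            raise ValueError("cage_size must divide n_daughters_per_sire "
                             "(cages hold half-sisters of a single sire)")
        n_markers = sum(self.n_markers_per_chromosome.values())
        trait_names = {t.name for t in self.traits}
        kinds = {t.name: t.kind for t in self.traits}
        for q in self.qtl_spec:
            if not 0 <= q.marker_index < n_markers:
                raise ValueError(f"QTL marker index {q.marker_index} outside map")
            if q.trait not in trait_names:
                raise ValueError(f"QTL trait {q.trait!r} not among simulated traits")
            if isinstance(q.alpha, dict):
                bad = set(q.alpha) - {"HE", "LE", "AGE50", "AGE70"}
                if bad:
                    raise ValueError(f"unknown condition keys {sorted(bad)}")
                if kinds[q.trait] == "production" and {"AGE50", "AGE70"} & set(q.alpha):
                    raise ValueError(
                        f"age-dependent QTL on production trait {q.trait!r}")


def _trait_variances(t: TraitSpec, cfg: SimConfig) -> tuple[float, float]:
    sg = cfg.sigma2_g if t.sigma2_g is None else t.sigma2_g
    se = cfg.sigma2_e if t.sigma2_e is None else t.sigma2_e
    return sg, se


def _simulate_genotypes(cfg: SimConfig, rng: np.random.Generator
                        ) -> tuple[GenotypeMatrix, np.ndarray, list[str]]:
    sire_ids = [f"S{i + 1:04d}" for i in range(cfg.n_sires)]
    rows = []
    for chrom, m in cfg.n_markers_per_chromosome.items():
        pos = np.sort(rng.choice(np.arange(1, 50_000_000), size=m, replace=False))
        for k in range(m):
            rows.append({"marker": f"AX-{chrom}-{k + 1:05d}",
                         "chrom": str(chrom), "pos": int(pos[k])})
    markers = pd.DataFrame(rows)
    m_total = len(markers)
    maf = rng.uniform(*cfg.maf_bounds, size=m_total)
    dos = rng.binomial(2, maf, size=(cfg.n_sires, m_total)).astype(float)
    if cfg.missing_rate > 0:
        qtl_cols = {q.marker_index for q in cfg.qtl_spec}
        mask = rng.random(dos.shape) < cfg.missing_rate
        if qtl_cols:  # planted QTL markers stay fully observed
            mask[:, sorted(qtl_cols)] = False
        dos[mask] = np.nan
    # fold each column to the OBSERVED minor allele, exactly as the
    # format readers do, so written genotypes round-trip bit for bit;
    # the planted alpha then refers to the counted (observed-minor)
    # allele and the dam pool segregates at that allele's frequency
    with np.errstate(invalid="ignore"):
        observed = np.nanmean(dos, axis=0) / 2.0
    flip = observed > 0.5
    dos[:, flip] = 2.0 - dos[:, flip]
    allele_freq = np.where(flip, 1.0 - maf, maf)
    g = GenotypeMatrix(sire_ids=sire_ids, dosages=dos, markers=markers)
    return g, allele_freq, sire_ids


def simulate_dataset(cfg: SimConfig) -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame]:
    """Simulate pedigree, sire genotypes and daughter phenotype records.

    Returns the pedigree (sires as founders, daughters with unknown
    dams), the sire minor-allele dosage matrix with its marker map, and
    a long-format phenotype table (one row per cage x production trait
    and per egg x quality trait).
    """
    root = np.random.SeedSequence(cfg.seed)
    keys = ("genotypes", "pedigree", "polygenic", "transmission",
            "environment", "residual")
    rngs = {k: np.random.default_rng(s)
            for k, s in zip(keys, root.spawn(len(keys)))}

    g, maf, sire_ids = _simulate_genotypes(cfg, rngs["genotypes"])

    # pedigree: grandsire half-sib families above the sires (unless
    # n_grandsires == 0), daughters each knowing their sire only
    n_gs = (max(1, cfg.n_sires // 10) if cfg.n_grandsires is None
            else cfg.n_grandsires)
    gs_ids = [f"G{i + 1:03d}" for i in range(n_gs)]
    sire_gs = np.arange(cfg.n_sires) % n_gs if n_gs else None
    n_d = cfg.n_daughters_per_sire
    daughter_ids = [f"D{i + 1:06d}" for i in range(cfg.n_sires * n_d)]
    daughter_sire = np.repeat(np.arange(cfg.n_sires), n_d)
    sire_parent = ([UNKNOWN_PARENT] * cfg.n_sires if n_gs == 0
                   else [gs_ids[k] for k in sire_gs])
    ped = Pedigree(pd.DataFrame({
        "id": gs_ids + sire_ids + daughter_ids,
        "sire": [UNKNOWN_PARENT] * n_gs + sire_parent
                + [sire_ids[i] for i in daughter_sire],
        "dam": [UNKNOWN_PARENT] * (n_gs + cfg.n_sires + len(daughter_ids)),
    }))

    # cages of half-sisters; cages alternate diet so each sire's
    # daughters are split evenly between HE and LE
    n_daughters = cfg.n_sires * n_d
    cage_of = np.arange(n_daughters) // cfg.cage_size
    n_cages = int(cage_of.max()) + 1
    env = rngs["environment"]
    cage_diet = np.where(np.arange(n_cages) % 2 == 0, "HE", "LE")
    cage_hatch = env.integers(1, cfg.n_hatches + 1, size=n_cages)
    cage_battery = env.integers(1, 5, size=n_cages)
    cage_column = env.integers(1, 3, size=n_cages)
    cage_floor = env.integers(1, 3, size=n_cages)

    # per-trait fixed-effect level values, scaled by the trait's
    # phenotypic SD so effect sizes are comparable across trait scales
    trait_sd = {t.name: np.sqrt(sum(_trait_variances(t, cfg)))
                for t in cfg.traits}
    fx: dict[tuple[str, str], np.ndarray] = {}
    for t in cfg.traits:
        sd = trait_sd[t.name]
        for factor, n_levels in (("diet", 2), ("age", 2), ("battery", 4),
                                 ("column", 2), ("floor", 2),
                                 ("operator", cfg.n_operators)):
            # draw first, scale after: configs differing only in one
            # magnitude stay paired on every other random stream
            mag = cfg.fixed_effect_sd.get(factor, 0.0) * sd
            fx[(t.name, factor)] = env.standard_normal(n_levels) * mag

    # polygenic values: per trait, sire value + daughter Mendelian term
    poly = rngs["polygenic"]
    sire_bv = {}
    daughter_bv = {}
    for t in cfg.traits:
        sg, _ = _trait_variances(t, cfg)
        if n_gs:
            u_gs = poly.standard_normal(n_gs) * np.sqrt(sg)
            u_s = 0.5 * u_gs[sire_gs] + poly.standard_normal(cfg.n_sires) \
                * np.sqrt(0.75 * sg)
        else:
            u_s = poly.standard_normal(cfg.n_sires) * np.sqrt(sg)
        u_d = 0.5 * u_s[daughter_sire] + poly.standard_normal(n_daughters) \
            * np.sqrt(0.75 * sg)
        sire_bv[t.name] = u_s
        daughter_bv[t.name] = u_d

    # daughter dosages at planted QTL markers: one transmitted sire
    # allele (probability dosage/2) plus one dam-pool allele at the MAF
    trans = rngs["transmission"]
    qtl_dosage: dict[int, np.ndarray] = {}
    for j in sorted({q.marker_index for q in cfg.qtl_spec}):
        sire_dos = g.dosages[daughter_sire, j]
        transmitted = trans.random(n_daughters) < sire_dos / 2.0
        dam = trans.random(n_daughters) < maf[j]
        qtl_dosage[j] = transmitted.astype(float) + dam.astype(float)

    def qtl_contrib(trait: str, diet_arr: np.ndarray, age: int | None) -> np.ndarray:
        total = np.zeros(n_daughters)
        for q in cfg.qtl_spec:
            if q.trait != trait:
                continue
            centred = qtl_dosage[q.marker_index] - 2.0 * maf[q.marker_index]
            eff = np.array([q.effect(d, age) for d in ("HE", "LE")])
            total += centred * np.where(diet_arr == "HE", eff[0], eff[1])
        return total

    resid = rngs["residual"]
    d_diet = cage_diet[cage_of]
    d_hatch = cage_hatch[cage_of]
    d_batt = cage_battery[cage_of]
    d_col = cage_column[cage_of]
    d_floor = cage_floor[cage_of]
    diet_idx = (d_diet == "LE").astype(int)

    frames: list[pd.DataFrame] = []
    for t in cfg.traits:
        sg, se = _trait_variances(t, cfg)
        sd = trait_sd[t.name]
        if t.kind == "production":
            # cage-level record: cage mean of daughter genetic values
            # plus cage environment and a cage residual
            genetic = daughter_bv[t.name] + qtl_contrib(t.name, d_diet, None)
            cage_gen = np.bincount(cage_of, weights=genetic, minlength=n_cages) \
                / np.bincount(cage_of, minlength=n_cages)
            value = (t.mean + cage_gen
                     + fx[(t.name, "diet")][(cage_diet == "LE").astype(int)]
                     + fx[(t.name, "battery")][cage_battery - 1]
                     + fx[(t.name, "column")][cage_column - 1]
                     + fx[(t.name, "floor")][cage_floor - 1]
                     + resid.standard_normal(n_cages) * np.sqrt(se))
            frames.append(pd.DataFrame({
                "record_id": [f"CAGE{c + 1:05d}" for c in range(n_cages)],
                "sire": [sire_ids[daughter_sire[np.searchsorted(cage_of, c)]]
                         for c in range(n_cages)],
                "hatch": cage_hatch, "diet": cage_diet, "age": np.nan,
                "battery": cage_battery, "column": cage_column,
                "floor": cage_floor, "operator": np.nan,
                "W": np.nan, "R": np.nan,
                "trait": t.name, "value": value,
            }))
        else:
            for age in (50, 70):
                operator = env.integers(1, cfg.n_operators + 1, n_daughters)
                wait = env.integers(0, 7, n_daughters).astype(float)
                hen_age = age * 7 + env.integers(-10, 11, n_daughters).astype(float)
                value = (t.mean + daughter_bv[t.name]
                         + qtl_contrib(t.name, d_diet, age)
                         + fx[(t.name, "diet")][diet_idx]
                         + fx[(t.name, "age")][0 if age == 50 else 1]
                         + fx[(t.name, "battery")][d_batt - 1]
                         + fx[(t.name, "column")][d_col - 1]
                         + fx[(t.name, "floor")][d_floor - 1]
                         + fx[(t.name, "operator")][operator - 1]
                         + cfg.beta_w * sd * (wait - wait.mean())
                         + cfg.beta_r * sd * (hen_age - hen_age.mean())
                         + resid.standard_normal(n_daughters) * np.sqrt(se))
                if t.ordinal:
                    value = np.clip(np.round(value), 0, 3)
                frames.append(pd.DataFrame({
                    "record_id": [f"EGG{age}_{i + 1:06d}"
                                  for i in range(n_daughters)],
                    "sire": [sire_ids[s] for s in daughter_sire],
                    "hatch": d_hatch, "diet": d_diet, "age": float(age),
                    "battery": d_batt, "column": d_col, "floor": d_floor,
                    "operator": operator.astype(float),
                    "W": wait, "R": hen_age,
                    "trait": t.name, "value": value,
                }))
    phenotypes = pd.concat(frames, ignore_index=True)
    return ped, g, validate_phenotypes(phenotypes)
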