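"""Phenotype pre-adjustment for the daughter design.

Daughter records are corrected for environmental effects before the sire
means are formed, separately within each hatch:

1. fit a fixed-effect linear model with sire plus the candidate
   environment terms (diet, age class, cage location, operator,
   measurement-delay and hen-age covariates, depending on trait type);
2. retain only environment terms significant at the screening level
   (p < 0.2 by default; sire is always kept) and refit the sub-model;
3. subtract every retained non-sire effect from each record, so an
   adjusted record is the estimated sire effect (centred within hatch)
   plus residual;
4. discard records more than four phenotypic standard deviations from
   the adjusted-trait mean (computed per trait per hatch);
5. average adjusted records per sire — overall and within each
   condition (diet HE/LE, collection age 50/70 weeks) — to form the
   "sire performances" used by the association scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .data import AGE_CONDITIONS, CONDITION_ALL, DIET_CONDITIONS

__all__ = ["ModelSpec", "FittedModel", "fit_fixed_model", "select_and_adjust",
           "sire_means", "adjust_phenotypes"]

PRODUCTION_TERMS = ["C(diet)", "C(battery)", "C(column)", "C(floor)"]
QUALITY_TERMS = ["C(diet)", "C(age)", "C(battery)", "C(column)", "C(floor)",
                 "C(operator)", "W", "R"]


@dataclass
class ModelSpec:
    """Candidate fixed-effect structure for one trait.

    ``kind`` is ``"production"`` (cage-level records: diet and cage
    location only) or ``"quality"`` (egg-level records: additionally age
    class, operator and the two covariates). Sire is always included and
    never subject to selection.
    """

    trait: str
    kind: str = "quality"
    retained: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("production", "quality"):
            raise ValueError(f"unknown trait kind {self.kind!r}")

    @property
    def candidate_terms(self) -> list[str]:
        return list(PRODUCTION_TERMS if self.kind == "production" else QUALITY_TERMS)

    def formula(self, terms: list[str] | None = None) -> str:
        terms = self.candidate_terms if terms is None else terms
        rhs = " + ".join(["C(sire)"] + terms)
        return f"value ~ {rhs}"


@dataclass
class FittedModel:
    """An OLS fit with Type-II F p-values for the non-sire terms.

    Coding is reference-level (first level as reference), recorded here
    so downstream consumers know the parameterisation.
    """

    spec: ModelSpec
    result: object
    term_pvalues: dict[str, float]
    coding: str = "treatment (first level reference)"

    def term_contribution(self, term_name: str) -> np.ndarray:
        """Fitted contribution of one model term for every record."""
        design_info = self.result.model.data.design_info
        sl = design_info.term_name_slices[term_name]
        return np.asarray(self.result.model.exog[:, sl] @ self.result.params[sl])


def _drop_degenerate(records: pd.DataFrame, terms: list[str]) -> list[str]:
    """Drop factor terms with a single observed level and constant covariates."""
    kept = []
    for t in terms:
        col = t[2:-1] if t.startswith("C(") else t
        if records[col].nunique(dropna=True) > 1:
            kept.append(t)
    return kept


def fit_fixed_model(records: pd.DataFrame, spec: ModelSpec,
                    terms: list[str] | None = None) -> FittedModel:
    """Fit the fixed-effect model for one trait on one hatch's records.

    Returns least-squares estimates under reference coding together with
    Type-II F-test p-values for every non-sire term (Type II is invariant
    to term order). Raises on a rank-deficient design, naming the
    confounded columns.
    """
    terms = _drop_degenerate(records, spec.candidate_terms if terms is None else terms)
    formula = spec.formula(terms)
    model = smf.ols(formula, data=records)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # identify offending columns via the pivoted QR
        r = np.linalg.qr(model.exog, mode="r")
        diag = np.abs(np.diag(r))
        bad = [model.exog_names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"design matrix is rank deficient; confounded terms: {bad}")
    result = model.fit()
    pvals: dict[str, float] = {}
    if terms:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # anova warns on near-zero SSR
            table = anova_lm(result, typ=2)
        for t in terms:
            pvals[t] = float(table.loc[t, "PR(>F)"])
    return FittedModel(spec=spec, result=result, term_pvalues=pvals)


def _adjust_one_hatch(records: pd.DataFrame, spec: ModelSpec,
                      p_keep: float) -> tuple[np.ndarray, list[str]]:
    """Adjusted values for one hatch: centred sire effect + residual."""
    full = fit_fixed_model(records, spec)
    retained = [t for t, p in full.term_pvalues.items() if p < p_keep]
    fit = full if retained == list(full.term_pvalues) else fit_fixed_model(
        records, spec, terms=retained)
    resid = np.asarray(fit.result.resid)
    sire_part = fit.term_contribution("C(sire)")
    adjusted = resid + sire_part - sire_part.mean()
    return adjusted, retained


def select_and_adjust(records: pd.DataFrame, spec: ModelSpec, *,
                      p_keep: float = 0.2, sd_trim: float = 4.0
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select the sub-model, adjust records and trim outliers, per hatch.

    Parameters
    ----------
    records
        Long-format phenotype rows for ``spec.trait`` (other traits are
        ignored if present).
    p_keep
        Screening level: non-sire terms with Type-II p below this are
        retained in the adjustment model.
    sd_trim
        Records strictly more than this many standard deviations from
        the adjusted-trait mean (per hatch) are discarded, once, after
        adjustment.

    Returns
    -------
    (adjusted, exclusions)
        ``adjusted`` is a copy of the surviving rows with an
        ``adjusted_value`` column and the retained terms recorded;
        ``exclusions`` lists discarded records with a reason code.
    """
    rec = records[records["trait"] == spec.trait].copy()
    if rec.empty:
        raise ValueError(f"no records for trait {spec.trait!r}")
    out_frames = []
    excl_rows = []
    for hatch, grp in rec.groupby("hatch", sort=True):
        grp = grp.copy()
        adjusted, retained = _adjust_one_hatch(grp, spec, p_keep)
        grp["adjusted_value"] = adjusted
        grp["retained_terms"] = ",".join(retained)
        mu, sd = adjusted.mean(), adjusted.std(ddof=1)
        if sd > 0:
            far = np.abs(adjusted - mu) > sd_trim * sd
        else:
            far = np.zeros(len(grp), bool)
        for rid in grp.loc[far, "record_id"]:
            excl_rows.append({"record_id": rid, "trait": spec.trait,
                              "hatch": hatch, "reason": f"gt_{sd_trim}_sd"})
        out_frames.append(grp.loc[~far])
    adjusted_df = pd.concat(out_frames, ignore_index=True)
    lost = set(rec["sire"]) - set(adjusted_df["sire"])
    if lost:
        warnings.warn(f"all records removed for sires: {sorted(lost)[:5]}",
                      stacklevel=2)
    exclusions = pd.DataFrame(excl_rows,
                              columns=["record_id", "trait", "hatch", "reason"])
    return adjusted_df, exclusions


def sire_means(adjusted: pd.DataFrame, grouping: str = "ALL") -> pd.DataFrame:
    """Per-sire means of adjusted records: the sire "performances".

    ``grouping`` is ``"ALL"`` (one mean per sire over all its daughters'
    records), ``"diet"`` (HE and LE means) or ``"age"`` (50- and 70-week
    means; rows without an age label, i.e. production records, are
    excluded). Groups with zero records are omitted.

    Returns a table with columns sire, condition, trait, mean, n_records.
    """
    df = adjusted
    if grouping == "ALL":
        df = df.assign(condition=CONDITION_ALL)
    elif grouping == "diet":
        df = df.assign(condition=df["diet"])
        assert set(df["condition"]) <= set(DIET_CONDITIONS)
    elif grouping == "age":
        df = df[df["age"].notna()].copy()
        df["condition"] = "AGE" + df["age"].astype(int).astype(str)
        assert set(df["condition"]) <= set(AGE_CONDITIONS)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = (df.groupby(["sire", "condition", "trait"], as_index=False)
             .agg(mean=("adjusted_value", "mean"),
                  n_records=("adjusted_value", "size")))
    return out


def adjust_phenotypes(records: pd.DataFrame, trait_kinds: dict[str, str], *,
                      p_keep: float = 0.2, sd_trim: float = 4.0
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Adjust every trait and assemble sire means for all groupings.

    Returns (adjusted records, exclusions, sire means stacked over the
    ALL/diet/age groupings).
    """
    adj_frames, excl_frames, mean_frames = [], [], []
    for trait, kind in trait_kinds.items():
        spec = ModelSpec(trait=trait, kind=kind)
        adj, excl = select_and_adjust(records, spec, p_keep=p_keep, sd_trim=sd_trim)
        adj_frames.append(adj)
        excl_frames.append(excl)
        groupings = ["ALL", "diet"] + (["age"] if kind == "quality" else [])
        for grouping in groupings:
            mean_frames.append(sire_means(adj, grouping))
    return (pd.concat(adj_frames, ignore_index=True),
            pd.concat(excl_frames, ignore_index=True),
            pd.concat(mean_frames, ignore_index=True))
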