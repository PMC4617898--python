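"""QTL calling from per-marker association results.

A QTL is declared on a chromosome when at least one SNP passes the
genome-wide threshold; its confidence interval is the maximal run of
adjacent chromosome-wide-significant SNPs around it, the "top SNP" is
the run's SNP with the largest absolute allele-substitution effect, and
the genetic variance it explains is ``2 p (1 - p) alpha^2`` (``p`` the
top SNP's minor-allele frequency) expressed as a percentage of the
variance of the sire performances.

QTL found for different traits or conditions whose intervals overlap on
the same chromosome are merged into one catalogue identity (transitive
union), mirroring how multi-trait QTL are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import ThresholdSet

__all__ = ["QTLRecord", "call_qtls", "variance_explained", "merge_across_traits"]


@dataclass
class QTLRecord:
    """One called QTL for one trait in one condition."""

    chrom: str
    ci_start: int
    ci_end: int
    top_marker: str
    top_pos: int
    trait: str
    condition: str
    alpha: float
    maf: float
    pct_var: float | None = None
    n_markers_in_run: int = 0
    qtl_id: str | None = None

    def overlaps(self, other: "QTLRecord") -> bool:
        return (self.chrom == other.chrom
                and self.ci_start <= other.ci_end
                and other.ci_start <= self.ci_end)


def variance_explained(p: float, alpha: float, var_sire: float) -> float:
    """Percent of sire-performance variance explained: 100*2p(1-p)a^2/var.

    ``p`` is the minor-allele frequency of the top SNP, ``alpha`` its
    allele substitution effect on the sire-mean scale, ``var_sire`` the
    variance of the sire performances for the trait/condition scanned.
    """
    if not 0.0 <= p <= 0.5:
        raise ValueError("minor-allele frequency must be in [0, 0.5]")
    if var_sire <= 0:
        raise ValueError("variance of sire performances must be positive")
    return 100.0 * 2.0 * p * (1.0 - p) * alpha**2 / var_sire


def _runs(sig: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal runs of True, allowing gaps of at most gap_tolerance False."""
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > gap_tolerance:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    return runs


def call_qtls(results: pd.DataFrame, thresholds: ThresholdSet, *,
              trait: str, condition: str, var_sire: float | None = None,
              gap_tolerance: int = 0) -> list[QTLRecord]:
    """Call QTL from one trait/condition scan.

    Per chromosome, each maximal run of chromosome-wide-significant
    markers (runs broken by more than ``gap_tolerance`` consecutive
    non-significant markers) that contains at least one
    genome-wide-significant marker becomes a QTL. The confidence
    interval spans the run's first and last marker positions (closed).
    ``var_sire``, when given, fills in the percent variance explained at
    the top SNP.
    """
    qtls: list[QTLRecord] = []
    res = results[results["tested"]] if "tested" in results else results
    for chrom, grp in res.groupby("chrom", sort=False):
        if chrom not in thresholds.chrom_wide:
            continue
        grp = grp.sort_values("pos").reset_index(drop=True)
        cw = grp["p"].to_numpy() < thresholds.chrom_wide[chrom]
        gw = grp["p"].to_numpy() < thresholds.genome_wide[chrom]
        for lo, hi in _runs(cw, gap_tolerance):
            if not gw[lo:hi + 1].any():
                continue
            run = grp.iloc[lo:hi + 1]
            top = run.loc[run["alpha"].abs().idxmax()]
            rec = QTLRecord(
                chrom=str(chrom),
                ci_start=int(run["pos"].iloc[0]),
                ci_end=int(run["pos"].iloc[-1]),
                top_marker=str(top["marker"]),
                top_pos=int(top["pos"]),
                trait=trait,
                condition=condition,
                alpha=float(top["alpha"]),
                maf=float(top["maf"]),
                n_markers_in_run=len(run),
            )
            if var_sire is not None:
                rec.pct_var = variance_explained(rec.maf, rec.alpha, var_sire)
            qtls.append(rec)
    return qtls


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), chrom)
    except ValueError:
        return (1, 0, chrom)


def merge_across_traits(qtls: list[QTLRecord]) -> pd.DataFrame:
    """Assign shared catalogue ids to QTL with overlapping intervals.

    Union-find over the interval-overlap graph per chromosome: if A
    overlaps B and B overlaps C, all three share one id even if A and C
    are disjoint. Ids are assigned deterministically by chromosome
    (numeric labels first) then by interval start.

    Returns the catalogue as a data frame (one row per QTL, with the
    catalogue id repeated across its member trait/condition records) and
    stamps ``qtl_id`` on the input records.
    """
    parent = list(range(len(qtls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    by_chrom: dict[str, list[int]] = {}
    for i, q in enumerate(qtls):
        by_chrom.setdefault(q.chrom, []).append(i)
    for members in by_chrom.values():
        members.sort(key=lambda i: (qtls[i].ci_start, qtls[i].ci_end))
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1:]:
                if qtls[j].ci_start > qtls[i].ci_end:
                    break
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(qtls)):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(
        groups.values(),
        key=lambda m: (_chrom_sort_key(qtls[m[0]].chrom),
                       min(qtls[i].ci_start for i in m)))
    rows = []
    for k, members in enumerate(ordered, start=1):
        qid = f"QTL{k}"
        for i in members:
            qtls[i].qtl_id = qid
            q = qtls[i]
            rows.append({
                "qtl_id": qid, "chrom": q.chrom,
                "ci_start": min(qtls[j].ci_start for j in members),
                "ci_end": max(qtls[j].ci_end for j in members),
                "trait": q.trait, "condition": q.condition,
                "top_marker": q.top_marker, "top_pos": q.top_pos,
                "alpha": q.alpha, "maf": q.maf, "pct_var": q.pct_var,
            })
    return pd.DataFrame(rows, columns=[
        "qtl_id", "chrom", "ci_start", "ci_end", "trait", "condition",
        "top_marker", "top_pos", "alpha", "maf", "pct_var"])
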