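"""Derived egg-trait formulas and egg-production-rate bookkeeping.

All functions are pure and accept scalars or numpy arrays.

Two of the published index formulas are internally inconsistent with the
summary statistics they accompany, so both variants are implemented:

* Shell shape index. The printed formula ``(SLE/10)/(EW/10)^(1/3)``
  evaluates to ~2.37 at typical means (SLE = 43 mm, EW = 61 g) while the
  reported trait mean is 1.1; the variant ``SLE/(10 * EW^(1/3))`` gives
  1.10. The table-consistent variant is the default.
* Shell colour index. The printed formula is ``100 - (L* - a* - b*)``
  (~75 at typical means) while the reported mean (~25) matches
  ``L* - a* - b*``. The printed formula is the default; the
  table-consistent variant sits behind a flag.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "DerivedTraits", "egg_shape_index", "egg_shell_colour", "haugh_unit",
    "yolk_index", "compute_derived_traits", "compute_epr", "EPR_PERIODS",
]

#: Laying-period windows in weeks of age, closed intervals.
EPR_PERIODS: dict[str, tuple[int, int]] = {
    "EPR": (18, 75),
    "EPR1": (18, 30),
    "EPR2": (31, 49),
    "EPR3": (50, 75),
}


class DerivedTraits(NamedTuple):
    ESshape: float | np.ndarray
    ESC: float | np.ndarray
    HU: float | np.ndarray
    YOLKIND: float | np.ndarray


def egg_shape_index(short_length_mm, egg_weight_g, *, printed_formula: bool = False):
    """Shell shape index from short egg length (mm) and egg weight (g).

    ``printed_formula=True`` selects ``(SLE/10)/(EW/10)^(1/3)``; the
    default is the table-consistent ``SLE/(10*EW^(1/3))``.
    """
    sle = np.asarray(short_length_mm, dtype=float)
    ew = np.asarray(egg_weight_g, dtype=float)
    if np.any(ew <= 0):
        raise ValueError("egg weight must be positive")
    if printed_formula:
        out = (sle / 10.0) / (ew / 10.0) ** (1.0 / 3.0)
    else:
        out = sle / (10.0 * ew ** (1.0 / 3.0))
    return out.item() if out.ndim == 0 else out


def egg_shell_colour(lightness, redness, yellowness, *, table_variant: bool = False):
    """Shell colour index from Minolta L* (lightness), a* (redness), b* (yellowness).

    Default is the printed ``100 - (L* - a* - b*)``; ``table_variant=True``
    returns ``L* - a* - b*``, which matches the reported trait means.
    """
    core = (np.asarray(lightness, dtype=float)
            - np.asarray(redness, dtype=float)
            - np.asarray(yellowness, dtype=float))
    out = core if table_variant else 100.0 - core
    return out.item() if out.ndim == 0 else out


def haugh_unit(albumen_height_mm, egg_weight_g, record_id=None):
    """Haugh unit, ``100 * log10(H - 1.7 * EW**0.37 + 7.57)``.

    The log argument must be positive; a non-positive argument raises a
    ``ValueError`` naming ``record_id`` when given.
    """
    h = np.asarray(albumen_height_mm, dtype=float)
    ew = np.asarray(egg_weight_g, dtype=float)
    arg = h - 1.7 * ew ** 0.37 + 7.57
    if np.any(arg <= 0):
        where = "" if record_id is None else f" (record {record_id})"
        raise ValueError(f"non-positive Haugh-unit log argument{where}")
    out = 100.0 * np.log10(arg)
    return out.item() if out.ndim == 0 else out


def yolk_index(yolk_weight_g, egg_weight_g):
    """Yolk index: yolk weight divided by egg weight."""
    ew = np.asarray(egg_weight_g, dtype=float)
    if np.any(ew <= 0):
        raise ValueError("egg weight must be positive")
    out = np.asarray(yolk_weight_g, dtype=float) / ew
    return out.item() if out.ndim == 0 else out


def compute_derived_traits(short_length_mm, egg_weight_g, lightness, redness,
                           yellowness, albumen_height_mm, yolk_weight_g, *,
                           esshape_printed: bool = False,
                           esc_table_variant: bool = False,
                           record_id=None) -> DerivedTraits:
    """All four derived egg-quality indices for one egg (or arrays of eggs)."""
    return DerivedTraits(
        ESshape=egg_shape_index(short_length_mm, egg_weight_g,
                                printed_formula=esshape_printed),
        ESC=egg_shell_colour(lightness, redness, yellowness,
                             table_variant=esc_table_variant),
        HU=haugh_unit(albumen_height_mm, egg_weight_g, record_id=record_id),
        YOLKIND=yolk_index(yolk_weight_g, egg_weight_g),
    )


def compute_epr(weeks, egg_counts, hen_days, period: str = "EPR") -> float:
    """Egg production rate (%) of one cage over a laying period.

    Parameters
    ----------
    weeks
        Week-of-age label for each ledger entry, within the laying window
        (18-75 weeks).
    egg_counts, hen_days
        Eggs produced and hen-days accumulated in each entry.
    period
        ``EPR`` (18-75), ``EPR1`` (18-30, increase), ``EPR2`` (31-49,
        plateau) or ``EPR3`` (50-75, persistence); closed week intervals.
    """
    if period not in EPR_PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {list(EPR_PERIODS)}")
    weeks = np.asarray(weeks, dtype=int)
    eggs = np.asarray(egg_counts, dtype=float)
    days = np.asarray(hen_days, dtype=float)
    if not (weeks.shape == eggs.shape == days.shape):
        raise ValueError("weeks, egg_counts and hen_days must align")
    lo, hi = EPR_PERIODS["EPR"]
    if np.any((weeks < lo) | (weeks > hi)):
        raise ValueError(f"week labels outside the laying window {lo}-{hi}")
    if np.any(eggs < 0) or np.any(days < 0):
        raise ValueError("counts must be non-negative")
    lo, hi = EPR_PERIODS[period]
    mask = (weeks >= lo) & (weeks <= hi)
    total_days = days[mask].sum()
    if total_days <= 0:
        raise ValueError(f"no hen-days recorded in period {period}")
    return 100.0 * eggs[mask].sum() / total_days
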