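"""Derived predictors from raw life-history and demographic traits.

All functions are deterministic pure functions of positive inputs.  Only
log-log regression slopes are interpreted downstream, so multiplicative
unit changes in any one predictor shift intercepts but never slopes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "propagule_size_mammal",
    "census_proxy",
    "density_proxy",
    "pn_ps_ratio",
    "fold_change_from_slope",
    "derive_traits",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value is None or not value > 0:
            raise InvalidInputError(f"{name} must be > 0, got {value}")


def propagule_size_mammal(
    adult_body_length: float,
    mass_at_weaning: float,
    adult_body_mass: float,
) -> float:
    """Approximate mammalian propagule size (cm):

        adult body length * (mass at weaning / adult body mass)^(1/3)

    The cube root converts the mass ratio to a linear-dimension ratio
    under isometric scaling.  Weaning mass above adult mass is unusual
    but not an error (a warning is emitted).
    """
    _require_positive(
        adult_body_length=adult_body_length,
        mass_at_weaning=mass_at_weaning,
        adult_body_mass=adult_body_mass,
    )
    if mass_at_weaning > adult_body_mass:
        warnings.warn(
            "mass_at_weaning exceeds adult_body_mass", stacklevel=2
        )
    return adult_body_length * (mass_at_weaning / adult_body_mass) ** (1.0 / 3.0)


def census_proxy(range_area: float, density: float) -> float:
    """Census population size proxy: range area (km^2) x density (per km^2)."""
    _require_positive(range_area=range_area, density=density)
    return range_area * density


def density_proxy(range_area: float, body_mass: float) -> float:
    """Population-density proxy: range area divided by adult body mass,
    leaning on the macroecological density-body size relationship."""
    _require_positive(range_area=range_area, body_mass=body_mass)
    return range_area / body_mass


def pn_ps_ratio(pi_n: float, pi_s: float) -> float:
    """piN/piS, the proportion of effectively neutral nonsynonymous
    variation; a proxy for the (in)efficiency of purifying selection."""
    if pi_s <= 0:
        raise InvalidInputError(f"pi_s must be > 0, got {pi_s}")
    if pi_n < 0:
        raise InvalidInputError(f"pi_n must be >= 0, got {pi_n}")
    return pi_n / pi_s


def fold_change_from_slope(slope: float, factor: float) -> float:
    """Fold change in the response implied by a log-log slope when the
    predictor changes by ``factor``: factor ** slope.

    E.g. a slope of 0.09 means a 10-fold increase in census size raises
    Ne by 10**0.09 = 1.23-fold.
    """
    if factor <= 0:
        raise InvalidInputError(f"factor must be > 0, got {factor}")
    return factor**slope


def derive_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns to a trait table where inputs permit.

    Adds ``propagule_size`` (filled only where missing, from the mammal
    approximation), ``census_size`` (range x density), ``density_proxy``
    (range / body mass) and ``pn_ps`` with a ``derived_`` flag column each.
    """
    out = traits.copy()

    def _have(*cols: str) -> pd.Series:
        mask = pd.Series(True, index=out.index)
        for c in cols:
            if c not in out.columns:
                return pd.Series(False, index=out.index)
            mask &= out[c].notna() & (out[c] > 0)
        return mask

    if "propagule_size" not in out.columns:
        out["propagule_size"] = np.nan
    m = (
        out["propagule_size"].isna()
        & _have("adult_body_length", "mass_at_weaning", "adult_body_mass")
    )
    if m.any():
        out.loc[m, "propagule_size"] = out.loc[m, "adult_body_length"] * (
            out.loc[m, "mass_at_weaning"] / out.loc[m, "adult_body_mass"]
        ) ** (1.0 / 3.0)
    out["derived_propagule"] = m

    m = _have("range_area", "density")
    out["census_size"] = np.nan
    if m.any():
        out.loc[m, "census_size"] = (
            out.loc[m, "range_area"] * out.loc[m, "density"]
        )

    m = _have("range_area", "adult_body_mass")
    out["density_proxy"] = np.nan
    if m.any():
        out.loc[m, "density_proxy"] = (
            out.loc[m, "range_area"] / out.loc[m, "adult_body_mass"]
        )

    if "pi_n" in out.columns and "pi_s" in out.columns:
        m = out["pi_n"].notna() & out["pi_s"].notna() & (out["pi_s"] > 0)
        out["pn_ps"] = np.nan
        out.loc[m, "pn_ps"] = out.loc[m, "pi_n"] / out.loc[m, "pi_s"]
    return out
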