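"""Trait screens: why are some species recorded more than others?

The response is the number of records per species; each candidate
trait (identification difficulty, rarity, height, ...) is tested in
its own log-link Poisson-family GLM with the dispersion estimated from
the Pearson statistic (the quasipoisson correction for
over-dispersion).  Significance comes from an F-test of the trait
model against the intercept-only model,

    F = (ΔDeviance / Δdf) / dispersion,   F ~ F(Δdf, df_resid),

matching R's ``anova(glm(..., family=quasipoisson), test="F")``.
Because such screens are exploratory, no familywise correction is
applied by default; the Bonferroni-adjusted alpha is reported alongside
so both interpretations are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import f as f_dist

__all__ = [
    "TraitModel",
    "TraitModelResult",
    "TraitScreenResults",
    "fit_trait_model",
    "bonferroni_alpha",
    "trait_screen",
]


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> tuple[float, float]:
    """Bonferroni-adjusted per-test alpha.

    Returns ``(exact, displayed)`` where the displayed value is rounded
    to 3 decimals with banker's rounding: (8, 0.05) -> (0.00625, 0.006)
    and (4, 0.05) -> (0.0125, 0.012).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    exact = family_alpha / n_tests
    displayed = float(
        Decimal(str(exact)).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN)
    )
    return exact, displayed


@dataclass
class TraitModelResult:
    """One single-trait quasipoisson screen."""

    trait: str
    n_species: int
    n_excluded: int
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    dispersion: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float

    @property
    def direction(self) -> str:
        slopes = {k: v for k, v in self.coefficients.items() if k != "Intercept"}
        if not slopes:
            return "none"
        signs = {np.sign(v) for v in slopes.values()}
        return {frozenset({1.0}): "positive", frozenset({-1.0}): "negative"}.get(
            frozenset(signs), "mixed"
        )

    def to_row(self) -> dict:
        return {
            "trait": self.trait,
            "n": self.n_species,
            "n_excluded": self.n_excluded,
            "coefficient": next(
                (v for k, v in self.coefficients.items() if k != "Intercept"), np.nan
            ),
            "direction": self.direction,
            "dispersion": self.dispersion,
            "F": self.f_statistic,
            "df_num": self.df[0],
            "df_den": self.df[1],
            "p": self.p_value,
        }


class TraitModel:
    """Quasipoisson model of records-per-species on a single trait.

    Parameters
    ----------
    data
        One row per species with an ``n_records`` count column and the
        trait columns (categorical levels or numeric values).  Rows
        with a missing value for the tested trait are excluded, and
        the exclusion count reported (the usual situation where a trait
        source does not list every species).
    trait
        Column to test.  Prefix-free patsy terms are built internally:
        categorical columns are wrapped in ``C(...)``.
    log_transform
        Apply ``log`` to a numeric trait before fitting (body length,
        plant height and occupancy are conventionally log-scaled).
    """

    def __init__(self, data: pd.DataFrame, trait: str, log_transform: bool = False):
        if "n_records" not in data.columns:
            raise ValueError("data must carry an n_records column")
        if trait not in data.columns:
            raise KeyError(f"trait {trait!r} not in data")
        self.trait = trait
        self.n_excluded = int(data[trait].isna().sum())
        rows = data.loc[data[trait].notna(), ["n_records", trait]].copy()
        if len(rows) < 3:
            raise ValueError(
                f"only {len(rows)} species with trait {trait!r}; need >= 3"
            )
        numeric = pd.api.types.is_numeric_dtype(rows[trait])
        if numeric:
            if log_transform:
                if (rows[trait] <= 0).any():
                    raise ValueError(f"log transform of non-positive {trait!r}")
                rows[trait] = np.log(rows[trait].astype(float))
            if rows[trait].nunique() < 2:
                raise ValueError(f"trait {trait!r} has zero variance")
            self.term = trait
        else:
            if rows[trait].nunique() < 2:
                raise ValueError(f"trait {trait!r} has a single level")
            self.term = f"C({trait})"
        self.data = rows

    def fit(self) -> TraitModelResult:
        """Fit trait and intercept-only models; F-test the trait."""
        fam = sm.families.Poisson()
        full = smf.glm(f"n_records ~ {self.term}", data=self.data, family=fam).fit()
        null = smf.glm("n_records ~ 1", data=self.data, family=fam).fit()
        df_num = int(null.df_resid - full.df_resid)
        df_den = int(full.df_resid)
        dispersion = float(full.pearson_chi2 / full.df_resid)
        f_stat = float(((null.deviance - full.deviance) / df_num) / dispersion)
        p = float(f_dist.sf(f_stat, df_num, df_den)) if f_stat >= 0 else 1.0
        return TraitModelResult(
            trait=self.trait,
            n_species=int(len(self.data)),
            n_excluded=self.n_excluded,
            coefficients={k: float(v) for k, v in full.params.items()},
            # quasipoisson inference scales the Poisson SEs by sqrt(dispersion)
            std_errors={
                k: float(v * np.sqrt(dispersion)) for k, v in full.bse.items()
            },
            dispersion=dispersion,
            f_statistic=f_stat,
            df=(df_num, df_den),
            p_value=p,
        )


def fit_trait_model(
    data: pd.DataFrame, trait: str, log_transform: bool = False
) -> TraitModelResult:
    """Convenience wrapper: build and fit a :class:`TraitModel`."""
    return TraitModel(data, trait, log_transform=log_transform).fit()


@dataclass
class TraitScreenResults:
    """A family of single-trait screens with multiplicity context."""

    results: list[TraitModelResult]
    family_alpha: float

    def summary(self) -> pd.DataFrame:
        n_tests = len(self.results)
        if n_tests == 0:
            return pd.DataFrame(
                columns=[
                    "trait", "n", "n_excluded", "coefficient", "direction",
                    "dispersion", "F", "df_num", "df_den", "p",
                    "sig_raw", "sig_bonferroni", "adjusted_alpha",
                ]
            )
        exact, displayed = bonferroni_alpha(n_tests, self.family_alpha)
        rows = []
        for r in self.results:
            row = r.to_row()
            row["sig_raw"] = r.p_value < self.family_alpha
            row["sig_bonferroni"] = r.p_value < exact
            row["adjusted_alpha"] = displayed
            rows.append(row)
        return pd.DataFrame(rows)


def trait_screen(
    data: pd.DataFrame,
    traits: list[str],
    family_alpha: float = 0.05,
    log_transforms: set[str] | None = None,
) -> TraitScreenResults:
    """Fit each trait independently and annotate significance.

    Each trait gets its own model (the screens report different df
    because trait sources exclude different species).  Flags are
    reported at the raw alpha and at the Bonferroni-adjusted alpha; the
    correction is an annotation, not a filter.
    """
    log_transforms = log_transforms or set()
    results = [
        TraitModel(data, t, log_transform=t in log_transforms).fit() for t in traits
    ]
    return TraitScreenResults(results=results, family_alpha=family_alpha)
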