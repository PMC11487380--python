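"""Simulated-vs-reference map comparison: agreement components and kappas.

Follows the expected-agreement decomposition used by categorical map
comparison tools: with p_ij the proportion of cells simulated as class i
and observed as class j, c_i the simulated marginals and r_j the reference
marginals,

    M    = Σ_i p_ii                    observed agreement
    N(n) = 1 / J_chance                agreement expected by pure chance
    N(m) = Σ_j c_j · r_j               agreement expected given quantities
    P(m) = Σ_j min(c_j, r_j)           maximum agreement given quantities

which yields the additive components (single-stratum case)

    chance       = min(N(n), N(m), M)
    quantity     = max(0, min(N(m), M) − chance)
    gridcell     = max(0, M − N(m))
    dis_gridcell = P(m) − M
    dis_quantity = 1 − P(m)

summing to 1 together with the (zero) stratum terms, and the kappa family

    Kno  = (M − N(n)) / (1 − N(n))
    Kstd = (M − N(m)) / (1 − N(m))
    Kloc = (M − N(m)) / (P(m) − N(m))

``J_chance`` defaults to 8, one more than the 7 mapped classes: the
comparison tool the reference tables come from counts a background/nodata
category in its chance level (its printed "agreement due to chance" is
exactly 1/8).  Pass ``J_chance=scheme.J`` for a pure J-class chance level.

Without a strata raster there is a single stratum covering the area of
interest: the stratum components are 0 and Klocstrata equals Kloc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import CategoricalRaster
from .transitions import CrossTab, cross_tabulate

__all__ = [
    "AgreementComponents",
    "KappaSet",
    "confusion_matrix",
    "agreement_components",
    "kappa_set",
]

COMPONENT_SUM_TOL = 1e-9

#: output labels, in report order
COMPONENT_LABELS = {
    "chance": "Agreement due to chance",
    "quantity": "Agreement due to quantity",
    "stratum": "Agreement at stratum level",
    "gridcell": "Agreement at gridcell level",
    "dis_gridcell": "Disagreement at gridcell level",
    "dis_stratum": "Disagreement at stratum level",
    "dis_quantity": "Disagreement due to quantity",
}
KAPPA_LABELS = {"Kstd": "KStd", "Kno": "Kno", "Kloc": "Kloc", "Klocstrata": "Klocstrata"}


@dataclass(frozen=True)
class AgreementComponents:
    """Additive decomposition of map agreement; all proportions in [0, 1]."""

    chance: float
    quantity: float
    stratum: float
    gridcell: float
    dis_gridcell: float
    dis_stratum: float
    dis_quantity: float
    J_chance: int = 8

    def __post_init__(self) -> None:
        parts = [
            self.chance, self.quantity, self.stratum, self.gridcell,
            self.dis_gridcell, self.dis_stratum, self.dis_quantity,
        ]
        if any(p < -COMPONENT_SUM_TOL for p in parts):
            raise ValueError(f"components must be non-negative, got {parts}")
        if abs(sum(parts) - 1.0) > 1e-3:
            raise ValueError(f"components must sum to 1, got {sum(parts)}")

    @property
    def M(self) -> float:
        """Observed agreement: sum of the four agreement components."""
        return self.chance + self.quantity + self.stratum + self.gridcell

    @property
    def N_m(self) -> float:
        """Expected agreement given quantities."""
        return self.chance + self.quantity

    @property
    def P_m(self) -> float:
        """Maximum agreement given quantities."""
        return self.M + self.dis_gridcell

    def to_series(self) -> pd.Series:
        return pd.Series(
            {label: getattr(self, key) for key, label in COMPONENT_LABELS.items()}
        )


@dataclass(frozen=True)
class KappaSet:
    """The four kappa variants; undefined values are reported as NaN."""

    Kstd: float
    Kno: float
    Kloc: float
    Klocstrata: float

    def to_series(self) -> pd.Series:
        return pd.Series({label: getattr(self, key) for key, label in KAPPA_LABELS.items()})


def confusion_matrix(sim: CategoricalRaster, ref: CategoricalRaster) -> CrossTab:
    """Cross-tabulation with rows = simulated class, columns = reference class."""
    return cross_tabulate(sim, ref)


def agreement_components(cm: CrossTab, J_chance: int = 8) -> AgreementComponents:
    """Decompose a confusion matrix into agreement/disagreement components."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    if J_chance < 1:
        raise ValueError("J_chance must be >= 1")
    p = cm.counts / total
    M = float(p.trace())
    c = p.sum(axis=1)  # simulated marginals
    r = p.sum(axis=0)  # reference marginals
    N_n = 1.0 / J_chance
    N_m = float((c * r).sum())
    P_m = float(np.minimum(c, r).sum())

    chance = min(N_n, N_m, M)
    quantity = max(0.0, min(N_m, M) - chance)
    gridcell = max(0.0, M - N_m)
    dis_gridcell = P_m - M
    dis_quantity = 1.0 - P_m
    return AgreementComponents(
        chance=chance,
        quantity=quantity,
        stratum=0.0,
        gridcell=gridcell,
        dis_gridcell=dis_gridcell,
        dis_stratum=0.0,
        dis_quantity=dis_quantity,
        J_chance=J_chance,
    )


def kappa_set(ac: AgreementComponents) -> KappaSet:
    """Compute the kappa family from agreement components.

    Degenerate denominators (N(m) = 1 or P(m) = N(m)) yield NaN rather than
    a misleading number.
    """
    M = ac.M
    N_n = 1.0 / ac.J_chance
    N_m = ac.N_m
    P_m = ac.P_m

    def ratio(num: float, den: float) -> float:
        return num / den if abs(den) > 1e-12 else math.nan

    kno = ratio(M - N_n, 1.0 - N_n)
    kstd = ratio(M - N_m, 1.0 - N_m)
    kloc = ratio(M - N_m, P_m - N_m)
    # single stratum covering the AOI: stratum-level location kappa == Kloc
    return KappaSet(Kstd=kstd, Kno=kno, Kloc=kloc, Klocstrata=kloc)


def write_report(ac: AgreementComponents, ks: KappaSet, path: str | Path) -> Path:
    """Emit components and kappas as a two-column delimited report."""
    path = Path(path)
    rows = list(ac.to_series().items()) + list(ks.to_series().items())
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(path, index=False)
    return path
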