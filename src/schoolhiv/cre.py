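"""Correlated random-effects (group-means) probit.

Pooled probit augmented with each woman's own means of the time-varying
covariates (attendance and the age dummies by default).  If the
time-constant unobserved heterogeneity is linear in those means, its
confounding influence is absorbed and the within-woman attendance
variation identifies beta.  Time-constant covariates are excluded from the
mean augmentation (they equal their own means), and year-dummy means are
excluded by default as near-collinear with the age-dummy means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UnidentifiedModelError
from .panel import DesignMatrices
from .probit import PartialEffect, ProbitFit, discrete_change_at_means, fit_probit

__all__ = ["CREDesign", "add_group_means", "fit_cre_probit"]


@dataclass
class CREDesign:
    base: DesignMatrices
    Xa: np.ndarray  # [X | s | mean columns]
    names: list[str]
    mean_names: list[str]
    notes: list[str] = field(default_factory=list)


def _person_means(values: np.ndarray, person_ids: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(person_ids, return_inverse=True)
    sums = np.zeros(len(uniq))
    cnt = np.zeros(len(uniq))
    np.add.at(sums, inv, values)
    np.add.at(cnt, inv, 1.0)
    return (sums / cnt)[inv]


def _time_varying(values: np.ndarray, person_ids: np.ndarray) -> bool:
    means = _person_means(values, person_ids)
    return bool(np.max(np.abs(values - means)) > 1e-12)


def add_group_means(design: DesignMatrices, variables: list[str] | None = None,
                    include_year_means: bool = False) -> CREDesign:
    """Append per-person means of attendance and time-varying controls.

    ``variables`` defaults to every X column plus attendance; requested
    columns that are constant within person are excluded with a note, and
    year dummies are excluded unless ``include_year_means``.
    """
    pid = design.person_ids
    if variables is None:
        variables = ["attendance"] + list(design.x_names)
    notes = []
    mean_cols, mean_names = [], []
    for name in variables:
        if name == "const":
            continue
        if name.startswith("year_") and not include_year_means:
            notes.append(f"{name}: year-dummy mean excluded (near-collinear)")
            continue
        col = (design.s if name == "attendance"
               else design.X[:, design.x_names.index(name)])
        if not _time_varying(col, pid):
            notes.append(f"{name}: time-constant, excluded from mean augmentation")
            continue
        mean_cols.append(_person_means(col, pid))
        mean_names.append(f"mean_{name}")
    Xa = np.column_stack([design.X, design.s] + mean_cols)
    names = list(design.x_names) + ["attendance"] + mean_names
    return CREDesign(base=design, Xa=Xa, names=names,
                     mean_names=mean_names, notes=notes)


def fit_cre_probit(cre: CREDesign) -> tuple[ProbitFit, PartialEffect]:
    """Pooled probit on the augmented design with household-cluster SEs.

    The partial effect of attendance holds every other column, the mean
    columns included, at its sample mean.
    """
    if not _time_varying(cre.base.s, cre.base.person_ids):
        raise UnidentifiedModelError(
            "attendance has no within-person variation; beta unidentified")
    fit = fit_probit(cre.base.y, cre.Xa, cre.base.cluster_ids, names=cre.names)
    return fit, discrete_change_at_means(fit, "attendance")
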