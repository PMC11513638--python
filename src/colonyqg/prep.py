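"""Model covariate preparation: age partition, standardization, age classes.

Within-subject centring splits each female's age into her mean age across
records (between-individual component) and the annual deviation from that
mean, delta age (within-individual component).  Fitting both separates
selective (dis)appearance from true within-individual change; their
posterior difference is the selective-disappearance test.

Standardization is to mean zero and unit standard deviation (population sd,
ddof = 0) by default; ``sd_multiples=2`` gives the Gelman convention in
which slopes are per two standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateColumnError, InvalidArgumentError, SchemaError


@dataclass(frozen=True)
class Standardizer:
    """Stored centre/scale of a standardized column, for back-transformation."""

    center: float
    scale: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.center) / self.scale

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.scale + self.center


def standardize(column, sd_multiples: float = 1.0):
    """Mean-centre and scale a column; returns (values, Standardizer).

    The result has mean 0 and standard deviation ``1 / sd_multiples``.
    Constant columns are rejected: a zero-variance covariate carries no
    information and would divide by zero.
    """
    x = np.asarray(column, dtype=float)
    if sd_multiples <= 0:
        raise InvalidArgumentError("sd_multiples must be positive")
    sd = float(np.std(x))
    if not np.isfinite(sd) or sd == 0.0:
        raise DegenerateColumnError("column has zero variance; cannot standardize")
    scaler = Standardizer(center=float(np.mean(x)), scale=sd_multiples * sd)
    values = scaler.transform(x)
    if isinstance(column, pd.Series):
        values = pd.Series(values, index=column.index, name=column.name)
    return values, scaler


def partition_age(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``mean_age`` and ``delta_age`` columns by within-subject centring.

    ``mean_age`` is each female's mean age over her records; ``delta_age`` is
    the record's deviation from it (exactly zero for single-record females,
    and summing to zero within every female).
    """
    for col in ("female_id", "age"):
        if col not in table.columns:
            raise SchemaError(f"missing required column(s): ['{col}']")
    if table["age"].isna().any():
        raise InvalidArgumentError(
            "age is unknown for some records; apply_study_filters first"
        )
    out = table.copy()
    out["mean_age"] = out.groupby("female_id")["age"].transform("mean")
    out["delta_age"] = out["age"] - out["mean_age"]
    return out


def assign_age_classes(ages, n_classes: int = 5) -> np.ndarray:
    """Quantile-based age classes (1-based labels), ties going to the lower bin.

    Used for the heterogeneous residual variances of the random-regression
    models.  If there are fewer distinct ages than classes, the number of
    classes is reduced with a warning so that every class is non-empty.
    """
    ages = np.asarray(ages, dtype=float)
    if n_classes < 1:
        raise InvalidArgumentError("n_classes must be >= 1")
    if np.isnan(ages).any():
        raise InvalidArgumentError("ages contain missing values")
    distinct = np.unique(ages)
    if len(distinct) < n_classes:
        warnings.warn(
            f"only {len(distinct)} distinct ages; reducing classes "
            f"from {n_classes} to {len(distinct)}",
            stacklevel=2,
        )
        n_classes = len(distinct)
    edges = np.unique(
        np.quantile(ages, [k / n_classes for k in range(1, n_classes)])
    )
    # side='left': a value equal to an edge is NOT counted past it -> lower bin
    labels = np.searchsorted(edges, ages, side="left") + 1
    # collapse any empty labels caused by duplicate quantile edges
    present = np.unique(labels)
    remap = {lab: k + 1 for k, lab in enumerate(present)}
    return np.array([remap[lab] for lab in labels], dtype=int)


#: columns standardized for the animal models (age enters raw in the
#: partitioned model and standardized, as ``age_std``, in random regressions)
STANDARDIZED_COLUMNS = (
    "year",
    "colony_density",
    "island_density",
    "laying_date",
    "wall_distance",
)


def prepare_model_table(
    trait_table: pd.DataFrame,
    sd_multiples: float = 1.0,
    n_age_classes: int = 5,
):
    """Augment a trait table with every model-ready covariate.

    Adds ``mean_age``/``delta_age`` (within-subject centring, raw years),
    ``age_std`` (standardized actual age, the random-regression gradient),
    ``age_class`` (quantile bins for heterogeneous residuals) and a
    ``<col>_std`` version of each column in :data:`STANDARDIZED_COLUMNS`
    that is present.  Returns ``(table, scalers)`` where ``scalers`` maps
    column name to its :class:`Standardizer`.
    """
    out = partition_age(trait_table)
    scalers = {}
    out["age_std"], scalers["age"] = standardize(out["age"], sd_multiples)
    out["age_class"] = assign_age_classes(out["age"].to_numpy(), n_age_classes)
    for col in STANDARDIZED_COLUMNS:
        if col in out.columns:
            out[col + "_std"], scalers[col] = standardize(out[col], sd_multiples)
    return out, scalers
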