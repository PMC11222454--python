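"""Differential-expression handling and model-input preparation.

The pipeline consumes per-time-point differential-expression (DE) tables from
any source. For synthetic data a stand-in DE test is provided: a Welch
two-sample t-test of each entity's time-point replicates against the control
replicates, Benjamini-Hochberg corrected separately within each entity type
(miRNA and mRNA are analysed as separate families throughout).

Model input for structure learning is the union of the DE miRNAs at a
time-point and the bi-clustered mRNAs at that time-point, taken over all
non-control samples and z-score normalised per entity (population 1/n
standard deviation; any consistent convention rescales rows identically and
leaves BIC search behaviour unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigurationError,
    DegenerateRowError,
    EmptyModelError,
    InvalidInputError,
)
from .simulate import ExpressionDataset

DE_COLUMNS = ["entity", "type", "timepoint", "log2fc", "p", "p_adjusted", "direction"]


@dataclass
class ModelInput:
    """Z-scored (entities x non-control samples) matrix for one time-point."""

    values: pd.DataFrame
    entity_types: dict[str, str]
    timepoint: str

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard FDR step-up: sort ascending, multiply p_(i) by m/i, take the
    running minimum from the largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stand_in_de_test(
    dataset: ExpressionDataset,
    timepoint: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test of time-point replicates vs controls, BH within entity type.

    Returns a DE table with one row per entity at this time-point; rows with
    ``p_adjusted < alpha`` carry ``de=True``. This is a deliberately simple DE
    engine for continuous synthetic expression; count-based engines can feed
    their own tables into the pipeline through the same schema.
    """
    control = dataset.sample_meta.loc[dataset.sample_meta["is_control"], "sample"].tolist()
    group = dataset.samples_at(timepoint)
    if not control:
        raise ConfigurationError("dataset has no control samples")
    if len(control) < 2 or len(group) < 2:
        raise ConfigurationError("need >= 2 replicates per group for the DE test")

    X = dataset.values[group].to_numpy(dtype=float)
    C = dataset.values[control].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, p = stats.ttest_ind(X, C, axis=1, equal_var=False)
    # Zero variance in both groups with equal means carries no evidence.
    p = np.where(np.isnan(p), 1.0, p)
    log2fc = X.mean(axis=1) - C.mean(axis=1)

    table = pd.DataFrame(
        {
            "entity": dataset.values.index,
            "type": dataset.entity_meta.set_index("entity")["type"].reindex(
                dataset.values.index
            ).to_numpy(),
            "timepoint": timepoint,
            "log2fc": log2fc,
            "p": p,
        }
    )
    table["p_adjusted"] = np.nan
    for _, idx in table.groupby("type").groups.items():
        table.loc[idx, "p_adjusted"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    table["de"] = table["p_adjusted"] < alpha
    return table[DE_COLUMNS + ["de"]]


def de_table_for_dataset(
    dataset: ExpressionDataset, alpha: float = 0.05
) -> pd.DataFrame:
    """Stand-in DE test applied at every non-control time-point."""
    tps = [
        tp
        for tp in dataset.sample_meta.loc[~dataset.sample_meta["is_control"], "timepoint"].unique()
    ]
    return pd.concat(
        [stand_in_de_test(dataset, tp, alpha) for tp in tps], ignore_index=True
    )


def de_entities(de: pd.DataFrame, timepoint: str, entity_type: str | None = None) -> set[str]:
    """Entities flagged DE at a time-point, optionally restricted by type."""
    mask = (de["timepoint"] == timepoint) & de["de"]
    if entity_type is not None:
        mask &= de["type"] == entity_type
    return set(de.loc[mask, "entity"])


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scoring with population (1/n) standard deviation."""
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = [str(matrix.index[i]) for i in flat]
        raise DegenerateRowError(f"constant rows cannot be z-scored: {names}")
    return pd.DataFrame((X - mu) / sd, index=matrix.index, columns=matrix.columns)


def select_model_variables(
    de: pd.DataFrame,
    biclustered: dict[str, set[str]],
    timepoint: str,
    dataset: ExpressionDataset,
) -> ModelInput:
    """Assemble the z-scored model input for one time-point.

    Entity set = DE miRNAs at the time-point union bi-clustered mRNAs at the
    time-point; values are all non-control samples, z-scored after subsetting.
    """
    mirnas = sorted(de_entities(de, timepoint, "miRNA"))
    mrnas = sorted(biclustered.get(timepoint, set()))
    entities = mirnas + [m for m in mrnas if m not in mirnas]
    if not entities:
        raise EmptyModelError(f"no DE miRNAs or bi-clustered mRNAs at {timepoint!r}")
    missing = [e for e in entities if e not in dataset.values.index]
    if missing:
        raise ConfigurationError(f"selected entities absent from dataset: {missing}")
    samples = dataset.noncontrol_samples()
    sub = dataset.values.loc[entities, samples]
    types = dataset.entity_types()
    return ModelInput(
        values=zscore_rows(sub),
        entity_types={e: types[e] for e in entities},
        timepoint=timepoint,
    )


def read_de_table(path) -> pd.DataFrame:
    """Read a DE table TSV; recomputes the ``de`` flag if absent (alpha 0.05)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"DE table missing columns: {missing}")
    if "de" not in table.columns:
        table["de"] = table["p_adjusted"] < 0.05
    return table


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
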