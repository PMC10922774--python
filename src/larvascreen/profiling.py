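"""Per-compound behavioral profiles normalized against DMSO controls.

A compound's profile is the behavior-wise difference between the mean
vector of its larvae and the mean vector of the DMSO vehicle controls of
the same batch, in percentage points (degrees for the two turn-angle
behaviors).  Profiles are the substrate of all clustering; an optional
per-behavior z-scoring puts percentage and degree scales on a common
footing before distances are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import pandas as pd

from .metrics import BEHAVIOR_NAMES

if TYPE_CHECKING:  # pragma: no cover
    from .pose_io import TreatmentMap

GLOBAL_BATCH = "__all__"


class NormalizationError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class ProfileMatrix:
    """Compounds x 25 behaviors, as differences vs DMSO controls.

    ``values`` is indexed by compound ID (e.g. "M1G11") with the
    canonical behavior names as columns.  DMSO controls are the
    normalization reference, never rows.  Missing cells stay missing
    (NaN), they are never silently zeroed.
    """

    values: pd.DataFrame
    n_larvae: pd.Series | None = None
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(BEHAVIOR_NAMES):
            raise ValueError(
                "profile matrix must have exactly the 25 canonical behavior columns"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound IDs: {dups}")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "compound_id"
        out.to_csv(path, float_format="%.6f")


@dataclass
class StandardizedMatrix:
    """Column z-scored profile matrix plus the parameters to invert it.

    Zero-variance columns are mapped to 0 (with a warning) and restored
    exactly on inversion.  The sample (n-1) standard deviation is used.
    """

    values: pd.DataFrame
    col_means: pd.Series
    col_sds: pd.Series

    def invert(self) -> pd.DataFrame:
        sds = self.col_sds.replace(0.0, 1.0)
        return self.values * sds + self.col_means

    def for_clustering(self) -> pd.DataFrame:
        """Values with missing cells imputed at the column mean (0 after
        z-scoring) — used for distance computations only."""
        return self.values.fillna(0.0)


def aggregate_compound(
    larva_table: pd.DataFrame, tmap: "TreatmentMap"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Average per-larva behavior vectors into per-compound and per-batch
    DMSO-control means.

    Returns ``(compound_means, dmso_means, n_larvae, compound_batch)``.
    Means are taken behavior-wise over non-missing larvae.  Compounds
    with zero surviving larvae simply do not appear.
    """
    ent = tmap.entries
    missing = [w for w in larva_table.index if w not in ent.index]
    if missing:
        raise KeyError(f"wells absent from treatment map: {missing[:5]}")

    meta = ent.loc[larva_table.index]
    batch = meta["batch"] if "batch" in meta.columns else pd.Series(
        GLOBAL_BATCH, index=meta.index
    )
    treat = meta["role"] == "treatment"
    dmso = meta["role"] == "dmso_control"

    tdf = larva_table[treat].groupby(meta.loc[treat, "compound_id"]).mean()
    n = larva_table[treat].notna().any(axis=1).groupby(
        meta.loc[treat, "compound_id"]
    ).sum().astype(int)
    cbatch = meta.loc[treat].groupby("compound_id")["batch"].first() if (
        "batch" in meta.columns
    ) else pd.Series(GLOBAL_BATCH, index=tdf.index)

    ddf = larva_table[dmso].groupby(batch[dmso]).mean()
    return tdf, ddf, n, cbatch.reindex(tdf.index)


def normalize_to_control(
    compound_means: pd.DataFrame,
    dmso_means: pd.DataFrame,
    compound_batch: pd.Series | None = None,
    n_larvae: pd.Series | None = None,
) -> ProfileMatrix:
    """Subtract the batch-matched DMSO mean from each compound mean.

    When a compound's batch has no DMSO control, a global DMSO mean
    (mean of all control batches) is used if available, otherwise a
    :class:`NormalizationError` names the batch.
    """
    if dmso_means.empty:
        raise NormalizationError("no DMSO control means available")
    if compound_batch is None:
        compound_batch = pd.Series(GLOBAL_BATCH, index=compound_means.index)
    global_mean = dmso_means.mean(axis=0)

    rows = {}
    for cid in compound_means.index:
        b = compound_batch.get(cid, GLOBAL_BATCH)
        if b in dmso_means.index:
            ref = dmso_means.loc[b]
        elif b == GLOBAL_BATCH or len(dmso_means) > 0:
            ref = global_mean
        else:  # pragma: no cover - unreachable given the empty check
            raise NormalizationError(f"no DMSO control for batch {b!r}")
        rows[cid] = compound_means.loc[cid] - ref
    vals = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(BEHAVIOR_NAMES)
    )
    vals = vals.loc[compound_means.index]
    return ProfileMatrix(values=vals, n_larvae=n_larvae, batch=compound_batch)


def standardize(pm: ProfileMatrix) -> StandardizedMatrix:
    """Z-score each behavior across compounds (sample SD, ddof=1)."""
    vals = pm.values
    if len(vals) < 2:
        raise DegenerateInputError("standardization needs at least 2 compounds")
    means = vals.mean(axis=0, skipna=True)
    sds = vals.std(axis=0, ddof=1, skipna=True)
    zero = (sds == 0) | sds.isna()
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance behavior column(s) mapped to 0",
            stacklevel=2,
        )
    safe = sds.where(~zero, 1.0)
    z = (vals - means) / safe
    z.loc[:, zero] = 0.0
    return StandardizedMatrix(
        values=z, col_means=means, col_sds=sds.where(~zero, 0.0)
    )
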