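"""Transdiagnostic questionnaire scoring.

Three symptom dimensions — anxious-depression (AD), compulsivity and
intrusive thought (CIT), and social withdrawal (SW) — are scored as weighted
sums of 209 items drawn from nine standard self-report instruments.  The
item weights come from a previously published factor analysis and are
consumed from a delimited weights file (one row per item, three loadings);
this package never embeds the published values, but can generate a synthetic
stand-in with the same shape (see :mod:`metacog.cohort`).

Also provided: Work and Social Adjustment Scale (WSAS) totals (five items,
0-8 each, total 0-40), per-instrument sum scores via a scoring key, and
detection of failed catch (attention-check) items, which are reported but do
not exclude anyone from analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INSTRUMENTS",
    "DIMENSIONS",
    "WSAS_ITEM_IDS",
    "CATCH_ITEMS",
    "SchemaError",
    "WeightsMatrix",
    "DimensionScores",
    "clinical_item_ids",
    "score_dimensions",
    "score_wsas",
    "wsas_totals",
    "scale_totals",
    "detect_catch_failures",
    "read_weights",
    "write_weights",
]

DIMENSIONS = ("AD", "CIT", "SW")


@dataclass(frozen=True)
class ItemScale:
    n_items: int
    lo: int
    hi: int


#: The nine clinical instruments and their ordinal response ranges.
#: Items total 209.  Ranges are generic per-instrument ordinals; only
#: weighted sums (and per-scale sums) are ever analysed.
INSTRUMENTS: dict[str, ItemScale] = {
    "zung": ItemScale(20, 1, 4),      # depression
    "stai_t": ItemScale(20, 1, 4),    # trait anxiety
    "ssms": ItemScale(43, 0, 1),      # schizotypy (short scales)
    "bis11": ItemScale(30, 1, 4),     # impulsivity
    "ocir": ItemScale(18, 0, 4),      # obsessive-compulsive
    "lsas": ItemScale(24, 0, 3),      # social anxiety
    "eat26": ItemScale(26, 0, 5),     # eating attitudes
    "aes": ItemScale(18, 1, 4),       # apathy
    "audit": ItemScale(10, 0, 4),     # alcohol misuse
}

N_CLINICAL_ITEMS = sum(s.n_items for s in INSTRUMENTS.values())
assert N_CLINICAL_ITEMS == 209

WSAS_ITEM_IDS = tuple(f"wsas_{i:02d}" for i in range(1, 6))
WSAS_SCALE = ItemScale(5, 0, 8)


@dataclass(frozen=True)
class CatchItem:
    required: int
    lo: int
    hi: int
    label: str


#: Attention checks embedded in the OCI-R and WSAS blocks, each with a
#: mandated response.  Failures are counted, never used for exclusion.
CATCH_ITEMS: dict[str, CatchItem] = {
    "catch_ocir": CatchItem(required=1, lo=0, hi=4, label="A little"),
    "catch_wsas": CatchItem(required=0, lo=0, hi=8, label="Not at all"),
}


class SchemaError(ValueError):
    """An item table does not match the expected item inventory."""


def clinical_item_ids() -> list[str]:
    """The 209 clinical item identifiers, instrument by instrument."""
    ids = []
    for name, scale in INSTRUMENTS.items():
        ids.extend(f"{name}_{i:02d}" for i in range(1, scale.n_items + 1))
    return ids


def item_scale(item_id: str) -> ItemScale:
    """Response range for any known item id."""
    if item_id in CATCH_ITEMS:
        c = CATCH_ITEMS[item_id]
        return ItemScale(1, c.lo, c.hi)
    if item_id in WSAS_ITEM_IDS:
        return ItemScale(1, WSAS_SCALE.lo, WSAS_SCALE.hi)
    prefix = item_id.rsplit("_", 1)[0]
    if prefix in INSTRUMENTS:
        s = INSTRUMENTS[prefix]
        return ItemScale(1, s.lo, s.hi)
    raise SchemaError(f"unknown item id {item_id!r}")


@dataclass(frozen=True)
class WeightsMatrix:
    """209 items x 3 dimension loadings (AD, CIT, SW)."""

    item_ids: tuple[str, ...]
    weights: np.ndarray  # (209, 3)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        expected = clinical_item_ids()
        if list(self.item_ids) != expected:
            extra = set(self.item_ids) - set(expected)
            missing = set(expected) - set(self.item_ids)
            raise SchemaError(
                f"weights must cover the 209 clinical items in order; "
                f"missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )
        if w.shape != (209, 3):
            raise SchemaError(f"weights must be 209x3, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise SchemaError("weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": list(self.item_ids),
                "w_AD": self.weights[:, 0],
                "w_CIT": self.weights[:, 1],
                "w_SW": self.weights[:, 2],
            }
        )


def write_weights(weights: WeightsMatrix, path) -> None:
    weights.to_frame().to_csv(path, index=False)


def read_weights(path) -> WeightsMatrix:
    frame = pd.read_csv(path)
    needed = {"item_id", "w_AD", "w_CIT", "w_SW"}
    if not needed <= set(frame.columns):
        raise SchemaError(f"weights file {path} must have columns {sorted(needed)}")
    order = {iid: i for i, iid in enumerate(clinical_item_ids())}
    unknown = [i for i in frame["item_id"] if i not in order]
    if unknown:
        raise SchemaError(f"weights file has unknown item ids {unknown[:5]}")
    frame = frame.sort_values("item_id", key=lambda s: s.map(order))
    return WeightsMatrix(
        item_ids=tuple(frame["item_id"]),
        weights=frame[["w_AD", "w_CIT", "w_SW"]].to_numpy(float),
    )


@dataclass
class DimensionScores:
    """Per participant x timepoint AD/CIT/SW scores.

    ``frame`` has columns ``participant_id, timepoint, AD, CIT, SW``.  When
    centred, the per-dimension offsets estimated on the baseline sample were
    subtracted from *both* timepoints, so within-person change scores are
    unaffected by centring.
    """

    frame: pd.DataFrame
    centred: bool
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _item_matrix(items: pd.DataFrame, item_ids: Sequence[str]) -> pd.DataFrame:
    for col in ("participant_id", "timepoint", "item_id", "response"):
        if col not in items.columns:
            raise SchemaError(f"item table is missing column {col!r}")
    sub = items[items["item_id"].isin(set(item_ids))]
    wide = sub.pivot_table(
        index=["participant_id", "timepoint"],
        columns="item_id",
        values="response",
        aggfunc="first",
    )
    missing_cols = set(item_ids) - set(wide.columns)
    if missing_cols:
        raise SchemaError(f"item table is missing items {sorted(missing_cols)[:10]}")
    wide = wide[list(item_ids)]
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise SchemaError(f"missing responses for items {bad[:10]}")
    dup = sub.duplicated(["participant_id", "timepoint", "item_id"])
    if dup.any():
        raise SchemaError("duplicate responses for the same participant/timepoint/item")
    return wide


def score_dimensions(
    items: pd.DataFrame,
    weights: WeightsMatrix,
    centre: bool = True,
    zscore_items: bool = False,
    baseline_label: str = "baseline",
) -> DimensionScores:
    """Weighted-sum dimension scores from a long item table.

    ``items`` has one row per (participant, timepoint, item) with columns
    ``participant_id, timepoint, item_id, response`` and must cover all 209
    clinical items for every participant x timepoint (completer semantics).
    Each dimension score is sum(item x loading).  ``zscore_items`` applies
    the weights to within-sample z-scored items instead of raw responses
    (the default is raw).  Centring subtracts the baseline-sample mean per
    dimension from every row.
    """
    wide = _item_matrix(items, weights.item_ids)
    X = wide.to_numpy(float)
    if zscore_items:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [weights.item_ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"cannot z-score zero-variance items {zero[:10]}")
        X = (X - X.mean(axis=0)) / sd
    scores = X @ weights.weights
    frame = wide.index.to_frame(index=False)
    for j, dim in enumerate(DIMENSIONS):
        frame[dim] = scores[:, j]
    offsets = np.zeros(3)
    if centre:
        base = frame[frame["timepoint"] == baseline_label]
        if base.empty:
            raise ValueError(
                f"no rows with timepoint={baseline_label!r} to estimate centring offsets"
            )
        offsets = base[list(DIMENSIONS)].mean().to_numpy()
        frame[list(DIMENSIONS)] = frame[list(DIMENSIONS)] - offsets
    return DimensionScores(frame=frame, centred=centre, offsets=offsets)


def score_wsas(items: Iterable[int]) -> int:
    """WSAS total: five items each 0-8, summed to 0-40."""
    vals = list(items)
    if len(vals) != 5:
        raise ValueError(f"WSAS has five items, got {len(vals)}")
    for v in vals:
        if not (WSAS_SCALE.lo <= v <= WSAS_SCALE.hi):
            raise ValueError(f"WSAS item response {v} outside 0-8")
    return int(sum(vals))


def wsas_totals(items: pd.DataFrame) -> pd.DataFrame:
    """WSAS totals per participant x timepoint from a long item table."""
    wide = _item_matrix(items, WSAS_ITEM_IDS)
    out = wide.index.to_frame(index=False)
    out["wsas_total"] = [score_wsas(row) for row in wide.to_numpy(int)]
    return out


def scale_totals(
    items: pd.DataFrame, key: Mapping[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Per-instrument sum scores (the exploratory per-scale measures).

    ``key`` maps scale name -> item ids; the default key sums each of the
    nine instruments over its own items.
    """
    if key is None:
        key = default_scoring_key()
    all_ids = [iid for ids in key.values() for iid in ids]
    wide = _item_matrix(items, all_ids)
    out = wide.index.to_frame(index=False)
    for name, ids in key.items():
        out[name] = wide[list(ids)].sum(axis=1).to_numpy()
    return out


def default_scoring_key() -> dict[str, list[str]]:
    ids = clinical_item_ids()
    key: dict[str, list[str]] = {}
    for name in INSTRUMENTS:
        key[name] = [i for i in ids if i.startswith(name + "_")]
    return key


def write_scoring_key(key: Mapping[str, Sequence[str]], path) -> None:
    rows = [(scale, iid) for scale, ids in key.items() for iid in ids]
    pd.DataFrame(rows, columns=["scale", "item_id"]).to_csv(path, index=False)


def read_scoring_key(path) -> dict[str, list[str]]:
    frame = pd.read_csv(path)
    if not {"scale", "item_id"} <= set(frame.columns):
        raise SchemaError(f"scoring key {path} must have columns scale,item_id")
    return {s: g["item_id"].tolist() for s, g in frame.groupby("scale", sort=False)}


def detect_catch_failures(items: pd.DataFrame) -> pd.DataFrame:
    """Count failed attention checks per participant x timepoint.

    A failure is any response other than the catch item's mandated one.
    Returns columns ``participant_id, timepoint, n_catch, n_failed``.
    Participants who fail are flagged, not excluded.
    """
    catch = items[items["item_id"].isin(CATCH_ITEMS)]
    if catch.empty:
        raise SchemaError("no catch items present in the item table")
    catch = catch.copy()
    required = catch["item_id"].map({k: v.required for k, v in CATCH_ITEMS.items()})
    catch["failed"] = (catch["response"] != required).astype(int)
    out = (
        catch.groupby(["participant_id", "timepoint"], sort=False)
        .agg(n_catch=("failed", "size"), n_failed=("failed", "sum"))
        .reset_index()
    )
    return out
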