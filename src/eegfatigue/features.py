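"""Fuzzy-entropy feature extraction: one entropy value per channel per epoch."""

from __future__ import annotations

import logging
import warnings

import pandas as pd

from .fuzzyen import FuzzyEnParams, fuzzy_entropy
from .preprocess import Epoch, STATE_LABELS

logger = logging.getLogger(__name__)

__all__ = ["extract_features", "feature_columns", "write_feature_table", "read_feature_table"]

INDEX_COLS = ["subject_id", "epoch_index"]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-channel entropy columns of a feature table."""
    return [c for c in table.columns if c.startswith("fuzzyen_")]


def extract_features(
    epochs: list[Epoch], params: FuzzyEnParams = FuzzyEnParams()
) -> pd.DataFrame:
    """Build the feature table: rows = (subject, epoch time), columns =
    ``fuzzyen_<channel>`` entropies plus the 0/1 state label.

    Channels are joined side by side on (subject_id, epoch_index); an epoch
    time missing on any channel — e.g. after asymmetric artifact rejection —
    is dropped so every row is complete, and the drop count is logged.
    """
    if not epochs:
        warnings.warn("no epochs supplied; returning empty feature table", stacklevel=2)
        return pd.DataFrame(columns=INDEX_COLS + ["label"])
    fss = {ep.fs for ep in epochs}
    if len(fss) > 1:
        raise ValueError(f"mixed sampling rates in epoch list: {sorted(fss)}")

    records = []
    for ep in epochs:
        records.append(
            {
                "subject_id": ep.subject_id,
                "epoch_index": ep.epoch_index,
                "state": ep.state,
                "channel": ep.channel,
                "value": fuzzy_entropy(ep.samples, params),
            }
        )
    long = pd.DataFrame.from_records(records)
    channels = sorted(long["channel"].unique())

    wide = long.pivot_table(
        index=INDEX_COLS + ["state"], columns="channel", values="value", aggfunc="first"
    )
    n_before = len(wide)
    wide = wide.dropna()
    dropped = n_before - len(wide)
    if dropped:
        logger.info("dropped %d epoch-times missing on some channel", dropped)
    wide = wide.rename(columns={ch: f"fuzzyen_{ch}" for ch in channels}).reset_index()
    wide["label"] = wide["state"].map(STATE_LABELS)
    wide = wide.drop(columns=["state"])
    wide.columns.name = None
    cols = INDEX_COLS + [f"fuzzyen_{ch}" for ch in channels] + ["label"]
    table = wide[cols].sort_values(INDEX_COLS, kind="mergesort").reset_index(drop=True)
    table.attrs["params"] = {
        "m": params.m,
        "n": params.n,
        "r_factor": params.r_factor,
        "similarity_form": params.similarity_form,
    }
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in INDEX_COLS + ["label"] if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing required columns: {missing}")
    if not feature_columns(table):
        raise ValueError("feature table has no fuzzyen_<channel> columns")
    return table
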