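"""Per-protein feature assembly and feature-table I/O.

Each protein contributes a four-number feature vector: the length, curvature
and bottleneck radius of its largest surface tunnel (largest by
length × bottleneck radius) and the maximal TM-score against the OB-fold
template library. Bottleneck radius is stored but excluded from the default
classification subset — it shows no class separation — while remaining
selectable.

Proteins in which no tunnel is detected get NaN tunnel fields; they are
excluded from training and reported separately at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .obfold import TemplateLibrary, obfold_feature
from .structure_io import ProteinChain
from .tunnels import GeometryError, TunnelParams, detect_tunnels, select_largest_tunnel

logger = logging.getLogger(__name__)

ALL_FEATURES = ("length", "curvature", "bottleneck_radius", "tm_score")
#: default classification subset (bottleneck radius intentionally absent)
DEFAULT_SUBSET = ("length", "curvature", "tm_score")

TABLE_COLUMNS = ["protein_id", "length", "curvature", "bottleneck_radius",
                 "tm_score", "label", "form"]


@dataclass(frozen=True)
class FeatureSubset:
    names: tuple[str, ...] = DEFAULT_SUBSET

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("feature subset must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        bad = set(self.names) - set(ALL_FEATURES)
        if bad:
            raise ValueError(f"unknown features {sorted(bad)}; choose from {ALL_FEATURES}")

    @classmethod
    def parse(cls, text: str) -> "FeatureSubset":
        return cls(tuple(s.strip() for s in text.split(",") if s.strip()))


def extract_features(
    chain: ProteinChain,
    library: TemplateLibrary,
    protein_id: str = "",
    params: TunnelParams | None = None,
    label: str = "UNKNOWN",
    form: str = "HOLO",
) -> dict:
    """Feature vector of one chain: tunnel indexes + OB-fold TM-score.

    A chain without a detectable tunnel gets NaN tunnel fields and a
    logged notice; the TM-score is still computed.
    """
    pid = protein_id or chain.chain_id
    length = curvature = bottleneck = float("nan")
    try:
        ts = detect_tunnels(chain, params)
        tunnel = select_largest_tunnel(ts)
        length, curvature, bottleneck = tunnel.length, tunnel.curvature, tunnel.bottleneck_radius
    except GeometryError as exc:
        logger.info("%s: no usable tunnel (%s)", pid, exc)
    tm = obfold_feature(chain, library)
    return {
        "protein_id": pid,
        "length": length,
        "curvature": curvature,
        "bottleneck_radius": bottleneck,
        "tm_score": tm,
        "label": label,
        "form": form,
    }


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r between two feature vectors with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_feature_table(table: pd.DataFrame, path) -> None:
    out = table.reindex(columns=TABLE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature TSV, reporting the offending line on bad cells."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("length", "curvature", "bottleneck_radius", "tm_score"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"{path}: line {i + 2}: bad numeric value {v!r} in column {col}"
                    ) from None
            raise
    return df[TABLE_COLUMNS]


def usable_for_training(table: pd.DataFrame, subset: FeatureSubset) -> pd.DataFrame:
    """Rows with all subset features present (missing-tunnel rows drop out)."""
    mask = np.ones(len(table), bool)
    for name in subset.names:
        mask &= np.isfinite(table[name].to_numpy(float))
    dropped = int((~mask).sum())
    if dropped:
        logger.info("excluding %d rows with missing features from training", dropped)
    return table.loc[mask].reset_index(drop=True)
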