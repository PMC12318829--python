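"""Candidate transcription-factor screen.

Two filters applied to a TF list and intersected:

1. a directional differential-expression filter — the TF must be
   upregulated (log2FC > 1, p < .05) in the developmental series and
   downregulated in the activation series;
2. a two-dataset Pearson correlation screen — the TF's expression must
   correlate positively with the target gene (r > 0.3, p < .05) in *both*
   series.

Only positive correlations pass by default (the screen looks for positive
regulators of the target); ``two_sided_r`` switches to |r|.  Expression
values are used as provided — no internal re-normalisation.  A TF missing
from one dataset cannot be a candidate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import pearson

__all__ = [
    "ScreenConfig",
    "ScreenRecord",
    "filter_degs",
    "directional_candidates",
    "correlation_screen",
    "run_screen",
    "read_expression_table",
    "read_deg_table",
    "read_tf_list",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and gene lists of the screen (defaults per the method:
    r > 0.3, p < .05, |log2FC| > 1, DEG p < .05)."""

    target_gene: str
    tf_list: frozenset[str]
    r_threshold: float = 0.3
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    deg_p_threshold: float = 0.05
    two_sided_r: bool = False
    use_directional: bool = True
    use_correlation: bool = True

    def __post_init__(self) -> None:
        if min(self.r_threshold, self.p_threshold, self.lfc_threshold,
               self.deg_p_threshold) <= 0:
            raise ValueError("all thresholds must be positive")
        object.__setattr__(self, "tf_list", frozenset(self.tf_list))
        if self.target_gene in self.tf_list:
            object.__setattr__(
                self, "tf_list", self.tf_list - {self.target_gene}
            )


@dataclass(frozen=True)
class ScreenRecord:
    """Per-TF correlation statistics against the target in both series."""

    tf_id: str
    r_dev: float
    p_dev: float
    r_act: float
    p_act: float
    passes_dev: bool
    passes_act: bool
    candidate: bool
    missing_data: bool = False


def filter_degs(
    table: pd.DataFrame, lfc_threshold: float = 1.0, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Rows with |log2FC| strictly above the threshold and p strictly below.

    Adds a ``direction`` column ("up"/"down").  Raises if the log2FC or p
    column is missing.
    """
    missing = [c for c in ("log2FC", "p") if c not in table.columns]
    if missing:
        raise ValueError(f"DE table lacks required column(s): {missing}")
    keep = (table["log2FC"].abs() > lfc_threshold) & (table["p"] < p_threshold)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["log2FC"] > 0, "up", "down")
    return out


def directional_candidates(
    dev_table: pd.DataFrame, act_table: pd.DataFrame, cfg: ScreenConfig
) -> set[str]:
    """TFs up in the development table AND down in the activation table."""
    dev = filter_degs(dev_table, cfg.lfc_threshold, cfg.deg_p_threshold)
    act = filter_degs(act_table, cfg.lfc_threshold, cfg.deg_p_threshold)
    up_dev = set(dev.loc[dev["direction"] == "up", "gene_id"])
    down_act = set(act.loc[act["direction"] == "down", "gene_id"])
    return (up_dev & down_act) & cfg.tf_list


def _corr(series: pd.DataFrame, target: str, tf: str, cfg: ScreenConfig):
    """(r, p, passes, missing) of one TF vs the target in one series."""
    if tf not in series.index:
        return math.nan, math.nan, False, True
    try:
        res = pearson(series.loc[target].to_numpy(), series.loc[tf].to_numpy())
    except ValueError:  # constant TF row: correlation undefined, cannot pass
        return math.nan, math.nan, False, True
    r_eff = abs(res.r) if cfg.two_sided_r else res.r
    passes = (r_eff > cfg.r_threshold) and (res.p < cfg.p_threshold)
    return res.r, res.p, passes, False


def correlation_screen(
    dev: pd.DataFrame, act: pd.DataFrame, cfg: ScreenConfig
) -> list[ScreenRecord]:
    """Per-TF Pearson correlation against the target in both series.

    A TF passes a series when r > r_threshold (strict) and p < p_threshold
    (strict); a candidate passes both.  Records are sorted by
    min(r_dev, r_act) descending, ties broken by TF id, so the output is
    independent of TF input order.
    """
    for name, series in (("development", dev), ("activation", act)):
        if cfg.target_gene not in series.index:
            raise ValueError(
                f"target gene {cfg.target_gene!r} absent from the {name} table"
            )
        if series.shape[1] < 3:
            raise ValueError(f"{name} table has fewer than 3 samples")

    records = []
    for tf in sorted(cfg.tf_list):
        r_dev, p_dev, ok_dev, miss_dev = _corr(dev, cfg.target_gene, tf, cfg)
        r_act, p_act, ok_act, miss_act = _corr(act, cfg.target_gene, tf, cfg)
        records.append(
            ScreenRecord(
                tf_id=tf,
                r_dev=r_dev,
                p_dev=p_dev,
                r_act=r_act,
                p_act=p_act,
                passes_dev=ok_dev,
                passes_act=ok_act,
                candidate=ok_dev and ok_act,
                missing_data=miss_dev or miss_act,
            )
        )

    def sort_key(rec: ScreenRecord):
        worst = min(
            rec.r_dev if math.isfinite(rec.r_dev) else -2.0,
            rec.r_act if math.isfinite(rec.r_act) else -2.0,
        )
        return (-worst, rec.tf_id)

    return sorted(records, key=sort_key)


def run_screen(
    dev_expr: pd.DataFrame,
    act_expr: pd.DataFrame,
    dev_deg: pd.DataFrame,
    act_deg: pd.DataFrame,
    cfg: ScreenConfig,
) -> pd.DataFrame:
    """Full screen: directional DEG filter intersected with the two-dataset
    correlation screen; returns the annotated candidate table ranked by
    min(r_dev, r_act).

    An empty candidate set yields an empty table (logged, not an error).
    Either filter can be disabled via the config.
    """
    records = correlation_screen(dev_expr, act_expr, cfg)
    directional = (
        directional_candidates(dev_deg, act_deg, cfg)
        if cfg.use_directional
        else cfg.tf_list
    )
    rows = []
    for rec in records:
        corr_ok = rec.candidate if cfg.use_correlation else True
        dir_ok = rec.tf_id in directional
        if corr_ok and dir_ok:
            rows.append(
                {
                    "tf_id": rec.tf_id,
                    "r_dev": rec.r_dev,
                    "p_dev": rec.p_dev,
                    "r_act": rec.r_act,
                    "p_act": rec.p_act,
                    "directional_pass": dir_ok,
                    "min_r": min(rec.r_dev, rec.r_act),
                }
            )
    if not rows:
        logger.info("screen returned no candidate TF")
        return pd.DataFrame(
            columns=[
                "tf_id", "r_dev", "p_dev", "r_act", "p_act",
                "directional_pass", "min_r",
            ]
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_expression_table(path) -> pd.DataFrame:
    """Genes x samples TSV; the header row carries the ordered sample names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression table")
    return df


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: DE table lacks a gene_id column")
    return df


def read_tf_list(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
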