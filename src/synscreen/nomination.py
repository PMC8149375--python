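"""HSA filter and the five-criterion, multi-cell-line hit nomination.

An anchored screen yields, per drug and cell line, the metrics of
:mod:`synscreen.dose_response`.  Combination partners are nominated in two
stages:

1. the highest-single-agent (HSA) filter -- the combination must inhibit at
   least ``hsa_margin`` (default 10%) more than the better of the two single
   agents at the same dose, for at least ``hsa_min_doses`` (default 3) doses;
2. a vote over five criteria (GI50 fold change, AUC difference, AUC percent
   change, and top-ranked combination GI50 / AUC z-scores gated on minimum
   viability), each required in a stated fraction of cell lines; drugs with at
   least ``min_criteria`` (default 4) votes are nominated.

Cell-line counts from the original eight-line design are expressed as
fractions so the same rules apply to subsets (e.g. the five VHL-wild-type
lines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

__all__ = ["CriterionConfig", "hsa_filter", "criterion_votes", "nominate",
           "rank_classification"]

CRITERIA = ["c1_gi50_fold", "c2_auc_diff", "c3_auc_pct", "c4_gi50_rank", "c5_auc_rank"]


@dataclass(frozen=True)
class CriterionConfig:
    gi50_fold_min: float = 5.0
    frac_lines_gi50: float = 0.5
    auc_diff_min: float = 0.9
    frac_lines_aucdiff: float = 0.5
    auc_pct_min: float = 25.0
    frac_lines_aucpct: float = 2.0 / 3.0
    top_frac_rank: float = 0.5
    frac_lines_rank: float = 0.5
    min_viability_max: float = 0.15
    min_criteria: int = 4
    hsa_margin: float = 0.10
    hsa_min_doses: int = 3

    def __post_init__(self) -> None:
        for name in ("frac_lines_gi50", "frac_lines_aucdiff", "frac_lines_aucpct",
                     "top_frac_rank", "frac_lines_rank"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not (1 <= self.min_criteria <= 5):
            raise ConfigError(f"min_criteria must be in 1..5, got {self.min_criteria}")
        if self.hsa_min_doses < 1:
            raise ConfigError("hsa_min_doses must be >= 1")


def hsa_filter(
    drug_inhibition: np.ndarray,
    anchor_inhibition: np.ndarray,
    combo_inhibition: np.ndarray,
    config: CriterionConfig | None = None,
) -> tuple[bool, np.ndarray]:
    """Highest-single-agent filter on aligned per-dose inhibition fractions.

    Returns ``(passed, margins)`` where ``margins[i]`` is the combination's
    inhibition minus the better single agent at dose i.  The filter passes
    when at least ``hsa_min_doses`` margins reach ``hsa_margin``.
    """
    config = config or CriterionConfig()
    drug = np.asarray(drug_inhibition, dtype=float)
    anchor = np.asarray(anchor_inhibition, dtype=float)
    combo = np.asarray(combo_inhibition, dtype=float)
    if drug.shape != combo.shape or anchor.shape != combo.shape:
        raise SchemaError("hsa_filter requires aligned dose grids")
    margins = combo - np.maximum(drug, anchor)
    passed = int(np.sum(margins >= config.hsa_margin)) >= config.hsa_min_doses
    return bool(passed), margins


def _frac_lines(flags: pd.Series) -> float:
    return float(flags.mean())


def criterion_votes(metrics: pd.DataFrame, config: CriterionConfig | None = None) -> pd.DataFrame:
    """Boolean vote per drug over the five selection criteria.

    ``metrics`` is one row per (drug, cell line) with the columns produced by
    :func:`synscreen.dose_response.metrics_table` (z-score columns included).
    For the rank criteria (4 and 5) "top" means the most sensitive half:
    lowest combination GI50 / AUC z-scores within each line.
    """
    config = config or CriterionConfig()
    required = {"drug_id", "cell_line", "fold_change_gi50", "auc_diff",
                "auc_pct_change", "min_viability", "z_gi50_combo", "z_auc_combo"}
    missing = required - set(metrics.columns)
    if missing:
        raise SchemaError(f"metrics table missing columns: {sorted(missing)}")
    if metrics["cell_line"].nunique() < 2:
        raise SchemaError("criterion_votes requires metrics for >= 2 cell lines")

    df = metrics.copy()
    # Within-line percentile rank (ascending, average ties): a drug is in the
    # "top" fraction f of a lower-is-better score when rank/n <= f.
    for src, col in [("z_gi50_combo", "_pct_gi50"), ("z_auc_combo", "_pct_auc")]:
        df[col] = df.groupby("cell_line")[src].rank(method="average", pct=True)

    per_drug = df.groupby("drug_id", sort=True)
    votes = pd.DataFrame(index=per_drug.size().index)
    votes.index.name = "drug_id"
    c = config
    votes[CRITERIA[0]] = per_drug.apply(
        lambda g: _frac_lines(g["fold_change_gi50"] >= c.gi50_fold_min) >= c.frac_lines_gi50,
        include_groups=False)
    votes[CRITERIA[1]] = per_drug.apply(
        lambda g: _frac_lines(g["auc_diff"] > c.auc_diff_min) >= c.frac_lines_aucdiff,
        include_groups=False)
    votes[CRITERIA[2]] = per_drug.apply(
        lambda g: _frac_lines(g["auc_pct_change"] > c.auc_pct_min) >= c.frac_lines_aucpct,
        include_groups=False)
    mean_ymin = per_drug["min_viability"].mean()
    viab_ok = mean_ymin <= c.min_viability_max
    votes[CRITERIA[3]] = per_drug.apply(
        lambda g: _frac_lines(g["_pct_gi50"] <= c.top_frac_rank) >= c.frac_lines_rank,
        include_groups=False) & viab_ok
    votes[CRITERIA[4]] = per_drug.apply(
        lambda g: _frac_lines(g["_pct_auc"] <= c.top_frac_rank) >= c.frac_lines_rank,
        include_groups=False) & viab_ok
    votes["n_votes"] = votes[CRITERIA].sum(axis=1)
    votes["mean_z_auc_combo"] = per_drug["z_auc_combo"].mean()
    return votes


def nominate(votes: pd.DataFrame, config: CriterionConfig | None = None) -> pd.DataFrame:
    """Drugs with at least ``min_criteria`` votes, ranked.

    Order: vote count descending, then mean combination-AUC z-score ascending
    (most sensitive first), then drug id for determinism.
    """
    config = config or CriterionConfig()
    hits = votes[votes["n_votes"] >= config.min_criteria].reset_index()
    hits["drug_id"] = hits["drug_id"].astype(str)
    hits = hits.sort_values(
        by=["n_votes", "mean_z_auc_combo", "drug_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).set_index("drug_id")
    return hits


def rank_classification(
    metrics: pd.DataFrame,
    top50_frac: float = 0.5,
    top25_frac: float = 0.25,
    min_lines_frac_top50: float = 0.5,
    min_lines_frac_top25: float = 0.125,
) -> pd.DataFrame:
    """Heatmap-style pass labels per drug and measurement.

    For each of the three measurements (GI50 fold change, AUC difference, AUC
    percent change; larger = better), two booleans per drug: whether the drug
    is in the top ``top50_frac`` of all drugs in strictly more than
    ``min_lines_frac_top50`` of the cell lines, and likewise for the top
    ``top25_frac`` / ``min_lines_frac_top25`` rule.  Percentile ranks are
    within cell line with average-rank tie handling.
    """
    if metrics["cell_line"].nunique() < 2:
        raise SchemaError("rank_classification requires >= 2 cell lines")
    measures = ["fold_change_gi50", "auc_diff", "auc_pct_change"]
    df = metrics.copy()
    n_lines = df["cell_line"].nunique()
    out = {}
    for m in measures:
        # descending: larger metric = better, so rank on the negated value
        pct = df.groupby("cell_line")[m].rank(method="average", pct=True, ascending=False)
        for frac, min_frac, tag in [
            (top50_frac, min_lines_frac_top50, "top50"),
            (top25_frac, min_lines_frac_top25, "top25"),
        ]:
            in_top = pct <= frac
            count = in_top.groupby(df["drug_id"]).sum()
            out[f"{m}_{tag}"] = count > min_frac * n_lines
    labels = pd.DataFrame(out)
    labels.index.name = "drug_id"
    return labels.sort_index()
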