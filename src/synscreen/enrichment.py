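"""Shared Kolmogorov-Smirnov enrichment engine.

One running-sum statistic powers three analyses:

* **KSEA** -- kinase activity inferred from the rank distribution of a
  kinase's substrates in a fold-change-ordered phosphopeptide list;
* **master-regulator (regulon) enrichment** -- transcription-factor activity
  from the positions of its positive/negative targets in an
  interaction-coefficient-ranked gene list (negative-mode targets are
  scored on the mirrored ranking, so a repressed regulon of an active
  regulator still counts toward the same direction);
* **preranked gene-set enrichment** -- the same statistic without modes.

The statistic is the classic unweighted KS running sum: walking down the
ranked list, +1/hits at members and -1/(N-hits) at non-members; the
enrichment score (ES) is the signed maximum deviation.  Significance comes
from a permutation null of random same-size member sets on the fixed
ranking; the normalized score NKS divides the ES by the mean absolute null
ES, and p-values are two-sided permutation tails with BH correction across
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .interaction import bh_adjust

__all__ = [
    "RankedList", "AnnotationSet", "ks_enrichment_score", "permutation_null",
    "ksea", "regulon_enrichment", "gsea_preranked",
]


@dataclass(frozen=True)
class RankedList:
    """Items ordered by non-increasing signed score."""

    ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "scores", scores)
        if len(self.ids) != len(scores):
            raise SchemaError("ids and scores must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise SchemaError("ranked list contains duplicate identifiers")
        if not np.all(np.isfinite(scores)):
            raise SchemaError("ranked scores must be finite")
        if np.any(np.diff(scores) > 1e-12):
            raise SchemaError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {item: i for i, item in enumerate(self.ids)}

    @classmethod
    def from_scores(cls, scores) -> "RankedList":
        """Build from an id -> score mapping; descending score, ties broken
        by identifier for determinism."""
        s = pd.Series(scores, dtype=float)
        s.index = s.index.astype(str)
        s = s.sort_index(kind="mergesort")
        s = s.sort_values(ascending=False, kind="mergesort")
        return cls(tuple(s.index), s.to_numpy())

    def reversed(self) -> "RankedList":
        return RankedList(tuple(reversed(self.ids)), -self.scores[::-1])


@dataclass(frozen=True)
class AnnotationSet:
    """Named member set; optional per-member mode +1/-1 (regulon sign)."""

    name: str
    members: tuple[str, ...]
    modes: dict | None = None

    def __post_init__(self) -> None:
        members = tuple(str(m) for m in self.members)
        object.__setattr__(self, "members", members)
        if len(set(members)) != len(members):
            raise SchemaError(f"set {self.name!r} has duplicate members")
        if self.modes is not None:
            bad = {m: v for m, v in self.modes.items() if v not in (1, -1)}
            if bad:
                raise SchemaError(f"set {self.name!r} has modes outside +/-1: {bad}")

    def mode_of(self, member: str) -> int:
        return 1 if self.modes is None else int(self.modes.get(member, 1))


def _es_running_sum(positions: np.ndarray, n: int) -> float:
    """Signed max deviation of the KS running sum for hit ``positions``.

    ``positions`` may contain collisions (mode-reflected hits can land on an
    occupied rank); increments accumulate, and the miss penalty applies to
    unoccupied ranks only.
    """
    hits = len(positions)
    if hits == 0 or hits >= n:
        return np.nan
    delta = np.full(n, -1.0 / (n - hits))
    occupied = np.unique(positions)
    delta[occupied] = 0.0
    np.add.at(delta, positions, 1.0 / hits)
    running = np.cumsum(delta)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_sorted_distinct(positions: np.ndarray, n: int) -> float:
    """O(hits) extremum for sorted, distinct hit positions (permutation path).

    The running sum attains its extrema immediately after a hit or just
    before one; both candidate sets are evaluated in closed form.
    """
    k = len(positions)
    j = np.arange(1, k + 1)
    miss = 1.0 / (n - k)
    after = j / k - (positions + 1 - j) * miss
    before = (j - 1) / k - (positions - (j - 1)) * miss
    cand = np.concatenate([after, before, [-(n - positions[-1] - 1) * miss + 0.0]])
    # tail candidate: running sum returns toward 0 after the last hit; the
    # global minimum may sit at the end of a pure-miss suffix
    tail_min = after[-1] - (n - positions[-1] - 1) * miss
    cand[-1] = tail_min
    i = int(np.argmax(np.abs(cand)))
    return float(cand[i])


def ks_enrichment_score(ranked: RankedList, aset: AnnotationSet) -> float:
    """Unweighted KS enrichment score of ``aset`` in ``ranked``.

    Members with mode -1 contribute at their mirrored rank (N-1-i).  Returns
    NaN when the set has no overlap with the list, or no non-members exist.
    """
    n = len(ranked)
    index = ranked.index
    positions = []
    for m in aset.members:
        i = index.get(m)
        if i is None:
            continue
        positions.append(n - 1 - i if aset.mode_of(m) == -1 else i)
    if not positions:
        return np.nan
    return _es_running_sum(np.asarray(positions), n)


def overlap_count(ranked: RankedList, aset: AnnotationSet) -> int:
    index = ranked.index
    return sum(1 for m in aset.members if m in index)


def permutation_null(
    ranked: RankedList, set_size: int, B: int = 1000, seed: int = 0
) -> np.ndarray:
    """B enrichment scores of random ``set_size``-member sets on the fixed
    ranking.  Reproducible under ``seed``."""
    n = len(ranked)
    if set_size >= n:
        raise ConfigError(f"set_size must be < list length {n}, got {set_size}")
    if set_size < 1:
        raise ConfigError("set_size must be >= 1")
    if B < 100:
        raise ConfigError(f"permutation_null requires B >= 100, got {B}")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    for b in range(B):
        pos = np.sort(rng.choice(n, size=set_size, replace=False))
        out[b] = _es_sorted_distinct(pos, n)
    return out


def _enrich_table(
    ranked: RankedList,
    sets: dict[str, AnnotationSet],
    min_hits: int,
    B: int,
    seed: int,
) -> pd.DataFrame:
    """Shared engine: ES, NKS, two-sided permutation p and BH q per set.

    The null is cached per overlap size; each size draws from an independent
    seeded stream so results do not depend on set iteration order.
    """
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name in sorted(sets):
        aset = sets[name]
        hits = overlap_count(ranked, aset)
        es = ks_enrichment_score(ranked, aset)
        if hits < min_hits or not np.isfinite(es):
            rows.append({"set": name, "es": np.nan, "nks": np.nan,
                         "p_value": np.nan, "hits": hits})
            continue
        if hits not in null_cache:
            null_cache[hits] = permutation_null(
                ranked, hits, B=B, seed=int(np.random.default_rng([seed, hits]).integers(2**31)))
        null = null_cache[hits]
        nks = es / float(np.mean(np.abs(null))) if es != 0 else 0.0
        p = (1.0 + float(np.sum(np.abs(null) >= abs(es)))) / (B + 1.0)
        rows.append({"set": name, "es": es, "nks": nks, "p_value": p, "hits": hits})
    out = pd.DataFrame(rows).set_index("set")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def _as_sets(sets, with_modes: bool) -> dict[str, AnnotationSet]:
    out = {}
    for name, val in sets.items():
        if isinstance(val, AnnotationSet):
            out[name] = val if with_modes else AnnotationSet(val.name, val.members)
        else:
            out[name] = AnnotationSet(name, tuple(val))
    return out


def ksea(
    fold_changes: pd.Series,
    kinase_sets: dict,
    min_hits: int = 3,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Kinase-substrate enrichment analysis.

    Peptides are ranked by fold change (descending); each kinase with at
    least ``min_hits`` identified substrates gets an ES, an NKS (ES over the
    mean absolute null ES), a two-sided permutation p-value and a BH q-value.
    The conventional minimum overlap is 3 for phosphotyrosine data and 30
    for serine/threonine data.
    """
    ranked = RankedList.from_scores(fold_changes)
    table = _enrich_table(ranked, _as_sets(kinase_sets, with_modes=False),
                          min_hits, B, seed)
    if table["p_value"].isna().all():
        warnings.warn("no kinase set passed the min_hits filter")
    return table


def regulon_enrichment(
    ranked_scores: pd.Series,
    regulons: dict[str, AnnotationSet],
    B: int = 1000,
    seed: int = 0,
    alpha_q: float = 0.1,
    min_hits: int = 1,
) -> pd.DataFrame:
    """Signed regulon enrichment in an interaction-ranked gene list.

    Mode-aware: -1 (repressed) targets score on the mirrored ranking, so
    direction reflects regulator activity rather than raw target position.
    Adds ``direction`` (sign of ES) and ``significant`` (q < ``alpha_q``).
    """
    ranked = RankedList.from_scores(ranked_scores)
    table = _enrich_table(ranked, _as_sets(regulons, with_modes=True),
                          min_hits, B, seed)
    table["direction"] = np.sign(table["es"]).fillna(0).astype(int)
    table["significant"] = table["q_value"] < alpha_q
    return table


def gsea_preranked(
    ranked_scores: pd.Series,
    gene_sets: dict,
    B: int = 1000,
    seed: int = 0,
    alpha_q: float = 0.1,
    min_hits: int = 1,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with the shared KS engine (no modes)."""
    ranked = RankedList.from_scores(ranked_scores)
    table = _enrich_table(ranked, _as_sets(gene_sets, with_modes=False),
                          min_hits, B, seed)
    table["significant"] = table["q_value"] < alpha_q
    return table
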