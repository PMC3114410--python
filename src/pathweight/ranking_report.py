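"""Pathway screening, competition ranking, top-k selection and reports.

A *screen* scores every pathway in a collection under one (scheme,
method) combination — scheme in {uniform, absT, Qdiff, RWV, RWM}, method
in {global_test, random_forest} — and ranks pathways by ascending score
(p-value or OOB error; smaller is better).  Ranks are competition
("1224") ranks: tied pathways share the smallest applicable rank and the
next rank skips.  Top-k selection optionally expands through tie blocks,
the rule behind reporting 33 pathways when the 20th rank sits inside a
tie.

Per-pathway randomness is derived from the screen seed and the pathway's
position, and the permutation stream (or forest seed) is shared across
schemes at a fixed screen seed, so scheme comparisons are paired: an RWM
or RWV screen can never score worse than the uniform screen on any
pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_data import EmptyPathwayError, ExpressionDataset, PathwayCollection, \
    extract_pathway_matrix
from .rf_pathway import check_scheme_method, oob_objective
from .weighting import DEFAULT_COUNT, abs_t_weights, apply_weights, \
    global_test_objective, qdiff_weights, rwm_search, rwv_search

logger = logging.getLogger("pathweight")

__all__ = [
    "ScreenResult",
    "SCHEMES",
    "METHODS",
    "run_screen",
    "rank_with_ties",
    "select_top_k",
    "count_significant",
    "rank_changes",
    "find_overlaps",
    "iteration_sweep",
    "write_screen_tsv",
    "read_screen_tsv",
]

SCHEMES = ("uniform", "absT", "Qdiff", "RWV", "RWM")
METHODS = ("global_test", "random_forest")


@dataclass
class ScreenResult:
    method: str
    scheme: str
    rows: pd.DataFrame = field(repr=False)  # pathway_id, m_genes, score, rank
    score_kind: str = "p_value"             # "p_value" | "oob_error"
    params: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def rank_with_ties(scores) -> np.ndarray:
    """Competition ranks of ascending scores: rank = 1 + #{strictly smaller}."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return rankdata(scores, method="min").astype(int)


def _pathway_seeds(base_seed, index: int):
    """Two independent seed sequences per pathway: objective stream, search
    stream.  The objective stream depends only on (seed, pathway), not on
    the scheme, so scheme comparisons share permutations/forests."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return ss.spawn(2)


def _normalize_seed(seed) -> int:
    if seed is None:
        return int(np.random.default_rng().integers(2**31))
    return int(seed)


def run_screen(dataset: ExpressionDataset, pathways: PathwayCollection,
               scheme: str = "uniform", method: str = "global_test",
               n_perm: int = 10_000, count: int = DEFAULT_COUNT,
               range_lo: float = 0.1, range_hi: float = 1.0,
               n_trees: int = 1_000, seed=None) -> ScreenResult:
    """Score and rank every pathway under one scheme x method combination.

    Pathways with no gene in the dataset are skipped with a warning and
    listed in ``ScreenResult.skipped``; they are not ranked.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    check_scheme_method(scheme, method)
    base_seed = _normalize_seed(seed)
    records = []
    skipped = []
    for i, entry in enumerate(pathways):
        try:
            pm = extract_pathway_matrix(dataset, entry)
        except EmptyPathwayError:
            logger.warning("skipping pathway %s: empty intersection",
                           entry.pathway_id)
            skipped.append(entry.pathway_id)
            continue
        obj_ss, search_ss = _pathway_seeds(base_seed, i)
        X, Y = pm.values, pm.labels
        if method == "global_test":
            objective = global_test_objective(Y, n_perm, obj_ss)
            if scheme == "uniform":
                score = objective(X)[0]
            elif scheme == "absT":
                score = objective(apply_weights(X, abs_t_weights(X, Y)))[0]
            elif scheme == "Qdiff":
                score = objective(apply_weights(X, qdiff_weights(X, Y)))[0]
            elif scheme == "RWV":
                score = rwv_search(X, Y, count=count, range_lo=range_lo,
                                   range_hi=range_hi, objective=objective,
                                   seed=search_ss).best_objective
            else:  # RWM
                score = rwm_search(X, Y, count=count, range_lo=range_lo,
                                   range_hi=range_hi, objective=objective,
                                   seed=search_ss).best_objective
        else:  # random_forest: uniform or RWM only
            objective = oob_objective(Y, n_trees, obj_ss)
            if scheme == "uniform":
                score = objective(X)
            else:  # RWM
                score = rwm_search(X, Y, count=count, range_lo=range_lo,
                                   range_hi=range_hi, objective=objective,
                                   seed=search_ss).best_objective
        records.append({"pathway_id": entry.pathway_id,
                        "m_genes": X.shape[1], "score": float(score),
                        "order": i})
    if not records:
        raise ValueError("no pathway could be screened")
    df = pd.DataFrame(records)
    df["rank"] = rank_with_ties(df["score"].to_numpy())
    df = df.sort_values(["rank", "order"], kind="stable").reset_index(drop=True)
    df = df[["pathway_id", "m_genes", "score", "rank"]]
    params = {"n_perm": n_perm, "count": count, "range_lo": range_lo,
              "range_hi": range_hi, "n_trees": n_trees, "seed": base_seed}
    return ScreenResult(
        method=method, scheme=scheme, rows=df,
        score_kind="p_value" if method == "global_test" else "oob_error",
        params=params, skipped=skipped)


def select_top_k(result: ScreenResult, k: int, include_ties: bool = True
                 ) -> pd.DataFrame:
    """Top-k rows by (rank, pathway file order).

    With ``include_ties`` the selection expands to every row whose rank
    equals the k-th row's rank, so a tie block is never split (the rule
    that turns a nominal top 20 into a reported top 33).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = result.rows
    if k >= len(rows):
        if k > len(rows):
            logger.warning("k=%d exceeds %d screened pathways; returning all",
                           k, len(rows))
        return rows.copy()
    if not include_ties:
        return rows.iloc[:k].copy()
    cutoff_rank = int(rows["rank"].iloc[k - 1])
    return rows[rows["rank"] <= cutoff_rank].copy()


def count_significant(result: ScreenResult, alpha: float = 0.05) -> int:
    """Number of pathways with p-value strictly below alpha."""
    if result.score_kind != "p_value":
        raise ValueError("significance counts require p-value screens")
    return int((result.rows["score"] < alpha).sum())


def rank_changes(result_a: ScreenResult, result_b: ScreenResult,
                 threshold: int = 1) -> pd.DataFrame:
    """Pathways whose rank improves by >= threshold from screen a to b.

    Improvement is rank_a - rank_b (positive when b ranks the pathway
    higher, i.e. closer to 1).  Rows are sorted by decreasing improvement.
    """
    ids_a = set(result_a.rows["pathway_id"])
    ids_b = set(result_b.rows["pathway_id"])
    if ids_a != ids_b:
        raise ValueError("screens cover different pathway universes")
    merged = result_a.rows.merge(result_b.rows, on="pathway_id",
                                 suffixes=("_a", "_b"))
    merged["improvement"] = merged["rank_a"] - merged["rank_b"]
    out = merged[merged["improvement"] >= threshold].sort_values(
        "improvement", ascending=False, kind="stable")
    return out[["pathway_id", "rank_a", "rank_b", "score_a", "score_b",
                "improvement"]].reset_index(drop=True)


def find_overlaps(top_k_sets, min_schemes: int = 3) -> list[str]:
    """Pathway ids present in at least ``min_schemes`` of the given sets."""
    sets = [set(s) for s in top_k_sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 top-k sets")
    counts: dict[str, int] = {}
    for s in sets:
        for pid in s:
            counts[pid] = counts.get(pid, 0) + 1
    return sorted(pid for pid, c in counts.items() if c >= min_schemes)


def iteration_sweep(dataset: ExpressionDataset, pathways: PathwayCollection,
                    counts, scheme: str = "RWM", n_perm: int = 2_000,
                    range_lo: float = 0.1, range_hi: float = 1.0,
                    seed=None) -> pd.DataFrame:
    """Mean best p-value across pathways as the iteration budget grows.

    One candidate stream per pathway is grown to max(counts) and the best
    objective is read off at each requested count (prefix evaluation), so
    the curve is non-increasing by construction and cheap to compute.
    Returns a DataFrame with columns (count, mean_best_objective).
    """
    counts = [int(c) for c in counts]
    if counts != sorted(counts):
        raise ValueError("counts must be ascending")
    if scheme not in ("RWV", "RWM"):
        raise ValueError("iteration sweep applies to the search schemes only")
    base_seed = _normalize_seed(seed)
    max_count = counts[-1] if counts else 0
    search = rwv_search if scheme == "RWV" else rwm_search
    traces = []
    for i, entry in enumerate(pathways):
        try:
            pm = extract_pathway_matrix(dataset, entry)
        except EmptyPathwayError:
            continue
        obj_ss, search_ss = _pathway_seeds(base_seed, i)
        objective = global_test_objective(pm.labels, n_perm, obj_ss)
        res = search(pm.values, pm.labels, count=max_count,
                     range_lo=range_lo, range_hi=range_hi,
                     objective=objective, seed=search_ss, record_trace=True)
        traces.append(res.trace)
    if not traces:
        raise ValueError("no pathway could be screened")
    mat = np.vstack(traces)  # (n_pathways, max_count + 1)
    return pd.DataFrame({"count": counts,
                         "mean_best_objective": [mat[:, c].mean()
                                                 for c in counts]})


def read_screen_tsv(path) -> ScreenResult:
    """Read back a screen report written by :func:`write_screen_tsv`."""
    meta: dict[str, str] = {}
    skipped: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].strip().split("\t"):
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k == "skipped":
                        skipped = v.split(",")
                    else:
                        meta[k] = v
    rows = pd.read_csv(path, sep="\t", comment="#")
    params = {}
    for k in ("n_perm", "count", "n_trees", "seed"):
        if k in meta:
            params[k] = int(meta[k])
    for k in ("range_lo", "range_hi"):
        if k in meta:
            params[k] = float(meta[k])
    return ScreenResult(method=meta.get("method", "global_test"),
                        scheme=meta.get("scheme", "uniform"), rows=rows,
                        score_kind=meta.get("score_kind", "p_value"),
                        params=params, skipped=skipped)


def write_screen_tsv(result: ScreenResult, path) -> None:
    """Write a screen report with a '#'-prefixed parameter echo header."""
    with open(path, "w") as fh:
        fh.write(f"# method={result.method}\tscheme={result.scheme}\t"
                 f"score_kind={result.score_kind}\n")
        fh.write("# " + "\t".join(f"{k}={v}" for k, v in result.params.items())
                 + "\n")
        if result.skipped:
            fh.write("# skipped=" + ",".join(result.skipped) + "\n")
        result.rows.to_csv(fh, sep="\t", index=False, float_format="%.6g")
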